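"""Readers and writers for the map JSON dialect, registry indexes and
tabular outputs.

The on-disk map format is a UTF-8 JSON document with top-level keys
``map_id``, ``name``, ``mesh_id``, ``diagrams``, ``elements`` and
``reactions`` — a flat serialization of the content a MINERVA-style REST
API exposes per project, so that the comparison math is decoupled from any
live service.  Unknown keys are ignored on read.  See ``docs/methods.md``
for the full schema.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from pydantic import ValidationError

from .model import DiseaseMap, RegistryEntry

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

SIMILARITY_COLUMNS = [
    "map_a",
    "reaction_a",
    "map_b",
    "reaction_b",
    "similarity",
    "overlap_a",
    "overlap_b",
]


class MapFormatError(ValueError):
    """Raised when a map or registry file is malformed or inconsistent."""


def _load_json(path: PathLike):
    text = Path(path).read_text(encoding="utf-8")
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise MapFormatError(
            f"{path}: malformed JSON at byte offset {exc.pos} "
            f"(line {exc.lineno}, column {exc.colno}): {exc.msg}"
        ) from exc


def read_map(path: PathLike) -> DiseaseMap:
    """Read one disease map from the JSON dialect.

    Raises :class:`MapFormatError` naming the byte offset on a JSON parse
    failure, and a validation error naming the offending reaction/element
    on dangling cross-references or unknown role strings.
    """
    payload = _load_json(path)
    if not isinstance(payload, dict):
        raise MapFormatError(f"{path}: top-level JSON value must be an object")
    try:
        return DiseaseMap.model_validate(payload)
    except ValidationError as exc:
        raise MapFormatError(f"{path}: invalid map: {exc}") from exc


def write_map(disease_map: DiseaseMap, path: PathLike) -> None:
    """Write a map so that :func:`read_map` reproduces it field-for-field,
    including duplicate accession multiplicities."""
    payload = disease_map.model_dump(mode="json")
    Path(path).write_text(
        json.dumps(payload, indent=1, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def read_registry(path: PathLike) -> list[RegistryEntry]:
    """Read a registry index (JSON list of entry objects), in file order."""
    payload = _load_json(path)
    if not isinstance(payload, list):
        raise MapFormatError(f"{path}: registry index must be a JSON list")
    entries = []
    for i, item in enumerate(payload):
        try:
            entries.append(RegistryEntry.model_validate(item))
        except ValidationError as exc:
            raise MapFormatError(f"{path}: invalid registry entry #{i}: {exc}") from exc
    return entries


def write_registry(entries: Sequence[RegistryEntry], path: PathLike) -> None:
    payload = [e.model_dump(mode="json") for e in entries]
    Path(path).write_text(
        json.dumps(payload, indent=1, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def filter_registry(
    entries: Sequence[RegistryEntry], mesh_ids: Sequence[str]
) -> list[RegistryEntry]:
    """For each requested MeSH id, the entry with the latest ``shared_at``.

    Ties on ``shared_at`` are broken by file order (first wins, logged).
    MeSH ids with no entry are skipped with a warning; output follows the
    order of *mesh_ids*.
    """
    if not mesh_ids:
        raise ValueError("mesh_ids must be non-empty")
    best: dict[str, RegistryEntry] = {}
    for entry in entries:
        cur = best.get(entry.mesh_id)
        if cur is None:
            best[entry.mesh_id] = entry
        elif entry.shared_at > cur.shared_at:
            best[entry.mesh_id] = entry
        elif entry.shared_at == cur.shared_at:
            logger.info(
                "tie on shared_at for MeSH %s: keeping first-seen project %s",
                entry.mesh_id,
                cur.project_id,
            )
    out = []
    seen = set()
    for mesh_id in mesh_ids:
        if mesh_id in seen:
            continue
        seen.add(mesh_id)
        if mesh_id in best:
            out.append(best[mesh_id])
        else:
            logger.warning("no registry entry for MeSH id %s", mesh_id)
    return out


# -- tabular outputs --------------------------------------------------------


def write_similarity_table(records: Iterable, path: PathLike) -> None:
    """Write similarity records as TSV ("." decimal separator), similarity
    printed with 4 decimal places."""
    rows = [
        {
            "map_a": r.map_a,
            "reaction_a": r.reaction_a,
            "map_b": r.map_b,
            "reaction_b": r.reaction_b,
            "similarity": f"{r.similarity:.4f}",
            "overlap_a": r.overlap_a,
            "overlap_b": r.overlap_b,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=SIMILARITY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_similarity_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={
            "map_a": str,
            "reaction_a": str,
            "map_b": str,
            "reaction_b": str,
            "similarity": float,
            "overlap_a": int,
            "overlap_b": int,
        },
    )


def write_sif(graph, path: PathLike) -> None:
    """Export a bipartite element–reaction graph as a SIF-style edge list:
    ``source<TAB>edge-type<TAB>target``.

    Edge type encodes the role rule: ``input`` for element→reaction edges
    (reactants/modifiers) and ``output`` for reaction→element edges
    (products).
    """
    lines = []
    for u, v in sorted(graph.edges()):
        kind = "input" if graph.nodes[u]["kind"] == "element" else "output"
        lines.append(f"{u}\t{kind}\t{v}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_node_attributes(graph, path: PathLike) -> None:
    """Node-attribute TSV for a bipartite graph: node id, kind and (for
    components output) component id when annotated."""
    rows = []
    for node, data in sorted(graph.nodes(data=True)):
        rows.append(
            {
                "node_id": node,
                "kind": data.get("kind", ""),
                "component_id": data.get("component_id", ""),
            }
        )
    pd.DataFrame(rows, columns=["node_id", "kind", "component_id"]).to_csv(
        path, sep="\t", index=False
    )
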