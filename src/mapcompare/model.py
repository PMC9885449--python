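"""Data model for disease maps and registry entries.

A *disease map* is a curated collection of systems-biology diagrams for one
disease.  For comparison purposes a map reduces to its elements (species,
each optionally annotated with one or more UniProt accessions) and its
reactions (interactions whose participants carry a role: reactant, product
or modifier).  Registry entries mirror the minimal public metadata a map
project publishes to a shared registry (name, identifier, version,
timestamps, MeSH disease descriptor, NCBI taxonomy id, host URL).

All types are pydantic models; cross-references (participant element ids,
diagram ids) are validated at construction time so that downstream
comparison code can assume a consistent map.
"""

from __future__ import annotations

import re
from datetime import datetime
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: UniProt accession grammar: 6 or 10 alphanumeric characters starting with
#: a letter, with an optional "-<digits>" isoform suffix (e.g. "P04637-2").
#: Comparison everywhere in this package is exact, case-sensitive string
#: equality; isoform suffixes are kept verbatim unless explicitly stripped.
UNIPROT_RE = re.compile(r"^[A-Z][A-Z0-9]{5}(?:[A-Z0-9]{4})?(?:-\d+)?$")


def is_valid_accession(accession: str) -> bool:
    """True if *accession* matches the UniProt accession grammar."""
    return bool(UNIPROT_RE.match(accession))


def strip_isoform(accession: str) -> str:
    """Drop an isoform suffix: ``"P04637-2" -> "P04637"``."""
    return accession.split("-", 1)[0]


class Role(str, Enum):
    """Role of a participant in a reaction."""

    REACTANT = "reactant"
    PRODUCT = "product"
    MODIFIER = "modifier"


class Diagram(BaseModel):
    model_config = ConfigDict(frozen=True)

    diagram_id: str
    diagram_name: str = ""


class MapElement(BaseModel):
    """One drawable species in a diagram.

    ``uniprot_ids`` may be empty (unannotated element), may hold several
    distinct accessions (heteromeric complex) and may hold repeats of the
    same accession (homodimer complex) — repeats are meaningful and
    preserved.
    """

    model_config = ConfigDict(frozen=True)

    element_id: str
    diagram_id: str
    display_name: str = ""
    uniprot_ids: tuple[str, ...] = ()

    @field_validator("uniprot_ids")
    @classmethod
    def _check_accessions(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        for acc in v:
            if not is_valid_accession(acc):
                raise ValueError(f"invalid UniProt accession: {acc!r}")
        return v


class Participant(BaseModel):
    model_config = ConfigDict(frozen=True)

    element_id: str
    role: Role


class Reaction(BaseModel):
    """An interaction with role-tagged participants."""

    model_config = ConfigDict(frozen=True)

    reaction_id: str
    diagram_id: str
    participants: tuple[Participant, ...]

    @field_validator("participants")
    @classmethod
    def _non_empty(cls, v: tuple[Participant, ...]) -> tuple[Participant, ...]:
        if not v:
            raise ValueError("participants list must be non-empty")
        return v


class DiseaseMap(BaseModel):
    """A named, cross-reference-validated collection of diagrams, elements
    and reactions."""

    model_config = ConfigDict(frozen=True)

    map_id: str
    name: str = ""
    mesh_id: str = ""
    diagrams: tuple[Diagram, ...] = ()
    elements: tuple[MapElement, ...] = ()
    reactions: tuple[Reaction, ...] = ()

    @model_validator(mode="after")
    def _cross_check(self) -> "DiseaseMap":
        element_ids = set()
        for el in self.elements:
            if el.element_id in element_ids:
                raise ValueError(
                    f"duplicate element_id {el.element_id!r} in map {self.map_id!r}"
                )
            element_ids.add(el.element_id)
        diagram_ids = {d.diagram_id for d in self.diagrams}
        for el in self.elements:
            if el.diagram_id not in diagram_ids:
                raise ValueError(
                    f"element {el.element_id!r} references unknown diagram "
                    f"{el.diagram_id!r}"
                )
        for rx in self.reactions:
            if rx.diagram_id not in diagram_ids:
                raise ValueError(
                    f"reaction {rx.reaction_id!r} references unknown diagram "
                    f"{rx.diagram_id!r}"
                )
            for p in rx.participants:
                if p.element_id not in element_ids:
                    raise ValueError(
                        f"reaction {rx.reaction_id!r} references missing element "
                        f"{p.element_id!r}"
                    )
        return self

    # -- convenience lookups ------------------------------------------------

    def element(self, element_id: str) -> MapElement:
        try:
            return self._element_index[element_id]
        except KeyError:
            raise KeyError(
                f"no element {element_id!r} in map {self.map_id!r}"
            ) from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self._reaction_index[reaction_id]
        except KeyError:
            raise KeyError(
                f"no reaction {reaction_id!r} in map {self.map_id!r}"
            ) from None

    @property
    def _element_index(self) -> dict[str, MapElement]:
        idx = self.__dict__.get("_el_idx")
        if idx is None:
            idx = {el.element_id: el for el in self.elements}
            object.__setattr__(self, "_el_idx", idx)
        return idx

    @property
    def _reaction_index(self) -> dict[str, Reaction]:
        idx = self.__dict__.get("_rx_idx")
        if idx is None:
            idx = {rx.reaction_id: rx for rx in self.reactions}
            object.__setattr__(self, "_rx_idx", idx)
        return idx


class RegistryEntry(BaseModel):
    """Minimal public metadata about a shared map project."""

    model_config = ConfigDict(frozen=True)

    project_name: str
    project_id: str
    version: str
    created_at: datetime
    shared_at: datetime
    mesh_id: str
    taxonomy_id: str
    instance_url: str

    @model_validator(mode="after")
    def _timestamps_ordered(self) -> "RegistryEntry":
        if self.shared_at < self.created_at:
            raise ValueError(
                f"shared_at ({self.shared_at.isoformat()}) precedes created_at "
                f"({self.created_at.isoformat()}) for project {self.project_id!r}"
            )
        return self


class MapSummary(BaseModel):
    """Per-map headline counts: diagrams, elements, interactions and the
    size of the deduplicated union of all UniProt annotations."""

    model_config = ConfigDict(frozen=True)

    map_id: str
    n_diagrams: int
    n_elements: int
    n_interactions: int
    n_unique_uniprot: int


def summarize_map(disease_map: DiseaseMap) -> MapSummary:
    """Headline counts for one map.

    ``n_unique_uniprot`` deduplicates across all elements, so a homodimer
    annotated ``[P1, P1]`` contributes one accession.
    """
    unique: set[str] = set()
    for el in disease_map.elements:
        unique.update(el.uniprot_ids)
    return MapSummary(
        map_id=disease_map.map_id,
        n_diagrams=len(disease_map.diagrams),
        n_elements=len(disease_map.elements),
        n_interactions=len(disease_map.reactions),
        n_unique_uniprot=len(unique),
    )
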