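"""Set-level comparison of disease maps by unique UniProt content.

Two maps are compared on the deduplicated sets of UniProt accessions
annotating their elements: shared counts, the Jaccard index
|A∩B| / |A∪B|, proteins common to at least k maps, and a ranking of
proteins by the number of diagrams (across all maps) they appear in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from itertools import combinations
from typing import Sequence

from .model import DiseaseMap, strip_isoform


def round_half_even(value: float, ndigits: int = 3) -> float:
    """Round half-to-even at presentation time (internal values keep full
    precision)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ProteinSet:
    """Deduplicated UniProt accessions of one map."""

    map_id: str
    accessions: frozenset[str]

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass(frozen=True)
class PairwiseProteinResult:
    map_a: str
    map_b: str
    n_a: int
    n_b: int
    n_shared: int
    jaccard: float

    def swapped(self) -> "PairwiseProteinResult":
        return PairwiseProteinResult(
            self.map_b, self.map_a, self.n_b, self.n_a, self.n_shared, self.jaccard
        )


@dataclass
class FrequencyRow:
    """One protein with the diagrams containing it, per map."""

    accession: str
    diagrams_by_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_diagrams_total(self) -> int:
        return sum(len(v) for v in self.diagrams_by_map.values())


def extract_protein_set(
    disease_map: DiseaseMap, normalize_isoforms: bool = False
) -> ProteinSet:
    """Union of all elements' accessions, deduplicated.

    Elements without identifiers contribute nothing.  With
    ``normalize_isoforms`` the isoform suffix is stripped before
    deduplication ("P04637-2" counts as "P04637").
    """
    accs: set[str] = set()
    for el in disease_map.elements:
        for acc in el.uniprot_ids:
            accs.add(strip_isoform(acc) if normalize_isoforms else acc)
    return ProteinSet(map_id=disease_map.map_id, accessions=frozenset(accs))


def jaccard(a: ProteinSet, b: ProteinSet) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty (convention)."""
    union = a.accessions | b.accessions
    if not union:
        return 0.0
    return len(a.accessions & b.accessions) / len(union)


def jaccard_from_counts(n_a: int, n_b: int, n_shared: int) -> float:
    """Jaccard index from printed set sizes and a shared count."""
    union = n_a + n_b - n_shared
    if union <= 0:
        return 0.0
    return n_shared / union


def pairwise_compare(maps: Sequence[DiseaseMap]) -> list[PairwiseProteinResult]:
    """One result per unordered map pair, in input order of the pair."""
    if len(maps) < 2:
        raise ValueError("need at least two maps to compare")
    sets = [extract_protein_set(m) for m in maps]
    out = []
    for pa, pb in combinations(sets, 2):
        shared = len(pa.accessions & pb.accessions)
        out.append(
            PairwiseProteinResult(
                map_a=pa.map_id,
                map_b=pb.map_id,
                n_a=len(pa),
                n_b=len(pb),
                n_shared=shared,
                jaccard=jaccard(pa, pb),
            )
        )
    return out


def common_to_k_maps(maps: Sequence[DiseaseMap], k: int) -> frozenset[str]:
    """Accessions present in the protein sets of at least *k* maps."""
    if not 1 <= k <= len(maps):
        raise ValueError(f"k must be in [1, {len(maps)}], got {k}")
    counts: dict[str, int] = {}
    for m in maps:
        for acc in extract_protein_set(m).accessions:
            counts[acc] = counts.get(acc, 0) + 1
    return frozenset(acc for acc, c in counts.items() if c >= k)


def protein_diagram_frequency(
    maps: Sequence[DiseaseMap], top_n: int
) -> list[FrequencyRow]:
    """Rank proteins by the total number of diagrams containing them.

    A protein counts once per diagram regardless of how many elements in
    that diagram carry it.  Sorted by total descending, accession ascending
    on ties; truncated to *top_n*.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    rows: dict[str, FrequencyRow] = {}
    for m in maps:
        per_diagram: dict[str, set[str]] = {}
        for el in m.elements:
            for acc in el.uniprot_ids:
                per_diagram.setdefault(acc, set()).add(el.diagram_id)
        for acc, diagram_ids in per_diagram.items():
            row = rows.setdefault(acc, FrequencyRow(accession=acc))
            row.diagrams_by_map[m.map_id] = sorted(diagram_ids)
    ranked = sorted(rows.values(), key=lambda r: (-r.n_diagrams_total, r.accession))
    return ranked[:top_n]
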