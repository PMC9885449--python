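"""Duplicate-preserving similarity between interactions.

Each interaction is reduced to the ordered list of UniProt accessions of
its participants, roles discarded, elements without identifiers skipped,
and repeats kept (homodimer complexes, co-occurring modified forms of one
protein).  For two such lists A and B:

    Similarity(A, B) = n(A∘B) · n(B∘A) / (n(A) · n(B))

where n(·) is list length and ∘ is list intersection with duplicates:
A∘B keeps every occurrence in A whose accession appears anywhere in B.
Because multiplicities differ between lists, A∘B ≠ B∘A in general, but the
product of the two lengths makes the similarity symmetric.  Two interactions
with identical accession *support* score 1 regardless of multiplicities.

The all-vs-all map comparison retains pairs with similarity ≥ 0.7 and at
least three overlapping occurrences on both sides (defaults); threshold
comparisons are done in exact integer arithmetic so a pair at exactly the
cutoff is retained bit-stably.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Union

from .model import DiseaseMap, Reaction


@dataclass(frozen=True)
class IdentifierMultiset:
    """Ordered accession list of one interaction, duplicates preserved."""

    reaction_id: str
    map_id: str
    ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class SimilarityRecord:
    """One scored cross-map reaction pair with both asymmetric overlaps."""

    map_a: str
    reaction_a: str
    map_b: str
    reaction_b: str
    similarity: float
    overlap_a: int  # n(A∘B)
    overlap_b: int  # n(B∘A)


@dataclass(frozen=True)
class FilterCriteria:
    """Retention thresholds for the all-vs-all comparison."""

    min_similarity: Union[float, Fraction] = Fraction(7, 10)
    min_overlap: int = 3

    def __post_init__(self):
        if not 0 <= float(self.min_similarity) <= 1:
            raise ValueError("min_similarity must be in [0, 1]")
        if self.min_overlap < 0:
            raise ValueError("min_overlap must be >= 0")

    @property
    def min_similarity_exact(self) -> Fraction:
        # Floats go through their shortest decimal repr, so a user-supplied
        # 0.7 means 7/10, not the nearest binary double.
        ms = self.min_similarity
        return ms if isinstance(ms, Fraction) else Fraction(repr(float(ms)))


def interaction_multiset(
    reaction: Reaction, disease_map: DiseaseMap, first_id_only: bool = False
) -> IdentifierMultiset:
    """Accession list of a reaction: concatenation, in participant order, of
    each participant element's accessions, all roles treated alike.

    Heteromeric complexes contribute all their accessions by default;
    ``first_id_only`` takes only the first accession per element.
    """
    ids: list[str] = []
    for p in reaction.participants:
        el = disease_map.element(p.element_id)
        if not el.uniprot_ids:
            continue
        ids.extend(el.uniprot_ids[:1] if first_id_only else el.uniprot_ids)
    return IdentifierMultiset(
        reaction_id=reaction.reaction_id, map_id=disease_map.map_id, ids=tuple(ids)
    )


def list_intersect(a: IdentifierMultiset, b: IdentifierMultiset) -> IdentifierMultiset:
    """A∘B: the sublist of A (order and multiplicity preserved) whose
    accessions occur at least once in B.  Asymmetric by construction."""
    support_b = set(b.ids)
    return IdentifierMultiset(
        reaction_id=a.reaction_id,
        map_id=a.map_id,
        ids=tuple(x for x in a.ids if x in support_b),
    )


def _overlaps(a: IdentifierMultiset, b: IdentifierMultiset) -> tuple[int, int]:
    support_a = set(a.ids)
    support_b = set(b.ids)
    oa = sum(1 for x in a.ids if x in support_b)
    ob = sum(1 for x in b.ids if x in support_a)
    return oa, ob


def similarity(a: IdentifierMultiset, b: IdentifierMultiset) -> float:
    """n(A∘B)·n(B∘A) / (n(A)·n(B)); 0 when either list is empty."""
    if a.n == 0 or b.n == 0:
        return 0.0
    oa, ob = _overlaps(a, b)
    return (oa * ob) / (a.n * b.n)


def compare_maps(
    map_a: DiseaseMap,
    map_b: DiseaseMap,
    criteria: FilterCriteria = FilterCriteria(),
    first_id_only: bool = False,
) -> list[SimilarityRecord]:
    """Score every cross-map reaction pair and keep those meeting the
    similarity and both-sided overlap thresholds.

    Output is sorted by (reaction_a, reaction_b) lexicographically.  The
    similarity threshold is applied as an exact rational comparison
    (overlap_a·overlap_b / (n(A)·n(B)) ≥ min_similarity) so that pairs at
    exactly the cutoff are retained regardless of floating-point rounding.
    """
    if map_a.map_id == map_b.map_id:
        raise ValueError("compare_maps expects two distinct maps")
    ms = criteria.min_similarity_exact
    min_ov = criteria.min_overlap
    multisets_a = [
        interaction_multiset(rx, map_a, first_id_only) for rx in map_a.reactions
    ]
    multisets_b = [
        interaction_multiset(rx, map_b, first_id_only) for rx in map_b.reactions
    ]
    # accession -> B-multisets containing it; skips the quadratic scan over
    # pairs with disjoint supports.
    by_acc: dict[str, set[int]] = {}
    for j, mb in enumerate(multisets_b):
        for acc in set(mb.ids):
            by_acc.setdefault(acc, set()).add(j)
    # Zero thresholds retain even disjoint/empty pairs, so the index
    # shortcut only applies when some overlap is actually required.
    retain_disjoint = min_ov == 0 and ms <= 0
    records = []
    for ma in multisets_a:
        if ma.n == 0 and not retain_disjoint:
            continue
        if retain_disjoint:
            candidates = set(range(len(multisets_b)))
        else:
            candidates = set()
            for acc in set(ma.ids):
                candidates |= by_acc.get(acc, set())
        for j in candidates:
            mb = multisets_b[j]
            oa, ob = _overlaps(ma, mb)
            if oa < min_ov or ob < min_ov:
                continue
            if ma.n == 0 or mb.n == 0:
                if not retain_disjoint:
                    continue
            elif Fraction(oa * ob, ma.n * mb.n) < ms:
                continue
            records.append(
                SimilarityRecord(
                    map_a=map_a.map_id,
                    reaction_a=ma.reaction_id,
                    map_b=map_b.map_id,
                    reaction_b=mb.reaction_id,
                    similarity=(oa * ob) / (ma.n * mb.n) if ma.n and mb.n else 0.0,
                    overlap_a=oa,
                    overlap_b=ob,
                )
            )
    records.sort(key=lambda r: (r.reaction_a, r.reaction_b))
    return records
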