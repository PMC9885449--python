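"""Deterministic generator of disease-map fixtures.

Emits maps with exactly controlled cross-map protein overlap, planted
near-identical reaction pairs (guaranteed to pass the default similarity
filter) against a background of reactions guaranteed to fail it, and
planted pathway blocks (chains of matched reactions) that surface as
connected components.  Every planted quantity is recorded in a
:class:`GroundTruth` object so downstream comparisons can be checked
exactly, not statistically.

Construction guarantees:

* Protein overlap is allocated deterministically from a synthetic
  accession universe (``SYN0000001`` ...), so configured pairwise shared
  counts are exact, not expectations.
* Background reactions carry at most two occurrences of cross-map shared
  accessions, so every background pair fails the "at least three
  overlapping identifiers on both sides" filter by construction.
* Planted reaction pairs use per-pair dedicated shared accessions, so the
  retained record set equals the planted set exactly.
* Same seed, same config → byte-identical maps.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence, Union

from .model import (
    Diagram,
    DiseaseMap,
    MapElement,
    Participant,
    Reaction,
    RegistryEntry,
    Role,
)

Pair = tuple[str, str]


class ConfigurationError(ValueError):
    """Raised when the requested overlap structure is infeasible."""


@dataclass(frozen=True)
class MapConfig:
    map_id: str
    mesh_id: str = ""
    n_diagrams: int = 1
    n_proteins: int = 100
    n_reactions: int = 100
    reaction_size_range: tuple[int, int] = (2, 6)
    duplicate_prob: float = 0.0

    def __post_init__(self):
        if self.reaction_size_range[0] < 1:
            raise ConfigurationError("reaction_size_range minimum must be >= 1")
        if not 0.0 <= self.duplicate_prob <= 1.0:
            raise ConfigurationError("duplicate_prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic study: maps, planted overlaps,
    planted similar reaction pairs and planted pathway blocks.

    ``pairwise_shared`` fixes |protein set A ∩ protein set B| exactly for
    each map pair; ``shared_all_maps`` accessions are planted in every map
    (and count toward each pairwise intersection).  ``planted_similar``
    gives the number of stand-alone near-identical reaction pairs per map
    pair; ``planted_pathways`` gives, per map pair, the sizes (reactions
    per block) of matched reaction chains.
    """

    seed: int = 0
    universe_size: int = 1000
    maps: tuple[MapConfig, ...] = ()
    pairwise_shared: Mapping[Pair, int] = field(default_factory=dict)
    shared_all_maps: int = 0
    planted_similar: Mapping[Pair, int] = field(default_factory=dict)
    planted_pathways: Mapping[Pair, tuple[int, ...]] = field(default_factory=dict)

    @staticmethod
    def from_dict(payload: dict) -> "SyntheticConfig":
        """Build from a plain dict (e.g. parsed YAML); map pairs are
        written as "map_a,map_b" strings."""

        def pairs(d):
            return {tuple(k.split(",")): v for k, v in (d or {}).items()}

        maps = tuple(
            MapConfig(
                map_id=m["map_id"],
                mesh_id=m.get("mesh_id", ""),
                n_diagrams=m.get("n_diagrams", 1),
                n_proteins=m.get("n_proteins", 100),
                n_reactions=m.get("n_reactions", 100),
                reaction_size_range=tuple(m.get("reaction_size_range", (2, 6))),
                duplicate_prob=m.get("duplicate_prob", 0.0),
            )
            for m in payload.get("maps", [])
        )
        return SyntheticConfig(
            seed=payload.get("seed", 0),
            universe_size=payload.get("universe_size", 1000),
            maps=maps,
            pairwise_shared=pairs(payload.get("pairwise_shared")),
            shared_all_maps=payload.get("shared_all_maps", 0),
            planted_similar={
                k: int(v) for k, v in pairs(payload.get("planted_similar")).items()
            },
            planted_pathways={
                k: tuple(v) for k, v in pairs(payload.get("planted_pathways")).items()
            },
        )


@dataclass
class GroundTruth:
    """Planted quantities, auditable by recount on the emitted maps."""

    #: accessions planted in every map
    all_shared: frozenset[str] = field(default_factory=frozenset)
    #: pair -> exact intersection of the two maps' protein sets
    shared_accessions: dict[Pair, frozenset[str]] = field(default_factory=dict)
    #: map_id -> exact protein set
    protein_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    #: pair -> every (reaction_a, reaction_b) expected to pass the default
    #: similarity filter (stand-alone planted pairs and pathway reactions)
    planted_pair_ids: dict[Pair, list[tuple[str, str]]] = field(default_factory=dict)
    #: pair -> per pathway block, the matched reaction ids in each map
    planted_components: dict[Pair, list[tuple[tuple[str, ...], tuple[str, ...]]]] = (
        field(default_factory=dict)
    )


def _accession(i: int) -> str:
    # 10-character accessions satisfy the UniProt grammar used on read.
    return f"SYN{i:07d}"


def _pair_tag(pair: Pair) -> str:
    return f"{pair[0]}+{pair[1]}"


@dataclass
class _MapDraft:
    cfg: MapConfig
    diagrams: list[Diagram] = field(default_factory=list)
    elements: list[MapElement] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    background_pool: list[MapElement] = field(default_factory=list)
    n_elements: int = 0

    def new_element(
        self, rng: random.Random, uniprot_ids: tuple[str, ...], pool: bool
    ) -> MapElement:
        self.n_elements += 1
        diagram = self.diagrams[(self.n_elements - 1) % len(self.diagrams)]
        el = MapElement(
            element_id=f"{self.cfg.map_id}-e{self.n_elements}",
            diagram_id=diagram.diagram_id,
            display_name=uniprot_ids[0] if uniprot_ids else "unannotated",
            uniprot_ids=uniprot_ids,
        )
        self.elements.append(el)
        if pool:
            self.background_pool.append(el)
        return el


def _allocate_proteins(config: SyntheticConfig, pairs: list[Pair]):
    """Deterministic exact overlap allocation: all-maps block first, then
    per-pair exclusive blocks, then per-map private fill."""
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        if cursor + n > config.universe_size:
            raise ConfigurationError(
                f"universe_size={config.universe_size} too small for the "
                f"requested overlap structure (needs > {cursor + n})"
            )
        block = [_accession(i + 1) for i in range(cursor, cursor + n)]
        cursor += n
        return block

    all_block = take(config.shared_all_maps)
    per_map: dict[str, list[str]] = {
        m.map_id: list(all_block) for m in config.maps
    }
    pair_blocks: dict[Pair, list[str]] = {}
    for pair in pairs:
        want = config.pairwise_shared.get(pair, 0)
        excl = want - config.shared_all_maps
        if excl < 0:
            raise ConfigurationError(
                f"pairwise_shared for {pair} ({want}) is smaller than "
                f"shared_all_maps ({config.shared_all_maps})"
            )
        block = take(excl)
        pair_blocks[pair] = block
        per_map[pair[0]].extend(block)
        per_map[pair[1]].extend(block)
    private: dict[str, list[str]] = {}
    for m in config.maps:
        n_priv = m.n_proteins - len(per_map[m.map_id])
        if n_priv < 0:
            raise ConfigurationError(
                f"map {m.map_id!r}: n_proteins={m.n_proteins} is smaller than "
                f"its allocated shared accessions ({len(per_map[m.map_id])})"
            )
        block = take(n_priv)
        private[m.map_id] = block
        per_map[m.map_id].extend(block)
    return all_block, pair_blocks, private, per_map


def _reserve(pair: Pair, block: list[str], n: int, used: dict[Pair, int]) -> list[str]:
    start = used[pair]
    if start + n > len(block):
        raise ConfigurationError(
            f"pairwise_shared for {pair} leaves too few exclusive accessions "
            f"for the planted reactions (need {start + n}, have {len(block)})"
        )
    used[pair] = start + n
    return block[start : start + n]


def _background_reaction(
    rng: random.Random, draft: _MapDraft, shared_support: frozenset[str], index: int
) -> Reaction:
    smin, smax = draft.cfg.reaction_size_range
    size = rng.randint(smin, smax)
    pool = draft.background_pool
    chosen: list[MapElement] = []
    chosen_idx: set[int] = set()
    shared_occ = 0
    attempts = 0
    while len(chosen) < size and attempts < 60 * size:
        attempts += 1
        i = rng.randrange(len(pool))
        if i in chosen_idx:
            continue
        el = pool[i]
        occ = sum(1 for a in el.uniprot_ids if a in shared_support)
        if shared_occ + occ > 2:  # keeps every background pair below min_overlap=3
            continue
        chosen_idx.add(i)
        chosen.append(el)
        shared_occ += occ
    if not chosen:
        chosen = [pool[0]]
    participants = []
    for j, el in enumerate(chosen):
        if j == 0:
            role = Role.REACTANT
        elif j == len(chosen) - 1 and len(chosen) > 1:
            role = Role.PRODUCT
        else:
            role = rng.choice((Role.REACTANT, Role.MODIFIER))
        participants.append(Participant(element_id=el.element_id, role=role))
    return Reaction(
        reaction_id=f"{draft.cfg.map_id}-r{index}",
        diagram_id=chosen[0].diagram_id,
        participants=tuple(participants),
    )


def generate(config: SyntheticConfig) -> tuple[list[DiseaseMap], GroundTruth]:
    """Generate the configured maps and their ground truth.

    Raises :class:`ConfigurationError` (naming the offending map pair) on
    infeasible overlap constraints.
    """
    if not config.maps:
        return [], GroundTruth()
    map_ids = [m.map_id for m in config.maps]
    if len(set(map_ids)) != len(map_ids):
        raise ConfigurationError("duplicate map_id in config")
    order = {mid: i for i, mid in enumerate(map_ids)}

    def norm(pair: Pair) -> Pair:
        if pair[0] not in order or pair[1] not in order:
            raise ConfigurationError(f"pair {pair} references an unknown map_id")
        return pair if order[pair[0]] < order[pair[1]] else (pair[1], pair[0])

    pairs = sorted(
        {norm(p) for p in (*config.pairwise_shared, *config.planted_similar,
                           *config.planted_pathways)},
        key=lambda p: (order[p[0]], order[p[1]]),
    )
    # every pair named in planted_* must have a declared shared budget
    pairwise_shared = {norm(p): v for p, v in config.pairwise_shared.items()}
    planted_similar = {norm(p): v for p, v in config.planted_similar.items()}
    planted_pathways = {norm(p): tuple(v) for p, v in config.planted_pathways.items()}
    cfg = SyntheticConfig(
        seed=config.seed,
        universe_size=config.universe_size,
        maps=config.maps,
        pairwise_shared=pairwise_shared,
        shared_all_maps=config.shared_all_maps,
        planted_similar=planted_similar,
        planted_pathways=planted_pathways,
    )

    rng = random.Random(cfg.seed)
    all_block, pair_blocks, private, per_map = _allocate_proteins(cfg, pairs)
    shared_support = frozenset(all_block) | frozenset(
        a for block in pair_blocks.values() for a in block
    )

    drafts: dict[str, _MapDraft] = {}
    for m in cfg.maps:
        draft = _MapDraft(cfg=m)
        draft.diagrams = [
            Diagram(
                diagram_id=f"{m.map_id}-d{j + 1}",
                diagram_name="Core map" if j == 0 else f"Submap {j + 1}",
            )
            for j in range(m.n_diagrams)
        ]
        # one element per allocated protein; homodimer duplication emulated
        for acc in per_map[m.map_id]:
            dup = rng.random() < m.duplicate_prob
            draft.new_element(rng, (acc, acc) if dup else (acc,), pool=True)
        # a sprinkling of unannotated elements
        for _ in range(max(1, m.n_proteins // 10)):
            draft.new_element(rng, (), pool=True)
        drafts[m.map_id] = draft

    truth = GroundTruth(
        all_shared=frozenset(all_block),
        protein_sets={mid: frozenset(per_map[mid]) for mid in map_ids},
    )
    for pair in pairs:
        truth.shared_accessions[pair] = frozenset(all_block) | frozenset(
            pair_blocks[pair]
        )
        truth.planted_pair_ids[pair] = []
        truth.planted_components[pair] = []

    used: dict[Pair, int] = {pair: 0 for pair in pairs}

    # -- stand-alone planted similar reaction pairs -------------------------
    for pair in pairs:
        k = planted_similar.get(pair, 0)
        tag = _pair_tag(pair)
        for i in range(k):
            core_size = 3 + i % 3
            core = _reserve(pair, pair_blocks[pair], core_size, used)
            rids = {}
            for side, mid in enumerate(pair):
                draft = drafts[mid]
                els = [draft.new_element(rng, (acc,), pool=False) for acc in core]
                # every other pair gets one map-private extra participant so
                # planted similarities also exercise values strictly below 1
                if i % 2 == 1 and core_size >= 4 and side == 0 and private[mid]:
                    extra_acc = private[mid][i % len(private[mid])]
                    els.append(draft.new_element(rng, (extra_acc,), pool=False))
                participants = [Participant(element_id=els[0].element_id,
                                            role=Role.REACTANT)]
                participants += [
                    Participant(element_id=e.element_id, role=Role.MODIFIER)
                    for e in els[1:-1]
                ]
                if len(els) > 1:
                    participants.append(
                        Participant(element_id=els[-1].element_id, role=Role.PRODUCT)
                    )
                rid = f"{mid}-rp-{tag}-{i + 1}"
                draft.reactions.append(
                    Reaction(
                        reaction_id=rid,
                        diagram_id=els[0].diagram_id,
                        participants=tuple(participants),
                    )
                )
                rids[mid] = rid
            truth.planted_pair_ids[pair].append((rids[pair[0]], rids[pair[1]]))

    # -- planted pathway blocks (chains of matched reactions) ---------------
    for pair in pairs:
        for b_idx, b in enumerate(planted_pathways.get(pair, ())):
            if b < 1:
                raise ConfigurationError(
                    f"pathway block size must be >= 1 for pair {pair}"
                )
            cores = [_reserve(pair, pair_blocks[pair], 3, used) for _ in range(b)]
            links = _reserve(pair, pair_blocks[pair], max(b - 1, 0), used)
            tag = _pair_tag(pair)
            block_rids: dict[str, list[str]] = {}
            for mid in pair:
                draft = drafts[mid]
                link_els = [draft.new_element(rng, (a,), pool=False) for a in links]
                start = draft.new_element(rng, (), pool=False)
                end = draft.new_element(rng, (), pool=False)
                rids = []
                for i in range(b):
                    core_els = [
                        draft.new_element(rng, (a,), pool=False) for a in cores[i]
                    ]
                    reactant = link_els[i - 1] if i > 0 else start
                    product = link_els[i] if i < b - 1 else end
                    participants = (
                        Participant(element_id=reactant.element_id,
                                    role=Role.REACTANT),
                        *(
                            Participant(element_id=e.element_id, role=Role.MODIFIER)
                            for e in core_els
                        ),
                        Participant(element_id=product.element_id, role=Role.PRODUCT),
                    )
                    rid = f"{mid}-rb-{tag}-{b_idx + 1}-{i + 1}"
                    draft.reactions.append(
                        Reaction(
                            reaction_id=rid,
                            diagram_id=core_els[0].diagram_id,
                            participants=participants,
                        )
                    )
                    rids.append(rid)
                block_rids[mid] = rids
            a_rids, b_rids = block_rids[pair[0]], block_rids[pair[1]]
            truth.planted_components[pair].append((tuple(a_rids), tuple(b_rids)))
            truth.planted_pair_ids[pair].extend(zip(a_rids, b_rids))

    # -- background reactions ------------------------------------------------
    for m in cfg.maps:
        draft = drafts[m.map_id]
        for i in range(m.n_reactions):
            draft.reactions.append(
                _background_reaction(rng, draft, shared_support, i + 1)
            )

    maps = [
        DiseaseMap(
            map_id=m.map_id,
            name=f"Synthetic map {m.map_id}",
            mesh_id=m.mesh_id,
            diagrams=tuple(drafts[m.map_id].diagrams),
            elements=tuple(drafts[m.map_id].elements),
            reactions=tuple(drafts[m.map_id].reactions),
        )
        for m in cfg.maps
    ]
    for pair in pairs:
        truth.planted_pair_ids[pair].sort()
    return maps, truth


def generate_registry(
    config: SyntheticConfig,
    start: datetime = datetime(2022, 1, 1),
    older_versions: Union[int, Mapping[str, int]] = 0,
) -> list[RegistryEntry]:
    """Registry entries for the configured maps: one current entry per map
    plus *older_versions* superseded entries (same MeSH id, earlier
    ``shared_at``) per map."""
    entries: list[RegistryEntry] = []
    for i, m in enumerate(config.maps):
        n_old = (
            older_versions
            if isinstance(older_versions, int)
            else older_versions.get(m.map_id, 0)
        )
        current_shared = start + timedelta(days=30 * (i + 1))
        for v in range(n_old):
            shared = current_shared - timedelta(days=10 * (n_old - v))
            entries.append(
                RegistryEntry(
                    project_name=f"Synthetic map {m.map_id}",
                    project_id=m.map_id,
                    version=f"0.{v + 1}",
                    created_at=start,
                    shared_at=shared,
                    mesh_id=m.mesh_id,
                    taxonomy_id="9606",
                    instance_url=f"https://example.org/minerva/{m.map_id}",
                )
            )
        entries.append(
            RegistryEntry(
                project_name=f"Synthetic map {m.map_id}",
                project_id=m.map_id,
                version="1.0",
                created_at=start,
                shared_at=current_shared,
                mesh_id=m.mesh_id,
                taxonomy_id="9606",
                instance_url=f"https://example.org/minerva/{m.map_id}",
            )
        )
    return entries
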