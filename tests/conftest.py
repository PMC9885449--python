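import pytest

from mapcompare.model import Diagram, DiseaseMap, MapElement, Participant, Reaction
from mapcompare.synthetic import MapConfig, SyntheticConfig, generate


def make_map(map_id, elements, reactions, n_diagrams=1, mesh_id=""):
    """Compact constructor for hand-written fixture maps.

    *elements*: {element_id: [accessions]}; all elements go to diagram d1.
    *reactions*: {reaction_id: [(element_id, role_str), ...]}.
    """
    return DiseaseMap(
        map_id=map_id,
        name=map_id,
        mesh_id=mesh_id,
        diagrams=tuple(
            Diagram(diagram_id=f"d{i + 1}", diagram_name=f"d{i + 1}")
            for i in range(n_diagrams)
        ),
        elements=tuple(
            MapElement(
                element_id=eid,
                diagram_id=entry[0] if isinstance(entry, tuple) else "d1",
                uniprot_ids=tuple(entry[1] if isinstance(entry, tuple) else entry),
            )
            for eid, entry in elements.items()
        ),
        reactions=tuple(
            Reaction(
                reaction_id=rid,
                diagram_id="d1",
                participants=tuple(
                    Participant(element_id=eid, role=role) for eid, role in parts
                ),
            )
            for rid, parts in reactions.items()
        ),
    )


@pytest.fixture
def tiny_map():
    """1 diagram, 3 elements (one a homodimer, one unannotated), 1 reaction."""
    return make_map(
        "tiny",
        {"E1": ["P12345"], "E2": ["P12345", "P12345"], "E3": []},
        {"R1": [("E1", "reactant"), ("E2", "modifier"), ("E3", "product")]},
    )


@pytest.fixture(scope="session")
def synthetic_triple():
    """Three maps with planted overlaps, similar pairs and pathway blocks."""
    cfg = SyntheticConfig(
        seed=20,
        universe_size=3000,
        maps=(
            MapConfig("m1", "D010300", n_diagrams=3, n_proteins=400,
                      n_reactions=120, duplicate_prob=0.1),
            MapConfig("m2", "D000544", n_diagrams=1, n_proteins=300,
                      n_reactions=100, duplicate_prob=0.0),
            MapConfig("m3", "D008659", n_diagrams=2, n_proteins=200,
                      n_reactions=80, duplicate_prob=0.2),
        ),
        pairwise_shared={("m1", "m2"): 120, ("m1", "m3"): 80, ("m2", "m3"): 60},
        shared_all_maps=20,
        planted_similar={("m1", "m2"): 6, ("m2", "m3"): 2},
        planted_pathways={("m1", "m2"): (3, 5), ("m1", "m3"): (4,)},
    )
    maps, truth = generate(cfg)
    return cfg, maps, truth
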