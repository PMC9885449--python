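# Methods

## Problem and scope

Disease maps are curated diagram collections hosted on independent
servers; their content is comparable only through stable identifiers.
`mapcompare` compares maps through UniProt accessions at three
resolutions — protein sets, individual interactions, and connected map
areas — and ships a deterministic generator of synthetic maps so every
claim the package makes is checkable offline against planted ground
truth.  Out of scope by design: talking to any live map server, parsing
CellDesigner/SBML/SBGN sources, role- or modification-aware interaction
matching, layout-based (Euclidean) comparison, and automatic naming of
shared areas (that is curator work).

## Data model and file format

A map is `map_id, name, mesh_id, diagrams[], elements[], reactions[]`,
stored as one UTF-8 JSON document.  Elements carry
`element_id, diagram_id, display_name, uniprot_ids[]`; reactions carry
`reaction_id, diagram_id, participants[]` with
`{element_id, role ∈ {reactant, product, modifier}}`.  Unknown JSON keys
are ignored so files exported from richer services can be read directly.
Validation on read enforces: unique element ids, resolvable diagram and
participant references, non-empty participant lists, the role vocabulary,
and the UniProt accession grammar (6 or 10 alphanumeric characters with an
optional `-<digits>` isoform suffix).  Isoform suffixes are kept verbatim
(comparison is exact string equality); `extract_protein_set(...,
normalize_isoforms=True)` strips them when a coarser comparison is wanted.
Registry indexes are JSON lists of
`{project_name, project_id, version, created_at, shared_at, mesh_id,
taxonomy_id, instance_url}` with ISO-8601 timestamps and the invariant
`shared_at ≥ created_at`.  `filter_registry` keeps, per requested MeSH
disease id, the entry with the latest `shared_at`; ties are broken by
file order (first wins, logged) since no tie rule is otherwise defined.

## Protein-set comparison

Each map reduces to the deduplicated union of its elements' accessions.
Pairwise similarity is the Jaccard index |A∩B| / |A∪B|; the Jaccard of two
empty sets is defined as 0 (a conservative convention that avoids a 0/0).
Values are kept at full precision internally and rounded half-to-even to
3 decimals only at presentation, matching the precision at which such
tables are customarily printed.  `common_to_k_maps` counts membership over
all maps' sets; `protein_diagram_frequency` counts a protein once per
diagram regardless of element multiplicity and breaks ranking ties
lexicographically by accession, for determinism.

## Interaction similarity

An interaction is the concatenation, in participant order, of its
participants' accession lists: roles discarded, unannotated elements
skipped, repeats preserved (homodimers and co-occurring modified forms are
real signal).  Heteromeric complexes contribute all their accessions;
`first_id_only=True` is available where a single representative per
element is preferred.  For lists A and B,

    Similarity(A, B) = n(A∘B) · n(B∘A) / (n(A) · n(B)),

with A∘B the occurrences of A whose accession appears anywhere in B.  This
reading of ∘ — "left occurrences supported by the right list" — is the one
under which the operator is genuinely asymmetric (a min-multiplicity
intersection would make A∘B and B∘A equal up to order); the product of the
two lengths makes the similarity itself symmetric.  Consequences worth
knowing: equal supports score 1 regardless of multiplicities, and an empty
list scores 0 against everything (unannotated reactions are common and are
not an error).

The map-level scan scores all cross-map reaction pairs and retains those
with similarity ≥ 0.7 and at least 3 overlapping occurrences on both
sides (defaults, both configurable).  The similarity threshold is applied
as an exact rational comparison `overlap_a·overlap_b / (n(A)·n(B)) ≥ t`
with `t` taken from the decimal meaning of the given float (0.7 means
7/10), so pairs at exactly the cutoff are retained bit-stably.  An
inverted accession index skips pairs with disjoint supports, making the
scan near-linear in practice; the degenerate configuration
`min_similarity = 0, min_overlap = 0` falls back to the full quadratic
enumeration so that zero-overlap pairs are still reported.  Within-map
pairs are not compared: the comparison's semantics are cross-map, and
`compare_maps` rejects two maps with the same id.

## Shared mechanism areas

Each map becomes a directed bipartite graph: reactant and modifier
elements send edges into their reaction's node, the reaction node sends
edges to its product elements; duplicate participant entries collapse to
one edge and elements participating in no reaction are omitted.  The
graph is restricted to the reactions appearing in the retained similarity
records (membership is binary; a reaction retained by several records is
not weighted), and connected components are taken on the *undirected*
skeleton — mechanism areas are bidirectional neighborhoods, and strong
connectivity would shred linear cascades.  Components with ≥ 3 reactions
(default) are reported, sorted by reaction count then smallest reaction
id, and matched across the pair by counting the similarity records that
join a reaction of one component to a reaction of the other.  Graphs are
`networkx.DiGraph` objects with a `kind` node attribute; exports are
SIF-style edge lists (`node<TAB>input|output<TAB>node`) plus a
node-attribute TSV.

## Synthetic-map generator

The generator emulates the statistical structure the comparison operates
on — protein-set overlap, reaction-size spread, repeated identifiers
within a reaction, near-identical reaction pairs across maps, and chained
pathway blocks — with every planted quantity exact and recorded:

* **Accessions** come from a synthetic universe `SYN0000001…`
  (10-character ids, so generated maps pass the same accession grammar as
  real ones).  Overlap is allocated deterministically: the all-maps block
  first, then per-pair exclusive blocks, then per-map private fill, so
  configured intersections are exact counts, not expectations.
* **Elements**: one element per allocated accession; with probability
  `duplicate_prob` an element is a homodimer (`[p, p]`), emulating
  repeated identifiers; roughly one unannotated element per ten proteins
  exercises the "no identifier" path.  Default map sizes (hundreds of
  proteins, 1–6 participants per reaction) sit in the range spanned by
  real disease maps, which have 360–1370 unique proteins and ~1–4 k
  interactions across 1–22 diagrams.
* **Background reactions** sample participants so that a reaction carries
  at most two occurrences of cross-map shared accessions.  Every
  background pair therefore fails the both-sided ≥ 3-overlap filter *by
  construction*, making planted-pair recovery an exact, zero-false-positive
  test rather than a statistical one.
* **Planted similar pairs** copy a reaction's multiset across the pair
  using per-pair dedicated shared accessions (cores of 3–5); every other
  pair receives one map-private extra participant on one side so planted
  similarities also take values strictly between 0.7 and 1 (c/(c+1) ≥
  0.8).  Dedicated accessions make the retained record set equal the
  planted set exactly.
* **Planted pathway blocks** chain b matched reactions through annotated
  linker elements (reaction i's product is reaction i+1's reactant), with
  3 dedicated core accessions per reaction, so each block surfaces as one
  connected component of exactly b reactions per map and blocks match
  one-to-one across the pair.
* All randomness flows through one `random.Random(seed)`; the same config
  and seed give byte-identical files.

What the generator does **not** emulate: realistic pathway topology
statistics (degree distributions, hubs), diagram layout, protein states
and posttranslational modifications, or annotation noise (wrong or
missing accessions beyond the planted unannotated elements).  Passing
tests therefore demonstrate the *correctness* of the comparison
operations under controlled overlap structure, not the biological
plausibility of any particular similarity value on real maps — on real
content, results are known to depend on curatorial style (e.g. how
finely a mechanism is split into reactions), which no identifier-based
metric can correct for.

## Numerical and design choices

* Jaccard of empty sets: 0.  Similarity with an empty list: 0.  Both are
  documented conventions, not errors.
* Threshold comparisons on the similarity are exact rational arithmetic;
  reported similarity values are floats (products of small integers
  divided once, so exactly representable in the test alphabet sizes used).
* Rounding for presentation is half-to-even via `decimal`, applied once.
* Component ordering, frequency-ranking ties and record ordering are all
  deterministic (documented sort keys), so outputs are diffable.
* Tests cross-check the implementation against independent oracles: a
  brute-force occurrence counter for the similarity (exhaustive over all
  126×126 multiset pairs on a 5-accession alphabet with lengths ≤ 4), a
  hand-written union-find for connected components against networkx, and
  exhaustive membership scans for multi-map commonality.  Planted-pair
  recovery runs at 500 background reactions per map with 25 planted
  pairs; component recovery at 1, 2 and 5 planted blocks — sizes chosen
  to exercise the defaults well past the fixture scale while keeping the
  whole suite fast.

## Known limitations

* The JSON dialect is this package's own; content from a live MINERVA-style
  API must be exported into it (no HTTP client is included).
* Identifier-based comparison ignores protein state, modifications,
  stoichiometric coefficients and reaction direction; two mechanistically
  different reactions over the same proteins score 1.
* Component matching treats record membership as binary and does not
  attempt to label areas with pathway names.
* The empty-list and empty-set conventions make maps with sparse
  annotation look dissimilar; interpret low similarities on poorly
  annotated content with care.
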