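# Methods

## Scope and model

`hormonet` treats phytohormone crosstalk as a property of network structure
at the biosynthesis level. The primitive object is a pathway database
(compounds, reactions, enzymes, pathways with referential integrity) read
from BioCyc-style attribute–value flat-files. Enzymes are keyed by EC
string; distinct gene products sharing an EC collapse onto one node, which
matches how curated crosstalk maps label their nodes at enzyme-activity
resolution. EC wildcards (`6.3.-.-`) are kept verbatim at parse time;
matching against concrete ECs is the explicit operation `ec_match`, used
only where family-level aggregation is intended (evidence overlay).

Two enzyme graphs are derived:

- **Shared-compound graph (GECN).** Edge between two enzymes when at least
  one non-currency compound occurs in a reaction of each, on either side.
  This is deliberately broad: crosstalk reasoning needs "touches the same
  metabolite", not only directed flow.
- **Producer/consumer coupling graph.** Edge when a product of one
  enzyme's reaction is a substrate of the other's (reversible reactions
  contribute both sides). This stricter relation underlies consecutive
  metabolic routes. By construction every coupling edge is also a GECN
  edge.

The crosstalk network (EAPCN) adds one node per hormone and an `acts_in`
edge from each enzyme to every hormone whose annotated pathway contains a
reaction of that enzyme; enzyme–enzyme edges are the GECN edges restricted
to the included enzymes. Hormone vocabulary is closed (the eight major
Arabidopsis hormones); annotation roles are biosynthesis, inactivation,
degradation, conjugation.

**Currency policy.** Default currency set: water, H+, ATP, ADP, AMP,
phosphate, diphosphate, NAD+, NADH, NADP+, NADPH, CO2, O2, CoA, UDP.
S-adenosyl-L-methionine and UDP-D-glucose are deliberately *not* currency:
in hormone conjugation and methylation chemistry they are route-relevant
co-substrates, and excluding them would delete real crosstalk edges. The
set is fully configurable per run.

## Centrality indices

Twelve per-node indices on the simple undirected enzyme graph, following
the cytoHubba conventions. Definitions that needed a choice:

- **Closeness** is harmonic (Σ 1/d): well defined on disconnected
  networks, which hormone subnetworks often are.
- **Eccentricity score** is the reciprocal of graph-theoretic eccentricity
  within the node's component (0 for isolated nodes), so that larger means
  more central for all twelve columns.
- **Radiality** of v is (1/(n_c−1))·Σ_u (Δ_c + 1 − d(v,u)) over v's
  component, Δ_c its diameter.
- **Betweenness/stress** count each unordered pair once; both come from a
  single Brandes-style BFS sweep (stress uses the σ-weighted suffix-count
  recursion).
- **MCC** sums (|C|−1)! over maximal cliques of size ≥ 2 containing v
  (size-1 "cliques" excluded so isolated nodes score 0). Enumeration uses
  Bron–Kerbosch via networkx; a node-count guard (default 5000) aborts
  with a clear error rather than hanging on huge graphs.
- **MNC/DMNC**: largest connected component of the subgraph induced by
  N(v); DMNC divides its edge count by its node count to the power
  ε = 1.7 (default, configurable). Ties between equally large components
  are broken by edge count, then sorted node ids.
- **BottleNeck**: per source, a deterministic BFS shortest-path tree
  (parent = smallest-id candidate); v scores one point per source whose
  tree gives v a subtree larger than ¼ (default) of the tree. The
  deterministic tie-break makes results reproducible, at the cost of exact
  label-symmetry on graphs with equidistant parent choices (even cycles);
  odd cycles and complete graphs retain full symmetry.
- **EPC**: Monte-Carlo edge percolation — keep each edge with probability
  0.5 (default), 1000 realizations (default), score = mean fractional size
  of v's surviving component; seeded and reproducible. With keep
  probability 1 it equals the component fraction exactly.

Ranks are dense ("1, 2, 2, 3"), so tied nodes share a rank and hub sets
are reproducible. Hub selection takes the positional top *k* per index
(ties by score then node id) and keeps nodes appearing in ≥ *m* of the 12
lists.

## Clustering

Greedy cohesiveness growth with f(V) = w_in/(w_in + w_bound + p·|V|), unit
edge weights (the networks are unweighted), penalty p = 2 by default.
Growth applies the best single addition (boundary) or removal (never the
seed) while cohesiveness strictly improves; ties prefer additions, then
the smaller node id — the procedure is deterministic. Seeds are processed
in degree-descending order, skipping nodes already covered. Clusters are
merged while any pair has match coefficient ω(A,B) = |A∩B|²/(|A|·|B|) ≥
0.8, iterated to a fixed point so the final set is order-independent;
clusters below 3 members or density 0.5 are discarded. No cluster
p-values are computed.

## Routes and TF circuits

Consecutive metabolic routes are maximum-cardinality simple paths in the
coupling graph. Coupling is undirected because curated route chains mix
biosynthetic directions across pathways; the direction information stays
in the edge provenance. Longest-simple-path is NP-hard, so exact
exhaustive DFS is used up to 50 nodes (hub sets are small) with a greedy
beam-search fallback above that, logged when it engages. Routes are
canonicalized (lexicographically smaller endpoint first) and each
transition reports the lexicographically smallest shared compound;
presentation in biosynthetic step order may reverse a canonical route.

The TF co-target network joins two TFs sharing ≥ 1 target gene (optionally
filtered to enzyme-encoding targets). Circular control structures are the
simple cycles of length 3..15 (bounded Johnson enumeration; the cap is
logged when it can truncate). Cycles are grouped into control units by
transitive closure of edge sharing — the closest testable formalization of
hand-curated unit drawings; a biconnected-component alternative would give
coarser groups. Within a unit the consecutive PPI route is the longest
simple path of the induced protein-interaction subgraph (exhaustive; unit
sizes are small). On dense co-target cliques (the curated fixture's units
are full bipartite TF×target expansions) triangles already carry the
complete unit structure, so pipeline runs on the fixture set the cycle
bound to 3; longer bounds only add redundant cycles at combinatorial cost.

## Evidence overlay

Presence/absence only, matching how expression/proteome support is
reported for route maps: a step is transcript-supported if any gene of any
DB enzyme matching the step's EC (wildcards aggregate the family) is in
the expressed list, protein-supported likewise against the detected-protein
list; regulating TFs are those whose targets intersect the step's genes,
filtered to expressed TFs. The permutation null draws equal-size random
enzyme sets from the database and reports
p = (1 + #{coverage ≥ observed})/(n_perm + 1), seeded.

## Synthetic data: what it emulates and what it does not

The generator produces inputs with the shapes of the real resources
(pathway flat-files, hormone annotations, TF regulation, PPI pairs,
expressed/detected ID lists) and known planted structure:

- a producer/consumer chain of configurable length (default 13, the length
  of the curated route) through unique linker compounds; background
  reactions draw on a disjoint compound pool, and a post-hoc exact check
  asserts the planted chain is the unique maximum route;
- hormone-bridge enzymes per requested hormone pair (default: 11 for
  auxin–cytokinin, the curated bridge size);
- planted TF co-target cycles (consecutive TFs share a dedicated target)
  over sparse random background co-targeting (default density 0.02, and
  0.05 in the recovery tests), with a PPI chain over each cycle;
- evidence lists with sensitivity 0.9 and false-positive rate 0.05 by
  default — sensitive but imperfect single-tissue coverage.

Identical parameters and seed yield byte-identical files. The generator
does **not** mimic genome scale (hundreds of pathways, thousands of
enzymes), EC-family structure, reaction stoichiometry or correlated noise
in evidence lists; passing recovery tests therefore demonstrates
correctness of the algorithms under the stated conditions, not robustness
to every property of real curated databases.

## The curated fixture

A packaged, plain-text transcription of the published Arabidopsis
crosstalk entities: the 13-enzyme consecutive route with its named linking
metabolites (L-phenylalanine, ACC, indole-3-acetate,
trans-zeatin-O-glucoside, brassinolide, kaempferol, quercetin, gibberellin
A20, (22α)-hydroxy-campest-4-en-3-one), hormone annotations for all eight
hormones, the auxin–cytokinin bridge, TF control-unit regulation rows with
the unit-C PPI chain, and root-stele expressed/detected loci. Identifiers
prefixed `PLACEHOLDER-`, `ROUTE-LINKER-` or `MARKER-` are fixture
scaffolding standing in for entities the curated source does not name
(four route transitions have unnamed linking metabolites; hormone
memberships beyond the named pathways are carried by dedicated marker
reactions with unique inert compounds so they cannot create spurious
edges). The curated source lists twelve EC identifiers for the
auxin–cytokinin bridge while stating eleven enzymes; the fixture resolves
this by giving the cellulose synthase (EC 2.4.1.12) only the hormone
memberships its expression table assigns it (no auxin, no cytokinin), so
the bridge query returns eleven. The gene for EC 2.4.1.203 is a synthetic
stand-in locus, marked in the fixture comments.

## Numerical and degenerate-input choices

- All identifiers case-sensitive, whitespace-stripped; parser errors name
  line numbers; validation reports (dangling references, duplicate ids,
  empty reactions, duplicate ECs under distinct ids) never throw.
- Isolated nodes: centrality 0 on all path/neighborhood indices, EPC 1/n.
- Clustering of an empty graph returns an empty list; singleton density is
  defined as 1 but min_size filters singletons anyway.
- One pipeline seed derives per-stage substreams by fixed offsets (EPC:
  seed+101, permutation: seed+202); outputs carry the seed in their
  headers and contain no timestamps, so identical config + seed gives
  byte-identical files.

## Known limitations

Routes carry no flux, kinetics or thermodynamic direction; synergy versus
antagonism of a crosstalk edge is not classified; cycle enumeration cost
on dense co-target graphs forces a small length bound; regulation within
TF cycles is undirected co-targeting, not signed regulatory logic.
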