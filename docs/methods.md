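# Methods

## Data model

The analysis operates on three disjoint node roles — transcription
factors (TFs), miRNAs and non-TF protein-coding genes — connected by
four directed, typed regulation pair classes: TF→gene and TF→miRNA
(transcriptional), miRNA→gene and miRNA→TF (post-transcriptional).
Role disjointness is enforced at construction: an identifier implied to
be both a TF and a gene across tables is a hard error listing every
offender, because the motif definitions below require the joint target
to be a non-TF gene. Symbols are compared case-sensitively after
whitespace trimming and miRNA names are stored verbatim
(`hsa-mir-27b`), avoiding silent merges between casing variants.
Self-regulation rows are dropped at parse time (none of the four pair
classes includes them) and exact duplicate pairs collapse, both with
counts reported.

## Feed-forward-loop enumeration

A feed-forward loop (FFL) is a triple (TF, miRNA, gene) with TF→gene
and miRNA→gene edges plus at least one edge between the regulators.
The regulator link classifies the loop **exclusively**: both directions
present → motif C (a TF/miRNA feedback pair embedded in the loop);
TF→miRNA only → motif A; miRNA→TF only → motif B. Exclusivity makes
the three per-class counts partition the total, which is what makes
summary tables additive. Enumeration walks the TF–miRNA pairs that
share at least one link and intersects their target sets; output is
sorted by (tf, mirna, gene) so everything downstream is
byte-reproducible. Correctness is checked in the test suite against an
independent brute-force triple scan.

## Network assembly

Motif-restricted and combined networks are deduplicated unions of their
contributing instances' nodes and edges, keyed by (source, target,
edge type); each edge records the set of motif classes that contributed
it. Composition statistics (nodes by role, edges by type) are exact
counts, independent of insertion order.

## Hub ranking — maximal clique centrality

MCC(v) = Σ (|C| − 1)! over the maximal cliques C containing v, computed
on the simple undirected projection of the typed network (any directed
edge in either direction yields one undirected edge; types are ignored
for centrality). When a node's neighbourhood is edgeless the score
equals its degree; dense local structure is rewarded factorially, which
is what makes MCC effective at flagging essential regulators. Maximal
cliques come from networkx's Bron–Kerbosch implementation with
pivoting; factorials use exact integer arithmetic. Isolated nodes
score 0 (the singleton "clique" is not counted). Ranking ties break
lexicographically on node id, and a tie straddling the top-k cut is
reported as a warning since the hub set is then not determined by the
score alone.

## Module detection — Markov clustering

MCL alternates expansion (squaring the column-stochastic transition
matrix) and inflation (entrywise power r with column renormalization)
until the matrix stops changing. Conventions: unit edge weights on the
undirected projection, self-loops of weight 1 added before
normalization (standard practice; damps odd-cycle oscillation),
expansion e = 2, inflation r = 2.0, entries below 1e−5 pruned each
iteration, convergence when the largest entry change drops below 1e−6,
at most 100 iterations (non-convergence returns the current clustering
with a flag — not observed on networks of this scale). Clusters are
read off attractor rows of the converged matrix; identical supports
merge, and in the rare case of overlapping supports a node joins the
first cluster in sorted order, with the overlap logged. Modules with
fewer than 3 nodes are moved to an explicit `unassigned` set rather
than silently dropped. The dense-matrix implementation is adequate for
regulatory networks of this scale (tens to hundreds of nodes).

## Edge validation against independent expression

Each TF→gene edge of the queried network is tested for co-expression in
an independent matrix: sample Pearson r over pairwise-complete
observations, two-sided P from t = r·√((n−2)/(1−r²)) on n−2 degrees of
freedom (|r| = 1 → P = 0 by convention), and Benjamini–Hochberg FDR
computed across the network's testable edges — the family is
per-network, matching the headline "verified out of all TF–gene edges"
accounting. Verified ⇔ |r| > 0.3 ∧ P < 0.05 ∧ q < 0.1 (all three
gates, as stated conjunctively by the reference analysis). Edges whose
endpoints are missing from the matrix, have fewer than 3 complete
pairs, or constant vectors are *untestable*: reported, and counted in
the denominator of the verified fraction so the headline number stays
well-defined.

Cross-species matching (human network symbols vs mouse arrays) defaults
to case-insensitive symbol identity, overridable by an explicit
two-column ortholog map. Probe-level matrices are collapsed one row
per gene; the default `max_mean` rule keeps the probe with the highest
mean expression (the usual best-responding-probe choice), with
`mean`/`median` alternatives. Both the collapsing rule and the
ortholog mapping are declared sources of tolerance around any published
verified fraction, since reference analyses rarely state them.

## Enrichment

Over-representation uses the plain hypergeometric upper tail
P(X ≥ k) for k query hits in a K-member set, query size n, universe N
(scipy's log-space survival function; exactness is tested against
direct combinatorial enumeration for N ≤ 25), with BH adjustment across
all tested sets and a default significance level of FDR < 0.05. No
EASE-style shrinkage is applied. The background defaults to the union
of all GMT members — web enrichment services use tool-internal
universes that cannot be replicated, so the choice is surfaced and
overridable rather than hidden. Hub-target enrichment queries each hub
regulator's direct target set; gene hubs (no outgoing regulation) are
skipped.

## Pathway-seeded subnetworks

All FFLs whose joint-target gene is in the seed list are merged and
split into connected components of the undirected projection, ordered
by smallest node id. Seed matching is restricted to the gene slot by
default (the seeds are pathway *genes*); `match_slot="any"` relaxes
this to regulator slots. The reported "subnetworks" are exactly these
components — no further splitting rule.

## Synthetic data: what it emulates, what it does not

The generator emulates the reference study's input structure. Defaults
are the study's scale: universes of 27 TFs, 18 miRNAs, 127 genes;
planted FFL counts A = 71, B = 50, C = 7; background regulation rates
equal to the published pair counts divided by the number of possible
kind-consistent pairs of each type (671/3429 TF–gene, 76/486 TF–miRNA,
77/2286 miRNA–gene, 21/486 miRNA–TF); expression with n = 35 samples,
planted correlation ρ = 0.9 on a fraction 57/88 ≈ 0.648 of TF→gene
edges, values on a log-like scale 8 + noise.

Planting guarantees: each planted loop consumes a (TF, miRNA) regulator
pair exclusive to its motif class (a pair may host several loops of one
class via different genes), and background TF↔miRNA edges are never
drawn on a planted regulator pair in either direction — otherwise a
background edge could silently reclassify a planted A/B loop as C.
Hence enumeration recovers the planted counts exactly at background
rate 0 and at least the planted counts otherwise. Capacity is checked
up front (needed regulator pairs vs available ones). Expression
planting draws each correlated gene as ρ·z_TF + √(1−ρ²)·ε; when a gene
carries several selected edges only the first in deterministic order is
planted, so planted correlations never interfere — a deliberate
simplification, which also means the realized planted-edge count can be
below the requested fraction when targets are shared. One global seed
drives a named substream per artifact (tables vs expression), so
regenerating one artifact does not perturb the other.

Not emulated: promoter sequences or binding-site scores, miRNA seed
matches, expression mean/variance structure of real arrays, batch or
developmental-stage effects, and correlated TF–TF programs. Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under clean conditions, not robustness to real-array
artefacts.

## Problem sizes and numerical choices

Test-suite simulations use small universes (≤ 30 genes) and the two
calibration designs the validation statistics call for: 1000
independent planted edges at ρ = 0.9, n = 35 for power (checked against
the analytic Fisher-z approximation within ±5 points) and 100 null
edges × 100 seeds for the false-verification rate. The acceptance
script runs the full default study conditions (a few hundred nodes) and
completes in seconds. Tolerances: MCL stochasticity 1e−9 per column;
BH q-values compared to the textbook step-up at 1e−12; hypergeometric
p at relative 1e−10.

## Known limitations

- MCL is dense-matrix; fine for hundreds of nodes, not for
  genome-scale graphs.
- The ortholog heuristic (case-insensitive symbol identity) is a crude
  stand-in for a curated homology map and will mis-pair the minority of
  symbols that differ between species beyond casing.
- Enrichment results depend strongly on the chosen background; the
  default (union of GMT members) is conservative and should be replaced
  by the assayed-gene universe when available.
- The validation rule tests co-expression only; it cannot distinguish
  activation from repression, and a verified edge is correlational
  evidence, not mechanism.
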