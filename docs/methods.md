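# Methods

This note documents the models, conventions and numerical choices behind
`phagenet`, in the order of the analysis pipeline.

## The incidence matrix and its conventions

The central object is a binary host × phage matrix *A* with rows = bacterial
strains and columns = phage isolates; *A*<sub>hp</sub> = 1 records a
productive infection (single plaques). The orientation is fixed internally
(rows-hosts) to avoid silent transposition; display conventions elsewhere
may transpose. Input cells may also carry the value 2 for "lysis from
without" — a bacteriolytic clearing without productive infection — which is
coerced to 0 on ingest, since it is observed and reported but is not an
infection.

Derived scalars: fill *I* (number of ones), size *M* = n<sub>hosts</sub> ×
n<sub>phages</sub>, connectance *C* = *I*/*M* (identical to density). All
standard deviations in the package use the sample (n−1) denominator. The
bipartite diameter is the longest shortest path on the largest connected
component of the host∪phage graph; isolated nodes are ignored (degenerate
components carry no path information).

Phages indistinguishable on the panel — bitwise-identical columns — are
collapsed to one representative each (first-seen column, so the operation is
deterministic and order-stable); the cluster map retains all members and
re-expands losslessly. Phage-resistant hosts (all-zero rows) are removed
before structure analysis. This removal preserves *I*, every per-phage
degree and Barber's Q (zero-degree rows contribute nothing to Q), but it
*does* change NODF: all-zero rows form zero-scoring pairs that count in the
NODF denominator, so dropping them generally raises NODF. NODF values are
therefore always quoted for the reduced (permissive-host) matrix.

## NODF

For every unordered pair of rows (and of columns), order the pair by fill.
If fill(i) > fill(j) > 0, the pair scores 100 × |shared ones| / fill(j);
pairs with equal fills, or with an empty member, score 0. NODF is the mean
score over all n(n−1)/2 row pairs plus m(m−1)/2 column pairs, on the 0–100
scale (the scale on which results are conventionally printed). The strict
decreasing-fill condition makes the metric invariant under row/column
permutation, which the test suite checks against a literal brute-force
enumeration. An all-zero matrix is defined as NODF 0 with a warning.

## Barber bipartite modularity and LP-BRIM

Barber's modularity for a joint partition (g, h) of rows and columns is

    Q = (1/I) Σ_ij [A_ij − k_i d_j / I] δ(g_i, h_j)

with k, d the row/column degrees. Q of the all-in-one partition is exactly
0 for every matrix; −1 ≤ Q ≤ 1.

The optimizer is restarted LP-BRIM:

- **Seeding.** Even restarts use label propagation: every column starts
  with a unique random label (a seeded permutation), then rows and columns
  alternately adopt the majority label of their neighbours (synchronous
  within a side; ties toward the smallest label id). Odd restarts seed the
  columns with a uniformly random assignment to K modules, K drawn
  uniformly between 2 and min(n, m). The second family exists because pure
  label propagation can collapse to a single label on small or dense
  matrices, and BRIM sweeps can only merge modules, never split them; mixed
  seeding keeps module-count diversity in the restart population.
- **Refinement.** BRIM sweeps: reassign every row to the module maximizing
  its Q contribution given the column labels (ties to the smallest module
  id), then every column given the row labels. Each half-sweep is exact
  coordinate ascent, so Q is non-decreasing; iteration stops when the
  improvement falls below 10⁻¹².
- **Selection.** Best Q over restarts; exact ties broken toward fewer
  modules, then the earlier restart. Results are bit-reproducible given
  (matrix, n_restarts, seed). Empty modules are pruned and ids relabelled
  contiguously.

On 4×4 matrices the optimizer reproduces the exhaustive maximum over all
joint partitions (tested); on planted-block matrices at the study scale
(60×94, 4 modules, p_in = 0.5, p_out = 0.02) it recovers the planted labels
with adjusted Rand index 1.0 across seeds. The default of 100 restarts is
configurable.

## Fixed-fill null model

The r00 null model preserves only the dimensions and the fill: each draw
places I ones uniformly at random without replacement among the M cells.
Significance is one-sided (statistic assumed greater than simulated) with
the add-one convention p = (#{null ≥ observed} + 1)/(n_sim + 1); with the
default 100 simulations the smallest attainable p is 1/101 = 0.0099. The
z-score uses the sample (n−1) sd of the null values and is reported as NaN
when that sd is zero (e.g. for statistics conserved by r00, such as the
fill itself). The null 95th percentile uses linear interpolation between
order statistics, a convention that must be stated because none is implied
by the percentile itself. One seeded RNG stream drives all draws, so the
entire test is reproducible from a single seed.

## Host projection statistics

The one-mode projection has permissive hosts as nodes and edge weight
w(u, v) = number of phages infecting both u and v (the handshake identity
Σ w = Σ_p C(k_p, 2) is property-tested). Shared-phage means are taken over
*all* H(H−1)/2 host pairs with zero-weight pairs contributing zero — an
explicit convention, since omitting unconnected pairs would inflate every
stratum mean. Strata: same/different species, species group and biome
(plus named biome combinations), and resistance pairing with "drug-
resistant" pooling the resistant and MDR classes. Neighbor counts are graph
degrees, optionally filtered by a predicate on the focal and neighbor
records (e.g. drug-susceptible neighbors of drug-resistant hosts);
species-neighbor counts tally distinct species among neighbors. The
species-level network weights an edge by the number of *distinct* phages
infecting at least one strain of each species (strain-pair-summed weighting
is available behind a flag); edges above 20 shared phages are flagged.

The rank-sum test reports W = (sum of midranks of sample 1) − n₁(n₁+1)/2,
so 0 ≤ W ≤ n₁n₂. The p-value is exact wherever exactness is affordable:
the tie-free exact distribution for samples under 50 observations each, or
full enumeration of rank assignments (midranks, so ties are handled) for
pooled sizes up to 12 — the normal approximation with tie-corrected
variance and 0.5 continuity correction is accurate only asymptotically and
can err by several tenths at such sizes. Larger samples (the study-scale
case, with thousands of pairs) use that normal approximation. Degenerate
pooled samples (all values equal) return p = 1 with a flag.

## Dice phylogenomics

Protein hits (native 8-column dialect, or converted from 12-column
BLAST/DIAMOND outfmt-6 plus a protein→genome map; aligner execution is out
of scope) are filtered by identity ≥ 30%, bitscore ≥ 30, alignment length
≥ 30 aa, e-value ≤ 0.01. The genome distance is D_AB = 1 − 2·AB/(AA+BB)
over bitscore sums of all valid matches — multiple HSPs per protein pair
are summed by default, matching the "all valid matches" definition, with a
best-hit-only mode behind a flag. D_AB and D_BA share a denominator and
differ only through search asymmetries; the matrix is symmetrized by
averaging (neighbor joining requires symmetry), clamped to [0, 1] with a
warning when clamping occurs, and the directed values are recoverable from
the inputs. D is a pseudo-distance: the triangle inequality is not
guaranteed and is not asserted.

Neighbor joining is the canonical Saitou–Nei algorithm: join the pair
minimizing Q_ij = (r−2)d_ij − R_i − R_j, limb lengths from the standard
formulas, distance updates d(k, new) = (d_ik + d_jk − d_ij)/2, the final
three clades resolved by the three-leaf closed form. Ties in the Q
criterion (within 10⁻¹²) are broken toward the lexicographically smallest
pair of clade keys (smallest leaf name per clade), making the topology
deterministic. Negative limb lengths — possible for non-additive input —
are clamped to 0 with a warning. NJ exactly inverts additive matrices
(property-tested on random 4–8-taxon trees, and cross-checked against
scikit-bio's implementation). Newick serialization writes branch lengths at
6 significant digits and quotes reserved characters; round-tripping is
verified against an independent parser.

## Encapsidation frequency

With A = marker copies per ng of encapsidated DNA (replicate mean), the
genome copy number per ng is B = m·N_A/M_r where m = 10⁻⁹ g (the printed
formula's "1 ng × 10⁹" factor is dimensionally readable only as mass in
grams), N_A = 6.02214076 × 10²³ mol⁻¹ and M_r = genome_bp × 650 g/mol
(the 650 vs 660 Da/bp convention shifts B by ~1.5%; 650 is used and
documented). Capsid capacity C = genome_bp/plasmid_bp is kept as an exact
ratio — the definition is a plain quotient — with a floor mode for
sensitivity analysis. EF = A/(B·C) estimates the fraction of virions
carrying the marker; 1/EF is reported as "one transducing particle per N
phages" when EF > 0. EF is linear in A and independent of the mass basis
(A and B are both per ng). EF > 1 is physically implausible and flagged but
returned. Downstream transduction efficiency (delivery and expression in a
recipient) is explicitly out of scope.

## Synthetic generators

The generators emulate the statistical structure the pipeline assumes, not
real biology:

- **Incidence matrices.** `nested` draws host permissiveness ranks and
  phage breadths (binomial with mean fill × n_hosts, clamped ≥ 1) and sets
  a cell iff rank ≤ breadth, giving subset-structured host ranges; a
  noise-free square matrix uses permutation breadths and is a strict
  staircase (NODF exactly 100). `modular` plants balanced bipartite blocks
  with within/between probabilities p_in/p_out; `mixed` nests the fill
  inside blocks; `random` is Bernoulli. Noise flips each cell
  independently. Defaults target the study panel's marginals: 123 hosts ×
  94 phages at connectance ≈ 0.098, with resistant (all-zero) hosts arising
  naturally from the rank/breadth construction.
- **Metadata.** Host species are drawn from a 29-species staphylococcal
  table spanning the six multilocus species groups, with coagulase type
  fixed per species; biomes use the panel weights 40/53/23
  (human/veterinary/environmental) and resistance 40/48/35
  (susceptible/resistant/MDR). Phage origins use weights 80/8/6
  (inlet/outlet/induced) and morphologies 29/11 (myo/sipho); genome lengths
  are drawn per morphology class (myoviruses 128–145 kb, cluster C; induced
  siphoviruses 42–45 kb, cluster B; free siphoviruses 86–92 kb, cluster D).
- **Hit tables.** Genomes in blocks with fixed self-scores AA and
  cross-scores near the within/between level under multiplicative lognormal
  jitter, emitted as valid filtered-dialect rows; with zero jitter,
  intra-block D = 0 and (at between = 0) inter-block D = 1 exactly.
- **qPCR.** A = EF·B·C × a unit-mean lognormal multiplier with coefficient
  of variation `cv` (copy numbers span orders of magnitude, so the error
  model is multiplicative); cv = 0 recovers EF exactly.

What passing tests on synthetic data do **not** show: real panels have
phylogenetically correlated host ranges (species sit in modules because
receptors are conserved), assay noise that is not i.i.d. cell flips, and
metadata correlated with network position; the generators draw metadata
independently of the matrix. Synthetic results validate the *computations*,
not ecological conclusions.

## Problem sizes and known limitations

Simulation-based tests run at the study scale (60×94 matrices, 100 null
draws, 100 optimizer restarts, 10–20 seeds), which keeps the full suite
around ten seconds while exercising every code path at realistic size.
Exhaustive oracles (partition enumeration, rank-assignment enumeration,
brute-force NODF) are restricted to the small sizes where enumeration is
exact by construction.

Limitations: only the r00 null model is implemented (the interface accepts
a model name for future degree-preserving variants); LP-BRIM is a
stochastic local optimizer and Q values on empirical matrices are expected
to be reproducible only approximately across implementations; no weighted
NODF or matrix-temperature metrics; no ANI computation or tree rendering;
trees are unrooted and drawn rooted at the final trifurcation purely for
serialization.
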