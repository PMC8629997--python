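# phagenet

Analysis of phage–bacteria infection networks. `phagenet` takes a binary
host × phage incidence matrix — rows are bacterial strains, columns are
phage isolates, a 1 means the phage forms single plaques on the strain —
and quantifies its structure and its consequences for phage-mediated gene
flow:

- **Matrix handling** (`matrix_core`): TSV/CSV ingest with controlled-vocabulary
  host/phage metadata (species and multilocus species group, coagulase type,
  biome, resistance phenotype; origin, morphology, genome length),
  de-duplication of phages with identical host ranges, removal of
  phage-resistant hosts, and descriptive statistics (fill *I*, size *M*,
  connectance *C = I/M*, degree distributions, bipartite diameter,
  species-tendency and biome-span classification of host ranges).
- **Nestedness** (`nestedness`): NODF on the 0–100 scale. For each pair of
  rows (and columns) with strictly decreasing, non-zero fills the pair scores
  100 × |overlap| / (smaller fill); NODF is the mean over all pairs.
- **Bipartite modularity** (`modularity`): Barber's
  *Q* = (1/*I*) Σ<sub>ij</sub> [*A*<sub>ij</sub> − *k*<sub>i</sub>*d*<sub>j</sub>/*I*] δ(*g*<sub>i</sub>, *h*<sub>j</sub>),
  maximized by restarted LP-BRIM (label-propagation seeding + alternating
  best-response BRIM sweeps).
- **Null models** (`null_models`): fixed-fill *r00* randomization (dimensions
  and *I* preserved, positions uniform) with one-sided add-one p-values,
  *p* = (#{null ≥ observed} + 1)/(*n*<sub>sim</sub> + 1), z-scores and the
  null 95th percentile.
- **Host projection** (`projection_stats`): one-mode host graph with edge
  weight = number of shared phages; pair statistics stratified by species,
  species group, biome and resistance pairing (zero-weight pairs included in
  all means), filtered neighbor counts, a species-level shared-phage network,
  and a two-sided Wilcoxon rank-sum test.
- **Phylogenomics** (`phylogenomics`): Dice genome distances
  *D*<sub>AB</sub> = 1 − 2·AB/(AA + BB) from bitscore sums of validity-filtered
  all-vs-all protein hits (identity ≥ 30%, bitscore ≥ 30, length ≥ 30 aa,
  e-value ≤ 0.01), Saitou–Nei neighbor joining and newick output.
- **Encapsidation** (`encapsidation`): transducing-particle frequency
  EF = *A*/(*B*·*C*) from qPCR marker copies per ng (*A*), genome copies per
  ng (*B* = 10⁻⁹ g · N<sub>A</sub> / (genome_bp · 650 g/mol)) and capsid
  capacity in plasmid copies (*C* = genome_bp/plasmid_bp).
- **Synthetic data** (`synthetic_data`): seeded generators for nested,
  modular and mixed incidence matrices with panel-like metadata,
  block-structured protein hit tables and noisy qPCR replicates, so every
  stage runs without external data.

The package is aimed at microbial ecologists and phage biologists who assay
host ranges on strain panels (here: staphylococci and their wastewater
phages) and want the network statistics behind statements such as "the
matrix is significantly more nested than random" or "each drug-resistant
host shares phages with *n* drug-susceptible neighbors".

## Worked example

`examples/01_network_structure.py` generates a 123 × 94 panel with four
planted modules, drops phage-resistant hosts and measures structure:

```text
panel: IncidenceMatrix(123 hosts x 94 phages, I=1296, C=0.112)
dropped 35 phage-resistant hosts -> IncidenceMatrix(88 hosts x 94 phages, I=1296, C=0.157)
mean infections per permissive strain: 14.7 +- 9.3
bipartite diameter: 8
NODF = 21.34 (null 16.57 +- 0.31, z = 15.54, p = 0.0099)
Barber Q = 0.74 with 4 modules; 1.4% of interactions cross modules
```

Reading the numbers: connectance 0.112 means ~11% of all host–phage
combinations are productive infections. NODF 21.34 sits well above the
fixed-fill null mean 16.57 (z = 15.54), and *p* = 0.0099 = 1/101 is the
smallest p-value resolvable with 100 simulations — the matrix is
significantly more nested than random even though, in absolute terms, the
nesting is far from a perfect staircase (NODF 100). The optimizer recovers
the four planted modules with only 1.4% of infections crossing module
boundaries. The other examples cover the host projection and rank-sum
comparisons (`02`), Dice/NJ phylogenomics (`03`) and encapsidation
frequencies (`04`).

A thin CLI mirrors the library for shell use:

```bash
phagenet simulate --structure nested --seed 1 --out demo/
phagenet nodf demo/matrix.tsv --drop-empty-hosts --json
phagenet brim demo/matrix.tsv --restarts 100 --seed 42 --out partition.tsv
phagenet nulltest demo/matrix.tsv --stat nodf --nsim 100 --seed 7
```

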