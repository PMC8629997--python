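"""Seeded generators for synthetic study inputs.

Every stage of the pipeline can run without downloads: this module emits
incidence matrices with planted nested/modular structure and panel-like
metadata, block-structured all-vs-all protein hit tables, and noisy qPCR
marker copy counts. Defaults emulate the scale of the wastewater study
design: a 123-host x 94-phage panel at connectance ~0.1 with roughly half
the hosts phage-resistant, 29 staphylococcal species in six multilocus
species groups, biome weights 40/53/23 (human/veterinary/environmental) and
resistance weights 40/48/35 (susceptible/resistant/MDR). All generators are
bit-reproducible under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encapsidation import genome_copies_per_ng
from .matrix_core import HostRecord, IncidenceMatrix, PhageRecord

__all__ = ["MatrixSpec", "gen_incidence", "gen_hits", "gen_qpcr", "DEFAULT_SPECIES"]

# species -> (multilocus species group, coagulase type); 29 staphylococci
DEFAULT_SPECIES: dict[str, tuple[str, str]] = {
    "S. aureus": ("Epidermidis-Aureus", "CoPS"),
    "S. epidermidis": ("Epidermidis-Aureus", "CoNS"),
    "S. capitis": ("Epidermidis-Aureus", "CoNS"),
    "S. caprae": ("Epidermidis-Aureus", "CoNS"),
    "S. haemolyticus": ("Epidermidis-Aureus", "CoNS"),
    "S. hominis": ("Epidermidis-Aureus", "CoNS"),
    "S. lugdunensis": ("Epidermidis-Aureus", "CoNS"),
    "S. warneri": ("Epidermidis-Aureus", "CoNS"),
    "S. pasteuri": ("Epidermidis-Aureus", "CoNS"),
    "S. saccharolyticus": ("Epidermidis-Aureus", "CoNS"),
    "S. hyicus": ("Hyicus-Intermedius", "CoPS"),
    "S. agnetis": ("Hyicus-Intermedius", "CoPS"),
    "S. chromogenes": ("Hyicus-Intermedius", "CoNS"),
    "S. pseudintermedius": ("Hyicus-Intermedius", "CoPS"),
    "S. schleiferi": ("Hyicus-Intermedius", "CoPS"),
    "S. delphini": ("Hyicus-Intermedius", "CoPS"),
    "S. saprophyticus": ("Saprophyticus", "CoNS"),
    "S. xylosus": ("Saprophyticus", "CoNS"),
    "S. equorum": ("Saprophyticus", "CoNS"),
    "S. succinus": ("Saprophyticus", "CoNS"),
    "S. arlettae": ("Saprophyticus", "CoNS"),
    "S. cohnii": ("Saprophyticus", "CoNS"),
    "S. sciuri": ("Sciuri", "CoNS"),
    "S. lentus": ("Sciuri", "CoNS"),
    "S. vitulinus": ("Sciuri", "CoNS"),
    "S. fleurettii": ("Sciuri", "CoNS"),
    "S. simulans": ("Simulans", "CoNS"),
    "S. carnosus": ("Simulans", "CoNS"),
    "S. auricularis": ("Auricularis", "CoNS"),
}

_BIOME_WEIGHTS = {"human": 40, "veterinary": 53, "environmental": 23}
_RESISTANCE_WEIGHTS = {"susceptible": 40, "resistant": 48, "MDR": 35}
_ORIGIN_WEIGHTS = {"inlet": 80, "outlet": 8, "induced": 6}
_MORPHOLOGY_WEIGHTS = {"myovirus": 29, "siphovirus": 11}


@dataclass
class MatrixSpec:
    """Parameters of a synthetic incidence matrix.

    ``structure``: ``random`` (Bernoulli fill), ``nested`` (host
    permissiveness ranks vs phage breadths), ``modular`` (planted bipartite
    blocks with within/between probabilities p_in/p_out), or ``mixed``
    (nested fill inside planted blocks). ``noise`` flips each cell
    independently after construction.
    """

    n_hosts: int = 123
    n_phages: int = 94
    structure: str = "nested"
    fill: float = 0.098
    n_modules: int = 4
    p_in: float = 0.3
    p_out: float = 0.03
    noise: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("fill", "p_in", "p_out", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.fill < 1.0:
            raise ValueError("fill must lie strictly in (0, 1)")
        if self.structure not in ("random", "nested", "modular", "mixed"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure in ("modular", "mixed"):
            if self.p_in <= self.p_out:
                raise ValueError("planted modular signal requires p_in > p_out")
            if self.n_modules < 1 or self.n_modules > min(self.n_hosts, self.n_phages):
                raise ValueError("infeasible n_modules for the matrix shape")


def _nested_block(
    n_hosts: int, n_phages: int, fill: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Perfectly nested block: host permissiveness ranks vs phage breadths.

    Cell (h, p) = 1 iff the host's rank <= the phage's breadth, so host
    ranges are subsets of each other by construction. When the block is
    square and noise-free, breadths are a permutation of 1..n, making all
    marginals distinct (a strict staircase)."""
    ranks = rng.permutation(n_hosts) + 1
    if noise == 0.0 and n_hosts == n_phages:
        breadth = rng.permutation(n_hosts) + 1
    else:
        breadth = np.clip(rng.binomial(n_hosts, fill, size=n_phages), 1, n_hosts)
    return (ranks[:, None] <= breadth[None, :]).astype(np.int8)


def _apply_noise(a: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    if noise <= 0:
        return a
    flips = rng.random(a.shape) < noise
    return np.where(flips, 1 - a, a).astype(np.int8)


def _block_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced random assignment of n items to k blocks."""
    labels = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    return labels[rng.permutation(n)]


def gen_incidence(
    spec: MatrixSpec,
) -> tuple[IncidenceMatrix, list[HostRecord], list[PhageRecord]]:
    """Generate an incidence matrix plus panel-like host/phage metadata.

    Host species are drawn from :data:`DEFAULT_SPECIES` (every species
    appears at least once when the panel is large enough); biomes and
    resistance phenotypes follow the study-panel weights. Phage morphology
    determines the genome-length range (myoviruses 128-145 kb, cluster C;
    induced siphoviruses 42-45 kb, cluster B; free siphoviruses 86-92 kb,
    cluster D).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_hosts, spec.n_phages
    planted_rows = planted_cols = None
    if spec.structure == "random":
        a = (rng.random((n, m)) < spec.fill).astype(np.int8)
    elif spec.structure == "nested":
        a = _nested_block(n, m, spec.fill, spec.noise, rng)
    else:
        planted_rows = _block_labels(n, spec.n_modules, rng)
        planted_cols = _block_labels(m, spec.n_modules, rng)
        same = planted_rows[:, None] == planted_cols[None, :]
        if spec.structure == "modular":
            p = np.where(same, spec.p_in, spec.p_out)
            a = (rng.random((n, m)) < p).astype(np.int8)
        else:  # mixed: nested fill inside blocks, Bernoulli background
            a = (rng.random((n, m)) < spec.p_out).astype(np.int8)
            for b in range(spec.n_modules):
                ri = np.flatnonzero(planted_rows == b)
                ci = np.flatnonzero(planted_cols == b)
                if ri.size and ci.size:
                    block = _nested_block(ri.size, ci.size, spec.p_in, spec.noise, rng)
                    a[np.ix_(ri, ci)] = block
    a = _apply_noise(a, spec.noise, rng)

    host_ids = [f"H{i:03d}" for i in range(1, n + 1)]
    phage_ids = [f"PG-2021_{j}" for j in range(1, m + 1)]
    matrix = IncidenceMatrix(a, host_ids, phage_ids)

    species_pool = list(DEFAULT_SPECIES)
    # cover every species once, then sample the rest
    assigned = species_pool[: min(n, len(species_pool))]
    if n > len(assigned):
        assigned = assigned + list(rng.choice(species_pool, size=n - len(assigned)))
    assigned = [assigned[i] for i in rng.permutation(n)]

    biomes = list(_BIOME_WEIGHTS)
    bw = np.array(list(_BIOME_WEIGHTS.values()), dtype=float)
    resist = list(_RESISTANCE_WEIGHTS)
    rw = np.array(list(_RESISTANCE_WEIGHTS.values()), dtype=float)
    hosts = [
        HostRecord(
            host_id=hid,
            species=sp,
            species_group=DEFAULT_SPECIES[sp][0],
            coagulase=DEFAULT_SPECIES[sp][1],
            biome=str(rng.choice(biomes, p=bw / bw.sum())),
            resistance=str(rng.choice(resist, p=rw / rw.sum())),
        )
        for hid, sp in zip(host_ids, assigned)
    ]

    origins = list(_ORIGIN_WEIGHTS)
    ow = np.array(list(_ORIGIN_WEIGHTS.values()), dtype=float)
    morphs = list(_MORPHOLOGY_WEIGHTS)
    mw = np.array(list(_MORPHOLOGY_WEIGHTS.values()), dtype=float)
    phages = []
    for pid in phage_ids:
        origin = str(rng.choice(origins, p=ow / ow.sum()))
        morph = str(rng.choice(morphs, p=mw / mw.sum()))
        if morph == "myovirus":
            length = int(rng.integers(128_300, 145_100))
            cluster = "C"
        elif origin == "induced":
            length = int(rng.integers(42_200, 44_500))
            cluster = "B"
        else:
            length = int(rng.integers(85_800, 92_200))
            cluster = "D"
        phages.append(
            PhageRecord(
                phage_id=pid,
                origin=origin,
                morphology=morph,
                genome_length=length,
                cluster=cluster,
            )
        )
    matrix.planted_row_labels = planted_rows
    matrix.planted_col_labels = planted_cols
    return matrix, hosts, phages


def gen_hits(
    block_sizes: list[int],
    within_score: float = 1000.0,
    between_score: float = 100.0,
    jitter: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Block-structured all-vs-all protein hit table.

    Genomes fall into blocks; self-comparison sums AA are fixed at
    ``within_score``, cross-genome sums are drawn near ``within_score``
    (same block) or ``between_score`` (different block) with multiplicative
    lognormal jitter. Rows are emitted in the native filtered-format dialect
    and pass the default validity thresholds. With jitter 0, intra-block
    Dice distances are exactly 0 and (with between_score 0) inter-block
    distances exactly 1.
    """
    if within_score < 0 or between_score < 0 or jitter < 0:
        raise ValueError("scores and jitter must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    genomes = [f"genome_{i:02d}" for i in range(labels.size)]
    sigma = np.sqrt(np.log1p(jitter**2)) if jitter > 0 else 0.0
    rows = []
    for i, gi in enumerate(genomes):
        for j, gj in enumerate(genomes):
            if i == j:
                score = within_score
            else:
                base = within_score if labels[i] == labels[j] else between_score
                mult = rng.lognormal(-sigma**2 / 2, sigma) if sigma else 1.0
                score = base * mult
            if score <= 0:
                continue
            rows.append(
                {
                    "query_genome": gi,
                    "subject_genome": gj,
                    "query_protein": f"{gi}_p1",
                    "subject_protein": f"{gj}_p1",
                    "pct_identity": 90.0,
                    "align_len": 300,
                    "bitscore": score,
                    "evalue": 1e-30,
                }
            )
    return pd.DataFrame(rows)


def gen_qpcr(
    true_EF: float,
    genome_bp: int = 43_039,
    plasmid_bp: int = 3_830,
    cv: float = 0.2,
    n_replicates: int = 3,
    seed: int | None = None,
    phage_id: str = "PG-2021_sim",
    morphology: str = "siphovirus",
) -> pd.DataFrame:
    """Replicate qPCR marker copy numbers for a known encapsidation
    frequency: A = EF x B x C x lognormal multiplier with unit mean and
    coefficient of variation ``cv`` (copy numbers span orders of magnitude,
    so the error model is multiplicative). cv = 0 recovers EF exactly."""
    if not 0.0 <= true_EF <= 1.0:
        raise ValueError("true_EF must lie in [0, 1]")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    b = genome_copies_per_ng(genome_bp)
    c = genome_bp / plasmid_bp
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    rows = []
    for rep in range(1, n_replicates + 1):
        mult = rng.lognormal(-sigma**2 / 2, sigma) if sigma else 1.0
        rows.append(
            {
                "phage_id": phage_id,
                "replicate": rep,
                "A_copies_per_ng": true_EF * b * c * mult,
                "genome_bp": genome_bp,
                "plasmid_bp": plasmid_bp,
                "morphology": morphology,
            }
        )
    return pd.DataFrame(rows)
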