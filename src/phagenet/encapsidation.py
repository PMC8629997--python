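"""Transducing-particle (encapsidation) frequency estimation from qPCR
marker copy numbers.

A phage propagated on a donor strain carrying a small marker plasmid can
package plasmid DNA instead of its own genome. From the qPCR-measured
marker copies per nanogram of encapsidated DNA (A), the number of phage
genome copies per nanogram (B) and the number of plasmid copies that fit in
one capsid (C = genome length / plasmid length, assuming transducing
particles carry plasmid multimers filling the capsid), the encapsidation
frequency is

    EF = A / (B * C),        B = mass_g * N_A / (genome_bp * 650 g/mol)

with N_A Avogadro's number and 650 Da the average mass of a base pair.
EF estimates the fraction of virions that are transducing particles;
1/EF is the "one transducing particle per N phages" form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "DALTON_PER_BP",
    "EncapsidationInput",
    "EncapsidationResult",
    "genome_copies_per_ng",
    "encapsidation_frequency",
    "encapsidation_table",
    "morphology_summary",
]

AVOGADRO = 6.02214076e23  # 1/mol
DALTON_PER_BP = 650.0  # g/mol per base pair of dsDNA


@dataclass(frozen=True)
class EncapsidationInput:
    phage_id: str
    A: float  # marker copies per ng of encapsidated DNA (replicate mean)
    genome_bp: int
    plasmid_bp: int
    mass_ng: float = 1.0
    morphology: str = "unknown"

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("marker copy number A must be >= 0")
        if not (self.genome_bp > self.plasmid_bp > 0):
            raise ValueError("require genome_bp > plasmid_bp > 0")


@dataclass(frozen=True)
class EncapsidationResult:
    phage_id: str
    B: float  # phage genome copies per ng
    C: float  # plasmid copies per capsid equivalent
    Mr: float  # genome molar mass, g/mol
    EF: float
    one_in_N: float | None  # 1/EF, None when EF == 0
    implausible: bool  # EF > 1: more marker copies than capsid capacity


def genome_copies_per_ng(genome_bp: int, mass_ng: float = 1.0) -> float:
    """Number of genome copies in ``mass_ng`` ng of DNA of length
    ``genome_bp``: mass in grams times Avogadro over the molar mass
    genome_bp x 650 g/mol."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    mr = genome_bp * DALTON_PER_BP
    return mass_ng * 1e-9 * AVOGADRO / mr


def encapsidation_frequency(
    inp: EncapsidationInput, floor_capacity: bool = False
) -> EncapsidationResult:
    """EF = A / (B x C) for one phage sample.

    C is the exact genome/plasmid length ratio by default;
    ``floor_capacity`` floors it to whole plasmid copies (sensitivity
    analysis). EF > 1 is physically implausible and flagged but returned.
    """
    b = genome_copies_per_ng(inp.genome_bp, inp.mass_ng)
    c = inp.genome_bp / inp.plasmid_bp
    if floor_capacity:
        c = float(math.floor(c))
    # A is measured per ng too, so EF is independent of the mass basis
    a = inp.A * inp.mass_ng
    ef = a / (b * c)
    return EncapsidationResult(
        phage_id=inp.phage_id,
        B=b,
        C=c,
        Mr=inp.genome_bp * DALTON_PER_BP,
        EF=ef,
        one_in_N=(1.0 / ef) if ef > 0 else None,
        implausible=ef > 1.0,
    )


def encapsidation_table(df: pd.DataFrame, floor_capacity: bool = False) -> pd.DataFrame:
    """Batch EF computation from a table with columns phage_id,
    A_copies_per_ng, genome_bp, plasmid_bp and optionally morphology.
    Replicate rows per phage are averaged on A first."""
    required = {"phage_id", "A_copies_per_ng", "genome_bp", "plasmid_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"encapsidation table missing columns: {sorted(missing)}")
    agg = {
        "A_copies_per_ng": "mean",
        "genome_bp": "first",
        "plasmid_bp": "first",
    }
    if "morphology" in df.columns:
        agg["morphology"] = "first"
    grouped = df.groupby("phage_id", sort=False).agg(agg).reset_index()
    rows = []
    for r in grouped.itertuples():
        res = encapsidation_frequency(
            EncapsidationInput(
                phage_id=r.phage_id,
                A=float(r.A_copies_per_ng),
                genome_bp=int(r.genome_bp),
                plasmid_bp=int(r.plasmid_bp),
                morphology=getattr(r, "morphology", "unknown"),
            ),
            floor_capacity=floor_capacity,
        )
        rows.append(
            {
                "phage_id": res.phage_id,
                "morphology": getattr(r, "morphology", "unknown"),
                "B": res.B,
                "C": res.C,
                "EF": res.EF,
                "one_in_N": res.one_in_N,
                "implausible": res.implausible,
            }
        )
    return pd.DataFrame(rows)


def morphology_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd of EF per morphology group (n-1 denominator)."""
    return (
        results.groupby("morphology")["EF"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
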