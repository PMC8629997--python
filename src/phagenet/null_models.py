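"""Fixed-fill (r00) randomization and one-sided significance testing.

The r00 null model preserves only the matrix dimensions and the total
number of interactions I: each draw places I ones uniformly at random,
without replacement, among all M cells. For an observed statistic S the
one-sided p-value over n simulations uses the add-one convention

    p = (#{null >= observed} + 1) / (n + 1)

so the smallest attainable p with 100 simulations is 1/101 = 0.0099.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .matrix_core import IncidenceMatrix

__all__ = ["NullTestResult", "r00_shuffle", "null_test"]


@dataclass(frozen=True)
class NullTestResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when the null distribution is degenerate
    q95: float
    p: float
    n_sim: int
    null_values: np.ndarray

    @property
    def z_defined(self) -> bool:
        return np.isfinite(self.z)


def r00_shuffle(m: IncidenceMatrix, rng: np.random.Generator) -> IncidenceMatrix:
    """One r00 draw: same shape, same fill, positions uniform at random."""
    flat = np.zeros(m.M, dtype=np.int8)
    fill = m.I
    if fill:
        flat[rng.choice(m.M, size=fill, replace=False)] = 1
    return IncidenceMatrix(
        flat.reshape(m.entries.shape), m.host_ids, m.phage_ids
    )


def null_test(
    m: IncidenceMatrix,
    statistic: Callable[[IncidenceMatrix], float],
    n_sim: int = 100,
    seed: int | None = None,
    null_model: str = "r00",
) -> NullTestResult:
    """One-sided significance of ``statistic(m)`` against the r00 null.

    The test direction assumes the observed statistic is greater than
    simulated values. The z-score uses the sample (n-1) standard deviation
    of the null values and is NaN when that deviation is zero; q95 is the
    empirical 95th percentile with linear interpolation. A single seeded RNG
    stream drives all draws.
    """
    if null_model != "r00":
        raise ValueError(f"unknown null model {null_model!r} (only 'r00' in v1)")
    rng = np.random.default_rng(seed)
    observed = float(statistic(m))
    null_values = np.array(
        [float(statistic(r00_shuffle(m, rng))) for _ in range(n_sim)]
    )
    null_mean = float(null_values.mean())
    null_sd = float(null_values.std(ddof=1)) if n_sim > 1 else float("nan")
    z = (observed - null_mean) / null_sd if null_sd and null_sd > 0 else float("nan")
    p = (int((null_values >= observed).sum()) + 1) / (n_sim + 1)
    q95 = float(np.percentile(null_values, 95))
    return NullTestResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        q95=q95,
        p=p,
        n_sim=n_sim,
        null_values=null_values,
    )
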