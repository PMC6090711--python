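"""Analytic power for Mendelian randomisation with a binary outcome.

Normal-approximation ("mRnd"-style) power for a two-sided Wald test of the
causal effect estimated by an instrumental-variable analysis of a
case-control outcome.  Inputs are the case and control counts, the fraction
R^2 of exposure variance explained by the instrument, the hypothesized
causal odds ratio per SD of the exposure, and the type-I error alpha.

With N = n_cases + n_controls and case fraction K, the attenuated
regression coefficient of outcome on genetically predicted exposure is

    b = K * (OR / (1 + K * (OR - 1)) - 1)

with approximate variance  v = (K (1 - K) - b^2) / (N * R^2),  giving a
non-centrality parameter NCP = b^2 / v and two-sided power

    power = Phi(sqrt(NCP) - z_{1-alpha/2}) + Phi(-sqrt(NCP) - z_{1-alpha/2}).

Power is monotone increasing in N, R^2 and the distance of OR from 1, and
tends to alpha as OR -> 1.  (The binary-outcome approximation is not
exactly symmetric in OR vs. 1/OR.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PowerParams:
    """Design parameters for a binary-outcome MR power calculation."""

    n_cases: int
    n_controls: int
    r2: float
    or_per_sd: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not (0 < self.r2 < 1):
            raise ValueError(f"r2 must be in (0, 1), got {self.r2}")
        if not (self.or_per_sd > 0):
            raise ValueError(f"or_per_sd must be > 0, got {self.or_per_sd}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def mr_power_binary(params: PowerParams) -> float:
    """Two-sided analytic power for the given design; in [0, 1]."""
    n = params.n_cases + params.n_controls
    k = params.n_cases / n
    or_ = params.or_per_sd
    b = k * (or_ / (1.0 + k * (or_ - 1.0)) - 1.0)
    v = (k * (1.0 - k) - b**2) / (n * params.r2)
    ncp = b**2 / v
    z = stats.norm.isf(params.alpha / 2.0)
    power = stats.norm.cdf(np.sqrt(ncp) - z) + stats.norm.cdf(-np.sqrt(ncp) - z)
    return float(power)


def power_grid(
    base: PowerParams,
    or_values: Sequence[float],
    r2_values: Sequence[float],
) -> pd.DataFrame:
    """Cartesian grid of power over hypothesized ORs and instrument R^2.

    Returns a tidy frame with columns ``or_per_sd``, ``r2``, ``power``;
    sample sizes and alpha come from ``base``.
    """
    if len(or_values) == 0 or len(r2_values) == 0:
        raise ValueError("or_values and r2_values must be non-empty")
    rows = []
    for r2 in r2_values:
        for or_ in or_values:
            p = PowerParams(
                n_cases=base.n_cases,
                n_controls=base.n_controls,
                r2=r2,
                or_per_sd=or_,
                alpha=base.alpha,
            )
            rows.append({"or_per_sd": or_, "r2": r2, "power": mr_power_binary(p)})
    return pd.DataFrame(rows, columns=["or_per_sd", "r2", "power"])
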