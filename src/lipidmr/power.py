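"""Power of a summary-data MR test for a binary outcome.

The precision of the causal log-odds estimate is governed by the variance
the instrument explains in the exposure (R^2) and the effective sample size
of the case-control outcome study, n_eff = n_cases*n_controls/n. The
asymptotic standard error of the estimate is approximately
1/sqrt(R^2 * n_eff), giving a standard two-sided normal power curve in the
non-centrality lambda = |log OR| / SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PowerSpec:
    """Inputs of an MR power calculation for one binary outcome."""

    r2: float  # instrument variance explained in the exposure
    n_cases: int
    n_controls: int
    or_alt: float  # hypothesized OR per 1 SD (~mmol/L) of exposure
    alpha: float = 0.05  # two-sided significance level

    def __post_init__(self) -> None:
        if not 0 < self.r2 < 1:
            raise ValueError(f"r2 must be in (0, 1), got {self.r2}")
        if not self.or_alt > 0:
            raise ValueError(f"or_alt must be positive, got {self.or_alt}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")

    @property
    def n_eff(self) -> float:
        return self.n_cases * self.n_controls / (self.n_cases + self.n_controls)


def mr_power_binary(spec: PowerSpec) -> float:
    """Two-sided power to detect ``or_alt`` at level ``alpha``.

    SE ~= 1/sqrt(r2 * n_eff); lambda = |ln or_alt| / SE;
    power = Phi(lambda - z_{1-alpha/2}) + Phi(-lambda - z_{1-alpha/2}).
    At or_alt = 1 this reduces to the test size alpha.
    """
    se = 1.0 / np.sqrt(spec.r2 * spec.n_eff)
    lam = abs(np.log(spec.or_alt)) / se
    z = stats.norm.isf(spec.alpha / 2.0)
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))


def power_table(
    r2: float,
    n_cases: int,
    n_controls: int,
    or_grid,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Power across a grid of hypothesized ORs for one outcome study."""
    rows = [
        {
            "r2": r2,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "or_alt": float(or_),
            "alpha": alpha,
            "power": mr_power_binary(PowerSpec(r2, n_cases, n_controls, float(or_), alpha)),
        }
        for or_ in or_grid
    ]
    return pd.DataFrame(rows)
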