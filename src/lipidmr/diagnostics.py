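"""Heterogeneity and outlier diagnostics for a harmonized instrument.

Cochran's Q tests whether per-variant causal estimates are mutually
consistent around a given causal effect. The pleiotropy residual sum and
outlier (PRESSO-style) procedure compares the observed weighted residual
sum of squares — with each variant's expectation taken from a
leave-one-out fixed-effects IVW fit — against its parametric null
distribution, simulated by redrawing the outcome effects from their
standard errors. The global test detects horizontal pleiotropy anywhere in
the instrument; the per-variant test flags individual outliers
(Bonferroni-adjusted), which are then excluded and the estimators rerun.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import EstimationError, MREstimate, ivw, mr_egger, weighted_median
from .summary_io import HarmonizedPanel

logger = logging.getLogger(__name__)


def cochran_q(panel: HarmonizedPanel, outcome_id: str, theta: float) -> tuple[float, int, float]:
    """Cochran Q of per-variant outcome effects around ``theta``.

    Q = sum_j w_j (b_y_j - theta b_x_j)^2 with w_j = 1/se_y_j^2, on J-1
    degrees of freedom, p from the chi-square upper tail. At the IVW point
    estimate this is exactly the Q that drives the random-effects scale
    factor.
    """
    blk = panel.outcome(outcome_id)
    j = panel.n_variants
    if j < 2:
        raise EstimationError(f"Cochran Q needs >= 2 variants, got {j}")
    w = 1.0 / blk.se**2
    q = float(np.sum(w * (blk.beta - theta * panel.beta_exposure) ** 2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass
class PressoResult:
    """Global and per-variant results of the residual-sum outlier test."""

    global_rss: float
    global_p: float
    per_variant_p: dict[str, float]
    outliers: list[str]
    n_sim: int
    seed: int | None
    alpha: float = 0.05

    def report(self, panel: HarmonizedPanel, outcome_id: str):
        import pandas as pd

        loo = _loo_thetas(panel, outcome_id)
        blk = panel.outcome(outcome_id)
        w = 1.0 / blk.se**2
        resid = w * (blk.beta - loo * panel.beta_exposure) ** 2
        return pd.DataFrame(
            {
                "variant_id": panel.variant_ids,
                "loo_theta": loo,
                "residual": resid,
                "outlier_p": [self.per_variant_p[v] for v in panel.variant_ids],
                "flagged": [v in self.outliers for v in panel.variant_ids],
            }
        )


def _loo_thetas(panel: HarmonizedPanel, outcome_id: str) -> np.ndarray:
    """Leave-one-out fixed-effects IVW estimates, one per left-out variant."""
    blk = panel.outcome(outcome_id)
    bx, by, w = panel.beta_exposure, blk.beta, 1.0 / blk.se**2
    s_xy = float(np.sum(w * bx * by))
    s_xx = float(np.sum(w * bx**2))
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def _loo_thetas_matrix(bx: np.ndarray, by_mat: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW per variant for many simulated outcome vectors.

    ``by_mat`` has shape (n_sim, J); returns the same shape.
    """
    s_xy = (by_mat * (w * bx)).sum(axis=1, keepdims=True)
    s_xx = float(np.sum(w * bx**2))
    return (s_xy - w * bx * by_mat) / (s_xx - w * bx**2)


def presso_global(
    panel: HarmonizedPanel,
    outcome_id: str,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PressoResult:
    """Global pleiotropy residual-sum test (with per-variant p-values).

    The observed statistic is RSS = sum_j w_j (b_y_j - theta_(-j) b_x_j)^2,
    where theta_(-j) is the fixed-effects IVW estimate with variant j left
    out. Its null distribution is simulated: in each of ``n_sim`` rounds,
    outcome effects are redrawn as b_y*_j ~ Normal(theta_(-j) b_x_j, se_y_j)
    and the statistic recomputed (including the leave-one-out fits) on the
    simulated data. Empirical p-values use (1 + #exceed)/(n_sim + 1) and so
    are never exactly zero. A variant is flagged as an outlier when its
    per-variant empirical p times J falls below ``alpha``.
    """
    j = panel.n_variants
    if j < 4:
        raise EstimationError(f"PRESSO needs >= 4 variants, got {j}")
    if n_sim < 100:
        logger.warning("n_sim=%d gives coarse empirical p resolution", n_sim)
    if j / (n_sim + 1) >= alpha:
        logger.warning(
            "n_sim=%d cannot flag outliers at alpha=%g with %d variants "
            "(minimum Bonferroni-adjusted p is %g); increase n_sim",
            n_sim, alpha, j, j / (n_sim + 1),
        )
    blk = panel.outcome(outcome_id)
    bx, by, sy = panel.beta_exposure, blk.beta, blk.se
    w = 1.0 / sy**2

    loo = _loo_thetas(panel, outcome_id)
    obs_res = w * (by - loo * bx) ** 2
    obs_rss = float(obs_res.sum())

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, j))
    loo_sim = _loo_thetas_matrix(bx, by_sim, w)
    sim_res = w * (by_sim - loo_sim * bx) ** 2
    sim_rss = sim_res.sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))
    pv = (1 + (sim_res >= obs_res).sum(axis=0)) / (n_sim + 1)
    per_variant = {v: float(p) for v, p in zip(panel.variant_ids, pv)}
    outliers = [v for v, p in per_variant.items() if p * j < alpha]
    return PressoResult(
        global_rss=obs_rss,
        global_p=global_p,
        per_variant_p=per_variant,
        outliers=outliers,
        n_sim=n_sim,
        seed=seed,
        alpha=alpha,
    )


def presso_outliers(
    panel: HarmonizedPanel,
    outcome_id: str,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PressoResult:
    """Per-variant outlier test (same simulation as :func:`presso_global`)."""
    return presso_global(panel, outcome_id, n_sim=n_sim, seed=seed, alpha=alpha)


def exclude_and_reestimate(
    panel: HarmonizedPanel,
    outcome_id: str,
    presso: PressoResult,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[HarmonizedPanel, dict[str, dict[str, MREstimate]]]:
    """Drop flagged outliers and rerun IVW, Egger, weighted median and Q.

    Returns the filtered panel and a dict with "before"/"after" estimate
    sets so the attenuation of heterogeneity and pleiotropic bias can be
    reported side by side. Flagging every variant is fatal (no instrument
    left).
    """
    if set(presso.outliers) >= set(panel.variant_ids):
        raise EstimationError("all variants flagged as outliers; instrument destroyed")
    keep = [v for v in panel.variant_ids if v not in set(presso.outliers)]
    filtered = panel.subset(keep)

    def estimate_set(pnl: HarmonizedPanel) -> dict[str, MREstimate]:
        est = {
            "ivw_re": ivw(pnl, outcome_id, "random_multiplicative"),
            "egger": mr_egger(pnl, outcome_id),
            "weighted_median": weighted_median(pnl, outcome_id, n_boot=n_boot, seed=seed),
        }
        q, df, p = cochran_q(pnl, outcome_id, est["ivw_re"].theta)
        est["ivw_re"].q_statistic, est["ivw_re"].q_df, est["ivw_re"].q_p = q, df, p
        return est

    return filtered, {"before": estimate_set(panel), "after": estimate_set(filtered)}
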