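"""Causal-effect estimators for two-sample summary-data MR.

Given J harmonized variants with exposure effects beta_x (per allele, in
mmol/L of exposure) and outcome effects beta_y (log-odds per allele), all
estimators target theta, the causal log-odds ratio per 1 mmol/L higher
genetically determined exposure:

- IVW: weighted regression of beta_y on beta_x through the origin, weights
  1/se_y^2. The random-effects variant inflates the SE by the multiplicative
  overdispersion factor max(1, sqrt(Q/(J-1))).
- MR-Egger: same regression with a free intercept; a non-zero intercept
  estimates directional pleiotropy under the InSIDE assumption.
- Weighted median: median of per-variant Wald ratios weighted by first-order
  inverse ratio variance; robust when at least half the weight comes from
  valid instruments. SE by parametric bootstrap.
- Multivariable MR: beta_y regressed jointly on the effects of several
  lipid fractions (zero intercept); the exposure coefficient is the direct
  effect adjusting for the other fractions.

Confidence intervals use the normal 1.96 multiplier and two-sided normal
p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import HarmonizedPanel

Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


class EstimationError(ValueError):
    """The requested estimate is not defined for this input."""


@dataclass
class MREstimate:
    """One causal-effect estimate on the log-odds scale."""

    method: str
    outcome_id: str
    theta: float
    se_theta: float
    n_variants: int
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    p_value: float = field(default=np.nan)
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None
    q_statistic: float | None = None
    q_df: int | None = None
    q_p: float | None = None

    def __post_init__(self) -> None:
        if not self.se_theta > 0:
            raise EstimationError(f"se_theta must be positive, got {self.se_theta}")
        if np.isnan(self.ci_low):
            self.ci_low = self.theta - Z95 * self.se_theta
        if np.isnan(self.ci_high):
            self.ci_high = self.theta + Z95 * self.se_theta
        if np.isnan(self.p_value):
            self.p_value = float(2.0 * stats.norm.sf(abs(self.theta) / self.se_theta))

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "outcome": self.outcome_id,
            "n_variants": self.n_variants,
            "theta": self.theta,
            "se": self.se_theta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
        }
        or_, lo, hi = to_odds_ratio(self)
        out.update({"or": or_, "or_ci_low": lo, "or_ci_high": hi})
        if self.intercept is not None:
            out.update(
                {
                    "intercept": self.intercept,
                    "se_intercept": self.se_intercept,
                    "p_intercept": self.p_intercept,
                }
            )
        if self.q_statistic is not None:
            out.update({"q": self.q_statistic, "q_df": self.q_df, "q_p": self.q_p})
        return out


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Single-variant causal estimate beta_y / beta_x with first-order SE
    se_y / |beta_x| (exposure uncertainty ignored, the usual leading term)."""
    if beta_x == 0:
        raise EstimationError("Wald ratio undefined for beta_x = 0")
    return beta_y / beta_x, se_y / abs(beta_x)


def _xy(panel: HarmonizedPanel, outcome_id: str):
    blk = panel.outcome(outcome_id)
    return panel.beta_exposure, blk.beta, blk.se


def ivw(
    panel: HarmonizedPanel,
    outcome_id: str,
    effects_model: str = "random_multiplicative",
) -> MREstimate:
    """Inverse-variance weighted estimate (regression through the origin).

    With weights w_j = 1/se_y_j^2:
        theta = sum(w b_x b_y) / sum(w b_x^2),  SE_fixed = sum(w b_x^2)^-1/2.
    Heterogeneity Q = sum(w (b_y - theta b_x)^2) on J-1 df; under
    ``random_multiplicative`` the SE is scaled by max(1, sqrt(Q/(J-1))).
    """
    if effects_model not in ("fixed", "random_multiplicative"):
        raise EstimationError(f"unknown effects_model {effects_model!r}")
    bx, by, sy = _xy(panel, outcome_id)
    j = len(bx)
    min_j = 1 if effects_model == "fixed" else 2
    if j < min_j:
        raise EstimationError(f"IVW ({effects_model}) needs >= {min_j} variants, got {j}")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / sxx
    se = sxx**-0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    q_df = j - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan
    if effects_model == "random_multiplicative" and q_df > 0:
        se *= max(1.0, np.sqrt(q / q_df))
    return MREstimate(
        method="ivw_fe" if effects_model == "fixed" else "ivw_re",
        outcome_id=outcome_id,
        theta=theta,
        se_theta=se,
        n_variants=j,
        q_statistic=q,
        q_df=q_df,
        q_p=q_p,
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares via normal equations; returns (coef, cov_unscaled)."""
    xtw = x.T * w
    xtx = xtw @ x
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise EstimationError(f"singular design (condition number {cond:.3g})")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (xtw @ y)
    return coef, xtx_inv


def mr_egger(panel: HarmonizedPanel, outcome_id: str) -> MREstimate:
    """MR-Egger regression: weighted LS of beta_y on beta_x with intercept.

    The slope estimates the causal effect allowing all variants a direct
    (pleiotropic) effect, provided pleiotropy is independent of instrument
    strength (InSIDE); the intercept estimates the average directional
    pleiotropy per allele. Requires the panel's exposure betas to be
    non-negative (the orientation :func:`~lipidmr.summary_io.harmonize`
    produces); both SEs carry the multiplicative overdispersion factor
    max(1, sqrt(Q/(J-2))).
    """
    bx, by, sy = _xy(panel, outcome_id)
    j = len(bx)
    if j < 3:
        raise EstimationError(f"MR-Egger needs >= 3 variants, got {j}")
    if np.any(bx < 0):
        raise EstimationError(
            "MR-Egger requires betas oriented to the exposure-increasing allele "
            "(some beta_exposure < 0); harmonize the panel first"
        )
    w = 1.0 / sy**2
    design = np.column_stack([np.ones(j), bx])
    coef, cov_u = _wls(design, by, w)
    intercept, theta = float(coef[0]), float(coef[1])
    resid = by - design @ coef
    q = float(np.sum(w * resid**2))
    q_df = j - 2
    scale = max(1.0, np.sqrt(q / q_df)) if q_df > 0 else 1.0
    se_int = float(np.sqrt(cov_u[0, 0])) * scale
    se_theta = float(np.sqrt(cov_u[1, 1])) * scale
    return MREstimate(
        method="egger",
        outcome_id=outcome_id,
        theta=theta,
        se_theta=se_theta,
        n_variants=j,
        intercept=intercept,
        se_intercept=se_int,
        p_intercept=float(2.0 * stats.norm.sf(abs(intercept) / se_int)),
        q_statistic=q,
        q_df=q_df,
        q_p=float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan,
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median with mid-cumulative-weight interpolation."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ww = w[order]
    cum = np.cumsum(ww)
    p = (cum - ww / 2.0) / cum[-1]
    return float(np.interp(0.5, p, th))


def weighted_median(
    panel: HarmonizedPanel,
    outcome_id: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median of per-variant Wald ratios.

    Ratios theta_j = b_y/b_x are weighted by the inverse first-order ratio
    variance, w_j = b_x^2/se_y^2; the estimate interpolates the weighted
    quantile function at 0.5 and is consistent when valid instruments carry
    at least half the total weight. The SE is the standard deviation of the
    estimate over ``n_boot`` parametric-bootstrap resamples of (b_x, b_y);
    the point estimate itself does not depend on the seed.
    """
    bx, by, sy = _xy(panel, outcome_id)
    sx = panel.se_exposure
    j = len(bx)
    if j < 3:
        raise EstimationError(f"weighted median needs >= 3 variants, got {j}")
    if np.any(bx == 0):
        raise EstimationError("weighted median undefined with beta_exposure = 0")
    ratios = by / bx
    w = bx**2 / sy**2
    est = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    bx_s = rng.normal(bx, sx, size=(n_boot, j))
    by_s = rng.normal(by, sy, size=(n_boot, j))
    for k in range(n_boot):
        bxk = bx_s[k]
        ok = bxk != 0
        boots[k] = _weighted_median(by_s[k][ok] / bxk[ok], bxk[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted_median",
        outcome_id=outcome_id,
        theta=est,
        se_theta=se,
        n_variants=j,
    )


def multivariable_mr(panel: HarmonizedPanel, outcome_id: str) -> MREstimate:
    """Multivariable MR: beta_y on all lipid fractions jointly, no intercept.

    The design stacks the primary exposure column with every secondary
    exposure (HDL-C, triglycerides); weights 1/se_y^2. The reported theta is
    the primary-exposure coefficient — its direct effect holding the other
    fractions fixed. Secondary columns that are identically zero are dropped
    (the fit then reduces to univariable IVW); any remaining rank deficiency
    is fatal. Overdispersion scaling uses J - k df for k fitted columns.
    """
    bx, by, sy = _xy(panel, outcome_id)
    j = len(bx)
    if not panel.secondary:
        raise EstimationError("multivariable MR requires secondary exposure blocks")
    cols = [bx]
    names = [panel.exposure_id]
    for tid, blk in panel.secondary.items():
        if np.any(~np.isfinite(blk.beta)):
            raise EstimationError(f"secondary trait {tid} has missing betas")
        if np.all(blk.beta == 0):
            continue  # degenerate column carries no information
        cols.append(blk.beta)
        names.append(tid)
    design = np.column_stack(cols)
    k = design.shape[1]
    if j < k + 1:
        raise EstimationError(f"multivariable MR needs >= {k + 1} variants, got {j}")
    w = 1.0 / sy**2
    coef, cov_u = _wls(design, by, w)
    resid = by - design @ coef
    q = float(np.sum(w * resid**2))
    q_df = j - k
    scale = max(1.0, np.sqrt(q / q_df)) if q_df > 0 else 1.0
    theta = float(coef[0])
    se_theta = float(np.sqrt(cov_u[0, 0])) * scale
    return MREstimate(
        method="multivariable",
        outcome_id=outcome_id,
        theta=theta,
        se_theta=se_theta,
        n_variants=j,
        q_statistic=q,
        q_df=q_df,
        q_p=float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan,
    )


def to_odds_ratio(estimate: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its CI to the OR scale."""
    return (
        float(np.exp(estimate.theta)),
        float(np.exp(estimate.ci_low)),
        float(np.exp(estimate.ci_high)),
    )
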