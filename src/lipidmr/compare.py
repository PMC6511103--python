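"""Contrasting causal estimates across disease outcomes.

The headline question the pipeline answers is comparative: is the causal
effect of the exposure the same for two diseases (here, coronary heart
disease versus ischemic stroke and its subtypes)? With estimates from
independent case-control samples, a two-estimate Cochran Q — algebraically
the squared z-statistic of the difference — tests between-outcome
heterogeneity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, to_odds_ratio


def between_outcome_heterogeneity(
    est_a: MREstimate, est_b: MREstimate
) -> tuple[float, int, float]:
    """Cochran Q between two causal estimates (df = 1).

    Q = sum_i (theta_i - theta_bar)^2 / SE_i^2 around the inverse-variance
    weighted mean theta_bar; equal to z^2 for
    z = (theta_a - theta_b)/sqrt(SE_a^2 + SE_b^2). Assumes the two outcome
    samples are independent.
    """
    thetas = np.array([est_a.theta, est_b.theta])
    ses = np.array([est_a.se_theta, est_b.se_theta])
    w = 1.0 / ses**2
    theta_bar = float(np.sum(w * thetas) / np.sum(w))
    q = float(np.sum(w * (thetas - theta_bar) ** 2))
    return q, 1, float(stats.chi2.sf(q, 1))


def comparison_table(
    estimates: list[MREstimate], reference_outcome: str
) -> pd.DataFrame:
    """One row per outcome: OR (CI), p, variant count, and heterogeneity-vs-
    reference Q p-value (blank on the reference row). Row order follows the
    declared estimate order."""
    ids = [e.outcome_id for e in estimates]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate outcome ids in comparison: {ids}")
    if reference_outcome not in ids:
        raise ValueError(f"reference outcome {reference_outcome!r} not among {ids}")
    ref = next(e for e in estimates if e.outcome_id == reference_outcome)
    rows = []
    for est in estimates:
        or_, lo, hi = to_odds_ratio(est)
        row = {
            "outcome": est.outcome_id,
            "method": est.method,
            "n_variants": est.n_variants,
            "or": or_,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "p": est.p_value,
            "het_q_vs_ref": np.nan,
            "het_p_vs_ref": np.nan,
        }
        if est.outcome_id != reference_outcome:
            q, _, p = between_outcome_heterogeneity(est, ref)
            row["het_q_vs_ref"], row["het_p_vs_ref"] = q, p
        rows.append(row)
    return pd.DataFrame(rows)


def forest_plot(table: pd.DataFrame, path, title: str = "Causal effect per 1 mmol/L") -> None:
    """Forest plot of ORs with 95% CIs on a log axis (deterministic SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "lipidmr"}):
        fig, ax = plt.subplots(figsize=(6, 0.6 * len(table) + 1.2))
        y = np.arange(len(table))[::-1]
        ax.errorbar(
            table["or"],
            y,
            xerr=[table["or"] - table["or_ci_low"], table["or_ci_high"] - table["or"]],
            fmt="s",
            color="black",
            ecolor="black",
            capsize=3,
        )
        ax.axvline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xscale("log")
        ax.set_yticks(y)
        ax.set_yticklabels(table["outcome"])
        ax.set_xlabel("Odds ratio (95% CI)")
        ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None})
        plt.close(fig)
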