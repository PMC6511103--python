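import numpy as np
import pandas as pd
import pytest

from lipidmr.summary_io import HarmonizedPanel, StudyTable, TraitBlock


def make_panel(
    beta_x,
    se_x=None,
    beta_y=None,
    se_y=None,
    p_x=None,
    eaf=None,
    positions=None,
    chromosome=None,
    outcome_id="chd",
    secondary=None,
    n_cases=None,
    n_controls=None,
):
    """Hand-build a harmonized panel from plain arrays (test helper)."""
    beta_x = np.asarray(beta_x, dtype=float)
    j = len(beta_x)
    se_x = np.asarray(se_x, dtype=float) if se_x is not None else np.full(j, 0.01)
    p_x = np.asarray(p_x, dtype=float) if p_x is not None else np.full(j, 1e-10)
    eaf = np.asarray(eaf, dtype=float) if eaf is not None else np.full(j, 0.3)
    positions = (
        np.asarray(positions, dtype=int)
        if positions is not None
        else np.arange(j) * 10_000_000 + 1
    )
    chromosome = (
        np.asarray(chromosome, dtype=object)
        if chromosome is not None
        else np.array(["1"] * j, dtype=object)
    )
    outcomes = {}
    if beta_y is not None:
        beta_y = np.asarray(beta_y, dtype=float)
        se_y = np.asarray(se_y, dtype=float)
        outcomes[outcome_id] = TraitBlock(
            beta=beta_y,
            se=se_y,
            p=2.0 * __import__("scipy.stats", fromlist=["norm"]).norm.sf(np.abs(beta_y / se_y)),
            n_cases=n_cases,
            n_controls=n_controls,
        )
    sec = {}
    for tid, (b, s) in (secondary or {}).items():
        b = np.asarray(b, dtype=float)
        s = np.asarray(s, dtype=float)
        sec[tid] = TraitBlock(
            beta=b,
            se=s,
            p=2.0 * __import__("scipy.stats", fromlist=["norm"]).norm.sf(np.abs(b / s)),
        )
    return HarmonizedPanel(
        variant_ids=[f"rs{i + 1}" for i in range(j)],
        chromosome=chromosome,
        positions=positions,
        effect_allele=np.array(["A"] * j, dtype=object),
        other_allele=np.array(["G"] * j, dtype=object),
        eaf=eaf,
        beta_exposure=beta_x,
        se_exposure=se_x,
        p_exposure=p_x,
        exposure_id="ldl",
        secondary=sec,
        outcomes=outcomes,
    )


@pytest.fixture
def toy_ivw_panel():
    """The three-variant instrument with a hand-computable IVW solution:
    theta = 59/141, SE_fixed = 141**-0.5, Q ~= 1.312 on 2 df."""
    return make_panel(
        beta_x=[0.10, 0.05, 0.08],
        beta_y=[0.04, 0.03, 0.02],
        se_y=[0.01, 0.01, 0.02],
    )


def study_table(rows, trait_id="ldl", trait_type="quantitative", **kw) -> StudyTable:
    """Build a StudyTable from a list of dicts with canonical columns."""
    defaults = {
        "chromosome": "1",
        "position": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "se": 0.01,
        "p_value": 1e-10,
    }
    recs = pd.DataFrame([{**defaults, **r} for r in rows])
    return StudyTable(records=recs, trait_id=trait_id, trait_type=trait_type, **kw)
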