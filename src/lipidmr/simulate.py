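"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of consortium summary data for a
lipid exposure and binary vascular outcomes: per-variant true exposure
effects gamma_j (per allele, SD units ~ mmol/L) drawn uniformly over a
realistic per-allele range, observed with the sampling noise implied by
the GWAS sample size, and outcome effects generated under

    Gamma_j = theta * gamma_j + alpha_j  (+ planted outlier shifts),

where theta is the causal log-odds per mmol/L and alpha_j a horizontal
pleiotropy term (absent, balanced around zero, directional, or correlated
with instrument strength to violate the InSIDE assumption). Sampling noise
uses the standard approximation for standardized traits,
se = 1/sqrt(2 p (1-p) N), with the effective case-control sample size for
log-odds outcomes. Secondary lipid fractions (HDL-like, TG-like) are
generated with a configurable genetic correlation, optionally planting
strongly associated variants so that the lipid-specificity filter has work
to do. LD is block-diagonal with a configurable within-block r^2.

Every draw is governed by the config's mandatory seed; the same config
reproduces the same panel bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .summary_io import HarmonizedPanel, StudyTable, TraitBlock

#: non-palindromic allele pairs cycled over simulated variants
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class PleiotropySpec:
    """Distribution of the per-variant direct (pleiotropic) outcome effect."""

    kind: str = "none"  # none | balanced | directional | correlated
    mean: float = 0.0
    sd: float = 0.0
    correlation: float = 0.0  # with instrument strength (kind="correlated")

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional", "correlated"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced":
            self.mean = 0.0
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("pleiotropy correlation must be in [-1, 1]")


@dataclass
class OutcomeSpec:
    """Case-control study layout and true causal effect for one outcome."""

    n_cases: int
    n_controls: int
    theta: float  # causal log-odds per 1 mmol/L

    @property
    def n_eff(self) -> float:
        return self.n_cases * self.n_controls / (self.n_cases + self.n_controls)


@dataclass
class SimulationConfig:
    """Full description of one synthetic two-sample MR dataset."""

    n_variants: int
    seed: int
    n_exposure: int = 188_577
    exposure_effect_range: tuple[float, float] = (0.02, 0.10)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    outcomes: dict[str, OutcomeSpec] = field(default_factory=dict)
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    outlier_count: int = 0
    outlier_magnitude: float = 0.0  # shift in units of the outcome SE
    secondary_traits: dict[str, float] = field(default_factory=dict)  # id -> genetic corr
    secondary_theta: dict[str, float] = field(default_factory=dict)  # causal effect of each
    #: sd of the background true secondary effect; None means the spread of
    #: the exposure effects; 0 makes non-planted variants exactly specific
    secondary_background_sd: float | None = None
    n_secondary_strong: int = 0  # variants planted with strong secondary effects
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)  # (size, within r2)
    target_r2: float | None = None  # rescale gammas to this variance explained
    orient_to_increasing_allele: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        lo, hi = self.exposure_effect_range
        if not 0 < lo <= hi:
            raise ValueError("invalid exposure_effect_range")
        lo, hi = self.eaf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("invalid eaf_range")
        if self.n_secondary_strong > self.n_variants:
            raise ValueError("n_secondary_strong exceeds n_variants")
        if not self.outcomes:
            raise ValueError("at least one outcome is required")
        unknown = set(self.secondary_theta) - set(self.secondary_traits)
        if unknown:
            raise ValueError(f"secondary_theta for undeclared trait(s) {sorted(unknown)}")


@dataclass
class SimulationTruth:
    """Generating parameters paired with the drawn per-variant truth."""

    config: SimulationConfig
    gamma: np.ndarray  # true exposure effects, oriented like the panel
    alpha: dict[str, np.ndarray]  # per-outcome pleiotropy terms
    gamma_secondary: dict[str, np.ndarray]
    outlier_ids: list[str]
    theta: dict[str, float]

    def variance_explained(self) -> float:
        maf = np.minimum(self.eaf, 1.0 - self.eaf)
        return float(np.sum(2.0 * self.gamma**2 * maf * (1.0 - maf)))

    # populated by simulate_panel
    eaf: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "config": _config_dict(self.config),
            "gamma": self.gamma.tolist(),
            "alpha": {k: v.tolist() for k, v in self.alpha.items()},
            "gamma_secondary": {k: v.tolist() for k, v in self.gamma_secondary.items()},
            "outlier_ids": self.outlier_ids,
            "theta": self.theta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["outcomes"] = {k: asdict(v) for k, v in config.outcomes.items()}
    d["pleiotropy"] = asdict(config.pleiotropy)
    return d


def _se_standardized(eaf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def _draw_pleiotropy(
    spec: PleiotropySpec, gamma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    j = len(gamma)
    if spec.kind == "none":
        return np.zeros(j)
    z = rng.normal(size=j)
    if spec.kind in ("balanced", "directional"):
        return spec.mean + spec.sd * z
    # correlated: couple alpha to instrument strength (InSIDE violated)
    g_std = (gamma - gamma.mean()) / (gamma.std() if gamma.std() > 0 else 1.0)
    rho = spec.correlation
    return spec.mean + spec.sd * (rho * g_std + np.sqrt(1.0 - rho**2) * z)


def simulate_panel(
    config: SimulationConfig,
) -> tuple[HarmonizedPanel, LDMatrix, SimulationTruth]:
    """Draw one synthetic dataset: harmonized panel, LD matrix, truth.

    Rows are oriented to the observed exposure-increasing allele (as
    harmonization of real consortium tables would), so the panel is directly
    consumable by every estimator.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_variants
    ids = [f"rs{i + 1:05d}" for i in range(j)]

    eaf = rng.uniform(*config.eaf_range, size=j)
    gamma = rng.uniform(*config.exposure_effect_range, size=j)
    if config.target_r2 is not None:
        maf = np.minimum(eaf, 1.0 - eaf)
        current = float(np.sum(2.0 * gamma**2 * maf * (1.0 - maf)))
        gamma *= np.sqrt(config.target_r2 / current)

    se_x = _se_standardized(eaf, config.n_exposure)
    beta_x = rng.normal(gamma, se_x)

    # chromosome/position layout: LD blocks first, then singleton loci,
    # each locus >= 10 Mb from its neighbours on the same chromosome
    chrom = np.empty(j, dtype=object)
    pos = np.empty(j, dtype=int)
    r2 = np.eye(j)
    locus = 0
    idx = 0
    for size, within_r2 in config.ld_blocks:
        block = slice(idx, idx + size)
        chrom[block] = str(locus % 22 + 1)
        pos[block] = 10_000_000 * (locus // 22 + 1) + 10_000 * np.arange(size)
        sub = np.full((size, size), within_r2)
        np.fill_diagonal(sub, 1.0)
        r2[block, block] = sub
        idx += size
        locus += 1
    for i in range(idx, j):
        chrom[i] = str(locus % 22 + 1)
        pos[i] = 10_000_000 * (locus // 22 + 1)
        locus += 1

    # secondary lipid fractions: true effects first (they can feed the
    # outcome model), observed betas after
    gamma_sec: dict[str, np.ndarray] = {}
    secondary: dict[str, TraitBlock] = {}
    strong_idx = (
        rng.choice(j, size=config.n_secondary_strong, replace=False)
        if config.n_secondary_strong
        else np.array([], dtype=int)
    )
    if config.secondary_background_sd is None:
        tau = gamma.std() if gamma.std() > 0 else 0.01
    else:
        tau = config.secondary_background_sd
    se_s = _se_standardized(eaf, config.n_exposure)
    for k, (tid, rho) in enumerate(config.secondary_traits.items()):
        z = rng.normal(size=j)
        g = rho * gamma + np.sqrt(max(0.0, 1.0 - rho**2)) * tau * z
        # plant unmistakable secondary associations on alternating strong
        # variants so the specificity filter excludes exactly that subset
        mine = strong_idx[k::len(config.secondary_traits)] if len(strong_idx) else strong_idx
        g = g.copy()
        g[mine] += 10.0 * se_s[mine]
        gamma_sec[tid] = g

    alpha: dict[str, np.ndarray] = {}
    outcomes: dict[str, TraitBlock] = {}
    outlier_idx = (
        rng.choice(j, size=config.outlier_count, replace=False)
        if config.outlier_count
        else np.array([], dtype=int)
    )
    for oid, ospec in config.outcomes.items():
        a = _draw_pleiotropy(config.pleiotropy, gamma, rng)
        se_y = _se_standardized(eaf, ospec.n_eff)
        big_gamma = ospec.theta * gamma + a
        for tid, th_s in config.secondary_theta.items():
            big_gamma = big_gamma + th_s * gamma_sec[tid]
        big_gamma = big_gamma.copy()
        big_gamma[outlier_idx] += config.outlier_magnitude * se_y[outlier_idx]
        beta_y = rng.normal(big_gamma, se_y)
        alpha[oid] = a
        outcomes[oid] = TraitBlock(
            beta=beta_y,
            se=se_y,
            p=_two_sided_p(beta_y, se_y),
            n_cases=ospec.n_cases,
            n_controls=ospec.n_controls,
        )

    for tid in config.secondary_traits:
        g = gamma_sec[tid]
        beta_s = rng.normal(g, se_s)
        secondary[tid] = TraitBlock(beta=beta_s, se=se_s, p=_two_sided_p(beta_s, se_s))

    ea = np.array([_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(j)], dtype=object)
    oa = np.array([_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(j)], dtype=object)

    if config.orient_to_increasing_allele:
        flip = beta_x < 0
        sign = np.where(flip, -1.0, 1.0)
        beta_x = beta_x * sign
        gamma = gamma * sign
        eaf = np.where(flip, 1.0 - eaf, eaf)
        ea, oa = np.where(flip, oa, ea), np.where(flip, ea, oa)
        for blk in list(outcomes.values()) + list(secondary.values()):
            blk.beta = blk.beta * sign
        for oid in alpha:
            alpha[oid] = alpha[oid] * sign
        for tid in gamma_sec:
            gamma_sec[tid] = gamma_sec[tid] * sign

    panel = HarmonizedPanel(
        variant_ids=ids,
        chromosome=chrom,
        positions=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta_exposure=beta_x,
        se_exposure=se_x,
        p_exposure=_two_sided_p(beta_x, se_x),
        exposure_id="ldl",
        secondary=secondary,
        outcomes=outcomes,
    )
    ld = LDMatrix(variant_ids=ids, r2=r2, positions=pos.copy(), chromosome=chrom.copy())
    truth = SimulationTruth(
        config=config,
        gamma=gamma,
        alpha=alpha,
        gamma_secondary=gamma_sec,
        outlier_ids=[ids[i] for i in sorted(outlier_idx)],
        theta={oid: o.theta for oid, o in config.outcomes.items()},
        eaf=eaf,
    )
    return panel, ld, truth


# study layouts used by the named scenarios (cases, controls)
CHD_STUDY = (60_801, 123_504)
IS_STUDY = (12_389, 62_004)
IS_SUBTYPE_STUDIES = {
    "cardioembolic": (2_365, 62_004),
    "large_artery": (2_167, 62_004),
    "small_vessel": (1_894, 62_004),
}


def scenario_suite(name: str, seed: int = 0) -> SimulationConfig:
    """Named, fully specified simulation scenarios.

    - ``null``: no causal effect, no pleiotropy (type-I error checks).
    - ``causal``: theta = 0.4, valid instruments (unbiasedness/coverage).
    - ``balanced``: theta = 0.4 plus zero-mean pleiotropy.
    - ``directional``: theta = 0.4 plus mean-0.01 pleiotropy, InSIDE holds
      (Egger-intercept recovery).
    - ``inside_violated``: pleiotropy correlated (rho 0.7) with instrument
      strength; Egger intercept is biased in the direction of the
      correlation.
    - ``outliers``: one variant shifted by 10 outcome-SEs (PRESSO checks).
    - ``paper_mimic``: 62 LDL-specific variants rescaled to 4% variance
      explained, consortium-scale sample sizes, CHD/IS/IS-subtype outcomes
      with generating ORs 1.49 / 1.12 / 1.06 and subtype effects between.
    - ``paper_mimic_full``: 99-variant version with 37 variants planted with
      strong HDL-like/TG-like effects (11% variance explained) for the
      specificity-filtered vs all-variant instrument duality.
    """
    mid = {"outcome": OutcomeSpec(20_000, 60_000, 0.4)}
    scenarios = {
        "null": dict(
            n_variants=62,
            outcomes={"outcome": OutcomeSpec(*IS_STUDY, 0.0)},
        ),
        "causal": dict(n_variants=30, outcomes=mid),
        "balanced": dict(
            n_variants=30,
            outcomes=mid,
            pleiotropy=PleiotropySpec("balanced", sd=0.01),
        ),
        # estimator-validation scenarios: the exposure GWAS is large enough
        # that measurement error in the variant-exposure effects is
        # negligible (the NOME condition MR-Egger's consistency assumes);
        # otherwise weak-instrument dilution of the slope leaks ~1e-3 into
        # the intercept and the pleiotropy parameter is not identifiable at
        # Monte-Carlo precision
        "directional": dict(
            n_variants=62,
            n_exposure=5_000_000,
            outcomes=mid,
            pleiotropy=PleiotropySpec("directional", mean=0.01, sd=0.005),
        ),
        "inside_violated": dict(
            n_variants=62,
            n_exposure=5_000_000,
            outcomes=mid,
            pleiotropy=PleiotropySpec("correlated", mean=0.01, sd=0.005, correlation=0.7),
        ),
        "outliers": dict(
            n_variants=20,
            outcomes=mid,
            outlier_count=1,
            outlier_magnitude=10.0,
        ),
        "paper_mimic": dict(
            n_variants=62,
            target_r2=0.04,
            outcomes={
                "chd": OutcomeSpec(*CHD_STUDY, float(np.log(1.49))),
                "is": OutcomeSpec(*IS_STUDY, float(np.log(1.12))),
                "cardioembolic": OutcomeSpec(
                    *IS_SUBTYPE_STUDIES["cardioembolic"], float(np.log(1.06))
                ),
                "large_artery": OutcomeSpec(
                    *IS_SUBTYPE_STUDIES["large_artery"], float(np.log(1.40))
                ),
                "small_vessel": OutcomeSpec(
                    *IS_SUBTYPE_STUDIES["small_vessel"], float(np.log(1.35))
                ),
            },
            secondary_traits={"hdl": 0.0, "tg": 0.0},
            secondary_background_sd=0.0,
        ),
        "paper_mimic_full": dict(
            n_variants=99,
            target_r2=0.11,
            outcomes={
                "chd": OutcomeSpec(*CHD_STUDY, float(np.log(1.49))),
                "is": OutcomeSpec(*IS_STUDY, float(np.log(1.12))),
                "cardioembolic": OutcomeSpec(
                    *IS_SUBTYPE_STUDIES["cardioembolic"], float(np.log(1.06))
                ),
                "large_artery": OutcomeSpec(
                    *IS_SUBTYPE_STUDIES["large_artery"], float(np.log(1.40))
                ),
                "small_vessel": OutcomeSpec(
                    *IS_SUBTYPE_STUDIES["small_vessel"], float(np.log(1.35))
                ),
            },
            secondary_traits={"hdl": 0.0, "tg": 0.0},
            secondary_background_sd=0.0,
            n_secondary_strong=37,
        ),
    }
    if name not in scenarios:
        raise ValueError(f"unknown scenario {name!r}; valid: {sorted(scenarios)}")
    return SimulationConfig(seed=seed, **scenarios[name])


def panel_to_study_tables(
    panel: HarmonizedPanel,
    n_exposure: int | None = None,
) -> dict[str, StudyTable]:
    """Decompose a harmonized panel back into per-trait study tables
    (the TSV format :mod:`lipidmr.summary_io` reads)."""
    import pandas as pd

    base = {
        "variant_id": panel.variant_ids,
        "chromosome": panel.chromosome,
        "position": panel.positions,
        "effect_allele": panel.effect_allele,
        "other_allele": panel.other_allele,
        "eaf": panel.eaf,
    }

    def table(beta, se, p, trait_id, trait_type, **kw) -> StudyTable:
        df = pd.DataFrame({**base, "beta": beta, "se": se, "p_value": p})
        return StudyTable(records=df, trait_id=trait_id, trait_type=trait_type, **kw)

    tables = {
        panel.exposure_id: table(
            panel.beta_exposure,
            panel.se_exposure,
            panel.p_exposure,
            panel.exposure_id,
            "quantitative",
            n_total=n_exposure,
        )
    }
    for tid, blk in panel.secondary.items():
        tables[tid] = table(blk.beta, blk.se, blk.p, tid, "quantitative")
    for tid, blk in panel.outcomes.items():
        tables[tid] = table(
            blk.beta, blk.se, blk.p, tid, "binary",
            n_cases=blk.n_cases, n_controls=blk.n_controls,
        )
    return tables


def write_simulated_study(out_dir, panel, ld, truth) -> dict[str, str]:
    """Write the simulated dataset as the pipeline's on-disk input format:
    one TSV per trait, the LD matrix, and a truth JSON. Returns the file map."""
    from pathlib import Path

    from .summary_io import write_summary_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for tid, tab in panel_to_study_tables(panel, truth.config.n_exposure).items():
        path = out / f"{tid}.tsv"
        write_summary_table(tab, path)
        files[tid] = str(path)
    ld.write(out / "ld.tsv")
    files["ld"] = str(out / "ld.tsv")
    truth.to_json(out / "truth.json")
    files["truth"] = str(out / "truth.json")
    return files
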