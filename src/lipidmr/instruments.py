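"""Construction of the genetic instrument from a harmonized panel.

The instrument for a lipid exposure is built in three stages, mirroring
standard practice for consortium summary data:

1. genome-wide significance filter on the exposure association (p < 5e-8);
2. greedy LD clumping (retain index variants, discard anything within a
   physical window at r^2 above a ceiling), yielding independent variants;
3. a lipid-specificity filter that removes variants also associated with
   secondary lipid fractions (HDL-C, triglycerides) at a Bonferroni-style
   threshold, to limit horizontal pleiotropy through other lipid pathways.

The module also converts exposure effects between SD units and mmol/L and
computes the variance in the exposure explained by the instrument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import HarmonizedPanel, SummaryDataError, TraitBlock

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.01
CLUMP_WINDOW_BP = 1_000_000
SECONDARY_P = 0.0005


class LDMatrixError(ValueError):
    """LD matrix fails symmetry / range validation."""


@dataclass
class LDMatrix:
    """Symmetric r^2 matrix over a set of variants with their coordinates."""

    variant_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray
    chromosome: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise LDMatrixError(f"r2 matrix shape {self.r2.shape} != ({n}, {n})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise LDMatrixError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise LDMatrixError("r2 diagonal is not 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise LDMatrixError("r2 values outside [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float | None:
        """r^2 between two variants, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def read(cls, path, positions: dict[str, int], chromosome: dict[str, str]) -> "LDMatrix":
        """Read a whitespace-delimited square matrix with variant-ID header
        row and column; coordinates supplied separately."""
        df = pd.read_csv(path, sep=r"\s+", index_col=0)
        ids = [str(c) for c in df.columns]
        if list(df.index.astype(str)) != ids:
            raise LDMatrixError(f"{path}: row and column variant ids differ")
        return cls(
            variant_ids=ids,
            r2=df.to_numpy(dtype=float),
            positions=np.array([positions[v] for v in ids], dtype=int),
            chromosome=np.array([chromosome[v] for v in ids], dtype=object),
        )

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", float_format="%.6g"
        )


@dataclass
class InstrumentSelection:
    """Outcome of one selection stage: retained ids plus per-variant
    exclusion reasons (``retained + excluded`` partitions the input)."""

    retained_ids: list[str]
    excluded: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def apply(self, panel: HarmonizedPanel) -> HarmonizedPanel:
        return panel.subset(self.retained_ids)

    def report(self) -> pd.DataFrame:
        rows = [
            {"variant_id": v, "status": "retained", "reason": ""} for v in self.retained_ids
        ] + [
            {"variant_id": v, "status": "excluded", "reason": r}
            for v, r in self.excluded.items()
        ]
        df = pd.DataFrame(rows, columns=["variant_id", "status", "reason"])
        for k, v in self.thresholds.items():
            df[k] = v
        return df


def filter_genome_wide(
    panel: HarmonizedPanel, threshold: float = GENOME_WIDE_P
) -> InstrumentSelection:
    """Retain variants with exposure p strictly below ``threshold``."""
    keep = panel.p_exposure < threshold
    return InstrumentSelection(
        retained_ids=[v for v, k in zip(panel.variant_ids, keep) if k],
        excluded={v: "not_genome_wide" for v, k in zip(panel.variant_ids, keep) if not k},
        thresholds={"p_threshold": threshold},
    )


def clump(
    panel: HarmonizedPanel,
    ld: LDMatrix,
    r2_max: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> InstrumentSelection:
    """Greedy LD clumping.

    Repeatedly take the unprocessed variant with the smallest exposure
    p-value as an index, then discard every other unprocessed variant on the
    same chromosome within ``window_bp`` of it (center-to-center, boundary
    inclusive) whose r^2 with the index is >= ``r2_max``. Ties on p break by
    smaller position, then lexicographic id, making the output canonical
    regardless of input row order. Variant pairs absent from the LD matrix
    are treated as unlinked.
    """
    order = sorted(
        range(panel.n_variants),
        key=lambda i: (panel.p_exposure[i], panel.positions[i], panel.variant_ids[i]),
    )
    retained: list[str] = []
    excluded: dict[str, str] = {}
    done = np.zeros(panel.n_variants, dtype=bool)
    for i in order:
        if done[i]:
            continue
        vid = panel.variant_ids[i]
        retained.append(vid)
        done[i] = True
        for j in order:
            if done[j]:
                continue
            if panel.chromosome[j] != panel.chromosome[i]:
                continue
            if abs(int(panel.positions[j]) - int(panel.positions[i])) > window_bp:
                continue
            r2 = ld.lookup(vid, panel.variant_ids[j])
            if r2 is not None and r2 >= r2_max:
                excluded[panel.variant_ids[j]] = f"clumped:{vid}"
                done[j] = True
    return InstrumentSelection(
        retained_ids=retained,
        excluded=excluded,
        thresholds={"r2_max": r2_max, "window_bp": window_bp},
    )


def lipid_specificity_filter(
    panel: HarmonizedPanel, secondary_p_threshold: float = SECONDARY_P
) -> InstrumentSelection:
    """Exclude variants associated with any secondary lipid fraction.

    A variant is excluded when its smallest secondary-trait p-value (taken
    from the table, or computed as a two-sided normal p from beta/se when
    absent) is below ``secondary_p_threshold``. Variants with no secondary
    statistics at all are retained with a warning.
    """
    if not panel.secondary:
        logger.warning("no secondary traits on panel; specificity filter retains all")
        return InstrumentSelection(
            retained_ids=list(panel.variant_ids),
            thresholds={"secondary_p_threshold": secondary_p_threshold},
        )
    pmin = np.full(panel.n_variants, np.nan)
    for blk in panel.secondary.values():
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(
                np.isfinite(blk.p),
                blk.p,
                2.0 * stats.norm.sf(np.abs(blk.beta / blk.se)),
            )
        pmin = np.fmin(pmin, p)  # fmin ignores NaN
    missing = ~np.isfinite(pmin)
    if missing.any():
        logger.warning(
            "no secondary statistics for %d variant(s); retained", int(missing.sum())
        )
    exclude = np.where(np.isfinite(pmin), pmin < secondary_p_threshold, False)
    return InstrumentSelection(
        retained_ids=[v for v, e in zip(panel.variant_ids, exclude) if not e],
        excluded={
            v: "pleiotropic_secondary" for v, e in zip(panel.variant_ids, exclude) if e
        },
        thresholds={"secondary_p_threshold": secondary_p_threshold},
    )


def scale_effects(panel: HarmonizedPanel, sd_to_mmol: float = 1.0) -> HarmonizedPanel:
    """Convert exposure effects (and SEs) from SD units to mmol/L.

    Causal estimates downstream are then "per 1 mmol/L" of exposure. A
    factor of 1.0 (1 SD of LDL-C is about 1 mmol/L) leaves the panel
    numerically unchanged.
    """
    if not sd_to_mmol > 0:
        raise SummaryDataError(f"sd_to_mmol must be positive, got {sd_to_mmol}")
    return replace(
        panel,
        beta_exposure=panel.beta_exposure * sd_to_mmol,
        se_exposure=panel.se_exposure * sd_to_mmol,
    )


def variance_explained(panel: HarmonizedPanel) -> float:
    """Fraction of exposure variance explained by the panel's variants.

    Sum over variants of ``2 * beta^2 * MAF * (1 - MAF)`` with the exposure
    beta in SD units and MAF the folded effect-allele frequency. Requires a
    finite eaf for every variant.
    """
    bad = ~np.isfinite(panel.eaf)
    if bad.any():
        offending = [v for v, b in zip(panel.variant_ids, bad) if b]
        raise SummaryDataError(f"missing eaf for variant(s) {offending[:5]}")
    maf = np.minimum(panel.eaf, 1.0 - panel.eaf)
    return float(np.sum(2.0 * panel.beta_exposure**2 * maf * (1.0 - maf)))
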