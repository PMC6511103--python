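"""Reading, validating and harmonizing GWAS summary statistics.

Summary-data Mendelian randomization operates on per-variant association
tables: for each genetic variant, an effect size (beta), its standard error
and p-value against one trait. Exposure traits (lipid fractions) are on a
quantitative scale, disease outcomes on the log-odds scale. Before any
estimator can run, the exposure and outcome tables must be *harmonized*:
every effect expressed with respect to the same effect allele, and finally
oriented so that the effect allele is the exposure-increasing one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: default column mapping for summary-statistic TSV files
DEFAULT_SCHEMA: dict[str, str] = {
    "variant_id": "variant_id",
    "chromosome": "chr",
    "position": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p_value": "pval",
    "n_total": "n",
    "n_cases": "n_cases",
    "n_controls": "n_controls",
}

_MANDATORY = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p_value",
]

#: strand-ambiguous allele pairs (indistinguishable on the reverse strand)
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SummaryDataError(ValueError):
    """Fatal problem with a summary-statistics input."""


@dataclass
class StudyTable:
    """Per-variant association statistics of one trait in one study.

    ``records`` holds one row per variant with the canonical columns
    ``variant_id, chromosome, position, effect_allele, other_allele, eaf,
    beta, se, p_value``. Lipid exposures are quantitative (beta in SD or
    mmol/L units); disease outcomes are binary (beta on the log-odds scale)
    and carry case/control counts.
    """

    records: pd.DataFrame
    trait_id: str
    trait_type: str = "quantitative"  # quantitative | binary
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise SummaryDataError(f"unknown trait_type {self.trait_type!r}")
        if self.records["variant_id"].duplicated().any():
            dupes = self.records.loc[
                self.records["variant_id"].duplicated(), "variant_id"
            ].tolist()
            raise SummaryDataError(f"duplicate variant ids in {self.trait_id}: {dupes[:5]}")
        if self.trait_type == "binary":
            if self.n_cases is not None and self.n_controls is not None:
                if self.n_total is None:
                    self.n_total = self.n_cases + self.n_controls
                elif self.n_cases + self.n_controls != self.n_total:
                    raise SummaryDataError(
                        f"{self.trait_id}: n_cases + n_controls != n_total"
                    )

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def variant_ids(self) -> list[str]:
        return self.records["variant_id"].tolist()


def _validate_rows(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Drop rows violating hard invariants; warn on soft inconsistencies."""
    n0 = len(df)
    ok = (
        df["se"].gt(0)
        & df["p_value"].gt(0)
        & df["p_value"].le(1)
        & df["beta"].notna()
        & df["effect_allele"].ne(df["other_allele"])
    )
    if "eaf" in df.columns:
        ok &= df["eaf"].isna() | (df["eaf"].ge(0) & df["eaf"].le(1))
    dropped = n0 - int(ok.sum())
    if dropped:
        logger.warning("%s: dropped %d/%d rows failing validation", trait_id, dropped, n0)
    df = df[ok].reset_index(drop=True)

    # published tables round beta/se/p aggressively: only warn when the
    # two-sided normal p implied by beta/se is off by more than a factor of 2
    with np.errstate(divide="ignore", invalid="ignore"):
        implied = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(implied > 0, df["p_value"] / implied, np.inf)
    bad = (ratio > 2.0) | (ratio < 0.5)
    bad &= implied > 1e-300  # beyond float range the ratio is meaningless
    if bad.any():
        logger.warning(
            "%s: %d rows have p inconsistent with beta/se beyond a factor of 2",
            trait_id,
            int(bad.sum()),
        )
    return df


def read_summary_table(
    path,
    trait_id: str,
    trait_type: str = "quantitative",
    schema: dict[str, str] | None = None,
    n_total: int | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> StudyTable:
    """Read a tab-separated summary-statistics file into a :class:`StudyTable`.

    ``schema`` maps canonical field names to the file's column names
    (defaults in :data:`DEFAULT_SCHEMA`). Rows failing validation (se <= 0,
    p outside (0, 1], identical alleles) are dropped with a logged count;
    a missing mandatory column is fatal.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, sep="\t", dtype={colmap["variant_id"]: str})
    missing = [f for f in _MANDATORY if colmap[f] not in raw.columns]
    if missing:
        raise SummaryDataError(f"{path}: missing mandatory column(s) {missing}")
    rename = {colmap[f]: f for f in colmap if colmap[f] in raw.columns}
    df = raw.rename(columns=rename)
    keep = [c for c in DEFAULT_SCHEMA if c in df.columns and c not in ("n_total",)]
    df = df[[c for c in keep if c not in ("n_cases", "n_controls")]].copy()
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    for col in ("beta", "se", "p_value", "eaf"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["position"] = pd.to_numeric(df["position"], errors="coerce").astype("Int64")
    df["chromosome"] = df["chromosome"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df = _validate_rows(df, trait_id)
    df["position"] = df["position"].astype(int)
    return StudyTable(
        records=df,
        trait_id=trait_id,
        trait_type=trait_type,
        n_total=n_total,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def write_summary_table(table: StudyTable, path, schema: dict[str, str] | None = None) -> None:
    """Write a :class:`StudyTable` back to TSV (inverse of :func:`read_summary_table`)."""
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    out = table.records.rename(columns={f: colmap[f] for f in colmap})
    out.to_csv(path, sep="\t", index=False)


@dataclass
class TraitBlock:
    """Per-variant effects of one trait inside a harmonized panel."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n_cases: int | None = None
    n_controls: int | None = None

    def subset(self, idx: np.ndarray) -> "TraitBlock":
        return TraitBlock(
            beta=self.beta[idx],
            se=self.se[idx],
            p=self.p[idx],
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )


@dataclass
class HarmonizedPanel:
    """Allele-aligned per-variant effects of one exposure, optional secondary
    exposures, and one or more binary outcomes.

    All arrays share variant order. After :func:`harmonize`, every effect is
    expressed per copy of the exposure-increasing allele, so
    ``beta_exposure >= 0``.
    """

    variant_ids: list[str]
    chromosome: np.ndarray
    positions: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    eaf: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    p_exposure: np.ndarray
    exposure_id: str = "exposure"
    secondary: dict[str, TraitBlock] = field(default_factory=dict)
    outcomes: dict[str, TraitBlock] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        for name in ("chromosome", "positions", "effect_allele", "other_allele",
                     "eaf", "beta_exposure", "se_exposure", "p_exposure"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise SummaryDataError(f"panel column {name} has length {len(arr)} != {n}")
        for tid, blk in {**self.secondary, **self.outcomes}.items():
            if len(blk.beta) != n or len(blk.se) != n:
                raise SummaryDataError(f"trait block {tid} misaligned with panel")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def outcome_ids(self) -> list[str]:
        return list(self.outcomes)

    def outcome(self, outcome_id: str) -> TraitBlock:
        try:
            return self.outcomes[outcome_id]
        except KeyError:
            raise KeyError(
                f"unknown outcome {outcome_id!r}; have {list(self.outcomes)}"
            ) from None

    def subset(self, keep_ids) -> "HarmonizedPanel":
        """Return a panel restricted to ``keep_ids`` (panel order preserved)."""
        keep = set(keep_ids)
        idx = np.array([i for i, v in enumerate(self.variant_ids) if v in keep], dtype=int)
        return HarmonizedPanel(
            variant_ids=[self.variant_ids[i] for i in idx],
            chromosome=self.chromosome[idx],
            positions=self.positions[idx],
            effect_allele=self.effect_allele[idx],
            other_allele=self.other_allele[idx],
            eaf=self.eaf[idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            p_exposure=self.p_exposure[idx],
            exposure_id=self.exposure_id,
            secondary={t: b.subset(idx) for t, b in self.secondary.items()},
            outcomes={t: b.subset(idx) for t, b in self.outcomes.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame with one block of columns per trait."""
        df = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chr": self.chromosome,
                "pos": self.positions,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "eaf": self.eaf,
                f"beta_{self.exposure_id}": self.beta_exposure,
                f"se_{self.exposure_id}": self.se_exposure,
                f"pval_{self.exposure_id}": self.p_exposure,
            }
        )
        for tid, blk in {**self.secondary, **self.outcomes}.items():
            df[f"beta_{tid}"] = blk.beta
            df[f"se_{tid}"] = blk.se
            df[f"pval_{tid}"] = blk.p
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in PALINDROMIC_PAIRS


def _align_to_exposure(exp: pd.DataFrame, other: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Express ``other``'s effects for the exposure's effect allele.

    Returns a frame indexed like ``exp`` with columns beta/se/p (NaN where
    the variant is absent); variants with an irreconcilable allele pair get
    NaN and a log entry.
    """
    merged = exp[["variant_id", "effect_allele", "other_allele"]].merge(
        other[["variant_id", "effect_allele", "other_allele", "beta", "se", "p_value"]],
        on="variant_id",
        how="left",
        suffixes=("", "_o"),
    )
    same = merged["effect_allele"].eq(merged["effect_allele_o"]) & merged[
        "other_allele"
    ].eq(merged["other_allele_o"])
    swapped = merged["effect_allele"].eq(merged["other_allele_o"]) & merged[
        "other_allele"
    ].eq(merged["effect_allele_o"])
    present = merged["effect_allele_o"].notna()
    mismatch = present & ~same & ~swapped
    if mismatch.any():
        ids = merged.loc[mismatch, "variant_id"].tolist()
        logger.warning(
            "%s: allele pair mismatch for %d variant(s), dropped: %s",
            trait_id,
            len(ids),
            ids[:5],
        )
    beta = np.where(same, merged["beta"], np.where(swapped, -merged["beta"], np.nan))
    se = np.where(same | swapped, merged["se"], np.nan)
    p = np.where(same | swapped, merged["p_value"], np.nan)
    return pd.DataFrame(
        {"beta": beta, "se": se, "p": p, "present": present & ~mismatch},
        index=merged.index,
    )


def harmonize(
    exposure: StudyTable,
    secondary: list[StudyTable] | None = None,
    outcomes: list[StudyTable] | None = None,
    palindrome_policy: str = "drop",
) -> HarmonizedPanel:
    """Align exposure, secondary-exposure and outcome tables on a shared
    effect allele and orient all effects to the exposure-increasing allele.

    Variants are dropped when (a) strand-ambiguous (A/T, C/G) under
    ``palindrome_policy='drop'``, (b) absent from any outcome table, or
    (c) carrying an allele pair that is neither identical nor swapped
    relative to the exposure. Variants missing from a *secondary* table are
    retained with NaN in that block (downstream filters warn). Outcome
    effects recorded for the swapped allele pair are negated. Finally the
    whole row is sign-flipped (and eaf complemented, alleles swapped)
    wherever the exposure beta is negative, so ``min(beta_exposure) >= 0``.
    """
    if palindrome_policy not in ("drop", "keep"):
        raise SummaryDataError(f"unknown palindrome_policy {palindrome_policy!r}")
    if exposure.trait_type != "quantitative":
        raise SummaryDataError("exposure must be a quantitative trait")
    secondary = secondary or []
    outcomes = outcomes or []
    for out in outcomes:
        if out.trait_type != "binary":
            raise SummaryDataError(f"outcome {out.trait_id} must be binary")

    exp = exposure.records.reset_index(drop=True).copy()
    if palindrome_policy == "drop":
        pal = exp.apply(
            lambda r: _is_palindromic(r["effect_allele"], r["other_allele"]), axis=1
        )
        if pal.any():
            logger.info("dropping %d palindromic variant(s)", int(pal.sum()))
        exp = exp[~pal].reset_index(drop=True)

    aligned_out = {o.trait_id: _align_to_exposure(exp, o.records, o.trait_id) for o in outcomes}
    aligned_sec = {s.trait_id: _align_to_exposure(exp, s.records, s.trait_id) for s in secondary}

    keep = np.ones(len(exp), dtype=bool)
    for tid, al in aligned_out.items():
        keep &= al["present"].to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d variant(s) absent from at least one outcome", n_drop)

    exp = exp[keep].reset_index(drop=True)
    aligned_out = {t: a[keep].reset_index(drop=True) for t, a in aligned_out.items()}
    aligned_sec = {t: a[keep].reset_index(drop=True) for t, a in aligned_sec.items()}

    # orient to the exposure-increasing allele
    flip = exp["beta"].to_numpy() < 0
    sign = np.where(flip, -1.0, 1.0)
    ea = np.where(flip, exp["other_allele"], exp["effect_allele"])
    oa = np.where(flip, exp["effect_allele"], exp["other_allele"])
    eaf = np.where(flip, 1.0 - exp["eaf"].to_numpy(), exp["eaf"].to_numpy())

    def block(al: pd.DataFrame, table: StudyTable | None = None) -> TraitBlock:
        return TraitBlock(
            beta=al["beta"].to_numpy() * sign,
            se=al["se"].to_numpy(),
            p=al["p"].to_numpy(),
            n_cases=getattr(table, "n_cases", None),
            n_controls=getattr(table, "n_controls", None),
        )

    out_tables = {o.trait_id: o for o in outcomes}
    return HarmonizedPanel(
        variant_ids=exp["variant_id"].tolist(),
        chromosome=exp["chromosome"].to_numpy(),
        positions=exp["position"].to_numpy(),
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta_exposure=exp["beta"].to_numpy() * sign,
        se_exposure=exp["se"].to_numpy(),
        p_exposure=exp["p_value"].to_numpy(),
        exposure_id=exposure.trait_id,
        secondary={t: block(a) for t, a in aligned_sec.items()},
        outcomes={t: block(a, out_tables[t]) for t, a in aligned_out.items()},
    )
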