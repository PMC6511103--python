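"""End-to-end analysis pipeline: select, estimate, diagnose, compare, power.

A single YAML config names the input summary-statistic tables, the LD
matrix, the selection thresholds and the seeds; the pipeline then runs the
whole analysis for the lipid-specific instrument (secondary-associated
variants excluded) and, when secondary traits are provided, also for the
all-variant instrument, writing a report bundle:

    <out>/manifest.json
    <out>/<instrument>/selection.tsv        per-variant retention bookkeeping
    <out>/<instrument>/estimates.{tsv,json} every estimator x outcome
    <out>/<instrument>/diagnostics_<outcome>.tsv   PRESSO per-variant report
    <out>/<instrument>/presso_<outcome>.json       global test + re-estimates
    <out>/<instrument>/comparison.tsv       OR table with heterogeneity vs reference
    <out>/<instrument>/forest.svg           forest plot of the comparison
    <out>/<instrument>/power.tsv            power over an OR grid

The pipeline is a pure function of (inputs, config, seeds): rerunning with
identical inputs produces a byte-identical bundle. The manifest records the
config hash, seeds and row counts at every selection stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import compare, diagnostics, estimators, instruments, summary_io
from .power import power_table

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "genome_wide_p": 5e-8,
    "clump_r2": 0.01,
    "clump_window_kb": 1000,
    "secondary_p": 0.0005,
    "causal_p": 0.01,  # significance convention for causal associations
}
DEFAULT_OR_GRID = [1.1, 1.2, 1.3, 1.4, 1.5]


class PipelineError(RuntimeError):
    """Fatal pipeline-stage failure (message names the stage and cause)."""


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path} is not a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _read_tables(cfg: dict):
    exp_cfg = cfg["exposure"]
    exposure = summary_io.read_summary_table(
        exp_cfg["path"],
        trait_id=exp_cfg.get("trait_id", "ldl"),
        trait_type="quantitative",
        n_total=exp_cfg.get("n_total"),
        schema=cfg.get("schema"),
    )
    secondary = [
        summary_io.read_summary_table(
            s["path"], trait_id=s["trait_id"], trait_type="quantitative",
            schema=cfg.get("schema"),
        )
        for s in cfg.get("secondary", [])
    ]
    outcomes = [
        summary_io.read_summary_table(
            o["path"],
            trait_id=o["trait_id"],
            trait_type="binary",
            n_cases=o.get("n_cases"),
            n_controls=o.get("n_controls"),
            schema=cfg.get("schema"),
        )
        for o in cfg["outcomes"]
    ]
    if not outcomes:
        raise PipelineError("config lists no outcomes")
    return exposure, secondary, outcomes


def _estimate_all(panel, outcome_ids, methods, n_boot, seed):
    ests = []
    for k, oid in enumerate(outcome_ids):
        for method in methods:
            if method == "ivw_re":
                ests.append(estimators.ivw(panel, oid, "random_multiplicative"))
            elif method == "ivw_fe":
                ests.append(estimators.ivw(panel, oid, "fixed"))
            elif method == "egger":
                ests.append(estimators.mr_egger(panel, oid))
            elif method == "weighted_median":
                ests.append(
                    estimators.weighted_median(
                        panel, oid, n_boot=n_boot, seed=seed + 101 + k
                    )
                )
            elif method == "multivariable":
                if panel.secondary:
                    ests.append(estimators.multivariable_mr(panel, oid))
            else:
                raise PipelineError(f"unknown estimator {method!r}")
    return ests


def _write_estimates(ests, out_dir: Path) -> None:
    import pandas as pd

    rows = [e.to_dict() for e in ests]
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "estimates.tsv", sep="\t", index=False, float_format="%.8g")
    with open(out_dir / "estimates.json", "w") as fh:
        json.dump(rows, fh, indent=1, sort_keys=True, default=float)


def _run_instrument(
    label: str,
    panel,
    cfg: dict,
    out_root: Path,
    seed: int,
    selection_reports,
    manifest_counts: dict,
) -> None:
    out_dir = out_root / label
    out_dir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    sel = pd.concat(selection_reports, ignore_index=True)
    sel.insert(0, "instrument", label)
    sel.to_csv(out_dir / "selection.tsv", sep="\t", index=False)

    methods = cfg.get("estimators", ["ivw_re", "egger", "weighted_median", "multivariable"])
    n_boot = int(cfg.get("n_boot", 1000))
    outcome_ids = panel.outcome_ids
    ests = _stage(
        f"{label}:estimate", _estimate_all, panel, outcome_ids, methods, n_boot, seed
    )
    _write_estimates(ests, out_dir)

    presso_cfg = cfg.get("presso", {})
    # at J~60-100 variants an empirical p floor of 1/(n_sim+1) must clear
    # alpha/J for outlier flagging to be possible at all
    n_sim = int(presso_cfg.get("n_sim", 2500))
    alpha = float(presso_cfg.get("alpha", 0.05))
    for k, oid in enumerate(outcome_ids):
        res = _stage(
            f"{label}:presso:{oid}",
            diagnostics.presso_global,
            panel,
            oid,
            n_sim=n_sim,
            seed=seed + 201 + k,
            alpha=alpha,
        )
        res.report(panel, oid).to_csv(
            out_dir / f"diagnostics_{oid}.tsv", sep="\t", index=False, float_format="%.8g"
        )
        _, pairs = diagnostics.exclude_and_reestimate(
            panel, oid, res, n_boot=n_boot, seed=seed + 301 + k
        )
        payload = {
            "outcome": oid,
            "global_rss": res.global_rss,
            "global_p": res.global_p,
            "n_sim": res.n_sim,
            "outliers": res.outliers,
            "before": {m: e.to_dict() for m, e in pairs["before"].items()},
            "after": {m: e.to_dict() for m, e in pairs["after"].items()},
        }
        with open(out_dir / f"presso_{oid}.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=float)

    reference = cfg.get("reference_outcome", outcome_ids[0])
    ivw_ests = [e for e in ests if e.method == "ivw_re" and e.outcome_id in outcome_ids]
    if ivw_ests:
        table = _stage(
            f"{label}:comparison", compare.comparison_table, ivw_ests, reference
        )
        table.to_csv(out_dir / "comparison.tsv", sep="\t", index=False, float_format="%.8g")
        compare.forest_plot(table, out_dir / "forest.svg")

    # power over the configured OR grid, per outcome study
    r2 = manifest_counts.get(f"{label}:variance_explained")
    if r2 is not None:
        grids = []
        for oid in outcome_ids:
            blk = panel.outcome(oid)
            if blk.n_cases and blk.n_controls:
                tab = power_table(
                    r2,
                    blk.n_cases,
                    blk.n_controls,
                    cfg.get("or_grid", DEFAULT_OR_GRID),
                    alpha=float(
                        cfg.get("thresholds", {}).get(
                            "causal_p", DEFAULT_THRESHOLDS["causal_p"]
                        )
                    ),
                )
                tab.insert(0, "outcome", oid)
                grids.append(tab)
        if grids:
            pd.concat(grids, ignore_index=True).to_csv(
                out_dir / "power.tsv", sep="\t", index=False, float_format="%.8g"
            )


def run_pipeline(
    config,
    out_dir,
    seed: int | None = None,
    instrument: str = "both",
) -> dict:
    """Run the full analysis; returns the manifest dict (also written).

    ``config`` is a YAML path or an already-loaded mapping; ``instrument``
    selects the lipid-``specific`` instrument, the ``all``-variant one, or
    ``both`` (the all-variant branch needs secondary tables to differ).
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    if instrument not in ("specific", "all", "both"):
        raise PipelineError(f"unknown instrument selection {instrument!r}")
    out_root = Path(out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    thr = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}

    exposure, secondary, outcomes = _stage("read", _read_tables, cfg)
    panel = _stage(
        "harmonize",
        summary_io.harmonize,
        exposure,
        secondary,
        outcomes,
        palindrome_policy=cfg.get("palindrome_policy", "drop"),
    )
    counts: dict = {"input_variants": panel.n_variants}

    gw = _stage(
        "genome_wide_filter",
        instruments.filter_genome_wide,
        panel,
        float(thr["genome_wide_p"]),
    )
    panel_gw = gw.apply(panel)
    counts["genome_wide"] = panel_gw.n_variants

    do_clump = cfg.get("clump", True)
    if do_clump:
        if "ld_matrix" not in cfg:
            raise PipelineError(
                "stage 'clump' failed: clumping is enabled but the config names "
                "no 'ld_matrix' input"
            )
        ld = _stage(
            "read_ld",
            instruments.LDMatrix.read,
            cfg["ld_matrix"],
            dict(zip(panel.variant_ids, panel.positions)),
            dict(zip(panel.variant_ids, panel.chromosome)),
        )
        cl = _stage(
            "clump",
            instruments.clump,
            panel_gw,
            ld,
            float(thr["clump_r2"]),
            int(float(thr["clump_window_kb"]) * 1000),
        )
        panel_ind = cl.apply(panel_gw)
    else:
        cl = instruments.InstrumentSelection(retained_ids=list(panel_gw.variant_ids))
        panel_ind = panel_gw
    counts["independent"] = panel_ind.n_variants

    # variance explained on SD-unit betas, before mmol/L scaling
    sd_to_mmol = float(cfg.get("sd_to_mmol", 1.0))

    run_all = instrument in ("all", "both")
    run_specific = instrument in ("specific", "both")

    if run_specific:
        spec_sel = _stage(
            "lipid_specificity",
            instruments.lipid_specificity_filter,
            panel_ind,
            float(thr["secondary_p"]),
        )
        panel_spec = spec_sel.apply(panel_ind)
        counts["lipid_specific"] = panel_spec.n_variants
        r2_spec = (
            instruments.variance_explained(panel_spec)
            if np.all(np.isfinite(panel_spec.eaf))
            else None
        )
        counts["specific:variance_explained"] = r2_spec
        panel_spec = instruments.scale_effects(panel_spec, sd_to_mmol)
        _run_instrument(
            "specific", panel_spec, cfg, out_root, seed, [gw.report(), cl.report(), spec_sel.report()], counts
        )
    if run_all:
        r2_all = (
            instruments.variance_explained(panel_ind)
            if np.all(np.isfinite(panel_ind.eaf))
            else None
        )
        counts["all:variance_explained"] = r2_all
        panel_all = instruments.scale_effects(panel_ind, sd_to_mmol)
        _run_instrument(
            "all", panel_all, cfg, out_root, seed, [gw.report(), cl.report()], counts
        )

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "thresholds": thr,
        "instruments": [
            lab
            for lab, run in (("specific", run_specific), ("all", run_all))
            if run
        ],
        "counts": counts,
        "outcomes": [o.trait_id for o in outcomes],
    }
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    return manifest
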