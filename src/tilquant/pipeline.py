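"""End-to-end orchestration: simulate -> regions -> quantify -> survive.

A single YAML config drives a reproducible run producing the cohort measures
table, the univariable Cox results table (one row per measure and outcome,
hazard ratio with bootstrap CI and Wald p), median-split Kaplan-Meier
results for the intratumoural measures, optional density heatmaps, and a run
log with the seed, bootstrap count, exclusion counts and convergence flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .geometry import build_regions
from .quantify import (
    MARKERS,
    density_heatmap,
    measure_case,
    measure_columns,
    measures_table,
)
from .simulate import SimConfig, generate_cohort, generate_outcomes
from .survival import (
    SurvivalError,
    UnivariateCoxBootstrap,
    dichotomize_median,
    km_logrank,
)

log = logging.getLogger("tilquant")

OUTCOMES = (("RFS", "rfs_months", "rfs_event"), ("OS", "os_months", "os_event"))

#: Measures per marker/outcome family, for the Bonferroni annotation.
FAMILY_SIZE = 7


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    out_dir: Path
    measures: pd.DataFrame
    cox_results: pd.DataFrame
    km_results: pd.DataFrame
    n_cases: int
    errors: list


def compute_measures(cohort) -> pd.DataFrame:
    """RegionSet + measures row for every case of a loaded/simulated cohort."""
    rows = []
    for case, detections in cohort:
        regions = build_regions(case)
        rows.append(measure_case(regions, detections))
    return measures_table(rows)


def _measure_family(measure: str) -> str:
    """Marker or marker-pair family a measure column belongs to."""
    for a, b in (("CD8", "CD3"), ("FOXP3", "CD3"), ("CD8", "FOXP3")):
        if measure.startswith(f"{a}_{b}_ratio"):
            return f"{a}/{b}"
    return measure.split("_", 1)[0]


def cox_table(measures: pd.DataFrame, outcomes: pd.DataFrame, n_boot: int = 5000,
              seed: int = 0) -> pd.DataFrame:
    """Univariable Cox results for every TIL measure and both outcomes.

    p-values below 0.05 are annotated with whether they would survive a
    Bonferroni correction across the family of measures of that marker (or
    marker pair) and outcome; no correction is applied to the estimates.
    """
    joined = measures.join(outcomes, how="inner")
    rows = []
    for mi, measure in enumerate(measure_columns()):
        if measure not in joined.columns:
            continue
        for oi, (oname, tcol, ecol) in enumerate(OUTCOMES):
            rec = {"measure": measure, "outcome": oname, "family": _measure_family(measure)}
            try:
                ss = np.random.SeedSequence([seed, mi, oi])
                fit = UnivariateCoxBootstrap(n_boot=n_boot, random_state=ss).fit(
                    joined[measure], joined[tcol], joined[ecol]
                )
                rec.update(
                    hr=fit.hr, ci_low=fit.ci_low, ci_high=fit.ci_high, p=fit.p,
                    n_used=fit.n_used, n_excluded_undefined=fit.n_excluded_undefined,
                    n_events=fit.n_events, converged=fit.converged,
                    n_boot=fit.n_boot, n_boot_failed=fit.n_boot_failed,
                )
                sig = fit.p < 0.05 if np.isfinite(fit.p) else False
                rec["significant"] = bool(sig)
                rec["survives_bonferroni"] = bool(sig and fit.p < 0.05 / FAMILY_SIZE)
            except SurvivalError as exc:
                rec.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                           converged=False, error=str(exc))
                log.warning("Cox fit failed for %s/%s: %s", measure, oname, exc)
            rows.append(rec)
    return pd.DataFrame(rows)


def km_table(measures: pd.DataFrame, outcomes: pd.DataFrame,
             out_dir: Path | None = None, plots: bool = False) -> pd.DataFrame:
    """Median-split KM + log-rank for the intratumoural measures of each marker."""
    joined = measures.join(outcomes, how="inner")
    rows = []
    for marker in MARKERS:
        for region in ("ITA", "ITT", "ITS"):
            col = f"{marker}_{region}"
            vals = joined[col].dropna()
            sub = joined.loc[vals.index]
            for oname, tcol, ecol in OUTCOMES:
                rec = {"measure": col, "outcome": oname}
                try:
                    labels, cutoff = dichotomize_median(vals.to_numpy())
                    fit = km_logrank(labels, sub[tcol], sub[ecol], cutoff)
                    rec.update(cutoff=fit.cutoff, n_low=fit.n_low, n_high=fit.n_high,
                               logrank_stat=fit.logrank_stat, logrank_p=fit.logrank_p)
                    if out_dir is not None:
                        fit.curves.to_csv(out_dir / f"km_{col}_{oname}.csv", index=False)
                        if plots:
                            _plot_km(fit, col, oname, out_dir / f"km_{col}_{oname}.png")
                except SurvivalError as exc:
                    rec.update(logrank_p=np.nan, error=str(exc))
                rows.append(rec)
    return pd.DataFrame(rows)


def _plot_km(fit, measure: str, outcome: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, sub in fit.curves.groupby("group"):
        ax.step(sub["time"], sub["survival"], where="post", label=f"{group} (cut {fit.cutoff:.2f})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{measure} / {outcome} (log-rank p={fit.logrank_p:.3g})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_heatmap(grid: np.ndarray, path_tiff: Path, path_png: Path) -> None:
    """Density heatmap as single-channel TIFF plus a green-yellow-red PNG."""
    import tifffile

    tifffile.imwrite(str(path_tiff), grid.astype(np.float32))
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("til_density", ["green", "yellow", "red"])
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(grid, cmap=cmap, origin="upper")
    fig.colorbar(im, ax=ax, label="cells / mm$^2$")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path_png, dpi=120)
    plt.close(fig)


def _sim_config_from(doc: dict, seed: int | None) -> SimConfig:
    allowed = {f.name for f in fields(SimConfig)}
    unknown = set(doc) - allowed
    if unknown:
        raise PipelineError(f"unknown simulate config keys: {sorted(unknown)}")
    cfg = SimConfig(**doc)
    if seed is not None:
        cfg = SimConfig(**{**doc, "seed": seed})
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None,
                 seed: int | None = None) -> PipelineResult:
    """One reproducible end-to-end run from a YAML config (path or dict).

    Config keys: ``seed``; either ``simulate`` (SimConfig fields) or
    ``manifest`` (path to an existing cohort); ``n_boot`` (default 5000);
    ``out_dir``; ``heatmaps``/``km_plots`` booleans.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    out_dir = Path(out_dir or config.get("out_dir", "tilquant_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    n_boot = int(config.get("n_boot", 5000))
    errors: list = []

    if "manifest" in config:
        loaded = tio.load_cohort(config["manifest"])
        errors = loaded.errors
        cohort = [(lc.case, lc.detections) for lc in loaded.cases]
        outcomes = loaded.outcomes
        sim_cfg = None
    else:
        sim_cfg = _sim_config_from(dict(config.get("simulate", {})), seed)
        cohort = generate_cohort(sim_cfg)
        outcomes = None

    if not cohort:
        raise PipelineError("empty cohort: no valid cases to analyse")

    measures = compute_measures(cohort)
    if outcomes is None:
        if sim_cfg is None:
            raise PipelineError("manifest provides no outcomes and no simulation config")
        outcomes = generate_outcomes(measures, sim_cfg)
    measures.to_csv(out_dir / "measures.csv")
    outcomes.to_csv(out_dir / "outcomes.csv")

    cox = cox_table(measures, outcomes, n_boot=n_boot, seed=seed)
    cox.to_csv(out_dir / "cox_results.csv", index=False)
    km = km_table(measures, outcomes, out_dir=out_dir, plots=bool(config.get("km_plots", False)))
    km.to_csv(out_dir / "km_results.csv", index=False)

    if config.get("heatmaps", False):
        case, detections = cohort[0]
        for marker in MARKERS:
            grid, _, _ = density_heatmap(detections[marker], case.tissue_extent)
            save_heatmap(grid, out_dir / f"heatmap_{case.case_id}_{marker}.tif",
                         out_dir / f"heatmap_{case.case_id}_{marker}.png")

    import tilquant

    run_log = {
        "seed": seed,
        "n_boot": n_boot,
        "n_cases": len(cohort),
        "n_rejected_cases": len(errors),
        "rejected": errors,
        "n_nonconverged_fits": int((~cox["converged"].fillna(False)).sum()) if "converged" in cox else 0,
        "undefined_exclusions": {
            r["measure"] + "/" + r["outcome"]: int(r["n_excluded_undefined"])
            for _, r in cox.iterrows()
            if pd.notna(r.get("n_excluded_undefined")) and r.get("n_excluded_undefined", 0) > 0
        },
        "version": getattr(tilquant, "__version__", "unknown"),
    }
    (out_dir / "run_log.yaml").write_text(yaml.safe_dump(run_log, sort_keys=False))

    return PipelineResult(out_dir=out_dir, measures=measures, cox_results=cox,
                          km_results=km, n_cases=len(cohort), errors=errors)
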