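"""Cohort-level statistics and end-to-end pipeline orchestration.

Two-way ANOVA (sex x side, with interaction, Type II sums of squares for
unbalanced cohorts) on per-specimen scalars, and ``run_pipeline`` which
takes a directory of traces, force tables and metadata through the full
chain: CAP extraction, constitutive fitting, stretch-reduction mapping
with cohort confidence intervals, latency comparison, optional fiber-angle
comparison, and a finite-element demonstration on a representative
specimen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import fe_rod, fibers, io
from .mechanics import cauchy_stress, circular_area, fit_constitutive, StretchTrial
from .signal import (
    cap_reduction,
    compare_latencies,
    extract_and_average,
    measure_cap,
    preprocess,
)
from .stretch_map import cohort_ci, fit_reduction_spline, stretch_at_reduction

__all__ = ["AnovaResult", "PipelineConfig", "two_way_anova", "run_pipeline"]

logger = logging.getLogger("nervestretch")


@dataclass
class AnovaResult:
    """Two-way ANOVA summary for one response variable."""

    F: dict[str, float]
    p: dict[str, float]
    df: dict[str, float]
    ss_type: str = "II"

    def __post_init__(self):
        for term, pv in self.p.items():
            if not (np.isnan(pv) or 0.0 <= pv <= 1.0):
                raise ValueError(f"p-value for {term} outside [0, 1]")


def two_way_anova(values, sex, side, interaction: bool = True) -> AnovaResult:
    """Two-way ANOVA of a per-specimen scalar on sex and side.

    Uses Type II sums of squares (well-defined for the unbalanced designs
    that arise when a specimen is excluded). An empty design cell forces
    the interaction term to be dropped, with a warning; a factor with a
    single level is an error. A constant response returns F=0, p=1 for
    every term.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "sex": list(sex),
            "side": list(side),
        }
    )
    for f in ("sex", "side"):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level; ANOVA undefined")
    terms = ["sex", "side"] + (["sex:side"] if interaction else [])
    if np.ptp(df["y"].to_numpy()) == 0.0:
        z = {t: 0.0 for t in terms}
        return AnovaResult(F=z, p={t: 1.0 for t in terms}, df={t: 1.0 for t in terms})
    cells = df.groupby(["sex", "side"]).size()
    if interaction and len(cells) < df["sex"].nunique() * df["side"].nunique():
        warnings.warn("empty design cell: interaction term dropped", stacklevel=2)
        interaction = False
    formula = "y ~ C(sex) * C(side)" if interaction else "y ~ C(sex) + C(side)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {"C(sex)": "sex", "C(side)": "side", "C(sex):C(side)": "sex:side"}
    table = table.rename(index=rename)
    keep = [t for t in ("sex", "side", "sex:side") if t in table.index]
    return AnovaResult(
        F={t: float(table.loc[t, "F"]) for t in keep},
        p={t: float(table.loc[t, "PR(>F)"]) for t in keep},
        df={t: float(table.loc[t, "df"]) for t in keep},
    )


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis, in one place."""

    input_dir: str | Path = "."
    output_dir: str | Path = "report"
    band: tuple[float, float] = (100.0, 5000.0)
    baseline_window: float = 5e-3
    median_window: float = 100e-6
    blank_ms: float = 0.5
    epoch_window: float = 20e-3
    smoothing: float = 1.0
    grid_step: float = 2.5
    max_reduction: float = 50.0
    ci_level: float = 0.95
    alpha_significance: float = 0.05
    stop_reduction: float = 50.0   # terminal-trial rule threshold
    fe_n_elem: int = 50
    fe_lam_cap: float = 1.5
    seed: int = 0
    angles_csv: str | None = None  # optional fiber-angle input


def _process_specimen(cfg: PipelineConfig, row) -> dict:
    """CAP chain for one specimen: measurements table rows + spline inputs."""
    in_dir = Path(cfg.input_dir)
    sid = row["id"]
    trace_files = sorted(in_dir.glob(f"{sid}_trace_*.csv"))
    if not trace_files:
        raise FileNotFoundError(
            f"CAP processing: no trace files matching {sid}_trace_*.csv in {in_dir}"
        )
    rows = []
    for tf in trace_files:
        lam = float(tf.stem.rsplit("_", 1)[-1])
        stims = tf.with_name(tf.name.replace("_trace_", "_stims_"))
        trace = io.read_trace(tf, stims)
        clean = preprocess(
            trace, cfg.band, cfg.baseline_window, cfg.median_window,
            stim_blank=cfg.blank_ms * 1e-3,
        )
        t_ep, avg = extract_and_average(clean, cfg.epoch_window)
        meas = measure_cap(
            t_ep, avg, artifact_blank=cfg.blank_ms * 1e-3, n_sweeps=trace.stim_onsets.size
        )
        rows.append(
            dict(
                specimen_id=sid,
                stretch=lam,
                amplitude_mV=meas.amplitude,
                latency_ms=meas.latency,
                n_sweeps=meas.n_sweeps,
            )
        )
    rows.sort(key=lambda r: r["stretch"])
    c_ref = rows[0]["amplitude_mV"]
    for r in rows:
        r["reduction_pct"] = cap_reduction(c_ref, r["amplitude_mV"])
    # terminal-trial rule: stop at first trial reaching the stop threshold
    kept = []
    for r in rows:
        kept.append(r)
        if r["reduction_pct"] >= cfg.stop_reduction or r["stretch"] >= 1.20 - 1e-9:
            break
    return {"measurements": kept}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write the report tables.

    Expects ``cfg.input_dir`` to contain ``cohort_meta.csv`` plus, per
    specimen id, ``<id>_force.csv`` and trace/stimulus CSV pairs (the
    layout produced by :func:`nervestretch.synthetic.write_cohort`).
    Returns the report as a dict of DataFrames (also written as CSV under
    ``cfg.output_dir``).
    """
    in_dir = Path(cfg.input_dir)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = io.read_cohort_meta(in_dir / "cohort_meta.csv")

    fit_rows, meas_rows, stress_rows, curves = [], [], [], []
    lat_unstretched, lat_final = [], []
    lam50_rows = []
    for _, row in meta.iterrows():
        sid = row["id"]
        A0 = circular_area(row["d0_mm"])
        force = io.read_force_table(in_dir / f"{sid}_force.csv")
        stress = np.asarray(
            cauchy_stress(force["force_N"].to_numpy(), A0, force["stretch"].to_numpy())
        )
        trials = [
            StretchTrial(lam=l, force=f, stress=s)
            for l, f, s in zip(force["stretch"], force["force_N"], stress)
        ]
        fit = fit_constitutive(trials)
        fit_rows.append(
            dict(trial=sid, sex=row["sex"], side=row["side"],
                 alpha_MPa=fit.alpha, beta_MPa=fit.beta, r2=fit.r2)
        )
        for tr in trials:
            stress_rows.append(
                dict(specimen_id=sid, stretch=tr.lam, force_N=tr.force, T11_MPa=tr.stress)
            )

        sp = _process_specimen(cfg, row)
        meas = sp["measurements"]
        meas_rows.extend(meas)
        lat_unstretched.append(meas[0]["latency_ms"])
        lat_final.append(meas[-1]["latency_ms"])
        pts = [(m["stretch"], m["reduction_pct"]) for m in meas]
        if len(pts) >= 3:
            curve = fit_reduction_spline(pts, smoothing=cfg.smoothing, specimen_id=sid)
            curves.append(curve)
            try:
                lam50 = stretch_at_reduction(curve, cfg.max_reduction)
            except ValueError:
                lam50 = np.nan
                logger.info("specimen %s never reaches %g%% reduction", sid, cfg.max_reduction)
            lam50_rows.append(
                dict(specimen_id=sid, sex=row["sex"], side=row["side"],
                     lam_at_50=lam50, terminal_reduction=meas[-1]["reduction_pct"])
            )

    fits = pd.DataFrame(fit_rows)
    avg = dict(trial="Average", sex="", side="",
               alpha_MPa=fits["alpha_MPa"].mean(),
               beta_MPa=fits["beta_MPa"].mean(), r2=fits["r2"].mean())
    fits = pd.concat([fits, pd.DataFrame([avg])], ignore_index=True)
    measurements = pd.DataFrame(meas_rows)
    stresses = pd.DataFrame(stress_rows)
    lam50_df = pd.DataFrame(lam50_rows)

    ci = cohort_ci(curves, cfg.grid_step, cfg.max_reduction, cfg.ci_level)
    ci_df = pd.DataFrame(
        dict(
            reduction_pct=ci.reduction_grid,
            mean_stretch=ci.mean_stretch,
            ci_low=ci.mean_stretch - ci.half_width,
            ci_high=ci.mean_stretch + ci.half_width,
            n=ci.n_contributing,
        )
    )

    stats_rows = []
    ok = lam50_df["lam_at_50"].notna()
    try:
        an = two_way_anova(lam50_df.loc[ok, "lam_at_50"],
                           lam50_df.loc[ok, "sex"], lam50_df.loc[ok, "side"])
        for term in an.p:
            stats_rows.append(dict(test=f"anova_lam50_{term}", statistic=an.F[term], p=an.p[term]))
    except ValueError as err:
        logger.warning("ANOVA on stretch-at-50%% skipped: %s", err)
    for var in ("alpha_MPa", "beta_MPa"):
        sub = fits[fits["trial"] != "Average"]
        try:
            an = two_way_anova(sub[var], sub["sex"], sub["side"])
            for term in an.p:
                stats_rows.append(dict(test=f"anova_{var}_{term}", statistic=an.F[term], p=an.p[term]))
        except ValueError as err:
            logger.warning("ANOVA on %s skipped: %s", var, err)
    t_stat, t_p = compare_latencies(lat_unstretched, lat_final)
    stats_rows.append(dict(test="latency_t", statistic=t_stat, p=t_p))

    if cfg.angles_csv is not None:
        angle_df = io.read_fiber_angles(cfg.angles_csv)
        fwhm_by_group: dict[str, list[float]] = {}
        for (sid, group), g in angle_df.groupby(["specimen_id", "group"]):
            fs = fibers.normalize_angles(
                g["angle_deg"].to_numpy(), g["section"].to_numpy(), sid, group
            )
            fwhm_by_group.setdefault(group, []).append(fibers.fwhm(fibers.bin_histogram(fs)))
        if {"control", "stretched"} <= set(fwhm_by_group):
            pooled = np.array(fwhm_by_group["control"] + fwhm_by_group["stretched"])
            keep = fibers.iqr_outliers(pooled)
            nc = len(fwhm_by_group["control"])
            res = fibers.compare_groups(
                pooled[:nc][keep[:nc]], pooled[nc:][keep[nc:]]
            )
            stats_rows.append(dict(test="fwhm_F", statistic=res["F_stat"], p=res["F_p"]))
            stats_rows.append(
                dict(test=f"fwhm_t_{res['variant']}", statistic=res["t_stat"], p=res["t_p"])
            )
    stats_df = pd.DataFrame(stats_rows)

    # FE demonstration: representative (first) specimen, uniform geometry
    fe_df = pd.DataFrame()
    if curves and not lam50_df.empty and np.isfinite(lam50_df["lam_at_50"].iloc[0]):
        rep = meta.iloc[0]
        rep_fit = fit_rows[0]
        mesh = fe_rod.build_mesh(
            fe_rod.uniform_profile(rep["d0_mm"]), rep["L0_mm"], cfg.fe_n_elem
        )
        sol = fe_rod.solve_stretch_controlled(
            mesh, rep_fit["alpha_MPa"], rep_fit["beta_MPa"],
            float(lam50_df["lam_at_50"].iloc[0]), lam_cap=cfg.fe_lam_cap,
        )
        sol = fe_rod.map_cap_field(sol, curves[0])
        fe_rod.export_field(sol, mesh, out_dir / "fe_demo.vtk")
        z_mid = 0.5 * (mesh.z_nodes[:-1] + mesh.z_nodes[1:])
        fe_df = pd.DataFrame(
            dict(z_mid_mm=z_mid, lam=sol.lam_elem, T11_MPa=sol.T11_elem,
                 reduction_pct=sol.reduction_elem)
        )

    report = {
        "fits": fits,
        "measurements": measurements,
        "ci": ci_df,
        "stresses": stresses,
        "lam50": lam50_df,
        "stats": stats_df,
        "fe_field": fe_df,
    }
    names = dict(fits="fits.csv", measurements="measurements.csv", ci="ci.csv",
                 stresses="stresses.csv", lam50="stretch_at_50.csv",
                 stats="stats_summary.csv", fe_field="fe_field.csv")
    for key, fname in names.items():
        report[key].to_csv(out_dir / fname, index=False, float_format="%.10g")
    return report
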