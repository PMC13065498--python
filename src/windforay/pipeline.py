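"""End-to-end orchestration: simulate -> screen -> segment -> model.

The stages mirror the analysis workflow: estimate each individual's
home range and 95% isopleth, cut the fix series into within-range runs
and extra-home-range excursion tracks, cluster the complete tracks into
medium- and long-range movement types, annotate every fix with hourly
weather, then fit the ordinal additive model for movement type and the
Gamma mixed model for LRM duration.  All stage outputs are flat files
(CSV / JSON) plus a run report, and a single master seed propagates
deterministically to every stochastic stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, duration_glmm, home_range, ordinal_gam, segmentation
from . import synthetic, track_io, weather as weather_mod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    out_dir: str | Path | None = None
    offshore_max_km: float = 5.0
    min_duration_days: float = 300.0
    grid_cell_km: float = 0.5
    isopleth_level: float = 0.95
    k_clusters: int = 2
    do_screen: bool = True
    do_cluster: bool = True
    do_ordinal: bool = True
    do_duration: bool = True
    ordinal_spec: ordinal_gam.OrdinalGamSpec | None = None
    ordinal_lambda_grid: np.ndarray | None = None
    ordinal_refine: bool = False
    seed: int = 42


@dataclass
class RunResult:
    fixes: pd.DataFrame
    tracks: pd.DataFrame
    labels: np.ndarray
    truth: pd.DataFrame | None
    ordinal_fit: ordinal_gam.OrdinalGamFit | None
    duration_fit: duration_glmm.DurationGlmmFit | None
    duration_steps: pd.DataFrame | None
    report: dict


def _small_ordinal_spec() -> ordinal_gam.OrdinalGamSpec:
    """Reduced model used by the pipeline default: the weather terms.

    Direction x strength tensor, radiation spline and per-individual
    random intercepts — the terms the synthetic generator encodes.
    """
    return ordinal_gam.OrdinalGamSpec(
        terms=[
            ordinal_gam.Term("tensor", ("wind_dir_deg", "wind_kmh"),
                             k=(8, 5), period=360.0, name="te(dir,wind)"),
            ordinal_gam.Term("spline", ("radiation_wm2",), k=6, name="f(rad)"),
            ordinal_gam.Term("random", ("individual_id",), name="b(individual)"),
        ]
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all enabled stages and assemble the run report."""
    report: dict = {"seed": config.seed, "stages": {}}
    config.sim.seed = config.seed

    sim = synthetic.simulate_dataset(config.sim)
    fixes, weather, coast, truth = sim.fixes, sim.weather, sim.coast, sim.truth
    report["stages"]["simulate"] = {
        "n_fixes": int(len(fixes)),
        "n_individuals": int(fixes["individual_id"].nunique()),
    }

    if config.do_screen:
        fixes, removed = track_io.filter_offshore(fixes, coast, config.offshore_max_km)
        n_off = len(removed)
        fixes = track_io.filter_min_duration(fixes, config.min_duration_days)
        report["stages"]["screen"] = {
            "removed_offshore": int(n_off),
            "n_fixes_after": int(len(fixes)),
            "n_individuals_after": int(fixes["individual_id"].nunique()),
        }
        if truth is not None:
            key = ["individual_id", "timestamp"]
            truth = truth.merge(fixes[key], on=key, how="inner")

    all_tracks: list[pd.DataFrame] = []
    labels = np.array(["SRM"] * len(fixes), dtype=object)
    hr_info = {}
    per_ind_tracks: dict[str, list] = {}
    per_ind_slice: dict[str, np.ndarray] = {}
    for ind, sub in fixes.groupby("individual_id", sort=True):
        hr, poly = home_range.fit_home_range(sub.reset_index(drop=True),
                                             config.grid_cell_km,
                                             config.isopleth_level)
        tracks, inside = segmentation.segment_individual(sub.reset_index(drop=True), poly)
        per_ind_tracks[ind] = tracks
        per_ind_slice[ind] = sub.index.to_numpy()
        hr_info[ind] = {"tau_hat_h": hr.tau_hat_h, "n_eff": hr.n_eff,
                        "n_tracks": len(tracks)}
        frame = segmentation.tracks_to_frame(tracks)
        frame["individual_id"] = ind
        all_tracks.append(frame)
    track_table = pd.concat(all_tracks, ignore_index=True) if all_tracks else pd.DataFrame()
    if len(track_table):
        track_table["track_id"] = np.arange(len(track_table))
    report["stages"]["home_range"] = hr_info
    report["stages"]["segment"] = {
        "n_tracks": int(len(track_table)),
        "n_complete": int(track_table["complete"].sum()) if len(track_table) else 0,
    }

    duration_fit = duration_steps = None
    ordinal_fit = None
    if config.do_cluster and len(track_table):
        fm = clustering.build_features(track_table)
        pam_res = clustering.pam(fm, config.k_clusters)
        mapping = clustering.assign_movement_labels(pam_res, track_table, fm)
        track_table = clustering.apply_cluster_labels(track_table, fm, pam_res, mapping)
        # push labels back onto the per-individual track objects
        lab_by_id = dict(zip(track_table["track_id"], track_table["label"]))
        offset = 0
        for ind in sorted(per_ind_tracks):
            tracks = per_ind_tracks[ind]
            sub_ids = track_table[track_table["individual_id"] == ind]["track_id"]
            for t, tid in zip(tracks, sub_ids):
                t.label = lab_by_id.get(tid, "")
            sub_fixes = fixes.loc[per_ind_slice[ind]].reset_index(drop=True)
            ind_labels = segmentation.label_fixes(sub_fixes, tracks,
                                                  inside=np.zeros(len(sub_fixes)))
            labels[per_ind_slice[ind]] = ind_labels
        counts = pd.Series(labels).value_counts().to_dict()
        report["stages"]["cluster"] = {
            "k": config.k_clusters,
            "mean_silhouette": pam_res.silhouette_mean,
            "cluster_sizes": {m: int((track_table["label"] == m).sum())
                              for m in set(mapping.values())},
            "label_totals": {k: int(v) for k, v in counts.items()},
        }
    else:
        report["stages"]["cluster"] = {"skipped": True}

    annotated = weather_mod.annotate(fixes, weather)
    annotated["label"] = labels
    report["stages"]["annotate"] = {
        "n_missing_weather": int(annotated["weather_missing"].sum()),
        "n_calm": int(annotated["calm_flag"].sum()),
    }

    conservation = {
        "n_fixes": int(len(fixes)),
        "label_totals": {k: int(v) for k, v in
                         pd.Series(labels).value_counts().items()},
    }
    conservation["sum_labels"] = int(sum(conservation["label_totals"].values()))
    conservation["holds"] = conservation["sum_labels"] == conservation["n_fixes"]
    report["conservation"] = conservation

    if config.do_ordinal and config.do_cluster:
        model_data = annotated[~annotated["weather_missing"]].copy()
        spec = config.ordinal_spec or _small_ordinal_spec()
        grid = (config.ordinal_lambda_grid if config.ordinal_lambda_grid is not None
                else np.logspace(-2, 3, 6))
        ordinal_fit = ordinal_gam.fit_ordinal_gam(
            spec, model_data, lambda_grid=grid, refine=config.ordinal_refine)
        report["stages"]["ordinal"] = {
            "aic": ordinal_fit.aic,
            "edf": ordinal_fit.edf_total,
            "converged": bool(ordinal_fit.converged),
            "theta2": ordinal_fit.theta2,
        }

    if config.do_duration and config.do_cluster:
        try:
            lrm = duration_glmm.build_lrm_table(track_table, annotated)
            duration_fit, duration_steps = duration_glmm.stepwise_forward(lrm)
            report["stages"]["duration"] = {
                "n_lrm_tracks": int(len(lrm)),
                "selected_terms": list(duration_fit.terms),
                "aic": duration_fit.aic,
            }
        except ValueError as exc:
            report["stages"]["duration"] = {"failed": str(exc)}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        track_io.write_fixes(annotated, out / "annotated_fixes.csv")
        if len(track_table):
            track_table.to_csv(out / "excursion_tracks.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return RunResult(fixes=annotated, tracks=track_table, labels=labels,
                     truth=truth, ordinal_fit=ordinal_fit,
                     duration_fit=duration_fit, duration_steps=duration_steps,
                     report=report)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def make_figures(result: RunResult, out_dir: str | Path) -> list[Path]:
    """Probability surface, radiation marginal and duration-curve figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if result.ordinal_fit is not None:
        surf = ordinal_gam.predict_surface(result.ordinal_fit)
        fig, axes = plt.subplots(1, 3, figsize=(13, 4), constrained_layout=True)
        for ax, cat in zip(axes, ordinal_gam.CATEGORIES):
            pm = ax.pcolormesh(surf["dir_deg"], surf["wind_kmh"], surf["prob"][cat],
                               shading="auto")
            ax.set_title(f"P({cat})")
            ax.set_xlabel("wind direction (deg from N)")
            ax.set_ylabel("wind strength (km/h)")
            fig.colorbar(pm, ax=ax)
        p = out / "probability_surface.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        fit = result.ordinal_fit
        rad = np.linspace(0, 800, 80)
        frame = ordinal_gam.reference_frame(fit, len(rad), {"radiation_wm2": rad})
        excl = tuple(b.term.name for b in fit.blocks if b.term.kind == "random")
        probs = ordinal_gam.predict_probabilities(fit, frame, exclude=excl)
        fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
        for i, cat in enumerate(ordinal_gam.CATEGORIES):
            ax.plot(rad, probs[:, i], label=cat)
        ax.set_xlabel("solar radiation (W/m2)")
        ax.set_ylabel("probability")
        ax.legend()
        p = out / "radiation_marginal.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if result.duration_fit is not None and "median_radiation_z" in result.duration_fit.beta_names:
        fit = result.duration_fit
        z = np.linspace(-2, 2, 50)
        frame = pd.DataFrame({"median_radiation_z": z, "age_z": 0.0, "cohort": "c1"})
        X, _ = duration_glmm._design(
            frame, tuple(t for t in fit.terms if t != "random_intercept"))
        mu = np.exp(X @ fit.beta)
        fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
        ax.plot(z, mu)
        ax.set_xlabel("median solar radiation (z-score)")
        ax.set_ylabel("expected LRM duration (h)")
        p = out / "duration_vs_radiation.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
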