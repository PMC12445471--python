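"""Cross-depth, cross-hierarchy and cross-species comparison layer.

Consumes per-(parcel, depth) trajectory results and a hierarchy axis and
produces the comparison report: depth-wise slope ANOVAs, slope-versus-
hierarchy gradients, plateau proportions and timing, deep-superficial slope
gaps, and the 4:1 cross-species age scaling.  ``run_pipeline`` wires the
whole synthetic pipeline end to end from a config dict.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import depth as depth_mod
from . import gam, hierarchy, synthetic, tables
from .gam import DerivativeBand
from .hierarchy import GROUPS

__all__ = [
    "mean_slope",
    "depth_slope_anova",
    "slope_vs_hierarchy",
    "plateau_summaries",
    "deep_superficial_gap",
    "scale_age",
    "demo_config",
    "run_pipeline",
]

log = logging.getLogger(__name__)


def mean_slope(band: DerivativeBand) -> float:
    """Grid-uniform mean of the derivative estimate."""
    return band.mean_slope()


def depth_slope_anova(slopes: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA of per-parcel slopes across depth bins.

    ``slopes`` needs columns ``depth_bin`` and ``mean_slope``; parcels are the
    units.  Returns (F, p) with (bins - 1, N - bins) degrees of freedom.
    """
    groups = [g["mean_slope"].to_numpy(float) for _, g in slopes.groupby("depth_bin")]
    if len(groups) < 2:
        raise ValueError("need at least 2 depth bins")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every depth bin needs at least 2 parcels")
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ss_within <= 0:
        if ss_between <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    return float(f), float(stats.f.sf(f, df_between, df_within))


def slope_vs_hierarchy(
    slopes: pd.Series, axis: hierarchy.HierarchyAxis, *, use_rank: bool = True, seed: int = 0
) -> dict:
    """Smooth regression of per-parcel slope on hierarchy position.

    Uses the same rank-3 penalized smooth machinery as the trajectory fits.
    ``use_rank`` regresses on the normalized sensorimotor-to-association rank
    (0 = sensorimotor end); otherwise on the raw axis score.  Returns R^2,
    a nested-model p-value, the fitted curve with a pointwise 95% CI, and the
    mean derivative of the fit along the axis.
    """
    x = axis.sa_rank() if use_rank else axis.scores
    shared = slopes.index.intersection(x.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 parcels")
    xv = x.loc[shared].to_numpy(float)
    yv = slopes.loc[shared].to_numpy(float)
    if np.std(xv) == 0:
        raise ValueError("hierarchy axis is constant")
    df = pd.DataFrame({"age": xv, "value": yv})
    full = gam.fit_gam(df, sex_col=None, subject_col=None)
    reduced = gam.fit_gam(df, sex_col=None, subject_col=None, include_age=False)
    band = gam.derivative_band(full, seed=seed)
    grid = band.grid
    B = full.basis.evaluate(grid)
    icpt = full.term_slices["intercept"]
    s = full.term_slices["age"]
    Xg = np.hstack([np.ones((len(grid), 1)), B])
    cols = np.r_[np.arange(icpt.start, icpt.stop), np.arange(s.start, s.stop)]
    Vg = full.cov[np.ix_(cols, cols)]
    curve = Xg @ full.beta[cols]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, Vg, Xg), 0.0))
    zcrit = stats.norm.ppf(0.975)
    return {
        "r2": full.r2,
        "p": gam.age_significance(full, reduced),
        "grid": grid,
        "fitted": curve,
        "ci_lower": curve - zcrit * se,
        "ci_upper": curve + zcrit * se,
        "mean_derivative": float(band.estimate.mean()),
        "n_parcels": int(len(shared)),
    }


def plateau_summaries(
    results: pd.DataFrame, axis: hierarchy.HierarchyAxis, *, by_depth: bool = True
) -> dict:
    """Plateau proportions and timing per hierarchy group (and group x depth).

    The timing ANOVA runs across groups among plateaued parcels only; groups
    with no plateaued parcel are excluded with a warning and the censored
    fraction is reported alongside.
    """
    res = results.merge(
        axis.table.reset_index()[["parcel_id", "group"]], on="parcel_id", how="left"
    )
    prop_group = (
        res.groupby("group", sort=False)["plateau_reached"].mean().reindex(list(GROUPS))
    )
    out: dict = {
        "proportion_by_group": prop_group.to_dict(),
        "censored_fraction": float(1.0 - res["plateau_reached"].mean()),
    }
    if by_depth:
        out["proportion_by_group_depth"] = (
            res.groupby(["group", "depth_bin"], sort=True)["plateau_reached"]
            .mean()
            .unstack("depth_bin")
            .reindex(list(GROUPS))
            .to_dict(orient="index")
        )
    plateaued = res[res["plateau_reached"]]
    timing_groups = [
        g["plateau_age"].to_numpy(float)
        for name, g in plateaued.groupby("group")
        if len(g) >= 2
    ]
    dropped = set(res["group"].unique()) - {
        name for name, g in plateaued.groupby("group") if len(g) >= 2
    }
    if dropped:
        log.warning("timing ANOVA excludes groups with <2 plateaued parcels: %s", dropped)
    if len(timing_groups) >= 2:
        f, p = stats.f_oneway(*timing_groups)
        out["timing_anova"] = {"F": float(f), "p": float(p)}
        out["mean_plateau_age_by_group"] = (
            plateaued.groupby("group")["plateau_age"].mean().to_dict()
        )
    else:
        out["timing_anova"] = None
        log.warning("timing ANOVA skipped: fewer than 2 groups with plateaus")
    return out


def deep_superficial_gap(
    results: pd.DataFrame, axis: hierarchy.HierarchyAxis, *, seed: int = 0
) -> dict:
    """Per-parcel slope gap between deepest and most superficial retained bins.

    ``gap = slope(deepest) - slope(most superficial)``, then regressed on the
    hierarchy axis with the smooth machinery.  Parcels missing either extreme
    bin are skipped with a warning.
    """
    bins = sorted(results["depth_bin"].unique())
    deepest, superficial = bins[0], bins[-1]
    wide = results.pivot_table(
        index="parcel_id", columns="depth_bin", values="mean_slope"
    )
    ok = wide[[deepest, superficial]].dropna()
    skipped = len(wide) - len(ok)
    if skipped:
        log.warning("deep_superficial_gap: %d parcels missing an extreme bin", skipped)
    gap = ok[deepest] - ok[superficial]
    fit = slope_vs_hierarchy(gap, axis, seed=seed)
    return {
        "gap": gap,
        "deepest_bin": deepest,
        "superficial_bin": superficial,
        "fit": fit,
    }


def scale_age(age, factor: float = 4.0, direction: str = "macaque_to_human"):
    """Cross-species developmental age mapping (default 4:1 macaque:human)."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    if factor <= 0:
        raise ValueError("factor must be positive")
    if direction == "macaque_to_human":
        out = age * factor
    elif direction == "human_to_macaque":
        out = age / factor
    else:
        raise ValueError(f"unknown direction: {direction}")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# pipeline orchestration


def demo_config(seed: int = 0) -> dict:
    """Demo configuration: 60 parcels, 7->5 trimmed depth bins, inside-out +
    hierarchy truth, one human-like and one macaque-like design."""
    return {
        "seed": seed,
        "mesh": {"subdivisions": 3, "radius": 60.0},
        "n_parcels": 60,
        "depth": {"n_bins": 7, "trim": True},
        "hierarchy": {
            "region_fraction": 0.10,
            "n_clusters": 12,
            "seed_fraction": 0.25,
        },
        "truth": {
            "baseline": 1.2,
            "amplitude_fast": 0.50,
            "amplitude_slow": 0.45,
            "depth_rate_hi": 1.35,
            "depth_rate_lo": 0.65,
            "depth_amp_hi": 1.15,
            "depth_amp_lo": 0.85,
            "sigma": 0.03,
            "beta_sex": 0.02,
        },
        "designs": {
            "human_like": {
                "mode": "cross_sectional",
                "species": "human",
                "n_subjects": 200,
                "age_min": 5.5,
                "age_max": 36.0,
                "onset": 5.0,
                "rate_fast": 0.18,
                "rate_slow": 0.02,
                "sigma_b": 0.0,
                "random_intercept": "off",
            },
            "macaque_like": {
                "mode": "longitudinal",
                "species": "macaque",
                "n_subjects": 33,
                "timepoints": 5,
                "n_short_subjects": 1,
                "age_min": 1.0 / 12.0,
                "age_max": 3.0,
                "onset": 0.0,
                "rate_fast": 3.0,
                "rate_slow": 1.2,
                "amplitude_fast": 0.50,
                "amplitude_slow": 0.30,
                "sigma_b": 0.05,
                "random_intercept": "subject",
            },
        },
        "gam": {"k": 3, "grid_size": 100, "n_sim": 4000, "level": 0.95},
        "scaling_factor": 4.0,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic pipeline and build the comparison report.

    Stages: mesh + parcellation -> equi-volume depth bins -> geodesic
    hierarchy axis + tripartition -> ground-truth trajectories -> measurement
    tables -> per-cell GAM fits -> comparison report.  When ``out_dir`` is
    given, intermediate CSV/JSON artifacts and a manifest with seeds,
    parameters and file hashes are written; reruns with the same config are
    byte-identical.
    """
    t0 = time.time()
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    report: dict = {"config": config, "stages": {}}

    def stage_done(name):
        report["stages"][name] = round(time.time() - t0, 3)
        log.info("stage %-12s done at %.2fs", name, report["stages"][name])

    # --- mesh, parcellation ------------------------------------------------
    try:
        mesh = synthetic.make_test_mesh(
            config["mesh"]["subdivisions"], config["mesh"]["radius"]
        )
        labels = synthetic.assign_parcels(mesh, config["n_parcels"], seed=seed)
    except Exception as err:
        raise RuntimeError(f"stage 'mesh' failed: {err}") from err
    stage_done("mesh")

    # --- equi-volume depth bins -------------------------------------------
    try:
        dcfg = config["depth"]
        geoms = {}
        binnings = {}
        for pid in np.unique(labels):
            a_in = float(rng.uniform(0.8, 1.2))
            a_out = float(rng.uniform(0.8, 1.2))
            geoms[pid] = depth_mod.ColumnGeometry(A_in=a_in, A_out=a_out, thickness=2.5)
            b = depth_mod.bin_boundaries(dcfg["n_bins"], geoms[pid])
            binnings[pid] = depth_mod.trim_bins(b) if dcfg.get("trim") else b
        depth_bins = list(range(1, next(iter(binnings.values())).n_bins + 1))
    except Exception as err:
        raise RuntimeError(f"stage 'depth' failed: {err}") from err
    stage_done("depth")

    # --- hierarchy axis ----------------------------------------------------
    try:
        hcfg = config["hierarchy"]
        # association-like region: cap of vertices nearest the +z pole
        z = mesh.vertices[:, 2]
        n_region = max(int(np.ceil(hcfg["region_fraction"] * mesh.n_vertices)), 8)
        region = np.argsort(-z, kind="stable")[:n_region]
        seeds = hierarchy.select_seed_vertices(
            mesh, region, hcfg["n_clusters"], hcfg["seed_fraction"], seed=seed
        )
        dist = hierarchy.geodesic_distances(mesh, seeds)
        axis = hierarchy.parcel_hierarchy(mesh, labels, dist)
        axis = hierarchy.tripartition(axis, ordering="descending")
    except Exception as err:
        raise RuntimeError(f"stage 'hierarchy' failed: {err}") from err
    stage_done("hierarchy")

    # --- designs: truth, dataset, fits ------------------------------------
    sa = axis.sa_rank()
    per_design: dict = {}
    gcfg = config["gam"]
    for name, dcfg_i in config["designs"].items():
        try:
            truth_kwargs = dict(config.get("truth", {}))
            for key in (
                "onset", "rate_fast", "rate_slow", "sigma_b",
                "amplitude_fast", "amplitude_slow", "sigma", "beta_sex",
            ):
                if key in dcfg_i:
                    truth_kwargs[key] = dcfg_i[key]
            truth = synthetic.make_inside_out_truth(
                sa.index.to_numpy(), sa.to_numpy(), depth_bins, **truth_kwargs
            )
            design = synthetic.StudyDesign(
                mode=dcfg_i["mode"],
                n_subjects=dcfg_i["n_subjects"],
                age_min=dcfg_i["age_min"],
                age_max=dcfg_i["age_max"],
                timepoints=dcfg_i.get("timepoints"),
                n_short_subjects=dcfg_i.get("n_short_subjects", 0),
                species=dcfg_i["species"],
                seed=seed + zlib.crc32(name.encode()) % 100003,
            )
            table = synthetic.generate_dataset(design, truth)
            tables.validate_table(table)
            results, bands = gam.fit_trajectories(
                table,
                random_intercept=dcfg_i.get("random_intercept", "off"),
                k=gcfg.get("k", 3),
                grid_size=gcfg.get("grid_size", 100),
                n_sim=gcfg.get("n_sim", 10000),
                level=gcfg.get("level", 0.95),
                seed=seed,
            )
            per_design[name] = {
                "design": design,
                "truth": truth,
                "table": table,
                "results": results,
                "bands": bands,
            }
        except Exception as err:
            raise RuntimeError(f"stage 'fit:{name}' failed: {err}") from err
        stage_done(f"fit:{name}")

    # --- comparison report -------------------------------------------------
    comparison: dict = {"axis_orientation": axis.orientation, "anova_units": "parcels"}
    for name, d in per_design.items():
        res = d["results"]
        entry: dict = {}
        res_g = res.merge(
            axis.table.reset_index()[["parcel_id", "group"]], on="parcel_id"
        )
        entry["depth_anova_by_group"] = {}
        for g, sub in res_g.groupby("group"):
            f, p = depth_slope_anova(sub)
            entry["depth_anova_by_group"][g] = {"F": f, "p": p}
        f_all, p_all = depth_slope_anova(res)
        entry["depth_anova_all"] = {"F": f_all, "p": p_all}
        entry["mean_slope_by_depth"] = (
            res.groupby("depth_bin")["mean_slope"].mean().to_dict()
        )
        parcel_slopes = res.groupby("parcel_id")["mean_slope"].mean()
        svh = slope_vs_hierarchy(parcel_slopes, axis, seed=seed)
        entry["slope_vs_hierarchy"] = {
            k: v for k, v in svh.items() if k in ("r2", "p", "mean_derivative", "n_parcels")
        }
        entry["plateaus"] = plateau_summaries(res, axis)
        gap = deep_superficial_gap(res, axis, seed=seed)
        entry["deep_superficial_gap"] = {
            "mean_gap": float(gap["gap"].mean()),
            "deepest_bin": int(gap["deepest_bin"]),
            "superficial_bin": int(gap["superficial_bin"]),
            "fit": {
                k: v
                for k, v in gap["fit"].items()
                if k in ("r2", "p", "mean_derivative", "n_parcels")
            },
        }
        comparison[name] = entry
    comparison["scaling_factor"] = config.get("scaling_factor", 4.0)
    report["comparison"] = comparison
    report["axis"] = axis
    report["per_design"] = per_design
    stage_done("report")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = []
        axis.table.to_csv(out / "hierarchy_axis.csv")
        files.append(out / "hierarchy_axis.csv")
        pd.DataFrame({"vertex": np.arange(mesh.n_vertices), "parcel_id": labels}).to_csv(
            out / "parcellation.csv", index=False
        )
        files.append(out / "parcellation.csv")
        for name, d in per_design.items():
            d["table"].to_csv(out / f"table_{name}.csv", index=False)
            d["results"].to_csv(out / f"results_{name}.csv", index=False)
            files += [out / f"table_{name}.csv", out / f"results_{name}.csv"]
        with open(out / "report.json", "w") as fh:
            json.dump(comparison, fh, indent=1, default=_json_default)
        files.append(out / "report.json")
        manifest = {
            "seed": seed,
            "config": config,
            "files": {f.name: _sha256(f) for f in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
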