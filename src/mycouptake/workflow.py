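"""End-to-end synthetic study orchestration.

`run_study` executes the pipeline replica in dependency order —
simulate observations -> fit growth kinetics -> simulate / fit the P
depletion profile (with both 'total' and 'pore' length-density sources) ->
skeleton morphometrics per preset -> XRF correlation statistics -> XANES
speciation trend — and assembles a machine-readable `StudyReport`.

The report is deterministic given (config, seed): timestamps are kept out
of the report body, every stage derives its seed from the master seed, and
stage outputs are cached in ``out_dir/stages`` keyed by a hash of the
stage config so partial reruns skip completed stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chem import class_statistics, classify_phases, distance_classes, elemental_classes
from .growth import GrowthParams
from .inference import aggregate_replicates, fit_growth, fit_uptake
from .skeleton import compute_metrics
from .synthetic import (
    WEEK_S,
    gen_length_density_obs,
    gen_p_profile,
    gen_skeleton,
    gen_xanes,
    gen_xanes_library,
    gen_xrf_maps,
)
from .uptake import UptakeParams
from .xanes import speciation_vs_distance

logger = logging.getLogger("mycouptake.workflow")

__all__ = ["default_config", "run_study", "StudyReport"]


def default_config() -> dict:
    """Study-replica defaults mirroring the experimental design."""
    return {
        "seed": 0,
        "growth": {
            "treatments": {
                "inoculated": {"k": 4.66e-4, "v": 1.64e-5, "b_branch": 2.07e-6, "d": 0.0},
            },
            "positions_cm": [1.35, 2.85, 4.35],
            "times_wk": [2.0, 4.0],
            "n_replicates": 3,
            "noise_level": 0.10,
            "n_starts": 8,
            "fix_d": True,
        },
        "uptake": {
            "lambda_h_true": 1.05e-7,
            "d_eff": 1.05e-8,
            "r_m": 5e-4,
            "c_inf": 1.0,
            "t_final_wk": 4.0,
            "noise_sd": 0.0,
            "rho_sources": ["total", "pore"],
            "pore_fraction": 0.02,
            "profile_x_max_cm": 1.0,
            "n_profile_points": 21,
        },
        "skeleton": {
            "presets": ["inoculated", "control"],
            "length_um": 400.0,
            "radius_um": 150.0,
            "voxel_size_um": 4.0,
            "n_tips": 6,
            "voxelize": False,
        },
        "xrf": {
            "shape": [192, 192],
            "pixel_size_um": 10.0,
            "elements": ["P", "S", "Al"],
        },
        "xanes": {
            "distances_um": [25.0, 75.0, 150.0, 300.0, 600.0],
            "oxidized_near": 0.75,
            "oxidized_far": 0.25,
            "snr": 50.0,
            "bins_um": [0.0, 100.0, 200.0, 400.0, 800.0],
        },
    }


@dataclass
class StudyReport:
    """Machine-readable study outcome with provenance."""

    body: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.body, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def __getitem__(self, key):
        return self.body[key]


def _hash_cfg(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


class _StageCache:
    def __init__(self, out_dir: Path | None):
        self.dir = out_dir / "stages" if out_dir else None
        if self.dir:
            self.dir.mkdir(parents=True, exist_ok=True)

    def get(self, stage: str, key: str):
        if not self.dir:
            return None
        path = self.dir / f"{stage}-{key}.json"
        if path.exists():
            logger.info("stage %s: cached result reused", stage)
            return json.loads(path.read_text())
        return None

    def put(self, stage: str, key: str, value: dict) -> None:
        if self.dir:
            (self.dir / f"{stage}-{key}.json").write_text(
                json.dumps(value, sort_keys=True)
            )


def _growth_stage(cfg: dict, seed: int) -> dict:
    out = {}
    for i, (treatment, pdict) in enumerate(sorted(cfg["treatments"].items())):
        params = GrowthParams(**pdict)
        obs, truth = gen_length_density_obs(
            params,
            positions_cm=cfg["positions_cm"],
            times_s=[w * WEEK_S for w in cfg["times_wk"]],
            n_replicates=cfg["n_replicates"],
            noise_level=cfg["noise_level"],
            seed=seed + i,
        )
        fits = []
        for r in range(cfg["n_replicates"]):
            fit = fit_growth(
                obs.subset_replicate(r),
                fix_d=cfg.get("fix_d", True),
                n_starts=cfg["n_starts"],
                seed=seed + 100 + r,
            )
            fits.append(fit)
        agg = aggregate_replicates(fits)
        out[treatment] = {
            "true_params": pdict,
            "mean": agg.mean,
            "sd": agg.sd,
            "replicates": agg.replicate_table.to_dict(orient="records"),
        }
    return out


def _uptake_stage(cfg: dict, growth_results: dict, seed: int) -> dict:
    treatment = sorted(growth_results)[0]
    truth_params = GrowthParams(**growth_results[treatment]["true_params"])
    uparams = UptakeParams(
        d_eff=cfg["d_eff"],
        r_m=cfg["r_m"],
        lambda_h=cfg["lambda_h_true"],
        c_inf=cfg["c_inf"],
    )
    t_final = cfg["t_final_wk"] * WEEK_S
    x_pos = np.linspace(0.0, cfg["profile_x_max_cm"], cfg["n_profile_points"])
    profile, _ = gen_p_profile(
        uparams,
        truth_params,
        t_final=t_final,
        x_positions_cm=x_pos,
        noise_sd=cfg["noise_sd"],
        seed=seed,
    )
    fitted_mean = growth_results[treatment]["mean"]
    rho_total = GrowthParams(
        k=fitted_mean["k"],
        v=fitted_mean["v"],
        b_branch=fitted_mean["b_branch"],
        d=fitted_mean.get("d", 0.0),
    )
    results = {"profile": profile.to_dict(orient="list"), "fits": {}}
    from .growth import solve_growth_closed_form

    x_grid = np.linspace(0.0, 1.5, 201)
    t_grid = np.linspace(0.0, t_final, 81)
    rho_sol = solve_growth_closed_form(rho_total, x_grid, t_grid)
    for source in cfg["rho_sources"]:
        scale = 1.0 if source == "total" else cfg["pore_fraction"]
        rho_arr = rho_sol.rho * scale
        fit = fit_uptake(
            profile,
            rho_arr,
            uparams.replace(lambda_h=0.0),
            t_final=t_final,
            nx=201,
            nt=81,
            domain_length=1.5,
            seed=seed,
        )
        results["fits"][source] = {
            "lambda_h": fit.estimates["lambda_h"],
            "r_m": fit.extras["r_m"],
            "r2": None if not np.isfinite(fit.r2) else fit.r2,
            "objective": fit.objective,
            "rho_scale": scale,
        }
    results["lambda_h_true"] = cfg["lambda_h_true"]
    return results


def _skeleton_stage(cfg: dict, seed: int) -> dict:
    out = {}
    for i, preset in enumerate(cfg["presets"]):
        ds = gen_skeleton(
            length_um=cfg["length_um"],
            radius_um=cfg["radius_um"],
            voxel_size_um=cfg["voxel_size_um"],
            preset=preset,
            n_tips=cfg["n_tips"],
            voxelize=cfg.get("voxelize", False),
            seed=seed + i,
        )
        volume_um3 = cfg["length_um"] * np.pi * cfg["radius_um"] ** 2
        metrics = compute_metrics(ds.graph, (1.0, 0.0, 0.0), volume_um3)
        out[preset] = metrics.summary()
    return out


def _xrf_stage(cfg: dict, seed: int) -> dict:
    ds = gen_xrf_maps(
        shape=tuple(cfg["shape"]), pixel_size_um=cfg["pixel_size_um"], seed=seed
    )
    thr = ds.truth.params
    phases = classify_phases(ds.xrf_map, thr["air_threshold_total"], thr["si_threshold"])
    classes = distance_classes(ds.distance)
    out = {"class_stats": {}, "phase_counts": {}}
    labels, counts = np.unique(phases.labels, return_counts=True)
    out["phase_counts"] = {int(l): int(c) for l, c in zip(labels, counts)}
    for el in cfg["elements"]:
        st = class_statistics(ds.xrf_map, phases, classes, el)
        out["class_stats"][el] = st.to_dict()
    out["elemental_classes"] = elemental_classes(ds.xrf_map, phases, ds.distance)
    return out


def _xanes_stage(cfg: dict, seed: int) -> dict:
    lib = gen_xanes_library("S-K")
    distances = np.asarray(cfg["distances_um"], float)
    frac = np.linspace(cfg["oxidized_near"], cfg["oxidized_far"], distances.size)
    spectra = []
    planted = []
    for i, (d_um, ox) in enumerate(zip(distances, frac)):
        weights = {
            "thiol": 1.0 - ox,
            "sulfonate": 0.4 * ox,
            "sulfate": 0.6 * ox,
        }
        spec, _, _ = gen_xanes(
            weights, snr=cfg["snr"], library=lib, distance_um=d_um, seed=seed + i
        )
        spectra.append(spec)
        planted.append({"distance_um": d_um, "oxidized": ox})
    trend = speciation_vs_distance(spectra, lib, np.asarray(cfg["bins_um"], float))
    return {
        "planted": planted,
        "trend": trend.to_dict(orient="records"),
    }


def run_study(config: dict | str | Path | None = None, out_dir=None) -> StudyReport:
    """Run the full synthetic study replica and return a `StudyReport`.

    ``config`` may be a dict (merged over `default_config`) or a path to a
    JSON file.  Stages execute in dependency order, each seeded from the
    master seed; any stage failure aborts with the stage name logged.
    """
    cfg = default_config()
    if config is not None:
        if isinstance(config, (str, Path)):
            user = json.loads(Path(config).read_text())
        else:
            user = copy.deepcopy(config)
        _deep_update(cfg, user)
    seed = int(cfg["seed"])
    out_path = Path(out_dir) if out_dir else None
    cache = _StageCache(out_path)

    body: dict = {
        "provenance": {
            "seed": seed,
            "config_hash": _hash_cfg(cfg),
            "version": __version__,
        }
    }
    stages = [
        ("growth", lambda: _growth_stage(cfg["growth"], seed)),
        ("uptake", lambda: _uptake_stage(cfg["uptake"], body["growth"], seed + 1000)),
        ("skeleton", lambda: _skeleton_stage(cfg["skeleton"], seed + 2000)),
        ("xrf", lambda: _xrf_stage(cfg["xrf"], seed + 3000)),
        ("xanes", lambda: _xanes_stage(cfg["xanes"], seed + 4000)),
    ]
    for name, fn in stages:
        key = _hash_cfg([cfg.get(name, {}), seed])
        cached = cache.get(name, key)
        if cached is not None:
            body[name] = cached
            continue
        logger.info("running stage %s", name)
        try:
            result = json.loads(json.dumps(fn(), default=_np_default))
        except Exception:
            logger.error("stage %s failed", name)
            raise
        body[name] = result
        cache.put(name, key, result)

    report = StudyReport(body=body)
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)
        report.to_json(out_path / "report.json")
        (out_path / "summary.txt").write_text(_summary_text(body))
    return report


def _np_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _deep_update(base: dict, update: dict) -> None:
    for k, v in update.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _summary_text(body: dict) -> str:
    lines = ["mycouptake synthetic study summary", "=" * 36]
    for treatment, res in body["growth"].items():
        lines.append(f"growth [{treatment}]:")
        for p in ("k", "v", "b_branch"):
            lines.append(
                f"  {p:9s} = {res['mean'][p]:.3e} ± {res['sd'][p]:.3e}"
                f"   (true {res['true_params'][p]:.3e})"
            )
    up = body["uptake"]
    lines.append(f"uptake (true lambda_h = {up['lambda_h_true']:.3e} cm/s):")
    for source, fit in up["fits"].items():
        lines.append(
            f"  rho source {source:6s}: lambda_h = {fit['lambda_h']:.3e} cm/s"
            f" (r_m = {fit['r_m']:.1e} cm)"
        )
    lines.append("skeleton presets (branches per cluster):")
    for preset, m in body["skeleton"].items():
        lines.append(
            f"  {preset:11s}: {m['branches_per_cluster']:.2f} branches/cluster, "
            f"mean angle {m['mean_angle_deg']:.1f} deg"
        )
    lines.append("XRF close-vs-far (mixed phase):")
    for el, st in body["xrf"]["class_stats"].items():
        lines.append(
            f"  {el:2s}: close {st['close_mean']:.3g}, far {st['far_mean']:.3g}, "
            f"t p={st['t_p']:.2e}, KS p={st['ks_p']:.2e}"
        )
    return "\n".join(lines) + "\n"
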