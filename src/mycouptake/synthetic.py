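"""Seeded generators emulating every input the analysis pipeline consumes.

Each generator draws all randomness from one explicit seed, returns the
dataset together with a `SyntheticTruth` record of the planted parameters,
and regenerates byte-identically from (seed, config).  Defaults emulate the
study conditions: length-density observations on the three imaging heights
(13.5 / 28.5 / 43.5 mm) at 2 and 4 weeks with three replicates and 10%
multiplicative noise; skeletons in a cylindrical hyphal-compartment domain
with 'inoculated' (straight, sparsely branched) and 'control' (wandering,
heavily branched) presets; three-phase elemental maps whose P field is
elevated near hyphae (close/far mean ratio ~1.24 on defaults) and whose Al
field is depressed there; Gaussian-peak sulphur XANES standards at
2473 / 2480.5 / 2482 eV; and P depletion profiles from the transport model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .chem import DistancePlane, PhaseLabels, XRFMap, AIR, PRIMARY, MIXED
from .growth import GrowthParams, ObservationSet, evaluate_at
from .skeleton import SkeletonGraph
from .uptake import UptakeParams, solve_uptake
from .xanes import Spectrum

__all__ = [
    "SyntheticTruth",
    "gen_length_density_obs",
    "gen_skeleton",
    "gen_xrf_maps",
    "gen_xanes_library",
    "gen_xanes",
    "gen_p_profile",
    "SKELETON_PRESETS",
    "WEEK_S",
]

WEEK_S = 7 * 24 * 3600.0

#: Imaging heights along the hyphal compartment, cm.
DEFAULT_POSITIONS_CM = (1.35, 2.85, 4.35)
DEFAULT_TIMES_S = (2 * WEEK_S, 4 * WEEK_S)

#: Morphology presets: AMF-inoculated hyphae run straight with little
#: branching; control (native-fungi) hyphae wander and branch heavily.
SKELETON_PRESETS = {
    "inoculated": {"persistence": 0.95, "branch_prob": 0.01, "stop_prob": 0.01},
    "control": {"persistence": 0.80, "branch_prob": 0.06, "stop_prob": 0.02},
}


@dataclass
class SyntheticTruth:
    """Planted ground truth serialised with every synthetic dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "generator": self.generator,
            "seed": self.seed,
            "version": self.version,
            "params": _jsonable(self.params),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def gen_length_density_obs(
    true_params: GrowthParams,
    positions_cm=DEFAULT_POSITIONS_CM,
    times_s=DEFAULT_TIMES_S,
    n_replicates: int = 3,
    noise_type: str = "lognormal",
    noise_level: float = 0.10,
    seed: int = 0,
) -> tuple[ObservationSet, SyntheticTruth]:
    """Length-density observations from the closed-form growth model.

    Noise is multiplicative lognormal by default, parameterised so the
    noise factor has mean 1 and coefficient of variation ``noise_level``;
    'gaussian' gives additive noise with sd ``noise_level`` times the
    model value (clipped at zero).
    """
    if noise_level < 0:
        raise ValueError("noise level must be >= 0")
    rng = np.random.default_rng(seed)
    pos, tim, rep = [], [], []
    for r in range(n_replicates):
        for t in times_s:
            for x in positions_cm:
                pos.append(x)
                tim.append(t)
                rep.append(r)
    obs = ObservationSet.from_arrays(pos, tim, rep, np.zeros(len(pos)))
    model = evaluate_at(true_params, obs)
    if noise_level == 0:
        values = model
    elif noise_type == "lognormal":
        sigma2 = np.log1p(noise_level**2)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=model.size)
        values = model * factors
    elif noise_type == "gaussian":
        values = np.clip(model + rng.normal(0.0, noise_level * model), 0.0, None)
    else:
        raise ValueError(f"unknown noise type '{noise_type}'")
    obs.table["rho_cm2"] = values
    truth = SyntheticTruth(
        generator="length_density_obs",
        seed=seed,
        params={
            "growth": true_params.as_dict(),
            "positions_cm": list(positions_cm),
            "times_s": list(times_s),
            "n_replicates": n_replicates,
            "noise_type": noise_type,
            "noise_level": noise_level,
            "model_values": model,
        },
    )
    return obs, truth


@dataclass
class SkeletonDataset:
    volume: np.ndarray | None
    graph: SkeletonGraph  # exact polyline truth graph
    truth: SyntheticTruth


def gen_skeleton(
    length_um: float = 1000.0,
    radius_um: float = 500.0,
    voxel_size_um: float = 1.6,
    preset: str | None = None,
    n_tips: int = 6,
    step_um: float = 8.0,
    persistence: float = 0.95,
    branch_prob: float = 0.01,
    stop_prob: float = 0.01,
    launch_angle_sd: float = 0.0,
    max_branches: int = 400,
    voxelize: bool = True,
    seed: int = 0,
) -> SkeletonDataset:
    """Grow a synthetic hyphal skeleton in a cylindrical compartment.

    Tips are launched from the ``x = 0`` face (the mesh interface) heading
    along the compartment midline (+x), advance in steps of ``step_um``
    with direction persistence (the direction vector is blended with an
    isotropic perturbation of magnitude ``1 - persistence`` and
    renormalised), and may branch or stop at each step.  Tips leaving the
    cylinder terminate.  With ``persistence = 1`` and ``branch_prob = 0``
    every branch is a straight line at its launch angle.

    Returns the voxelised skeleton (unless ``voxelize=False``), the exact
    polyline truth graph and the planted per-branch lengths and midline
    angles.
    """
    if preset is not None:
        cfg = SKELETON_PRESETS[preset]
        persistence = cfg["persistence"]
        branch_prob = cfg["branch_prob"]
        stop_prob = cfg["stop_prob"]
    if length_um <= 0 or radius_um <= 0 or voxel_size_um <= 0 or step_um <= 0:
        raise ValueError("degenerate domain or step")
    if not (0 <= persistence <= 1):
        raise ValueError("persistence must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    wobble = 1.0 - persistence
    max_steps = int(np.ceil(length_um / step_um)) * 3

    def launch_direction() -> np.ndarray:
        d = np.array([1.0, 0.0, 0.0])
        if launch_angle_sd > 0:
            d = d + launch_angle_sd * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            if d[0] < 0:
                d[0] = -d[0]
        return d

    def inside(p: np.ndarray) -> bool:
        return (0.0 <= p[0] <= length_um) and (p[1] ** 2 + p[2] ** 2 <= radius_um**2)

    # seed tips on the x=0 face, uniform over the disc
    queue: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_tips):
        r = radius_um * 0.9 * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        start = np.array([0.0, r * np.cos(phi), r * np.sin(phi)])
        queue.append((start, launch_direction()))

    polylines: list[np.ndarray] = []
    while queue and len(polylines) < max_branches:
        pos, direction = queue.pop(0)
        path = [pos.copy()]
        for _ in range(max_steps):
            if wobble > 0:
                direction = direction + wobble * rng.standard_normal(3)
                nrm = np.linalg.norm(direction)
                direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
            nxt = path[-1] + step_um * direction
            if not inside(nxt):
                break
            path.append(nxt)
            if rng.uniform() < branch_prob and len(polylines) + len(queue) < max_branches:
                # a branch point ends the current branch: the tip continues
                # as a new branch and a child tip departs from the same
                # node, so the junction is a shared polyline endpoint
                child_dir = direction + 0.8 * rng.standard_normal(3)
                child_dir /= np.linalg.norm(child_dir)
                queue.append((nxt.copy(), direction.copy()))
                queue.append((nxt.copy(), child_dir))
                break
            if rng.uniform() < stop_prob:
                break
        if len(path) >= 2:
            polylines.append(np.array(path))

    graph = SkeletonGraph.from_polylines(polylines, voxel_size=voxel_size_um)
    midline = np.array([1.0, 0.0, 0.0])
    lengths, angles = [], []
    for b in graph.branches:
        lengths.append(b.length)
        chord = b.chord
        if chord > 0:
            cosang = abs(float(b.end_to_end @ midline)) / chord
            angles.append(float(np.degrees(np.arccos(np.clip(cosang, 0, 1)))))

    volume = None
    if voxelize:
        nx = int(np.ceil(length_um / voxel_size_um)) + 1
        nyz = 2 * int(np.ceil(radius_um / voxel_size_um)) + 1
        volume = np.zeros((nx, nyz, nyz), dtype=np.uint8)
        offset = np.array([0.0, radius_um, radius_um])
        for pl in polylines:
            for p0, p1 in zip(pl[:-1], pl[1:]):
                seg = p1 - p0
                n_sub = max(2, int(np.ceil(np.linalg.norm(seg) / (voxel_size_um / 3.0))))
                ts = np.linspace(0.0, 1.0, n_sub)
                pts = p0[None, :] + ts[:, None] * seg[None, :]
                idx = np.round((pts + offset) / voxel_size_um).astype(int)
                ok = (
                    (idx[:, 0] >= 0)
                    & (idx[:, 0] < nx)
                    & (idx[:, 1] >= 0)
                    & (idx[:, 1] < nyz)
                    & (idx[:, 2] >= 0)
                    & (idx[:, 2] < nyz)
                )
                idx = idx[ok]
                volume[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        if volume.any():
            # rasterised polylines can be locally thick; thin to the
            # 1-voxel-wide skeleton the tracing stage expects
            from .skeleton import skeletonize_mask

            volume = skeletonize_mask(volume)

    truth = SyntheticTruth(
        generator="skeleton",
        seed=seed,
        params={
            "length_um": length_um,
            "radius_um": radius_um,
            "voxel_size_um": voxel_size_um,
            "preset": preset,
            "n_tips": n_tips,
            "step_um": step_um,
            "persistence": persistence,
            "branch_prob": branch_prob,
            "stop_prob": stop_prob,
            "n_branches": len(polylines),
            "branch_lengths_um": lengths,
            "branch_angles_deg": angles,
            "total_length_um": float(sum(lengths)),
        },
    )
    return SkeletonDataset(volume=volume, graph=graph, truth=truth)


@dataclass
class XRFDataset:
    xrf_map: XRFMap
    phases: PhaseLabels
    hyphal_mask: np.ndarray
    distance: DistancePlane
    truth: SyntheticTruth


def _stamp_ellipses(mask: np.ndarray, rng, n: int, ax_lo: float, ax_hi: float) -> None:
    nr, nc = mask.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    for _ in range(n):
        r0, c0 = rng.uniform(0, nr), rng.uniform(0, nc)
        a, b = rng.uniform(ax_lo, ax_hi, size=2)
        th = rng.uniform(0, np.pi)
        dr, dc = rr - r0, cc - c0
        u = dr * np.cos(th) + dc * np.sin(th)
        v = -dr * np.sin(th) + dc * np.cos(th)
        mask[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = True


def gen_xrf_maps(
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 10.0,
    n_grains: int = 25,
    grain_axes_px: tuple[float, float] = (4.0, 14.0),
    n_pores: int = 20,
    pore_axes_px: tuple[float, float] = (3.0, 10.0),
    n_hyphae: int = 6,
    hypha_persistence: float = 0.9,
    p_coupling: float = 0.4,
    p_profile: str = "exp",  # 'exp' | 'step'
    coupling_length_um: float = 50.0,
    al_coupling: float = -0.3,
    n_s_patches: int = 0,
    s_patch_factor: float = 5.0,
    base_levels: dict | None = None,
    noise_cv: float = 0.10,
    seed: int = 0,
) -> XRFDataset:
    """Three-phase elemental maps with distance-coupled P, Al and S fields.

    Primary mineral grains are high-Si ellipses, pores carry near-zero
    signal, and the mixed phase carries base levels modulated by distance
    to a planted in-plane hyphal mask: ``P = base (1 + a_P g(d))`` with
    ``g`` either ``exp(-d / l)`` (default, l = 50 um) or a step inside the
    close class; Al uses the same form with a negative default coupling; S
    is uniform over the mixed phase by default (matching its role as a
    no-systematic-contrast channel), with optional discrete organic
    patches (``n_s_patches > 0``) for organic-fragment scenarios.  The default ``p_coupling = 0.4``
    with the exponential profile puts the close/far mean P ratio near 1.24
    on defaults.  Pixel noise is multiplicative lognormal with CV
    ``noise_cv``.  The planted phase labels, thresholds that bracket the
    planted levels, and all couplings are returned as truth.
    """
    rng = np.random.default_rng(seed)
    nr, nc = shape
    base = {
        "P": 8.3e3,
        "S": 600.0,
        "Al": 3.0e3,
        "Si": 500.0,
        "Si_grain": 5.0e4,
        "air": {"P": 20.0, "S": 10.0, "Al": 20.0, "Si": 50.0},
    }
    if base_levels:
        base.update(base_levels)

    # planted hyphal mask: persistent random walks entering from the left
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_hyphae):
        r = rng.uniform(0.1 * nr, 0.9 * nr)
        c = 0.0
        direction = np.array([rng.uniform(-0.3, 0.3), 1.0])
        direction /= np.linalg.norm(direction)
        wob = 1.0 - hypha_persistence
        while 0 <= r < nr and 0 <= c < nc:
            mask[int(r), int(c)] = True
            direction = direction + wob * rng.standard_normal(2)
            direction /= np.linalg.norm(direction)
            if direction[1] < 0.1:  # keep marching into the map
                direction[1] = 0.1
                direction /= np.linalg.norm(direction)
            r += direction[0]
            c += direction[1]

    dist_um = ndimage.distance_transform_edt(~mask, sampling=pixel_size_um)

    grain = np.zeros(shape, dtype=bool)
    _stamp_ellipses(grain, rng, n_grains, *grain_axes_px)
    pore = np.zeros(shape, dtype=bool)
    _stamp_ellipses(pore, rng, n_pores, *pore_axes_px)
    pore &= ~grain

    labels = np.full(shape, MIXED, dtype=np.int8)
    labels[grain] = PRIMARY
    labels[pore] = AIR

    if p_profile == "exp":
        g = np.exp(-dist_um / coupling_length_um)
    elif p_profile == "step":
        g = (dist_um <= coupling_length_um).astype(float)
    else:
        raise ValueError(f"unknown p_profile '{p_profile}'")

    p_map = base["P"] * (1.0 + p_coupling * g)
    al_map = base["Al"] * (1.0 + al_coupling * g)
    s_map = np.full(shape, base["S"])
    patches = np.zeros(shape, dtype=bool)
    _stamp_ellipses(patches, rng, n_s_patches, 5.0, 15.0)
    s_map[patches] *= s_patch_factor
    si_map = np.full(shape, base["Si"])

    fields = {"P": p_map, "S": s_map, "Al": al_map, "Si": si_map}
    for el in fields:
        fields[el] = np.where(labels == AIR, base["air"][el], fields[el])
    fields["Si"] = np.where(labels == PRIMARY, base["Si_grain"], fields["Si"])

    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        for el in fields:
            factors = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=shape)
            fields[el] = fields[el] * factors

    xrf = XRFMap(elements=fields, pixel_size_um=pixel_size_um, units="counts")
    truth = SyntheticTruth(
        generator="xrf_maps",
        seed=seed,
        params={
            "shape": list(shape),
            "pixel_size_um": pixel_size_um,
            "p_coupling": p_coupling,
            "p_profile": p_profile,
            "coupling_length_um": coupling_length_um,
            "al_coupling": al_coupling,
            "noise_cv": noise_cv,
            "base_levels": {k: v for k, v in base.items() if k != "air"},
            "air_threshold_total": 1.0e3,
            "si_threshold": 2.5e4,
        },
    )
    return XRFDataset(
        xrf_map=xrf,
        phases=PhaseLabels(labels),
        hyphal_mask=mask,
        distance=DistancePlane(dist_um),
        truth=truth,
    )


#: Sulphur K-edge standard models: (edge eV, white-line centre eV, height, width eV).
S_STANDARD_MODELS = {
    "thiol": (2472.5, 2473.0, 3.0, 0.7),
    "sulfonate": (2480.0, 2480.5, 2.5, 0.8),
    "sulfate": (2481.5, 2482.0, 3.5, 0.7),
}

#: Phosphorus K-edge standard models (synthetic, apatite-like white-line
#: shift and post-edge shoulder semantics).
P_STANDARD_MODELS = {
    "apatite": (2151.5, 2152.2, 2.6, 0.8),
    "organic_P": (2152.5, 2153.5, 2.2, 1.0),
    "Al_phosphate": (2153.0, 2154.3, 2.8, 0.9),
}


def _standard_curve(grid: np.ndarray, edge_ev: float, peak_ev: float, height: float, width: float) -> np.ndarray:
    step = 0.5 + np.arctan((grid - edge_ev) / 1.0) / np.pi
    peak = height * np.exp(-0.5 * ((grid - peak_ev) / width) ** 2)
    return step + peak


def gen_xanes_library(
    edge: str = "S-K",
    grid: np.ndarray | None = None,
    models: dict | None = None,
) -> dict[str, Spectrum]:
    """Synthetic standard library: arctan edge + Gaussian white line."""
    if grid is None:
        grid = (
            np.arange(2460.0, 2505.0, 0.25)
            if edge == "S-K"
            else np.arange(2140.0, 2185.0, 0.25)
        )
    if models is None:
        models = S_STANDARD_MODELS if edge == "S-K" else P_STANDARD_MODELS
    return {
        name: Spectrum(grid, _standard_curve(grid, *m), edge=edge, name=name)
        for name, m in models.items()
    }


def gen_xanes(
    weights: dict[str, float],
    snr: float = 50.0,
    edge: str = "S-K",
    library: dict[str, Spectrum] | None = None,
    distance_um: float | None = None,
    name: str = "mixture",
    seed: int = 0,
) -> tuple[Spectrum, dict[str, Spectrum], SyntheticTruth]:
    """Mixture spectrum from the standard library plus white noise.

    ``snr`` is the edge step over the noise standard deviation
    (``np.inf`` for noise-free).  Weights must be non-negative and sum to 1.
    """
    if library is None:
        library = gen_xanes_library(edge=edge)
    w = np.array([weights.get(n, 0.0) for n in library], float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    names = list(library)
    grid = library[names[0]].energies
    y = sum(wi * library[nm].intensities for wi, nm in zip(w, names))
    rng = np.random.default_rng(seed)
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be > 0")
        y = y + rng.normal(0.0, 1.0 / snr, size=grid.size)
    spec = Spectrum(grid, y, edge=edge, name=name, distance_um=distance_um)
    truth = SyntheticTruth(
        generator="xanes",
        seed=seed,
        params={"weights": dict(zip(names, w)), "snr": snr, "edge": edge},
    )
    return spec, library, truth


def gen_p_profile(
    uparams: UptakeParams,
    growth: GrowthParams | object,
    t_final: float = 4 * WEEK_S,
    x_positions_cm: np.ndarray | None = None,
    domain_length_cm: float = 1.5,
    nx: int = 201,
    nt: int = 81,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Normalised P depletion profile c_TOT(x, t_final) / c_inf.

    ``growth`` may be `GrowthParams` (closed form is used for rho) or any
    rho specification accepted by `solve_uptake`.  Additive Gaussian noise
    with sd ``noise_sd`` is applied to the normalised profile.
    """
    if x_positions_cm is None:
        x_positions_cm = np.linspace(0.0, 1.0, 21)
    x_grid = np.linspace(0.0, domain_length_cm, nx)
    t_grid = np.linspace(0.0, t_final, nt)
    if isinstance(growth, GrowthParams):
        from .growth import solve_growth_closed_form

        rho = solve_growth_closed_form(growth, x_grid, t_grid)
    else:
        rho = growth
    sol = solve_uptake(uparams, rho, x_grid, t_grid)
    c_rel = np.interp(x_positions_cm, x_grid, sol.c_tot[-1]) / uparams.c_inf
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        c_rel = c_rel + rng.normal(0.0, noise_sd, size=c_rel.size)
    profile = pd.DataFrame({"x_cm": x_positions_cm, "c_rel": c_rel})
    truth = SyntheticTruth(
        generator="p_profile",
        seed=seed,
        params={
            "lambda_h": uparams.lambda_h,
            "r_m": uparams.r_m,
            "d_eff": uparams.d_eff,
            "t_final": t_final,
            "noise_sd": noise_sd,
            "growth": growth.as_dict() if isinstance(growth, GrowthParams) else None,
        },
    )
    return profile, truth
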