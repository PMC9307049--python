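"""Correlating hyphal structure with elemental chemistry.

Implements the SXRCT-to-XRF correlation chain: a 3D Euclidean distance
transform of the segmented hyphal mask, registration of a 2D elemental map
into the volume frame, per-pixel soil-phase classification (air-filled
pore / primary mineral / mixed clay-water phase), close/far distance
classes around the hyphae, per-class elemental statistics (two-sample t and
Kolmogorov-Smirnov tests) and compound high/low elemental classes with
their distance-to-hypha summaries.

All class logic is unit-agnostic: maps may carry raw detector counts or
calibrated concentrations, and thresholds default to data-driven means
rather than fixed count levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "XRFMap",
    "DistancePlane",
    "PhaseLabels",
    "ClassStats",
    "distance_transform_3d",
    "classify_phases",
    "distance_classes",
    "class_statistics",
    "elemental_classes",
    "register_plane",
    "AIR",
    "PRIMARY",
    "MIXED",
    "CLOSE",
    "FAR",
    "NEITHER",
]

AIR, PRIMARY, MIXED = 0, 1, 2
CLOSE, FAR, NEITHER = 0, 1, 2


@dataclass
class XRFMap:
    """Registered per-element 2D intensity/concentration images.

    ``elements`` maps element symbols (P, S, Al, Si, ...) to 2D arrays on a
    common pixel grid.  ``affine`` is a row-major 3x4 matrix taking
    homogeneous in-plane coordinates ``(u_um, v_um, 0, 1)`` (u along rows,
    v along columns) to positions in the 3D volume frame, um.  The default
    identity places the map as the volume's first axis-2 slice.
    """

    elements: dict[str, np.ndarray]
    pixel_size_um: float
    units: str = "counts"  # 'counts' | 'ug_g'
    affine: np.ndarray = field(
        default_factory=lambda: np.hstack([np.eye(3), np.zeros((3, 1))])
    )

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {np.asarray(a).shape for a in self.elements.values()}
        if len(shapes) != 1:
            raise ValueError("all element maps must share one shape")
        self.elements = {k: np.asarray(v, float) for k, v in self.elements.items()}
        self.affine = np.asarray(self.affine, float)
        if self.affine.shape != (3, 4):
            raise ValueError("affine must be 3x4")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.elements.values())).shape

    def total_signal(self) -> np.ndarray:
        return np.sum([a for a in self.elements.values()], axis=0)

    def pixel_positions_um(self) -> np.ndarray:
        """(rows, cols, 3) positions of pixel centres in the volume frame."""
        nr, nc = self.shape
        rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        u = rr * self.pixel_size_um
        v = cc * self.pixel_size_um
        hom = np.stack([u, v, np.zeros_like(u), np.ones_like(u)], axis=-1)
        return hom @ self.affine.T


@dataclass
class DistancePlane:
    """Per-pixel distance to the nearest hyphal surface voxel, um."""

    distances_um: np.ndarray

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, float)
        if np.any(self.distances_um < 0):
            raise ValueError("distances must be >= 0")


@dataclass
class PhaseLabels:
    """Exhaustive per-pixel soil-phase labels (air / primary / mixed)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.all(np.isin(self.labels, (AIR, PRIMARY, MIXED))):
            raise ValueError("labels must be in {AIR, PRIMARY, MIXED}")

    def mask(self, phase: int) -> np.ndarray:
        return self.labels == phase


@dataclass
class ClassStats:
    """Close-vs-far elemental statistics in the mixed phase."""

    element: str
    close_mean: float
    far_mean: float
    close_n: int
    far_n: int
    bin_edges: np.ndarray
    close_hist: np.ndarray  # normalised to sum 1
    far_hist: np.ndarray
    t_stat: float
    t_p: float
    ks_stat: float
    ks_p: float

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "close_mean": self.close_mean,
            "far_mean": self.far_mean,
            "close_n": self.close_n,
            "far_n": self.far_n,
            "t_stat": self.t_stat,
            "t_p": self.t_p,
            "ks_stat": self.ks_stat,
            "ks_p": self.ks_p,
        }


class EmptyMaskError(ValueError):
    """The hyphal mask has no foreground: distances are undefined."""


def distance_transform_3d(hyphal_mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Exact Euclidean distance (um) to the nearest foreground voxel centre."""
    mask = np.asarray(hyphal_mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("hyphal mask is empty; distances undefined")
    return ndimage.distance_transform_edt(~mask, sampling=voxel_size)


def classify_phases(
    xrf_map: XRFMap, air_threshold_total: float, si_threshold: float
) -> PhaseLabels:
    """Label pixels air (low total signal), primary (high Si) or mixed.

    High-Si pixels are excluded from the mixed phase both because they are
    mineral grains and to keep Si signal overflow out of the neighbouring P
    and Al channels.
    """
    if air_threshold_total <= 0 or si_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    total = xrf_map.total_signal()
    si = xrf_map.elements.get("Si")
    if si is None:
        raise ValueError("phase classification requires an Si map")
    labels = np.full(total.shape, MIXED, dtype=np.int8)
    labels[si > si_threshold] = PRIMARY
    labels[total < air_threshold_total] = AIR
    return PhaseLabels(labels)


def distance_classes(
    dist: DistancePlane, close_um: float = 50.0, far_um: float = 200.0
) -> np.ndarray:
    """Close / far / neither labels from distance to hyphae.

    Tie rule: the close class is inclusive (``d <= close_um``) and the far
    class strict (``d > far_um``), matching the 'within 50 um' / 'further
    than 200 um' reading.
    """
    if not close_um < far_um:
        raise ValueError("close_um must be < far_um")
    d = dist.distances_um
    labels = np.full(d.shape, NEITHER, dtype=np.int8)
    labels[d <= close_um] = CLOSE
    labels[d > far_um] = FAR
    return labels


def class_statistics(
    xrf_map: XRFMap,
    phases: PhaseLabels,
    classes: np.ndarray,
    element: str,
    bin_width: float | None = None,
    n_bins: int = 30,
    equal_var: bool = True,
) -> ClassStats:
    """Close-vs-far statistics of one element over mixed-phase pixels.

    Restricted to the mixed phase; reports class means, normalised
    histograms on shared edges, the two-sample t test (equal-variance by
    default, Welch optional) and the two-sample KS test.
    """
    values = xrf_map.elements[element]
    mixed = phases.mask(MIXED)
    close_vals = values[mixed & (classes == CLOSE)]
    far_vals = values[mixed & (classes == FAR)]
    for name, vals in (("close", close_vals), ("far", far_vals)):
        if vals.size < 2:
            raise ValueError(
                f"distance class '{name}' has {vals.size} mixed-phase pixels (< 2)"
            )
    lo = float(min(close_vals.min(), far_vals.min()))
    hi = float(max(close_vals.max(), far_vals.max()))
    if bin_width is not None:
        edges = np.arange(lo, hi + bin_width, bin_width)
        if edges.size < 2:
            edges = np.array([lo, hi if hi > lo else lo + bin_width])
    else:
        edges = np.linspace(lo, hi if hi > lo else lo + 1.0, n_bins + 1)
    ch, _ = np.histogram(close_vals, bins=edges)
    fh, _ = np.histogram(far_vals, bins=edges)
    if np.array_equal(np.sort(close_vals), np.sort(far_vals)):
        t_stat, t_p = 0.0, 1.0
        ks_stat, ks_p = 0.0, 1.0
    else:
        t_stat, t_p = stats.ttest_ind(close_vals, far_vals, equal_var=equal_var)
        ks_stat, ks_p = stats.ks_2samp(close_vals, far_vals)
    return ClassStats(
        element=element,
        close_mean=float(close_vals.mean()),
        far_mean=float(far_vals.mean()),
        close_n=int(close_vals.size),
        far_n=int(far_vals.size),
        bin_edges=edges,
        close_hist=ch / ch.sum() if ch.sum() else ch.astype(float),
        far_hist=fh / fh.sum() if fh.sum() else fh.astype(float),
        t_stat=float(t_stat),
        t_p=float(t_p),
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
    )


def elemental_classes(
    xrf_map: XRFMap,
    phases: PhaseLabels,
    dist: DistancePlane,
    thresholds: str | dict[str, float] = "from-close-means",
    pairs: tuple[tuple[str, str], ...] = (("P", "Al"), ("S", "Al")),
    close_um: float = 50.0,
    bin_um: float = 100.0,
) -> dict:
    """High/low compound elemental classes and their hyphal distances.

    Each element is split high/low at a threshold: either explicit values
    or, by default, the mean of mixed-phase pixels within ``close_um`` of
    hyphae ('from-close-means').  For every requested pair (A, B) the
    compound classes highA/lowB and highA/highB are summarised by pixel
    count, mean distance to hyphae, a distance histogram (default bin
    100 um) and the fraction of pixels within 100 um.  Empty classes are
    reported with ``empty: True`` rather than silent NaNs.
    """
    mixed = phases.mask(MIXED)
    if not mixed.any():
        raise ValueError("no mixed-phase pixels")
    d = dist.distances_um
    if isinstance(thresholds, str):
        if thresholds != "from-close-means":
            raise ValueError(f"unknown threshold mode '{thresholds}'")
        close_mask = mixed & (d <= close_um)
        if not close_mask.any():
            raise ValueError("close class empty: cannot derive thresholds")
        thr = {
            el: float(arr[close_mask].mean()) for el, arr in xrf_map.elements.items()
        }
    else:
        thr = dict(thresholds)

    high = {
        el: xrf_map.elements[el] > thr[el]
        for el in {e for pair in pairs for e in pair}
    }
    d_max = float(d[mixed].max())
    edges = np.arange(0.0, d_max + bin_um, bin_um)

    out: dict = {"thresholds": thr, "bin_um": bin_um, "classes": {}}
    for a, b in pairs:
        for b_state, b_mask in (("low", ~high[b]), ("high", high[b])):
            name = f"high{a}_{b_state}{b}"
            cls_mask = mixed & high[a] & b_mask
            dists = d[cls_mask]
            entry: dict = {"count": int(dists.size)}
            if dists.size == 0:
                entry["empty"] = True
            else:
                hist, _ = np.histogram(dists, bins=edges)
                entry.update(
                    {
                        "empty": False,
                        "mean_distance_um": float(dists.mean()),
                        "hist_edges_um": edges.tolist(),
                        "hist_fraction": (hist / hist.sum()).tolist(),
                        "fraction_within_100um": float(np.mean(dists <= 100.0)),
                    }
                )
            out["classes"][name] = entry
    return out


def register_plane(
    xrf_map: XRFMap, distance_volume: np.ndarray, voxel_size: float
) -> DistancePlane:
    """Sample a 3D distance field at each map pixel centre (nearest voxel).

    The map's affine places pixel centres in the volume frame (um); each
    position is divided by the voxel size and rounded to the nearest voxel
    index.  Raises if any pixel falls outside the volume, listing the
    out-of-bounds extent.
    """
    pos = xrf_map.pixel_positions_um()  # (nr, nc, 3)
    idx = np.round(pos / voxel_size).astype(int)
    shape = np.asarray(distance_volume.shape)
    below = idx < 0
    above = idx >= shape
    if below.any() or above.any():
        mn = idx.reshape(-1, 3).min(axis=0)
        mx = idx.reshape(-1, 3).max(axis=0)
        raise ValueError(
            "registered plane extends outside the volume: voxel index range "
            f"{mn.tolist()}..{mx.tolist()} vs volume shape {shape.tolist()}"
        )
    sampled = distance_volume[idx[..., 0], idx[..., 1], idx[..., 2]]
    return DistancePlane(np.asarray(sampled, float))
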