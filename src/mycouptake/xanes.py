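"""XANES linear-combination fitting and speciation trends.

A measured K-edge spectrum is modelled as a convex combination of standard
spectra: non-negative weights constrained to sum to one, fitted by least
squares.  The sum-to-one constraint is enforced through an augmented row
with a weight many orders of magnitude above the data scale, so the
constraint holds to well below 1e-6 without post-hoc renormalisation
(renormalising after an unconstrained fit would bias the residuals).

Speciation trends aggregate fitted fractions over distance bins (distance
from hyphae or from the root-compartment interface), grouping standards
into species classes — for sulphur the conventional split is reduced
(amino-acid thiols) versus oxidized (sulfonate + sulfate).

Energy alignment (edge-shift fitting) is deliberately omitted: spectra are
assumed energy-calibrated against mineral standards upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "Spectrum",
    "LCFResult",
    "preprocess",
    "lcf_fit",
    "speciation_vs_distance",
    "DEFAULT_S_GROUPS",
]

#: Default sulphur species grouping for trend reports.
DEFAULT_S_GROUPS = {
    "thiol": "reduced",
    "sulfonate": "oxidized",
    "sulfate": "oxidized",
}

MIN_POINTS = 20


@dataclass
class Spectrum:
    """A single XANES spectrum: strictly increasing energies (eV) and
    intensities, with the edge label and an optional position annotation."""

    energies: np.ndarray
    intensities: np.ndarray
    edge: str = "S-K"  # 'P-K' | 'S-K'
    name: str = ""
    distance_um: float | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.energies.ndim != 1 or self.energies.size < MIN_POINTS:
            raise ValueError(f"spectrum needs >= {MIN_POINTS} points")
        if self.energies.shape != self.intensities.shape:
            raise ValueError("energies and intensities must match")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energies must be strictly increasing")

    @classmethod
    def from_csv(cls, path, **kw) -> "Spectrum":
        table = pd.read_csv(path)
        cols = list(table.columns[:2])
        return cls(table[cols[0]].to_numpy(), table[cols[1]].to_numpy(), **kw)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"energy_eV": self.energies, "intensity": self.intensities}
        ).to_csv(path, index=False)


@dataclass
class LCFResult:
    """Weights of a linear-combination fit (non-negative, summing to one)."""

    weights: dict[str, float]
    rss: float
    r_factor: float  # sum (data - fit)^2 / sum data^2
    condition_number: float
    rank_warning: bool = False

    def grouped(self, groups: dict[str, str]) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, w in self.weights.items():
            out[groups.get(name, name)] = out.get(groups.get(name, name), 0.0) + w
        return out

    def to_dict(self) -> dict:
        return {
            "weights": self.weights,
            "rss": self.rss,
            "r_factor": self.r_factor,
            "condition_number": self.condition_number,
            "rank_warning": self.rank_warning,
        }


def preprocess(
    spec: Spectrum,
    grid: np.ndarray,
    pre_edge_fraction: float = 0.15,
    post_edge_fraction: float = 0.15,
) -> Spectrum:
    """Interpolate to a common grid and edge-step normalise.

    A straight line fitted over the leading ``pre_edge_fraction`` of the
    grid is subtracted (linear pre-edge background) and the result is
    scaled so the mean over the trailing ``post_edge_fraction`` equals one
    (unit edge step).  Already-normalised spectra pass through unchanged;
    the output is invariant to overall intensity scaling.
    """
    grid = np.asarray(grid, float)
    if grid[0] < spec.energies[0] - 1e-9 or grid[-1] > spec.energies[-1] + 1e-9:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside spectrum span "
            f"[{spec.energies[0]}, {spec.energies[-1]}]"
        )
    y = np.interp(grid, spec.energies, spec.intensities)
    n = grid.size
    n_pre = max(2, int(round(pre_edge_fraction * n)))
    n_post = max(2, int(round(post_edge_fraction * n)))
    coeff = np.polyfit(grid[:n_pre], y[:n_pre], 1)
    y = y - np.polyval(coeff, grid)
    step = float(np.mean(y[-n_post:]))
    if step <= 0:
        raise ValueError("non-positive edge step; cannot normalise")
    y = y / step
    return Spectrum(
        grid, y, edge=spec.edge, name=spec.name, distance_um=spec.distance_um
    )


def lcf_fit(
    spec: Spectrum,
    standards: dict[str, Spectrum] | list[Spectrum],
    constraint_weight: float = 1e8,
    cond_threshold: float = 1e8,
) -> LCFResult:
    """Non-negative, sum-to-one linear combination fit against standards.

    All spectra must share the target spectrum's energy grid and edge.
    The sum-to-one constraint enters as an augmented row scaled by
    ``constraint_weight`` times the data norm; with the default weight the
    fitted weights sum to one to ~1e-12.  A rank-deficient standard set
    (condition number above ``cond_threshold``) triggers a warning but the
    best-fitting weights are still returned.
    """
    if isinstance(standards, list):
        standards = {s.name or f"standard_{i}": s for i, s in enumerate(standards)}
    if len(standards) < 2:
        raise ValueError("need at least two standards")
    names = list(standards)
    for nm in names:
        st = standards[nm]
        if st.edge != spec.edge:
            raise ValueError(
                f"standard '{nm}' edge {st.edge} does not match spectrum edge {spec.edge}"
            )
        if st.energies.shape != spec.energies.shape or not np.allclose(
            st.energies, spec.energies
        ):
            raise ValueError(f"standard '{nm}' is not on the spectrum's grid")

    A = np.column_stack([standards[nm].intensities for nm in names])
    y = spec.intensities
    cond = float(np.linalg.cond(A))
    rank_warning = cond > cond_threshold
    if rank_warning:
        warnings.warn(
            f"standard set is near rank-deficient (condition number {cond:.3g}); "
            "weights are not uniquely determined"
        )
    gamma = constraint_weight * max(np.linalg.norm(A), 1.0)
    A_aug = np.vstack([A, gamma * np.ones((1, A.shape[1]))])
    y_aug = np.concatenate([y, [gamma]])
    w, _ = nnls(A_aug, y_aug)
    total = w.sum()
    if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
        raise RuntimeError(f"sum-to-one constraint violated: sum(w) = {total}")
    fit = A @ w
    rss = float(np.sum((y - fit) ** 2))
    denom = float(np.sum(y**2))
    return LCFResult(
        weights={nm: float(wi) for nm, wi in zip(names, w)},
        rss=rss,
        r_factor=rss / denom if denom > 0 else np.inf,
        condition_number=cond,
        rank_warning=rank_warning,
    )


def speciation_vs_distance(
    spectra: list[Spectrum],
    standards: dict[str, Spectrum],
    bins: np.ndarray,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-distance-bin mean +/- SD of grouped LCF fractions.

    Every spectrum must carry a ``distance_um`` annotation.  Returns a
    tidy frame with one row per (bin, group): bin edges and centre, group,
    mean fraction, SD and spectrum count.  Empty bins are flagged with
    ``n = 0`` and NaN statistics.
    """
    if groups is None:
        groups = DEFAULT_S_GROUPS
    bins = np.asarray(bins, float)
    if bins.ndim != 1 or bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be ascending with >= 2 edges")
    if not spectra:
        raise ValueError("no spectra supplied")
    for s in spectra:
        if s.distance_um is None:
            raise ValueError(f"spectrum '{s.name}' lacks a distance annotation")

    records = []
    for s in spectra:
        res = lcf_fit(s, standards)
        frac = res.grouped(groups)
        records.append({"distance_um": s.distance_um, **frac})
    table = pd.DataFrame(records)
    group_names = [c for c in table.columns if c != "distance_um"]
    which = np.digitize(table["distance_um"], bins) - 1

    rows = []
    for i in range(bins.size - 1):
        in_bin = table[which == i]
        for gname in group_names:
            vals = in_bin[gname].to_numpy() if len(in_bin) else np.array([])
            rows.append(
                {
                    "bin_lo_um": bins[i],
                    "bin_hi_um": bins[i + 1],
                    "bin_centre_um": 0.5 * (bins[i] + bins[i + 1]),
                    "group": gname,
                    "mean_fraction": float(vals.mean()) if vals.size else np.nan,
                    "sd_fraction": float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size == 1 else np.nan),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
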