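"""Filament skeleton morphometrics.

Converts 1-voxel-wide 3D skeletons (26-connectivity) into a branch graph
and computes the morphometrics used to characterise hyphal networks:
total length, length density, number of connected clusters, branches per
cluster, mean branch length, arc-chord tortuosity and the orientation angle
of each branch relative to the compartment midline.

Junction handling: voxels with three or more skeleton neighbours that touch
each other are merged into a single junction node at their centroid (a
26-connected junction is otherwise ambiguous, because the first voxels of
meeting arms are mutually adjacent).  Branch polylines run along the actual
voxel chain from the junction-blob voxel the chain attaches to, so arc
lengths are sums of inter-voxel Euclidean steps scaled by the voxel size.
Isolated cycles with no junction are broken at their lexicographically
smallest voxel, which keeps re-tracing deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SkeletonGraph",
    "Branch",
    "HyphalMetrics",
    "voxel_skeleton_to_graph",
    "compute_metrics",
    "skeletonize_mask",
]

_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


@dataclass
class Branch:
    """One traced branch: an ordered polyline of 3D positions in um."""

    points: np.ndarray  # (m, 3) positions, um
    node_ids: tuple[int, int]
    cluster: int = -1

    @property
    def length(self) -> float:
        """Arc length: sum of inter-point Euclidean steps, um."""
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord(self) -> float:
        """Euclidean end-to-end distance, um."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def end_to_end(self) -> np.ndarray:
        return self.points[-1] - self.points[0]


@dataclass
class SkeletonGraph:
    """Filament network: nodes, branch polylines and cluster labels."""

    nodes: pd.DataFrame  # id, x_um, y_um, z_um, degree
    branches: list[Branch] = field(default_factory=list)
    voxel_size: float = 1.0

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def n_clusters(self) -> int:
        ids = {b.cluster for b in self.branches}
        # nodes with no branches (isolated voxels) are clusters too
        orphan = set(self.nodes["id"]) - {
            nid for b in self.branches for nid in b.node_ids
        }
        return len(ids) + len(orphan)

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    @classmethod
    def from_polylines(
        cls, polylines: list[np.ndarray], voxel_size: float = 1.0
    ) -> "SkeletonGraph":
        """Build a graph directly from polylines in um (one branch each).

        Endpoints closer than 1e-9 um are merged into shared nodes, so
        polylines emitted by a branching generator reconnect correctly.
        """
        import networkx as nx

        key_of: dict[tuple, int] = {}
        rows = []
        branches = []

        def node_for(p: np.ndarray) -> int:
            key = tuple(np.round(np.asarray(p, float), 9))
            if key not in key_of:
                key_of[key] = len(key_of)
                rows.append(
                    {"id": key_of[key], "x_um": p[0], "y_um": p[1], "z_um": p[2]}
                )
            return key_of[key]

        g = nx.Graph()
        for pl in polylines:
            pl = np.asarray(pl, float)
            if pl.ndim != 2 or pl.shape[1] != 3 or len(pl) < 2:
                raise ValueError("each polyline must be an (m>=2, 3) array")
            u, v = node_for(pl[0]), node_for(pl[-1])
            branches.append(Branch(points=pl, node_ids=(u, v)))
            g.add_edge(u, v)
        comp_of: dict[int, int] = {}
        for ci, comp in enumerate(sorted(nx.connected_components(g), key=min)):
            for nid in comp:
                comp_of[nid] = ci
        for b in branches:
            b.cluster = comp_of[b.node_ids[0]]
        nodes = pd.DataFrame(rows)
        deg = {}
        for b in branches:
            for nid in b.node_ids:
                deg[nid] = deg.get(nid, 0) + 1
        nodes["degree"] = nodes["id"].map(deg).fillna(0).astype(int)
        return cls(nodes=nodes, branches=branches, voxel_size=voxel_size)

    def transformed(self, rotation: np.ndarray) -> "SkeletonGraph":
        """Apply a 3x3 linear map to every coordinate (for invariance checks)."""
        R = np.asarray(rotation, float)
        nodes = self.nodes.copy()
        xyz = nodes[["x_um", "y_um", "z_um"]].to_numpy() @ R.T
        nodes[["x_um", "y_um", "z_um"]] = xyz
        branches = [
            Branch(points=b.points @ R.T, node_ids=b.node_ids, cluster=b.cluster)
            for b in self.branches
        ]
        return SkeletonGraph(nodes=nodes, branches=branches, voxel_size=self.voxel_size)

    def to_json(self, path) -> None:
        payload = {
            "voxel_size": self.voxel_size,
            "nodes": self.nodes.to_dict(orient="records"),
            "branches": [
                {
                    "node_ids": list(b.node_ids),
                    "cluster": int(b.cluster),
                    "points": b.points.tolist(),
                }
                for b in self.branches
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def to_swc(self, path) -> None:
        """Write an SWC-like CSV (id, x_um, y_um, z_um, radius, parent_id)."""
        rows = []
        nid = 0
        for b in self.branches:
            parent = -1
            for p in b.points:
                nid += 1
                rows.append(
                    {
                        "id": nid,
                        "x_um": p[0],
                        "y_um": p[1],
                        "z_um": p[2],
                        "radius": self.voxel_size / 2.0,
                        "parent_id": parent,
                    }
                )
                parent = nid
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_swc(cls, path, voxel_size: float = 1.0) -> "SkeletonGraph":
        """Read an SWC-like CSV; each root-to-leaf chain becomes a polyline."""
        table = pd.read_csv(path)
        pos = {
            int(r.id): np.array([r.x_um, r.y_um, r.z_um]) for r in table.itertuples()
        }
        children: dict[int, list[int]] = {}
        roots = []
        for r in table.itertuples():
            if int(r.parent_id) == -1:
                roots.append(int(r.id))
            else:
                children.setdefault(int(r.parent_id), []).append(int(r.id))
        polylines = []
        for root in roots:
            # follow chains; branch points in SWC restart polylines
            stack = [(root, [pos[root]])]
            while stack:
                nid, path_pts = stack.pop()
                kids = children.get(nid, [])
                if not kids:
                    if len(path_pts) >= 2:
                        polylines.append(np.array(path_pts))
                    continue
                for kid in kids:
                    if len(kids) == 1:
                        stack.append((kid, path_pts + [pos[kid]]))
                    else:
                        if len(path_pts) >= 2:
                            polylines.append(np.array(path_pts))
                        stack.append((kid, [pos[nid], pos[kid]]))
        return cls.from_polylines(polylines, voxel_size=voxel_size)


def voxel_skeleton_to_graph(volume: np.ndarray, voxel_size: float = 1.0) -> SkeletonGraph:
    """Trace a 1-voxel-wide 26-connected skeleton into a branch graph.

    Nodes sit at voxels with a neighbour count different from 2 (endpoints
    and junctions); touching junction voxels are merged into one node at
    their centroid.  An empty volume yields an empty graph.
    """
    vol = np.asarray(volume)
    uniq = np.unique(vol)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("skeleton volume must be binary (0/1 or bool)")
    vol = vol.astype(bool)
    coords = np.argwhere(vol)
    if coords.size == 0:
        return SkeletonGraph(
            nodes=pd.DataFrame(columns=["id", "x_um", "y_um", "z_um", "degree"]),
            branches=[],
            voxel_size=voxel_size,
        )

    vox = {tuple(c) for c in coords}

    def neighbours(c):
        arr = np.array(c) + _OFFSETS
        return [tuple(a) for a in arr if tuple(a) in vox]

    nbrs = {c: neighbours(c) for c in vox}
    degree = {c: len(nbrs[c]) for c in vox}

    markers = {c for c in vox if degree[c] != 2}

    # components with no marker are pure cycles: break at the lex-min voxel
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(vox)
    for c, ns in nbrs.items():
        for n in ns:
            g.add_edge(c, n)
    for comp in nx.connected_components(g):
        if not comp & markers:
            markers.add(min(comp))

    # merge touching junction voxels (degree >= 3) into single nodes
    junction_vox = {c for c in markers if degree[c] >= 3}
    node_of: dict[tuple, int] = {}
    node_rows = []
    jg = g.subgraph(junction_vox)
    next_id = 0
    for comp in sorted(nx.connected_components(jg), key=min):
        centroid = np.mean([np.array(c) for c in comp], axis=0) * voxel_size
        for c in comp:
            node_of[c] = next_id
        node_rows.append(
            {
                "id": next_id,
                "x_um": centroid[0],
                "y_um": centroid[1],
                "z_um": centroid[2],
            }
        )
        next_id += 1
    for c in sorted(markers - junction_vox):
        node_of[c] = next_id
        p = np.array(c) * voxel_size
        node_rows.append({"id": next_id, "x_um": p[0], "y_um": p[1], "z_um": p[2]})
        next_id += 1

    branches: list[Branch] = []
    visited_interior: set[tuple] = set()
    visited_direct: set[frozenset] = set()

    for m in sorted(markers):
        for nb in sorted(nbrs[m]):
            if nb in markers:
                if node_of[nb] == node_of[m]:
                    continue  # intra-junction-blob edge, part of the node
                key = frozenset((m, nb))
                if key in visited_direct:
                    continue
                visited_direct.add(key)
                pts = np.array([m, nb], float) * voxel_size
                branches.append(Branch(points=pts, node_ids=(node_of[m], node_of[nb])))
                continue
            if nb in visited_interior:
                continue
            # walk the degree-2 chain until the next marker
            path = [m, nb]
            prev, cur = m, nb
            while cur not in markers:
                visited_interior.add(cur)
                nxt = [x for x in nbrs[cur] if x != prev]
                if not nxt:  # dangling chain end (should be a marker already)
                    break
                # prefer continuing off already-walked voxels deterministically
                step = sorted(nxt)[0] if len(nxt) > 1 else nxt[0]
                path.append(step)
                prev, cur = cur, step
            pts = np.array(path, float) * voxel_size
            end_node = node_of[cur] if cur in markers else node_of[m]
            branches.append(Branch(points=pts, node_ids=(node_of[m], end_node)))

    # cluster labels from voxel connectivity
    comp_of_voxel: dict[tuple, int] = {}
    for ci, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for c in comp:
            comp_of_voxel[c] = ci
    for b in branches:
        first_vox = tuple(int(round(v)) for v in b.points[0] / voxel_size)
        b.cluster = comp_of_voxel[first_vox]

    deg_nodes = {}
    for b in branches:
        for nid in b.node_ids:
            deg_nodes[nid] = deg_nodes.get(nid, 0) + 1
    nodes = pd.DataFrame(node_rows)
    nodes["degree"] = nodes["id"].map(deg_nodes).fillna(0).astype(int)
    return SkeletonGraph(nodes=nodes, branches=branches, voxel_size=voxel_size)


@dataclass
class HyphalMetrics:
    """Morphometric summary of a skeleton graph."""

    total_length: float  # um
    length_density: float  # cm hyphae per cm^3 analysed volume (cm^-2)
    n_clusters: int
    n_branches: int
    branches_per_cluster: float
    mean_branch_length: float  # um
    tortuosity: np.ndarray  # per branch, >= 1
    angle_deg: np.ndarray  # per branch, [0, 90]
    n_zero_chord_excluded: int

    def summary(self) -> dict:
        return {
            "total_length_um": self.total_length,
            "length_density_cm2": self.length_density,
            "n_clusters": self.n_clusters,
            "n_branches": self.n_branches,
            "branches_per_cluster": self.branches_per_cluster,
            "mean_branch_length_um": self.mean_branch_length,
            "mean_tortuosity": float(np.mean(self.tortuosity)) if self.tortuosity.size else np.nan,
            "mean_angle_deg": float(np.mean(self.angle_deg)) if self.angle_deg.size else np.nan,
            "n_zero_chord_excluded": self.n_zero_chord_excluded,
        }


def compute_metrics(
    graph: SkeletonGraph,
    midline_vector,
    analysed_volume_um3: float,
) -> HyphalMetrics:
    """Morphometrics of a skeleton graph.

    * tortuosity — arc-chord ratio per branch (path length over end-to-end
      distance), the standard filament convention, minimum 1;
    * angle — arccos(|e_hat . m_hat|) between the branch end-to-end vector
      and the compartment midline, folded to [0, 90] degrees;
    * zero-chord branches (closed loops) are excluded from tortuosity and
      angle, with the exclusion count reported.
    """
    m = np.asarray(midline_vector, float)
    nm = np.linalg.norm(m)
    if nm == 0:
        raise ValueError("midline vector must be non-zero")
    if analysed_volume_um3 <= 0:
        raise ValueError("analysed volume must be > 0")
    m = m / nm

    torts, angles = [], []
    excluded = 0
    for b in graph.branches:
        chord = b.chord
        if chord < 1e-12:
            excluded += 1
            continue
        torts.append(b.length / chord)
        e = b.end_to_end / chord
        cosang = np.clip(abs(float(e @ m)), 0.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))

    total = graph.total_length
    n_cl = graph.n_clusters
    n_br = graph.n_branches
    length_density = (total * 1e-4) / (analysed_volume_um3 * 1e-12)
    return HyphalMetrics(
        total_length=total,
        length_density=length_density,
        n_clusters=n_cl,
        n_branches=n_br,
        branches_per_cluster=(n_br / n_cl) if n_cl else np.nan,
        mean_branch_length=(total / n_br) if n_br else np.nan,
        tortuosity=np.asarray(torts),
        angle_deg=np.asarray(angles),
        n_zero_chord_excluded=excluded,
    )


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin a thick binary mask to a 1-voxel skeleton (skimage thinning)."""
    from skimage.morphology import skeletonize

    return skeletonize(np.asarray(mask).astype(bool)).astype(np.uint8)
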