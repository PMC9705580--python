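"""Centerline trees and arc-length resampling.

A labeled coronary centerline tree is the second input of the pipeline
(alongside the CT volume). Arteries are paths from an ostium to a distal
endpoint; before MPR reconstruction each artery is resampled to a uniform
0.5 mm point spacing along its arc length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

MAIN_BRANCH_LABELS = frozenset({"LM", "LAD", "LCX", "RCA"})
SLICE_SPACING_MM = 0.5


@dataclass
class ArteryCenterline:
    """Ordered centerline points (ostium -> distal) at uniform arc-length spacing."""

    points: np.ndarray                      # (S, 3) mm
    labels: list[str]                       # per-point segment label
    successor_counts: np.ndarray            # per-point child count in the tree
    spacing: float = SLICE_SPACING_MM

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.successor_counts = np.asarray(self.successor_counts, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be (S, 3)")
        if self.points.shape[0] < 3:
            raise ValueError("a centerline needs at least 3 points")
        if len(self.labels) != len(self.points) or len(self.successor_counts) != len(self.points):
            raise ValueError("labels and successor counts must match the point count")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class TreeNode:
    id: int
    position: np.ndarray     # (3,) mm
    parent: int | None
    label: str


@dataclass
class CenterlineTree:
    """Acyclic labeled coronary tree; one root per ostium (parent = None)."""

    nodes: dict[int, TreeNode] = field(default_factory=dict)

    def __post_init__(self):
        self._children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise ValueError(f"node {node.id} has unknown parent {node.parent}")
                self._children[node.parent].append(node.id)
        self._check_acyclic()
        self._kdtree = None

    def _check_acyclic(self):
        for start in self.nodes:
            seen = set()
            nid = start
            while nid is not None:
                if nid in seen:
                    raise ValueError("centerline tree contains a cycle")
                seen.add(nid)
                nid = self.nodes[nid].parent

    def children(self, nid: int) -> list[int]:
        return self._children[nid]

    def successor_count(self, nid: int) -> int:
        return len(self._children[nid])

    def nearest_node(self, point: np.ndarray, max_dist: float = 1.0) -> int:
        """Id of the closest tree node; error if farther than ``max_dist`` mm."""
        if self._kdtree is None:
            self._ids = np.array(sorted(self.nodes))
            self._kdtree = cKDTree(np.stack([self.nodes[i].position for i in self._ids]))
        dist, idx = self._kdtree.query(np.asarray(point, dtype=float))
        if dist > max_dist:
            raise ValueError(f"point {point} is {dist:.2f} mm from the nearest tree node "
                             f"(tolerance {max_dist} mm)")
        return int(self._ids[idx])

    def path_to_root(self, nid: int) -> list[int]:
        out = []
        cur: int | None = nid
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    # -- persistence (JSON: list of {id, xyz mm, parent, label}) --------------

    def to_json(self, path) -> None:
        payload = [{"id": n.id, "position_mm": np.asarray(n.position).tolist(),
                    "parent": n.parent, "label": n.label}
                   for n in sorted(self.nodes.values(), key=lambda n: n.id)]
        with open(path, "w") as fh:
            json.dump({"nodes": payload}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CenterlineTree":
        with open(path) as fh:
            payload = json.load(fh)
        nodes = {int(n["id"]): TreeNode(int(n["id"]), np.array(n["position_mm"], dtype=float),
                                        None if n["parent"] is None else int(n["parent"]),
                                        str(n["label"]))
                 for n in payload["nodes"]}
        return cls(nodes)


def resample_centerline(raw_points: np.ndarray,
                        labels: list[str] | None = None,
                        successor_counts: np.ndarray | None = None,
                        spacing: float = SLICE_SPACING_MM) -> ArteryCenterline:
    """Resample a raw polyline to uniform arc-length spacing (default 0.5 mm).

    The polyline is parameterized piecewise-linearly by cumulative arc
    length and sampled at 0, spacing, 2*spacing, ... up to the total length.
    Labels and successor counts are carried over from the nearest raw point.
    """
    raw = np.asarray(raw_points, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3 or raw.shape[0] < 2:
        raise ValueError("raw centerline must be (N>=2, 3)")
    seg = np.linalg.norm(np.diff(raw, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total < 1.0:
        raise ValueError(f"centerline length {total:.3f} mm is below the 1.0 mm minimum")
    # tolerant floor: a length within 1e-6 of a spacing multiple still yields
    # the boundary point (keeps the slice count stable under rigid motion)
    n_out = int(np.floor(total / spacing + 1e-6)) + 1
    s = np.arange(n_out) * spacing
    pts = np.column_stack([np.interp(s, arclen, raw[:, ax]) for ax in range(3)])

    nearest = np.searchsorted(arclen, s)
    nearest = np.clip(nearest, 0, len(arclen) - 1)
    left = np.clip(nearest - 1, 0, len(arclen) - 1)
    use_left = np.abs(arclen[left] - s) <= np.abs(arclen[nearest] - s)
    src = np.where(use_left, left, nearest)

    if labels is None:
        labels = ["LAD"] * raw.shape[0]
    if successor_counts is None:
        successor_counts = np.ones(raw.shape[0], dtype=int)
    successor_counts = np.asarray(successor_counts, dtype=int)
    out_labels = [labels[i] for i in src]
    out_succ = successor_counts[src]
    return ArteryCenterline(points=pts, labels=out_labels,
                            successor_counts=out_succ, spacing=spacing)


def centerline_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (one-sided at the ends)."""
    pts = np.asarray(points, dtype=float)
    t = np.empty_like(pts)
    t[1:-1] = pts[2:] - pts[:-2]
    t[0] = pts[1] - pts[0]
    t[-1] = pts[-1] - pts[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate tangent: repeated centerline points")
    return t / norms


def rotation_minimizing_frames(points: np.ndarray) -> np.ndarray:
    """Per-point orthonormal frames (tangent, e1, e2) with minimal twist.

    Uses the double-reflection method to propagate the initial normal along
    the curve, avoiding the torsion artifacts of Frenet frames at inflection
    points. The initial normal is an arbitrary fixed vector orthogonal to the
    ostial tangent.
    """
    pts = np.asarray(points, dtype=float)
    tangents = centerline_tangents(pts)
    n = pts.shape[0]
    frames = np.empty((n, 3, 3))

    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, t0) * t0
    e1 /= np.linalg.norm(e1)
    frames[0] = (t0, e1, np.cross(t0, e1))

    for i in range(n - 1):
        ti, ri = frames[i, 0], frames[i, 1]
        v1 = pts[i + 1] - pts[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-24:
            raise ValueError("degenerate tangent: repeated centerline points")
        rl = ri - (2.0 / c1) * np.dot(v1, ri) * v1
        tl = ti - (2.0 / c1) * np.dot(v1, ti) * v1
        v2 = tangents[i + 1] - tl
        c2 = np.dot(v2, v2)
        r_next = rl if c2 < 1e-24 else rl - (2.0 / c2) * np.dot(v2, rl) * v2
        t_next = tangents[i + 1]
        r_next = r_next - np.dot(r_next, t_next) * t_next
        r_next /= np.linalg.norm(r_next)
        frames[i + 1] = (t_next, r_next, np.cross(t_next, r_next))
    return frames
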