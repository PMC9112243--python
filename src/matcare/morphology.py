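"""Dendritic morphometry on SWC-style neuronal reconstructions.

Sholl profiles on concentric 20-µm shells centred on the soma, cumulative
dendritic length, branch-point counts, soma area, five-class dendritic
spine typing and spine densities.

Sholl intersections are counted as *edge straddles*: an edge contributes
one intersection at radius r when its two endpoints' Euclidean distances
from the soma centroid lie on opposite sides of r (an endpoint exactly on
the shell counts as crossing).  All distances are 3-D; quasi-2-D
camera-lucida data may simply carry z = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SWC_SOMA, SWC_AXON, SWC_DENDRITE = 1, 2, 3
SPINE_CLASSES = ("stubby", "mushroom", "thin", "long_thin", "filopodia")


@dataclass
class Morphology:
    """Rooted tree of 3-D nodes with SWC semantics.

    ``parent[i]`` is the index (not SWC id) of node i's parent, -1 for the
    root; the root must be a soma node and parents precede children.
    """

    xyz: np.ndarray                  # (n, 3) µm
    radius: np.ndarray               # (n,) µm
    node_type: np.ndarray            # (n,) SWC type codes
    parent: np.ndarray               # (n,) parent index, -1 = root

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.node_type = np.asarray(self.node_type, dtype=int)
        self.parent = np.asarray(self.parent, dtype=int)
        n = self.xyz.shape[0]
        if not (self.radius.size == self.node_type.size
                == self.parent.size == n):
            raise ValueError("node arrays must have equal length")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise ValueError(f"expected exactly one root, found {roots.size}")
        if self.node_type[roots[0]] != SWC_SOMA:
            raise ValueError("root must be a soma node")
        if np.any(self.parent >= np.arange(n)):
            raise ValueError("parent must precede child")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    @property
    def n_nodes(self) -> int:
        return self.xyz.shape[0]

    def soma_centroid(self) -> np.ndarray:
        return self.xyz[self.node_type == SWC_SOMA].mean(axis=0)

    def children_count(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        for p in self.parent:
            if p >= 0:
                counts[p] += 1
        return counts

    def edges(self, types: Sequence[int] = (SWC_DENDRITE,)) -> np.ndarray:
        """(child, parent) index pairs for edges whose child has one of the
        given types."""
        mask = np.isin(self.node_type, list(types)) & (self.parent >= 0)
        child = np.flatnonzero(mask)
        return np.column_stack([child, self.parent[child]])


@dataclass(frozen=True)
class ShollProfile:
    radii_um: np.ndarray
    intersections: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.radii_um,
                             "intersections": self.intersections})


@dataclass(frozen=True)
class DendriteMetrics:
    cumulative_length_um: float
    n_branch_points: int
    soma_area_um2: float


@dataclass(frozen=True)
class SpineThresholds:
    """Ordered decision-tree thresholds for spine typing (µm)."""
    filopodia_length: float = 2.0    # L above this -> filopodia
    mushroom_head: float = 0.6       # else HW above this -> mushroom
    stubby_ratio: float = 1.0        # else L/max(HW, NW) below -> stubby
    long_thin_length: float = 1.0    # else L above this -> long_thin


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Parse an SWC file; errors name the offending line."""
    ids, types, xyz, radii, parents_id = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields, "
                                 f"got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                types.append(int(parts[1]))
                xyz.append([float(parts[2]), float(parts[3]),
                            float(parts[4])])
                radii.append(float(parts[5]))
                parents_id.append(int(parts[6]))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed SWC line "
                                 f"({e})") from None
    id_to_idx = {i: k for k, i in enumerate(ids)}
    if len(id_to_idx) != len(ids):
        raise ValueError(f"{path}: duplicate node ids")
    parent = np.empty(len(ids), dtype=int)
    for k, pid in enumerate(parents_id):
        if pid == -1:
            parent[k] = -1
        elif pid in id_to_idx:
            parent[k] = id_to_idx[pid]
        else:
            raise ValueError(f"{path}: node id {ids[k]} references missing "
                             f"parent {pid}")
    order = _topological_order(parent)
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    parent_sorted = np.array(
        [-1 if parent[i] == -1 else inv[parent[i]] for i in order])
    return Morphology(xyz=np.asarray(xyz)[order],
                      radius=np.asarray(radii)[order],
                      node_type=np.asarray(types)[order],
                      parent=parent_sorted)


def _topological_order(parent: np.ndarray) -> np.ndarray:
    """Parents-before-children ordering; raises on cycles."""
    n = parent.size
    order, seen = [], np.zeros(n, dtype=bool)

    def visit(i, stack):
        if seen[i]:
            return
        if i in stack:
            raise ValueError("cyclic parent references in SWC data")
        stack.add(i)
        if parent[i] >= 0:
            visit(parent[i], stack)
        stack.discard(i)
        seen[i] = True
        order.append(i)

    for i in range(n):
        visit(i, set())
    return np.asarray(order, dtype=int)


def write_swc(m: Morphology, path) -> None:
    """Write SWC with ids renumbered contiguously from 1."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(m.n_nodes):
            p = m.parent[i]
            fh.write(f"{i + 1} {m.node_type[i]} "
                     f"{m.xyz[i, 0]:.6f} {m.xyz[i, 1]:.6f} {m.xyz[i, 2]:.6f} "
                     f"{m.radius[i]:.6f} {p + 1 if p >= 0 else -1}\n")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def sholl(m: Morphology, r0_um: float = 20.0,
          step_um: float = 20.0) -> ShollProfile:
    """Sholl profile: per shell, the number of dendritic edges whose
    endpoint distances from the soma centroid straddle the shell radius.

    Shells run r0, r0+step, ... out to the maximal node distance.
    """
    center = m.soma_centroid()
    dist = np.linalg.norm(m.xyz - center, axis=1)
    edges = m.edges()
    max_dist = dist.max() if dist.size else 0.0
    radii = []
    r = r0_um
    while r <= max_dist + 1e-9:
        radii.append(r)
        r += step_um
    radii = np.asarray(radii)
    counts = np.zeros(radii.size, dtype=int)
    if edges.size:
        d1 = dist[edges[:, 0]]
        d2 = dist[edges[:, 1]]
        lo = np.minimum(d1, d2)
        hi = np.maximum(d1, d2)
        for k, rr in enumerate(radii):
            counts[k] = int(np.sum((lo <= rr) & (rr <= hi)))
    return ShollProfile(radii_um=radii, intersections=counts)


def _soma_area(m: Morphology) -> float:
    """Soma area from the xy outline polygon (shoelace) when the soma has
    >= 3 nodes, else pi * r^2 of the root radius."""
    soma = m.xyz[m.node_type == SWC_SOMA]
    if soma.shape[0] >= 3:
        x, y = soma[:, 0], soma[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1))
                               - np.dot(y, np.roll(x, -1))))
    root = int(np.flatnonzero(m.parent == -1)[0])
    return math.pi * float(m.radius[root]) ** 2


def dendrite_metrics(m: Morphology) -> DendriteMetrics:
    """Cumulative dendritic length, branch-point count and soma area.

    Branch points are non-soma nodes with >= 2 children (stem count at the
    soma is not a branch point, by reconstruction convention).
    """
    edges = m.edges()
    length = 0.0
    if edges.size:
        seg = m.xyz[edges[:, 0]] - m.xyz[edges[:, 1]]
        length = float(np.linalg.norm(seg, axis=1).sum())
    counts = m.children_count()
    branch = int(np.sum((counts >= 2) & (m.node_type != SWC_SOMA)))
    return DendriteMetrics(cumulative_length_um=length,
                           n_branch_points=branch,
                           soma_area_um2=_soma_area(m))


def classify_spine(length_um: float, head_width_um: float,
                   neck_width_um: float,
                   thresholds: SpineThresholds = SpineThresholds()) -> str:
    """Five-class spine typing via an ordered decision tree.

    filopodia (long) -> mushroom (big head) -> stubby (length below the
    largest width) -> long_thin -> thin; exactly one class for any
    positive (L, HW, NW).
    """
    L, HW, NW = length_um, head_width_um, neck_width_um
    if L <= 0 or HW <= 0 or NW <= 0:
        raise ValueError("spine dimensions must be positive")
    th = thresholds
    if L > th.filopodia_length:
        return "filopodia"
    if HW > th.mushroom_head:
        return "mushroom"
    if L / max(HW, NW) < th.stubby_ratio:
        return "stubby"
    if L > th.long_thin_length:
        return "long_thin"
    return "thin"


def spine_density(counts: Sequence[int], segment_lengths_um: Sequence[float]
                  ) -> tuple[float, np.ndarray]:
    """Spines per 10 µm, pooled over segments, plus per-segment densities."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(segment_lengths_um, dtype=float)
    if counts.size != lengths.size:
        raise ValueError("counts and lengths must pair up")
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total segment length must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_seg = np.where(lengths > 0, 10.0 * counts / lengths, np.nan)
    return 10.0 * counts.sum() / total, per_seg
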