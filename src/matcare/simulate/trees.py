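"""Synthetic dendritic trees (SWC semantics) with known ground truth.

Two modes: a deterministic full binary tree of radial segments (handy for
closed-form expectations) and a randomized tree with jittered segment
lengths and directions.  Ground truth records the exact total dendritic
length and branch-point count as built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..config import SimConfig
from ..morphology import SWC_DENDRITE, SWC_SOMA, Morphology
from ._rng import substream


@dataclass(frozen=True)
class MorphologyTruth:
    total_length_um: float
    n_branch_points: int
    n_tips: int


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def gen_morphology(cfg: SimConfig, deterministic: bool = False,
                   rng: np.random.Generator | None = None
                   ) -> tuple[Morphology, MorphologyTruth]:
    """Rooted tree of depth ``cfg.tree_depth``; depth 0 is a bare soma.

    Deterministic mode: full binary tree, every segment ``branch_len`` µm,
    trunk along +x, daughters fanning at ±30° in the xy plane.  Random
    mode: each non-root node bifurcates with probability ``branch_prob``
    (otherwise terminates), segment lengths are branch_len x U(0.6, 1.4),
    directions jitter around the parent direction.
    """
    if rng is None:
        rng = substream(cfg.seed, "morphology")
    xyz = [np.zeros(3)]
    radius = [5.0]
    ntype = [SWC_SOMA]
    parent = [-1]
    total_len = 0.0
    n_branch = 0
    n_tips = 0

    def add_node(p_idx: int, pos: np.ndarray) -> int:
        xyz.append(pos)
        radius.append(0.5)
        ntype.append(SWC_DENDRITE)
        parent.append(p_idx)
        return len(xyz) - 1

    # stack of (parent index, direction, remaining depth)
    stack = []
    if cfg.tree_depth >= 1:
        stack.append((0, np.array([1.0, 0.0, 0.0]), cfg.tree_depth))
    while stack:
        p_idx, direction, depth = stack.pop()
        if deterministic:
            seg = cfg.branch_len
            d = direction
        else:
            seg = cfg.branch_len * rng.uniform(0.6, 1.4)
            d = _unit(direction + 0.4 * rng.normal(size=3))
        pos = xyz[p_idx] + seg * d
        idx = add_node(p_idx, pos)
        total_len += float(seg)
        if depth > 1:
            branch = True if deterministic else rng.random() < cfg.branch_prob
            if branch:
                n_branch += 1
                angle = np.deg2rad(30.0)
                for sign in (1.0, -1.0):
                    c, s = np.cos(angle), np.sin(sign * angle)
                    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
                    stack.append((idx, _unit(rot @ d), depth - 1))
            else:
                stack.append((idx, d, depth - 1))
        else:
            n_tips += 1
    m = Morphology(xyz=np.array(xyz), radius=np.array(radius),
                   node_type=np.array(ntype), parent=np.array(parent))
    return m, MorphologyTruth(total_length_um=total_len,
                              n_branch_points=n_branch, n_tips=n_tips)
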