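"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles along a different
code path than the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def bursts_by_enumeration(times_s, isi_max_s=0.080, span_max_s=0.160):
    """All maximal contiguous runs satisfying the two burst constraints,
    resolved left-to-right, via exhaustive pair checking."""
    t = list(map(float, times_s))
    n = len(t)

    def run_ok(i, j):
        if j <= i:
            return False
        if t[j] - t[i] > span_max_s:
            return False
        return all(t[k + 1] - t[k] < isi_max_s for k in range(i, j))

    bursts = []
    i = 0
    while i < n:
        best = None
        for j in range(n - 1, i, -1):        # largest valid j first
            if run_ok(i, j):
                best = j
                break
        if best is None:
            i += 1
        else:
            bursts.append(tuple(range(i, best + 1)))
            i = best + 1
    return bursts


def sholl_from_swc_text(swc_path, radii):
    """Shell-straddle counts recomputed from the serialized SWC file with
    plain loops (independent of the Morphology container)."""
    nodes = {}
    with open(swc_path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            f = s.split()
            nodes[int(f[0])] = (int(f[1]), float(f[2]), float(f[3]),
                                float(f[4]), int(f[6]))
    soma = [(x, y, z) for (ty, x, y, z, _p) in nodes.values() if ty == 1]
    cx = sum(p[0] for p in soma) / len(soma)
    cy = sum(p[1] for p in soma) / len(soma)
    cz = sum(p[2] for p in soma) / len(soma)

    def dist(nid):
        _ty, x, y, z, _p = nodes[nid]
        return math.dist((x, y, z), (cx, cy, cz))

    counts = []
    for r in radii:
        c = 0
        for nid, (ty, _x, _y, _z, pid) in nodes.items():
            if ty != 3 or pid == -1:
                continue
            d1, d2 = dist(nid), dist(pid)
            if min(d1, d2) <= r <= max(d1, d2):
                c += 1
        counts.append(c)
    return counts


def spearman_perm_p(x, y):
    """Exact two-sided permutation p for Spearman rho via np.corrcoef on
    ranks over all n! pairings."""
    import itertools

    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        if abs(r) >= abs(obs) - 1e-12:
            hits += 1
        total += 1
    return hits / total


def twoway_ss_balanced(y, a, b):
    """Textbook balanced two-way ANOVA sums of squares (explicit means)."""
    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    lev_a, lev_b = np.unique(a), np.unique(b)
    n_cell = len(y) / (len(lev_a) * len(lev_b))
    ss_a = sum((y[a == la].mean() - grand) ** 2 * (y[a == la].size)
               for la in lev_a)
    ss_b = sum((y[b == lb].mean() - grand) ** 2 * (y[b == lb].size)
               for lb in lev_b)
    ss_ab = 0.0
    for la in lev_a:
        for lb in lev_b:
            cell = y[(a == la) & (b == lb)]
            ss_ab += n_cell * (cell.mean() - y[a == la].mean()
                               - y[b == lb].mean() + grand) ** 2
    ss_err = 0.0
    for la in lev_a:
        for lb in lev_b:
            cell = y[(a == la) & (b == lb)]
            ss_err += ((cell - cell.mean()) ** 2).sum()
    df = {"a": len(lev_a) - 1, "b": len(lev_b) - 1,
          "ab": (len(lev_a) - 1) * (len(lev_b) - 1),
          "err": len(y) - len(lev_a) * len(lev_b)}
    return {"a": ss_a, "b": ss_b, "ab": ss_ab, "err": ss_err, "df": df}


def splitplot_ss_balanced(Y, groups):
    """Split-plot sums of squares for a balanced design via explicit
    nested loops (subjects x within matrix, one group per subject)."""
    Y = np.asarray(Y, float)
    groups = np.asarray(groups)
    n, k = Y.shape
    glabels = list(dict.fromkeys(groups))
    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    grp_mean = {g: Y[groups == g].mean() for g in glabels}
    w_mean = Y.mean(axis=0)
    cell_mean = {g: Y[groups == g].mean(axis=0) for g in glabels}

    ss_between = sum(k * (groups == g).sum() * (grp_mean[g] - grand) ** 2
                     for g in glabels)
    ss_subj = sum(k * (subj_mean[i] - grp_mean[groups[i]]) ** 2
                  for i in range(n))
    ss_within = sum(n * (w_mean[j] - grand) ** 2 for j in range(k))
    ss_inter = sum((groups == g).sum()
                   * (cell_mean[g][j] - grp_mean[g] - w_mean[j] + grand) ** 2
                   for g in glabels for j in range(k))
    ss_err = sum((Y[i, j] - cell_mean[groups[i]][j] - subj_mean[i]
                  + grp_mean[groups[i]]) ** 2
                 for i in range(n) for j in range(k))
    G = len(glabels)
    df = {"between": (G - 1, n - G),
          "within": (k - 1, (n - G) * (k - 1)),
          "interaction": ((G - 1) * (k - 1), (n - G) * (k - 1))}
    return {"between": ss_between, "subj": ss_subj, "within": ss_within,
            "interaction": ss_inter, "err": ss_err, "df": df}
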