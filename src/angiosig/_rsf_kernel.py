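"""Numba kernels for survival-tree growth and traversal.

One tree is grown per call on a bootstrap sample: at each node ``mtry``
features are drawn without replacement and the split maximizing the
two-group log-rank statistic over candidate thresholds (midpoints of
sorted distinct values; optionally a random subset of ``n_split`` of
them) is taken.  A split is admissible only if both children receive at
least ``min_node_events`` events; a node with fewer than
``2 * min_node_events`` events becomes a terminal node holding the
Nelson–Aalen cumulative hazard of its in-bag samples evaluated on the
shared time grid.
"""

import numpy as np
from numba import njit

__all__ = ["grow_tree", "predict_tree_chf"]


@njit(cache=True)
def _best_split_feature(x, t, d, n_events, min_node_events, n_split):
    """Best log-rank split for one feature within a node.

    ``x``, ``t``, ``d`` are node samples sorted by time ascending.
    Returns ``(statistic, threshold)``; statistic is -1 when no
    admissible split exists.
    """
    m = x.shape[0]
    xs = np.sort(x.copy())
    cand = np.empty(m - 1)
    nc = 0
    for i in range(m - 1):
        if xs[i + 1] > xs[i]:
            cand[nc] = 0.5 * (xs[i] + xs[i + 1])
            nc += 1
    if nc == 0:
        return -1.0, 0.0
    if 0 < n_split < nc:
        sel = np.random.choice(nc, n_split, replace=False)
        thresholds = np.empty(n_split)
        for i in range(n_split):
            thresholds[i] = cand[sel[i]]
        nc = n_split
    else:
        thresholds = cand[:nc]

    best_stat = -1.0
    best_thr = 0.0
    for ci in range(nc):
        thr = thresholds[ci]
        n1_risk = 0
        for i in range(m):
            if x[i] <= thr:
                n1_risk += 1
        n_risk = m
        obs = 0.0
        exp = 0.0
        var = 0.0
        d1_tot = 0
        i = 0
        while i < m:
            j = i
            dt = 0
            d1 = 0
            r1 = 0
            ti = t[i]
            while j < m and t[j] == ti:
                if d[j] == 1:
                    dt += 1
                    if x[j] <= thr:
                        d1 += 1
                if x[j] <= thr:
                    r1 += 1
                j += 1
            if dt > 0:
                frac = n1_risk / n_risk
                exp += dt * frac
                if n_risk > 1:
                    var += dt * frac * (1.0 - frac) * (n_risk - dt) / (n_risk - 1.0)
                obs += d1
                d1_tot += d1
            n_risk -= j - i
            n1_risk -= r1
            i = j
        if d1_tot < min_node_events or (n_events - d1_tot) < min_node_events:
            continue
        if var > 0.0:
            stat = (obs - exp) * (obs - exp) / var
            if stat > best_stat:
                best_stat = stat
                best_thr = thr
    return best_stat, best_thr


@njit(cache=True)
def grow_tree(X, t, d, mtry, min_node_events, n_split, grid, tree_seed):
    """Grow one survival tree on (bootstrap) arrays X, t, d.

    Returns ``(feat, thr, left, right, leaf_slot, leaf_chf)`` where
    ``feat[i] == -1`` marks a terminal node whose Nelson–Aalen cumulative
    hazard on ``grid`` is ``leaf_chf[leaf_slot[i]]``.
    """
    np.random.seed(tree_seed)
    m, p = X.shape
    max_nodes = 2 * m + 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    node_start = np.zeros(max_nodes, np.int64)
    node_end = np.zeros(max_nodes, np.int64)
    idx = np.arange(m)
    stack = np.empty(max_nodes, np.int64)

    node_start[0] = 0
    node_end[0] = m
    n_nodes = 1
    stack[0] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        node = stack[sp]
        s, e = node_start[node], node_end[node]
        mm = e - s
        n_events = 0
        for q in range(s, e):
            n_events += d[idx[q]]
        if n_events < 2 * min_node_events or mm < 2:
            continue
        # sort node samples by time
        tt = np.empty(mm)
        for q in range(mm):
            tt[q] = t[idx[s + q]]
        order = np.argsort(tt)
        sub = np.empty(mm, np.int64)
        for q in range(mm):
            sub[q] = idx[s + order[q]]
        tt_s = np.empty(mm)
        dd_s = np.empty(mm, np.int8)
        for q in range(mm):
            tt_s[q] = t[sub[q]]
            dd_s[q] = d[sub[q]]

        perm = np.random.permutation(p)
        best_stat = -1.0
        best_f = -1
        best_thr = 0.0
        n_try = mtry if mtry < p else p
        xv = np.empty(mm)
        for fi in range(n_try):
            f = perm[fi]
            for q in range(mm):
                xv[q] = X[sub[q], f]
            stat, th = _best_split_feature(xv, tt_s, dd_s, n_events,
                                           min_node_events, n_split)
            if stat > best_stat:
                best_stat = stat
                best_f = f
                best_thr = th
        if best_f < 0 or best_stat <= 0.0:
            continue
        # stable partition of idx[s:e]
        tmp = np.empty(mm, np.int64)
        nl = 0
        for q in range(s, e):
            if X[idx[q], best_f] <= best_thr:
                tmp[nl] = idx[q]
                nl += 1
        nr = nl
        for q in range(s, e):
            if X[idx[q], best_f] > best_thr:
                tmp[nr] = idx[q]
                nr += 1
        for q in range(mm):
            idx[s + q] = tmp[q]
        if nl == 0 or nl == mm:
            continue
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feat[node] = best_f
        thr[node] = best_thr
        left[node] = lid
        right[node] = rid
        node_start[lid] = s
        node_end[lid] = s + nl
        node_start[rid] = s + nl
        node_end[rid] = e
        stack[sp] = lid
        sp += 1
        stack[sp] = rid
        sp += 1

    # terminal Nelson–Aalen estimators on the shared grid
    n_leaves = 0
    leaf_slot = np.full(n_nodes, -1, np.int64)
    for node in range(n_nodes):
        if feat[node] < 0:
            leaf_slot[node] = n_leaves
            n_leaves += 1
    G = grid.shape[0]
    leaf_chf = np.zeros((n_leaves, G))
    for node in range(n_nodes):
        if feat[node] >= 0:
            continue
        s, e = node_start[node], node_end[node]
        mm = e - s
        tt = np.empty(mm)
        dd = np.empty(mm, np.int8)
        for q in range(mm):
            tt[q] = t[idx[s + q]]
            dd[q] = d[idx[s + q]]
        order = np.argsort(tt)
        slot = leaf_slot[node]
        gpos = 0
        chf = 0.0
        n_risk = mm
        i = 0
        while i < mm:
            j = i
            dt = 0
            ti = tt[order[i]]
            while j < mm and tt[order[j]] == ti:
                dt += dd[order[j]]
                j += 1
            while gpos < G and grid[gpos] < ti:
                leaf_chf[slot, gpos] = chf
                gpos += 1
            if dt > 0:
                chf += dt / n_risk
            n_risk -= j - i
            i = j
        while gpos < G:
            leaf_chf[slot, gpos] = chf
            gpos += 1
    return feat[:n_nodes], thr[:n_nodes], left[:n_nodes], right[:n_nodes], \
        leaf_slot, leaf_chf


@njit(cache=True)
def predict_tree_chf(X, feat, thr, left, right, leaf_slot, leaf_chf, rows, out):
    """Accumulate this tree's terminal CHF into ``out`` for ``rows`` of X."""
    for ri in range(rows.shape[0]):
        i = rows[ri]
        node = 0
        while feat[node] >= 0:
            if X[i, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        slot = leaf_slot[node]
        for g in range(leaf_chf.shape[1]):
            out[i, g] += leaf_chf[slot, g]
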