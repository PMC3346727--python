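"""Numba kernels for the classification random forest.

Everything here is deliberately self-contained integer/float arithmetic so a
fit is bit-reproducible across runs and platforms.  Randomness is
counter-based (splitmix64 hashing of a key plus a counter), which gives three
properties the surrounding modules rely on:

* determinism given the seed, with no global RNG state;
* per-(tree, SNP) importance-permutation streams keyed by a stable hash of
  the SNP identity, so importance does not depend on column order;
* the caller presents the features in identity-hash-sorted (canonical)
  order, so per-node mtry sampling — exact sampling without replacement via
  Floyd's algorithm — and split tie-breaking are exactly invariant under
  permuting the SNP columns of the input matrix.

Dosage features take values in {0, 1, 2}; candidate splits are the two cut
points (<=0 and <=1), scored by Gini impurity decrease.  Exact score ties
between features break toward the smaller identity hash (= smaller canonical
index); ties between the two cut points of one feature keep the lower cut.
If none of the mtry candidates yields an impurity decrease, all features are
scanned once before declaring a leaf.  Majority-vote ties predict class 0
(control).
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64

_GOLDEN = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)
_SALT_BOOT = U64(0xA5A5A5A517C0FFEE)
_SALT_NODE = U64(0xC3C3C3C35EEDF00D)
_SALT_IMP = U64(0x1234567890ABCDEF)


@njit(cache=True, inline="always")
def _mix(z):
    z = (z ^ (z >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _randint(key, counter, bound):
    """counter-th draw from stream `key`, uniform on [0, bound)."""
    return np.int64(_mix(key + U64(counter) * _GOLDEN) % U64(bound))


@njit(cache=True)
def fit_forest_kernel(G, y, cols, colhash, n_trees, min_node, mtry, seed,
                      compute_importance):
    """Grow a forest and return (oob_error, importance_z, case_vote_fraction).

    G : int8 (n_samples, n_features_total), C-contiguous
    y : int8 (n_samples,) in {0, 1}
    cols : int64 column indices of the features to use, already sorted by
           their identity hash (canonical order)
    colhash : uint64 stable identity hash per column of G
    mtry : number of split candidates drawn (without replacement) per node
    """
    n = G.shape[0]
    p = cols.size
    max_nodes = 2 * n + 1
    nwords = (p + 63) // 64
    if mtry > p:
        mtry = p

    votes0 = np.zeros(n, np.int64)
    votes1 = np.zeros(n, np.int64)
    imp_sum = np.zeros(p, np.float64)
    imp_ssq = np.zeros(p, np.float64)

    feat = np.empty(max_nodes, np.int32)
    thresh = np.empty(max_nodes, np.int8)
    left = np.empty(max_nodes, np.int32)
    right = np.empty(max_nodes, np.int32)
    pred = np.empty(max_nodes, np.int8)
    idx = np.empty(n, np.int64)
    buf = np.empty(n, np.int64)
    wt = np.empty(n, np.int64)
    wbuf = np.empty(n, np.int64)
    inbag = np.empty(n, np.int64)
    stack = np.empty((max_nodes, 3), np.int64)
    used = np.empty(p, np.uint8)
    oob_idx = np.empty(n, np.int64)
    oob_pred = np.empty(n, np.int8)
    permvals = np.empty(n, np.int8)
    cand = np.empty(p, np.int64)
    stamp = np.zeros(p, np.uint64)  # Floyd-sampling membership marks
    # bitmask of the features on each OOB sample's decision path; lets the
    # importance loop re-traverse only the samples a permutation can affect
    pathmask = np.zeros((n, nwords), np.uint64)

    min_split = 2 * min_node if 2 * min_node > 2 else 2
    node_serial = U64(0)  # never reset: keeps stamp marks unambiguous

    for t in range(n_trees):
        tkey = _mix(seed + U64(t + 1) * _GOLDEN)
        bkey = _mix(tkey ^ _SALT_BOOT)

        for i in range(n):
            inbag[i] = 0
        for i in range(n):
            inbag[_randint(bkey, i, n)] += 1
        n_unique = 0
        for i in range(n):
            if inbag[i] > 0:
                idx[n_unique] = i
                wt[n_unique] = inbag[i]
                n_unique += 1
        for j in range(p):
            used[j] = 0

        n_nodes = 1
        stack[0, 0] = 0
        stack[0, 1] = 0
        stack[0, 2] = n_unique
        sp = 1

        while sp > 0:
            sp -= 1
            node = stack[sp, 0]
            s = stack[sp, 1]
            e = stack[sp, 2]
            size = 0
            c1 = 0
            for i in range(s, e):
                size += wt[i]
                c1 += wt[i] * y[idx[i]]
            c0 = size - c1
            pred[node] = 1 if c1 > c0 else 0
            feat[node] = -1
            if c1 == 0 or c0 == 0 or size < min_split:
                continue

            node_serial += U64(1)
            nkey = _mix((tkey ^ _SALT_NODE) + node_serial * _GOLDEN)

            # Floyd's sampling: mtry distinct canonical feature indices
            n_cand = 0
            for k in range(p - mtry, p):
                r = _randint(nkey, k, k + 1)
                pos = r
                if stamp[pos] == node_serial:
                    pos = k
                stamp[pos] = node_serial
                cand[n_cand] = pos
                n_cand += 1

            parent_score = (c0 * c0 + c1 * c1) / size
            best_score = -1.0
            best_j = -1
            best_t = 0

            for rep in range(2):
                if rep == 1:
                    if best_j >= 0 and best_score > parent_score:
                        break
                    n_cand = p  # fallback: scan every feature once
                for c in range(n_cand):
                    j = cand[c] if rep == 0 else c
                    g = cols[j]
                    c00 = 0
                    c01 = 0
                    c10 = 0
                    c11 = 0
                    for i in range(s, e):
                        v = G[idx[i], g]
                        if v == 0:
                            if y[idx[i]] == 0:
                                c00 += wt[i]
                            else:
                                c01 += wt[i]
                        elif v == 1:
                            if y[idx[i]] == 0:
                                c10 += wt[i]
                            else:
                                c11 += wt[i]
                    for tt in range(2):
                        if tt == 0:
                            l0 = c00
                            l1 = c01
                        else:
                            l0 = c00 + c10
                            l1 = c01 + c11
                        lsize = l0 + l1
                        rsize = size - lsize
                        if lsize == 0 or rsize == 0:
                            continue
                        r0 = c0 - l0
                        r1 = c1 - l1
                        score = (l0 * l0 + l1 * l1) / lsize + (
                            r0 * r0 + r1 * r1
                        ) / rsize
                        take = False
                        if score > best_score:
                            take = True
                        elif score == best_score and best_j >= 0 and j < best_j:
                            take = True
                        if take:
                            best_score = score
                            best_j = j
                            best_t = tt

            if best_j < 0 or best_score <= parent_score:
                continue  # no impurity decrease anywhere: leaf

            used[best_j] = 1
            g = cols[best_j]
            th = best_t
            usize = e - s
            nl = 0
            for i in range(s, e):
                if G[idx[i], g] <= th:
                    buf[nl] = idx[i]
                    wbuf[nl] = wt[i]
                    nl += 1
            nr = nl
            for i in range(s, e):
                if G[idx[i], g] > th:
                    buf[nr] = idx[i]
                    wbuf[nr] = wt[i]
                    nr += 1
            for i in range(usize):
                idx[s + i] = buf[i]
                wt[s + i] = wbuf[i]

            lnode = n_nodes
            rnode = n_nodes + 1
            n_nodes += 2
            feat[node] = best_j
            thresh[node] = th
            left[node] = lnode
            right[node] = rnode
            stack[sp, 0] = lnode
            stack[sp, 1] = s
            stack[sp, 2] = s + nl
            sp += 1
            stack[sp, 0] = rnode
            stack[sp, 1] = s + nl
            stack[sp, 2] = e
            sp += 1

        # ---- out-of-bag predictions for this tree
        n_oob = 0
        for i in range(n):
            if inbag[i] == 0:
                k = n_oob
                for w in range(nwords):
                    pathmask[k, w] = U64(0)
                node = 0
                while feat[node] >= 0:
                    jf = feat[node]
                    pathmask[k, jf >> 6] |= U64(1) << U64(jf & 63)
                    if G[i, cols[jf]] <= thresh[node]:
                        node = left[node]
                    else:
                        node = right[node]
                pr = pred[node]
                oob_idx[k] = i
                oob_pred[k] = pr
                n_oob += 1
                if pr == 1:
                    votes1[i] += 1
                else:
                    votes0[i] += 1

        # ---- per-tree permutation importance
        if compute_importance and n_oob > 0:
            bc = 0
            for k in range(n_oob):
                if oob_pred[k] == y[oob_idx[k]]:
                    bc += 1
            ikey0 = _mix(seed ^ _SALT_IMP)
            for j in range(p):
                if used[j] == 0:
                    continue  # permuting an unused SNP changes nothing: d = 0
                wj = j >> 6
                bit = U64(1) << U64(j & 63)
                touched = 0
                for k in range(n_oob):
                    if pathmask[k, wj] & bit:
                        touched += 1
                if touched == 0:
                    continue  # no OOB path crosses this SNP: d = 0
                g = cols[j]
                for k in range(n_oob):
                    permvals[k] = G[oob_idx[k], g]
                pkey = _mix(_mix(ikey0 + U64(t + 1) * _GOLDEN) + colhash[g])
                for k in range(n_oob - 1, 0, -1):
                    r = _randint(pkey, k, k + 1)
                    tmp = permvals[k]
                    permvals[k] = permvals[r]
                    permvals[r] = tmp
                pc = bc
                for k in range(n_oob):
                    if not (pathmask[k, wj] & bit):
                        continue  # prediction cannot change
                    i = oob_idx[k]
                    node = 0
                    while feat[node] >= 0:
                        jf = feat[node]
                        if jf == j:
                            v = permvals[k]
                        else:
                            v = G[i, cols[jf]]
                        if v <= thresh[node]:
                            node = left[node]
                        else:
                            node = right[node]
                    was = 1 if oob_pred[k] == y[i] else 0
                    now = 1 if pred[node] == y[i] else 0
                    pc += now - was
                d = (bc - pc) / n_oob
                imp_sum[j] += d
                imp_ssq[j] += d * d

    # ---- aggregate
    wrong = 0
    covered = 0
    vote_frac = np.full(n, np.nan, np.float64)
    for i in range(n):
        tot = votes0[i] + votes1[i]
        if tot > 0:
            covered += 1
            pr = 1 if votes1[i] > votes0[i] else 0
            if pr != y[i]:
                wrong += 1
            vote_frac[i] = votes1[i] / tot
    oob_error = wrong / covered if covered > 0 else np.nan

    z = np.zeros(p, np.float64)
    if compute_importance and n_trees >= 2:
        T = float(n_trees)
        for j in range(p):
            mean = imp_sum[j] / T
            var = (imp_ssq[j] - T * mean * mean) / (T - 1.0)
            if var > 0.0:
                z[j] = mean / np.sqrt(var / T)
    return oob_error, z, vote_frac
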