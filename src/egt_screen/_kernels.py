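"""Numba dynamic-programming kernels.

All profile-HMM kernels work on an (L+1) x (M+1) lattice where row r means
"r residues consumed" and column k is the model node (0 = begin).  Scores are
log2 odds against the background null model.  Viterbi runs directly in log
space; forward runs in linear odds space with per-row rescaling so that no
per-cell transcendental calls are needed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def viterbi_fill(lom, loi, tmm, tmi, tmd, tim, tii, tdm, tdd, seq, local):
    """Fill Viterbi matrices.

    lom: (M, 21) match log2-odds (column 20 = ambiguous X, odds 0)
    loi: (21,) insert log2-odds
    t**: (M+1,) log2 transition probabilities indexed by source node
    seq: (L,) int8/int64 residue indices
    local: if True, free entry into any match state (cost -log2 M) and free
           exit from any match state (cost -log2 M); unaligned flanking
           residues score 0.
    Returns (VM, VI, VD, best_score).
    """
    L = seq.shape[0]
    M = lom.shape[0]
    VM = np.full((L + 1, M + 1), NEG_INF)
    VI = np.full((L + 1, M + 1), NEG_INF)
    VD = np.full((L + 1, M + 1), NEG_INF)

    entry = -np.log2(M) if local else NEG_INF
    if not local:
        VM[0, 0] = 0.0
        # begin -> D1 -> D2 ... chain (r = 0)
        VD[0, 1] = tmd[0]
        for k in range(2, M + 1):
            VD[0, k] = VD[0, k - 1] + tdd[k - 1]
        # begin -> I0 handled in the r loop via VM[r-1, 0]

    for r in range(1, L + 1):
        s = seq[r - 1]
        for k in range(1, M + 1):
            best = NEG_INF
            v = VM[r - 1, k - 1] + tmm[k - 1]
            if v > best:
                best = v
            v = VI[r - 1, k - 1] + tim[k - 1]
            if v > best:
                best = v
            v = VD[r - 1, k - 1] + tdm[k - 1]
            if v > best:
                best = v
            if local and entry > best:
                best = entry
            VM[r, k] = lom[k - 1, s] + best
        for k in range(0, M + 1):
            a = VM[r - 1, k] + tmi[k]
            b = VI[r - 1, k] + tii[k]
            VI[r, k] = loi[s] + (a if a > b else b)
        for k in range(1, M + 1):
            a = VM[r, k - 1] + tmd[k - 1]
            b = VD[r, k - 1] + tdd[k - 1]
            VD[r, k] = a if a > b else b

    if local:
        ext = -np.log2(M)
        best = NEG_INF
        for r in range(1, L + 1):
            for k in range(1, M + 1):
                v = VM[r, k] + ext
                if v > best:
                    best = v
    else:
        best = VM[L, M] + tmm[M]
        v = VI[L, M] + tim[M]
        if v > best:
            best = v
        v = VD[L, M] + tdm[M]
        if v > best:
            best = v
    return VM, VI, VD, best


@njit(cache=True)
def forward_score_kernel(pom, poi, pmm, pmi, pmd, pim, pii, pdm, pdd, seq, local):
    """Forward log2-odds score via scaled linear-space recursion.

    pom/poi are linear odds (emission / background); p** are linear transition
    probabilities.  Per-row rescaling keeps values in range; the log2 of the
    cumulative scale is carried separately.
    """
    L = seq.shape[0]
    M = pom.shape[0]
    PM = np.zeros((L + 1, M + 1))
    PI = np.zeros((L + 1, M + 1))
    PD = np.zeros((L + 1, M + 1))
    logscale = 0.0
    entry_p = 1.0 / M if local else 0.0

    if not local:
        PM[0, 0] = 1.0
        PD[0, 1] = pmd[0]
        for k in range(2, M + 1):
            PD[0, k] = PD[0, k - 1] * pdd[k - 1]

    total_local = 0.0  # accumulated exit mass (local), in current scale... see below
    # local exit mass must be accumulated in a fixed (unscaled) frame; we instead
    # accumulate it per row and rescale it together with the lattice rows.
    for r in range(1, L + 1):
        s = seq[r - 1]
        # fresh local entry mass enters unscaled; bring it into the current frame
        if local:
            fresh = entry_p * np.exp2(-logscale) if logscale > -1000.0 else 0.0
        else:
            fresh = 0.0
        for k in range(1, M + 1):
            acc = (
                PM[r - 1, k - 1] * pmm[k - 1]
                + PI[r - 1, k - 1] * pim[k - 1]
                + PD[r - 1, k - 1] * pdm[k - 1]
            )
            PM[r, k] = pom[k - 1, s] * (acc + fresh)
        for k in range(0, M + 1):
            PI[r, k] = poi[s] * (PM[r - 1, k] * pmi[k] + PI[r - 1, k] * pii[k])
        for k in range(1, M + 1):
            PD[r, k] = PM[r, k - 1] * pmd[k - 1] + PD[r, k - 1] * pdd[k - 1]
        if local:
            ext = 1.0 / M
            for k in range(1, M + 1):
                total_local += PM[r, k] * ext
        # rescale
        rowmax = total_local if local else 0.0
        for k in range(0, M + 1):
            if PM[r, k] > rowmax:
                rowmax = PM[r, k]
            if PI[r, k] > rowmax:
                rowmax = PI[r, k]
            if PD[r, k] > rowmax:
                rowmax = PD[r, k]
        if rowmax > 0.0 and (rowmax > 1e100 or rowmax < 1e-100):
            inv = 1.0 / rowmax
            for k in range(0, M + 1):
                PM[r, k] *= inv
                PI[r, k] *= inv
                PD[r, k] *= inv
            total_local *= inv
            logscale += np.log2(rowmax)

    if local:
        final = total_local
    else:
        final = (
            PM[L, M] * pmm[M] + PI[L, M] * pim[M] + PD[L, M] * pdm[M]
        )
    if final <= 0.0:
        return NEG_INF
    return np.log2(final) + logscale


@njit(cache=True)
def pdist_kernel(enc, cap, dmax, mode):
    """Pairwise protein distances on an encoded alignment.

    enc: (R, C) int8, residues 0..19, 20 = X, -1 = gap.  Gap and X columns are
    pairwise-deleted.  mode: 0 = p-distance, 1 = Poisson, 2 = Kimura protein.
    Pairs with p >= cap get distance dmax.  A pair with zero comparable
    columns is flagged with -1 in the output.
    """
    R, C = enc.shape
    D = np.zeros((R, R))
    for i in range(R):
        for j in range(i + 1, R):
            n = 0
            diff = 0
            for c in range(C):
                a = enc[i, c]
                b = enc[j, c]
                if a < 0 or b < 0 or a == 20 or b == 20:
                    continue
                n += 1
                if a != b:
                    diff += 1
            if n == 0:
                D[i, j] = -1.0
                D[j, i] = -1.0
                continue
            p = diff / n
            if p >= cap:
                d = dmax
            elif mode == 0:
                d = p
            elif mode == 1:
                d = -np.log(1.0 - p)
            else:
                arg = 1.0 - p - 0.2 * p * p
                d = dmax if arg <= 0.0 else -np.log(arg)
            if d > dmax:
                d = dmax
            D[i, j] = d
            D[j, i] = d
    return D


@njit(cache=True)
def nj_kernel(D0):
    """Classic neighbor joining on a distance matrix.

    Returns (merges, lengths): merges is an (n-2, 2) array of working-node
    indices joined at each step, lengths the corresponding child branch
    lengths (pre-clamping).  Working indices: 0..n-1 are the input leaves and
    n+s is the node created at step s.  The last step joins the final three
    nodes recorded as merges[n-3] = (i, j) plus the remaining node implicitly;
    callers finish with the three-point formulas.  Ties in the Q criterion are
    broken by the lowest (i, j) index pair.
    """
    n = D0.shape[0]
    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = D0
    active = np.zeros(size, dtype=np.int64)
    act = np.empty(n, dtype=np.int64)
    for i in range(n):
        act[i] = i
        active[i] = 1
    merges = np.zeros((n - 3, 2), dtype=np.int64)
    lengths = np.zeros((n - 3, 2))
    m = n
    nxt = n
    for step in range(n - 3):
        # row sums over active nodes
        r = np.zeros(size)
        for ii in range(m):
            i = act[ii]
            s = 0.0
            for jj in range(m):
                s += D[i, act[jj]]
            r[i] = s
        best_q = 1e300
        bi = -1
        bj = -1
        for ii in range(m):
            i = act[ii]
            for jj in range(ii + 1, m):
                j = act[jj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    bi = i
                    bj = j
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = D[bi, bj] - li
        merges[step, 0] = bi
        merges[step, 1] = bj
        lengths[step, 0] = li
        lengths[step, 1] = lj
        u = nxt
        nxt += 1
        for ii in range(m):
            k = act[ii]
            if k == bi or k == bj:
                continue
            duk = 0.5 * (D[bi, k] + D[bj, k] - D[bi, bj])
            D[u, k] = duk
            D[k, u] = duk
        # update active list
        new_act = np.empty(m - 1, dtype=np.int64)
        w = 0
        for ii in range(m):
            k = act[ii]
            if k != bi and k != bj:
                new_act[w] = k
                w += 1
        new_act[w] = u
        act = new_act
        m -= 1
    return merges, lengths, act, D


@njit(cache=True)
def ungapped_filter_kernel(lom, tmm, seq):
    """Best ungapped (match-states-only) local alignment score in log2 odds,
    including uniform entry/exit (1/M each) and M->M transition costs.

    A lower bound on the local Viterbi score used as a fast pre-filter:
    insert/delete excursions can only raise the full score above this by a
    bounded amount, so pairs scoring far below the reporting threshold here
    cannot become hits.
    """
    L = seq.shape[0]
    M = lom.shape[0]
    entry = -np.log2(M)
    best = NEG_INF
    prev = np.full(M + 1, NEG_INF)
    cur = np.full(M + 1, NEG_INF)
    for i in range(L):
        s = seq[i]
        for k in range(1, M + 1):
            stay = prev[k - 1] + tmm[k - 1]
            start = entry
            v = stay if stay > start else start
            cur[k] = v + lom[k - 1, s]
            if cur[k] > best:
                best = cur[k]
        for k in range(M + 1):
            prev[k] = cur[k]
            cur[k] = NEG_INF
    return best + entry  # exit weight
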