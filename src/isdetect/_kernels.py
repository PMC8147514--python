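"""Dynamic-programming kernels (numba-compiled).

Two engines live here:

* a local (subsequence-to-submodel) profile-HMM Viterbi search used for
  catalytic-domain seeding, and
* an affine-gap Smith-Waterman used by the extension stage.

Both are written as plain loops and JIT-compiled; both are oracle-tested
against exhaustive enumeration on small instances. Scores use -1e30 as
"minus infinity" so that max() stays NaN-free.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def viterbi_local(obs, match_lo, insert_lo, log_t, entry_lo):
    """Best local alignment of a profile against a target sequence.

    Parameters
    ----------
    obs : int64[L]
        Target symbols as alphabet indices; -1 marks unemittable positions
        (stop codons, already-reported domain spans).
    match_lo, insert_lo : float64[M+1, K]
        Emission log-odds (bits) for match/insert states 1..M (row 0 unused).
    log_t : float64[M+1, 7]
        log2 transition scores out of node j:
        [M->M, M->I, M->D, I->M, I->I, D->M, D->D].
    entry_lo : float64
        log2 probability of entering the model at a given match state
        (uniform local entry); charged once per local path. Exit from any
        match state is free.

    Returns (best_score, t_start, t_end, m_start, m_end): the maximal path
    score in bits and the half-open target/model spans of the best path.
    """
    M = match_lo.shape[0] - 1
    L = obs.shape[0]
    vm = np.full(M + 1, NEG_INF)
    vi = np.full(M + 1, NEG_INF)
    vd = np.full(M + 1, NEG_INF)
    # start/model-entry bookkeeping propagated alongside scores
    sm = np.zeros(M + 1, np.int64)
    si = np.zeros(M + 1, np.int64)
    sd = np.zeros(M + 1, np.int64)
    em = np.zeros(M + 1, np.int64)
    ei = np.zeros(M + 1, np.int64)
    ed = np.zeros(M + 1, np.int64)

    best = NEG_INF
    b_ts = 0
    b_te = 0
    b_ms = 0
    b_me = 0

    nvm = np.empty(M + 1)
    nvi = np.empty(M + 1)
    nvd = np.empty(M + 1)
    nsm = np.empty(M + 1, np.int64)
    nsi = np.empty(M + 1, np.int64)
    nsd = np.empty(M + 1, np.int64)
    nem = np.empty(M + 1, np.int64)
    nei = np.empty(M + 1, np.int64)
    ned = np.empty(M + 1, np.int64)

    for i in range(1, L + 1):
        x = obs[i - 1]
        for j in range(M + 1):
            nvm[j] = NEG_INF
            nvi[j] = NEG_INF
            nvd[j] = NEG_INF
            nsm[j] = 0
            nsi[j] = 0
            nsd[j] = 0
            nem[j] = 0
            nei[j] = 0
            ned[j] = 0
        if x >= 0:
            for j in range(1, M + 1):
                # match: fresh local entry or continue from node j-1
                sc = entry_lo
                st = i - 1
                en = j
                v = vm[j - 1] + log_t[j - 1, 0]
                if v > sc:
                    sc = v
                    st = sm[j - 1]
                    en = em[j - 1]
                v = vi[j - 1] + log_t[j - 1, 3]
                if v > sc:
                    sc = v
                    st = si[j - 1]
                    en = ei[j - 1]
                v = vd[j - 1] + log_t[j - 1, 5]
                if v > sc:
                    sc = v
                    st = sd[j - 1]
                    en = ed[j - 1]
                nvm[j] = match_lo[j, x] + sc
                nsm[j] = st
                nem[j] = en
                # insert on node j
                a = vm[j] + log_t[j, 1]
                b = vi[j] + log_t[j, 4]
                if a >= b:
                    nvi[j] = insert_lo[j, x] + a
                    nsi[j] = sm[j]
                    nei[j] = em[j]
                else:
                    nvi[j] = insert_lo[j, x] + b
                    nsi[j] = si[j]
                    nei[j] = ei[j]
        # delete sweep within the current column
        for j in range(1, M + 1):
            a = nvm[j - 1] + log_t[j - 1, 2]
            b = nvd[j - 1] + log_t[j - 1, 6]
            if a >= b:
                nvd[j] = a
                nsd[j] = nsm[j - 1]
                ned[j] = nem[j - 1]
            else:
                nvd[j] = b
                nsd[j] = nsd[j - 1]
                ned[j] = ned[j - 1]
        for j in range(1, M + 1):
            if nvm[j] > best:
                best = nvm[j]
                b_ts = nsm[j]
                b_te = i
                b_ms = nem[j] - 1
                b_me = j
        for j in range(M + 1):
            vm[j] = nvm[j]
            vi[j] = nvi[j]
            vd[j] = nvd[j]
            sm[j] = nsm[j]
            si[j] = nsi[j]
            sd[j] = nsd[j]
            em[j] = nem[j]
            ei[j] = nei[j]
            ed[j] = ned[j]
    return best, b_ts, b_te, b_ms, b_me


@njit(cache=True)
def sw_score(q, d, sub, gap_open, gap_extend):
    """Affine-gap Smith-Waterman score and footprint, O(|d|) memory.

    A gap of length k costs ``gap_open + k * gap_extend``. Returns
    (score, q_start, q_end, d_start, d_end) with half-open spans of the
    best-scoring local alignment (empty alignment scores 0).
    """
    n = q.shape[0]
    m = d.shape[0]
    first = gap_open + gap_extend
    H = np.zeros(m + 1)           # row i-1, overwritten in place to row i
    E = np.full(m + 1, NEG_INF)   # horizontal gap state (consumes d)
    F = np.full(m + 1, NEG_INF)   # vertical gap state (consumes q)
    hqs = np.zeros(m + 1, np.int64)
    hds = np.zeros(m + 1, np.int64)
    eqs = np.zeros(m + 1, np.int64)
    eds = np.zeros(m + 1, np.int64)
    fqs = np.zeros(m + 1, np.int64)
    fds = np.zeros(m + 1, np.int64)
    best = 0.0
    bqs = 0
    bqe = 0
    bds = 0
    bde = 0
    for i in range(1, n + 1):
        diag = H[0]
        dqs = hqs[0]
        dds = hds[0]
        hqs[0] = i
        hds[0] = 0
        for j in range(1, m + 1):
            # F first: needs row i-1 values of H[j] (not yet overwritten)
            a = H[j] - first
            b = F[j] - gap_extend
            if a >= b:
                F[j] = a
                fqs[j] = hqs[j]
                fds[j] = hds[j]
            else:
                F[j] = b
            # E: needs row i values at column j-1 (already overwritten)
            a = H[j - 1] - first
            b = E[j - 1] - gap_extend
            if a >= b:
                E[j] = a
                eqs[j] = hqs[j - 1]
                eds[j] = hds[j - 1]
            else:
                E[j] = b
                eqs[j] = eqs[j - 1]
                eds[j] = eds[j - 1]
            sc = diag + sub[q[i - 1], d[j - 1]]
            sqs = dqs
            sds = dds
            if F[j] > sc:
                sc = F[j]
                sqs = fqs[j]
                sds = fds[j]
            if E[j] > sc:
                sc = E[j]
                sqs = eqs[j]
                sds = eds[j]
            if sc < 0.0:
                sc = 0.0
                sqs = i
                sds = j
            diag = H[j]
            dqs = hqs[j]
            dds = hds[j]
            H[j] = sc
            hqs[j] = sqs
            hds[j] = sds
            if sc > best:
                best = sc
                bqs = sqs
                bqe = i
                bds = sds
                bde = j
    return best, bqs, bqe, bds, bde


@njit(cache=True)
def sw_trace(q, d, sub, gap_open, gap_extend):
    """Full-matrix Smith-Waterman with traceback on a (small) region.

    Returns (score, identities, aligned_len, q_start, q_end, d_start,
    d_end). ``aligned_len`` counts alignment columns including gaps.
    Ties prefer diagonal over gap-in-db over gap-in-query, making the
    traced path deterministic.
    """
    n = q.shape[0]
    m = d.shape[0]
    first = gap_open + gap_extend
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    # pointers: 0 stop, 1 diag, 2 from F (gap in db), 3 from E (gap in query)
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    e_ext = np.zeros((n + 1, m + 1), np.uint8)
    f_ext = np.zeros((n + 1, m + 1), np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a = H[i, j - 1] - first
            b = E[i, j - 1] - gap_extend
            if b > a:
                E[i, j] = b
                e_ext[i, j] = 1
            else:
                E[i, j] = a
            a = H[i - 1, j] - first
            b = F[i - 1, j] - gap_extend
            if b > a:
                F[i, j] = b
                f_ext[i, j] = 1
            else:
                F[i, j] = a
            sc = H[i - 1, j - 1] + sub[q[i - 1], d[j - 1]]
            p = 1
            if F[i, j] > sc:
                sc = F[i, j]
                p = 2
            if E[i, j] > sc:
                sc = E[i, j]
                p = 3
            if sc <= 0.0:
                sc = 0.0
                p = 0
            H[i, j] = sc
            ptr[i, j] = p
            if sc > best:
                best = sc
                bi = i
                bj = j
    # traceback
    i = bi
    j = bj
    ident = 0
    alen = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            if q[i - 1] == d[j - 1]:
                ident += 1
            i -= 1
            j -= 1
            alen += 1
        elif p == 2:
            # gap in db: walk up through F extensions
            while f_ext[i, j] == 1:
                i -= 1
                alen += 1
            i -= 1
            alen += 1
        else:
            while e_ext[i, j] == 1:
                j -= 1
                alen += 1
            j -= 1
            alen += 1
    return best, ident, alen, i, bi, j, bj
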