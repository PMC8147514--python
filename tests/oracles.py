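"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package's dynamic programmes:
the alignment oracle enumerates every local alignment recursively and the
profile oracle enumerates every state path through the model.
"""

from __future__ import annotations

import sys

from isdetect._kernels import NEG_INF


def brute_force_local_alignment(q, d, sub, gap_open, gap_extend) -> float:
    """Maximum score over all local alignments of q vs d (affine gaps,
    a gap of length k costing gap_open + k*gap_extend). Sequences are
    index lists; exponential enumeration, for tiny inputs only."""
    n, m = len(q), len(d)
    best = [0.0]
    sys.setrecursionlimit(100_000)

    def rec(i, j, score, state):
        best[0] = max(best[0], score)
        if i < n and j < m:
            rec(i + 1, j + 1, score + sub[q[i], d[j]], 0)
        if j < m:
            rec(i, j + 1, score - (gap_extend if state == 1 else gap_open + gap_extend), 1)
        if i < n:
            rec(i + 1, j, score - (gap_extend if state == 2 else gap_open + gap_extend), 2)

    for si in range(n + 1):
        for sj in range(m + 1):
            rec(si, sj, 0.0, 0)
    return best[0]


def brute_force_profile_best(model, target: str) -> float:
    """Maximum bit score over every local state path of the profile
    through the target, by explicit path enumeration. A path enters at any
    match state (paying the model's entry score), may leave from any match
    state, and emits a contiguous target substring."""
    mlo, ilo, lt = model._scores()
    obs = model.encode(target)
    M, L = model.M, len(obs)
    best = [NEG_INF]

    def rec(i, j, state, score):
        if state == "m":
            best[0] = max(best[0], score)
            moves = (("m", j + 1, lt[j, 0]), ("i", j, lt[j, 1]), ("d", j + 1, lt[j, 2]))
        elif state == "i":
            moves = (("m", j + 1, lt[j, 3]), ("i", j, lt[j, 4]))
        else:
            moves = (("m", j + 1, lt[j, 5]), ("d", j + 1, lt[j, 6]))
        for st, nj, tc in moves:
            if nj > M or tc <= NEG_INF / 2:
                continue
            if st == "d":
                rec(i, nj, st, score + tc)
            elif i < L and obs[i] >= 0:
                em = mlo[nj, obs[i]] if st == "m" else ilo[nj, obs[i]]
                if em > NEG_INF / 2:
                    rec(i + 1, nj, st, score + tc + em)

    for start in range(L):
        if obs[start] < 0:
            continue
        for entry in range(1, M + 1):
            if mlo[entry, obs[start]] > NEG_INF / 2:
                rec(start + 1, entry, "m", model.entry_score + mlo[entry, obs[start]])
    return best[0]
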