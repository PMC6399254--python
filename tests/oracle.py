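"""Independent reference implementations used as test oracles."""

import itertools
import math
from functools import lru_cache


def chain_score(q, r, pairs, params):
    """Score of an explicit monotone pairing under the alignment model."""
    score = params.match_bonus
    for (qi, ri), (qj, rj) in zip(pairs[:-1], pairs[1:]):
        dq = q[qj] - q[qi]
        dr = r[rj] - r[ri]
        pen = min(
            params.outlier_pen,
            (dq - dr) ** 2 / (params.sf_pen ** 2 + (params.sr_pen * dr) ** 2),
        )
        score += params.match_bonus - pen
        score -= params.cq * (qj - qi - 1) + params.cr * (rj - ri - 1)
    return score


def brute_force_best_score(q, r, params):
    """Best monotone-chain score by memoized forward recursion."""
    K = params.max_skip

    @lru_cache(maxsize=None)
    def best_from(i, j):
        best_cont = 0.0
        for ni in range(i + 1, min(i + K + 2, len(q))):
            for nj in range(j + 1, min(j + K + 2, len(r))):
                dq = q[ni] - q[i]
                dr = r[nj] - r[j]
                pen = min(
                    params.outlier_pen,
                    (dq - dr) ** 2 / (params.sf_pen ** 2 + (params.sr_pen * dr) ** 2),
                )
                cont = (
                    best_from(ni, nj)
                    - pen
                    - params.cq * (ni - i - 1)
                    - params.cr * (nj - j - 1)
                )
                best_cont = max(best_cont, cont)
        return params.match_bonus + best_cont

    return max(best_from(i, j) for i in range(len(q)) for j in range(len(r)))


def enumerate_best_score(q, r, params):
    """Literal enumeration of every monotone pairing (tiny instances only)."""
    best = -math.inf
    nq, nr = len(q), len(r)
    for k in range(1, min(nq, nr) + 1):
        for qs in itertools.combinations(range(nq), k):
            for rs in itertools.combinations(range(nr), k):
                pairs = list(zip(qs, rs))
                ok = all(
                    qj - qi - 1 <= params.max_skip and rj - ri - 1 <= params.max_skip
                    for (qi, ri), (qj, rj) in zip(pairs[:-1], pairs[1:])
                )
                if ok:
                    best = max(best, chain_score(q, r, pairs, params))
    return best


def split_score_direct(n1, l1, n2, l2):
    """Direct evaluation of the split-molecule score for one adjacent pair."""
    return min(
        n1 / (n1 + l1) * math.log(n1),
        n2 / (n2 + l2) * math.log(n2),
    )
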