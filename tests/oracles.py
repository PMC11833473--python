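"""Independent brute-force oracles used only by the test suite.

Each oracle is written from the defining formulas, deliberately avoiding the
code paths (and libraries) used by the implementation it checks.
"""

from __future__ import annotations

import math
from collections import Counter

from scipy.stats import hypergeom


def partitions(n: int):
    """All set partitions of range(n) as label tuples (restricted growth strings)."""
    def grow(prefix, k):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for label in range(k + 1):
            yield from grow(prefix + [label], max(k, label + 1))

    yield from grow([0], 1) if n else iter(())


def ami_oracle(u, v) -> float:
    """AMI from first principles with the exhaustive hypergeometric E[MI].

    MI and entropies are computed from the contingency table; the expected MI
    under the permutation model sums, for every (row, column) margin pair,
    over every feasible cell count weighted by its hypergeometric probability.
    Normalizer: arithmetic mean of the entropies.
    """
    n = len(u)
    assert len(v) == n and n > 0
    a = Counter(u)
    b = Counter(v)
    joint = Counter(zip(u, v))
    mi = 0.0
    for (ui, vj), nij in joint.items():
        mi += (nij / n) * math.log(n * nij / (a[ui] * b[vj]))
    h_u = -sum((c / n) * math.log(c / n) for c in a.values())
    h_v = -sum((c / n) * math.log(c / n) for c in b.values())
    emi = 0.0
    for ai in a.values():
        for bj in b.values():
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                p = hypergeom.pmf(nij, n, ai, bj)
                emi += p * (nij / n) * math.log(n * nij / (ai * bj))
    denom = 0.5 * (h_u + h_v) - emi
    if abs(denom) < 1e-15:
        return 1.0 if abs(mi - emi) < 1e-15 else 0.0
    return (mi - emi) / denom


def _words(text: str):
    out, cur = [], []
    for ch in text.lower():
        if ch.isalnum():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def _lcs_recursive(a, b) -> int:
    """Memoized recursive LCS (independent of the DP used in the package)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + rec(i + 1, j + 1)
        return max(rec(i + 1, j), rec(i, j + 1))

    return rec(0, 0)


def rouge_oracle(candidate: str, reference: str, variant: str):
    """Reference ROUGE from explicit dict counting and recursive LCS."""
    cand, ref = _words(candidate), _words(reference)
    if not cand or not ref:
        return (0.0, 0.0, 0.0)
    if str(variant).upper() == "L":
        overlap = _lcs_recursive(tuple(cand), tuple(ref))
        denom_p, denom_r = len(cand), len(ref)
    else:
        k = int(variant)
        def grams(tokens):
            table = {}
            for i in range(len(tokens) - k + 1):
                g = tuple(tokens[i : i + k])
                table[g] = table.get(g, 0) + 1
            return table
        gc, gr = grams(cand), grams(ref)
        overlap = sum(min(c, gr.get(g, 0)) for g, c in gc.items())
        denom_p, denom_r = sum(gc.values()), sum(gr.values())
        if denom_p == 0 or denom_r == 0:
            return (0.0, 0.0, 0.0)
    p = overlap / denom_p
    r = overlap / denom_r
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return (p, r, f)
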