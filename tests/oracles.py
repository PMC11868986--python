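"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive pure Python (lists, loops,
itertools.product) and shares no code with the package's scanning or
p-value machinery.
"""

from __future__ import annotations

import itertools
import math

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def naive_log_odds(probs, bg, pseudocount=1e-4):
    """probs: list of rows [pA,pC,pG,pT]; returns list of rows, log2 units."""
    out = []
    for row in probs:
        out.append([math.log2((p + pseudocount) / (1 + 4 * pseudocount) / b)
                    for p, b in zip(row, bg)])
    return out


def naive_window_score(lo, seq: str) -> float:
    return sum(lo[j][BASES.index(seq[j])] for j in range(len(lo)))


def naive_best_score(lo, seq: str, focal: int) -> float:
    """Best window score over both strands, windows covering focal."""
    L = len(lo)
    best = None
    for start in range(max(0, focal - L + 1), min(len(seq) - L, focal) + 1):
        window = seq[start:start + L]
        for w in (window, naive_revcomp(window)):
            s = naive_window_score(lo, w)
            if best is None or s > best:
                best = s
    if best is None:
        raise ValueError("no window covers focal")
    return best


def naive_exact_affinity_p(lo, bg, scan_len: int, focal: int,
                           observed: float, tol: float = 1e-9) -> float:
    total = 0.0
    hit = 0.0
    for combo in itertools.product(BASES, repeat=scan_len):
        seq = "".join(combo)
        w = 1.0
        for b in seq:
            w *= bg[BASES.index(b)]
        total += w
        if naive_best_score(lo, seq, focal) >= observed - tol:
            hit += w
    return hit / total


def naive_exact_rank_p(lo, bg, scan_len: int, focal: int, ref: str, alt: str,
                       observed: float, tol: float = 1e-9) -> float:
    total = 0.0
    hit = 0.0
    for combo in itertools.product(BASES, repeat=scan_len):
        seq = list(combo)
        w = 1.0
        for b in combo:
            w *= bg[BASES.index(b)]
        total += w
        seq[focal] = ref
        s_ref = naive_best_score(lo, "".join(seq), focal)
        seq[focal] = alt
        s_alt = naive_best_score(lo, "".join(seq), focal)
        if abs(s_ref - s_alt) >= observed - tol:
            hit += w
    return hit / total


def naive_pwm_similarity(q_probs, t_probs, min_overlap=4):
    """Best Pearson correlation over all ungapped offsets, both strands."""

    def pearson(xs, ys):
        n = len(xs)
        mx = sum(xs) / n
        my = sum(ys) / n
        num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        dx = math.sqrt(sum((x - mx) ** 2 for x in xs))
        dy = math.sqrt(sum((y - my) ** 2 for y in ys))
        if dx == 0 or dy == 0:
            return 0.0
        return num / (dx * dy)

    def rc(mat):
        return [row[::-1] for row in mat[::-1]]

    lq, lt = len(q_probs), len(t_probs)
    best = None
    for target in (t_probs, rc(t_probs)):
        for offset in range(-(lt - min_overlap), lq - min_overlap + 1):
            qlo, qhi = max(0, offset), min(lq, offset + lt)
            if qhi - qlo < min_overlap:
                continue
            xs, ys = [], []
            for i in range(qlo, qhi):
                xs.extend(q_probs[i])
                ys.extend(target[i - offset])
            sim = pearson(xs, ys)
            if best is None or sim > best:
                best = sim
    return best


def naive_bh(pvalues):
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return q


def naive_r2(f00, f01, f10, f11):
    pa = f10 + f11
    pb = f01 + f11
    d = f11 - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def dinuc_counts(seq: str):
    out = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out
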