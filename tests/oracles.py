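"""Independent brute-force oracles used only by the test suite.

These reimplement the statistical primitives from first principles (plain
loops, exact rational arithmetic, stdlib statistics) so that the package's
vectorized implementations are checked against a route that shares no code
with them.
"""

from __future__ import annotations

import math
from fractions import Fraction


def median_oracle(values):
    xs = sorted(values)
    n = len(xs)
    mid = n // 2
    return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2.0


def robust_z_oracle(column):
    """Direct median/MAD robust z of one column (quantified cells only)."""
    quant = [v for v in column if v is not None and not math.isnan(v)]
    med = median_oracle(quant)
    mad = median_oracle([abs(v - med) for v in quant])
    return [(v - med) / mad if v is not None and not math.isnan(v)
            else float("nan") for v in column]


def call_oracle(log2_matrix, tau=2.0, r_min=3):
    """Exhaustive per-unit regulation rule on a small oriented matrix.

    Returns one of up/down/unchanged/insufficient_data per row.
    """
    n_reps = len(log2_matrix[0])
    columns = [[row[j] for row in log2_matrix] for j in range(n_reps)]
    zcols = [robust_z_oracle(col) for col in columns]
    statuses = []
    for i in range(len(log2_matrix)):
        z = [zcols[j][i] for j in range(n_reps)]
        quant = [v for v in z if not math.isnan(v)]
        n_up = sum(1 for v in quant if v >= tau)
        n_down = sum(1 for v in quant if v <= -tau)
        if len(quant) < r_min:
            statuses.append("insufficient_data")
        elif n_up >= r_min and n_down == 0:
            statuses.append("up")
        elif n_down >= r_min and n_up == 0:
            statuses.append("down")
        else:
            statuses.append("unchanged")
    return statuses


def hypergeom_tail_oracle(a, b, c, d):
    """Exact rational P(X >= a), X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b)."""
    n_total = a + b + c + d
    k_ann = a + c
    n_reg = a + b
    denom = math.comb(n_total, n_reg)
    tail = Fraction(0)
    for k in range(a, min(k_ann, n_reg) + 1):
        tail += Fraction(math.comb(k_ann, k)
                         * math.comb(n_total - k_ann, n_reg - k), denom)
    return tail


def bh_oracle(pvalues):
    """Step-up Benjamini-Hochberg by the textbook recursion."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvalues[i] * m / rank)
        q[i] = val
        prev = val
    return q


def gsea_running_sum_oracle(metrics, hit_flags):
    """Plain-loop weighted KS running sum; returns (sums, ES)."""
    n = len(metrics)
    n_hits = sum(hit_flags)
    total = sum(abs(m) for m, h in zip(metrics, hit_flags) if h)
    sums = []
    s = 0.0
    for m, h in zip(metrics, hit_flags):
        if h:
            s += (abs(m) / total) if total else 1.0 / n_hits
        else:
            s -= 1.0 / (n - n_hits)
        sums.append(s)
    es = max(sums, key=abs)
    return sums, es


def normal_two_sided_p(z):
    return math.erfc(abs(z) / math.sqrt(2.0))
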