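"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity from first principles (explicit loops,
exhaustive enumeration) without touching the production code paths it
checks.
"""

import itertools
import math


def brute_smooth(x, y, b):
    """Direct O(n^2) evaluation of the kernel-smoothing equations:
    d_k = (x_k - x_i)/b; wt_k = exp(-d_k^2/2)/sqrt(2 pi);
    yhat_i = sum(wt_k * y_k) / sum(wt_k)."""
    out = []
    for i in range(len(x)):
        num = den = 0.0
        for k in range(len(x)):
            d = (x[k] - x[i]) / b
            wt = math.exp(-0.5 * d * d) / math.sqrt(2.0 * math.pi)
            num += wt * y[k]
            den += wt
        out.append(num / den)
    return out


def brute_average_slope(y_hat, x):
    """Mean of adjacent tangents via an explicit loop."""
    total = 0.0
    for i in range(len(y_hat) - 1):
        total += (y_hat[i + 1] - y_hat[i]) / (x[i + 1] - x[i])
    return total / (len(y_hat) - 1)


def brute_runs(y_hat):
    """Longest strict up/down runs by scanning every window."""
    n = len(y_hat)
    max_up = max_down = 0
    for i in range(n):
        for j in range(i + 1, n):
            if all(y_hat[k + 1] > y_hat[k] for k in range(i, j)):
                max_up = max(max_up, j - i)
            if all(y_hat[k + 1] < y_hat[k] for k in range(i, j)):
                max_down = max(max_down, j - i)
    return max_up, max_down


def oracle_classify(y_hat, x, T, C, B, E, biphasic_down="B", end_rule="range"):
    """Independent restatement of the response-pattern rules.

    Returns one of "hyper", "hypo", "biphasic", "NR".
    """
    rng = max(y_hat) - min(y_hat)
    if rng <= T:
        return "NR"
    up, down = brute_runs(y_hat)
    slope = brute_average_slope(y_hat, x)
    end_diff = abs(y_hat[-1] - y_hat[0])
    down_req = B if biphasic_down == "B" else C
    bound = E * rng if end_rule == "range" else E * T
    if up >= B and down >= down_req and end_diff <= bound:
        return "biphasic"
    if slope > 0 and up >= B:
        return "hyper"
    if slope < 0 and down >= C:
        return "hypo"
    return "NR"


def enum_hypergeom_sf(N, K, n, k):
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws.

    The background is 0..N-1 with the first K elements forming the set.
    """
    if n == 0:
        return 1.0 if k <= 0 else 0.0
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        overlap = sum(1 for item in draw if item < K)
        if overlap >= k:
            hits += 1
    return hits / total
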