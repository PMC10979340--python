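"""Independent brute-force oracles used by the statistics tests.

These deliberately avoid scipy: exact p-values are computed by full
enumeration of the permutation/sign null distribution, so agreement with
the package's tests is evidence, not circularity.
"""

from itertools import combinations

import numpy as np


def mw_exact_oracle(x, y, alternative: str) -> tuple[float, float]:
    """Exact Mann-Whitney U (x vs y, tie-free) by enumerating all
    C(n+m, n) rank assignments. Returns (U_x, p)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n, m = len(x), len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == n + m, "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2

    us = []
    all_ranks = range(1, n + m + 1)
    for subset in combinations(all_ranks, n):
        us.append(sum(subset) - n * (n + 1) / 2)
    us = np.asarray(us, dtype=float)
    p_greater = float(np.mean(us >= u_obs))
    p_less = float(np.mean(us <= u_obs))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return float(u_obs), p


def wilcoxon_exact_oracle(diffs, alternative: str) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank on nonzero tie-free differences by
    enumerating all 2^n sign patterns. Returns (W+, p)."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    n = d.size
    absd = np.abs(d)
    assert len(set(absd)) == n, "oracle requires tie-free |differences|"
    ranks = 1 + np.argsort(np.argsort(absd))
    w_obs = float(ranks[d > 0].sum())

    ws = []
    for mask in range(2 ** n):
        w = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += ranks[i]
        ws.append(w)
    ws = np.asarray(ws)
    p_greater = float(np.mean(ws >= w_obs))
    p_less = float(np.mean(ws <= w_obs))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return w_obs, p


def cliff_delta_oracle(x, y) -> float:
    """Cliff's delta straight from its pairwise definition."""
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))


def tie_free_samples(rng: np.random.Generator, n: int, m: int = 0):
    """Draw tie-free real-valued samples (x of size n, y of size m)."""
    while True:
        vals = rng.normal(0, 1, size=n + m)
        if len(set(np.abs(vals))) == n + m and np.all(vals != 0):
            return vals[:n].tolist(), vals[n:].tolist()
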