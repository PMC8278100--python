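"""Shared test helpers and independent oracle implementations.

The oracles here deliberately use naive, direct formulations (explicit
loops, residual regressions, exhaustive enumeration) so they stay
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from immumirna import ExpressionMatrix


def make_expr(values, state="log2", features=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), state)


def residual_pcc_oracle(x, y, c):
    """Partial correlation as Pearson correlation of regression residuals."""
    x, y, c = (np.asarray(v, dtype=float) for v in (x, y, c))
    design = np.column_stack([np.ones_like(c), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def naive_es(gene_ids, rs, gene_set, weight_exponent=1.0):
    """Enrichment score by an explicit position-by-position running sum."""
    rs = np.asarray(rs, dtype=float)
    hits = np.array([g in gene_set for g in gene_ids])
    n, k = len(gene_ids), int(hits.sum())
    weights = np.abs(rs) ** weight_exponent
    total = weights[hits].sum()
    if total == 0:
        weights = np.ones(n)
        total = float(k)
    running = 0.0
    high, low = -np.inf, np.inf
    for i in range(n):
        if hits[i]:
            running += weights[i] / total
        else:
            running -= 1.0 / (n - k) if n > k else 0.0
        high = max(high, running)
        low = min(low, running)
    # signed deviation of maximal absolute value; ties (to rounding) positive
    return high if high >= -low - 1e-12 else low


def exhaustive_null_p(gene_ids, rs, gene_set, weight_exponent=1.0):
    """Exact permutation p by enumerating every same-size subset."""
    obs = naive_es(gene_ids, rs, gene_set, weight_exponent)
    k = sum(1 for g in gene_ids if g in gene_set)
    null = [
        naive_es(gene_ids, rs, set(combo), weight_exponent)
        for combo in itertools.combinations(gene_ids, k)
    ]
    null = np.array(null)
    same = np.sign(null) == np.sign(obs)
    exceed = same & (np.abs(null) >= abs(obs))
    return exceed.sum() / same.sum(), obs


def hand_bh(p):
    """Benjamini–Hochberg step-up, written out explicitly."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        q[idx] = min(running_min, 1.0)
    return q


def hand_logrank(time, event, group1_mask):
    """Two-group log-rank chi-square by an explicit event-time loop."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(group1_mask, dtype=bool)
    observed_minus_expected = 0.0
    variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        observed_minus_expected += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0
    return observed_minus_expected**2 / variance
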