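"""Small shared statistical utilities.

Pairwise group comparisons follow the estimated-marginal-means recipe: a
one-way linear model supplies a pooled residual variance, every pair of
group means is compared by a t test on that pooled variance, p-values are
Bonferroni-adjusted, and the result is summarized as a compact letter
display (groups sharing a letter are not significantly different).
"""

from __future__ import annotations

import itertools
import math
import string

import numpy as np
import pandas as pd
from scipy import stats as sps


def pairwise_bonferroni(
    values: np.ndarray | pd.Series, groups: np.ndarray | pd.Series
) -> pd.DataFrame:
    """All pairwise mean comparisons from a one-way linear model.

    Returns a frame with one row per unordered group pair: the two group
    labels, mean difference, t statistic, raw and Bonferroni-adjusted p.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    means, ns = {}, {}
    sse = 0.0
    for g in labels:
        v = values[groups == g]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        means[g] = v.mean()
        ns[g] = len(v)
        sse += ((v - v.mean()) ** 2).sum()
    df_resid = len(values) - len(labels)
    mse = sse / df_resid if df_resid > 0 else np.nan
    rows = []
    pairs = list(itertools.combinations(labels, 2))
    for a, b in pairs:
        diff = means[a] - means[b]
        se = math.sqrt(mse * (1 / ns[a] + 1 / ns[b])) if mse > 0 else 0.0
        if se == 0:
            t = 0.0 if diff == 0 else math.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = 2 * sps.t.sf(abs(t), df_resid)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "diff": diff,
                "t": t,
                "p": p,
                "p_adj": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def compact_letter_display(
    labels: list, pairwise: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Insert-and-absorb compact letter display.

    ``pairwise`` must carry group_a/group_b/p_adj columns.  Pairs with
    adjusted p exactly equal to alpha are treated as non-significant.
    Output letters are stable under reordering of the label list.
    """
    order = sorted(labels, key=str)
    sig = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples(index=False)
        if r.p_adj < alpha
    }
    # columns: sets of mutually non-different groups
    columns: list[set] = []
    for g in order:
        placed = False
        for col in columns:
            if all(frozenset((g, h)) not in sig for h in col):
                col.add(g)
                placed = True
        if not placed:
            columns.append({g})
    # absorb: drop columns fully contained in another
    kept = []
    for i, col in enumerate(columns):
        if not any(i != j and col < other for j, other in enumerate(columns)):
            if col not in kept:
                kept.append(col)
    alphabet = string.ascii_lowercase
    letters: dict = {g: "" for g in order}
    for idx, col in enumerate(kept):
        ch = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for g in order:
            if g in col:
                letters[g] += ch
    return letters


def anderson_darling_normal(x: np.ndarray) -> tuple[float, float]:
    """Anderson-Darling normality test with estimated mean and variance.

    Returns (A2, p).  A2 is the statistic on standardized values; the
    p-value uses the small-sample modification A2* = A2 (1 + 0.75/n +
    2.25/n^2) and the standard piecewise exponential approximation for the
    composite-normal case.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 8:
        raise ValueError("Anderson-Darling needs at least 8 observations")
    s = x.std(ddof=1)
    if s == 0:
        return math.nan, math.nan
    z = (x - x.mean()) / s
    cdf = sps.norm.cdf(z)
    cdf = np.clip(cdf, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1])))
    a2m = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a2m >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2m + 0.0186 * a2m**2)
    elif a2m > 0.34:
        p = math.exp(0.9177 - 4.279 * a2m - 1.38 * a2m**2)
    elif a2m > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2m - 59.938 * a2m**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2m - 223.73 * a2m**2)
    return float(a2), float(min(max(p, 0.0), 1.0))
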