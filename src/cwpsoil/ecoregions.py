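"""Edaphoclimatic ecoregion delineation.

Sites are ordinated by PCA on centred and scaled environmental variables;
the leading axes are weighted by the square root of their eigenvalues so
Euclidean distances in the reduced space reflect axis importance; K-means
is run over a cascade of cluster numbers and the Calinski-Harabasz (CH)
index picks the number of ecoregions.  Per-CWP position on each axis is
tested with Wilcoxon signed-rank tests and Bonferroni-corrected pairwise
mean comparisons with compact letters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .stats import compact_letter_display, pairwise_bonferroni


@dataclasses.dataclass
class PCAResult:
    loadings: pd.DataFrame        # variables x components (unit eigenvectors)
    scores: pd.DataFrame          # sites x components, variance = eigenvalue
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    squared_cosines: pd.DataFrame  # variables x components


@dataclasses.dataclass
class EcoregionAssignment:
    labels: pd.Series              # site -> cluster label in 1..k_selected
    k_selected: int
    ch_values: dict[int, float]
    within_ss: dict[int, float]


def run_pca(env: pd.DataFrame) -> PCAResult:
    """PCA of the correlation structure of a complete environmental table.

    Variables are standardized to zero mean and unit variance (denominator
    n-1).  Scores are the site coordinates with column variance equal to the
    eigenvalue.  Sign convention: the largest-magnitude loading of each
    component is made positive, so results are reproducible across BLAS
    backends.
    """
    if env.isna().to_numpy().any():
        raise ValueError("environment table has missing cells; impute first")
    n, p = env.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 sites and 2 variables")
    sd = env.std(ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant variables cannot be scaled: {list(constant.index)}")
    Z = (env - env.mean()) / sd
    u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    eig = s**2 / (n - 1)
    # deterministic sign: largest |loading| per component positive
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    comp = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=env.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=env.columns, columns=comp)
    # variable coordinates = corr(variable, score); cos2 sums to 1 per variable
    coords = loadings * np.sqrt(eig)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=eig,
        variance_fraction=eig / eig.sum(),
        squared_cosines=coords**2,
    )


def weight_scores(pca: PCAResult, n_axes: int) -> pd.DataFrame:
    """First ``n_axes`` score columns, unit-variance-standardized then scaled
    by sqrt(eigenvalue), so column c has variance exactly eigenvalue_c and
    squared Euclidean distances are eigenvalue-weighted distances in PC
    space.  Zero-eigenvalue axes come out identically zero.
    """
    if n_axes <= 0:
        raise ValueError(f"n_axes must be positive, got {n_axes}")
    if n_axes > pca.scores.shape[1]:
        raise ValueError(
            f"n_axes={n_axes} exceeds the {pca.scores.shape[1]} available components"
        )
    out = {}
    for c, col in enumerate(pca.scores.columns[:n_axes]):
        eig = pca.eigenvalues[c]
        if eig <= 1e-12:
            out[col] = np.zeros(len(pca.scores))
        else:
            sd = pca.scores[col].std(ddof=1)
            out[col] = (pca.scores[col] / sd * np.sqrt(eig)).to_numpy()
    return pd.DataFrame(out, index=pca.scores.index)


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """CH(k) = [B/(k-1)] / [W/(n-k)] with B, W between/within sums of squares."""
    return float(calinski_harabasz_score(points, labels))


def select_k_calinski(
    points: pd.DataFrame,
    k_range: tuple[int, int] = (2, 10),
    n_starts: int = 25,
    seed: int | None = None,
) -> EcoregionAssignment:
    """K-means cascade over ``k_range`` with CH-based selection of k.

    Best-of-``n_starts`` Lloyd K-means (greedy k-means++ initialization) per
    candidate k; ties in CH break toward smaller k; final labels are
    renumbered 1..k by descending cluster size for determinism.
    """
    lo, hi = k_range
    if lo < 2:
        raise ValueError("CH is undefined at k=1; k_range must start at >= 2")
    n = len(points)
    if n <= hi:
        raise ValueError(f"need more sites ({n}) than max k ({hi})")
    X = points.to_numpy(dtype=float)
    ch_values: dict[int, float] = {}
    within: dict[int, float] = {}
    best_labels: dict[int, np.ndarray] = {}
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit(X)
        ch_values[k] = calinski_harabasz(X, km.labels_)
        within[k] = float(km.inertia_)
        best_labels[k] = km.labels_
    k_selected = lo
    for k in range(lo, hi + 1):
        if ch_values[k] > ch_values[k_selected]:
            k_selected = k
    raw = best_labels[k_selected]
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda lbl: (-sizes[lbl], lbl))
    remap = {old: i + 1 for i, old in enumerate(order)}
    labels = pd.Series([remap[v] for v in raw], index=points.index, name="ecoregion")
    return EcoregionAssignment(
        labels=labels, k_selected=k_selected, ch_values=ch_values, within_ss=within
    )


def test_axis_differences(
    scores: pd.DataFrame, site_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-CWP, per-axis location tests.

    For every CWP species and PCA axis: a Wilcoxon signed-rank test of the
    scores against zero (exact null for n <= 25, normal approximation with
    continuity correction above), plus, per axis, Bonferroni-adjusted
    pairwise comparisons of CWP means from a one-way linear model summarized
    as compact letters.
    """
    cwps = site_table.loc[scores.index, "cwp_species"]
    rows = []
    for axis in scores.columns:
        letters = {}
        groups_ok = cwps.value_counts()
        if (groups_ok >= 2).all() and cwps.nunique() >= 2:
            pw = pairwise_bonferroni(scores[axis].to_numpy(), cwps.to_numpy())
            letters = compact_letter_display(list(cwps.unique()), pw, alpha=alpha)
        for cwp, sub in scores[axis].groupby(cwps):
            v = sub.to_numpy(dtype=float)
            if len(v) < 2:
                raise ValueError(f"CWP {cwp!r} has fewer than 2 sites")
            if np.all(v == 0):
                p = np.nan  # test undefined: no nonzero differences
            else:
                # exact null when feasible (n <= 25, no ties or zeros),
                # otherwise normal approximation with continuity correction
                has_ties = len(np.unique(np.abs(v[v != 0]))) < len(v[v != 0])
                exact = len(v) <= 25 and np.all(v != 0) and not has_ties
                p = float(
                    sps.wilcoxon(
                        v, method="exact" if exact else "approx", correction=not exact
                    ).pvalue
                )
            rows.append(
                {
                    "cwp_species": cwp,
                    "axis": axis,
                    "n": len(v),
                    "median": float(np.median(v)),
                    "wilcoxon_p": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                    "letter": letters.get(cwp, ""),
                }
            )
    return pd.DataFrame(rows)
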