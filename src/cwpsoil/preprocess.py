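"""Environmental imputation and count-table preprocessing.

Missing edaphoclimatic cells (about 4% of the table in the survey this
pipeline targets) are filled by chained-equation predictive mean matching
(PMM): each incomplete variable is regressed on all others, and every
missing cell receives an *observed* value donated by one of the cases whose
predicted mean is nearest.  Count tables are rarefied — subsampled without
replacement — to a fixed per-kingdom depth, then converted to relative
abundances and presence/absence for the downstream stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WALKLEY_BLACK_TO_DRY_COMBUSTION = 1.15


def walkley_black_to_dry_combustion(soc: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Convert Walkley-Black soil organic carbon to dry-combustion scale.

    Walkley-Black wet oxidation recovers organic carbon incompletely; the
    conventional correction multiplies by 1.15.  Apply only to columns
    measured by Walkley-Black (in the survey, the little-millet batch).
    """
    return soc * WALKLEY_BLACK_TO_DRY_COMBUSTION


def impute_pmm(
    env: pd.DataFrame,
    n_cycles: int = 999,
    n_donors: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Impute missing cells by chained predictive mean matching.

    For each incomplete variable in turn, an OLS regression on all other
    (currently completed) variables predicts the variable for every site;
    each missing cell is filled with the observed value of one of the
    ``n_donors`` cases with the closest predicted mean, chosen at random.
    The sweep over variables is repeated ``n_cycles`` times and the final
    completed table returned.  Observed cells are never modified, and every
    imputed value is by construction a member of its column's observed set.
    """
    if n_cycles < 1 or n_donors < 1:
        raise ValueError("n_cycles and n_donors must be >= 1")
    if env.shape[1] < 2:
        raise ValueError("PMM needs at least 2 variables")
    missing = env.isna()
    for col in env.columns:
        n_obs = int((~missing[col]).sum())
        if n_obs == 0:
            raise ValueError(f"variable {col!r} is entirely missing; cannot impute")
        if 0 < missing[col].sum() and n_obs < n_donors:
            raise ValueError(
                f"variable {col!r} has {n_obs} observed values, fewer than "
                f"n_donors={n_donors}"
            )
    if not missing.to_numpy().any():
        return env.copy()

    rng = np.random.default_rng(seed)
    work = env.copy()
    # start from column means so the first cycle has a complete predictor matrix
    work = work.fillna(work.mean())
    incomplete = [c for c in env.columns if missing[c].any()]

    values = work.to_numpy(dtype=float)
    miss = missing.to_numpy()
    col_idx = {c: i for i, c in enumerate(env.columns)}

    for _ in range(n_cycles):
        for col in incomplete:
            j = col_idx[col]
            obs = ~miss[:, j]
            others = np.delete(np.arange(values.shape[1]), j)
            X = np.column_stack([np.ones(len(values)), values[:, others]])
            beta, *_ = np.linalg.lstsq(X[obs], env[col].to_numpy()[obs], rcond=None)
            pred = X @ beta
            obs_pred = pred[obs]
            obs_vals = env[col].to_numpy()[obs]
            for i in np.flatnonzero(miss[:, j]):
                k = min(n_donors, len(obs_vals))
                donors = np.argpartition(np.abs(obs_pred - pred[i]), k - 1)[:k]
                values[i, j] = obs_vals[rng.choice(donors)]

    out = pd.DataFrame(values, index=env.index, columns=env.columns)
    out[~missing] = env[~missing]  # exact restore of observed cells
    return out


def rarefy(
    counts: pd.DataFrame, depth: int, seed: int | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below the depth are dropped (and returned in the
    second element so the caller can log them).  Sampling is multivariate
    hypergeometric, i.e. drawing reads without replacement from the sample's
    observed read pool.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    kept_cols: list[str] = []
    dropped: list[str] = []
    out = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            out[sample] = col.copy()
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth)
        kept_cols.append(sample)
    if dropped:
        log.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    result = pd.DataFrame(out, index=counts.index, columns=kept_cols, dtype=np.int64)
    return result, dropped


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; columns sum to 1."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"zero-total samples {list(zero.index)}; drop them (rarefy) first"
        )
    return counts / totals


def presence_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Binary matrix: 1 where count > 0."""
    return (counts > 0).astype(np.int8)
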