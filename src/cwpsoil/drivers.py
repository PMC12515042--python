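"""Environmental driver analysis of module abundances.

Per module and kingdom, the mean standardized module abundance across wild
populations is modelled with a Gaussian linear mixed model with the CWP
species as a categorical random intercept.  Candidate predictors are first
screened for collinearity (variance inflation factor, threshold 5), the
fixed structure is reduced by backward selection on the ML Akaike
information criterion, coefficients are reported from the REML refit with
parametric-bootstrap 95% confidence intervals, and the marginal R^2 is
decomposed into unique and shared variance per predictor group by
hierarchical partitioning.

The random-intercept model is fitted by profiled (restricted) maximum
likelihood: for a candidate variance ratio lambda = sigma2_u / sigma2_e the
GLS solution and profiled variances are closed-form per group, leaving a
one-dimensional optimization in log(lambda).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .stats import anderson_darling_normal

#: Predictor groups of the driver models (the carbon-sink group holds the
#: productivity and soil-carbon storage proxies).
PREDICTOR_GROUPS: dict[str, tuple[str, ...]] = {
    "climate": ("MAT", "MDR", "PSEA", "AI"),
    "soil_properties": ("pH", "conductivity", "sand"),
    "soil_nutrients": ("NH4", "NO3", "PO4", "Ca", "B", "K", "Mg", "Zn", "Fe", "Mn", "Mo"),
    "carbon_sink": ("NDVI", "SOC"),
}


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance (ddof=1) columns."""
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant predictors: {list(sd.index[sd == 0])}")
    return (df - df.mean()) / sd


# ---------------------------------------------------------------------------
# collinearity screen


def vif_filter(
    predictors: pd.DataFrame, threshold: float = 5.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the predictor with the largest VIF until all <= threshold.

    VIF_v = 1 / (1 - R^2_v) with R^2_v from regressing v on the other
    retained predictors (with intercept).  Perfectly collinear variables
    have infinite VIF and are dropped first.  Returns the retained variable
    list and a report with the drop order and final VIFs.
    """
    if predictors.shape[1] < 2:
        raise ValueError("VIF screen needs at least 2 predictors")
    if predictors.isna().to_numpy().any():
        raise ValueError("predictors contain missing values")
    retained = list(predictors.columns)
    rows = []
    step = 0

    def vif_of(col: str, cols: list[str]) -> float:
        others = [c for c in cols if c != col]
        y = predictors[col].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(y))] + [predictors[c].to_numpy(dtype=float) for c in others]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1 - resid @ resid / tss if tss > 0 else 1.0
        return math.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)

    while len(retained) > 1:
        vifs = {c: vif_of(c, retained) for c in retained}
        worst = max(retained, key=lambda c: vifs[c])
        if vifs[worst] <= threshold:
            break
        step += 1
        rows.append({"step": step, "dropped": worst, "vif": vifs[worst]})
        retained.remove(worst)
    final = {c: vif_of(c, retained) for c in retained} if len(retained) > 1 else {
        c: 1.0 for c in retained
    }
    report = pd.DataFrame(rows, columns=["step", "dropped", "vif"])
    report_final = pd.DataFrame(
        {"variable": list(final), "vif_final": list(final.values())}
    )
    return retained, pd.concat(
        [report, report_final], axis=0, ignore_index=True
    )


# ---------------------------------------------------------------------------
# random-intercept linear mixed model


@dataclasses.dataclass
class LMMFit:
    """Fitted Gaussian random-intercept mixed model."""

    params: pd.Series              # fixed coefficients (incl. Intercept)
    se: pd.Series
    sigma2_u: float                # random-intercept variance
    sigma2_e: float                # residual variance
    loglik: float
    method: str                    # "REML" or "ML"
    aic: float                     # from the ML criterion only (nan for REML)
    r2m: float
    r2c: float
    response: pd.Series
    fixed: pd.DataFrame            # predictor columns used (no intercept)
    grouping: pd.Series
    boundary: bool                 # sigma2_u pinned at ~0
    bootstrap_ci: pd.DataFrame | None = None

    @property
    def fitted_fixed(self) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(self.response))] + [self.fixed[c] for c in self.fixed.columns]
        )
        return X @ self.params.to_numpy()

    def random_effects(self) -> pd.Series:
        """Empirical BLUPs of the group intercepts."""
        lam = self.sigma2_u / self.sigma2_e if self.sigma2_e > 0 else 0.0
        marg = self.response.to_numpy() - self.fitted_fixed
        out = {}
        for g, idx in self.grouping.groupby(self.grouping).groups.items():
            r = marg[self.grouping.index.get_indexer(idx)]
            out[g] = lam * len(r) / (1 + lam * len(r)) * r.mean() if lam > 0 else 0.0
        return pd.Series(out)

    def residuals(self) -> np.ndarray:
        """Conditional residuals (observed minus fixed part minus BLUP)."""
        u = self.random_effects()
        return (
            self.response.to_numpy()
            - self.fitted_fixed
            - u[self.grouping].to_numpy()
        )


class _Sufficient:
    """Group-level sufficient statistics for the profiled likelihood.

    For V = I + lam * J within groups (residual variance factored out),
    X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V| are rank-one corrections of the
    OLS cross-products by per-group sums, so each candidate lam costs one
    small matrix product.
    """

    def __init__(self, y, X, codes, sizes):
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        G = len(sizes)
        p = X.shape[1]
        self.Xg = np.zeros((G, p))
        np.add.at(self.Xg, codes, X)
        self.yg = np.bincount(codes, weights=y, minlength=G)
        self.sizes = np.asarray(sizes, dtype=float)

    def pieces(self, lam):
        w = lam / (1 + lam * self.sizes)
        A = self.XtX - (self.Xg.T * w) @ self.Xg
        b = self.Xty - self.Xg.T @ (w * self.yg)
        yy = self.yty - float(w @ self.yg**2)
        logdet = float(np.log1p(lam * self.sizes).sum())
        return A, b, yy, logdet


def _profile_pieces(y, X, group_codes, group_sizes, lam):
    return _Sufficient(y, X, group_codes, group_sizes).pieces(lam)


def _neg_profiled_ll(log_lam, suff, n, p, reml):
    lam = math.exp(log_lam)
    A, b, yy, logdet = suff.pieces(lam)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return math.inf
    rss = yy - b @ beta
    if rss <= 0:
        rss = 1e-300
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * (
            dof * math.log(2 * math.pi * sigma2) + logdet + logdetA + dof
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return -ll


def _optimize_lambda(suff, n, p, reml):
    """Coarse log-grid plus bounded refinement; returns (log_lam, nll)."""
    grid = np.linspace(-10, 8, 19)
    vals = [_neg_profiled_ll(g, suff, n, p, reml) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        _neg_profiled_ll,
        bounds=(lo, hi),
        args=(suff, n, p, reml),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam, nll = float(res.x), float(res.fun)
    boundary_nll = _neg_profiled_ll(-30.0, suff, n, p, reml)
    if boundary_nll <= nll:
        return -30.0, boundary_nll
    return log_lam, nll


def fit_lmm(
    response: pd.Series,
    fixed: pd.DataFrame,
    grouping: pd.Series,
    method: str = "REML",
) -> LMMFit:
    """Fit y = Xb + u_g + e with u_g ~ N(0, sigma2_u), e ~ N(0, sigma2_e).

    The variance ratio is profiled out and optimized on a log grid plus a
    bounded 1-D refinement; coefficients are the GLS solution at the
    optimum.  A fit with sigma2_u at the zero boundary is returned with
    ``boundary=True`` rather than raising.  R2m and R2c follow the
    variance-components definition: R2m = var(Xb) / (var(Xb) + sigma2_u +
    sigma2_e) and R2c adds sigma2_u to the numerator.
    """
    if method not in {"REML", "ML"}:
        raise ValueError(f"method must be REML or ML, got {method!r}")
    y = response.to_numpy(dtype=float)
    n = len(y)
    names = ["Intercept"] + list(fixed.columns)
    X = np.column_stack([np.ones(n)] + [fixed[c].to_numpy(dtype=float) for c in fixed.columns])
    codes, uniques = pd.factorize(grouping.to_numpy())
    if len(uniques) < 2:
        raise ValueError("need at least 2 grouping levels")
    sizes = np.bincount(codes)
    reml = method == "REML"

    suff = _Sufficient(y, X, codes, sizes)
    log_lam, nll = _optimize_lambda(suff, n, X.shape[1], reml)
    lam = math.exp(log_lam)

    A, b, yy, _ = suff.pieces(lam)
    beta = np.linalg.solve(A, b)
    rss = max(yy - b @ beta, 1e-300)
    sigma2_e = rss / (n - X.shape[1]) if reml else rss / n
    sigma2_u = lam * sigma2_e
    boundary = lam < 1e-8
    if boundary:
        sigma2_u = 0.0
        warnings.warn("random-intercept variance estimated at the zero boundary")
    cov = np.linalg.inv(A) * sigma2_e
    se = np.sqrt(np.diag(cov))
    ll = -nll
    p_all = X.shape[1] + 2  # fixed coefs + two variance components
    aic = -2 * ll + 2 * p_all if not reml else math.nan

    fitted = X @ beta
    var_fixed = float(np.var(fitted, ddof=1))
    denom = var_fixed + sigma2_u + sigma2_e
    return LMMFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        loglik=float(ll),
        method=method,
        aic=float(aic),
        r2m=var_fixed / denom,
        r2c=(var_fixed + sigma2_u) / denom,
        response=response,
        fixed=fixed,
        grouping=grouping,
        boundary=boundary,
    )


def backward_aic(
    response: pd.Series,
    candidates: pd.DataFrame,
    grouping: pd.Series,
) -> tuple[LMMFit, pd.DataFrame]:
    """Backward elimination of fixed terms by the ML Akaike criterion.

    At each step the single term whose removal most decreases the AIC is
    dropped; elimination stops when no removal improves the AIC (an empty
    fixed set is a legal endpoint).  Selection uses ML fits (REML criteria
    are not comparable across fixed structures); the final model is refit by
    REML.  Returns the REML fit and the full AIC trace.
    """
    terms = list(candidates.columns)
    current = fit_lmm(response, candidates[terms], grouping, method="ML")
    trace = [{"step": 0, "action": "start", "terms": "+".join(terms), "aic": current.aic}]
    step = 0
    while terms:
        options = []
        for t in terms:
            reduced = [c for c in terms if c != t]
            fit = fit_lmm(response, candidates[reduced], grouping, method="ML")
            options.append((fit.aic, t, fit))
        options.sort(key=lambda o: (o[0], o[1]))
        best_aic, drop, best_fit = options[0]
        if best_aic >= current.aic:
            break
        step += 1
        terms.remove(drop)
        current = best_fit
        trace.append(
            {"step": step, "action": f"drop {drop}", "terms": "+".join(terms) or "1",
             "aic": best_aic}
        )
    final = fit_lmm(response, candidates[terms], grouping, method="REML")
    return final, pd.DataFrame(trace)


def bootstrap_ci(
    fit: LMMFit,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    method: str = "parametric",
) -> pd.DataFrame:
    """Bootstrap confidence intervals for the fixed coefficients.

    ``parametric`` (default) simulates responses from the fitted model
    (new group intercepts and residuals at the estimated variances) and
    refits; ``case`` resamples whole groups with replacement.  Percentile
    intervals at the requested level.  Replicates that fail to fit are
    dropped and counted; more than 20% failures aborts.
    """
    rng = np.random.default_rng(seed)
    codes, uniques = pd.factorize(fit.grouping.to_numpy())
    n_groups = len(uniques)
    Xb = fit.fitted_fixed
    draws = []
    failures = 0
    for _ in range(n_boot):
        try:
            if method == "parametric":
                u = rng.normal(0.0, math.sqrt(fit.sigma2_u), n_groups)
                eps = rng.normal(0.0, math.sqrt(fit.sigma2_e), len(Xb))
                y_star = pd.Series(Xb + u[codes] + eps, index=fit.response.index)
                refit = fit_lmm(y_star, fit.fixed, fit.grouping, method=fit.method)
            elif method == "case":
                chosen = rng.integers(0, n_groups, n_groups)
                idx = np.concatenate([np.flatnonzero(codes == g) for g in chosen])
                new_groups = np.repeat(
                    np.arange(n_groups), [np.sum(codes == g) for g in chosen]
                )
                refit = fit_lmm(
                    fit.response.iloc[idx].reset_index(drop=True),
                    fit.fixed.iloc[idx].reset_index(drop=True),
                    pd.Series(new_groups),
                    method=fit.method,
                )
            else:
                raise ValueError(f"unknown bootstrap method {method!r}")
            draws.append(refit.params.to_numpy())
        except (np.linalg.LinAlgError, ValueError):
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed; inspect the model"
        )
    arr = np.asarray(draws)
    q = (1 - level) / 2
    lo = np.quantile(arr, q, axis=0)
    hi = np.quantile(arr, 1 - q, axis=0)
    return pd.DataFrame(
        {
            "estimate": fit.params.to_numpy(),
            "ci_lower": lo,
            "ci_upper": hi,
            "n_failed": failures,
        },
        index=fit.params.index,
    )


def significance_stars(p: float) -> str:
    """Fixed-effect significance codes at the 0.1/0.05/0.01/0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def partition_r2(
    response: pd.Series,
    fixed: pd.DataFrame,
    grouping: pd.Series,
    groups: dict[str, list[str]],
    method: str = "REML",
) -> pd.DataFrame:
    """Hierarchical partitioning of the marginal R^2 over predictor groups.

    Every variable in ``fixed`` must belong to exactly one group.  For each
    group the total contribution is its Shapley value: the average, over all
    orderings of the groups, of the increase in R2m when the group enters
    the model; unique_g = R2m(all) - R2m(all minus g); shared = total -
    unique.  Totals sum to the full model's R2m by construction.  Groups
    with no selected terms contribute zero.  The report also carries the
    random-effect and residual variance fractions of the full model.
    """
    assignment: dict[str, str] = {}
    for gname, cols in groups.items():
        for c in cols:
            if c in assignment:
                raise ValueError(f"predictor {c!r} assigned to two groups")
            assignment[c] = gname
    unassigned = [c for c in fixed.columns if c not in assignment]
    if unassigned:
        raise ValueError(f"predictors without a group: {unassigned}")
    gnames = list(groups)
    if len(gnames) > 6:
        raise ValueError("hierarchical partitioning limited to <= 6 groups (2^g fits)")

    cache: dict[frozenset, float] = {}

    def r2m_of(subset: frozenset) -> float:
        if subset in cache:
            return cache[subset]
        cols = [c for c in fixed.columns if assignment[c] in subset]
        fit = fit_lmm(response, fixed[cols], grouping, method=method)
        cache[subset] = fit.r2m
        return fit.r2m

    full = frozenset(gnames)
    r2_full = r2m_of(full)
    G = len(gnames)
    fact = [math.factorial(i) for i in range(G + 1)]
    rows = []
    for g in gnames:
        others = [x for x in gnames if x != g]
        total = 0.0
        for r in range(len(others) + 1):
            w = fact[r] * fact[G - r - 1] / fact[G]
            for combo in itertools.combinations(others, r):
                s = frozenset(combo)
                total += w * (r2m_of(s | {g}) - r2m_of(s))
        unique = r2_full - r2m_of(full - {g})
        rows.append(
            {
                "group": g,
                "total": total,
                "unique": unique,
                "shared": total - unique,
                "n_terms": sum(1 for c in fixed.columns if assignment[c] == g),
            }
        )
    out = pd.DataFrame(rows)
    full_fit = fit_lmm(response, fixed, grouping, method=method)
    denom = (
        float(np.var(full_fit.fitted_fixed, ddof=1))
        + full_fit.sigma2_u
        + full_fit.sigma2_e
    )
    out.attrs["r2m_full"] = r2_full
    out.attrs["random_fraction"] = full_fit.sigma2_u / denom
    out.attrs["residual_fraction"] = full_fit.sigma2_e / denom
    return out


def residual_normality(fit: LMMFit) -> tuple[float, float]:
    """Anderson-Darling normality test of the conditional residuals."""
    resid = fit.residuals()
    if len(resid) < 8:
        raise ValueError("need at least 8 residuals")
    if np.ptp(resid) == 0:
        return math.nan, math.nan
    return anderson_darling_normal(resid)
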