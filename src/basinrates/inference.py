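"""Statistical core: standardization, VIF screening, standardized OLS,
lmg hierarchical partitioning, group commonality analysis, and spatial
diagnostics of regression residuals.

Conventions that matter numerically and are therefore fixed here:

* z-scores use the sample (n-1) standard deviation;
* VIF screening is iterative — refit, drop the single highest-VIF
  predictor, repeat while any VIF >= threshold;
* lmg shares are computed by weighted subset enumeration (2^p subset
  R^2 fits with weights |S|! (p-|S|-1)! / p!), which equals averaging
  incremental R^2 over all p! predictor orderings;
* commonality components come from Moebius inversion of the group-union
  R^2 lattice and may legitimately be negative (suppression) — they are
  reported raw with a flag, never truncated;
* confidence intervals are t-based, two-sided, alpha = 0.05, with no
  multiplicity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial import distance_matrix as _distance_matrix
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "standardize",
    "vif_table",
    "vif_screen",
    "fit_standardized_ols",
    "OLSReport",
    "lmg_partition",
    "group_commonality",
    "spatial_weights",
    "morans_i",
    "MoranResult",
    "coordinate_correlation",
]


def standardize(
    table: pd.DataFrame, log_cols: tuple[str, ...] | list[str] = ()
) -> pd.DataFrame:
    """z-score every column (sample SD), log10-transforming ``log_cols`` first.

    Missing cells and zero-variance columns are errors (reported by name).
    """
    if table.isna().any().any():
        bad = [c for c in table.columns if table[c].isna().any()]
        raise ValueError(f"missing values in columns {bad}")
    out = table.astype(float).copy()
    for col in log_cols:
        if col not in out.columns:
            raise KeyError(f"log column {col!r} not present")
        if (out[col] <= 0).any():
            raise ValueError(f"column {col!r} must be positive for log transform")
        out[col] = np.log10(out[col])
    sd = out.std(ddof=1)
    zero = list(sd.index[~(sd > 0)])
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    return (out - out.mean()) / sd


def vif_table(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_k) of each predictor."""
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    exog = sm.add_constant(X.astype(float), has_constant="add")
    vals = [
        variance_inflation_factor(exog.to_numpy(), i + 1) for i in range(X.shape[1])
    ]
    return pd.Series(vals, index=X.columns, name="VIF")


def vif_screen(
    X: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively remove the highest-VIF predictor while any VIF >= threshold.

    Returns the reduced design and a removal log (predictor, VIF at
    removal, round).  Collapsing to a single predictor is an error.
    """
    out = X.copy()
    removed = []
    rnd = 0
    while True:
        vifs = vif_table(out)
        worst = vifs.idxmax()
        if vifs[worst] < threshold:
            break
        if out.shape[1] <= 2:
            raise ValueError(
                "VIF screening would collapse the design to a single predictor"
            )
        rnd += 1
        removed.append({"predictor": worst, "VIF": float(vifs[worst]), "round": rnd})
        out = out.drop(columns=[worst])
    log = pd.DataFrame(removed, columns=["predictor", "VIF", "round"])
    return out, log


@dataclass
class OLSReport:
    """Standardized multiple-regression fit."""

    coefficients: pd.DataFrame  # coef, ci_low, ci_high, p_value, significant
    r_squared: float
    residuals: pd.Series = field(repr=False)
    nobs: int = 0
    alpha: float = 0.05


def fit_standardized_ols(
    y: pd.Series, X: pd.DataFrame, alpha: float = 0.05
) -> OLSReport:
    """OLS of y on X (plus intercept) with t-based two-sided CIs.

    Inputs are expected standardized; the intercept is retained in the fit
    but not reported.  Residuals are kept for spatial diagnostics.
    """
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    exog = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.OLS(y.astype(float), exog)
    res = model.fit()
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("singular design matrix")
    ci = res.conf_int(alpha=alpha)
    coeffs = pd.DataFrame(
        {
            "coef": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": res.pvalues,
            "significant": res.pvalues < alpha,
        }
    ).drop(index="const")
    return OLSReport(
        coefficients=coeffs,
        r_squared=float(res.rsquared),
        residuals=pd.Series(res.resid, index=y.index, name="residual"),
        nobs=n,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# R^2 subset machinery (shared by lmg and commonality)


class _SubsetR2:
    """R^2 of y on arbitrary predictor subsets, from the correlation matrix."""

    def __init__(self, y: pd.Series, X: pd.DataFrame):
        if y.isna().any() or X.isna().any().any():
            raise ValueError("missing values in y or X")
        Z = np.column_stack([X.to_numpy(dtype=float), y.to_numpy(dtype=float)])
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        C = (Z.T @ Z) / (Z.shape[0] - 1)
        self.p = X.shape[1]
        self.names = list(X.columns)
        self.Cxx = C[: self.p, : self.p]
        self.cxy = C[: self.p, -1]
        self._cache: dict[int, float] = {0: 0.0}

    def r2(self, mask: int) -> float:
        got = self._cache.get(mask)
        if got is not None:
            return got
        idx = [i for i in range(self.p) if mask >> i & 1]
        A = self.Cxx[np.ix_(idx, idx)]
        b = self.cxy[idx]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        val = float(b @ beta)
        self._cache[mask] = val
        return val


def lmg_partition(y: pd.Series, X: pd.DataFrame, max_predictors: int = 20) -> pd.DataFrame:
    """lmg decomposition of model R^2 into per-predictor shares.

    ``share_k = sum over subsets S not containing k of
    w(|S|) * (R^2(S + k) - R^2(S))`` with ``w(s) = s! (p-s-1)! / p!`` —
    the average incremental R^2 of predictor k over all orderings.  Shares
    are non-negative and sum to the full-model R^2 (asserted to 1e-8).
    Also reported as percent of explained variance.
    """
    p = X.shape[1]
    if p > max_predictors:
        raise ValueError(
            f"p={p} exceeds the {max_predictors}-predictor cap for 2^p subset "
            "enumeration; group predictors or raise max_predictors"
        )
    sub = _SubsetR2(y, X)
    fact = [math.factorial(i) for i in range(p + 1)]
    w = [fact[s] * fact[p - s - 1] / fact[p] for s in range(p)]
    shares = np.zeros(p)
    for mask in range(1 << p):
        s = bin(mask).count("1")
        if s == p:
            continue
        base = sub.r2(mask)
        for k in range(p):
            if not mask >> k & 1:
                shares[k] += w[s] * (sub.r2(mask | 1 << k) - base)
    full = sub.r2((1 << p) - 1)
    if abs(shares.sum() - full) > 1e-8:
        raise AssertionError(
            f"lmg shares sum {shares.sum():.12f} != R^2 {full:.12f}"
        )
    out = pd.DataFrame(
        {
            "share": shares,
            "pct_of_r2": 100.0 * shares / full if full > 0 else np.nan,
        },
        index=pd.Index(X.columns, name="predictor"),
    )
    out.attrs["r_squared"] = full
    return out


def group_commonality(
    y: pd.Series, X: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Unique and shared R^2 components across predictor groups.

    Every predictor must carry a group label; with groups G1..Gg the R^2 of
    each of the 2^g - 1 nonempty group unions is fitted and the commonality
    component of each group subset S recovered by Moebius inversion of
    ``F(T) = R^2(all) - R^2(all minus T)``:
    ``C(S) = sum over T subset of S of (-1)^(|S|-|T|) F(T)``.
    Components sum to the full-model R^2; negative shared components
    (suppression) are flagged, not truncated.
    """
    unlabeled = [c for c in X.columns if c not in groups]
    if unlabeled:
        raise ValueError(f"predictors without a group label: {unlabeled}")
    names = sorted({groups[c] for c in X.columns})
    g = len(names)
    if g < 2:
        raise ValueError("need at least 2 groups present in the design")
    members = {nm: [c for c in X.columns if groups[c] == nm] for nm in names}
    sub = _SubsetR2(y, X)
    col_bit = {c: i for i, c in enumerate(X.columns)}

    def mask_of(group_set: tuple[str, ...]) -> int:
        m = 0
        for nm in group_set:
            for c in members[nm]:
                m |= 1 << col_bit[c]
        return m

    full_mask = (1 << X.shape[1]) - 1
    r2_full = sub.r2(full_mask)

    def F(T: tuple[str, ...]) -> float:
        if not T:
            return 0.0
        rest = tuple(nm for nm in names if nm not in T)
        return r2_full - sub.r2(mask_of(rest))

    rows = []
    total = 0.0
    for size in range(1, g + 1):
        for S in itertools.combinations(names, size):
            comp = 0.0
            for t in range(len(S) + 1):
                for T in itertools.combinations(S, t):
                    comp += (-1) ** (len(S) - t) * F(T)
            total += comp
            rows.append(
                {
                    "groups": " & ".join(S),
                    "n_groups": size,
                    "component": comp,
                    "unique": size == 1,
                    "negative": comp < 0,
                }
            )
    if abs(total - r2_full) > 1e-8:
        raise AssertionError(
            f"commonality components sum {total:.12f} != R^2 {r2_full:.12f}"
        )
    out = pd.DataFrame(rows).set_index("groups")
    out.attrs["r_squared"] = r2_full
    return out


# ---------------------------------------------------------------------------
# Spatial diagnostics


def spatial_weights(
    centroids: np.ndarray | pd.DataFrame,
    method: str = "knn",
    k: int = 8,
    band: float | None = None,
    row_standardize: bool = True,
) -> np.ndarray:
    """Binary spatial weights from basin centroids.

    ``knn``: each row links to its k nearest neighbours (directed graph,
    exactly k nonzeros per row; distance ties broken by smaller index).
    ``distance_band``: symmetric links within distance ``band``; an
    isolated basin is an error.  The diagonal is zero; rows are
    standardized to sum 1 when ``row_standardize``.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 basins with coordinate pairs")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    n = pts.shape[0]
    D = _distance_matrix(pts, pts)
    W = np.zeros((n, n))
    if method == "knn":
        if k < 1 or k >= n:
            raise ValueError(f"k must satisfy 1 <= k < n (k={k}, n={n})")
        for i in range(n):
            order = np.argsort(D[i], kind="stable")  # self first; ties by index
            W[i, order[1 : k + 1]] = 1.0
    elif method == "distance_band":
        if band is None or band <= 0:
            raise ValueError("distance_band needs a positive band")
        W = ((D <= band) & (D > 0)).astype(float)
        if (W.sum(axis=1) == 0).any():
            iso = np.flatnonzero(W.sum(axis=1) == 0).tolist()
            raise ValueError(f"distance band isolates basins {iso}")
    else:
        raise ValueError(f"unknown method {method!r}")
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return W


@dataclass
class MoranResult:
    I: float
    expected: float
    p_value: float
    n_perm: int


def morans_i(
    residuals: np.ndarray | pd.Series,
    weights: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with a two-sided permutation p-value.

    ``I = (n / W) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with z the centred
    residuals and W the total weight; the analytical null expectation is
    ``-1 / (n - 1)``.  The p-value is the two-sided permutation tail around
    that expectation.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.shape[0]
    if weights.shape != (n, n):
        raise ValueError("weights shape does not match residuals")
    z = x - x.mean()
    denom = float(z @ z)
    if denom <= 0:
        raise ValueError("residuals have zero variance")
    Wtot = float(weights.sum())

    def stat(v: np.ndarray) -> float:
        return float(n / Wtot * (v @ weights @ v) / (v @ v))

    I = stat(z)
    e0 = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        Ip = stat(rng.permutation(z))
        if abs(Ip - e0) >= abs(I - e0):
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MoranResult(I=I, expected=e0, p_value=p, n_perm=n_perm)


def coordinate_correlation(
    values: pd.Series, centroids: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (+ two-sided t-test p) of basin values against x and y."""
    v = values.to_numpy(dtype=float)
    if v.shape[0] < 3:
        raise ValueError("need at least 3 basins")
    if v.std() == 0:
        raise ValueError("values have zero variance")
    rows = {}
    for axis in ("x", "y"):
        c = centroids[axis].to_numpy(dtype=float)
        if c.std() == 0:
            raise ValueError(f"coordinate {axis!r} has zero variance")
        r, p = stats.pearsonr(v, c)
        rows[axis] = {"r": float(r), "p_value": float(p)}
    return pd.DataFrame(rows).T.rename_axis("axis")
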