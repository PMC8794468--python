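"""Relative abundance, missing-value imputation and normalization.

The fixed preprocessing order is: per-mille scaling -> zeros interpreted as
missing -> single-component NIPALS imputation -> cyclic-loess (and/or
quantile) normalization on the log2 scale.  Statistics downstream run on the
final log2 values.  Each step appends to the table's provenance log and
imputation never alters observed entries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dims import FeatureTable, QCReport

__all__ = [
    "to_permille",
    "zeros_to_missing",
    "drop_all_missing_features",
    "NIPALSImputer",
    "floor_nonpositive",
    "nipals_impute",
    "CyclicLoessNormalizer",
    "cyclic_loess_normalize",
]


def to_permille(table: FeatureTable) -> FeatureTable:
    """Scale each sample so its feature values sum to 1000 (per mille)."""
    sums = table.values.sum(axis=1, skipna=True)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total intensity: {list(zero.index)}")
    values = table.values.div(sums, axis=0) * 1000.0
    out = FeatureTable(values, table.features.copy(), table.meta.copy(),
                       None if table.snr is None else table.snr.copy(),
                       list(table.provenance))
    out.log("to_permille")
    return out


def zeros_to_missing(table: FeatureTable) -> FeatureTable:
    """Interpret exact zeros as not-measured (NaN)."""
    values = table.values.mask(table.values == 0)
    n_zero = int((table.values == 0).sum().sum())
    all_missing = [c for c in values.columns if values[c].isna().all()]
    out = FeatureTable(values, table.features.copy(), table.meta.copy(),
                       None if table.snr is None else table.snr.copy(),
                       list(table.provenance))
    out.log("zeros_to_missing", n_zeros=n_zero, all_missing_features=all_missing)
    return out


def drop_all_missing_features(table: FeatureTable) -> tuple[FeatureTable, QCReport]:
    """Drop features flagged all-missing (imputation requires observed data)."""
    all_missing = [c for c in table.values.columns if table.values[c].isna().all()]
    out = table.select_features([c for c in table.values.columns if c not in all_missing])
    out.log("drop_all_missing_features", n_dropped=len(all_missing))
    report = QCReport("drop_all_missing_features",
                      summary={"n_dropped": len(all_missing), "dropped": all_missing})
    return out, report


class NIPALSImputer(BaseEstimator, TransformerMixin):
    """Impute missing entries with a single-component NIPALS projection.

    The model is ``x_ij ~ mu_j + t_i p_j``: column means plus one score/
    loading component, fitted using only observed entries (missing entries
    are skipped in every inner product, the NIPALS trick).  Because column
    means estimated from observed entries alone are biased whenever the
    missing pattern is uneven, the mean-center/fit/impute cycle is iterated
    to a fixed point: completed-matrix column means are recomputed from the
    current imputations and the component refitted until the imputed values
    stop changing.  At the fixed point a rank-one data matrix is recovered
    exactly.  Observed entries are never altered and imputed abundances are
    floored at zero.

    Parameters
    ----------
    max_iter : int
        Cap on inner NIPALS iterations per fit (t-convergence).
    tol : float
        Relative change in the score vector declaring inner convergence.
    max_refine : int
        Cap on outer mean-refinement cycles.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-8, max_refine: int = 2000):
        self.max_iter = max_iter
        self.tol = tol
        self.max_refine = max_refine

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def _nipals_component(self, Xc: np.ndarray, obs: np.ndarray):
        """One NIPALS component on a centered matrix with missing entries."""
        Xz = np.where(obs, Xc, 0.0)
        col_var = np.where(obs, Xc, np.nan)
        col_var = np.nanvar(col_var, axis=0)
        t = Xz[:, int(np.nanargmax(col_var))].astype(float)
        if not np.any(t):
            t = Xz[:, 0].copy()
        for iteration in range(self.max_iter):
            tt = (t[:, None] ** 2 * obs).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = (Xz * t[:, None]).sum(axis=0) / tt
            p = np.nan_to_num(p)
            norm = np.linalg.norm(p)
            if norm == 0:
                return t * 0.0, p, iteration + 1
            p /= norm
            pp = (p[None, :] ** 2 * obs).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_new = (Xz * p[None, :]).sum(axis=1) / pp
            t_new = np.nan_to_num(t_new)
            delta = np.linalg.norm(t_new - t)
            scale = np.linalg.norm(t_new)
            t = t_new
            if scale == 0 or delta / scale < self.tol:
                return t, p, iteration + 1
        raise RuntimeError(
            f"NIPALS did not converge in {self.max_iter} iterations "
            f"(last relative change {delta / max(scale, 1e-300):.3e})"
        )

    def fit_transform(self, X, y=None):
        frame = isinstance(X, pd.DataFrame)
        arr = X.to_numpy(float) if frame else np.asarray(X, float)
        obs = ~np.isnan(arr)
        if not obs.any(axis=0).all():
            missing_cols = np.where(~obs.any(axis=0))[0]
            raise ValueError(f"feature column(s) entirely missing: {missing_cols.tolist()}")
        if not obs.any(axis=1).all():
            missing_rows = np.where(~obs.any(axis=1))[0]
            raise ValueError(f"sample row(s) entirely missing: {missing_rows.tolist()}")
        mask = ~obs
        self.n_missing_ = int(mask.sum())
        if self.n_missing_ == 0:
            self.n_refine_ = 0
            self.n_iterations_ = 0
            result = arr.copy()
        else:
            mu = np.nanmean(arr, axis=0)
            filled = np.where(mask, mu[None, :], arr)
            scale = np.nanstd(arr) or 1.0
            inner_total = 0
            for refine in range(self.max_refine):
                mu = filled.mean(axis=0)
                t, p, n_iter = self._nipals_component(filled - mu[None, :], obs)
                inner_total += n_iter
                imputed = mu[None, :] + np.outer(t, p)
                delta = np.abs(imputed[mask] - filled[mask]).max()
                filled[mask] = imputed[mask]
                if delta < self.tol * scale:
                    break
            else:
                raise RuntimeError(
                    f"imputation means did not stabilise in {self.max_refine} cycles "
                    f"(last change {delta:.3e}, n_missing={self.n_missing_})"
                )
            self.n_refine_ = refine + 1
            self.n_iterations_ = inner_total
            self.scores_ = t
            self.loadings_ = p
            result = arr.copy()
            result[mask] = np.maximum(filled[mask], 0.0)  # abundances are non-negative
        if frame:
            return pd.DataFrame(result, index=X.index, columns=X.columns)
        return result

    def transform(self, X):
        # stateless by design: imputation is a per-matrix operation
        return self.fit_transform(X)


def nipals_impute(table: FeatureTable, max_iter: int = 500, tol: float = 1e-8) -> FeatureTable:
    """Impute the table's missing values (see :class:`NIPALSImputer`)."""
    imputer = NIPALSImputer(max_iter=max_iter, tol=tol)
    values = imputer.fit_transform(table.values)
    out = FeatureTable(values, table.features.copy(), table.meta.copy(),
                       None if table.snr is None else table.snr.copy(),
                       list(table.provenance))
    out.log("nipals_impute", n_imputed=imputer.n_missing_,
            n_refine=imputer.n_refine_, n_iterations=imputer.n_iterations_)
    return out


def floor_nonpositive(table: FeatureTable) -> FeatureTable:
    """Raise non-positive (zero-floored imputed) entries to a detection floor.

    Log-scale normalization needs strictly positive values, but imputation
    clips at zero because abundances cannot be negative.  Entries <= 0 are
    replaced by half the smallest positive value of their feature column,
    the conventional detection-limit floor.  A no-op on all-positive tables.
    """
    values = table.values.copy()
    arr = values.to_numpy(float)
    nonpos = arr <= 0
    n = int(nonpos.sum())
    if n:
        pos = np.where(arr > 0, arr, np.nan)
        floors = np.nanmin(pos, axis=0) / 2.0
        if np.isnan(floors).any():
            bad = values.columns[np.isnan(floors)]
            raise ValueError(f"feature(s) with no positive values: {list(bad)}")
        arr[nonpos] = np.broadcast_to(floors, arr.shape)[nonpos]
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    out = FeatureTable(values, table.features.copy(), table.meta.copy(),
                       None if table.snr is None else table.snr.copy(),
                       list(table.provenance))
    out.log("floor_nonpositive", n_floored=n)
    return out


def _quantile_normalize(L: np.ndarray) -> np.ndarray:
    """Map each sample (row) onto the mean order-statistic distribution."""
    order = np.argsort(L, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(L.shape[0])[:, None]
    ranks[rows, order] = np.arange(L.shape[1])[None, :]
    sorted_vals = np.take_along_axis(L, order, axis=1)
    reference = sorted_vals.mean(axis=0)
    return reference[ranks]


class CyclicLoessNormalizer(BaseEstimator, TransformerMixin):
    """Remove intensity-dependent between-sample bias on the log2 scale.

    For every unordered sample pair the log-ratio M is regressed on the
    log-average A with a locally weighted (tri-cube) fit at the given span
    and two robustness iterations; half the fitted trend is subtracted from
    one sample and added to the other.  The sweep over all pairs is repeated
    ``iterations`` times.  ``method`` may instead select plain quantile
    normalization (each sample mapped onto the mean order-statistic
    distribution) or chain loess then quantile.  This is a whole-batch
    normalizer: ``fit`` is a no-op and ``transform`` normalizes the matrix
    it is given, returning log2-scale values.
    """

    def __init__(self, iterations: int = 3, span: float = 0.7,
                 method: str = "cyclicloess"):
        self.iterations = iterations
        self.span = span
        self.method = method

    def fit(self, X, y=None):
        return self

    def _cyclic_loess(self, L: np.ndarray) -> np.ndarray:
        n = L.shape[0]
        for _ in range(self.iterations):
            for i in range(n):
                for j in range(i + 1, n):
                    M = L[i] - L[j]
                    if not np.any(M):
                        continue
                    A = 0.5 * (L[i] + L[j])
                    fitted = lowess(M, A, frac=self.span, it=2,
                                    return_sorted=False)
                    L[i] -= fitted / 2.0
                    L[j] += fitted / 2.0
        return L

    def transform(self, X):
        if self.method not in {"cyclicloess", "quantile", "cyclicloess_then_quantile"}:
            raise ValueError(f"unknown normalization method {self.method!r}")
        frame = isinstance(X, pd.DataFrame)
        arr = X.to_numpy(float) if frame else np.asarray(X, float)
        if np.isnan(arr).any():
            raise ValueError("normalization requires a complete matrix (impute first)")
        if (arr <= 0).any():
            raise ValueError("non-positive value at the log step")
        L = np.log2(arr)
        if self.method in {"cyclicloess", "cyclicloess_then_quantile"}:
            L = self._cyclic_loess(L)
        if self.method in {"quantile", "cyclicloess_then_quantile"}:
            L = _quantile_normalize(L)
        if frame:
            return pd.DataFrame(L, index=X.index, columns=X.columns)
        return L


def cyclic_loess_normalize(
    table: FeatureTable, iterations: int = 3, span: float = 0.7,
    method: str = "cyclicloess",
) -> FeatureTable:
    """Normalize the table (result is on the log2 scale)."""
    normalizer = CyclicLoessNormalizer(iterations=iterations, span=span, method=method)
    values = normalizer.transform(table.values)
    out = FeatureTable(values, table.features.copy(), table.meta.copy(),
                       None if table.snr is None else table.snr.copy(),
                       list(table.provenance))
    out.log("normalize", method=method, iterations=iterations, span=span, scale="log2")
    return out
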