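"""Lipid-class aggregation and the statistical calls of the analysis.

The regulation call for an individual lipid species is the conjunction of a
univariate test and a multivariate importance score:

* a Shapiro-Wilk gate routes each feature to a two-sided Student t-test
  (both groups normal at alpha 0.05) or a Mann-Whitney U test otherwise;
* PLS-DA (NIPALS PLS1 on autoscaled data, group coded -1/+1) supplies a
  Variable Importance in Projection (VIP) score per feature, with the
  identity sum(VIP^2) = number of features;
* a species is "regulated" iff p < 0.05 and VIP > 1, with the fold change
  reported as mean(OB)/mean(CTL) on the pre-log per-mille scale.

Class-level analyses use summed per-class abundances, factorial (diet x sex)
Type-II ANOVA, Pearson maternal-fetal correlations and column-centered PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .dims import FeatureTable

__all__ = [
    "PHOSPHOLIPID_CLASSES",
    "sum_lipid_classes",
    "saturation_totals",
    "normality_gated_test",
    "PLSDiscriminantAnalysis",
    "plsda_vip",
    "call_regulated",
    "regulation_analysis",
    "factorial_anova",
    "cross_compartment_correlation",
    "pca_scores",
]

#: Classes summed into the phospholipid (PL) denominator of the TG/PL ratio.
PHOSPHOLIPID_CLASSES = ("PC", "PE", "PG", "PS", "PA", "PI")

#: Glyceride classes pooled into the TG total (mono-, di- and triglycerides).
GLYCERIDE_CLASSES = ("MG", "DG", "TG")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def sum_lipid_classes(table: FeatureTable) -> pd.DataFrame:
    """Per-sample summed abundance per lipid class, plus the TG/PL ratio.

    Each feature contributes once, under the top-ranked annotation of its
    isobar group; MG/DG/TG are pooled as "TG"; features without annotation
    are reported under "unassigned".  Class columns with no member features
    are 0.
    """
    feats = table.features
    classes = []
    for fid in table.values.columns:
        row = feats.loc[fid]
        top = row.get("top_annotation")
        code = None
        if isinstance(top, str):
            code = top.split(" ", 1)[0]
        elif row.get("annotated") and isinstance(row.get("class_code"), str):
            code = row["class_code"]
        if code is None:
            classes.append("unassigned")
        elif code in GLYCERIDE_CLASSES:
            classes.append("TG")
        else:
            classes.append(code)
    groups = pd.Series(classes, index=table.values.columns)
    sums = table.values.T.groupby(groups).sum(min_count=1).T.fillna(0.0)
    pl_cols = [c for c in PHOSPHOLIPID_CLASSES if c in sums.columns]
    pl = sums[pl_cols].sum(axis=1) if pl_cols else pd.Series(0.0, index=sums.index)
    tg = sums["TG"] if "TG" in sums.columns else pd.Series(0.0, index=sums.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        sums["TG_PL_ratio"] = np.where(pl > 0, tg / pl, np.nan)
    return sums


def saturation_totals(table: FeatureTable) -> pd.DataFrame:
    """SFA / MUFA / PUFA sums per sample for fatty-acid annotated features.

    SFA = sum over double bonds 0, MUFA = 1, PUFA >= 2.  Unannotated signals
    are excluded and reported in the ``n_unannotated`` attribute column.
    """
    feats = table.features
    is_fa = (feats.get("class_code") == "FA") & feats["annotated"].astype(bool)
    db = feats.loc[is_fa, "double_bonds"].astype(float)
    buckets = pd.Series(
        np.select([db == 0, db == 1], ["SFA", "MUFA"], default="PUFA"),
        index=db.index,
    )
    out = pd.DataFrame(0.0, index=table.values.index, columns=["SFA", "MUFA", "PUFA"])
    fa_vals = table.values[buckets.index]
    grouped = fa_vals.T.groupby(buckets).sum(min_count=1).T
    for col in grouped.columns:
        out[col] = grouped[col].fillna(0.0)
    out.attrs["n_unannotated"] = int((~is_fa).sum())
    return out


# ---------------------------------------------------------------------------
# Univariate testing
# ---------------------------------------------------------------------------

def normality_gated_test(
    x, y, alpha_norm: float = 0.05
) -> tuple[str, float]:
    """Shapiro-Wilk-gated two-group test.

    Both groups normal at ``alpha_norm`` -> two-sided pooled-variance
    Student t-test; otherwise a two-sided Mann-Whitney U (exact when both
    groups have n <= 8 and there are no ties, normal approximation with tie
    correction otherwise).  Zero-variance groups cannot be assessed by
    Shapiro-Wilk and take the Mann-Whitney route; two identical constant
    groups return p = 1 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
    if degenerate:
        normal = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = (sps.shapiro(x).pvalue >= alpha_norm
                      and sps.shapiro(y).pvalue >= alpha_norm)
    if normal:
        return "t", float(sps.ttest_ind(x, y, equal_var=True).pvalue)
    if np.ptp(np.concatenate([x, y])) == 0:
        return "mann_whitney", 1.0
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    return "mann_whitney", float(p)


# ---------------------------------------------------------------------------
# PLS-DA and VIP
# ---------------------------------------------------------------------------

class PLSDiscriminantAnalysis(BaseEstimator, ClassifierMixin):
    """Two-class PLS-DA via NIPALS PLS1 with VIP scores.

    Features are autoscaled internally (mean 0, unit variance); the class
    label is coded -1/+1.  Components are extracted by the deterministic
    PLS1 sequence (w = X'y normalised, t = Xw, deflation of X and y) and
    capped at the effective rank.  VIP_j = sqrt(p * sum_a[SSY_a w_aj^2] /
    sum_a SSY_a) with SSY_a = c_a^2 t_a't_a, so sum_j VIP_j^2 = p.

    Attributes (after ``fit``): ``vip_``, ``x_weights_``, ``x_scores_``,
    ``x_loadings_``, ``y_loadings_``, ``coef_``, ``classes_``,
    ``n_components_``.
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("PLS-DA here is two-class")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 2:
            raise ValueError("each class needs >= 2 samples")
        yv = np.where(y == self.classes_[1], 1.0, -1.0)
        yv = yv - yv.mean()

        self._mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self._zero_var = sd == 0
        if self._zero_var.any():
            warnings.warn(
                f"{int(self._zero_var.sum())} zero-variance feature(s); "
                "their VIP is reported as 0", stacklevel=2,
            )
        self._sd = np.where(self._zero_var, 1.0, sd)
        Xa = (X - self._mean) / self._sd if self.scale else X - self._mean
        Xa[:, self._zero_var] = 0.0

        n, p = Xa.shape
        cap = min(self.n_components, n - 1, p)
        W, T, P, C = [], [], [], []
        Xr, yr = Xa.copy(), yv.copy()
        eps = np.finfo(float).eps
        x_scale = max(np.linalg.norm(Xa), eps)
        for _ in range(cap):
            w = Xr.T @ yr
            wn = np.linalg.norm(w)
            if wn < 1e-12 * x_scale or np.linalg.norm(Xr) < 1e-10 * x_scale:
                break  # rank exhausted
            w /= wn
            t = Xr @ w
            tt = t @ t
            if tt < eps:
                break
            pvec = Xr.T @ t / tt
            c = yr @ t / tt
            Xr = Xr - np.outer(t, pvec)
            yr = yr - c * t
            W.append(w); T.append(t); P.append(pvec); C.append(c)
        if not W:
            raise ValueError("no PLS component could be extracted (X has no signal)")
        self.n_components_ = len(W)
        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(T)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.asarray(C)

        ssy = self.y_loadings_ ** 2 * (self.x_scores_ ** 2).sum(axis=0)
        w2 = self.x_weights_ ** 2  # columns already unit norm
        vip = np.sqrt(p * (w2 @ ssy) / ssy.sum())
        vip[self._zero_var] = 0.0
        self.vip_ = vip

        # regression coefficients in the autoscaled space: B = W (P'W)^-1 c
        PtW = self.x_loadings_.T @ self.x_weights_
        self.coef_ = self.x_weights_ @ np.linalg.solve(PtW, self.y_loadings_)
        self._intercept = 0.0
        return self

    def decision_function(self, X):
        X = np.asarray(X, float)
        Xa = (X - self._mean) / self._sd if self.scale else X - self._mean
        Xa[:, self._zero_var] = 0.0
        return Xa @ self.coef_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])

    def transform(self, X):
        X = np.asarray(X, float)
        Xa = (X - self._mean) / self._sd if self.scale else X - self._mean
        Xa[:, self._zero_var] = 0.0
        # scores via the weight matrix in the original (non-deflated) space
        PtW = self.x_loadings_.T @ self.x_weights_
        R = self.x_weights_ @ np.linalg.inv(PtW)
        return Xa @ R


def plsda_vip(X, y, n_components: int = 2) -> np.ndarray:
    """VIP score per feature from a fitted two-class PLS-DA."""
    return PLSDiscriminantAnalysis(n_components=n_components).fit(X, y).vip_


# ---------------------------------------------------------------------------
# Regulation calls
# ---------------------------------------------------------------------------

def call_regulated(
    records: pd.DataFrame, alpha: float = 0.05, vip_min: float = 1.0
) -> pd.DataFrame:
    """Apply the conjunction rule: regulated iff p < alpha and VIP > vip_min.

    ``records`` needs ``p_value`` and ``vip`` columns; a BH-FDR column is
    added for transparency (the call itself uses the raw p-value).
    """
    out = records.copy()
    out["regulated"] = (out["p_value"] < alpha) & (out["vip"] > vip_min)
    ok = out["p_value"].notna()
    out["p_bh_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh_fdr"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    return out


def regulation_analysis(
    stats_table: FeatureTable,
    fold_change_table: FeatureTable,
    group_col: str = "diet",
    control: str = "CTL",
    case: str = "OB",
    alpha: float = 0.05,
    vip_min: float = 1.0,
    alpha_norm: float = 0.05,
    n_components: int = 2,
) -> pd.DataFrame:
    """Per-feature regulation records for case vs control.

    ``stats_table`` carries the final (normalized, log2) values the tests
    and the PLS-DA run on; ``fold_change_table`` carries the pre-log
    per-mille values from which mean(case)/mean(control) fold changes are
    computed, matching the figure convention.
    """
    groups = stats_table.meta[group_col]
    a_ids = list(stats_table.values.index[groups == case])
    b_ids = list(stats_table.values.index[groups == control])
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError(f"need >= 3 samples per group, got {len(a_ids)} vs {len(b_ids)}")

    rows = []
    for fid in stats_table.values.columns:
        x = stats_table.values.loc[a_ids, fid].to_numpy(float)
        y = stats_table.values.loc[b_ids, fid].to_numpy(float)
        test_used, p = normality_gated_test(x, y, alpha_norm=alpha_norm)
        rows.append({"feature_id": fid, "test_used": test_used, "p_value": p})
    records = pd.DataFrame(rows).set_index("feature_id")

    X = stats_table.values.loc[a_ids + b_ids].to_numpy(float)
    y = np.array([case] * len(a_ids) + [control] * len(b_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records["vip"] = plsda_vip(X, y, n_components=n_components)

    fc = fold_change_table.values
    case_mean = fc.loc[[i for i in a_ids if i in fc.index]].mean(axis=0)
    ctl_mean = fc.loc[[i for i in b_ids if i in fc.index]].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        records["fold_change"] = (case_mean / ctl_mean).reindex(records.index)

    records = call_regulated(records, alpha=alpha, vip_min=vip_min)
    records.insert(0, "top_annotation", stats_table.features["top_annotation"])
    records.insert(1, "class_code", stats_table.features["class_code"])
    return records


# ---------------------------------------------------------------------------
# Factorial ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaRecord:
    feature_id: str
    f_diet: float
    p_diet: float
    f_sex: float
    p_sex: float
    f_interaction: float
    p_interaction: float
    df_resid: float


def factorial_anova(values, diet, sex, feature_id: str = "") -> AnovaRecord:
    """Two-way (diet x sex) ANOVA with interaction, Type-II sums of squares."""
    df = pd.DataFrame({
        "value": np.asarray(values, float),
        "diet": np.asarray(diet, dtype=object),
        "sex": np.asarray(sex, dtype=object),
    })
    cells = df.groupby(["diet", "sex"], observed=True).size()
    if (cells >= 2).sum() < 3:
        raise ValueError("factorial ANOVA needs >= 2 observations in >= 3 of 4 cells")
    model = ols("value ~ C(diet) * C(sex)", data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    if model.ssr <= np.finfo(float).eps * max(1.0, abs(df["value"]).max()) ** 2:
        raise ValueError("zero residual variance: all observations identical within cells")
    table = anova_lm(model, typ=2)
    get = lambda term, col: float(table.loc[term, col])
    return AnovaRecord(
        feature_id,
        get("C(diet)", "F"), get("C(diet)", "PR(>F)"),
        get("C(sex)", "F"), get("C(sex)", "PR(>F)"),
        get("C(diet):C(sex)", "F"), get("C(diet):C(sex)", "PR(>F)"),
        float(model.df_resid),
    )


# ---------------------------------------------------------------------------
# Cross-compartment correlation
# ---------------------------------------------------------------------------

def cross_compartment_correlation(
    maternal: pd.DataFrame, fetal: pd.DataFrame, dam_col: str = "dam_id"
) -> pd.DataFrame:
    """Per-species Pearson correlation and OLS regression between maternal
    values (indexed by dam) and fetal values (averaged per dam first, to
    avoid pseudo-replication of littermates)."""
    fetal_by_dam = fetal.groupby(dam_col).mean(numeric_only=True)
    common = maternal.index.intersection(fetal_by_dam.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched dam-fetus pairs")
    species = [c for c in maternal.columns if c in fetal_by_dam.columns]
    rows = []
    for sp in species:
        x = maternal.loc[common, sp].to_numpy(float)
        y = fetal_by_dam.loc[common, sp].to_numpy(float)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"species": sp, "n": len(x), "pearson_r": np.nan,
                         "pearson_p": np.nan, "slope": np.nan,
                         "intercept": np.nan, "regression_p": np.nan})
            continue
        r, rp = sps.pearsonr(x, y)
        reg = sps.linregress(x, y)
        rows.append({"species": sp, "n": len(x), "pearson_r": r, "pearson_p": rp,
                     "slope": reg.slope, "intercept": reg.intercept,
                     "regression_p": reg.pvalue})
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(X, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered SVD scores and explained-variance fractions.

    Sign convention: within each component the largest-|loading| entry is
    made positive.  Returns (scores for the first ``n_components``,
    explained-variance fractions for all components).
    """
    frame = isinstance(X, pd.DataFrame)
    arr = X.to_numpy(float) if frame else np.asarray(X, float)
    if arr.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    if np.isnan(arr).any():
        raise ValueError("PCA requires a complete matrix")
    Xc = arr - arr.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(len(s)):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    index = X.index if frame else pd.RangeIndex(arr.shape[0])
    return pd.DataFrame(scores, index=index, columns=cols), explained
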