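"""Peak-to-library matching and QC filtering for direct-infusion runs.

The stages here turn a centroided peak list into a samples x features table:

1. :func:`match_features` — assign each observed peak to the theoretical ion
   with the smallest |ppm| deviation (9 ppm default for intact lipids,
   12.5 ppm for the in-source CID fatty-acid mode, where unmatched signals
   above noise are carried forward as unannotated features).
2. :func:`apply_signal_filters` — drop features with median S/N < 3 or
   detected in fewer than 20% of samples.
3. :func:`dilution_linearity_filter` — keep features whose intensity is
   linearly proportional to the QC-pool dilution factor (Pearson r > 0.75).
4. :func:`exclude_low_detection_samples` — remove samples detecting fewer
   than 66.7% of the retained features (plus advisory PCA outlier flags).

Every filter returns a :class:`QCReport` in which each discarded feature or
sample names the first rule it failed, so nothing is dropped silently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .library import IonLibrary

__all__ = [
    "PeakMatrix",
    "FeatureTable",
    "QCReport",
    "match_features",
    "apply_signal_filters",
    "dilution_linearity_filter",
    "exclude_low_detection_samples",
    "drop_qc_pools",
    "load_peaks_csv",
    "load_sample_meta_csv",
]

META_COLUMNS = ["compartment", "diet", "sex", "dilution", "tissue_mg"]


@dataclass
class PeakMatrix:
    """Long-format centroided peaks: one row per (sample, m/z) signal."""

    peaks: pd.DataFrame  # columns: sample_id, mz, intensity, snr
    polarity: str
    mode: str  # "intact" or "cid_fa"

    def __post_init__(self):
        required = {"sample_id", "mz", "intensity", "snr"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        if self.mode not in {"intact", "cid_fa"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.peaks["intensity"] < 0).any() or (self.peaks["snr"] < 0).any():
            raise ValueError("intensities and snr must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.peaks["sample_id"]))


@dataclass
class FeatureTable:
    """Samples x features matrix with feature annotations and sample metadata.

    ``values`` holds intensities (0 = not detected before missing handling,
    NaN = missing afterwards); ``features`` is indexed by feature id with the
    annotation columns; ``meta`` is indexed by sample id; ``snr`` mirrors
    ``values`` where signal-to-noise is known.  ``provenance`` accumulates a
    machine-readable log of every transformation applied.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    meta: pd.DataFrame
    snr: pd.DataFrame | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if list(self.values.columns) != list(self.features.index):
            raise ValueError("values columns and feature index disagree")
        if list(self.values.index) != list(self.meta.index):
            raise ValueError("values index and sample metadata index disagree")
        if self.snr is not None and self.snr.shape != self.values.shape:
            raise ValueError("snr matrix shape differs from values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def log(self, step: str, **info) -> None:
        self.provenance.append({"step": step, **info})

    def select_features(self, keep: Sequence[str]) -> "FeatureTable":
        keep = list(keep)
        return FeatureTable(
            self.values[keep].copy(),
            self.features.loc[keep].copy(),
            self.meta.copy(),
            None if self.snr is None else self.snr[keep].copy(),
            list(self.provenance),
        )

    def select_samples(self, keep: Sequence[str]) -> "FeatureTable":
        keep = list(keep)
        return FeatureTable(
            self.values.loc[keep].copy(),
            self.features.copy(),
            self.meta.loc[keep].copy(),
            None if self.snr is None else self.snr.loc[keep].copy(),
            list(self.provenance),
        )

    def qc_pool_ids(self) -> list[str]:
        if "dilution" not in self.meta.columns:
            return []
        return list(self.meta.index[self.meta["dilution"].notna()])

    def experimental_ids(self) -> list[str]:
        pools = set(self.qc_pool_ids())
        return [s for s in self.values.index if s not in pools]


@dataclass
class QCReport:
    """Per-feature and per-sample QC outcomes for one filtering stage."""

    stage: str
    features: pd.DataFrame | None = None  # index: feature id; 'passed', 'failed_rule', metrics
    samples: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"stage": self.stage, "summary": self.summary}
        if self.features is not None:
            out["features"] = self.features.reset_index().to_dict(orient="records")
        if self.samples is not None:
            out["samples"] = self.samples.reset_index().to_dict(orient="records")
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)

    def to_text(self) -> str:
        lines = [f"[{self.stage}]"]
        for key, val in self.summary.items():
            lines.append(f"  {key}: {val}")
        for frame, what in ((self.features, "feature"), (self.samples, "sample")):
            if frame is None or "failed_rule" not in frame.columns:
                continue
            failed = frame[frame["failed_rule"].notna()]
            for idx, row in failed.iterrows():
                lines.append(f"  discarded {what} {idx}: {row['failed_rule']}")
        return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if obj is pd.NA or (isinstance(obj, float) and np.isnan(obj)):
        return None
    return str(obj)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_peaks_csv(path, polarity: str, mode: str) -> PeakMatrix:
    """Read a long (sample_id, mz, intensity[, snr]) or wide (mz x samples)
    peak CSV.  Wide tables get snr = +inf (unknown, never filtered on)."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"sample_id", "mz", "intensity"} <= cols:
        if "snr" not in cols:
            df["snr"] = np.inf
        return PeakMatrix(df[["sample_id", "mz", "intensity", "snr"]], polarity, mode)
    if "mz" in cols:
        long = df.melt(id_vars="mz", var_name="sample_id", value_name="intensity")
        long = long[long["intensity"] > 0]
        long["snr"] = np.inf
        return PeakMatrix(
            long[["sample_id", "mz", "intensity", "snr"]].reset_index(drop=True),
            polarity, mode,
        )
    raise ValueError("peak CSV must be long (sample_id, mz, intensity) or wide (mz x samples)")


def load_sample_meta_csv(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "sample_id" not in meta.columns:
        raise ValueError("sample metadata CSV requires a sample_id column")
    meta = meta.set_index("sample_id")
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    return meta[META_COLUMNS]


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _nearest_ion(mz_obs: np.ndarray, lib_mz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index of the library ion minimising |ppm| for each observed m/z.

    Ties in |ppm| go to the lower-m/z ion (documented tie-break).
    """
    idx = np.searchsorted(lib_mz, mz_obs)
    lo = np.clip(idx - 1, 0, len(lib_mz) - 1)
    hi = np.clip(idx, 0, len(lib_mz) - 1)
    ppm_lo = (mz_obs - lib_mz[lo]) / lib_mz[lo] * 1e6
    ppm_hi = (mz_obs - lib_mz[hi]) / lib_mz[hi] * 1e6
    # tie (equal |ppm| within float noise) -> lower m/z
    take_lo = np.abs(ppm_lo) <= np.abs(ppm_hi) + 1e-6
    best = np.where(take_lo, lo, hi)
    ppm = np.where(take_lo, ppm_lo, ppm_hi)
    # ions with identical m/z (isomeric formulas): deterministically assign
    # to the first of the equal-m/z run regardless of jitter sign
    best = np.searchsorted(lib_mz, lib_mz[best], side="left")
    return best, ppm


def _cluster_unmatched(mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Single-linkage m/z clustering of unannotated signals across samples."""
    order = np.argsort(mz)
    groups = np.empty(len(mz), dtype=int)
    gid = -1
    prev = None
    for i in order:
        if prev is None or (mz[i] - prev) / prev * 1e6 > tol_ppm:
            gid += 1
        groups[i] = gid
        prev = mz[i]
    return groups


def match_features(
    peaks: PeakMatrix,
    library: IonLibrary,
    tol_ppm: float | None = None,
    meta: pd.DataFrame | None = None,
) -> tuple[FeatureTable, QCReport]:
    """Assign observed peaks to theoretical ions within a ppm tolerance.

    Default tolerance is 9 ppm for intact mode and 12.5 ppm for the CID
    fatty-acid mode.  In intact mode unmatched peaks are dropped; in CID
    mode every signal above noise is carried forward, unannotated signals
    keyed by their cross-sample mean m/z.  Replicate peaks from one sample
    matching the same ion are summed.
    """
    if peaks.polarity != library.polarity:
        raise ValueError(
            f"polarity mismatch: peaks {peaks.polarity} vs library {library.polarity}"
        )
    if tol_ppm is None:
        tol_ppm = 12.5 if peaks.mode == "cid_fa" else 9.0
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if len(library) == 0:
        raise ValueError("empty ion library")

    df = peaks.peaks.copy()
    lib_mz = np.asarray(library.mz_values())
    ions = library.ions
    best, ppm = _nearest_ion(df["mz"].to_numpy(float), lib_mz)
    matched = np.abs(ppm) <= tol_ppm
    df["ppm"] = ppm
    df["feature_id"] = [ions[b].feature_id if m else None for b, m in zip(best, matched)]

    n_unmatched = int((~matched).sum())
    if peaks.mode == "cid_fa" and n_unmatched:
        un = df.loc[~matched]
        groups = _cluster_unmatched(un["mz"].to_numpy(float), tol_ppm)
        means = un.groupby(groups)["mz"].transform("mean")
        df.loc[~matched, "feature_id"] = [f"mz {m:.4f}" for m in means]

    kept = df[df["feature_id"].notna()]
    if len(kept):
        values = kept.pivot_table(index="sample_id", columns="feature_id",
                                  values="intensity", aggfunc="sum", fill_value=0.0)
        snr = kept.pivot_table(index="sample_id", columns="feature_id",
                               values="snr", aggfunc="max", fill_value=0.0)
    else:
        values = pd.DataFrame(index=pd.Index([], name="sample_id"))
        snr = values.copy()
    # keep every sample that had peaks, even if all were unmatched
    all_samples = peaks.sample_ids
    values = values.reindex(index=all_samples, fill_value=0.0)
    snr = snr.reindex(index=all_samples, fill_value=0.0)

    by_id = {ion.feature_id: ion for ion in ions}
    feat_rows = []
    for fid in values.columns:
        ion = by_id.get(fid)
        if ion is not None:
            s = ion.species
            feat_rows.append({
                "feature_id": fid, "mz": ion.mz, "label": s.label,
                "class_code": s.class_code, "carbons": s.total_carbons,
                "double_bonds": s.double_bonds, "hydroxyls": s.hydroxyls,
                "adduct": ion.adduct.name, "annotated": True,
                "isobar_group": ion.isobar_group,
                "top_annotation": ion.annotations[0] if ion.annotations else s.label,
            })
        else:
            feat_rows.append({
                "feature_id": fid, "mz": float(fid.split()[1]), "label": fid,
                "class_code": None, "carbons": None, "double_bonds": None,
                "hydroxyls": None, "adduct": None, "annotated": False,
                "isobar_group": None, "top_annotation": None,
            })
    feat_cols = ["feature_id", "mz", "label", "class_code", "carbons",
                 "double_bonds", "hydroxyls", "adduct", "annotated",
                 "isobar_group", "top_annotation"]
    features = pd.DataFrame(feat_rows, columns=feat_cols).set_index("feature_id")
    order = features["mz"].sort_values().index
    features = features.loc[order]
    values = values[order]
    snr = snr[order]

    if meta is None:
        meta = pd.DataFrame(index=values.index, columns=META_COLUMNS)
    else:
        meta = meta.reindex(values.index)
    table = FeatureTable(values, features, meta, snr)
    table.log("match_features", mode=peaks.mode, tol_ppm=tol_ppm,
              n_peaks=len(df), n_matched=int(matched.sum()),
              n_unmatched=n_unmatched,
              unmatched_policy="carried_forward" if peaks.mode == "cid_fa" else "dropped")

    match_stats = (
        df[matched].groupby("feature_id")["ppm"]
        .agg(["count", "mean"]).rename(columns={"count": "n_peaks", "mean": "mean_ppm"})
    )
    report = QCReport(
        "match_features",
        features=match_stats,
        summary={
            "tol_ppm": tol_ppm, "mode": peaks.mode,
            "n_peaks": len(df), "n_matched": int(matched.sum()),
            "n_unmatched": n_unmatched, "n_features": table.n_features,
        },
    )
    return table, report


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_signal_filters(
    table: FeatureTable, snr_min: float = 3.0, presence_min: float = 0.20
) -> tuple[FeatureTable, QCReport]:
    """Discard features with median S/N < ``snr_min`` (over detections) or
    detected in fewer than ``presence_min`` of samples.  Thresholds are
    strict as worded: S/N exactly at ``snr_min`` and presence exactly at
    ``presence_min`` are retained."""
    if table.n_samples == 0:
        raise ValueError("feature table has no samples")
    detected = table.values > 0
    presence = detected.mean(axis=0)
    if table.snr is not None:
        med_snr = table.snr.where(detected).median(axis=0)
    else:
        med_snr = pd.Series(np.inf, index=table.values.columns)

    failed = pd.Series([None] * table.n_features, index=table.values.columns, dtype=object)
    failed[med_snr < snr_min] = f"median_snr<{snr_min}"
    low_presence = (presence < presence_min) & failed.isna()
    failed[low_presence] = f"presence<{presence_min}"

    keep = failed.isna()
    out = table.select_features(table.values.columns[keep])
    out.log("apply_signal_filters", snr_min=snr_min, presence_min=presence_min,
            n_in=table.n_features, n_out=int(keep.sum()),
            n_discarded=int((~keep).sum()))
    report = QCReport(
        "apply_signal_filters",
        features=pd.DataFrame({
            "median_snr": med_snr, "presence": presence,
            "passed": keep, "failed_rule": failed,
        }),
        summary={
            "n_in": table.n_features, "n_out": int(keep.sum()),
            "discarded_snr": int((failed == f"median_snr<{snr_min}").sum()),
            "discarded_presence": int((failed == f"presence<{presence_min}").sum()),
        },
    )
    return out, report


def dilution_linearity_filter(
    table: FeatureTable, r_min: float = 0.75, use_log: bool = False
) -> tuple[FeatureTable, QCReport]:
    """Keep features whose intensity correlates with the QC-pool dilution
    factor with Pearson r strictly greater than ``r_min``.

    Requires >= 3 QC-pool samples with distinct dilution values.  Features
    with zero intensity variance across the pools have undefined r and are
    discarded with reason "degenerate".  ``use_log`` computes r on
    log2(intensity + 1) instead of the raw scale.
    """
    pools = table.qc_pool_ids()
    dilutions = table.meta.loc[pools, "dilution"].astype(float)
    if len(pools) < 3 or dilutions.nunique() < 3:
        raise ValueError("dilution linearity requires >= 3 QC pools with distinct dilutions")
    x = dilutions.to_numpy()
    y = table.values.loc[pools].to_numpy(float)
    if use_log:
        y = np.log2(y + 1.0)
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    degenerate = (yc ** 2).sum(axis=0) == 0

    failed = pd.Series([None] * table.n_features, index=table.values.columns, dtype=object)
    failed[degenerate] = "degenerate"
    failed[(~degenerate) & ~(r > r_min)] = f"r<={r_min}"
    keep = failed.isna()
    out = table.select_features(table.values.columns[keep])
    out.log("dilution_linearity_filter", r_min=r_min, use_log=use_log,
            n_in=table.n_features, n_out=int(keep.sum()))
    report = QCReport(
        "dilution_linearity_filter",
        features=pd.DataFrame({
            "linearity_r": r, "passed": keep, "failed_rule": failed,
        }, index=table.values.columns),
        summary={"n_in": table.n_features, "n_out": int(keep.sum()),
                 "r_min": r_min, "n_pools": len(pools)},
    )
    return out, report


def exclude_low_detection_samples(
    table: FeatureTable, detection_min: float = 0.667
) -> tuple[FeatureTable, QCReport]:
    """Remove samples detecting strictly fewer than ``detection_min`` of the
    retained features.  PCA-score outliers (|score| > 3 SD on PC1/PC2) are
    flagged as advisory only, never auto-excluded."""
    detected = table.values > 0
    fraction = detected.mean(axis=1)
    excluded = fraction < detection_min

    # advisory multivariate outlier flags
    advisory = pd.Series(False, index=table.values.index)
    if table.n_samples >= 3 and table.n_features >= 2:
        X = np.log2(table.values.to_numpy(float) + 1.0)
        X = X - X.mean(axis=0)
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        scores = u[:, :2] * s[:2]
        sd = scores.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            flag = (np.abs(scores) > 3 * sd).any(axis=1)
        advisory = pd.Series(flag, index=table.values.index)

    keep_ids = table.values.index[~excluded]
    if len(keep_ids) == 0:
        raise ValueError(
            "all samples fall below the detection threshold; "
            f"fractions: {fraction.round(3).to_dict()}"
        )
    out = table.select_samples(keep_ids)
    out.log("exclude_low_detection_samples", detection_min=detection_min,
            n_in=table.n_samples, n_out=len(keep_ids))
    report = QCReport(
        "exclude_low_detection_samples",
        samples=pd.DataFrame({
            "detection_fraction": fraction,
            "passed": ~excluded,
            "failed_rule": np.where(excluded, f"detection<{detection_min}", None),
            "pca_outlier_advisory": advisory,
        }),
        summary={"n_in": table.n_samples, "n_out": len(keep_ids),
                 "detection_min": detection_min,
                 "n_advisory_flags": int(advisory.sum())},
    )
    return out, report


def drop_qc_pools(table: FeatureTable) -> FeatureTable:
    """Remove QC-pool (dilution-series) samples before statistics."""
    pools = table.qc_pool_ids()
    out = table.select_samples(table.experimental_ids())
    out.log("drop_qc_pools", n_dropped=len(pools), dropped=pools)
    return out
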