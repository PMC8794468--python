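"""End-to-end orchestration of the lipidomics stages in their fixed order.

library -> match -> signal filters -> dilution linearity -> sample QC ->
per-mille -> zeros-to-missing -> NIPALS imputation -> normalization ->
statistics.  Every threshold lives in :class:`PipelineConfig` (defaults are
the method's printed constants) and is echoed into the run report; any stage
rejection aborts with the stage name and reason.  Re-running with identical
config and inputs is byte-identical: nothing downstream of the simulator
draws random numbers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dims, preprocess, stats
from .dims import FeatureTable, PeakMatrix, QCReport
from .library import IonLibrary

__all__ = [
    "ConfigError",
    "StageError",
    "PipelineConfig",
    "DimsPipelineResult",
    "run_dims_pipeline",
]


class ConfigError(ValueError):
    """Invalid configuration (unknown key, bad value)."""


class StageError(RuntimeError):
    """A pipeline stage rejected its input."""

    def __init__(self, stage: str, reason: Exception | str):
        self.stage = stage
        self.reason = str(reason)
        super().__init__(f"stage {stage!r} failed: {reason}")


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the pipeline, defaulting to the method's constants."""

    ppm_intact: float = 9.0
    ppm_cid: float = 12.5
    snr_min: float = 3.0
    presence_min: float = 0.20
    linearity_r_min: float = 0.75
    linearity_on_log: bool = False
    detection_min: float = 0.667
    alpha: float = 0.05
    vip_min: float = 1.0
    alpha_norm: float = 0.05
    normalization: str = "cyclicloess"
    loess_iterations: int = 3
    loess_span: float = 0.7
    plsda_components: int = 2
    rt_drift_max: float = 0.1
    blank_factor: float = 3.0
    is_conc_uM: float = 5.0
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a flat key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DimsPipelineResult:
    """Bundle of every stage output for one DIMS analysis run."""

    config: PipelineConfig
    qc_reports: list[QCReport]
    feature_table: FeatureTable  # post-QC, pre-transform (raw intensities)
    permille: FeatureTable  # per-mille scale, experimental samples
    normalized: FeatureTable  # final log2 values statistics ran on
    regulation: pd.DataFrame
    regulation_by_sex: dict[str, pd.DataFrame]
    class_table: pd.DataFrame
    class_tests: pd.DataFrame
    class_anova: pd.DataFrame
    saturation: pd.DataFrame | None
    pca_scores: pd.DataFrame
    pca_explained: list[float]
    provenance: list[dict]

    def run_report(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "provenance": self.provenance,
            "qc": [r.summary for r in self.qc_reports],
            "n_samples": self.normalized.n_samples,
            "n_features": self.normalized.n_features,
            "n_regulated": int(self.regulation["regulated"].sum()),
        }


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValueError, RuntimeError) as exc:
            raise StageError(name, exc) from exc
    return wrap


def run_dims_pipeline(
    peaks: PeakMatrix,
    meta: pd.DataFrame,
    library: IonLibrary,
    config: PipelineConfig | None = None,
    by_sex: bool = True,
) -> DimsPipelineResult:
    """Run matching, QC, preprocessing and statistics on one DIMS run.

    ``by_sex`` additionally produces per-sex regulation tables whenever both
    sexes have at least three samples per diet group.
    """
    cfg = config or PipelineConfig()
    reports: list[QCReport] = []

    tol = cfg.ppm_cid if peaks.mode == "cid_fa" else cfg.ppm_intact
    table, rep = _stage("match_features")(dims.match_features, peaks, library, tol, meta)
    reports.append(rep)

    table, rep = _stage("signal_filters")(
        dims.apply_signal_filters, table, cfg.snr_min, cfg.presence_min)
    reports.append(rep)
    if table.n_features == 0:
        raise StageError("signal_filters", "empty feature set after filtering")

    if len(table.qc_pool_ids()) >= 3:
        table, rep = _stage("dilution_linearity")(
            dims.dilution_linearity_filter, table, cfg.linearity_r_min, cfg.linearity_on_log)
        reports.append(rep)
        if table.n_features == 0:
            raise StageError("dilution_linearity", "empty feature set after filtering")

    table, rep = _stage("sample_qc")(
        dims.exclude_low_detection_samples, table, cfg.detection_min)
    reports.append(rep)

    table = dims.drop_qc_pools(table)
    if table.n_samples == 0:
        raise StageError("sample_qc", "no experimental samples remain")

    permille = _stage("to_permille")(preprocess.to_permille, table)
    masked = preprocess.zeros_to_missing(permille)
    masked, rep = preprocess.drop_all_missing_features(masked)
    reports.append(rep)
    imputed = _stage("nipals_impute")(preprocess.nipals_impute, masked)
    imputed = _stage("normalize")(preprocess.floor_nonpositive, imputed)
    normalized = _stage("normalize")(
        preprocess.cyclic_loess_normalize, imputed,
        cfg.loess_iterations, cfg.loess_span, cfg.normalization)

    permille = permille.select_features(normalized.values.columns)

    regulation = _stage("regulation")(
        stats.regulation_analysis, normalized, permille,
        alpha=cfg.alpha, vip_min=cfg.vip_min, alpha_norm=cfg.alpha_norm,
        n_components=cfg.plsda_components)

    regulation_by_sex: dict[str, pd.DataFrame] = {}
    if by_sex:
        for sex in ("M", "F"):
            ids = normalized.meta.index[normalized.meta["sex"] == sex]
            if len(ids) == 0:
                continue
            sub_n = normalized.select_samples(ids)
            sub_p = permille.select_samples([i for i in ids if i in permille.values.index])
            counts = sub_n.meta["diet"].value_counts()
            if counts.get("CTL", 0) >= 3 and counts.get("OB", 0) >= 3:
                regulation_by_sex[sex] = _stage(f"regulation_{sex}")(
                    stats.regulation_analysis, sub_n, sub_p,
                    alpha=cfg.alpha, vip_min=cfg.vip_min,
                    alpha_norm=cfg.alpha_norm, n_components=cfg.plsda_components)

    class_table = _stage("class_sums")(stats.sum_lipid_classes, permille)
    diet = permille.meta["diet"]
    class_rows = []
    for col in class_table.columns:
        vals = class_table[col]
        a = vals[diet == "OB"].dropna()
        b = vals[diet == "CTL"].dropna()
        if len(a) >= 3 and len(b) >= 3:
            test_used, p = stats.normality_gated_test(a, b, cfg.alpha_norm)
            class_rows.append({"class": col, "test_used": test_used, "p_value": p,
                               "significant": p < cfg.alpha})
    class_tests = pd.DataFrame(class_rows).set_index("class") if class_rows else pd.DataFrame()

    anova_rows = []
    sex = permille.meta["sex"]
    for col in class_table.columns:
        try:
            rec = stats.factorial_anova(class_table[col], diet, sex, feature_id=col)
            anova_rows.append(dataclasses.asdict(rec))
        except ValueError:
            continue
    class_anova = (pd.DataFrame(anova_rows).set_index("feature_id")
                   if anova_rows else pd.DataFrame())

    saturation = None
    if peaks.mode == "cid_fa":
        saturation = stats.saturation_totals(permille)

    scores, explained = _stage("pca")(stats.pca_scores, normalized.values)

    return DimsPipelineResult(
        config=cfg,
        qc_reports=reports,
        feature_table=table,
        permille=permille,
        normalized=normalized,
        regulation=regulation,
        regulation_by_sex=regulation_by_sex,
        class_table=class_table,
        class_tests=class_tests,
        class_anova=class_anova,
        saturation=saturation,
        pca_scores=scores,
        pca_explained=list(map(float, explained)),
        provenance=list(normalized.provenance),
    )
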