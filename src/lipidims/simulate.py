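"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design the pipeline is built for: a 2x2
diet (CTL/OB) x sex (M/F) layout of direct-infusion lipidomics samples plus
a 0.25/0.5/1.0 dilution series of QC pools; a targeted acyl-carnitine run
with internal standards, blanks and retention-time drift; and point-count
grids over sections of a body of known volume.  Each generator is the
measurable inverse of its pipeline stage: with noise set to zero the stage
recovers the ground truth exactly.  All randomness flows through one
``numpy.random.Generator`` seeded from the design; no global RNG state is
touched.

Default magnitudes are chosen to look like real DIMS data: log-normal
intensities with a between-replicate spread of ~0.5 on the log2 scale
(a coefficient of variation near 40%), +/-2 ppm mass jitter (truncated at
3 sigma, well inside the 9 ppm matching tolerance), detection-limit-driven
missingness concentrated in low-intensity signals, and two-fold (1.0 log2)
diet effects on a 10% subset of features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .carnitine import CarnitineMeasurement, CarnitineTarget
from .dims import META_COLUMNS, PeakMatrix
from .library import IonLibrary, group_isobars, isobar_representatives
from .stereology import SectionGrid

__all__ = [
    "SimulationDesign",
    "simulate_dims_study",
    "simulate_log2_matrix",
    "simulate_carnitine_run",
    "simulate_stereology_counts",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Study design and noise model for the DIMS simulator.

    ``n_per_cell`` samples per diet x sex cell (the study ran 6-12);
    ``effect_fraction`` of features carry a diet effect of ``effect_log2``
    (OB means multiplied by 2**effect_log2).  ``sex_specific_effects``
    optionally assigns separate affected-feature counts per sex, emulating
    the asymmetric female/male response; when set it overrides
    ``effect_fraction``.
    """

    n_per_cell: int = 7
    n_features: int = 200
    effect_fraction: float = 0.1
    effect_log2: float = 1.0
    sex_specific_effects: dict[str, int] | None = None
    base_log2_mean: float = 17.0
    feature_log2_sd: float = 3.0
    within_log2_sd: float = 0.5
    sample_sum_log2_sd: float = 0.25
    ppm_sd: float = 2.0
    missingness: float = 0.05
    mcar: bool = False
    snr_log2_median: float = 4.5  # median S/N ~ 23
    snr_log2_sd: float = 1.0
    dilution_factors: tuple[float, ...] = (0.25, 0.5, 1.0)
    n_qc_pools: int = 3
    pool_noise_log2_sd: float = 0.05
    min_separation_ppm: float = 30.0
    compartment: str = "fetal_heart"
    seed: int = 0

    def __post_init__(self):
        for name in ("effect_fraction", "missingness"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_cell < 1 or self.n_features < 1:
            raise ValueError("n_per_cell and n_features must be positive")


def _select_ions(library: IonLibrary, design: SimulationDesign, rng: np.random.Generator):
    """Pick simulated true features the matcher can always recover.

    Candidates are isobar-group representatives whose nearest distinct-m/z
    neighbour anywhere in the full library is further than
    ``min_separation_ppm`` away (jittered peaks then always match their
    source ion) and which win the documented tie-break against any
    exact-m/z duplicates.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    lib = library
    if any(ion.isobar_group is None for ion in lib):
        lib = group_isobars(lib)
    all_mz = np.asarray(lib.mz_values())
    reps = isobar_representatives(lib).ions

    from .dims import _nearest_ion  # matcher tie-break, reused for the check

    def isolated(ion) -> bool:
        gaps = np.abs(all_mz - ion.mz) / ion.mz * 1e6
        near = gaps[(gaps > 1e-4) ]  # distinct m/z only (duplicates handled below)
        if near.size and near.min() <= design.min_separation_ppm:
            return False
        best, _ = _nearest_ion(np.array([ion.mz]), all_mz)
        return lib.ions[int(best[0])].feature_id == ion.feature_id

    candidates = [ion for ion in reps if isolated(ion)]
    if len(candidates) < design.n_features:
        raise ValueError(
            f"library yields only {len(candidates)} well-separated ions, "
            f"{design.n_features} requested"
        )
    order = rng.permutation(len(candidates))
    chosen = [candidates[i] for i in order[: design.n_features]]
    return sorted(chosen, key=lambda i: i.mz)


def _sample_layout(design: SimulationDesign) -> pd.DataFrame:
    rows = []
    for diet in ("CTL", "OB"):
        for sex in ("M", "F"):
            for k in range(design.n_per_cell):
                rows.append({
                    "sample_id": f"{diet}_{sex}_{k + 1}",
                    "compartment": design.compartment,
                    "diet": diet, "sex": sex,
                    "dilution": np.nan, "tissue_mg": np.nan,
                })
    for k in range(design.n_qc_pools):
        factor = design.dilution_factors[k % len(design.dilution_factors)]
        rows.append({
            "sample_id": f"QC_{k + 1}",
            "compartment": design.compartment,
            "diet": np.nan, "sex": np.nan,
            "dilution": factor, "tissue_mg": np.nan,
        })
    return pd.DataFrame(rows).set_index("sample_id")[META_COLUMNS]


def _effect_matrix(design: SimulationDesign, meta: pd.DataFrame,
                   rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Per-(sample, feature) log2 effect offsets plus the ground-truth map."""
    exp_ids = meta.index[meta["dilution"].isna()]
    n = len(exp_ids)
    offsets = np.zeros((n, design.n_features))
    is_ob = (meta.loc[exp_ids, "diet"] == "OB").to_numpy()
    truth: dict = {"effect_log2": design.effect_log2, "affected": {}}
    if design.sex_specific_effects is not None:
        pool = rng.permutation(design.n_features)
        start = 0
        for sex, count in design.sex_specific_effects.items():
            feats = np.sort(pool[start:start + count])
            start += count
            rows = is_ob & (meta.loc[exp_ids, "sex"] == sex).to_numpy()
            offsets[np.ix_(rows, feats)] += design.effect_log2
            truth["affected"][sex] = feats.tolist()
    else:
        n_affected = int(round(design.effect_fraction * design.n_features))
        feats = np.sort(rng.choice(design.n_features, size=n_affected, replace=False))
        offsets[np.ix_(is_ob, feats)] += design.effect_log2
        truth["affected"]["all"] = feats.tolist()
    return offsets, truth


def simulate_log2_matrix(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Experimental-sample log2 intensity matrix (no peaks, no pools).

    This is the generator's core intensity model — feature baselines drawn
    once, diet effects added for OB samples, replicate noise and a per-sample
    loading offset — exposed directly so statistical calibration studies can
    run many replicates without the peak-building stages.  Returns
    (log2 values, sample metadata, ground truth).
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    meta = _sample_layout(design)
    exp_ids = meta.index[meta["dilution"].isna()]
    base = rng.normal(design.base_log2_mean, design.feature_log2_sd, design.n_features)
    offsets, truth = _effect_matrix(design, meta, rng)
    noise = rng.normal(0.0, design.within_log2_sd, (len(exp_ids), design.n_features))
    loading = rng.normal(0.0, design.sample_sum_log2_sd, len(exp_ids))
    log2 = base[None, :] + offsets + noise + loading[:, None]
    values = pd.DataFrame(log2, index=exp_ids,
                          columns=[f"f{j}" for j in range(design.n_features)])
    truth["base_log2"] = base.tolist()
    return values, meta.loc[exp_ids], truth


def _missing_probability(log2: np.ndarray, design: SimulationDesign) -> np.ndarray:
    if design.mcar:
        return np.full(log2.shape, design.missingness)
    # detection-limit-driven: probability decays with intensity rank, mean
    # over the matrix equals the nominal rate
    flat_rank = _rankdata(log2)
    u = (flat_rank - 0.5) / log2.size
    return np.clip(2.0 * design.missingness * (1.0 - u), 0.0, 1.0).reshape(log2.shape)


def _rankdata(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, axis=None, kind="stable")
    ranks = np.empty(a.size)
    ranks[order] = np.arange(1, a.size + 1)
    return ranks


def simulate_dims_study(
    design: SimulationDesign, library: IonLibrary
) -> tuple[PeakMatrix, pd.DataFrame, dict]:
    """Full DIMS study: peaks with m/z jitter, S/N, missingness and QC pools.

    Returns (PeakMatrix, sample metadata, ground truth).  The truth maps
    feature ids (library feature ids of the chosen ions) to their affected
    status, so pipeline recovery can be scored exactly.
    """
    rng = np.random.default_rng(design.seed)
    ions = _select_ions(library, design, rng)
    meta = _sample_layout(design)
    log2_values, exp_meta, truth = simulate_log2_matrix(design, rng)
    exp_ids = list(exp_meta.index)
    log2 = log2_values.to_numpy()

    feature_ids = [ion.feature_id for ion in ions]
    truth["feature_ids"] = feature_ids
    truth["affected_feature_ids"] = {
        key: [feature_ids[j] for j in feats] for key, feats in truth["affected"].items()
    }

    p_miss = _missing_probability(log2, design)
    missing = rng.uniform(size=log2.shape) < p_miss
    snr = 2.0 ** rng.normal(design.snr_log2_median, design.snr_log2_sd, log2.shape)

    pool_ids = [s for s in meta.index if s not in exp_ids]
    pool_base = log2.mean(axis=0)
    rows = []
    theo_mz = np.array([ion.mz for ion in ions])

    def jitter(size):
        eps = rng.normal(0.0, design.ppm_sd, size)
        return np.clip(eps, -3 * design.ppm_sd, 3 * design.ppm_sd) * 1e-6

    for i, sid in enumerate(exp_ids):
        keep = ~missing[i]
        mz_obs = theo_mz[keep] * (1.0 + jitter(int(keep.sum())))
        for mz, inten, s in zip(mz_obs, 2.0 ** log2[i, keep], snr[i, keep]):
            rows.append((sid, mz, inten, s))
    for k, sid in enumerate(pool_ids):
        factor = float(meta.loc[sid, "dilution"])
        noise = rng.normal(0.0, design.pool_noise_log2_sd, design.n_features)
        inten = 2.0 ** (pool_base + noise) * factor
        mz_obs = theo_mz * (1.0 + jitter(design.n_features))
        s = 2.0 ** rng.normal(design.snr_log2_median, design.snr_log2_sd, design.n_features)
        for mz, iv, sv in zip(mz_obs, inten, s):
            rows.append((sid, mz, iv, sv))

    peaks = pd.DataFrame(rows, columns=["sample_id", "mz", "intensity", "snr"])
    mode = "cid_fa" if library.polarity == "negative" else "intact"
    truth["true_log2"] = log2.tolist()
    truth["missing_mask"] = missing.astype(int).tolist()
    return PeakMatrix(peaks, library.polarity, mode), meta, truth


def simulate_carnitine_run(
    panel: dict[str, CarnitineTarget],
    true_concentrations: pd.DataFrame,  # samples x target names, uM/mg
    tissue_mg: dict[str, float],
    blank_areas: dict[str, float] | float = 0.0,
    rt_jitter_sd: float = 0.02,
    area_cv: float = 0.0,
    is_area: float = 1.0e5,
    is_conc: float = 5.0,
    seed: int = 0,
) -> tuple[list[CarnitineMeasurement], pd.DataFrame]:
    """Generate integration rows whose quantification recovers the truth.

    With ``rt_jitter_sd`` and ``area_cv`` at 0 the quant chain inverts the
    generator exactly (truths below the 3x-blank equivalent report 0).
    Returns (measurements, truth table as given).
    """
    if (true_concentrations < 0).any().any():
        raise ValueError("true concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    measurements = []
    for sid in true_concentrations.index:
        mg = tissue_mg[sid]
        for name in true_concentrations.columns:
            target = panel[name]
            blank = blank_areas if isinstance(blank_areas, (int, float)) else blank_areas.get(name, 0.0)
            conc = float(true_concentrations.loc[sid, name])
            area = conc * mg / is_conc * is_area
            if area_cv > 0:
                area *= np.exp(rng.normal(0.0, area_cv))
            rt = target.expected_rt + rng.normal(0.0, rt_jitter_sd) if rt_jitter_sd > 0 else target.expected_rt
            measurements.append(CarnitineMeasurement(
                sid, target, max(rt, 1e-6), area, is_area, float(blank), mg
            ))
    return measurements, true_concentrations.copy()


def simulate_stereology_counts(
    true_volume_um3: float,
    area_per_point_um2: float = 9000.0,
    spacing_um: float = 50.0,
    n_sections: int = 10,
    seed: int = 0,
) -> list[SectionGrid]:
    """Section point counts whose Cavalieri estimate is unbiased for the truth.

    The expected total count is V / (a_p x spacing); per-section counts are
    Poisson with that mean split evenly over sections, the counting noise of
    a random grid placement.
    """
    if true_volume_um3 <= 0:
        raise ValueError("true volume must be positive")
    rng = np.random.default_rng(seed)
    lam = true_volume_um3 / (area_per_point_um2 * spacing_um) / n_sections
    counts = rng.poisson(lam, n_sections)
    return [SectionGrid(i, int(c), area_per_point_um2, spacing_um)
            for i, c in enumerate(counts)]
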