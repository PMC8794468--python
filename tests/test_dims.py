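import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from lipidims.dims import (PeakMatrix, apply_signal_filters,
                           dilution_linearity_filter,
                           exclude_low_detection_samples, load_peaks_csv,
                           load_sample_meta_csv, match_features)
from lipidims.library import (ADDUCTS, IonLibrary, TheoreticalIon,
                              build_intact_library, make_species)
from lipidims.simulate import SimulationDesign, simulate_dims_study


def peaks_from_rows(rows, polarity="positive", mode="intact"):
    df = pd.DataFrame(rows, columns=["sample_id", "mz", "intensity", "snr"])
    return PeakMatrix(df, polarity, mode)


class TestMatchFeatures:
    def test_observed_peak_matched_with_ppm_deviation(self):
        lib = build_intact_library([("PC", (34, 34), (1, 1))], ["[M+H]+"])
        peaks = peaks_from_rows([("s1", 760.5855, 1000.0, 20.0)])
        table, report = match_features(peaks, lib, 9.0)
        assert table.n_features == 1
        assert table.features.iloc[0]["label"] == "PC 34:1"
        assert report.features.iloc[0]["mean_ppm"] == pytest.approx(0.55, abs=0.01)

    def test_deviation_beyond_tolerance_dropped_in_intact_mode(self):
        lib = build_intact_library([("PC", (34, 34), (1, 1))], ["[M+H]+"])
        mz = 760.58508 * (1 + 10e-6)
        table, report = match_features(peaks_from_rows([("s1", mz, 1.0, 20.0)]), lib, 9.0)
        assert table.n_features == 0
        assert report.summary["n_unmatched"] == 1

    def test_unmatched_carried_forward_in_cid_mode(self):
        lib = IonLibrary(
            [TheoreticalIon(make_species("FA", 16, 0), ADDUCTS["[M-H]-"],
                            255.2330, "negative")], "negative")
        peaks = peaks_from_rows([("s1", 300.0, 5.0, 10.0), ("s2", 300.0005, 6.0, 10.0)],
                                polarity="negative", mode="cid_fa")
        table, _ = match_features(peaks, lib, 12.5)
        assert table.n_features == 1
        assert not table.features.iloc[0]["annotated"]
        assert (table.values > 0).all().all()  # clustered across samples

    def test_equidistant_tie_assigned_to_lower_mz(self):
        m1, m2 = 500.0, 500.01
        ions = [
            TheoreticalIon(make_species("FA", 16, 0), ADDUCTS["[M-H]-"], m1, "negative"),
            TheoreticalIon(make_species("FA", 17, 0), ADDUCTS["[M-H]-"], m2, "negative"),
        ]
        lib = IonLibrary(ions, "negative")
        obs = 2 * m1 * m2 / (m1 + m2)  # equal |ppm| to both
        table, _ = match_features(
            peaks_from_rows([("s1", obs, 1.0, 5.0)], "negative", "cid_fa"), lib, 50.0)
        assert table.features.iloc[0]["mz"] == m1

    def test_polarity_mismatch_rejected(self):
        lib = build_intact_library([("PC", (34, 34), (1, 1))], ["[M+H]+"])
        with pytest.raises(ValueError, match="polarity"):
            match_features(peaks_from_rows([("s1", 760.6, 1.0, 5.0)],
                                           polarity="negative"), lib)

    def test_replicate_peaks_summed_per_sample(self):
        lib = build_intact_library([("PC", (34, 34), (1, 1))], ["[M+H]+"])
        mz = 760.58508
        peaks = peaks_from_rows([("s1", mz, 100.0, 5.0), ("s1", mz * (1 + 1e-6), 50.0, 5.0)])
        table, _ = match_features(peaks, lib, 9.0)
        assert table.values.iloc[0, 0] == 150.0

    def test_synthetic_study_fully_recovered(self, positive_library):
        """Peaks jittered within tolerance all map back to their source ion."""
        design = SimulationDesign(n_per_cell=3, n_features=80, effect_fraction=0.0,
                                  missingness=0.0, seed=5)
        peaks, meta, truth = simulate_dims_study(design, positive_library)
        table, report = match_features(peaks, positive_library, 9.0, meta)
        assert report.summary["n_unmatched"] == 0
        assert set(table.values.columns) == set(truth["feature_ids"])
        assert (table.values > 0).all().all()


class TestSignalFilters:
    def test_low_snr_and_low_presence_discarded(self):
        values = pd.DataFrame(
            {"a": [1.0] * 20, "b": [1.0] * 3 + [0.0] * 17, "c": [1.0] * 20},
            index=[f"s{i}" for i in range(20)])
        snr = values.copy()
        snr["a"] = 2.5
        snr["b"] = 10.0
        snr["c"] = 10.0
        table = make_table(values, snr=snr)
        out, report = apply_signal_filters(table)
        assert list(out.values.columns) == ["c"]
        assert report.features.loc["a", "failed_rule"].startswith("median_snr")
        assert report.features.loc["b", "failed_rule"].startswith("presence")

    def test_accounting_no_silent_drops(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.integers(0, 3, (10, 30)).astype(float))
        values.columns = [f"f{i}" for i in range(30)]
        snr = pd.DataFrame(rng.uniform(1, 10, (10, 30)), columns=values.columns)
        table = make_table(values, snr=snr)
        out, report = apply_signal_filters(table)
        discarded = report.features["failed_rule"].notna().sum()
        assert table.n_features == out.n_features + discarded

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.uniform(0, 5, (12, 20)),
                              columns=[f"f{i}" for i in range(20)])
        values.iloc[:, :4] = 0.0
        snr = pd.DataFrame(rng.uniform(1, 20, values.shape), columns=values.columns)
        table = make_table(values, snr=snr)
        once, _ = apply_signal_filters(table)
        twice, _ = apply_signal_filters(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_empty_table_rejected(self):
        table = make_table(pd.DataFrame(columns=["a"], dtype=float))
        with pytest.raises(ValueError):
            apply_signal_filters(table)


class TestDilutionLinearity:
    def _table(self, intensities):
        values = pd.DataFrame({"f": intensities}, index=["q1", "q2", "q3"])
        meta = {"dilution": [0.25, 0.5, 1.0]}
        return make_table(values, meta=meta)

    @pytest.mark.parametrize(
        "intensities, kept, r",
        [
            ((1.0, 2.0, 4.0), True, 1.0),
            ((1.0, 2.0, 3.0), True, 0.9819805),
            ((4.0, 2.0, 1.0), False, -0.9285714),
        ],
    )
    def test_pearson_r_rule(self, intensities, kept, r):
        out, report = dilution_linearity_filter(self._table(intensities))
        assert (out.n_features == 1) is kept
        assert report.features.iloc[0]["linearity_r"] == pytest.approx(r, abs=1e-6)

    def test_zero_variance_degenerate(self):
        _, report = dilution_linearity_filter(self._table((3.0, 3.0, 3.0)))
        assert report.features.iloc[0]["failed_rule"] == "degenerate"

    def test_too_few_pools_rejected(self):
        values = pd.DataFrame({"f": [1.0, 2.0]}, index=["q1", "q2"])
        table = make_table(values, meta={"dilution": [0.25, 1.0]})
        with pytest.raises(ValueError):
            dilution_linearity_filter(table)


class TestSampleDetection:
    def test_boundary_and_exclusion(self):
        # 12 features; s_edge detects 8/12 = exactly 2/3
        values = pd.DataFrame(np.ones((3, 12)),
                              index=["s_edge", "s_full", "s_also"],
                              columns=[f"f{i}" for i in range(12)])
        values.loc["s_edge"] = [1.0] * 8 + [0.0] * 4
        table = make_table(values)
        out, report = exclude_low_detection_samples(table, detection_min=2 / 3)
        assert "s_edge" in out.values.index  # rule is strictly "lower than"
        low = values.copy()
        low.loc["s_edge"] = [1.0] * 7 + [0.0] * 5  # 58%
        out2, report2 = exclude_low_detection_samples(make_table(low), detection_min=2 / 3)
        assert "s_edge" not in out2.values.index
        assert report2.samples.loc["s_edge", "failed_rule"] is not None

    def test_all_excluded_rejected(self):
        values = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 1.0], "c": [0.0, 0.0]},
                              index=["s1", "s2"])
        with pytest.raises(ValueError):
            exclude_low_detection_samples(make_table(values), detection_min=0.9)

    def test_full_detection_retained(self):
        values = pd.DataFrame(np.ones((4, 5)), index=list("abcd"),
                              columns=[f"f{i}" for i in range(5)])
        out, report = exclude_low_detection_samples(make_table(values))
        assert out.n_samples == 4
        assert report.summary["n_out"] == 4


def test_peaks_and_meta_csv_loaders(tmp_path):
    long = pd.DataFrame({"sample_id": ["s1", "s2"], "mz": [500.0, 500.0],
                         "intensity": [10.0, 12.0], "snr": [5.0, 6.0]})
    path = tmp_path / "peaks.csv"
    long.to_csv(path, index=False)
    pm = load_peaks_csv(path, "positive", "intact")
    assert len(pm.peaks) == 2

    wide = pd.DataFrame({"mz": [500.0, 600.0], "s1": [10.0, 0.0], "s2": [1.0, 2.0]})
    wide.to_csv(path, index=False)
    pm = load_peaks_csv(path, "positive", "intact")
    assert len(pm.peaks) == 3  # zero-intensity cell not a peak

    meta = pd.DataFrame({"sample_id": ["s1"], "diet": ["CTL"], "sex": ["M"]})
    mpath = tmp_path / "meta.csv"
    meta.to_csv(mpath, index=False)
    loaded = load_sample_meta_csv(mpath)
    assert loaded.loc["s1", "diet"] == "CTL"
    assert "dilution" in loaded.columns
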