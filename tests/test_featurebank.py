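"""Feature definitions: registry structure, hand examples, oracle agreement,
scale behaviour, and degenerate-input conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
import painmap as pm
from painmap import featurebank as fb


class TestRegistry:
    def test_total_and_partition(self):
        names = pm.FEATURE_NAMES
        assert len(names) == 155
        prefix_counts = {p: sum(n.startswith(p) for n in names) for p in "zctsh"}
        assert prefix_counts == {"z": 39, "c": 39, "t": 39, "s": 35, "h": 3}

    def test_names_unique_and_prefixed(self):
        assert len(set(pm.FEATURE_NAMES)) == 155
        assert "cP2P" in pm.FEATURE_NAMES
        assert "sSDSD" in pm.FEATURE_NAMES
        assert "hslopeRR" in pm.FEATURE_NAMES

    def test_scl_has_no_high_frequency_features(self):
        # SCL carries features #1-#35: BW/CF yes, MDF/MNF/MOF/ZC no
        assert "sBW" in pm.FEATURE_NAMES and "sCF" in pm.FEATURE_NAMES
        for absent in ("sMDF", "sMNF", "sMOF", "sZC"):
            assert absent not in pm.FEATURE_NAMES

    def test_seven_theoretical_groups(self):
        groups = {e.group for e in pm.REGISTRY}
        assert groups == {
            "Amplitude",
            "Variability",
            "Stationarity",
            "Entropy",
            "Linearity",
            "Similarity",
            "Frequency",
        }


class TestAmplitude:
    def test_hand_example(self):
        v = pm.amplitude_features([1.0, -1.0, 2.0, -2.0])
        assert v["MAV"] == pytest.approx(1.5)
        assert v["PK"] == 2 and v["P2P"] == 4
        assert v["HOMAV1"] == pytest.approx(3.0)
        assert v["HOMAV1n"] == pytest.approx(2.0)

    def test_constant_conventions(self):
        v = pm.amplitude_features(np.full(100, 3.0))
        assert v["MAV"] == v["RMS"] == 3.0
        assert v["P2P"] == 0.0
        assert v["TMNP"] == v["TMNV"] == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pm.amplitude_features([1.0, 2.0])


class TestVariability:
    def test_hand_example(self):
        v = pm.variability_features([0.0, 2.0, 4.0])
        assert v["VAR"] == pytest.approx(4.0)
        assert v["SD"] == pytest.approx(2.0)
        assert v["R"] == 4.0

    def test_constant_is_zero(self):
        v = pm.variability_features(np.full(50, 7.0))
        assert all(val == 0.0 for val in v.values())


class TestStationarity:
    def test_constant_subwindow_dispersion_zero(self):
        hs = pm.hilbert_spectrum(np.full(512, 2.0), 128.0)
        v = pm.stationarity_features(np.full(512, 2.0), 128.0, hs)
        assert v["SDMN"] == 0.0 and v["SDSD"] == 0.0 and v["MD"] == 2.0

    def test_mean_shift_between_halves_detected(self, rng):
        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(5, 1, 250)])
        hs = pm.hilbert_spectrum(x, 128.0)
        v = pm.stationarity_features(x, 128.0, hs, n_segments=2)
        assert v["SDMN"] > 3.0

    def test_ids_orders_stationary_vs_ramped(self):
        wins = 0
        for s in range(100):
            r = np.random.default_rng(s)
            flat = r.standard_normal(512)
            ramp = np.linspace(0.2, 2.0, 512) * r.standard_normal(512)
            ids = {}
            for name, x in (("flat", flat), ("ramp", ramp)):
                hs = pm.hilbert_spectrum(x, 128.0)
                ids[name] = pm.stationarity_features(x, 128.0, hs)["IDS"]
            wins += ids["ramp"] > ids["flat"]
        assert wins >= 95


class TestEntropy:
    def test_constant_all_zero(self):
        v = pm.entropy_features(np.full(100, 1.0))
        assert all(val == 0.0 for val in v.values())

    def test_alternating_two_values_one_bit(self):
        x = np.tile([0.0, 1.0], 50)
        v = pm.entropy_features(x, n_bins=2)
        assert v["ShannonEn"] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal(500)
        got = pm.entropy_features(x)
        exp = oracles.entropy(x)
        for k in ("ApEn", "SampEn", "FuzzyEn"):
            assert got[k] == pytest.approx(exp[k], rel=1e-9, abs=1e-9), k


class TestLinearity:
    def test_ar1_has_no_excess_dependence(self):
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            x = np.empty(1000)
            x[0] = r.standard_normal()
            for t in range(1, 1000):
                x[t] = 0.7 * x[t - 1] + r.standard_normal()
            if pm.linearity_features(x, 16)["LDF"] < 0.05:
                hits += 1
        assert hits >= 90

    def test_logistic_map_exceeds_white_noise(self):
        wins = 0
        for s in range(50):
            r = np.random.default_rng(s)
            x = np.empty(800)
            x[0] = r.uniform(0.1, 0.9)
            for t in range(1, 800):
                x[t] = 4 * x[t - 1] * (1 - x[t - 1])
            noise = r.standard_normal(800)
            if (
                pm.linearity_features(x, 16)["LDF"]
                > pm.linearity_features(noise, 16)["LDF"]
            ):
                wins += 1
        assert wins >= 48  # >= 95% of draws

    def test_white_noise_pooled_near_zero(self, rng):
        x = rng.standard_normal(2000)
        assert pm.linearity_features(x, 16)["PLDF"] < 0.02


class TestSimilarity:
    BAND = (20.0, 57.6)

    def test_self_similarity(self, rng):
        x = rng.standard_normal(704)
        v = pm.similarity_features(x, x, 128.0, self.BAND)
        assert v["CC"] == pytest.approx(1.0)
        assert v["MNCOH"] == pytest.approx(1.0)
        assert v["MDCOH"] == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self, rng):
        x = rng.standard_normal(2816)
        ref = rng.standard_normal(2816)
        v = pm.similarity_features(x, ref, 512.0, (20.0, 250.0))
        assert abs(v["CC"]) < 0.1

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pm.similarity_features(rng.standard_normal(100), rng.standard_normal(99), 128.0, self.BAND)

    def test_coherence_matches_oracle_at_0db(self, rng):
        x = rng.standard_normal(704)
        ref = x + rng.standard_normal(704)
        got = pm.similarity_features(ref, x, 128.0, self.BAND)
        exp = oracles.similarity(ref, x, 128.0, self.BAND)
        for k in ("MNCOH", "MDCOH", "MICOH", "MMNCOH", "CC", "MI"):
            assert got[k] == pytest.approx(exp[k], rel=1e-9, abs=1e-12), k


class TestFrequency:
    def test_pure_tone(self):
        fs = 1000.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * 50 * t)
        v = pm.frequency_features(x, fs)
        df = fs / 256  # one Welch bin
        for k in ("MNF", "MDF", "MOF"):
            assert abs(v[k] - 50.0) <= df + 1e-9, k
        assert v["ZC"] == 100 - 1

    def test_bandlimited_noise_mean_frequency(self):
        from painmap.preprocess import bandpass_filter

        inside = 0
        for s in range(100):
            r = np.random.default_rng(s)
            x = bandpass_filter(r.standard_normal(2816), 512.0, 20.0, 250.0)
            mnf = pm.frequency_features(x, 512.0)["MNF"]
            inside += 100.0 <= mnf <= 170.0
        assert inside >= 95

    def test_mdf_within_support(self, rng):
        x = rng.standard_normal(704)
        v = pm.frequency_features(x, 128.0)
        assert 0.0 <= v["MDF"] <= 64.0

    def test_all_zero_signal_zeros(self):
        v = pm.frequency_features(np.zeros(128), 128.0)
        assert all(val == 0.0 for val in v.values())


class TestHRV:
    def test_constant_rhythm(self):
        v = pm.hrv_from_rr([800.0] * 6)
        assert v["MNRR"] == pytest.approx(800.0)
        assert v["RMSSD"] == pytest.approx(0.0)
        assert v["slopeRR"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_example(self):
        v = pm.hrv_from_rr([800.0, 810.0, 820.0])
        assert v["RMSSD"] == pytest.approx(10.0)
        assert v["slopeRR"] == pytest.approx(10.0)

    def test_detection_against_construction(self):
        fs = 512.0
        rng = np.random.default_rng(11)
        t = np.arange(int(5.5 * fs)) / fs
        peak_times = np.arange(0.3, 5.4, 0.8)
        ecg = 0.02 * rng.standard_normal(len(t))
        for pt in peak_times:
            ecg += np.exp(-0.5 * ((t - pt) / 0.02) ** 2)
        peaks = fb.detect_r_peaks(ecg, fs)
        assert len(peaks) == len(peak_times)
        assert np.abs(peaks / fs - peak_times).max() <= 1.5 / fs

    def test_too_few_peaks_zeros(self):
        v = pm.hrv_features(np.zeros(704), 128.0)
        assert v == {"MNRR": 0.0, "RMSSD": 0.0, "slopeRR": 0.0}


class TestScaleBehaviour:
    """Equivariance/invariance of features under x -> a*x (a > 0)."""

    LINEAR = ("MAV", "RMS", "PK", "P2P")
    LINEAR_VAR = ("SD", "R", "IQR")

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_amplitude_scales_linearly(self, a):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(256)
        v1 = pm.amplitude_features(x)
        v2 = pm.amplitude_features(a * x)
        for k in self.LINEAR:
            assert v2[k] == pytest.approx(a * v1[k], rel=1e-9)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_variability_scales_linearly(self, a):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(256)
        v1 = pm.variability_features(x)
        v2 = pm.variability_features(a * x)
        for k in self.LINEAR_VAR:
            assert v2[k] == pytest.approx(a * v1[k], rel=1e-9)

    def test_scale_invariant_features(self, rng):
        x = rng.standard_normal(704)
        ref = rng.standard_normal(704)
        for a in (0.1, 3.0, 42.0):
            f1 = pm.frequency_features(x, 128.0)
            f2 = pm.frequency_features(a * x, 128.0)
            assert f1["ZC"] == f2["ZC"]
            s1 = pm.similarity_features(x, ref, 128.0, (20.0, 57.6))
            s2 = pm.similarity_features(a * x, ref, 128.0, (20.0, 57.6))
            for k in ("CC", "MNCOH", "MDCOH", "MICOH"):
                assert s2[k] == pytest.approx(s1[k], rel=1e-9)
            e1 = pm.entropy_features(x)
            e2 = pm.entropy_features(a * x)
            assert e2["ShannonEn"] == pytest.approx(e1["ShannonEn"], rel=1e-9)


class TestExtractFeatures:
    def test_full_vector_counts(self, trial_pair):
        trial, base = trial_pair
        vec = pm.extract_features(trial, base)
        assert len(vec) == 155
        assert sum(k.startswith("c") for k in vec) == 39
        assert sum(k.startswith("h") for k in vec) == 3
        assert all(np.isfinite(v) for v in vec.values())

    def test_subject_mismatch_rejected(self, reduced_cfg, trial_pair):
        trial, _ = trial_pair
        other = pm.synth_subject_profile("S999", 1)
        base = pm.synth_trial(other, pm.PainLevel.B, "b", 3, reduced_cfg)
        with pytest.raises(ValueError):
            pm.extract_features(trial, base)


class TestZScore:
    def test_fit_on_all_rows(self, small_matrix):
        z = pm.zscore_normalize(small_matrix)
        col_means = z.values.mean(axis=0).to_numpy()
        col_sds = z.values.std(axis=0, ddof=1).to_numpy()
        nonconst = small_matrix.values.std(axis=0).to_numpy() > 0
        assert np.abs(col_means[nonconst]).max() < 1e-12
        assert np.abs(col_sds[nonconst] - 1).max() < 1e-9

    def test_constant_column_maps_to_zero(self, small_matrix):
        m = pm.FeatureMatrix(
            values=small_matrix.values.copy(), meta=small_matrix.meta.copy()
        )
        m.values.iloc[:, 0] = 5.0
        z = pm.zscore_normalize(m)
        assert (z.values.iloc[:, 0] == 0).all()
        assert not z.values.isna().any().any()

    def test_fit_subset_leaves_heldout_uncentered(self, rng):
        import pandas as pd

        vals = np.concatenate([rng.normal(0, 1, (50, 3)), rng.normal(4, 1, (50, 3))])
        m = pm.FeatureMatrix(
            values=pd.DataFrame(vals, columns=["a", "b", "c"]),
            meta=pd.DataFrame({"subject": ["s"] * 100, "trial": [str(i) for i in range(100)], "level": ["B"] * 100}),
        )
        z = pm.zscore_normalize(m, fit_rows=np.arange(50))
        held = z.values.iloc[50:].mean(axis=0).to_numpy()
        assert np.abs(held).min() > 0.5  # no leakage of held-out statistics

    def test_empty_fit_rows_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            pm.zscore_normalize(small_matrix, fit_rows=[])
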