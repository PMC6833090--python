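"""Feature extraction: statistical moments, HRV time/frequency measures,
window handling and matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import interpolate, signal

import relpa
from relpa.errors import DataError
from relpa.features import (HR_BPM_NAMES, MODALITY_GROUPS, extract_trial_features,
                            hr_time_features, rr_frequency_features,
                            rr_time_features)

from conftest import make_record


def naive_moments(x):
    """Independent brute-force oracle for the six moment/order statistics."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    sd = var**0.5
    if sd == 0:
        skew = kurt = 0.0
    else:
        m2 = sum((v - mean) ** 2 for v in x) / n
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        skew = m3 / m2**1.5
        kurt = m4 / m2**2  # non-excess: normal -> 3
    return mean, var, sd, skew, kurt, float(np.median(x))


class TestMoments:
    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=60)
        .map(np.asarray)
        .filter(lambda x: np.ptp(x) > 1e-6)  # degenerate spread tested separately
    )
    def test_agree_with_bruteforce_oracle(self, x):
        got = relpa.eda_features(x)
        mean, var, sd, skew, kurt, median = naive_moments(x)
        for name, expected in zip(
            ["eda_mean", "eda_var", "eda_sd", "eda_skew", "eda_kurt", "eda_median"],
            [mean, var, sd, skew, kurt, median],
        ):
            assert got[name] == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_constant_series(self):
        got = relpa.temp_features(np.full(40, 33.2))
        assert got["temp_mean"] == pytest.approx(33.2)
        assert got["temp_median"] == pytest.approx(33.2)
        assert got["temp_var"] == 0 and got["temp_sd"] == 0

    def test_symmetric_series_has_zero_skew(self):
        x = np.concatenate([np.arange(10), 18 - np.arange(10)])
        assert relpa.eda_features(x)["eda_skew"] == pytest.approx(0.0, abs=1e-12)

    def test_outlier_raises_kurtosis(self):
        base = np.full(50, 1.0) + np.linspace(-0.01, 0.01, 50)
        spiked = base.copy()
        spiked[25] += 5.0
        assert (
            relpa.eda_features(spiked)["eda_kurt"]
            > relpa.eda_features(base)["eda_kurt"]
        )

    def test_small_triple(self):
        got = relpa.eda_features(np.array([100.0, 110.0, 120.0]))
        assert got["eda_mean"] == pytest.approx(110.0)
        assert got["eda_median"] == pytest.approx(110.0)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            relpa.eda_features(np.asarray([]))


class TestHrTime:
    def test_constant_series(self):
        got = hr_time_features(np.full(60, 100.0))
        assert got["hr_var"] == 0 and got["hr_sd"] == 0
        assert got["hr_on_response"] == pytest.approx(0.0)
        assert got["hr_off_response"] == pytest.approx(0.0)
        assert got["hr_n_increase_norm"] == 0 and got["hr_n_decrease_norm"] == 0

    def test_ramp_counts_by_enumeration(self):
        n = 60
        got = hr_time_features(np.arange(n, dtype=float) + 80.0)
        assert got["hr_n_increase_norm"] == pytest.approx((n - 1) / n)
        assert got["hr_n_decrease_norm"] == 0.0
        assert got["hr_on_response"] == pytest.approx(1.0)  # 1 bpm/s ramp

    def test_group_has_ten_features(self):
        got = hr_time_features(np.random.default_rng(0).normal(100, 5, 120))
        assert sorted(got) == sorted(HR_BPM_NAMES)

    def test_short_window_rejected(self):
        with pytest.raises(DataError):
            hr_time_features(np.full(20, 100.0))


class TestRrTime:
    def test_hand_oracle_rmssd(self):
        # diffs (20, -30, 20): mean square 566.67, sqrt = 23.805
        got = rr_time_features(np.array([800.0, 820.0, 790.0, 810.0]))
        assert got["rr_rmssd"] == pytest.approx(23.8048, abs=1e-3)

    def test_hand_oracle_pnnx_strict_inequality(self):
        got = rr_time_features(np.array([800.0, 820.0, 790.0, 810.0]))
        assert got["rr_pnn20"] == pytest.approx(1 / 3)  # only |-30| > 20
        assert got["rr_pnn50"] == 0.0

    def test_constant_sequence(self):
        got = rr_time_features(np.full(50, 800.0))
        assert got["rr_sdsd"] == got["rr_rmssd"] == 0.0
        assert got["rr_pnn20"] == got["rr_pnn50"] == 0.0

    def test_fewer_than_three_rejected(self):
        with pytest.raises(DataError):
            rr_time_features(np.array([800.0, 810.0]))

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.floats(300, 2000, allow_nan=False), min_size=3, max_size=100).map(
            np.asarray
        )
    )
    def test_pnn20_at_least_pnn50(self, rr):
        got = rr_time_features(rr)
        assert got["rr_pnn20"] >= got["rr_pnn50"]

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(st.floats(400, 1500, allow_nan=False), min_size=3, max_size=50).map(
            np.asarray
        )
    )
    def test_sdsd_rmssd_bruteforce(self, rr):
        got = rr_time_features(rr)
        d = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
        mean_d = sum(d) / len(d)
        if len(d) > 1:
            sdsd = (sum((v - mean_d) ** 2 for v in d) / (len(d) - 1)) ** 0.5
            assert got["rr_sdsd"] == pytest.approx(sdsd, rel=1e-9, abs=1e-9)
        rmssd = (sum(v**2 for v in d) / len(d)) ** 0.5
        assert got["rr_rmssd"] == pytest.approx(rmssd, rel=1e-9, abs=1e-9)


def synth_rr(duration=300.0, mean_ms=800.0, amp=50.0, freq=0.1):
    """RR sequence whose tachogram is a pure sinusoid at ``freq`` Hz."""
    rr, t = [], 0.0
    while t < duration:
        v = mean_ms + amp * np.sin(2 * np.pi * freq * t)
        rr.append(v)
        t += v / 1000.0
    return np.asarray(rr)


class TestRrFrequency:
    def test_band_decomposition_identity(self):
        got = rr_frequency_features(synth_rr())
        assert got["rr_atotal"] == pytest.approx(
            got["rr_avlf"] + got["rr_alf"] + got["rr_ahf"]
        )
        assert got["rr_pvlf"] + got["rr_plf"] + got["rr_phf"] == pytest.approx(1.0)
        assert got["rr_nlf"] + got["rr_nhf"] == pytest.approx(1.0)

    def test_lf_sinusoid_concentrates_in_lf_band(self):
        got = rr_frequency_features(synth_rr(freq=0.1))
        assert got["rr_alf"] / got["rr_atotal"] > 0.9
        assert got["rr_nlf"] > 0.9

    def test_hf_sinusoid_concentrates_in_hf_band(self):
        got = rr_frequency_features(synth_rr(freq=0.25))
        assert got["rr_nhf"] > 0.9

    def test_against_periodogram_oracle(self):
        """Band dominance agrees with a direct periodogram of the same
        resampled tachogram (independent spectral route)."""
        rr = synth_rr(freq=0.1)
        beat_t = np.concatenate(([0.0], np.cumsum(rr)[:-1])) / 1000.0
        grid = np.arange(0.0, beat_t[-1], 0.25)
        tach = interpolate.interp1d(beat_t, rr, kind="cubic")(grid)
        freqs, psd = signal.periodogram(tach - tach.mean(), fs=4.0)
        lf = np.trapezoid(psd[(freqs >= 0.04) & (freqs <= 0.15)],
                          freqs[(freqs >= 0.04) & (freqs <= 0.15)])
        total = np.trapezoid(psd[freqs <= 0.40], freqs[freqs <= 0.40])
        assert lf / total > 0.9  # oracle agrees the LF band dominates
        got = rr_frequency_features(rr)
        assert got["rr_plf"] > 0.9

    def test_constant_rr_flat_spectrum_flagged(self):
        got = rr_frequency_features(np.full(400, 800.0))
        assert got["rr_atotal"] == pytest.approx(0.0, abs=1e-6)
        assert np.isnan(got["rr_plf"]) and np.isnan(got["rr_nlf"])
        assert np.isnan(got["rr_lf_hf"])

    def test_short_span_rejected(self):
        with pytest.raises(DataError):
            rr_frequency_features(np.full(30, 800.0))  # 24 s span


class TestExtractMatrix:
    def test_feature_group_sizes(self, tiny_matrix):
        assert len(tiny_matrix.groups["hr"]) == 30
        assert len(tiny_matrix.groups["eda"]) == 6
        assert len(tiny_matrix.groups["temp"]) == 6
        assert len(tiny_matrix.groups["person"]) == 6
        assert tiny_matrix.data.shape[1] == 48
        assert len(set(tiny_matrix.data.columns)) == 48

    def test_row_count_matches_ledger(self, tiny_study, tiny_matrix):
        _, ledger = relpa.filter_trials(tiny_study.records)
        assert len(tiny_matrix.data) + len(tiny_matrix.dropped) == ledger.analyzable

    def test_without_person_features(self, tiny_study):
        kept, _ = relpa.filter_trials(tiny_study.records)
        m = relpa.extract_matrix(kept, tiny_study.participants, include_person=False)
        assert m.data.shape[1] == 42
        assert m.columns_for(("hr",), include_person=False) == MODALITY_GROUPS["hr"]

    def test_labels_match_rpe_mapping(self, tiny_matrix):
        for rpe, cls in zip(tiny_matrix.meta["rpe"], tiny_matrix.meta["intensity"]):
            assert cls == int(relpa.rpe_to_class(int(rpe)))

    def test_last_60s_window_differs_from_full(self, tiny_study):
        kept, _ = relpa.filter_trials(tiny_study.records)
        full = relpa.extract_matrix(kept, tiny_study.participants, "full_trial")
        last = relpa.extract_matrix(kept, tiny_study.participants, "last_60s")
        assert len(full.data) == len(last.data)
        # steady-state-only windows shift the mean-HR feature upward for
        # long trials that include the on-transient
        assert (last.data["hr_mean"] >= full.data["hr_mean"] - 1e-9).mean() > 0.9

    def test_window_sizes_after_trim(self):
        """A 300 s trial yields a 280 s analysis window; last-60s mode uses
        the final 60 s of that window."""
        rng = np.random.default_rng(0)
        rec = make_record(
            hr=rng.normal(100, 2, 300),
            rr=synth_rr(300, 700, 20, 0.25),
            eda=rng.normal(2, 0.1, 1200),
            temp=rng.normal(33, 0.1, 1200),
        )
        from relpa.dataio import smooth_record, trim_trial

        prepped = trim_trial(smooth_record(rec), 10)
        assert prepped.duration == 280
        feats_full = extract_trial_features(prepped, "full_trial")
        feats_last = extract_trial_features(prepped, "last_60s")
        assert set(feats_full) == set(feats_last)

    def test_csv_export_with_group_sidecar(self, tiny_matrix, tmp_path):
        import json

        tiny_matrix.to_csv(tmp_path / "features.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "features.csv")
        assert len(df) == len(tiny_matrix.data)
        assert "meta_participant_id" in df.columns
        groups = json.loads((tmp_path / "features.csv.groups.json").read_text())
        assert groups == tiny_matrix.groups

    def test_noiseless_monotone_hr_and_rr_features(self):
        cfg = relpa.SimulationConfig(
            n_participants=2, n_sessions=1, rng_seed=6
        ).noiseless()
        study = relpa.simulate_study(cfg)
        m = relpa.extract_matrix(study.records, study.participants)
        for pid, grp in m.meta.groupby("participant_id"):
            hr_means = m.data.loc[grp.index, "hr_mean"].to_numpy()
            rr_means = m.data.loc[grp.index, "rr_mean"].to_numpy()
            assert np.all(np.diff(hr_means) > 0)
            assert np.all(np.diff(rr_means) < 0)
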