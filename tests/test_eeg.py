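"""EEG spectral pipeline: filtering, epoching, band power, t-test screen."""

import numpy as np
import pytest
from scipy import stats

from neurofuse import (
    CHANNELS_14,
    DEFAULT_BANDS,
    EEGRecording,
    band_power,
    bandpass_filter,
    eeg_feature_table,
    epoch_and_reject,
    region_band_features,
    ttest_screen,
)
from neurofuse.eeg import FIXED12, feature_columns
from neurofuse.types import BandDefinition

BANDS = {b.name: b for b in DEFAULT_BANDS}
FS = 128.0


def tone(freq, dur_s, amp=1.0, fs=FS):
    t = np.arange(0, dur_s, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


def recording(sig_1d, fs=FS):
    return EEGRecording(data=np.tile(sig_1d, (14, 1)), fs=fs,
                        channels=CHANNELS_14, subject_id="t")


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestBandpassFilter:
    def test_50hz_mains_attenuated_below_10_percent(self):
        rec = recording(tone(50, 8))
        out = bandpass_filter(rec).data[0]
        mid = slice(int(FS), -int(FS))  # skip forward-backward transients
        assert rms(out[mid]) < 0.10 * rms(rec.data[0][mid])

    def test_10hz_passband_within_5_percent(self):
        rec = recording(tone(10, 8))
        out = bandpass_filter(rec).data[0]
        mid = slice(int(FS), -int(FS))
        assert rms(out[mid]) == pytest.approx(rms(rec.data[0][mid]),
                                              rel=0.05)

    def test_zero_in_zero_out(self):
        out = bandpass_filter(recording(np.zeros(1024)))
        assert np.allclose(out.data, 0.0)

    def test_invalid_band_errors(self):
        rec = recording(np.zeros(512))
        with pytest.raises(ValueError, match="band"):
            bandpass_filter(rec, low=0.2, high=80.0)  # beyond Nyquist


class TestEpochAndReject:
    def test_epoch_count(self):
        rec = recording(np.zeros(int(40 * FS)))
        assert len(epoch_and_reject(rec, epoch_s=2.0, amp_thresh=10)) == 20

    def test_spike_epoch_dropped(self):
        sig = np.ones(int(10 * FS))
        sig[int(3 * FS)] = 1000.0  # spike inside epoch 1 (2 s epochs)
        kept = epoch_and_reject(recording(sig), epoch_s=2.0, amp_thresh=100)
        assert len(kept) == 4

    def test_all_rejected_errors(self):
        rec = recording(np.full(int(4 * FS), 500.0))
        with pytest.raises(ValueError, match="no epoch"):
            epoch_and_reject(rec, epoch_s=2.0, amp_thresh=100)


class TestBandPower:
    def test_zero_epoch_zero_power(self):
        for band in DEFAULT_BANDS:
            assert band_power(np.zeros((3, 256)), FS, band).tolist() == \
                [0.0, 0.0, 0.0]

    def test_5hz_tone_power_in_theta(self):
        epoch = tone(5, 2)
        total = sum(band_power(epoch, FS, BandDefinition("all", lo, hi))[0]
                    for lo, hi in [(0.2, 45)])
        theta = band_power(epoch, FS, BANDS["theta"])[0]
        assert theta >= 0.95 * total

    def test_two_tone_amplitude_ratio(self):
        a, b = 1.0, 0.4
        epoch = tone(5, 2, a) + tone(25, 2, b)
        p_theta = band_power(epoch, FS, BANDS["theta"])[0]
        p_hbeta = band_power(epoch, FS, BANDS["high_beta"])[0]
        assert p_theta / p_hbeta == pytest.approx((a / b) ** 2, rel=0.05)

    def test_band_beyond_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros(256), FS, BandDefinition("x", 60, 70))

    def test_band_sum_bounded_by_total_power(self, rng):
        epoch = rng.standard_normal(512)
        total = band_power(epoch, FS, BandDefinition("tot", 0.2, 45))[0]
        parts = sum(band_power(epoch, FS, b)[0] for b in DEFAULT_BANDS)
        assert parts <= total + 1e-12


class TestRegionBandFeatures:
    def test_single_channel_region_equals_channel_power(self, rng):
        data = rng.standard_normal((14, int(16 * FS)))
        rec = EEGRecording(data=data, fs=FS, channels=CHANNELS_14,
                           subject_id="s")
        table = region_band_features(rec)
        # LT = {T7}: region mean must equal that channel's own epoch-mean
        t7 = CHANNELS_14.index("T7")
        filtered = bandpass_filter(rec)
        epochs = np.stack(epoch_and_reject(filtered))
        manual = band_power(epochs, FS, BANDS["alpha"])[:, t7].mean()
        assert table.loc["LT", "alpha"] == pytest.approx(manual, rel=1e-12)

    def test_amplitude_doubling_quadruples_power(self, rng):
        data = rng.standard_normal((14, int(8 * FS)))
        rec1 = EEGRecording(data=data, fs=FS, subject_id="a")
        rec2 = EEGRecording(data=2 * data, fs=FS, subject_id="b")
        t1, t2 = region_band_features(rec1), region_band_features(rec2)
        assert np.allclose(t2.to_numpy(), 4 * t1.to_numpy(), rtol=1e-9)

    def test_all_powers_nonnegative(self, small_cohort):
        table = region_band_features(small_cohort.subjects[0].eeg)
        assert (table.to_numpy() >= 0).all()


def closed_form_pooled(a, b):
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / \
        (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def closed_form_welch(a, b):
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
    t = (a.mean() - b.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def tables_from_values(values):
    """Wrap scalar feature values into constant region x band tables."""
    import pandas as pd
    return [pd.DataFrame(v, index=["LF"], columns=["theta"])
            for v in values]


class TestTtestScreen:
    def test_identical_groups_not_selected(self):
        vals = [1.0, 2.0, 3.0]
        out = ttest_screen(tables_from_values(vals),
                           tables_from_values(vals))
        row = out.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)
        assert not row["selected"]

    def test_shifted_group_matches_closed_form(self):
        a, b = np.array([11.0, 12.0, 13.0]), np.array([1.0, 2.0, 3.0])
        out = ttest_screen(tables_from_values(a), tables_from_values(b))
        t_ref, p_ref = closed_form_pooled(a, b)
        row = out.iloc[0]
        assert not row["welch"]  # equal spreads -> pooled
        assert row["t"] == pytest.approx(t_ref, abs=1e-10)
        assert row["p"] == pytest.approx(p_ref, abs=1e-10)
        assert row["selected"] and row["mean_difference"] == 10.0

    def test_degenerate_zero_variance_equal_means(self):
        vals = [2.0, 2.0, 2.0]
        out = ttest_screen(tables_from_values(vals),
                           tables_from_values(vals))
        assert out.iloc[0]["t"] == 0.0 and out.iloc[0]["p"] == 1.0

    @pytest.mark.parametrize("trial", range(10))
    def test_agrees_with_reference_formulas(self, trial):
        rng = np.random.default_rng(100 + trial)
        for _ in range(5):
            a = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(4, 15))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3),
                           size=rng.integers(4, 15))
            out = ttest_screen(tables_from_values(a),
                               tables_from_values(b)).iloc[0]
            ref = closed_form_welch(a, b) if out["welch"] else \
                closed_form_pooled(a, b)
            assert out["t"] == pytest.approx(ref[0], abs=1e-8)
            assert out["p"] == pytest.approx(ref[1], abs=1e-8)

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError, match="2 subjects"):
            ttest_screen(tables_from_values([1.0]),
                         tables_from_values([1.0, 2.0]))


class TestEegFeatureTable:
    def test_fixed12_columns_in_canonical_order(self, small_cohort):
        recs = [s.eeg for s in small_cohort.subjects]
        df = eeg_feature_table(recs, mode="fixed12")
        assert list(df.columns) == feature_columns(FIXED12)
        assert df.shape == (len(recs), 12)

    def test_identical_recordings_identical_rows(self, rng):
        data = rng.standard_normal((14, int(8 * FS)))
        recs = [EEGRecording(data=data.copy(), fs=FS, subject_id=f"s{i}")
                for i in range(2)]
        df = eeg_feature_table(recs, mode="fixed12")
        assert (df.iloc[0] == df.iloc[1]).all()

    def test_screened_mode_recovers_planted_theta(self):
        from neurofuse import CohortSpec, generate_cohort
        spec = CohortSpec(n_asd=10, n_td=10, seed=5, eeg_duration_s=20.0,
                          video_duration_s=4.0, theta_gain_asd=2.0)
        cohort = generate_cohort(spec)
        recs = [s.eeg for s in cohort.subjects]
        df = eeg_feature_table(recs, mode="screened",
                               labels=cohort.labels)
        got = set(df.columns)
        planted = {f"{r}_theta" for r in spec.theta_regions}
        assert planted <= got

    def test_screened_selection_ignores_heldout_labels(self, small_cohort):
        recs = [s.eeg for s in small_cohort.subjects]
        labels = list(small_cohort.labels)
        train = set(small_cohort.subject_ids[:-1])
        df1 = eeg_feature_table(recs, mode="screened", labels=labels,
                                train_ids=train)
        corrupted = labels.copy()
        corrupted[-1] = "TD" if corrupted[-1] == "ASD" else "ASD"
        df2 = eeg_feature_table(recs, mode="screened", labels=corrupted,
                                train_ids=train)
        assert list(df1.columns) == list(df2.columns)

    def test_missing_channels_error(self, rng):
        rec = EEGRecording(data=rng.standard_normal((2, 512)), fs=FS,
                           channels=("AF3", "F7"), subject_id="s")
        with pytest.raises(ValueError, match="missing channels"):
            eeg_feature_table([rec], mode="fixed12")
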