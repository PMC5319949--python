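"""PSD and fractal-dimension features, screening, asymmetry, labeling."""

import numpy as np
import pandas as pd
import pytest

from eegfam import FeatureConfig, assemble_feature_table, band_psd, higuchi_fd
from eegfam.features import (
    DegenerateSeriesWarning,
    LabelingError,
    apply_exclusions,
    asymmetry_augment,
    fd_feature_columns,
    label_windows,
    psd_feature_columns,
    screen_bad_psd,
)
from eegfam.preprocess import BandSpec, Window

ALPHA = BandSpec("alpha", 8.0, 13.0)
BETA = BandSpec("beta", 13.0, 30.0)


def brute_higuchi(x, kmax):
    """Independent reference: explicit loops over scales and offsets."""
    x = np.asarray(x, float)
    n = len(x)
    log_l, log_k = [], []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            total = 0.0
            i = 1
            count = 0
            while m + i * k < n:
                total += abs(x[m + i * k] - x[m + (i - 1) * k])
                i += 1
                count += 1
            if count > 0:
                lm.append(total * (n - 1) / (count * k) / k)
        log_l.append(np.log(sum(lm) / len(lm)))
        log_k.append(np.log(1.0 / k))
    log_l, log_k = np.asarray(log_l), np.asarray(log_k)
    xc = log_k - log_k.mean()
    return float(np.dot(xc, log_l - np.mean(log_l)) / np.dot(xc, xc))


class TestBandPsd:
    def test_tone_concentrates_in_its_band(self):
        t = np.arange(1000) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)
        assert band_psd(x, 250.0, ALPHA) / band_psd(x, 250.0, BETA) >= 100

    def test_white_noise_is_flat_across_bands(self, rng):
        windows = rng.standard_normal((100, 1000))
        a = np.array([band_psd(w, 250.0, ALPHA) for w in windows])
        b = np.array([band_psd(w, 250.0, BETA) for w in windows])
        se = np.std(a - b, ddof=1) / np.sqrt(len(a))
        assert abs(a.mean() - b.mean()) <= 3 * se

    def test_zero_signal_gives_zero(self):
        assert band_psd(np.zeros(1000), 250.0, ALPHA) == 0.0

    def test_amplitude_doubling_quadruples_psd(self, rng):
        x = rng.standard_normal(1000)
        assert band_psd(2 * x, 250.0, ALPHA) == pytest.approx(
            4 * band_psd(x, 250.0, ALPHA), rel=1e-9
        )

    def test_nonfinite_samples_rejected(self):
        x = np.zeros(1000)
        x[3] = np.nan
        with pytest.raises(ValueError):
            band_psd(x, 250.0, ALPHA)


class TestHiguchiFd:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            x = rng.standard_normal(rng.integers(200, 1200))
            assert higuchi_fd(x, kmax=8) == pytest.approx(brute_higuchi(x, 8), abs=1e-9)

    def test_linear_ramp_is_one_dimensional(self):
        assert higuchi_fd(np.linspace(0.0, 1.0, 1000)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_is_two_dimensional(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert higuchi_fd(x) == pytest.approx(2.0, abs=0.1)

    def test_sine_strictly_between_bounds(self):
        x = np.sin(2 * np.pi * 5 * np.linspace(0, 4, 1000))
        assert 1.0 < higuchi_fd(x) < 2.0

    def test_constant_series_flagged_as_one(self):
        with pytest.warns(DegenerateSeriesWarning):
            assert higuchi_fd(np.full(1000, 3.7)) == 1.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.zeros(50), kmax=8)  # length < 10*kmax
        with pytest.raises(ValueError):
            higuchi_fd(np.zeros(1000), kmax=1)


def tiny_psd_table():
    return pd.DataFrame(
        {
            "subject_id": ["A", "A", "B", "B"],
            "PSD:Fz:alpha": [150.0, 100.0, 20.0, 30.0],
            "PSD:Fz:beta": [10.0, 11.0, 12.0, 13.0],
        }
    )


class TestScreening:
    def test_value_above_threshold_flagged(self):
        flags = screen_bad_psd(tiny_psd_table(), threshold=100.0)
        assert len(flags) == 1
        assert flags.iloc[0]["psd_value"] == 150.0
        assert flags.iloc[0]["electrode"] == "Fz"

    def test_value_exactly_at_threshold_not_flagged(self):
        flags = screen_bad_psd(tiny_psd_table(), threshold=150.0)
        assert flags.empty

    def test_clean_table_gives_empty_flags(self):
        flags = screen_bad_psd(tiny_psd_table(), threshold=1000.0)
        assert flags.empty


class TestExclusions:
    @staticmethod
    def _table_with_flag_fraction(frac, n_rows=50):
        """Subject A has `frac` of its PSD entries flagged; B is clean."""
        n_bad = int(round(frac * n_rows * 2))  # 2 PSD columns
        col = np.full(n_rows, 10.0)
        col[: min(n_bad, n_rows)] = 500.0
        col2 = np.full(n_rows, 10.0)
        if n_bad > n_rows:
            col2[: n_bad - n_rows] = 500.0
        table = pd.DataFrame(
            {
                "subject_id": ["A"] * n_rows + ["B"] * n_rows,
                "PSD:Fz:alpha": np.concatenate([col, np.full(n_rows, 10.0)]),
                "PSD:Cz:alpha": np.concatenate([col2, np.full(n_rows, 10.0)]),
            }
        )
        return table

    def test_fraction_above_quarter_drops_subject(self):
        table = self._table_with_flag_fraction(0.26)
        flags = screen_bad_psd(table)
        out, log = apply_exclusions(flags, table)
        assert "A" not in out["subject_id"].values
        assert "B" in out["subject_id"].values

    def test_fraction_exactly_quarter_retained(self):
        table = self._table_with_flag_fraction(0.25)
        flags = screen_bad_psd(table)
        out, _ = apply_exclusions(flags, table)
        assert "A" in out["subject_id"].values
        # but the flagged electrode's PSDs are masked for that subject
        assert out.loc[out["subject_id"] == "A", "PSD:Fz:alpha"].isna().all()
        assert out.loc[out["subject_id"] == "B", "PSD:Fz:alpha"].notna().all()

    def test_no_flags_leaves_table_unchanged(self):
        table = tiny_psd_table()
        out, log = apply_exclusions(screen_bad_psd(table, threshold=1e6), table)
        pd.testing.assert_frame_equal(out, table)
        assert log.empty


class TestAsymmetry:
    def test_left_minus_right(self):
        table = pd.DataFrame({"FD:F3": [5.0], "FD:F4": [3.0]})
        out = asymmetry_augment(table, (("F3", "F4"),))
        assert out["dASYM:F3-F4"].iloc[0] == 2.0

    def test_identical_hemispheres_give_zero(self):
        table = pd.DataFrame({"FD:F3": [1.5], "FD:F4": [1.5]})
        out = asymmetry_augment(table, (("F3", "F4"),))
        assert out["dASYM:F3-F4"].iloc[0] == 0.0

    def test_unknown_electrode_raises(self):
        table = pd.DataFrame({"FD:F3": [1.5]})
        with pytest.raises(KeyError):
            asymmetry_augment(table, (("F3", "F4"),))

    def test_five_pairs_on_twelve_electrodes_give_17_fd_columns(self, music_table):
        assert len(fd_feature_columns(music_table)) == 17


def make_window(start_sample, length=1000, rate=250.0):
    return Window("r", start_sample, length, np.zeros((1, length)), rate, ("Cz",))


class TestLabeling:
    def test_majority_wins(self):
        ann = pd.DataFrame(
            {"t": [0.0, 3.0], "arousal": [0.8, -0.8], "valence": [0.5, 0.5]}
        )
        labels = label_windows(ann, [make_window(0)], "positivity")
        assert labels["arousal_class"].iloc[0] == "high"  # 3 s high vs 1 s low
        assert labels["valence_class"].iloc[0] == "positive"

    def test_uniform_annotation(self):
        ann = pd.DataFrame({"t": [0.0], "arousal": [-0.2], "valence": [0.9]})
        labels = label_windows(ann, [make_window(0), make_window(1000)], "positivity")
        assert (labels["arousal_class"] == "low").all()
        assert (labels["valence_class"] == "positive").all()

    def test_exact_tie_goes_to_earlier_annotation(self):
        ann = pd.DataFrame(
            {"t": [0.0, 2.0], "arousal": [0.5, -0.5], "valence": [-0.5, 0.5]}
        )
        labels = label_windows(ann, [make_window(0)], "positivity")
        assert labels["arousal_class"].iloc[0] == "high"
        assert labels["valence_class"].iloc[0] == "negative"

    def test_zero_annotation_is_not_positive(self):
        ann = pd.DataFrame({"t": [0.0], "arousal": [0.0], "valence": [0.0]})
        labels = label_windows(ann, [make_window(0)], "positivity")
        assert labels["arousal_class"].iloc[0] == "low"
        assert labels["valence_class"].iloc[0] == "negative"

    def test_uncovered_window_raises(self):
        ann = pd.DataFrame({"t": [8.0], "arousal": [0.5], "valence": [0.5]})
        with pytest.raises(LabelingError):
            label_windows(ann, [make_window(0)], "positivity")

    def test_single_trial_rating_inherited_by_every_window(self):
        labels = label_windows((6.0, 3.0), [make_window(0), make_window(1000)], "deap45")
        assert (labels["valence_class"] == "positive").all()  # 6.0 > 4.5
        assert (labels["arousal_class"] == "low").all()  # 3.0 <= 4.5


class TestAssembledTable:
    def test_music_feature_counts(self, music_table):
        assert len(fd_feature_columns(music_table)) == 12 + 5
        assert len(psd_feature_columns(music_table)) == (12 + 5) * 5

    def test_video_feature_counts(self, video_table):
        assert len(fd_feature_columns(video_table)) == 32 + 14
        assert len(psd_feature_columns(video_table)) == (32 + 14) * 4

    def test_no_missing_values(self, music_table, video_table):
        assert not music_table.isna().any().any()
        assert not video_table.isna().any().any()

    def test_every_window_labeled_on_both_axes(self, music_table):
        assert music_table["arousal_class"].isin(["low", "high"]).all()
        assert music_table["valence_class"].isin(["negative", "positive"]).all()

    def test_video_score_three_is_high_familiarity(self, video_table):
        rows = video_table[video_table["familiarity"] == 3]
        assert not rows.empty
        assert (rows["familiarity_group"] == "high").all()

    def test_mixed_montages_rejected(self, music_recs, video_recs):
        with pytest.raises(ValueError):
            assemble_feature_table(
                [music_recs[0], video_recs[0]], FeatureConfig("music12")
            )

    def test_column_count_formula_for_custom_pairs(self, music_recs):
        config = FeatureConfig("music12", pairs=(("F3", "F4"), ("C3", "C4")))
        table = assemble_feature_table(music_recs[:2], config)
        assert len(fd_feature_columns(table)) == 12 + 2
        assert len(psd_feature_columns(table)) == (12 + 2) * 5
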