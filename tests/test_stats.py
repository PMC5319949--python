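"""Replication balancing, two-way ANOVA, paired tests, ratio screen."""

import numpy as np
import pytest
from scipy import stats as sps

from eegfam import balance_replications, familiarity_ratio_screen, paired_connectivity_test, two_way_anova
from eegfam.stats import DesignError


def hand_anova(data):
    """Independent sums-of-squares decomposition for a balanced design."""
    gm = data["value"].mean()
    ss_a = sum(len(g) * (g["value"].mean() - gm) ** 2 for _, g in data.groupby("familiarity"))
    ss_b = sum(len(g) * (g["value"].mean() - gm) ** 2 for _, g in data.groupby("subject"))
    ss_cells = sum(
        len(g) * (g["value"].mean() - gm) ** 2
        for _, g in data.groupby(["familiarity", "subject"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = sum(
        ((g["value"] - g["value"].mean()) ** 2).sum()
        for _, g in data.groupby(["familiarity", "subject"])
    )
    a = data["familiarity"].nunique()
    b = data["subject"].nunique()
    r = len(data) // (a * b)
    ms_e = ss_e / (a * b * (r - 1))
    return {
        "ss": (ss_a, ss_b, ss_ab, ss_e),
        "f_a": (ss_a / (a - 1)) / ms_e,
        "f_b": (ss_b / (b - 1)) / ms_e,
        "f_ab": (ss_ab / ((a - 1) * (b - 1))) / ms_e,
    }


def random_cells(rng, n_subjects=4, size_range=(5, 9), shift=0.0):
    cells = {}
    for fam in ("low", "high"):
        for s in range(n_subjects):
            n = int(rng.integers(*size_range))
            mu = (shift if fam == "high" else 0.0) + 0.5 * s
            cells[(fam, f"S{s}")] = rng.normal(mu, 1.0, n)
    return cells


class TestBalancing:
    def test_minimum_cell_size_rule(self, rng):
        cells = {
            ("low", "S1"): rng.normal(size=8),
            ("low", "S2"): rng.normal(size=5),
            ("high", "S1"): rng.normal(size=7),
            ("high", "S2"): rng.normal(size=6),
        }
        design = balance_replications(cells, seed=0)
        assert design.r == 5
        assert (design.data.groupby(["familiarity", "subject"]).size() == 5).all()

    def test_equal_cells_preserved_as_multiset(self, rng):
        cells = {("low", "S1"): [1.0, 2.0, 3.0], ("high", "S1"): [4.0, 5.0, 6.0]}
        design = balance_replications(cells, seed=3)
        low = sorted(design.data[design.data["familiarity"] == "low"]["value"])
        assert low == [1.0, 2.0, 3.0]

    def test_same_seed_gives_identical_subsample(self, rng):
        cells = random_cells(rng)
        d1 = balance_replications(cells, seed=42)
        d2 = balance_replications(cells, seed=42)
        assert d1.data.equals(d2.data)

    def test_empty_cell_names_the_cell(self):
        with pytest.raises(DesignError, match="S2"):
            balance_replications({("low", "S1"): [1.0], ("high", "S2"): []})


class TestTwoWayAnova:
    def test_matches_hand_computed_sums_of_squares(self, rng):
        cells = {
            ("low", "S1"): [1.0, 2.0, 3.0],
            ("low", "S2"): [2.0, 3.0, 4.0],
            ("high", "S1"): [2.0, 2.0, 4.0],
            ("high", "S2"): [5.0, 4.0, 6.0],
        }
        design = balance_replications(cells, seed=0)
        out = two_way_anova(design)
        oracle = hand_anova(design.data)
        assert out.f_familiarity == pytest.approx(oracle["f_a"], abs=1e-9)
        assert out.f_subject == pytest.approx(oracle["f_b"], abs=1e-9)
        assert out.f_interaction == pytest.approx(oracle["f_ab"], abs=1e-9)
        assert out.dof == {"familiarity": 1, "subject": 1, "interaction": 1, "error": 8}

    def test_sum_of_squares_identity_on_random_designs(self, rng):
        for _ in range(10):
            design = balance_replications(random_cells(rng), seed=1)
            ss_a, ss_b, ss_ab, ss_e = hand_anova(design.data)["ss"]
            ss_tot = ((design.data["value"] - design.data["value"].mean()) ** 2).sum()
            assert ss_tot == pytest.approx(ss_a + ss_b + ss_ab + ss_e, abs=1e-9)

    def test_injected_shift_detected_and_directed(self, rng):
        design = balance_replications(
            random_cells(rng, n_subjects=6, size_range=(20, 25), shift=1.0), seed=0
        )
        out = two_way_anova(design)
        assert out.p_familiarity < 0.001
        assert out.high_greater
        assert out.tukey is not None  # 6 subject levels, strong subject effect

    def test_permutation_destroys_familiarity_effect(self, rng):
        cells = random_cells(rng, n_subjects=5, size_range=(12, 15), shift=1.0)
        design = balance_replications(cells, seed=0)
        assert two_way_anova(design).p_familiarity < 0.01
        rejections = 0
        n_perm = 60
        for i in range(n_perm):
            data = design.data.copy()
            for s, grp in data.groupby("subject"):
                data.loc[grp.index, "familiarity"] = rng.permutation(
                    grp["familiarity"].to_numpy()
                )
            perm = balance_replications(
                {
                    (fam, s): g["value"].to_numpy()
                    for (fam, s), g in data.groupby(["familiarity", "subject"])
                },
                seed=i,
            )
            rejections += two_way_anova(perm, post_hoc=False).p_familiarity < 0.05
        assert rejections / n_perm <= 0.15  # back to ~nominal alpha

    def test_single_replication_rejected(self):
        with pytest.raises(DesignError):
            two_way_anova(
                balance_replications(
                    {("low", "S1"): [1.0], ("high", "S1"): [2.0]}, seed=0
                )
            )


class TestPairedTest:
    def test_identical_vectors_degenerate_null(self):
        out = paired_connectivity_test([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert out.t == 0.0 and out.p == 1.0 and out.degenerate

    def test_constant_difference_gives_infinite_t(self):
        out = paired_connectivity_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(out.t) and out.t > 0
        assert out.degenerate and out.direction == "high"

    def test_equals_one_sample_t_on_differences(self, rng):
        low = rng.normal(0.3, 0.1, 12)
        high = rng.normal(0.5, 0.1, 12)
        out = paired_connectivity_test(low, high)
        ref = sps.ttest_1samp(high - low, 0.0)
        assert out.t == pytest.approx(ref.statistic, abs=1e-12)
        assert out.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_direction_reflects_larger_stratum(self, rng):
        out = paired_connectivity_test([0.8, 0.9, 0.7], [0.2, 0.1, 0.3])
        assert out.direction == "low"


class TestTableDrivers:
    def test_anova_scan_covers_every_psd_column(self, music_table):
        from eegfam import familiarity_anova_scan

        scan = familiarity_anova_scan(music_table)
        # only plain per-electrode PSD columns enter the scan
        n_psd = sum(c.startswith("PSD:") for c in music_table.columns)
        assert len(scan) == n_psd == 60
        assert scan["p"].between(0, 1).all()
        assert set(scan["band"]) == {"delta", "theta", "alpha", "beta", "gamma"}

    def test_connectivity_contrast_recovers_injected_direction(self):
        import eegfam
        from eegfam import connectivity_contrast_table
        from eegfam.connectivity import connectivity_matrix
        from eegfam.preprocess import bands_for
        import pandas as pd

        spec = eegfam.SessionSpec.music12(
            n_subjects=3, n_stimuli_per_subject=4, stimulus_duration=16.0,
            coupling_effect_map=(eegfam.CouplingEffect(("F3", "F4"), "gamma", 0.8, 0.2),),
            emotion_coupling=None, seed=8,
        )
        frames = [
            connectivity_matrix(rec, bands_for("music12")[4:], ("psi",),
                                pairs=(("F3", "F4"),), geometry="music12")
            for rec in eegfam.simulate_session(spec)
        ]
        contrast = connectivity_contrast_table(pd.concat(frames, ignore_index=True))
        assert len(contrast) == 1
        row = contrast.iloc[0]
        assert row["direction"] == "high" and row["p"] < 0.05


class TestRatioScreen:
    def test_imbalanced_subject_dropped(self):
        keep, reason = familiarity_ratio_screen(37, 3)
        assert not keep and "0.081" in reason

    def test_balanced_subject_kept(self):
        assert familiarity_ratio_screen(28, 12)[0]

    def test_equal_counts_kept(self):
        assert familiarity_ratio_screen(10, 10)[0]

    def test_no_reports_dropped_with_reason(self):
        keep, reason = familiarity_ratio_screen(0, 0)
        assert not keep and "no familiarity" in reason
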