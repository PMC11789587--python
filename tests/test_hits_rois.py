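"""Hit ranking, extreme-group statistics, ROI classes, and translation comparison."""

import numpy as np
import pandas as pd
import pytest

from dogscreen.hits_rois import (
    classify_rois,
    compact_letter_display,
    compare_extremes,
    compare_screen_vs_translation,
    rank_hits,
    sidak_adjust,
    tukey_pairwise,
)


def _table(values, dogs=None):
    n = len(values)
    return pd.DataFrame(
        dict(
            dog=dogs if dogs is not None else ["S-W"] * n,
            col=np.arange(n) % 7,
            row=np.arange(n) // 7,
            density=np.linspace(50, 300, n),
            median_ctcf_asma=values,
        )
    )


class TestRankHits:
    def test_sorted_ascending_and_permutation(self):
        rk = rank_hits(_table([3.0, 1.0, 2.0]), "median_ctcf_asma")
        assert list(rk.table["median_ctcf_asma"]) == [1.0, 2.0, 3.0]
        assert list(rk.table["rank"]) == [1, 2, 3]

    def test_extreme_groups_disjoint(self):
        rk = rank_hits(_table([5.0, 2.0, 9.0, 1.0, 7.0, 3.0]), "median_ctcf_asma", k=2)
        low = set(rk.lowest()["median_ctcf_asma"])
        high = set(rk.highest()["median_ctcf_asma"])
        assert low == {1.0, 2.0} and high == {7.0, 9.0}
        assert not low & high

    def test_ties_broken_deterministically(self):
        vals = [2.0, 1.0, 2.0, 2.0, 1.0]
        t = _table(vals, dogs=["T-W", "S-W", "S-W", "T-S", "T-W"])
        a = rank_hits(t, "median_ctcf_asma").table
        b = rank_hits(t.sample(frac=1.0, random_state=3), "median_ctcf_asma").table
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_missing_excluded_all_missing_errors(self):
        t = _table([1.0, np.nan, 2.0])
        assert len(rank_hits(t, "median_ctcf_asma").table) == 2
        with pytest.raises(ValueError):
            rank_hits(_table([np.nan, np.nan]), "median_ctcf_asma")


class TestCompareExtremes:
    def test_identical_groups_fold_one(self):
        vals = [2.0] * 8  # lowest and highest groups coincide
        rk = rank_hits(_table(vals), "median_ctcf_asma", k=4)
        comp = compare_extremes(rk)
        assert comp.fold_change == pytest.approx(1.0)
        assert comp.p_value > 0.9

    def test_planted_extremes_exceed_fifteen_fold(self, sim_merged):
        """Ground-truth-quantified screen reproduces the planted dynamic range."""
        rk = rank_hits(sim_merged, "median_ctcf_asma", k=50)
        comp = compare_extremes(rk)
        assert comp.fold_change >= 15.0
        assert comp.p_value < 1e-10

    def test_two_way_anova_variant(self, sim_merged):
        rk = rank_hits(sim_merged, "median_ctcf_asma", k=50)
        comp = compare_extremes(rk, method="anova2")
        assert comp.p_value < 1e-10
        assert "ANOVA" in comp.method

    def test_nonpositive_low_mean_fold_undefined(self):
        vals = [-3.0, -2.0, -1.0, 5.0, 6.0, 7.0]
        rk = rank_hits(_table(vals), "median_ctcf_asma", k=3)
        assert compare_extremes(rk).fold_change is None

    def test_k_too_large_rejected(self):
        rk = rank_hits(_table([1.0, 2.0, 3.0]), "median_ctcf_asma", k=2)
        with pytest.raises(ValueError):
            compare_extremes(rk)

    def test_null_type_one_error_calibrated(self):
        """Welch comparison of two same-distribution groups rejects ~5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            vals = rng.normal(100.0, 20.0, size=40)
            rk = rank_hits(_table(vals), "median_ctcf_asma", k=20)
            # split at random, not by rank, to simulate the null
            a, b = vals[:20], vals[20:]
            from scipy import stats

            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        base = rng.normal(100.0, 10.0, size=50)
        shifted = rng.normal(100.0 + 5 * 10.0, 10.0, size=50)
        vals = np.concatenate([base, shifted])
        rk = rank_hits(_table(vals), "median_ctcf_asma", k=50)
        assert compare_extremes(rk).p_value < 1e-6


class TestClassifyRois:
    def test_tier_definitions_with_explicit_cutpoints(self):
        t = pd.DataFrame(
            dict(
                dog=["S-W"] * 4, col=range(4), row=[0] * 4,
                density=[10.0, 90.0, 90.0, 50.0],
                median_ctcf_asma=[5.0, 50.0, 95.0, 50.0],
            )
        )
        out, candidates, thr = classify_rois(
            t, density_cutpoints=(30.0, 70.0), ctcf_cutpoints=(30.0, 70.0)
        )
        assert list(out["roi_class"]) == [
            "low_density_low_asma",
            "high_density_mid_asma",
            "high_density_high_asma",
            "unclassified",
        ]
        assert thr["density_cutpoints"] == (30.0, 70.0)

    def test_degenerate_cutpoints_rejected(self):
        t = _table([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="cutpoints"):
            classify_rois(t, density_cutpoints=(5.0, 5.0))

    def test_mid_asma_candidates_are_hydrophilic(self, sim_merged):
        """Adhesion-supporting, moderate-marker hits live on the hydrophilic side."""
        out, candidates, _ = classify_rois(sim_merged, n_candidates=3)
        mid = candidates[candidates["roi_class"] == "high_density_mid_asma"]
        assert len(mid) > 0
        assert (mid["wca_deg"] < 70.0).all()


class TestAdjustmentsAndLetters:
    def test_sidak_at_least_raw(self):
        p = np.array([0.001, 0.02, 0.5, 0.9])
        adj = sidak_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_tukey_at_least_raw_pairwise(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(m, 1.0, 10) for m in (0.0, 0.5, 3.0)])
        groups = np.repeat(["a", "b", "c"], 10)
        tab = tukey_pairwise(vals, groups)
        assert (tab["p-adj"] >= 0).all() and (tab["p-adj"] <= 1).all()

    def test_identical_groups_share_a_letter(self):
        letters = compact_letter_display(
            ["a", "b"], {frozenset(("a", "b")): 0.99}, alpha=0.05
        )
        assert set(letters["a"]) & set(letters["b"])

    def test_different_groups_get_distinct_letters(self):
        letters = compact_letter_display(
            ["a", "b"], {frozenset(("a", "b")): 0.001}, alpha=0.05
        )
        assert not (set(letters["a"]) & set(letters["b"]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_letters_consistent_with_pairwise_tests(self, seed):
        """Groups share a letter iff their adjusted p-value exceeds alpha."""
        rng = np.random.default_rng(seed)
        means = rng.uniform(0, 6, size=5)
        vals = np.concatenate([rng.normal(m, 1.0, 12) for m in means])
        groups = list("abcde")
        labels = np.repeat(groups, 12)
        tab = tukey_pairwise(vals, labels)
        pairs = {
            frozenset((r["group1"], r["group2"])): float(r["p-adj"])
            for _, r in tab.iterrows()
        }
        letters = compact_letter_display(groups, pairs, alpha=0.05)
        for pair, p in pairs.items():
            g1, g2 = sorted(pair)
            share = bool(set(letters[g1]) & set(letters[g2]))
            assert share == (p > 0.05), (g1, g2, p, letters)


class TestScreenVsTranslation:
    def _roi_data(self, shift_sd=0.0, seed=0, n_roi=6):
        rng = np.random.default_rng(seed)
        rows_s, rows_t = [], []
        for roi in range(1, n_roi + 1):
            mu, sd = 1000.0 * roi, 150.0
            for v in rng.normal(mu, sd, 6):
                rows_s.append(dict(roi=f"ROI{roi}", median_ctcf_asma=v, density=50.0 * roi))
            for v in rng.normal(mu + shift_sd * sd, sd, 5):
                rows_t.append(dict(roi=f"ROI{roi}", median_ctcf_asma=v, density=50.0 * roi))
        return pd.DataFrame(rows_s), pd.DataFrame(rows_t)

    def test_matched_translation_not_flagged(self):
        """Translation drawn from the screen's distribution: contrasts stay null."""
        flagged = total = 0
        for seed in range(5):
            scr, tra = self._roi_data(0.0, seed)
            res = compare_screen_vs_translation(scr, tra, responses=("median_ctcf_asma",))
            tab = res["median_ctcf_asma"]["screen_vs_translation"]
            flagged += int(tab["significant"].sum())
            total += len(tab)
        assert flagged / total <= 0.05

    def test_large_shift_detected(self):
        scr, tra = self._roi_data(shift_sd=5.0, seed=1)
        res = compare_screen_vs_translation(scr, tra, responses=("median_ctcf_asma",))
        tab = res["median_ctcf_asma"]["screen_vs_translation"]
        assert tab["significant"].all()

    def test_letters_and_anova_outputs_present(self):
        scr, tra = self._roi_data(0.0, 2)
        res = compare_screen_vs_translation(scr, tra, responses=("median_ctcf_asma",))
        entry = res["median_ctcf_asma"]
        assert "anova2" in entry and "one_way" in entry
        letters = entry["one_way"]["letters"]
        assert set(letters) == {f"ROI{i}" for i in range(1, 7)}
        # well-separated ROI means: no two ROIs share a letter
        assert len({v for v in letters.values()}) == 6

    def test_small_group_skipped_with_warning(self):
        scr, tra = self._roi_data(0.0, 3)
        tra = tra[~((tra["roi"] == "ROI1") & (tra.index > tra.index[0]))]
        with pytest.warns(UserWarning, match="ROI1"):
            compare_screen_vs_translation(scr, tra, responses=("median_ctcf_asma",))
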