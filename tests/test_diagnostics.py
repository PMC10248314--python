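"""Confusion metrics, sweeps, AUC, likelihood ratios, effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from erdodi import (
    ConfusionCounts,
    FailDirection,
    auc_mann_whitney,
    base_rate_fail,
    chi2_rxc,
    classification_metrics,
    cohens_d,
    confusion_at_cutoff,
    likelihood_ratio,
    lr_profile_vs_zero,
    phi_squared,
    range_br_analysis,
    roc_sweep,
)
from erdodi.formatting import round_half_away


def pairwise_auc(pos, neg):
    """Exhaustive pairwise oracle: mean of win=1 / tie=.5 / loss=0."""
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_hand_counted_at_or_above(self):
        c = confusion_at_cutoff([0, 5, 2, 7], [False, True, False, True], 4)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_below_cutoff_flags_none(self):
        c = confusion_at_cutoff([0, 1, 2], [True, False, False], 10)
        assert (c.tp, c.fp) == (0, 0)
        assert (c.fn, c.tn) == (1, 2)

    def test_hand_counted_at_or_below(self):
        c = confusion_at_cutoff([45, 50], [True, False], 45, "at_or_below")
        assert (c.tp, c.tn) == (1, 1)

    def test_length_mismatch_and_empty_raise(self):
        with pytest.raises(ValueError):
            confusion_at_cutoff([1, 2], [True], 1)
        with pytest.raises(ValueError):
            confusion_at_cutoff([], [], 1)


class TestMetrics:
    def test_perfect_separation(self):
        m = classification_metrics(ConfusionCounts(tp=2, fp=0, tn=2, fn=0))
        assert (m.sensitivity, m.specificity, m.occ) == (1.0, 1.0, 1.0)

    def test_arithmetic(self):
        m = classification_metrics(ConfusionCounts(tp=13, fp=3, tn=27, fn=7))
        assert m.sensitivity == pytest.approx(0.65)
        assert m.specificity == pytest.approx(0.90)
        assert m.occ == pytest.approx(0.80)
        assert m.br_fail == pytest.approx(16 / 50)

    def test_degenerate_margins_raise(self):
        with pytest.raises(ZeroDivisionError):
            classification_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        tn=st.integers(0, 30), fn=st.integers(0, 30),
    )
    @settings(max_examples=200, deadline=None)
    def test_occ_identity(self, tp, fp, tn, fn):
        """occ = sens * prevalence + spec * (1 - prevalence)."""
        c = ConfusionCounts(tp, fp, tn, fn)
        if c.n_positive == 0 or c.n_negative == 0:
            return
        m = classification_metrics(c)
        prev = c.n_positive / c.n
        assert m.occ == pytest.approx(
            m.sensitivity * prev + m.specificity * (1 - prev)
        )


class TestBaseRate:
    def test_hand_count(self):
        assert base_rate_fail([0, 1, 4, 6], 4) == pytest.approx(0.5)

    def test_cutoff_below_minimum_flags_everyone(self):
        assert base_rate_fail([3, 9, 5], 0) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            base_rate_fail([], 1)


class TestSweep:
    def test_monotone_tradeoff_on_toy_cohort(self):
        scores = [0, 1, 1, 2, 3, 4, 5, 6]
        truth = [False, False, False, False, True, True, True, True]
        table = roc_sweep(scores, truth, [1, 2, 3, 4])
        assert (np.diff(table["sensitivity"]) <= 1e-12).all()
        assert (np.diff(table["specificity"]) >= -1e-12).all()
        assert (np.diff(table["br_fail"]) <= 1e-12).all()

    def test_single_cutoff_matches_direct_calls(self):
        scores, truth = [0, 5, 2, 7], [False, True, False, True]
        row = roc_sweep(scores, truth, [4]).iloc[0]
        m = classification_metrics(confusion_at_cutoff(scores, truth, 4))
        assert row["sensitivity"] == m.sensitivity
        assert row["occ"] == m.occ

    def test_single_class_truth_raises(self):
        with pytest.raises(ZeroDivisionError):
            roc_sweep([1, 2], [True, True], [1])

    @given(
        scores=st.lists(st.integers(0, 10), min_size=6, max_size=30),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity_is_exact_for_any_scores(self, scores, seed):
        rng = np.random.default_rng(seed)
        truth = rng.random(len(scores)) < 0.5
        if truth.all() or not truth.any():
            return
        table = roc_sweep(scores, truth, list(range(0, 12)))
        assert (np.diff(table["sensitivity"]) <= 1e-12).all()
        assert (np.diff(table["specificity"]) >= -1e-12).all()


class TestAuc:
    def test_identical_distributions_give_half(self):
        est = auc_mann_whitney([1, 2, 3, 1, 2, 3],
                               [True, True, True, False, False, False])
        assert est.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        est = auc_mann_whitney([5, 6, 1, 2], [True, True, False, False])
        assert est.auc == 1.0
        assert est.ci_high <= 1.0

    def test_brute_force_nine_pair_example(self):
        scores = [3, 5, 5, 1, 5, 2]
        truth = [True, True, True, False, False, False]
        expected = pairwise_auc([3, 5, 5], [1, 5, 2])
        assert auc_mann_whitney(scores, truth).auc == pytest.approx(expected)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2], [True, True])

    def test_at_or_below_direction_flips_orientation(self):
        scores = [45, 40, 50, 48]
        truth = [True, True, False, False]
        est = auc_mann_whitney(scores, truth, "at_or_below")
        assert est.auc == 1.0

    @given(data=st.data(), n=st.integers(2, 8))
    @settings(max_examples=150, deadline=None)
    def test_equals_exhaustive_oracle_on_small_cohorts(self, data, n):
        scores = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
        truth = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda t: any(t) and not all(t)
            )
        )
        pos = [s for s, t in zip(scores, truth) if t]
        neg = [s for s, t in zip(scores, truth) if not t]
        assert auc_mann_whitney(scores, truth).auc == pytest.approx(
            pairwise_auc(pos, neg)
        )

    def test_matches_trapezoidal_roc_area_on_random_cohorts(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(10, 60)
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            scores = rng.integers(0, 15, size=n) + truth * rng.integers(0, 6, n)
            est = auc_mann_whitney(scores, truth)
            assert est.auc == pytest.approx(roc_auc_score(truth, scores))

    def test_hanley_mcneil_interval_brackets_auc(self):
        rng = np.random.default_rng(3)
        truth = rng.random(100) < 0.3
        scores = rng.normal(size=100) + truth * 1.5
        est = auc_mann_whitney(scores, truth)
        assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0
        assert est.se > 0


class TestLikelihoodRatios:
    def test_published_band_ratios(self):
        # Borderline/Pass and Fail/Pass ratios from printed base rates
        assert round_half_away(likelihood_ratio(36.3, 6.9), 2) == 5.26
        assert round_half_away(likelihood_ratio(82.9, 6.9), 1) == 12.0

    def test_equal_rates_give_unity(self):
        assert likelihood_ratio(0.25, 0.25) == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            likelihood_ratio(0.5, 0.0)


class TestRangeBrAnalysis:
    def _bands(self, n_pass, n_bord, n_fail):
        return (["Pass"] * n_pass + ["Borderline"] * n_bord + ["Fail"] * n_fail)

    def test_planted_band_rates_recovered(self):
        """Plant 5% / 25% / 60% failure rates; recover LR F/P = 12."""
        rng = np.random.default_rng(0)
        sizes, rates = (2000, 2000, 2000), (0.05, 0.25, 0.60)
        bands, fails = [], []
        for band, n, r in zip(["Pass", "Borderline", "Fail"], sizes, rates):
            bands += [band] * n
            k = int(round(n * r))  # exact planted counts
            fails += [True] * k + [False] * (n - k)
        table = range_br_analysis(bands, {"crit": fails})
        assert table.br.loc["crit", "Pass"] == pytest.approx(0.05)
        assert table.lr.loc["crit", "F/P"] == pytest.approx(12.0)

    def test_identical_rates_give_unit_lrs(self):
        bands = self._bands(4, 4, 4)
        fails = [True, False, False, False] * 3
        table = range_br_analysis(bands, {"a": fails, "b": fails})
        assert np.allclose(table.lr.loc[["a", "b"]].to_numpy(), 1.0)

    def test_lr_multiplicativity(self):
        rng = np.random.default_rng(1)
        bands = self._bands(50, 30, 20)
        fails = rng.random(100) < np.repeat([0.1, 0.3, 0.7], [50, 30, 20])
        table = range_br_analysis(bands, {"c": fails})
        row = table.lr.loc["c"]
        assert row["F/P"] == pytest.approx(row["F/B"] * row["B/P"])

    def test_empty_band_raises(self):
        with pytest.raises(ValueError):
            range_br_analysis(self._bands(3, 0, 3), {"c": [True] * 6})

    def test_mean_lr_row_from_published_pass_borderline_rates(self):
        """Six criteria at their printed Pass/Borderline/Fail base rates."""
        printed = {
            "WMT": (12.4, 35.7, 69.1),
            "MSVT": (7.4, 30.6, 58.2),
            "NV-MSVT": (6.7, 26.5, 58.2),
            "TOMM-1": (7.3, 29.3, 41.9),
            "G-3 >=1": (19.1, 48.0, 87.3),
            "G-3 >=2": (6.9, 36.3, 82.9),
        }
        lrs = pd.DataFrame(
            {
                name: {
                    "B/P": likelihood_ratio(b, p),
                    "F/B": likelihood_ratio(f, b),
                    "F/P": likelihood_ratio(f, p),
                }
                for name, (p, b, f) in printed.items()
            }
        ).T
        means = lrs.mean()
        assert round_half_away(means["B/P"], 2) == 3.79
        assert round_half_away(means["F/B"], 2) == 1.93
        assert round_half_away(means["F/P"], 2) == 7.41

    def test_lr_profile_relative_to_zero(self):
        values = [0] * 10 + [1] * 10 + [2] * 10
        fails = [True] * 2 + [False] * 8 + [True] * 4 + [False] * 6 \
            + [True] * 8 + [False] * 2
        prof = lr_profile_vs_zero(values, {"c": fails})
        assert prof.loc[0, "c"] == pytest.approx(1.0)
        assert prof.loc[1, "c"] == pytest.approx(2.0)
        assert prof.loc[2, "c"] == pytest.approx(4.0)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (284.5, 20.4, 237.8, 40.0, 1.47),  # Pass vs Fail contrast
            (284.5, 20.4, 265.1, 33.6, 0.70),  # Pass vs Borderline
            (10.0, 2.0, 10.0, 3.0, 0.0),
        ],
    )
    def test_average_variance_cohens_d(self, m1, s1, m2, s2, expected):
        assert round_half_away(cohens_d(m1, s1, m2, s2), 2) == expected

    def test_pooled_df_variant_differs(self):
        d_avg = cohens_d(284.5, 20.4, 237.8, 40.0)
        d_pool = cohens_d(284.5, 20.4, 237.8, 40.0,
                          pooled_df=True, n1=299, n2=55)
        assert d_pool != pytest.approx(d_avg, abs=0.05)

    def test_non_positive_sd_raises(self):
        with pytest.raises(ValueError):
            cohens_d(1, 0, 2, 1)

    @pytest.mark.parametrize(
        "chi2,n,expected", [(90.0, 452, 0.199), (29.6, 239, 0.124)]
    )
    def test_phi_squared_identity(self, chi2, n, expected):
        assert round_half_away(phi_squared(chi2, n), 3) == expected

    def test_chi2_rxc_matches_hand_computed_2x2(self):
        # [[30, 10], [10, 30]]: expected 20 everywhere, chi2 = 4*100/20 = 20
        assert chi2_rxc([[30, 10], [10, 30]]) == pytest.approx(20.0)

    def test_identical_row_distributions_give_zero(self):
        assert chi2_rxc([[10, 20], [20, 40]]) == pytest.approx(0.0)
        assert phi_squared(chi2_rxc([[10, 20], [20, 40]]), 90) == 0.0

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi2_rxc([[0, 0], [1, 2]])
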