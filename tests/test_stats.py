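import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.inter_rater import cohens_kappa

from coroct import (
    analyze_cohort,
    chisq_2x2,
    diff_ci_wald,
    kruskal_holm,
    sample_size_noninferiority,
    simulate_cohort,
    weighted_kappa,
)
from coroct.cohort import CohortParams
from coroct.stats import holm_adjust, kappa_band, kappa_from_table, proportion_pct

from oracles import holm_bruteforce, pearson_chi2_bruteforce, wald_diff_ci_bruteforce


class TestWaldCI:
    def test_reproduces_published_interval(self):
        res = diff_ci_wald(91, 103, 89, 100, 0.95, margin=0.10)
        assert res.ci_low == pytest.approx(-0.0937, abs=5e-5)
        assert res.ci_high == pytest.approx(0.0807, abs=5e-5)
        assert res.noninferior

    def test_symmetric_when_groups_equal(self):
        res = diff_ci_wald(50, 100, 50, 100)
        assert res.diff == 0.0
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_matches_bruteforce(self):
        res = diff_ci_wald(90, 100, 80, 100, 0.95)
        lo, hi = wald_diff_ci_bruteforce(90, 100, 80, 100, 0.95)
        assert res.ci_low == pytest.approx(lo, rel=1e-12)
        assert res.ci_high == pytest.approx(hi, rel=1e-12)

    def test_degenerate_proportion_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = diff_ci_wald(100, 100, 80, 100)
        assert res.degenerate

    @pytest.mark.parametrize("args", [(5, 0, 3, 10), (11, 10, 3, 10), (-1, 10, 3, 10)])
    def test_invalid_counts(self, args):
        with pytest.raises(ValueError):
            diff_ci_wald(*args)

    @given(x=st.integers(1, 99), n=st.integers(100, 500))
    @settings(max_examples=30, deadline=None)
    def test_same_group_twice_centred_on_zero(self, x, n):
        res = diff_ci_wald(x, n, x, n)
        assert res.diff == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high
        assert res.ci_low == pytest.approx(-res.ci_high, rel=1e-12)


class TestSampleSize:
    def test_reproduces_published_design(self):
        res = sample_size_noninferiority(0.92, 0.10, 0.05, 0.80)
        assert res.n_per_group == 91
        assert res.total == 182

    def test_margin_doubled(self):
        res = sample_size_noninferiority(0.92, 0.20, 0.05, 0.80)
        assert res.n_per_group == 23

    def test_ceil_convention_available(self):
        # the unrounded value is 91.007..., so strict rounding-up gives 92
        res = sample_size_noninferiority(0.92, 0.10, 0.05, 0.80, rounding="ceil")
        assert res.n_per_group == 92

    def test_lower_power_needs_fewer(self):
        hi = sample_size_noninferiority(0.92, 0.10, 0.05, 0.80)
        lo = sample_size_noninferiority(0.92, 0.10, 0.05, 0.51)
        assert lo.n_per_group < hi.n_per_group

    @pytest.mark.parametrize("margin", [0.0, -0.1])
    def test_zero_margin_rejected(self, margin):
        with pytest.raises(ValueError):
            sample_size_noninferiority(0.92, margin, 0.05, 0.80)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_rates_in_open_interval(self, bad):
        with pytest.raises(ValueError):
            sample_size_noninferiority(bad, 0.1, 0.05, 0.8)

    @given(
        margins=st.lists(st.floats(0.02, 0.5), min_size=2, max_size=2, unique=True),
        powers=st.lists(st.floats(0.5, 0.99), min_size=2, max_size=2, unique=True),
        rate=st.floats(0.55, 0.98),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_margin_and_power(self, margins, powers, rate):
        m1, m2 = sorted(margins)
        p1, p2 = sorted(powers)
        assert (
            sample_size_noninferiority(rate, m2, 0.05, 0.8).n_per_group
            <= sample_size_noninferiority(rate, m1, 0.05, 0.8).n_per_group
        )
        assert (
            sample_size_noninferiority(rate, 0.1, 0.05, p1).n_per_group
            <= sample_size_noninferiority(rate, 0.1, 0.05, p2).n_per_group
        )


class TestChiSquared:
    def test_reproduces_published_p(self):
        _, p = chisq_2x2(91, 12, 89, 11)
        assert round(p, 3) == 0.884

    def test_identical_rows(self):
        stat, p = chisq_2x2(10, 10, 10, 10)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_bruteforce_and_scipy(self):
        stat, p = chisq_2x2(44, 11, 47, 16)
        bstat, bp = pearson_chi2_bruteforce(44, 11, 47, 16)
        assert stat == pytest.approx(bstat, rel=1e-12)
        assert p == pytest.approx(bp, rel=1e-12)
        sstat, sp, _, _ = sps.chi2_contingency([[44, 11], [47, 16]], correction=False)
        assert stat == pytest.approx(sstat, rel=1e-12)
        assert p == pytest.approx(sp, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chisq_2x2(0, 0, 5, 5)


class TestProportions:
    def test_rates(self):
        assert proportion_pct(89, 100) == 89.0
        assert proportion_pct(1220, 1441) == 84.7

    def test_half_up(self):
        assert proportion_pct(5, 8, 0) == 63.0  # 62.5 rounds up


class TestWeightedKappa:
    def test_identical_ratings(self):
        res = weighted_kappa([1, 2, 3, 4, 2, 3], [1, 2, 3, 4, 2, 3])
        assert res.kappa == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        r1 = rng.integers(1, 5, size=10_000)
        r2 = rng.integers(1, 5, size=10_000)
        res = weighted_kappa(r1, r2)
        assert abs(res.kappa) < 0.03  # ~3 SE of the chance-level estimate

    def test_band_mapping(self):
        assert kappa_band(0.70) == "substantial"
        assert kappa_band(-0.2) == "poor"
        assert kappa_band(0.10) == "slight"
        assert kappa_band(0.305) == "fair"
        assert kappa_band(0.55) == "moderate"
        assert kappa_band(0.90) == "excellent"

    @pytest.mark.parametrize("weights,wt", [("linear", "linear"), ("quadratic", "quadratic")])
    def test_matches_statsmodels(self, weights, wt):
        rng = np.random.default_rng(3)
        r1 = rng.integers(1, 5, size=400)
        shift = rng.integers(-1, 2, size=400)
        r2 = np.clip(r1 + shift, 1, 4)
        res = weighted_kappa(r1, r2, weights=weights)
        table = np.zeros((4, 4))
        for a, b in zip(r1, r2):
            table[a - 1, b - 1] += 1
        expected = cohens_kappa(table, wt=f"{wt}" if wt == "quadratic" else "ca").kappa
        assert res.kappa == pytest.approx(expected, rel=1e-9)

    def test_constant_ratings_rejected(self):
        with pytest.raises(ValueError, match="constant|undefined"):
            weighted_kappa([2, 2, 2], [2, 2, 2])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_kappa([1, 2], [1, 2, 3])

    def test_table_validation(self):
        with pytest.raises(ValueError):
            kappa_from_table(np.zeros((3, 3)))


class TestHolm:
    def test_hand_stepped_example(self):
        # sorted: .01*3=.03; .03*2=.06; .04*1=.04 -> monotone => .06
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 8))
            assert holm_adjust(p) == pytest.approx(holm_bruteforce(p))

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_dominance(self, p):
        adj = holm_adjust(p)
        bonf = [min(1.0, v * len(p)) for v in p]
        for raw, a, b in zip(p, adj, bonf):
            assert raw <= a + 1e-12
            assert a <= b + 1e-12
            assert a <= 1.0


class TestKruskalHolm:
    def test_identical_groups(self):
        with pytest.warns(UserWarning, match="identical"):
            h, p, pairwise = kruskal_holm({"a": [1, 1, 1], "b": [1, 1, 1]})
        assert h == 0.0
        assert p == 1.0
        assert (pairwise["p_holm"] == 1.0).all()

    def test_separated_supports(self):
        groups = {
            "low": list(np.linspace(0, 1, 20)),
            "mid": list(np.linspace(10, 11, 20)),
            "high": list(np.linspace(20, 21, 20)),
        }
        h, p, pairwise = kruskal_holm(groups)
        assert p < 1e-3
        assert pairwise["p_holm"].min() < 1e-3
        assert (pairwise["p_holm"] >= pairwise["p_raw"] - 1e-12).all()

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_holm({"only": [1, 2, 3]})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_holm({"a": [1.0], "b": []})


@pytest.fixture(scope="module")
def small_cohort():
    params = dataclasses.replace(
        CohortParams(),
        n_a=60,
        n_b=60,
        n_score_segments=6,
        seed=17,
    )
    return simulate_cohort(params)


class TestAnalyzeCohort:
    def test_report_structure(self, small_cohort):
        report = analyze_cohort(small_cohort)
        assert set(report.rates["group"]) == {"A", "B"}
        assert {"A", "B"} == set(report.kappa)
        assert len(report.cnr_summary) == 6  # 2 groups x 3 scenarios
        assert (report.segment_scores["p_holm"] >= report.segment_scores["p_raw"] - 1e-12).all()
        assert not report.attenuation_tests.empty

    def test_noninferiority_consistency(self, small_cohort):
        report = analyze_cohort(small_cohort, margin=0.10)
        ni = report.noninferiority
        assert ni.ci_low <= ni.diff <= ni.ci_high
        assert ni.noninferior == (ni.ci_low > -0.10 and ni.ci_high < 0.10)
        summary = report.summary_json()
        assert summary["noninferior"] == ni.noninferior

    def test_kappa_skipped_without_raters(self, small_cohort):
        crippled = dataclasses.replace(
            small_cohort, scores=small_cohort.scores.drop(columns=["rater2"])
        )
        with pytest.warns(UserWarning, match="kappa skipped"):
            report = analyze_cohort(crippled)
        assert report.kappa == {}

    def test_requires_both_groups(self, small_cohort):
        only_a = dataclasses.replace(
            small_cohort,
            patients=small_cohort.patients[small_cohort.patients["group"] == "A"],
        )
        with pytest.raises(ValueError, match="both groups"):
            analyze_cohort(only_a)

    def test_power_sanity_over_seeds(self):
        """The fraction of replicates declaring noninferiority must agree
        with the normal-approximation prediction for the configured truth.

        Declaring requires the whole CI inside +/-margin, i.e. roughly
        |diff_hat| < margin - z*se; predict that probability under
        diff_hat ~ N(d0, se0^2) and allow generous Monte-Carlo slack."""
        margin = 0.10
        base = CohortParams()
        d0 = base.p_diag_a - base.p_diag_b
        se0 = math.sqrt(
            base.p_diag_a * (1 - base.p_diag_a) / base.n_a
            + base.p_diag_b * (1 - base.p_diag_b) / base.n_b
        )
        z = sps.norm.ppf(0.975)
        cut = margin - z * se0
        predicted = sps.norm.cdf((cut - d0) / se0) - sps.norm.cdf((-cut - d0) / se0)

        wins = 0
        n_seeds = 100
        aorta = {"ascending_aorta": base.segment_attenuation_params["ascending_aorta"]}
        for seed in range(n_seeds):
            params = dataclasses.replace(
                base,
                segment_attenuation_params=aorta,
                n_score_segments=1,
                seed=seed,
            )
            table = simulate_cohort(params)
            grp = table.patients.groupby("group")["diagnostic"]
            res = diff_ci_wald(
                int(grp.sum()["A"]), int(grp.count()["A"]),
                int(grp.sum()["B"]), int(grp.count()["B"]),
                margin=margin,
            )
            wins += res.noninferior
        assert abs(wins / n_seeds - predicted) < 0.15
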