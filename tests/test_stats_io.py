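"""Statistics gates, group comparisons, cohorts, and bundle I/O."""

import itertools
import time

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from navblock import get_scenario, make_protocol, read_bundle, simulate_experiment, write_bundle
from navblock.stats import compare_groups, dunn_posthoc, significance_stars, summarize, synthetic_cohort


class TestSummarize:
    def test_normal_data_uses_mean_sem(self):
        rng = np.random.default_rng(0)
        hits = sum(
            summarize(rng.normal(10, 2, 30)).descriptor == "mean±SEM"
            for _ in range(100)
        )
        assert hits >= 90

    def test_skewed_data_uses_median(self):
        rng = np.random.default_rng(1)
        hits = sum(
            summarize(rng.lognormal(0, 1.5, 30)).descriptor == "median"
            for _ in range(100)
        )
        assert hits >= 90

    def test_degenerate_variance_flagged(self):
        s = summarize([3.0, 3.0, 3.0])
        assert s.degenerate and s.descriptor == "median"

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            summarize([1.0, 2.0])


class TestCompareGroups:
    def test_identical_small_groups_not_significant(self):
        res = compare_groups([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]])
        assert res.p > 0.9
        assert res.stars == "ns"

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)   # 3 SD shift
        res = compare_groups([a, b])
        assert res.p < 0.001

    def test_mann_whitney_matches_brute_force_small_n(self):
        # rank-based brute force: U = #(a_i > b_j) + 0.5 #(ties); the
        # exact p is the permutation tail probability
        a = [1.3, 2.1, 0.4, 3.3, 2.8]
        b = [4.1, 3.9, 2.2, 5.0, 4.4]
        res = compare_groups([a, b], force="nonparametric")
        U = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        U_stat = max(U, len(a) * len(b) - U)
        pooled = a + b
        count = 0
        total = 0
        for comb in itertools.combinations(range(10), 5):
            aa = [pooled[i] for i in comb]
            bb = [pooled[i] for i in range(10) if i not in comb]
            u = sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)
            total += 1
            if max(u, 25 - u) >= U_stat:
                count += 1
        # scipy reports U of the first sample; compare the larger tail
        assert res.test == "Mann-Whitney"
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_three_group_rank_pattern(self):
        # synthetic time-constant data at three holding potentials with
        # realistic scatter: the extreme pair separates, adjacent mid
        # pair separates, and the nonparametric path is used
        rng = np.random.default_rng(7)
        tau60 = rng.lognormal(np.log(180), 0.25, 7)
        tau80 = rng.lognormal(np.log(460), 0.25, 7)
        tau100 = rng.lognormal(np.log(520), 0.25, 7)
        res = compare_groups([tau60, tau80, tau100],
                             labels=["-60", "-80", "-100"])
        if res.posthoc is None:     # ANOVA branch (data passed normality)
            ph = dunn_posthoc([tau60, tau80, tau100], ["-60", "-80", "-100"])
        else:
            ph = res.posthoc
        assert res.p < 0.01
        row = ph[(ph.group_a == "-60") & (ph.group_b == "-100")].iloc[0]
        assert row.p_adjusted < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0, 2.0], []])

    def test_star_mapping(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(5e-5) == "****"
        assert significance_stars(0.2) == "ns"


class TestSyntheticCohort:
    def test_zero_cv_identical_cells(self):
        sc = get_scenario("somatic_wt")
        df = synthetic_cohort(sc, 5, 0.0, seed=0)
        assert df.plateau_block.nunique() == 1
        assert df.tau_s.nunique() == 1

    def test_wildtype_spread_covers_observed_range(self):
        sc = get_scenario("somatic_wt")
        df = synthetic_cohort(sc, 21, 0.3, seed=1)
        # double-pulse ratios scatter widely around the 0.5 median
        assert df.i1_i2.min() > 0.02 and df.i1_i2.max() < 1.0
        assert df.i1_i2.max() - df.i1_i2.min() > 0.2

    def test_two_seeds_distribution_equal(self):
        sc = get_scenario("somatic_wt")
        d1 = synthetic_cohort(sc, 40, 0.3, seed=2)
        d2 = synthetic_cohort(sc, 40, 0.3, seed=3)
        assert not np.allclose(d1.tau_s, d2.tau_s)
        assert sps.ks_2samp(d1.tau_s, d2.tau_s).pvalue > 0.01


@pytest.fixture(scope="module")
def bundle():
    sc = get_scenario("somatic_wt")
    sc.noise = sc.noise.model_copy(update=dict(noise_sd=10.0))
    return simulate_experiment(sc, make_protocol("diary_step", n_sweeps=4), seed=9)


class TestBundleIO:
    def test_round_trip(self, bundle, tmp_path):
        write_bundle(bundle, tmp_path / "b")
        back = read_bundle(tmp_path / "b")
        assert len(back.sweeps) == len(bundle.sweeps)
        for s1, s2 in zip(bundle.sweeps, back.sweeps):
            assert np.allclose(s1.i_pA, s2.i_pA, rtol=0, atol=1e-12)
        assert back.scenario == bundle.scenario
        assert back.drug_onset_s == bundle.drug_onset_s

    def test_missing_units_rejected(self, bundle, tmp_path):
        import json
        d = write_bundle(bundle, tmp_path / "c")
        meta = json.loads((d / "meta.json").read_text())
        del meta["units"]
        (d / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="units"):
            read_bundle(d)

    def test_large_bundle_reads_quickly(self, tmp_path):
        sc = get_scenario("vehicle")
        b = simulate_experiment(sc, make_protocol("diary_step", n_sweeps=160),
                                seed=0, include_pn=False)
        d = write_bundle(b, tmp_path / "big")
        t0 = time.time()
        read_bundle(d)
        assert time.time() - t0 < 1.0


class TestReport:
    def test_metrics_table_contents_and_determinism(self, tmp_path):
        from navblock.report import run_report
        df1 = run_report(tmp_path / "r1", seed=5, include_iclamp=False,
                         make_figures=False)
        df2 = run_report(tmp_path / "r2", seed=5, include_iclamp=False,
                         make_figures=False)
        names = set(df1.metric)
        for required in ("plateau_block_pct", "availability_delta_V05_mV",
                         "tau_ratio_m100_over_m60", "recovery_t50_control_ms",
                         "recovery_t50_modified_ms", "use_dep_block_cycled_500s",
                         "eq1_reference_tau_s"):
            assert required in names
        assert (tmp_path / "r1" / "metrics.csv").read_bytes() == \
            (tmp_path / "r2" / "metrics.csv").read_bytes()
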