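"""Monte Carlo reduction engine: density/slope draws, the two aggregation
modes, stratified tables, and mode comparison."""

import numpy as np
import pytest

from monarchdd import (
    FieldDensitySummary,
    MonteCarloConfig,
    ReductionEstimate,
    SiteSurveyRecord,
    compare_modes,
    draw_densities,
    draw_slope,
    filter_nonzero,
    reduction_mean_density,
    reduction_site_specific,
    region_phase_table,
    site_density,
    summarize_sites,
)
from monarchdd.reduction import PHASES, REGIONS, STAGE_SETS


def make_record(site_id="s1", eggs=4, instars=(1, 1, 2, 0, 2), n_plants=10,
                region="South", phase="early"):
    return SiteSurveyRecord(
        site_id=site_id, region=region, phase=phase, n_plants=n_plants,
        n_eggs=eggs, n_instar1=instars[0], n_instar2=instars[1],
        n_instar3=instars[2], n_instar4=instars[3], n_instar5=instars[4],
    )


def eggs_only_record(site_id, n_eggs, n_plants=10, region="South", phase="early"):
    return make_record(site_id, eggs=n_eggs, instars=(0, 0, 0, 0, 0),
                       n_plants=n_plants, region=region, phase=phase)


class TestSiteDensity:
    @pytest.mark.parametrize("stage_set,expected", [
        ("large_larvae", 0.4), ("eggs", 0.4), ("eggs_and_larvae", 1.0),
    ])
    def test_stage_set_definitions(self, stage_set, expected):
        assert site_density(make_record(), stage_set) == pytest.approx(expected)

    def test_unknown_stage_set(self):
        with pytest.raises(ValueError):
            site_density(make_record(), "pupae")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_record(eggs=-1)


class TestFilterNonzero:
    def test_exclusion_depends_on_stage_set(self):
        records = [
            make_record("zero", eggs=0, instars=(0, 0, 0, 0, 0)),
            eggs_only_record("eggs_only", 1),
        ]
        assert [r.site_id for r in filter_nonzero(records, "eggs")] == ["eggs_only"]
        assert filter_nonzero(records, "large_larvae") == []

    def test_all_positive_retained(self):
        records = [make_record(f"s{i}") for i in range(10)]
        assert len(filter_nonzero(records, "eggs_and_larvae")) == 10


class TestSummarizeSites:
    def test_hand_arithmetic(self):
        records = [eggs_only_record("a", 1), eggs_only_record("b", 3)]
        s = summarize_sites(records, "eggs")
        assert s.mean_density == pytest.approx(0.2, abs=1e-12)
        assert s.se_density == pytest.approx(0.1, abs=1e-12)
        assert s.n_sites == 2
        assert s.region == "South" and s.phase == "early"

    def test_equal_densities_have_zero_se(self):
        records = [eggs_only_record(f"s{i}", 2) for i in range(5)]
        s = summarize_sites(records, "eggs")
        assert s.mean_density == pytest.approx(0.2)
        assert s.se_density == 0.0

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            summarize_sites([eggs_only_record("a", 1)], "eggs")

    def test_matches_brute_force_mean_and_se(self):
        rng = np.random.default_rng(49)
        records = [
            eggs_only_record(f"s{i}", int(c))
            for i, c in enumerate(rng.integers(1, 30, size=49))
        ]
        s = summarize_sites(records, "eggs")
        dens = [r.n_eggs / r.n_plants for r in records]
        mean = sum(dens) / len(dens)
        var = sum((x - mean) ** 2 for x in dens) / (len(dens) - 1)
        assert s.mean_density == pytest.approx(mean, abs=1e-12)
        assert s.se_density == pytest.approx((var / len(dens)) ** 0.5, abs=1e-12)


class TestDraws:
    def summary(self, mean=0.202, se=0.041):
        return FieldDensitySummary("South", "early", "large_larvae", mean, se)

    def test_zero_se_is_degenerate(self):
        rng = np.random.default_rng(0)
        d = draw_densities(self.summary(se=0.0), 50, rng)
        assert np.all(d == 0.202)

    def test_law_of_large_numbers(self):
        rng = np.random.default_rng(1)
        d = draw_densities(self.summary(), 100_000, rng)
        assert abs(d.mean() - 0.202) < 3 * 0.041 / np.sqrt(100_000)

    def test_truncation_keeps_draws_nonnegative(self):
        rng = np.random.default_rng(2)
        d = draw_densities(self.summary(mean=0.05, se=0.5), 10_000, rng)
        assert np.all(d >= 0)
        assert d.size == 10_000

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            draw_densities(self.summary(), 10, np.random.default_rng(0), sd=-1.0)

    def test_slope_draw_degenerate_and_spread(self, paper_curve):
        rng = np.random.default_rng(3)
        assert draw_slope(paper_curve, rng) == paper_curve.slope  # se = 0
        sd = abs(paper_curve.slope) * 0.35
        draws = draw_slope(paper_curve, rng, size=100_000, sd=sd)
        assert abs(draws.std(ddof=1) - sd) / sd < 0.02


class TestReductionMeanDensity:
    def test_degenerate_monte_carlo_is_point_evaluation(self, paper_curve):
        s = FieldDensitySummary("South", "early", "eggs", 0.736, 0.0)
        cfg = MonteCarloConfig(n_draws=100, seed=0)
        est = reduction_mean_density(s, paper_curve, cfg)
        assert est.mean_pct == pytest.approx(
            100 * paper_curve.reduction_at(0.736), abs=1e-12
        )
        assert est.se_pct == 0.0

    def test_combined_stage_density_matches_point_oracle(self, paper_curve):
        s = FieldDensitySummary("South", "early", "eggs_and_larvae", 0.982, 0.138)
        cfg = MonteCarloConfig(n_draws=100, seed=1, slope_cv=0.35)
        est = reduction_mean_density(s, paper_curve, cfg)
        oracle = 100 * paper_curve.reduction_at(0.982)  # 5.36
        assert abs(est.mean_pct - oracle) <= 3 * est.se_pct

    def test_se_shrinks_with_sqrt_n(self, paper_curve):
        s = FieldDensitySummary("South", "early", "eggs", 0.736, 0.120)
        small = reduction_mean_density(
            s, paper_curve, MonteCarloConfig(n_draws=100, seed=4, slope_cv=0.35))
        big = reduction_mean_density(
            s, paper_curve, MonteCarloConfig(n_draws=10_000, seed=4, slope_cv=0.35))
        ratio = small.se_pct / big.se_pct
        assert 5 < ratio < 20  # ~10x from sqrt(n), plus Monte Carlo noise

    def test_reproducible_and_seed_sensitivity(self, paper_curve):
        s = FieldDensitySummary("South", "early", "large_larvae", 0.202, 0.041)
        cfg = MonteCarloConfig(n_draws=100, seed=7, slope_cv=0.35)
        a = reduction_mean_density(s, paper_curve, cfg)
        b = reduction_mean_density(s, paper_curve, cfg)
        assert a == b
        # Re-seeding moves the mean by no more than ~3 SEs nearly always.
        ref = a.mean_pct
        within = sum(
            abs(reduction_mean_density(
                s, paper_curve,
                MonteCarloConfig(n_draws=100, seed=1000 + i, slope_cv=0.35)
            ).mean_pct - ref) <= 3 * a.se_pct
            for i in range(300)
        )
        assert within / 300 >= 0.95

    def test_monotone_in_mean_density(self, paper_curve):
        means = np.linspace(0.05, 2.0, 16)
        vals = [
            reduction_mean_density(
                FieldDensitySummary("South", "early", "eggs", m, 0.02),
                paper_curve,
                MonteCarloConfig(n_draws=200, seed=9, slope_cv=0.35),
            ).mean_pct
            for m in means
        ]
        assert np.all(np.diff(vals) >= 0)

    def test_positive_slope_draws_floor_at_zero(self):
        from monarchdd import SurvivalFunction
        fn = SurvivalFunction(intercept_logit=1.0, slope=0.2)  # density benefit
        s = FieldDensitySummary("South", "early", "eggs", 0.5, 0.0)
        est = reduction_mean_density(fn=fn, summary=s,
                                     cfg=MonteCarloConfig(n_draws=50, seed=0))
        assert est.mean_pct == 0.0
        assert est.raw_mean_pct < 0.0


class TestReductionSiteSpecific:
    def test_single_site_degenerate(self, paper_curve):
        rec = eggs_only_record("a", 5)  # density 0.5
        cfg = MonteCarloConfig(n_reps=100, seed=0)
        est = reduction_site_specific([rec], paper_curve, cfg, "eggs")
        assert est.mean_pct == pytest.approx(
            100 * paper_curve.reduction_at(0.5), abs=1e-12
        )
        assert est.se_pct == 0.0

    def test_jensen_inequality_over_sites(self, paper_curve):
        # Two sites at 0.1 and 1.9 eggs/plant: the convex reduction curve
        # makes their average reduction exceed the reduction at the mean.
        records = [eggs_only_record("a", 1), eggs_only_record("b", 19)]
        cfg = MonteCarloConfig(n_reps=50, seed=0)
        est = reduction_site_specific(records, paper_curve, cfg, "eggs")
        assert est.mean_pct > 100 * paper_curve.reduction_at(1.0)

    def test_consistency_with_mean_density_mode(self, paper_curve):
        records = [eggs_only_record(f"s{i}", 5) for i in range(4)]
        cfg = MonteCarloConfig(n_draws=100, n_reps=100, seed=0)
        site = reduction_site_specific(records, paper_curve, cfg, "eggs")
        mean = reduction_mean_density(
            FieldDensitySummary("South", "early", "eggs", 0.5, 0.0),
            paper_curve, cfg)
        assert site.mean_pct == pytest.approx(mean.mean_pct, abs=1e-12)

    def test_empty_after_filter_raises(self, paper_curve):
        records = [eggs_only_record("a", 3)]
        with pytest.raises(ValueError, match="no non-zero sites"):
            reduction_site_specific(
                records, paper_curve, MonteCarloConfig(seed=0), "large_larvae")

    def test_shared_slope_option_runs(self, paper_curve):
        records = [eggs_only_record("a", 1), eggs_only_record("b", 9)]
        cfg = MonteCarloConfig(n_reps=20, seed=5, slope_cv=0.35,
                               shared_slope_per_rep=True)
        est = reduction_site_specific(records, paper_curve, cfg, "eggs")
        assert est.mean_pct > 0


class TestRegionPhaseTable:
    def all_strata(self):
        return [
            FieldDensitySummary(region, phase, stage_set,
                                0.1 + 0.01 * i, 0.02)
            for i, (region, phase, stage_set) in enumerate(
                (r, p, s) for r in REGIONS for p in PHASES for s in ["eggs"]
            )
        ]

    def test_single_stratum(self, paper_curve):
        out = region_phase_table(self.all_strata()[:1], paper_curve,
                                 MonteCarloConfig(seed=0))
        assert len(out) == 1

    def test_nine_strata_fixed_order(self, paper_curve):
        summaries = self.all_strata()
        out = region_phase_table(list(reversed(summaries)), paper_curve,
                                 MonteCarloConfig(seed=0))
        assert [(e.region, e.phase) for e in out] == [
            (r, p) for r in REGIONS for p in PHASES
        ]

    def test_input_order_does_not_change_results(self, paper_curve):
        summaries = self.all_strata()
        cfg = MonteCarloConfig(seed=3, slope_cv=0.35)
        a = region_phase_table(summaries, paper_curve, cfg)
        b = region_phase_table(list(reversed(summaries)), paper_curve, cfg)
        assert a == b

    def test_duplicate_strata_rejected(self, paper_curve):
        summaries = self.all_strata()
        with pytest.raises(ValueError, match="duplicate"):
            region_phase_table(summaries + summaries[:1], paper_curve,
                               MonteCarloConfig(seed=0))


class TestCompareModes:
    def _est(self, mean_pct, mode, stage_set="large_larvae"):
        return ReductionEstimate(
            mean_pct=mean_pct, se_pct=0.1, sd_pct=1.0, n_draws=100, mode=mode,
            seed=0, stage_set=stage_set, region="South", phase="early",
        )

    def test_published_large_larvae_ratio(self):
        ratio = compare_modes(self._est(2.22, "site_specific"),
                              self._est(1.13, "mean_density"))
        assert ratio == pytest.approx(1.965, abs=1e-3)

    def test_published_combined_stage_ratio(self):
        ratio = compare_modes(
            self._est(10.87, "site_specific", "eggs_and_larvae"),
            self._est(5.31, "mean_density", "eggs_and_larvae"))
        assert ratio == pytest.approx(2.047, abs=1e-3)

    def test_equal_inputs_give_one(self):
        assert compare_modes(self._est(1.0, "site_specific"),
                             self._est(1.0, "mean_density")) == 1.0

    def test_mismatched_stratum_rejected(self):
        with pytest.raises(ValueError):
            compare_modes(self._est(1.0, "site_specific", "eggs"),
                          self._est(1.0, "mean_density", "large_larvae"))

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            compare_modes(self._est(1.0, "site_specific"),
                          self._est(0.0, "mean_density"))
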