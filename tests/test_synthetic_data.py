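import numpy as np
import pandas as pd
import pytest

import skintact as sk
from skintact.stats_core import relative_sd
from skintact.surface_models import FIBRIL_SAMPLES, PILLAR_SAMPLES, ROUGH_SAMPLES
from skintact.synthetic_data import (
    COPULA_VARIABLES,
    CohortConfig,
    FrictionModelConfig,
    PerceptionModelConfig,
    TrialConfig,
    generate_cohort,
    generate_force_trace,
    generate_friction_coefficients,
    generate_perception_data,
    nearest_psd_correlation,
    split_seed,
)


class TestCohortGeneration:
    def test_seed_determinism(self):
        c1 = generate_cohort(CohortConfig(n_participants=50, seed=42))
        c2 = generate_cohort(CohortConfig(n_participants=50, seed=42))
        pd.testing.assert_frame_equal(c1, c2)

    def test_different_seeds_differ(self):
        c1 = generate_cohort(CohortConfig(n_participants=50, seed=1))
        c2 = generate_cohort(CohortConfig(n_participants=50, seed=2))
        assert not c1["SC_hydration"].equals(c2["SC_hydration"])

    def test_degenerate_noise_collapses_to_means(self):
        cfg = CohortConfig(
            n_participants=5,
            seed=0,
            marginal_rsd={k: 0.0 for k in CohortConfig().marginal_rsd},
            target_correlations={},
            mc_log_noise_sd=0.0,
            sex_ratios={},
        )
        cohort = generate_cohort(cfg)
        for var, mean in cfg.marginal_means.items():
            np.testing.assert_allclose(cohort[var], mean, rtol=1e-9)

    def test_marginal_closure(self, large_cohort):
        cfg = CohortConfig()
        for var, rsd in cfg.marginal_rsd.items():
            if rsd == 0:
                continue
            assert large_cohort[var].mean() == pytest.approx(
                cfg.marginal_means[var], rel=0.05
            )
            assert relative_sd(large_cohort[var]) == pytest.approx(rsd, rel=0.05)
        assert large_cohort["MC_density"].mean() == pytest.approx(7.2, rel=0.05)

    def test_correlation_closure(self, large_cohort):
        for (a, b), target in CohortConfig().target_correlations.items():
            got = sk.pearson_with_p(large_cohort[a], large_cohort[b]).r
            assert got == pytest.approx(target, abs=0.05), (a, b)

    def test_mc_decay_structure(self, large_cohort):
        fit = sk.fit_age_decay(large_cohort["age"], large_cohort["MC_density"])
        assert fit.half_life == pytest.approx(19.0, abs=1.0)

    def test_age_range_and_positivity(self, large_cohort):
        lo, hi = CohortConfig().age_range
        assert large_cohort["age"].between(lo, hi).all()
        numeric = large_cohort.drop(columns="sex")
        assert (numeric > 0).all().all()
        assert large_cohort["R2"].le(1.0).all()

    def test_sex_proportions_and_dimorphism(self, large_cohort):
        frac = (large_cohort["sex"] == "F").mean()
        assert frac == pytest.approx(37 / 60, abs=0.01)
        by_sex = large_cohort.groupby("sex")["SG_density"].mean()
        assert by_sex["F"] > by_sex["M"]

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_participants=2)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(target_correlations={("R0", "SC_hydration"): 1.5})

    def test_missingness(self):
        cfg = CohortConfig(n_participants=500, seed=3, missing_rate=0.1)
        cohort = generate_cohort(cfg)
        rate = cohort["MC_density"].isna().mean()
        assert rate == pytest.approx(0.1, abs=0.04)

    def test_nearest_psd_repair(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        repaired = nearest_psd_correlation(bad)
        eigs = np.linalg.eigvalsh(repaired)
        assert eigs.min() >= -1e-12
        np.testing.assert_allclose(np.diag(repaired), 1.0)

    def test_split_seed_below_2_31(self):
        seeds = split_seed(123, 10)
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)


class TestFrictionGeneration:
    def test_determinism(self, small_cohort):
        m1 = generate_friction_coefficients(small_cohort, FrictionModelConfig(seed=9))
        m2 = generate_friction_coefficients(small_cohort, FrictionModelConfig(seed=9))
        pd.testing.assert_frame_equal(m1, m2)

    def test_all_positive(self, large_mu):
        assert (large_mu > 0).all().all()

    def test_shared_effect_only_gives_perfect_correlation(self, small_cohort):
        cfg = FrictionModelConfig(
            r2_rough=0.0,
            r2_fibril=0.0,
            participant_effect_share={"rough": 1.0, "fibril": 1.0},
            seed=4,
        )
        mu = generate_friction_coefficients(small_cohort, cfg)
        r = np.corrcoef(mu["S01"], mu["S02"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_within_sample_rsd(self, large_mu):
        cfg = FrictionModelConfig()
        for s in ROUGH_SAMPLES:
            assert relative_sd(large_mu[s]) == pytest.approx(
                cfg.within_sample_rsd[s], abs=0.02
            )
        for s in FIBRIL_SAMPLES:
            assert relative_sd(large_mu[s]) == pytest.approx(
                cfg.within_sample_rsd[s], abs=0.02
            )

    def test_pillar_friction_increases_with_aspect_ratio(self, large_mu):
        means = {s.label: large_mu[s.label].mean() for s in PILLAR_SAMPLES}
        aspect = {s.label: s.aspect_ratio for s in PILLAR_SAMPLES}
        labels = sorted(means, key=aspect.get)
        values = [means[lab] for lab in labels]
        assert values[0] < values[-1]
        assert means["100/100"] == pytest.approx(1.2, abs=0.05)
        assert means["40/120"] == pytest.approx(2.0, abs=0.05)

    def test_inter_sample_correlation_ranges(self, large_mu):
        rough_pairs = np.corrcoef(large_mu[list(ROUGH_SAMPLES)].T)
        off = rough_pairs[np.triu_indices(6, 1)]
        assert off.min() > 0.9
        fib = np.corrcoef(large_mu[list(FIBRIL_SAMPLES)].T)
        off_f = fib[np.triu_indices(4, 1)]
        assert 0.3 < off_f.min() and off_f.max() < 0.85

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            FrictionModelConfig(r2_rough=1.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_friction_coefficients(pd.DataFrame(), FrictionModelConfig())


class TestForceTraceGeneration:
    def test_noiseless_closure(self):
        trial = TrialConfig(sensor_noise_sd=0.0, fn_jitter=0.0)
        trace = generate_force_trace(0.77, trial, seed=0)
        assert sk.friction_coefficient(trace).mu_median == pytest.approx(
            0.77, rel=1e-12
        )

    def test_length_and_sampling(self):
        trial = TrialConfig(duration=30.0)
        trace = generate_force_trace(1.0, trial, seed=1)
        assert trace.t.size == 1500
        assert trace.sampling_rate == pytest.approx(50.0)

    def test_cycle_rate_recovery(self):
        trial = TrialConfig(circle_rate=0.4, duration=30.0)
        trace = generate_force_trace(1.0, trial, seed=5)
        summary = sk.friction_coefficient(trace)
        assert summary.cycle_rate == pytest.approx(0.4, abs=0.02)

    def test_monte_carlo_extraction_bias(self):
        mus = [
            sk.friction_coefficient(
                generate_force_trace(0.92, TrialConfig(), seed=s)
            ).mu_median
            for s in range(200)
        ]
        assert abs(np.mean(mus) - 0.92) < 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrialConfig(duration=10.0)  # below protocol minimum
        with pytest.raises(ValueError):
            TrialConfig(duration=16.0, pre_post_idle=8.0)
        with pytest.raises(ValueError):
            generate_force_trace(-1.0, TrialConfig(), seed=0)


class TestPerceptionGeneration:
    def test_determinism(self, small_cohort):
        p1 = generate_perception_data(small_cohort, PerceptionModelConfig(seed=3))
        p2 = generate_perception_data(small_cohort, PerceptionModelConfig(seed=3))
        pd.testing.assert_frame_equal(p1["two_point"], p2["two_point"])
        pd.testing.assert_frame_equal(p1["pairwise"], p2["pairwise"])

    def test_chance_level_at_zero_difference(self):
        assert sk.weibull_probability(0.0, 5.55, 2.0) == 0.5

    def test_huge_k_makes_every_comparison_correct(self, small_cohort):
        perc = generate_perception_data(
            small_cohort, PerceptionModelConfig(weibull_k=1e9, seed=0)
        )
        assert perc["pairwise"]["success"].mean() == 1.0

    def test_mean_success_rate_matches_study(self, small_cohort):
        perc = generate_perception_data(small_cohort, PerceptionModelConfig(seed=1))
        assert perc["pairwise"]["success"].mean() == pytest.approx(0.90, abs=0.04)

    def test_detection_increases_with_stiffness(self, large_cohort):
        from skintact.surface_models import bending_stiffness

        perc = generate_perception_data(large_cohort, PerceptionModelConfig(seed=2))
        rates = perc["pillar_detection"].mean()
        k = {s.label: bending_stiffness(s) for s in PILLAR_SAMPLES}
        ordered = sorted(rates.index, key=k.get)
        assert rates[ordered[0]] < rates[ordered[-1]]
        # same diameter, shorter pillars are detected more often
        assert rates["100/100"] > rates["100/300"]

    def test_two_point_thresholds_in_protocol_range(self, small_cohort):
        perc = generate_perception_data(small_cohort, PerceptionModelConfig(seed=4))
        thr = perc["two_point"]["threshold_mm"]
        finite = thr[np.isfinite(thr)]
        assert finite.isin([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]).all()

    def test_unknown_sample_in_design_rejected(self, small_cohort):
        from skintact.psychophysics import build_triplet_design

        design = build_triplet_design(tuple("UVWXYZ"), seed=0)
        with pytest.raises(KeyError):
            generate_perception_data(small_cohort, design=design)

    def test_jnd_recovery_from_generated_responses(self, small_cohort):
        perc = generate_perception_data(
            small_cohort, PerceptionModelConfig(seed=6), n_repetitions=5
        )
        pooled = sk.aggregate_pairwise(perc["pairwise"])
        pos = pooled[pooled["rel_diff"] > 0]
        fit = sk.fit_weibull(pos["rel_diff"], pos["n_success"], pos["n_trials"])
        assert fit.jnd == pytest.approx(0.15, abs=0.01)
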