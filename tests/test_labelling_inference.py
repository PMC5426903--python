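"""Tests for TH/KH fitting, model comparison, source profiling, bootstrap
and derived summaries."""

import numpy as np
import pandas as pd
import pytest

from memokin.labelling.inference import (
    BrdUKi67Model,
    compare_labelling_models,
    derived_summaries,
    fit_labelling_model,
    profile_source_magnitude,
)
from memokin.labelling.spec import KineticModelSpec, resolve_steady_state
from memokin.synthetic import LabellingTruth, generate_labelling_dataset


class TestDerivedSummaries:
    def test_pool_averages_are_size_weighted_means(self, tem_space):
        d = derived_summaries(tem_space)
        q = d["q_fast"]
        assert d["pool_avg_lifetime"] == pytest.approx(
            q * d["lifetime_fast"] + (1 - q) * d["lifetime_slow"], rel=1e-12
        )
        assert d["pool_avg_interdiv"] == pytest.approx(
            q * d["interdiv_fast"] + (1 - q) * d["interdiv_slow"], rel=1e-12
        )

    def test_effector_memory_reference_values(self, tem_space):
        # q = 0.38 with fast/slow lifetimes 5.7 / 43 d gives a pool average
        # of ~29 d; interdivision times 5.7 / 138 d give ~88 d
        d = derived_summaries(tem_space)
        assert d["pool_avg_lifetime"] == pytest.approx(29.0, rel=0.02)
        assert d["pool_avg_interdiv"] == pytest.approx(88.0, rel=0.02)
        assert d["source_fraction_of_production"] == pytest.approx(0.12, abs=0.01)

    def test_central_memory_reference_values(self):
        from memokin.synthetic import labelling_spec_preset

        d = derived_summaries(resolve_steady_state(labelling_spec_preset("tcm")))
        # q = 0.49 with interdivision times 3.4 / 167 d -> ~86-87 d
        assert d["pool_avg_interdiv"] == pytest.approx(86.5, rel=0.02)
        assert d["pool_avg_lifetime"] == pytest.approx(21.0, rel=0.05)

    def test_equal_subpopulations_average_to_common_value(self):
        spec = KineticModelSpec(
            structure="KH", khat=4, bhat=2, beta=0.3, epsilon=0.8, tau=1.0,
            s_week=0.07, alpha_fast=0.05, alpha_slow=0.05, q_fast=0.3,
            f_slow=0.7,
        )
        d = derived_summaries(resolve_steady_state(spec))
        assert d["pool_avg_interdiv"] == pytest.approx(20.0, rel=1e-9)
        assert d["pool_avg_lifetime"] == pytest.approx(d["lifetime_fast"], rel=1e-9)

    def test_occupancy_weighted_lifetime_for_unequal_death_rates(self):
        spec = KineticModelSpec(
            structure="KH", khat=4, bhat=2, beta=0.3, epsilon=0.8, tau=1.0,
            s_week=0.07, alpha_fast=0.15, alpha_slow=0.02, q_fast=0.4,
            f_slow=0.8, death_ratio=10.0,
        )
        space = resolve_steady_state(spec)
        d = derived_summaries(space)
        fast = space.subpops[0]
        expected = fast.kappa / fast.delta_hi + (1 - fast.kappa) / fast.delta_lo
        assert d["lifetime_fast"] == pytest.approx(expected, rel=1e-12)


class TestRecoveryFit:
    def test_noiseless_fit_is_near_perfect(self, tem_recovery_fit):
        assert tem_recovery_fit.rss < 1e-8

    def test_kinetic_parameters_recovered(self, tem_recovery_fit, tem_spec):
        fit = tem_recovery_fit
        assert fit.theta["alpha_fast"] == pytest.approx(tem_spec.alpha_fast, rel=0.02)
        assert fit.theta["beta"] == pytest.approx(tem_spec.beta, rel=0.02)
        assert fit.theta["epsilon"] == pytest.approx(tem_spec.epsilon, rel=0.02)
        assert fit.theta["q_fast"] == pytest.approx(tem_spec.q_fast, rel=0.02)

    def test_kappa_constraint_honoured_end_to_end(self, tem_recovery_fit):
        d = tem_recovery_fit.derived
        q = d["q_fast"]
        blended = q * d["kappa_fast"] + (1 - q) * d["kappa_slow"]
        assert blended == pytest.approx(tem_recovery_fit.model.kappa_obs, rel=1e-9)

    def test_neglecting_the_source_misfits(
        self, noiseless_labelling_data, tem_recovery_fit, tem_kappa
    ):
        """A no-influx model cannot reproduce source-fed kinetics, and
        neglecting the source underestimates interdivision times
        (by roughly two- to three-fold here)."""
        no_src = fit_labelling_model(
            noiseless_labelling_data, structure="KH", s_week=0.0,
            kappa_obs=tem_kappa, seed=4, n_starts=4,
        )
        assert no_src.rss > 100 * max(tem_recovery_fit.rss, 1e-12)
        assert no_src.derived["pool_avg_interdiv"] < (
            0.7 * tem_recovery_fit.derived["pool_avg_interdiv"]
        )


class TestCompare:
    def test_identical_fits_tie(self, tem_recovery_fit):
        table = compare_labelling_models([tem_recovery_fit, tem_recovery_fit])
        assert np.allclose(table["delta_aic"], 0.0)
        assert np.allclose(table["rel_prob"], 1.0)

    def test_mismatched_data_rejected(self, tem_recovery_fit, tem_spec):
        other = generate_labelling_dataset(
            LabellingTruth(spec=tem_spec, sigma=0.02, mice_per_timepoint=1), seed=9
        )
        other_fit = fit_labelling_model(
            other, s_week=0.07, kappa_obs=tem_recovery_fit.model.kappa_obs,
            seed=1, n_starts=0, x0=tem_recovery_fit.theta,
        )
        with pytest.raises(ValueError, match="fingerprint"):
            compare_labelling_models([tem_recovery_fit, other_fit])


class TestProfile:
    def test_single_point_profile_equals_direct_fit(
        self, noiseless_labelling_data, tem_kappa
    ):
        direct = fit_labelling_model(
            noiseless_labelling_data, s_week=0.07, kappa_obs=tem_kappa,
            seed=7, n_starts=3,
        )
        profile, fits = profile_source_magnitude(
            noiseless_labelling_data, s_grid=[0.07], seed=7, n_starts=3,
            kappa_obs=tem_kappa,
        )
        assert len(fits) == 1
        assert profile["aic"].iloc[0] == pytest.approx(direct.aic, abs=1e-6)

    def test_profile_minimised_near_truth(
        self, noiseless_labelling_data, tem_kappa
    ):
        """On data generated with s_week = 0.07 the profile RSS is smallest
        at the grid point nearest the truth."""
        profile, _ = profile_source_magnitude(
            noiseless_labelling_data, s_grid=[0.0, 0.07, 0.20], seed=3,
            n_starts=4, kappa_obs=tem_kappa,
        )
        assert profile["rss"].idxmin() == 1


class TestBootstrap:
    def test_bootstrap_is_deterministic(self, tem_recovery_fit):
        a = tem_recovery_fit.bootstrap(n_boot=5, seed=42)
        b = tem_recovery_fit.bootstrap(n_boot=5, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_gives_degenerate_intervals(self, tem_recovery_fit):
        tem_recovery_fit.bootstrap(n_boot=5, seed=42)
        ci = tem_recovery_fit.conf_int()
        width = (ci["hi"] - ci["lo"]) / ci["estimate"].abs().clip(lower=1e-9)
        assert width["beta"] < 1e-3
        assert width["alpha_fast"] < 1e-2

    def test_s_week_distribution_propagates(self, tem_recovery_fit):
        draws = np.array([0.05, 0.07, 0.09])
        table = tem_recovery_fit.bootstrap(
            n_boot=6, seed=1, s_week_distribution=draws
        )
        assert set(np.round(table["s_week"], 3)) <= {0.05, 0.07, 0.09}
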