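"""Tests for the replacement ODEs, closed-form replacement fractions and
model fitting/comparison."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from memokin.chimera import (
    ChimeraModelSpec,
    ChimeraReplacementModel,
    ChimeraResults,
    compare_chimera_models,
    quick_influx_estimate,
    replacement_fraction,
    simulate_chimera,
)
from memokin.exceptions import ModelDomainError
from memokin.source import SourceDescriptor, eval_source_chimerism, eval_source_size
from memokin.synthetic import generate_chimera_dataset


def source(**kw):
    base = dict(S0=1.8e7, R=0.0025, rho_max=0.92, rho_0=0.35, r=0.03)
    base.update(kw)
    return SourceDescriptor(**base)


def constant_chimerism_source(c):
    # degenerate sigmoid: rho_S(t) = c for all t
    return source(rho_max=c, rho_0=c)


T_GRID = np.linspace(0.0, 322.0, 30)[1:]


class TestSimulate:
    def test_constant_source_chimerism_freezes_memory_chimerism(self):
        # with rho_S == rho_M0 and no incumbent pool, drho/dt vanishes
        spec = ChimeraModelSpec(gamma0=1e-3, lam=0.01, M_inc=0.0)
        sim = simulate_chimera(spec, constant_chimerism_source(0.4), 1e6, 0.4, T_GRID)
        assert np.allclose(sim["rho_M"], 0.4, atol=1e-7)

    def test_no_influx_decays_exponentially(self):
        spec = ChimeraModelSpec(gamma0=0.0, lam=0.02, M_inc=0.0)
        sim = simulate_chimera(spec, source(), 1e6, 0.1, T_GRID)
        # solver atol is ~1 cell, so compare at that absolute resolution
        assert np.allclose(sim["M"], 1e6 * np.exp(-0.02 * T_GRID),
                           rtol=1e-5, atol=2.0)

    def test_incumbent_is_fixed_point_without_influx(self):
        spec = ChimeraModelSpec(gamma0=0.0, lam=0.05, M_inc=4e5)
        sim = simulate_chimera(spec, source(), 1e6, 0.1, np.array([600.0]))
        assert sim["M"].iloc[-1] == pytest.approx(4e5, rel=1e-4)

    def test_agrees_with_independent_integrator(self):
        spec = ChimeraModelSpec(
            gamma0=7e-4, lam=0.012, M_inc=5e5, phi=0.004, variant="combined"
        )
        src = source()
        M0, rho0 = 1.4e6, 0.07
        sim = simulate_chimera(spec, src, M0, rho0, T_GRID)

        def rhs(t, y):
            M, rho = y
            influx = spec.gamma0 * math.exp(-spec.phi * t) * eval_source_size(src, t)
            return [
                influx - spec.lam * (M - spec.M_inc),
                influx / M * (eval_source_chimerism(src, t) - rho)
                - spec.lam * spec.M_inc / M * rho,
            ]

        ref = solve_ivp(rhs, (0, T_GRID[-1]), [M0, rho0], t_eval=T_GRID,
                        method="DOP853", rtol=1e-11, atol=1e-11)
        assert np.allclose(sim["M"], ref.y[0], rtol=1e-6)
        assert np.allclose(sim["rho_M"], ref.y[1], rtol=1e-6)

    def test_starting_at_or_below_incumbent_aborts(self):
        spec = ChimeraModelSpec(gamma0=0.0, lam=0.5, M_inc=9e5)
        with pytest.raises(ModelDomainError):
            simulate_chimera(spec, source(), 8e5, 0.1, np.array([200.0]))

    def test_chimerism_bounded_by_source_plateau(self):
        spec = ChimeraModelSpec(gamma0=2e-3, lam=0.0, M_inc=0.0)
        src = source()
        sim = simulate_chimera(spec, src, 1e6, 0.02, T_GRID)
        assert sim["rho_M"].max() <= src.rho_max * (1 + 1e-8)


class TestReplacementFraction:
    def test_zero_horizon_zero_replacement(self):
        spec = ChimeraModelSpec(gamma0=1e-3, lam=0.01, M_inc=2e5)
        rs = replacement_fraction(spec, source(), 1e6, 0.0)
        assert rs.f_replace == 0.0 and rs.Y == 0.0

    def test_small_constant_influx_first_order(self):
        # lam = 0, R = 0, no incumbent: f(7) -> 7c for small daily influx c
        M0 = 1e6
        c = 1e-4
        spec = ChimeraModelSpec(gamma0=c * M0 / 1e7, lam=0.0, M_inc=0.0)
        rs = replacement_fraction(spec, source(S0=1e7, R=0.0), M0, 7.0)
        assert rs.f_replace == pytest.approx(7 * c, rel=5e-3)
        assert rs.psi == 0.0  # exercises the series branch

    def test_closed_form_matches_ode_on_random_draws(self, rng):
        for _ in range(20):
            spec = ChimeraModelSpec(
                gamma0=10 ** rng.uniform(-4, -2.5),
                lam=rng.uniform(-0.01, 0.05),
                M_inc=rng.uniform(0, 5e5),
                phi=rng.uniform(0, 0.01),
                variant="combined",
            )
            rs = replacement_fraction(
                spec, source(R=rng.uniform(0, 0.01)), 1e6, rng.uniform(1, 300)
            )
            assert rs.Y == pytest.approx(rs.Y_numeric, rel=1e-8)
            assert 0.0 <= rs.f_replace <= 1.0
            assert rs.f_replace_displaceable >= rs.f_replace

    def test_psi_zero_branch_continuous(self):
        spec0 = ChimeraModelSpec(gamma0=1e-3, lam=0.0025, M_inc=0.0)
        rs0 = replacement_fraction(spec0, source(R=0.0025), 1e6, 7.0)  # psi = 0
        spec1 = ChimeraModelSpec(gamma0=1e-3, lam=0.0025 - 1e-9, M_inc=0.0)
        rs1 = replacement_fraction(spec1, source(R=0.0025), 1e6, 7.0)
        assert rs0.f_replace == pytest.approx(rs1.f_replace, rel=1e-6)


class TestQuickInflux:
    def test_values_and_errors(self):
        assert quick_influx_estimate(0.0, 0.5, 0.1) == 0.0
        assert quick_influx_estimate(0.01, 0.75, 0.25) == pytest.approx(0.02)
        with pytest.raises(ValueError):
            quick_influx_estimate(0.01, 0.2, 0.3)

    def test_converges_to_true_influx_for_small_memory_chimerism(self):
        # small rho_M and lam ~ 0: slope ratio approximates gamma S / M
        src = source()
        spec = ChimeraModelSpec(gamma0=3e-4, lam=0.0, M_inc=0.0)
        M0 = 1.5e6
        t = np.array([10.0, 12.0])
        sim = simulate_chimera(spec, src, M0, 0.001, t)
        drho = np.gradient(sim["rho_M"].to_numpy(), t)[0]
        est = quick_influx_estimate(
            drho, src.chimerism(t[0]), sim["rho_M"].iloc[0]
        )
        true = spec.gamma0 * src.size(t[0]) / np.interp(t[0], sim["t"], sim["M"])
        assert est == pytest.approx(true, rel=0.05)


class TestFitAndCompare:
    def test_noiseless_recovery(self, noiseless_chimera_data, tem_chimera_truth):
        """Parameter recovery on noiseless resistant-memory data."""
        truth = tem_chimera_truth
        model = ChimeraReplacementModel(
            noiseless_chimera_data, truth.source, "TEM", variant="resistant"
        )
        fit = model.fit(n_boot=0, seed=2, n_starts=20)
        assert fit.spec.gamma0 == pytest.approx(truth.spec.gamma0, rel=0.01)
        assert fit.spec.lam == pytest.approx(truth.spec.lam, rel=0.01)
        assert fit.spec.M_inc == pytest.approx(truth.spec.M_inc, rel=0.01)
        assert fit.M0 == pytest.approx(truth.M0, rel=0.01)

    def test_nested_variants_agree_when_truth_is_plain(self, tem_chimera_truth):
        # data generated with M_inc = 0 and phi = 0: the two variants share
        # the common nested sub-model and should fit about equally well
        truth = dataclasses.replace(
            tem_chimera_truth,
            spec=ChimeraModelSpec(
                gamma0=tem_chimera_truth.spec.gamma0, lam=0.01,
                M_inc=0.0, phi=0.0, variant="combined",
            ),
            sigma_logcount=0.08,
            sigma_chimerism=0.04,
        )
        data = generate_chimera_dataset(truth, seed=21)
        fits = [
            ChimeraReplacementModel(data, truth.source, "TEM", variant=v).fit(
                n_boot=0, seed=3, n_starts=15
            )
            for v in ("resistant", "declining")
        ]
        assert abs(fits[0].loglik - fits[1].loglik) < 2.0

    def test_compare_table(self, noiseless_chimera_data, tem_chimera_truth):
        model = ChimeraReplacementModel(
            noiseless_chimera_data, tem_chimera_truth.source, "TEM"
        )
        fit = model.fit(n_boot=0, seed=2, n_starts=5)
        twin = dataclasses.replace(fit, aic=fit.aic + 8.3)
        table = compare_chimera_models([fit, twin])
        assert table["delta_aic"].tolist() == [0.0, pytest.approx(8.3)]
        assert table["rel_prob"].iloc[1] == pytest.approx(0.02, abs=0.005)
        # closed form: delta = 2 ln 100 -> relative probability 1/100
        twin2 = dataclasses.replace(fit, aic=fit.aic + 2 * math.log(100))
        assert compare_chimera_models([fit, twin2])["rel_prob"].iloc[1] == (
            pytest.approx(0.01, rel=1e-9)
        )

    def test_compare_rejects_mismatched_data(
        self, noiseless_chimera_data, noisy_chimera_data, tem_chimera_truth
    ):
        src = tem_chimera_truth.source
        a = ChimeraReplacementModel(noiseless_chimera_data, src, "TEM").fit(
            n_boot=0, seed=2, n_starts=3
        )
        b = ChimeraReplacementModel(noisy_chimera_data, src, "TEM").fit(
            n_boot=0, seed=2, n_starts=3
        )
        with pytest.raises(ValueError, match="fingerprint"):
            compare_chimera_models([a, b])


@pytest.fixture(scope="module")
def projection_fit(noiseless_chimera_data, tem_chimera_truth):
    return ChimeraReplacementModel(
        noiseless_chimera_data, tem_chimera_truth.source, "TEM"
    ).fit(n_boot=0, seed=2, n_starts=10)


class TestProjection:
    def test_first_point_matches_replacement_summary(self, projection_fit):
        fit = projection_fit
        proj = fit.project(np.array([98.0, 200.0]), n_draws=0)
        assert proj["f_replace_week_total"].iloc[0] == pytest.approx(
            fit.replacement_summary(7.0).f_replace, rel=1e-6
        )

    def test_displaceable_curve_dominates_total(self, projection_fit):
        proj = projection_fit.project(np.arange(98.0, 800.0, 50.0), n_draws=0)
        assert (
            proj["f_replace_week_displaceable"]
            >= proj["f_replace_week_total"] - 1e-12
        ).all()
        assert proj["extrapolated"].iloc[-1]
        assert not proj["extrapolated"].iloc[0]

    def test_monotone_decline_when_drivers_shrink(self, tem_chimera_truth):
        # phi > 0 and R > 0 with lam <= 0: both influx drivers shrink while
        # the pool grows, so weekly replacement falls with age
        src = tem_chimera_truth.source
        for phi, lam in [(0.005, 0.0), (0.01, -0.001), (0.002, -0.002)]:
            spec = ChimeraModelSpec(
                gamma0=8e-4, lam=lam, M_inc=0.0, phi=phi, variant="declining"
            )
            tot = []
            for t0 in np.arange(0.0, 400.0, 50.0):
                shifted = ChimeraModelSpec(
                    gamma0=spec.gamma0 * np.exp(-phi * t0),
                    lam=lam, M_inc=0.0, phi=phi, variant="declining",
                )
                src_t = SourceDescriptor(
                    S0=src.S0 * np.exp(-src.R * t0), R=src.R,
                    rho_max=src.rho_max, rho_0=src.rho_0, r=src.r,
                )
                sim = simulate_chimera(spec, src, 1.2e6, 0.05,
                                       np.array([max(t0, 1e-6)]))
                rs = replacement_fraction(
                    shifted, src_t, float(sim["M"].iloc[-1]), 7.0, check=False
                )
                tot.append(rs.f_replace)
            assert all(np.diff(tot) < 0)
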