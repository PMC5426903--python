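"""Tests for the BrdU x Ki67 state space, steady-state resolution and
forward solver."""

import numpy as np
import pytest

from memokin.exceptions import InfeasibleParameterError
from memokin.labelling.solve import LabellingProtocol, solve_labelling
from memokin.labelling.spec import (
    KineticModelSpec,
    build_state_space,
    ki67_residence_summary,
    resolve_steady_state,
)


def kh_spec(**kw):
    base = dict(
        structure="KH", khat=6, bhat=2, beta=0.3, epsilon=0.8, tau=1.0,
        s_week=0.07, alpha_fast=0.15, alpha_slow=0.01, q_fast=0.4, f_slow=0.8,
    )
    base.update(kw)
    return KineticModelSpec(**base)


class TestStateSpace:
    @pytest.mark.parametrize(
        "structure,khat,bhat,expected",
        [("TH", 2, 2, 9), ("KH", 2, 2, 18), ("KH", 12, 2, 78), ("TH", 12, 3, 52)],
    )
    def test_state_counts(self, structure, khat, bhat, expected):
        spec = KineticModelSpec(structure=structure, khat=khat, bhat=bhat,
                                q_fast=0.5, kappa_obs=0.3)
        assert build_state_space(spec).n_states == expected

    def test_dilution_rule(self):
        space = build_state_space(kh_spec(bhat=2))
        # unlabelled stays unlabelled; labelled classes advance; the last
        # labelled class reverts to unlabelled after bhat divisions
        assert space.dilute(0) == 0
        assert space.dilute(1) == 2
        assert space.dilute(2) == 0


class TestResolution:
    def test_zero_source_equal_death_gives_delta_equals_alpha(self):
        # binary division balance: no source, ratio 1 -> delta = alpha
        spec = kh_spec(s_week=0.0, alpha_fast=0.15, alpha_slow=0.15)
        space = resolve_steady_state(spec)
        for sp in space.subpops:
            assert sp.delta_lo == pytest.approx(sp.alpha, rel=1e-9)

    def test_resolved_equilibrium_is_stationary(self, tem_space):
        # 100 unlabelled days leave pool size and Ki67 split unchanged
        spec = tem_space.spec
        protocol = LabellingProtocol(100.0, (0.0, 25.0, 50.0, 100.0))
        pred = solve_labelling(tem_space, protocol)
        totals = pred.states.sum(axis=1)
        assert np.allclose(totals, spec.N, rtol=1e-6)
        assert np.allclose(pred.kappa_model, tem_space.kappa_model, rtol=1e-6)

    def test_kh_kappa_constraint_resolves_alpha_slow(self, tem_kappa):
        spec = kh_spec(khat=12, alpha_slow=None, kappa_obs=tem_kappa,
                       alpha_fast=1 / 5.7, q_fast=0.38, f_slow=1.0,
                       beta=1 / 3.28, epsilon=0.76, tau=2.5)
        space = resolve_steady_state(spec)
        assert space.kappa_model == pytest.approx(tem_kappa, rel=1e-9)
        assert space.spec.alpha_slow == pytest.approx(1 / 138.0, rel=1e-3)

    def test_th_resolution_recovers_equal_death_rates(self):
        # when the Ki67 target comes from a ratio-1 model, the freely
        # resolved TH death rates must coincide
        base = kh_spec(alpha_fast=0.06, alpha_slow=0.06, q_fast=0.4, f_slow=0.6)
        kappa = resolve_steady_state(base).kappa_model
        th = KineticModelSpec(structure="TH", khat=6, bhat=2, beta=0.3,
                              epsilon=0.8, tau=1.0, s_week=0.07,
                              kappa_obs=kappa, alpha_fast=0.06)
        sp = resolve_steady_state(th).subpops[0]
        assert sp.delta_lo == pytest.approx(sp.delta_hi, rel=1e-8)
        assert sp.delta_lo == pytest.approx(0.06 + 0.01, rel=1e-8)

    def test_infeasible_kappa_raises(self):
        with pytest.raises(InfeasibleParameterError):
            resolve_steady_state(
                KineticModelSpec(structure="TH", khat=12, beta=0.3,
                                 alpha_fast=1.5, kappa_obs=0.3, s_week=0.07)
            )


class TestKi67Residence:
    def test_erlang_summaries(self):
        assert ki67_residence_summary(1, 0.5) == {"mean": 2.0, "cv": 1.0}
        s = ki67_residence_summary(12, 0.5)
        assert s["mean"] == 2.0  # mean invariant to staging
        assert s["cv"] == pytest.approx(1 / np.sqrt(12))


class TestSolveLabelling:
    def test_unlabelled_at_time_zero(self, tem_space):
        pred = solve_labelling(tem_space, LabellingProtocol(7.0, (0.0,)))
        assert pred.frac_brdu_in_ki67high[0] == 0.0
        assert pred.frac_brdu_in_ki67low[0] == 0.0

    def test_perfect_uptake_long_feed_saturates(self):
        spec = kh_spec(epsilon=1.0, alpha_slow=0.02)
        pred = solve_labelling(spec, LabellingProtocol(600.0, (600.0,)))
        assert pred.frac_brdu_in_ki67high[0] > 0.995
        assert pred.frac_brdu_in_ki67low[0] > 0.995

    def test_nondecreasing_during_feeding(self):
        times = np.linspace(0.0, 21.0, 40)
        for spec in [
            kh_spec(),
            kh_spec(epsilon=0.5, khat=1),
            kh_spec(death_ratio=10.0),
            kh_spec(death_ratio=0.1, alpha_fast=0.1),
        ]:
            pred = solve_labelling(spec, LabellingProtocol(21.0, tuple(times)))
            assert np.all(np.diff(pred.frac_brdu_in_ki67high) >= -1e-9)
            assert np.all(np.diff(pred.frac_brdu_in_ki67low) >= -1e-9)

    def test_more_ki67_stages_sharpen_post_chase_decline(self):
        prot = LabellingProtocol(7.0, (7.0, 10.0))
        at_10 = []
        for khat in (1, 2, 4, 8, 12):
            spec = KineticModelSpec(structure="TH", khat=khat, bhat=2, beta=0.3,
                                    epsilon=0.8, tau=1.0, s_week=0.07,
                                    kappa_obs=0.3, alpha_fast=0.06)
            at_10.append(solve_labelling(spec, prot).frac_brdu_in_ki67high[1])
        assert all(np.diff(at_10) < 0)

    def test_kh_collapses_to_th(self):
        # equal rates and proportional source split make the two KH
        # subpopulations indistinguishable from one TH population
        kh = kh_spec(alpha_fast=0.06, alpha_slow=0.06, q_fast=0.4, f_slow=0.6)
        sp_kh = resolve_steady_state(kh)
        th = KineticModelSpec(structure="TH", khat=6, bhat=2, beta=0.3,
                              epsilon=0.8, tau=1.0, s_week=0.07,
                              kappa_obs=sp_kh.kappa_model, alpha_fast=0.06)
        prot = LabellingProtocol(7.0, (1.0, 4.0, 7.0, 9.0, 12.0, 17.0, 21.0))
        a = solve_labelling(sp_kh, prot)
        b = solve_labelling(th, prot)
        assert np.allclose(a.frac_brdu_in_ki67high, b.frac_brdu_in_ki67high,
                           atol=1e-12)
        assert np.allclose(a.frac_brdu_in_ki67low, b.frac_brdu_in_ki67low,
                           atol=1e-12)

    def test_expm_and_stiff_integrator_agree(self, tem_space):
        prot = LabellingProtocol(4.0, (1.0, 2.0, 4.0, 6.0, 9.0, 13.0, 18.0))
        a = solve_labelling(tem_space, prot, method="expm")
        b = solve_labelling(tem_space, prot, method="ivp")
        assert np.allclose(a.frac_brdu_in_ki67high, b.frac_brdu_in_ki67high,
                           atol=1e-6)
        assert np.allclose(a.frac_brdu_in_ki67low, b.frac_brdu_in_ki67low,
                           atol=1e-6)
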