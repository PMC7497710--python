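"""Biophysical model builders: structure, closed forms and scan shapes."""

import numpy as np
import pytest

from regencycle import (
    CooperativeParams,
    MotorParams,
    RateMatrix,
    SlidingParams,
    TugOfWarParams,
    ValidationError,
    analyze,
    bound_state_velocity,
    build_cooperative,
    build_four_state,
    build_sliding,
    build_tug_of_war,
    build_two_state,
    embed_ctmc,
    homogenized_transport,
)

KINESIN = dict(N=2, F_s=6.0, F_d=3.0, eps0=1.0, pi0=5.0, v_f=1.0, v_b=0.006)
DYNEIN = dict(N=2, F_s=1.1, F_d=0.75, eps0=0.27, pi0=1.6, v_f=0.65, v_b=0.072)


class TestTwoState:
    def test_structure(self):
        m = build_two_state(0.5, 1.3, 0.9, 0.7)
        assert np.array_equal(m.P, [[0, 1], [1, 0]])
        assert m.laws[0].family == "exp_diffusion"
        assert m.laws[1].family == "exp_drift"
        assert m.base_state == 0

    def test_equal_rates_equal_sojourns(self):
        m = build_two_state(0.8, 0.8, 1.0, 1.0)
        assert m.laws[0].E_tau == m.laws[1].E_tau

    def test_rejects_nonpositive_params(self):
        with pytest.raises(ValidationError):
            build_two_state(-0.5, 1.0, 1.0, 1.0)


class TestFourState:
    def test_backward_speed_negated(self, rng):
        m = random_rates = rng.uniform(0.01, 0.1, (4, 4))
        m = build_four_state(random_rates, v_plus=0.8, v_minus=0.5, D=0.3)
        assert m.laws[1].params["v"] == 0.8
        assert m.laws[2].params["v"] == -0.5
        assert m.laws[3].family == "exp_pause"

    def test_renewal_matches_homogenization(self, rng):
        rates = rng.uniform(0.01, 0.1, (4, 4))
        vp, vm, D = 0.8, 0.5, 0.3
        m = build_four_state(rates, vp, vm, D)
        rm = RateMatrix.from_rates(rates, [0.0, vp, -vm, 0.0], [D, 0, 0, 0])
        r, h = analyze(m), homogenized_transport(rm)
        assert abs(r.v_eff - h.v_eff) < 1e-10
        assert abs(r.D_eff - h.D_eff) < 1e-8

    def test_opposite_speeds_all_equal_rates_cancel(self):
        """With a symmetric chain and v_- = -v_+ the transport contributions
        cancel, leaving only the diffusive state's weighted diffusivity."""
        rates = np.full((4, 4), 0.05)
        m = build_four_state(rates, v_plus=0.7, v_minus=0.7, D=0.4)
        et = analyze(m)
        assert abs(et.v_eff) < 1e-14
        h = homogenized_transport(
            RateMatrix.from_rates(rates, [0, 0.7, -0.7, 0], [0.4, 0, 0, 0]))
        assert et.D_eff == pytest.approx(h.D_eff, abs=1e-8)


class TestCooperative:
    def test_no_load_full_speed_in_every_bound_state(self):
        p = CooperativeParams(N=3, v=1.2, eps=1.0, pi=5.0, F=0.0, w=0.5)
        assert [p.velocity(n) for n in range(4)] == [0.0, 1.2, 1.2, 1.2]

    def test_single_motor_stalls_at_stall_force(self):
        p = CooperativeParams(N=1, v=1.0, eps=1.0, pi=5.0, F=6.0,
                              F_s=6.0, F_d=3.0)
        et = analyze(build_cooperative(p))
        assert et.v_eff == pytest.approx(0.0, abs=1e-14)

    def test_substall_velocity_clipped_to_zero(self):
        p = CooperativeParams(N=2, v=1.0, eps=1.0, pi=5.0, F=10.0,
                              F_s=6.0, F_d=3.0)
        assert p.velocity(1) == 0.0       # F > F_s: stalled, not reversing
        assert p.velocity(2) > 0.0

    def test_n2_closed_form_velocities(self):
        """Overall v_eff from the full chain and the bound-state average both
        reduce to ratios of binding/unbinding rate products."""
        p = CooperativeParams(N=2, v=1.0, eps=1.0, pi=5.0, F=2.0,
                              F_s=6.0, F_d=3.0, w=1.0)
        m = build_cooperative(p)
        e1, e2 = p.unbind_rate(1), p.unbind_rate(2)
        pi0, pi1 = p.bind_rate(0), p.bind_rate(1)
        v1, v2 = p.velocity(1), p.velocity(2)
        den = e1 * e2 + pi0 * e2 + pi0 * pi1
        assert analyze(m).v_eff == pytest.approx(
            (v1 * pi0 * e2 + v2 * pi0 * pi1) / den, rel=1e-10)
        assert bound_state_velocity(m) == pytest.approx(
            (v1 * pi0 * e2 + v2 * pi0 * pi1) / (pi0 * e2 + pi0 * pi1),
            rel=1e-10)

    @pytest.mark.parametrize("w", [0.5, 1.0, 2.0])
    def test_velocities_decrease_with_load(self, w):
        Fs = np.linspace(0.0, 12.0, 13)
        overall, bound = [], []
        for F in Fs:
            p = CooperativeParams(N=2, v=1.0, eps=1.0, pi=5.0, F=F,
                                  F_s=6.0, F_d=3.0, w=w)
            m = build_cooperative(p)
            overall.append(analyze(m).v_eff)
            bound.append(bound_state_velocity(m))
        overall, bound = np.array(overall), np.array(bound)
        assert np.all(np.diff(overall) <= 1e-12)
        assert np.all(np.diff(bound) <= 1e-12)
        # ordering: overall <= bound <= fastest state
        for F, vo, vb in zip(Fs, overall, bound):
            p = CooperativeParams(N=2, v=1.0, eps=1.0, pi=5.0, F=F,
                                  F_s=6.0, F_d=3.0, w=w)
            vmax = max(p.velocity(n) for n in (1, 2))
            assert vo <= vb + 1e-12 <= vmax + 1e-9

    def test_diffusivity_nonmonotone_in_load(self):
        """Switching noise first grows with load (more detachment churn) and
        then dies as the moving states stall."""
        D = [analyze(build_cooperative(
            CooperativeParams(N=2, v=1.0, eps=1.0, pi=5.0, F=F,
                              F_s=6.0, F_d=3.0))).D_eff
             for F in np.linspace(0.0, 20.0, 21)]
        k = int(np.argmax(D))
        assert 0 < k < len(D) - 1
        assert D[k] > D[0] and D[k] > D[-1]


class TestTugOfWar:
    def test_symmetric_teams_have_zero_velocity(self):
        for F_s in (1.0, 3.0, 6.0, 12.0):
            kin = dict(KINESIN, F_s=F_s)
            p = TugOfWarParams(plus=MotorParams(**kin),
                               minus=MotorParams(**kin))
            assert abs(analyze(build_tug_of_war(p)).v_eff) <= 1e-12

    def test_swapping_teams_negates_velocity(self):
        a = analyze(build_tug_of_war(TugOfWarParams(
            plus=MotorParams(**KINESIN), minus=MotorParams(**DYNEIN))))
        b = analyze(build_tug_of_war(TugOfWarParams(
            plus=MotorParams(**DYNEIN), minus=MotorParams(**KINESIN))))
        assert abs(a.v_eff + b.v_eff) < 1e-10
        assert abs(a.D_eff - b.D_eff) < 1e-10

    def test_minus_team_absent_reduces_to_cooperative(self):
        p = TugOfWarParams(plus=MotorParams(**KINESIN),
                           minus=MotorParams(N=0, F_s=1, F_d=1, eps0=1,
                                             pi0=1, v_f=1, v_b=1))
        tow = analyze(build_tug_of_war(p))
        coop = analyze(build_cooperative(CooperativeParams(
            N=2, v=KINESIN["v_f"], eps=KINESIN["eps0"], pi=KINESIN["pi0"],
            F=0.0, F_s=6.0, F_d=3.0)))
        assert tow.v_eff == pytest.approx(coop.v_eff, rel=1e-12)
        assert tow.D_eff == pytest.approx(coop.D_eff, rel=1e-12)

    def test_plus_only_states_run_at_forward_speed(self):
        p = TugOfWarParams(plus=MotorParams(**KINESIN),
                           minus=MotorParams(**DYNEIN))
        m = build_tug_of_war(p)
        # states (n_+, 0) for n_+ > 0 carry velocity v_f+
        for n_p in (1, 2):
            i = m.labels.index(f"(+{n_p},-0)")
            assert m.laws[i].params["v"] == pytest.approx(KINESIN["v_f"])

    def test_run_length_nondecreasing_in_reattachment(self):
        rl = []
        for rho in (1.0, 2.0, 5.0, 10.0, 20.0, 50.0):
            p = TugOfWarParams(plus=MotorParams(**KINESIN),
                               minus=MotorParams(**dict(DYNEIN, N=1)),
                               rho=rho)
            rl.append(analyze(build_tug_of_war(p)).run_length)
        assert np.all(np.diff(rl) >= -1e-12)

    def test_diffusive_unbound_state_raises_diffusivity_only(self):
        base = TugOfWarParams(plus=MotorParams(**KINESIN),
                              minus=MotorParams(**DYNEIN))
        diff = TugOfWarParams(plus=MotorParams(**KINESIN),
                              minus=MotorParams(**DYNEIN), D_c=0.1)
        a, b = analyze(build_tug_of_war(base)), analyze(build_tug_of_war(diff))
        assert b.v_eff == pytest.approx(a.v_eff, abs=1e-12)
        assert b.D_eff > a.D_eff

    def test_empty_model_rejected(self):
        with pytest.raises(ValidationError):
            TugOfWarParams(plus=MotorParams(N=0, F_s=1, F_d=1, eps0=1, pi0=1,
                                            v_f=1, v_b=1),
                           minus=MotorParams(N=0, F_s=1, F_d=1, eps0=1, pi0=1,
                                             v_f=1, v_b=1))


class TestSliding:
    def test_zero_velocity_by_symmetry(self):
        for gamma in (0.0, 1.0, 3.0):
            p = SlidingParams(K=10, kappa0=0.25, gamma=gamma, V_m=0.78)
            assert abs(analyze(build_sliding(p)).v_eff) < 1e-10

    def test_gamma_zero_is_ehrenfest_chain(self):
        p = SlidingParams(K=6, kappa0=0.5, gamma=0.0, V_m=1.0)
        m = build_sliding(p)
        lam = np.array([1.0 / law.E_tau for law in m.laws])
        # exit rate of state i is (K - i) kappa0 + i kappa0 = K kappa0
        np.testing.assert_allclose(lam, 6 * 0.5, rtol=1e-12)

    def test_diffusivity_invariant_under_relabeling(self):
        """The chain is symmetric under i <-> K - i with negated velocities."""
        p = SlidingParams(K=8, kappa0=0.3, gamma=1.5, V_m=0.6)
        m = build_sliding(p)
        K = p.K
        R = np.zeros((K + 1, K + 1))
        v = np.zeros(K + 1)
        for i in range(K + 1):
            j = K - i
            if i < K:
                R[j, K - (i + 1)] = (K - i) * p.kappa0 * np.exp(p.gamma * i / K)
            if i > 0:
                R[j, K - (i - 1)] = i * p.kappa0 * np.exp(p.gamma * (K - i) / K)
            v[j] = -p.V_m * (2 * i - K) / K
        rm = RateMatrix.from_rates(R, v, np.zeros(K + 1))
        et, et_rel = analyze(m), analyze(embed_ctmc(rm, m.base_state))
        assert et_rel.D_eff == pytest.approx(et.D_eff, rel=1e-10)

    def test_diffusivity_increases_with_load_sensitivity(self):
        D = [analyze(build_sliding(SlidingParams(K=35, kappa0=0.25, gamma=g,
                                                 V_m=0.78))).D_eff
             for g in np.linspace(0.0, 4.0, 9)]
        assert np.all(np.diff(D) > 0)
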