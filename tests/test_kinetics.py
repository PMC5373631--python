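"""Whole-cell kinetic model: rates, conservation, phase plane, regimes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from scipy.optimize import brentq

from podofp.kinetics import (ActinState, ConservationError, KineticParams,
                             RegimeLabel, calibrated_params, classify_regime,
                             default_effacement_threshold, effacement_check,
                             find_equilibria, ga_from_conservation,
                             healthy_state, nullclines, reduced_rhs, rhs,
                             simulate)
from podofp.presets import get_params
from podofp.protocols import step_protocol


def grid_partition_count(p: KineticParams, n: int = 600) -> int:
    """Independent equilibrium-count oracle: sign partition of the vector
    field on a dense grid, stated directly from the model equations."""
    hi = p.total_actin / p.phi_fp
    f = np.linspace(0, hi, n)
    F, B = np.meshgrid(f, f, indexing="ij")
    Ga = np.clip(p.total_actin - p.phi_fp * (F + B), 0, None)
    h, nuc = p.hill_h, p.nucleation
    dF = p.alpha_f * Ga * F**h / (F**h + p.k**h) + p.gamma_f * Ga * F \
        + 2 * nuc * Ga**2 - p.alpha_b * F * (2 * F + B) - p.beta_f * F
    dB = p.alpha_b * F * (2 * F + B) + p.gamma_b * Ga * B - p.beta_b * B
    sF, sB = np.sign(dF), np.sign(dB)

    def changes(s):
        return (s[:-1, :-1] * s[1:, :-1] <= 0) \
            | (s[:-1, :-1] * s[:-1, 1:] <= 0) \
            | (s[:-1, :-1] * s[1:, 1:] <= 0)

    cand = changes(sF) & changes(sB) & ((F + B) <= hi)[:-1, :-1]
    _, ncomp = ndimage.label(cand, structure=np.ones((3, 3), int))
    return ncomp


class TestRates:
    def test_stoichiometric_closure(self, baseline):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fa, bu = rng.uniform(0, 1.5, 2)
            ga = rng.uniform(0, 0.4)
            d = rhs(ActinState(ga, fa, bu), baseline)
            assert abs(sum(d)) < 1e-15

    def test_no_filaments_pure_nucleation(self, baseline):
        g = 0.3
        dfa, dbu, _ = rhs(ActinState(g, 0.0, 0.0), baseline)
        assert dfa == pytest.approx(2 * baseline.gamma_f * g**2)
        assert dbu == 0.0

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            ActinState(-0.1, 0.0, 0.0)

    def test_healthy_state_is_equilibrium(self, baseline):
        hs = healthy_state(baseline)
        assert np.max(np.abs(rhs(hs, baseline))) < 1e-8

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(k=0.0)
        with pytest.raises(ValueError):
            KineticParams(phi_fp=1.2)


class TestConservation:
    @given(fa=st.floats(0, 1.0), bu=st.floats(0, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_identity_exact(self, fa, bu):
        p = calibrated_params()
        ga = float(ga_from_conservation(fa, bu, p))
        assert ga + p.phi_fp * (fa + bu) == pytest.approx(p.total_actin,
                                                          abs=1e-12)

    def test_empty_pools_give_total(self, baseline):
        assert ga_from_conservation(0.0, 0.0, baseline) \
            == pytest.approx(baseline.total_actin)

    def test_overfull_pool_raises(self, baseline):
        hi = baseline.total_actin / baseline.phi_fp
        with pytest.raises(ConservationError):
            ga_from_conservation(hi, hi, baseline)

    def test_healthy_monomer_polymer_ratio(self, baseline):
        # healthy podocyte holds monomeric : polymerised actin at 1:2
        hs = healthy_state(baseline)
        poly = (hs.Fa + hs.Bu) * baseline.phi_fp
        assert poly / hs.Ga == pytest.approx(2.0, rel=1e-9)

    def test_trajectory_conserves_total(self, baseline):
        hs = healthy_state(baseline)
        init = ActinState(float(ga_from_conservation(0.5, 0.3, baseline)),
                          0.5, 0.3)
        traj = simulate(baseline, init, t_end=800.0)
        tot = traj.total_actin(baseline)
        assert np.max(np.abs(tot - baseline.total_actin)) < 1e-7


class TestSimulation:
    def test_all_rates_zero_constant(self):
        p = calibrated_params().replace(alpha_f=0, gamma_f=0, alpha_b=0,
                                        gamma_b=0, beta_f=0, beta_b=0)
        init = ActinState(float(ga_from_conservation(0.4, 0.2, p)), 0.4, 0.2)
        traj = simulate(p, init, t_end=100.0)
        assert np.allclose(traj.fa, 0.4) and np.allclose(traj.bu, 0.2)

    def test_monostable_trajectories_converge(self, baseline):
        finals = []
        for fa0, bu0 in ((0.6, 0.2), (0.05, 1.8)):
            ga0 = float(ga_from_conservation(fa0, bu0, baseline))
            traj = simulate(baseline, ActinState(ga0, fa0, bu0), t_end=4000.0)
            finals.append((traj.fa[-1], traj.bu[-1]))
        assert finals[0] == pytest.approx(finals[1], abs=1e-4)

    def test_oscillatory_period_tolerance_robust(self):
        # sustained cycles; period stable under halved tolerances
        from scipy.signal import find_peaks

        p = get_params("fig2E")

        def period(rtol):
            traj = simulate(p, t_end=4000.0, rtol=rtol, n_out=4000)
            tail = traj.bu[traj.t > 1500]
            tt = traj.t[traj.t > 1500]
            peaks, _ = find_peaks(tail, prominence=0.05)
            assert len(peaks) >= 3
            return float(np.diff(tt[peaks]).mean())

        p1, p2 = period(1e-8), period(5e-9)
        assert p1 == pytest.approx(p2, rel=0.01)
        assert 200 < p1 < 600

    def test_inconsistent_init_raises(self, baseline):
        with pytest.raises(ConservationError):
            simulate(baseline, ActinState(0.4, 0.5, 0.5), t_end=10.0)


class TestPhasePlane:
    def test_nullcline_points_are_roots(self, baseline):
        curves = nullclines(baseline, resolution=150)
        for idx, key in ((0, "fa"), (1, "bu")):
            pts = np.vstack(curves[key])
            resid = np.abs([reduced_rhs(f, b, baseline)[idx]
                            for f, b in pts[::7]])
            assert resid.max() < 1e-6

    @pytest.mark.parametrize("param,idx,direction", [
        ("alpha_f", 0, +1), ("beta_f", 0, -1),
        ("alpha_b", 1, +1), ("beta_b", 1, -1)])
    def test_nullcline_shift_directions(self, baseline, param, idx,
                                        direction):
        # finite-difference displacement of the nullcline at fixed Fa
        fa0 = 0.23

        def bu_root(q):
            return brentq(lambda b: reduced_rhs(fa0, b, q)[idx], 0.3, 5.0)

        q = baseline.replace(**{param: getattr(baseline, param) * 1.05})
        shift = bu_root(q) - bu_root(baseline)
        assert np.sign(shift) == direction

    def test_nullcline_intersections_match_equilibria(self):
        # every equilibrium lies on both sampled nullclines (within a few
        # grid steps: steep fold sections are sampled sparsely transversely)
        p = get_params("fig2D")
        curves = nullclines(p, fa_range=(0.0, 0.5), resolution=800)
        fa_pts = np.vstack(curves["fa"])
        bu_pts = np.vstack(curves["bu"])
        step = 0.5 / 800
        for e in find_equilibria(p):
            x = np.array([e.state.Fa, e.state.Bu])
            d_fa = np.min(np.hypot(*(fa_pts - x).T))
            d_bu = np.min(np.hypot(*(bu_pts - x).T))
            assert max(d_fa, d_bu) < 5 * step


class TestEquilibria:
    def test_fig2c_single_stable(self):
        eqs = find_equilibria(get_params("fig2C"))
        assert len(eqs) == 1 and eqs[0].stability == "stable"
        assert not eqs[0].in_effacement_region
        assert eqs[0].state.Bu == pytest.approx(1.1066667, abs=1e-5)

    def test_fig2d_three_roots_two_stable(self):
        eqs = find_equilibria(get_params("fig2D"))
        assert len(eqs) == 3
        stable = [e for e in eqs if e.stability == "stable"]
        assert len(stable) == 2
        assert sum(e.in_effacement_region for e in stable) == 1

    def test_pure_decay_origin_stable(self, baseline):
        p = baseline.replace(alpha_f=0, gamma_f=0, alpha_b=0, gamma_b=0)
        eqs = find_equilibria(p)
        assert len(eqs) == 1
        e = eqs[0]
        assert e.stability == "stable"
        assert e.state.Fa == pytest.approx(0.0, abs=1e-9)
        assert e.state.Bu == pytest.approx(0.0, abs=1e-9)

    def test_residual_below_tolerance(self, baseline):
        for e in find_equilibria(baseline):
            resid = np.hypot(*reduced_rhs(e.state.Fa, e.state.Bu, baseline))
            assert resid < 1e-10

    def test_count_matches_grid_oracle_random_sets(self, baseline):
        # root finder agrees with the sign-partition oracle across a box of
        # random parameter sets
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 20:
            p = baseline.replace(
                alpha_f=rng.uniform(0.05, 0.4),
                alpha_b=rng.uniform(0.01, 0.06),
                beta_f=rng.uniform(0.02, 0.08),
                beta_b=rng.uniform(0.005, 0.02),
                gamma_f=rng.uniform(0.001, 0.004),
                gamma_b=rng.uniform(0.0, 0.004))
            n_found = len(find_equilibria(p))
            n_oracle = grid_partition_count(p)
            if n_oracle != n_found:
                # coarse grids can split one root region into several
                # candidate clusters near tangencies; settle at high density
                n_oracle = grid_partition_count(p, n=2000)
            assert n_found == n_oracle
            checked += 1


class TestRegimes:
    def test_calibrated_regime_table(self):
        expect = {"fig2C": RegimeLabel.MONOSTABLE_HEALTHY,
                  "fig2D": RegimeLabel.BISTABLE,
                  "fig2E": RegimeLabel.OSCILLATORY,
                  "fig2F": RegimeLabel.COLLAPSE}
        for name, label in expect.items():
            assert classify_regime(get_params(name)) is label

    def test_pure_decay_collapse(self, baseline):
        p = baseline.replace(alpha_f=0, gamma_f=0, alpha_b=0, gamma_b=0)
        assert classify_regime(p) is RegimeLabel.COLLAPSE

    def test_reduced_actin_pool_collapses_under_high_bundling(self):
        # at 70% of the baseline pool, raised bundling collapses the
        # cytoskeleton; at 115% it oscillates with stronger bundles
        p = get_params("fig2E")
        hs = healthy_state(get_params("fig2C"))
        low = p.replace(total_actin=0.7 * p.total_actin)
        init = ActinState(float(ga_from_conservation(hs.Fa, hs.Bu, low,
                                                     strict=False)),
                          hs.Fa, hs.Bu)
        traj = simulate(low, init, t_end=8000.0)
        assert traj.bu[-1] < default_effacement_threshold()
        high = p.replace(total_actin=1.15 * p.total_actin)
        init = ActinState(float(ga_from_conservation(hs.Fa, hs.Bu, high)),
                          hs.Fa, hs.Bu)
        traj = simulate(high, init, t_end=8000.0)
        tail = traj.bu[traj.t > 6000]
        assert tail.max() > hs.Bu  # stronger yet still unstable bundles
        assert tail.max() - tail.min() > 0.1

    def test_nucleation_split_preserves_regimes(self):
        base = calibrated_params(nucleation_n=0.0025)
        assert classify_regime(base) is RegimeLabel.MONOSTABLE_HEALTHY
        assert classify_regime(base.replace(alpha_f=0.1)) \
            is RegimeLabel.BISTABLE


class TestEffacement:
    def test_zero_bundles_effaced(self):
        assert effacement_check(ActinState(0.1, 0.1, 0.0))

    def test_healthy_equilibrium_not_effaced(self, baseline):
        eq = find_equilibria(baseline)[0]
        assert not effacement_check(eq.state)

    def test_tiny_threshold_never_fires(self):
        assert not effacement_check(ActinState(0.1, 0.1, 0.01),
                                    threshold=1e-12)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            effacement_check(ActinState(0, 0, 0), threshold=0.0)
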