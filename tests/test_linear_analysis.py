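"""Stability of the linearized circuit and the reduced delayed oscillator."""

import numpy as np
import pytest

from bgbeta.linear_analysis import (
    LoopWeights,
    ReducedModelParams,
    critical_long_loop,
    default_linear_base,
    delay_scan,
    linear_simulate,
    reduced_boundary,
    reduced_boundary_numeric,
    reduced_critical_wss,
    reduced_rightmost_root,
    stability_surface,
)
from bgbeta.params import preset


# -- independent characteristic-equation oracle for the full linear model --

def _char_det(lam, p):
    """det of the 4x4 characteristic matrix of the identity-activation
    model (independent transcription used as test oracle)."""
    e = np.exp
    M = np.array([
        [p.tau_S * lam + 1, p.w_GS * e(-lam * p.T_GS),
         -p.w_CS * e(-lam * p.T_CS), 0],
        [-p.w_SG * e(-lam * p.T_SG),
         p.tau_G * lam + 1 + p.w_GG * e(-lam * p.T_GG), 0, 0],
        [p.w_SC * e(-lam * p.T_SC), 0, p.tau_E * lam + 1,
         p.w_CC * e(-lam * p.T_CC)],
        [0, 0, -p.w_CC * e(-lam * p.T_CC), p.tau_I * lam + 1],
    ], dtype=complex)
    return np.linalg.det(M)


def _rightmost_root(p):
    from scipy.optimize import root

    best = None
    for re0 in (-0.05, -0.01, 0.01, 0.05):
        for im0 in np.linspace(0.01, 0.45, 23):
            sol = root(
                lambda v: [
                    _char_det(v[0] + 1j * v[1], p).real,
                    _char_det(v[0] + 1j * v[1], p).imag,
                ], [re0, im0], tol=1e-13)
            if not sol.success:
                continue
            z = complex(sol.x[0], abs(sol.x[1]))
            if abs(_char_det(z, p)) > 1e-6:
                continue
            if best is None or z.real > best.real:
                best = z
    return best


class TestLinearSimulate:
    def test_uncoupled_loops_decay(self):
        r = linear_simulate(LoopWeights(0, 0, 0), duration=1500.0)
        assert r.classification == "stable"

    def test_strong_long_loop_alone_destabilizes(self):
        r = linear_simulate(LoopWeights(0, 0, 2.5), duration=1500.0)
        assert r.classification == "unstable"
        assert 5.0 < r.frequency < 35.0

    @pytest.mark.parametrize("seed", range(6))
    def test_classification_matches_characteristic_roots(self, seed):
        rng = np.random.default_rng(1000 + seed)
        lw = LoopWeights(rng.uniform(0, 2.5), rng.uniform(0, 2.5),
                         rng.uniform(0, 2.2))
        sim = linear_simulate(lw, duration=2500.0)
        z = _rightmost_root(lw.to_params())
        assert z is not None
        if abs(z.real) < 2e-5:
            return  # too close to the boundary to compare signs
        assert (z.real > 0) == (sim.classification == "unstable"), \
            f"{lw} root {z} vs {sim.classification} ({sim.growth_rate})"

    def test_constant_drives_do_not_change_classification(self):
        base = default_linear_base()
        driven = base.replace(C=172.18, Str=8.46)
        for triple in [(0.5, 0.5, 0.5), (0.0, 0.0, 2.0), (1.8, 0.0, 0.8)]:
            r0 = linear_simulate(LoopWeights(*triple, base=base),
                                 duration=1500.0)
            r1 = linear_simulate(LoopWeights(*triple, base=driven),
                                 duration=1500.0)
            assert r0.classification == r1.classification
            assert r0.growth_rate == pytest.approx(r1.growth_rate,
                                                   abs=1e-4)

    def test_gpe_self_inhibition_damps_in_fitted_regime(self):
        """Within the fitted range of the GPe self-inhibition (w_GG below
        about 1) the delayed self-connection acts as a leak: it never turns
        a stable triple unstable.  (At much larger gains its 4 ms delay can
        itself add destabilizing phase lag, so the claim is regime-bound.)"""
        base = default_linear_base()
        for triple in [(1.0, 1.0, 1.0), (0.0, 0.0, 1.2), (1.5, 0.5, 0.5)]:
            low = linear_simulate(
                LoopWeights(*triple, base=base.replace(w_GG=0.0)),
                duration=1500.0)
            if low.classification != "stable":
                continue
            for wgg in (0.3, 0.6, 0.9):
                high = linear_simulate(
                    LoopWeights(*triple, base=base.replace(w_GG=wgg)),
                    duration=1500.0)
                assert high.classification == "stable"


class TestStabilitySurface:
    def test_critical_long_loop_matches_root_finding(self):
        wc = critical_long_loop(duration=2500.0, tol=2e-3)
        # independent boundary from the characteristic equation
        from scipy.optimize import brentq

        base = default_linear_base()

        def sigma(w):
            p = LoopWeights(0.0, 0.0, w, base=base).to_params()
            return _rightmost_root(p).real

        wc_root = brentq(sigma, 0.5, 3.0, xtol=1e-4)
        assert wc == pytest.approx(wc_root, abs=0.02)

    def test_surface_interaction_region_exists(self):
        """A triple below every single-loop threshold can still be
        unstable: the loops destabilize cooperatively."""
        r = linear_simulate(LoopWeights(1.5, 1.5, 1.2), duration=2500.0)
        assert r.classification == "unstable"
        for lone in (LoopWeights(1.5, 0, 0), LoopWeights(0, 1.5, 0),
                     LoopWeights(0, 0, 1.2)):
            assert linear_simulate(lone,
                                   duration=2500.0).classification \
                == "stable"

    def test_raising_any_coupling_from_boundary_destabilizes(self):
        sb, freq = stability_surface([0.0, 1.0], [0.0, 1.0],
                                     duration=1500.0, tol=5e-3)
        assert np.all(np.isfinite(sb.critical))
        for i, wsg in enumerate((0.0, 1.0)):
            for j, wcc in enumerate((0.0, 1.0)):
                wc = sb.critical[i, j]
                above = linear_simulate(LoopWeights(wsg, wcc, wc + 0.1),
                                        duration=1500.0)
                below = linear_simulate(
                    LoopWeights(wsg, wcc, max(wc - 0.1, 0.0)),
                    duration=1500.0)
                assert above.growth_rate > below.growth_rate
                assert above.classification == "unstable"

    def test_onset_frequencies_in_beta_band(self):
        _, freq = stability_surface([0.0, 1.5], [0.0, 1.5],
                                    duration=1500.0, tol=5e-3)
        vals = freq[np.isfinite(freq)]
        assert vals.size > 0
        assert np.all((vals > 5.0) & (vals < 35.0))


class TestDelayScan:
    def test_identity_scaling_reproduces_base_frequency(self, feedback_best):
        from bgbeta.core_model import simulate
        from bgbeta.metrics_and_fit import extract_metrics

        df = delay_scan(feedback_best, alphas=[1.0], duration=4000.0)
        base = extract_metrics(simulate(feedback_best, duration=4000.0,
                                        step=0.05, transient=1000.0))
        assert df.frequency.iloc[0] == pytest.approx(base.frequency_fft,
                                                     rel=1e-9)

    def test_frequency_delay_curve_non_monotonic(self, feedback_best):
        df = delay_scan(feedback_best,
                        alphas=np.linspace(0.25, 3.0, 10),
                        duration=4000.0)
        f = df.frequency.to_numpy()
        assert np.isfinite(f).all()
        d = np.diff(f)
        # at least one decreasing and one increasing segment: a local
        # minimum exists inside the scanned 3-fold delay range
        assert np.any(d < -0.1) and np.any(d > 0.1)


class TestReducedModel:
    def test_no_delay_limit_is_stable_for_any_feedback(self):
        # at T -> 0 the characteristic polynomial has all-positive
        # coefficients: stable for every w_SS >= 0
        for w in (0.5, 2.0, 8.0):
            z = reduced_rightmost_root(w, 0.05, ReducedModelParams().b)
            assert z.real < 0

    def test_stability_alternates_with_delay_at_wss_2(self):
        Ts = np.linspace(0.3, 6.0, 25)
        crit = np.array([reduced_critical_wss(T) for T in Ts])
        unstable = crit < 2.0  # w_SS = 2 sits above the boundary here
        assert unstable.any() and (~unstable).any()
        # and the pattern alternates more than once (periodic dependence)
        assert np.sum(np.abs(np.diff(unstable.astype(int)))) >= 3

    def test_analytic_boundary_matches_simulation_within_two_percent(self):
        Ts = [0.5, 1.0, 1.6875, 2.5, 4.0]
        numeric = reduced_boundary_numeric(Ts, duration=800.0, tol=2e-3)
        for T, w_num in zip(Ts, numeric.critical):
            w_ana = reduced_critical_wss(T)
            assert abs(w_num - w_ana) / w_ana < 0.02

    def test_boundary_roots_cross_imaginary_axis(self):
        rp = ReducedModelParams()
        for T in (0.8, 1.6875, 3.0):
            wc = reduced_critical_wss(T, rp)
            assert reduced_rightmost_root(0.9 * wc, T, rp.b).real < 0
            assert reduced_rightmost_root(1.1 * wc, T, rp.b).real > 0

    def test_onset_frequencies_reported_in_hertz(self):
        sb = reduced_boundary(ReducedModelParams(), T_range=(1.0, 3.0))
        # omega ~ beta band once rescaled by tau = 16 ms
        assert np.all(sb.frequency > 0)
        band = sb.frequency[(sb.values > 1.5) & (sb.values < 2.0)]
        assert np.any((band > 10.0) & (band < 30.0))
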