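"""Oscillation metrics, the cost function and the annealing optimizer."""

import numpy as np
import pytest

from bgbeta.core_model import ConfigError, Trajectory, simulate
from bgbeta.metrics_and_fit import (
    DEFAULT_BOUNDS,
    FIT_PARAM_NAMES,
    FitConstraints,
    OscillationMetrics,
    PopulationStats,
    bounds_violation_penalty,
    cost,
    evaluate_candidate,
    extract_metrics,
    fft_frequency,
    fit,
    interpeak_frequency,
    params_to_vector,
    vector_to_params,
)
from bgbeta.params import LesionSpec, LesionTarget, ProtocolError, preset
from bgbeta.spiketrain import RateProcessParams, simulate_rate


def make_trajectory(S, G, dt=0.5, transient=1000.0):
    t = np.arange(S.size) * dt
    zero = np.zeros_like(S)
    return Trajectory(times=t, S=S, G=G, E=zero, I=zero,
                      params=preset("fig3A"), lesion=LesionSpec(),
                      step=dt, transient=transient)


def sine(amp, base, freq, dt=0.5, total=6000.0):
    t = np.arange(0, total, dt)
    return base + amp * np.sin(2 * np.pi * freq * t / 1000.0)


def metrics_bundle(stn, gpe, freq, oscillating=True):
    return OscillationMetrics(
        stn=PopulationStats(*stn), gpe=PopulationStats(*gpe),
        frequency=freq, frequency_fft=freq, is_oscillating=oscillating,
    )


class TestExtractMetrics:
    def test_pure_sine_recovers_target_statistics(self):
        traj = make_trajectory(sine(60, 65, 14.0), sine(55, 100, 14.0))
        m = extract_metrics(traj)
        assert m.stn.minimum == pytest.approx(5.0, abs=0.1)
        assert m.stn.mean == pytest.approx(65.0, abs=0.1)
        assert m.stn.maximum == pytest.approx(125.0, abs=0.1)
        assert m.gpe.minimum == pytest.approx(45.0, abs=0.1)
        assert m.gpe.maximum == pytest.approx(155.0, abs=0.1)
        assert m.frequency == pytest.approx(14.0, abs=0.05)
        assert m.is_oscillating

    def test_constant_trace_reports_no_frequency(self):
        traj = make_trajectory(np.full(8000, 50.0), np.full(8000, 80.0))
        m = extract_metrics(traj)
        assert not m.is_oscillating
        assert m.stn.amplitude == pytest.approx(0.0, abs=1e-12)
        assert m.frequency is None

    def test_too_short_trajectory_rejected(self):
        traj = make_trajectory(sine(60, 65, 14, total=1500.0),
                               sine(55, 100, 14, total=1500.0))
        with pytest.raises(ConfigError):
            extract_metrics(traj)

    def test_interpeak_and_fft_estimates_agree_under_phase_noise(self):
        # noisy sinusoid rate traces, phase-noise strengths up to N = 4
        for N in (0.0, 1.0, 2.5, 4.0):
            for seed in range(3):
                p = RateProcessParams(A=60, b=65, f=14.0, N=N, duration=40.0)
                r = simulate_rate(p, seed=seed)
                t = np.arange(r.size, dtype=float)
                f1, _ = interpeak_frequency(t, r)
                f2 = fft_frequency(t, r)
                assert abs(f1 - f2) < 0.5


ZERO_AMP = dict(stn=(65.0, 65.0, 65.0), gpe=(100.0, 100.0, 100.0),
                freq=None, oscillating=False)


def perfect_bundle():
    """Metrics that satisfy every term of the cost exactly."""
    intact = metrics_bundle((5, 65, 125), (45, 100, 155), 14.0)
    flat = metrics_bundle(**ZERO_AMP)
    str_keep = metrics_bundle((5, 70, 125), (50, 105, 160), 14.0)
    lesioned = {"cut_w_SG": flat, "cut_w_GS": flat, "cut_w_CS": flat,
                "cut_Str": str_keep}
    return intact, lesioned


class TestCost:
    def test_perfect_protocol_costs_zero(self):
        intact, lesioned = perfect_bundle()
        assert cost(intact, lesioned) == pytest.approx(0.0, abs=1e-12)

    def test_one_hertz_frequency_error_costs_k(self):
        intact, lesioned = perfect_bundle()
        off = metrics_bundle((5, 65, 125), (45, 100, 155), 15.0)
        assert cost(off, lesioned) == pytest.approx(20.0)  # k * (15-14)^2

    def test_termwise_independent_evaluation(self):
        intact = metrics_bundle((12, 60, 110), (50, 95, 150), 16.0)
        cut = metrics_bundle((30, 55, 42 + 30), (60, 80, 95), 15.0)
        strm = metrics_bundle((20, 72, 130), (52, 108, 150), 13.0)
        lesioned = {"cut_w_SG": cut, "cut_w_GS": cut, "cut_w_CS": cut,
                    "cut_Str": strm}
        c = FitConstraints()
        # spreadsheet-style term-by-term evaluation, written independently
        expected = (
            (5 - 12) ** 2 + (65 - 60) ** 2 + (125 - 110) ** 2
            + (45 - 50) ** 2 + (100 - 95) ** 2 + (155 - 150) ** 2
            + 20 * (14 - 16) ** 2
            + 3 * ((72 - 30) ** 2 + (95 - 60) ** 2)
            + ((125 - 5) - (130 - 20)) ** 2 + ((155 - 45) - (150 - 52)) ** 2
        )
        assert cost(intact, lesioned, c) == pytest.approx(expected)

    def test_one_sided_striatal_term(self):
        intact, lesioned = perfect_bundle()
        big = metrics_bundle((5, 65, 145), (40, 100, 175), 14.0)
        lesioned = dict(lesioned, cut_Str=big)
        # amplitudes larger than the data are not penalized one-sided
        assert cost(intact, lesioned, str_form="one_sided") == \
            pytest.approx(0.0, abs=1e-12)
        assert cost(intact, lesioned, str_form="symmetric") > 0

    def test_missing_lesion_condition_rejected(self):
        intact, lesioned = perfect_bundle()
        del lesioned["cut_Str"]
        with pytest.raises(ProtocolError):
            cost(intact, lesioned)

    def test_penalty_monotone_in_excursion(self):
        lo = np.zeros(3)
        hi = np.ones(3)
        base = bounds_violation_penalty(np.array([0.5, 1.2, 0.5]), lo, hi)
        worse = bounds_violation_penalty(np.array([0.5, 1.7, 0.5]), lo, hi)
        assert worse > base >= 1e6


class TestEvaluateCandidate:
    def test_best_fit_has_finite_cost_and_oscillates(self, resonance_best):
        metrics, c = evaluate_candidate(resonance_best, duration=2500.0)
        assert np.isfinite(c)
        assert metrics["intact"].is_oscillating
        # the compensated cortical cut silences both populations
        assert not metrics["cut_w_CS"].is_oscillating

    def test_composition_equals_manual_protocol(self, resonance_best):
        kw = dict(duration=2500.0, step=0.1, transient=1000.0)
        metrics, c = evaluate_candidate(resonance_best, **kw)
        intact = simulate(resonance_best, **kw)
        mean_E = intact.mean_rate("E")
        manual = {"intact": extract_metrics(intact)}
        for key, les in [
            ("cut_w_SG", LesionSpec(LesionTarget.STN_TO_GPE)),
            ("cut_w_GS", LesionSpec(LesionTarget.GPE_TO_STN)),
            ("cut_w_CS", LesionSpec(LesionTarget.CTX_TO_STN,
                                    compensate=True)),
            ("cut_Str", LesionSpec(LesionTarget.STR_TO_GPE)),
        ]:
            manual[key] = extract_metrics(
                simulate(resonance_best, lesion=les,
                         pre_lesion_mean_E=mean_E, **kw))
        manual_cost = cost(manual["intact"],
                           {k: v for k, v in manual.items()
                            if k != "intact"})
        assert c == pytest.approx(manual_cost, rel=1e-12)


class TestFit:
    def test_same_seed_reproduces_result_exactly(self, resonance_best):
        kw = dict(seed=11, n_iter=5, duration=1500.0, step=0.1,
                  transient=500.0)
        r1 = fit(resonance_best, **kw)
        r2 = fit(resonance_best, **kw)
        assert np.array_equal(r1.x, r2.x)
        assert r1.cost == r2.cost
        assert np.array_equal(r1.trace, r2.trace)

    def test_best_cost_is_minimum_of_trace(self, resonance_best):
        r = fit(resonance_best, seed=2, n_iter=10, duration=1500.0,
                transient=500.0)
        assert r.cost == pytest.approx(np.min(r.trace))

    def test_start_outside_bounds_rejected(self, resonance_best):
        with pytest.raises(ConfigError):
            fit(resonance_best, bounds={"w_CS": (0.0, 1.0)}, n_iter=2)

    def test_quadratic_surrogate_minimizer_recovered(self):
        # shifted quadratic in the 15-dimensional search box
        lo = np.array([DEFAULT_BOUNDS[n][0] for n in FIT_PARAM_NAMES])
        hi = np.array([DEFAULT_BOUNDS[n][1] for n in FIT_PARAM_NAMES])
        rng = np.random.default_rng(5)
        target = lo + rng.uniform(0.2, 0.8, lo.size) * (hi - lo)

        def quad(x):
            z = (x - target) / (hi - lo)
            return float(np.dot(z, z))

        start = preset("fig3C")
        res = fit(start, seed=7, n_iter=400, objective=quad, polish=True)
        assert np.all(np.abs(res.x - target) < 0.01 * (hi - lo))

    def test_recovery_from_perturbed_start(self, resonance_best):
        """Fitting targets generated by a known set, from a start perturbed
        by +-20%, reaches a cost within 5x of the generating set's own."""
        kw = dict(duration=2000.0, step=0.1, transient=1000.0)
        m, _ = evaluate_candidate(resonance_best, **kw)
        cons = FitConstraints(
            stn_min=m["intact"].stn.minimum, stn_mean=m["intact"].stn.mean,
            stn_max=m["intact"].stn.maximum,
            gpe_min=m["intact"].gpe.minimum, gpe_mean=m["intact"].gpe.mean,
            gpe_max=m["intact"].gpe.maximum,
            frequency=m["intact"].frequency)
        _, self_cost = evaluate_candidate(resonance_best, constraints=cons,
                                          **kw)
        rng = np.random.default_rng(42)
        x = params_to_vector(resonance_best)
        lo = np.array([DEFAULT_BOUNDS[n][0] for n in FIT_PARAM_NAMES])
        hi = np.array([DEFAULT_BOUNDS[n][1] for n in FIT_PARAM_NAMES])
        start = vector_to_params(
            np.clip(x * (1 + rng.uniform(-0.2, 0.2, x.size)), lo, hi),
            resonance_best)
        res = fit(start, seed=3, n_iter=40, n_restarts=3, constraints=cons,
                  **kw)
        assert res.cost <= 5.0 * self_cost
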