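"""Linear stability analysis of the three-loop circuit and of the reduced
delayed STN-GPe oscillator.

Three nested feedback loops can destabilize the circuit: the STN-GPe loop
(``w_SG``, ``w_GS``), the cortical E-I loop (``w_CC``) and the long
STN->GPi->thalamus->cortex->STN loop (``w_CS``, ``w_SC``).  With identity
activations (``F(x) = x``) the model is linear, so each parameter triple is
either stable (perturbations decay) or unstable (growing oscillations); the
boundary is located by bisection on the sign of the fitted exponential
growth rate of the STN envelope.

The reduced model collapses everything outside the STN-GPe pair into a
single delayed self-feedback of strength ``w_SS`` and delay ``T_SS``
(dimensionless after rescaling time by the membrane time constant):
``s' = -w_GS g - w_SS s(t - T_SS) - s``, ``g' = w_SG s - g``.  Its Hopf
boundary follows analytically from the characteristic equation

.. math::

    \\lambda^2 + 2\\lambda + (w_{GS} w_{SG} + 1)
        + w_{SS} (1 + \\lambda) e^{-\\lambda T} = 0

by substituting :math:`\\lambda = i\\omega` and solving the real/imaginary
pair parametrically in :math:`\\omega`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import root
from scipy.signal import hilbert

from . import _integrator
from .core_model import simulate
from .metrics_and_fit import interpeak_frequency
from .params import ModelParameters, preset

__all__ = [
    "LoopWeights",
    "ReducedModelParams",
    "StabilityBoundary",
    "LinearSimResult",
    "linear_simulate",
    "stability_surface",
    "delay_scan",
    "reduced_boundary",
    "reduced_boundary_numeric",
    "reduced_critical_wss",
    "reduced_rightmost_root",
    "reduced_simulate",
    "growth_rate",
    "default_linear_base",
]

#: growth rates with magnitude below this (1/ms) are flagged as boundary
BOUNDARY_RATE_TOL = 1e-6


def default_linear_base() -> ModelParameters:
    """Base parameter set for the loop analysis: the feedback-model fit
    supplies the delays, time constants and ``w_GG``; the constant drives
    are zeroed (they only shift the fixed point of a linear system)."""
    return preset("fig3A-feedback").replace(C=0.0, Str=0.0)


@dataclass(frozen=True)
class LoopWeights:
    """The three independent loop couplings of the tied-weight scan.

    ``w_loop_SG`` is applied as ``w_SG = w_GS``; ``w_loop_long`` as
    ``w_CS = w_SC``; ``w_CC`` couples the cortical pair both ways.  The tie
    is part of the type, not the caller's responsibility.
    """

    w_loop_SG: float
    w_CC: float
    w_loop_long: float
    base: ModelParameters = field(default_factory=default_linear_base)

    def __post_init__(self) -> None:
        if min(self.w_loop_SG, self.w_CC, self.w_loop_long) < 0:
            raise ValueError("loop couplings must be >= 0")

    def to_params(self) -> ModelParameters:
        return self.base.replace(
            variant="feedback",
            w_SG=self.w_loop_SG, w_GS=self.w_loop_SG,
            w_CC=self.w_CC,
            w_CS=self.w_loop_long, w_SC=self.w_loop_long,
        )


@dataclass(frozen=True)
class ReducedModelParams:
    """Reduced delayed oscillator in dimensionless time."""

    w_GS: float = 1.33
    w_SG: float = 4.87
    w_SS: float = 0.0
    T_SS: float = 1.6875  # (T_CS + T_SC)/tau at the published delays
    tau: float = 16.0  # ms, used only to report frequencies in Hz

    @property
    def b(self) -> float:
        """The restoring coefficient w_GS * w_SG of the second-order form."""
        return self.w_GS * self.w_SG


@dataclass
class StabilityBoundary:
    """Critical couplings and onset frequencies along a scan."""

    values: np.ndarray  # the parameterization variable (omega, delay, ...)
    critical: np.ndarray  # critical coupling at each value (NaN = not found)
    frequency: np.ndarray  # onset frequency, Hz (NaN where stable/unknown)
    method: str  # "analytic" | "simulation" | "root-finding"


@dataclass
class LinearSimResult:
    times: np.ndarray
    S: np.ndarray
    growth_rate: float  # 1/ms
    classification: str  # "stable" | "unstable" | "boundary"
    frequency: Optional[float]  # Hz


def growth_rate(times: np.ndarray, x: np.ndarray,
                fit_fraction: float = 0.6) -> float:
    """Exponential growth rate (1/ms) of the oscillation envelope.

    The envelope is the magnitude of the analytic (Hilbert) signal; its log
    is regressed on time over the final ``fit_fraction`` of the window, with
    10% trimmed at each end against edge artefacts.
    """
    x = np.asarray(x, float)
    n = x.size
    i0 = int(n * (1.0 - fit_fraction))
    xw = x[i0:] - np.mean(x[i0:])
    tw = times[i0:]
    if np.max(np.abs(xw)) < 1e-12:
        return -1.0  # decayed to numerical zero: strongly stable
    env = np.abs(hilbert(xw))
    trim = max(1, int(0.1 * env.size))
    env = env[trim:-trim]
    tw = tw[trim:-trim]
    env = np.maximum(env, 1e-300)
    slope = np.polyfit(tw, np.log(env), 1)[0]
    return float(slope)


def _oscillation_frequency(times: np.ndarray, x: np.ndarray
                           ) -> Optional[float]:
    """Frequency (Hz) from zero crossings over the final 60% of the window;
    robust to exponential growth or decay of the envelope."""
    n = x.size
    xw = x[int(0.4 * n):]
    tw = times[int(0.4 * n):]
    if np.max(np.abs(xw)) < 1e-12:
        return None
    signs = np.sign(xw)
    signs[signs == 0] = 1
    crossings = np.nonzero(np.diff(signs))[0]
    if crossings.size < 4:
        return None
    period_ms = 2.0 * float(np.median(np.diff(tw[crossings])))
    return 1000.0 / period_ms


def _classify(rate: float) -> str:
    if abs(rate) < BOUNDARY_RATE_TOL:
        return "boundary"
    return "unstable" if rate > 0 else "stable"


def linear_simulate(lw: LoopWeights, duration: float = 3000.0,
                    step: float = 0.05) -> LinearSimResult:
    """Integrate the identity-activation model and classify its stability.

    The run starts from zero history with a +1 spk/s kick on S.  Strongly
    unstable runs are truncated once the state leaves ``|y| < 1e9``; the
    growth fit then uses the available window.  Constant drives, if present
    in ``lw.base``, are removed by subtracting the linear fixed point before
    the envelope fit.
    """
    p = lw.to_params()
    fp = _linear_fixed_point(p)
    traj = simulate(p, duration=duration, step=step, linear=True,
                    record_dt=0.5, transient=0.0, blowup=1e9,
                    history=fp + np.array([1.0, 0.0, 0.0, 0.0]))
    s = traj.S - fp[0]
    rate = growth_rate(traj.times, s)
    freq = _oscillation_frequency(traj.times, s)
    return LinearSimResult(times=traj.times, S=traj.S, growth_rate=rate,
                           classification=_classify(rate), frequency=freq)


def _linear_fixed_point(p: ModelParameters) -> np.ndarray:
    """Fixed point of the identity-activation model (delays irrelevant)."""
    W = np.array([
        [0.0, -p.w_GS, p.w_CS, 0.0],
        [p.w_SG, -p.w_GG, 0.0, 0.0],
        [-p.w_SC, 0.0, 0.0, -p.w_CC],
        [0.0, 0.0, p.w_CC, 0.0],
    ])
    c = np.array([0.0, -p.Str, p.C, 0.0])
    A = np.eye(4) - W
    try:
        return np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return np.zeros(4)


def stability_surface(
    w_sg_values: Sequence[float],
    w_cc_values: Sequence[float],
    base: Optional[ModelParameters] = None,
    long_range: Tuple[float, float] = (0.0, 5.0),
    tol: float = 1e-3,
    duration: float = 2000.0,
    step: float = 0.05,
) -> Tuple[StabilityBoundary, np.ndarray]:
    """Critical long-loop coupling over a (w_SG=w_GS, w_CC) grid.

    For each grid cell the tied long-loop weight is bisected between
    ``long_range`` on the growth-rate sign.  Cells already unstable at the
    lower end get critical 0; cells still stable at the upper end get NaN
    (boundary out of range).  The second return value is the onset frequency
    (Hz) measured just above the boundary, NaN where no boundary was found.
    """
    if base is None:
        base = default_linear_base()
    w_sg_values = np.asarray(w_sg_values, float)
    w_cc_values = np.asarray(w_cc_values, float)
    crit = np.full((w_sg_values.size, w_cc_values.size), np.nan)
    freq = np.full_like(crit, np.nan)

    def rate_at(wsg, wcc, wl):
        lw = LoopWeights(wsg, wcc, wl, base=base)
        return linear_simulate(lw, duration=duration, step=step)

    for i, wsg in enumerate(w_sg_values):
        for j, wcc in enumerate(w_cc_values):
            lo, hi = long_range
            r_lo = rate_at(wsg, wcc, lo)
            if r_lo.growth_rate > 0:
                crit[i, j] = lo
                freq[i, j] = r_lo.frequency or np.nan
                continue
            r_hi = rate_at(wsg, wcc, hi)
            if r_hi.growth_rate <= 0:
                continue  # boundary outside the scanned range
            a, b = lo, hi
            while b - a > tol:
                m = 0.5 * (a + b)
                if rate_at(wsg, wcc, m).growth_rate > 0:
                    b = m
                else:
                    a = m
            crit[i, j] = 0.5 * (a + b)
            probe = rate_at(wsg, wcc, crit[i, j] * 1.02 + 0.05)
            freq[i, j] = probe.frequency or np.nan

    grid = np.stack(np.meshgrid(w_sg_values, w_cc_values, indexing="ij"),
                    axis=-1)
    boundary = StabilityBoundary(values=grid, critical=crit, frequency=freq,
                                 method="simulation")
    return boundary, freq


def critical_long_loop(base: Optional[ModelParameters] = None,
                       w_sg: float = 0.0, w_cc: float = 0.0,
                       long_range: Tuple[float, float] = (0.0, 5.0),
                       tol: float = 1e-3, duration: float = 3000.0,
                       step: float = 0.05) -> float:
    """Critical tied long-loop weight for fixed values of the other loops."""
    sb, _ = stability_surface([w_sg], [w_cc], base=base,
                              long_range=long_range, tol=tol,
                              duration=duration, step=step)
    return float(sb.critical[0, 0])


def delay_scan(
    params: Optional[ModelParameters] = None,
    alphas: Sequence[float] = tuple(np.round(np.linspace(0.25, 3.0, 12), 4)),
    duration: float = 5000.0,
    step: float = 0.05,
    transient: float = 1000.0,
):
    """Oscillation frequency of the full nonlinear feedback model as the
    long-loop delays are scaled by ``alpha``.

    Both ``T_CS`` and ``T_SC`` are multiplied by each ``alpha``; the result
    is indexed by the total loop delay ``T_SS = alpha (T_CS + T_SC)``.
    Returns a DataFrame with columns alpha, T_SS (ms), frequency (Hz,
    NaN where no sustained oscillation).  The frequency is the dominant
    spectral peak, which stays well defined when long delays produce
    harmonic-rich (multi-peaked) waveforms.
    """
    import pandas as pd

    from .metrics_and_fit import extract_metrics

    if params is None:
        params = preset("fig3A-feedback")
    if params.w_SC <= 0:
        raise ValueError("delay scan requires a feedback model with w_SC > 0")
    rows = []
    for a in alphas:
        p = params.replace(T_CS=a * params.T_CS, T_SC=a * params.T_SC)
        traj = simulate(p, duration=duration, step=step, transient=transient)
        m = extract_metrics(traj)
        rows.append({
            "alpha": float(a),
            "T_SS": float(a * (params.T_CS + params.T_SC)),
            "frequency": m.frequency_fft
            if m.is_oscillating and m.frequency_fft else np.nan,
        })
    return pd.DataFrame(rows)


# -- reduced model ------------------------------------------------------

def _char(lmbda: complex, w_SS: float, T: float, b: float) -> complex:
    return (lmbda ** 2 + 2.0 * lmbda + (b + 1.0)
            + w_SS * (1.0 + lmbda) * np.exp(-lmbda * T))


def reduced_rightmost_root(w_SS: float, T: float, b: float,
                           omega_max: float = 12.0) -> complex:
    """Rightmost characteristic root, located by damped-Newton root finding
    from a grid of starting points in the right half of the root chain."""
    best = None
    starts = [complex(s, w) for w in np.linspace(0.05, omega_max, 40)
              for s in (-0.5, -0.1, 0.1)]
    for z0 in starts:
        sol = root(lambda v: [np.real(_char(v[0] + 1j * v[1], w_SS, T, b)),
                              np.imag(_char(v[0] + 1j * v[1], w_SS, T, b))],
                   [z0.real, z0.imag], tol=1e-12)
        if not sol.success:
            continue
        z = complex(sol.x[0], abs(sol.x[1]))
        if abs(_char(z, w_SS, T, b)) > 1e-8:
            continue
        if best is None or z.real > best.real:
            best = z
    if best is None:
        raise RuntimeError("no characteristic root located")
    return best


def reduced_boundary(
    rp: ReducedModelParams = ReducedModelParams(),
    omega: Optional[np.ndarray] = None,
    n_branches: int = 3,
    T_range: Tuple[float, float] = (0.05, 8.0),
) -> StabilityBoundary:
    """Analytic Hopf boundary of the reduced model, parametric in omega.

    Substituting ``lambda = i omega`` into the characteristic equation and
    splitting into real and imaginary parts gives, for each omega, the
    critical feedback strength

    ``w_SS(omega) = sqrt(((omega^2 - b - 1)^2 + 4 omega^2) / (1 + omega^2))``

    and the delays ``T_k(omega)`` of the crossing branches.  Onset frequency
    is reported as ``omega / (2 pi tau)`` in Hz with ``tau`` in ms.
    """
    b = rp.b
    if omega is None:
        omega = np.linspace(0.02, 12.0, 4000)
    w = np.sqrt(((omega ** 2 - b - 1.0) ** 2 + 4.0 * omega ** 2)
                / (1.0 + omega ** 2))
    # solve cos/sin of (omega T) from the linear 2x2 system
    r1 = (omega ** 2 - b - 1.0) / w
    r2 = -2.0 * omega / w
    denom = 1.0 + omega ** 2
    c = (r1 + omega * r2) / denom
    s = (omega * r1 - r2) / denom
    phi = np.mod(np.arctan2(s, c), 2.0 * np.pi)  # omega*T modulo 2 pi
    Ts, Ws, Fs = [], [], []
    for k in range(n_branches):
        T = (phi + 2.0 * np.pi * k) / omega
        m = (T >= T_range[0]) & (T <= T_range[1])
        Ts.append(T[m])
        Ws.append(w[m])
        Fs.append(omega[m] / (2.0 * np.pi * rp.tau * 1e-3))
    T_all = np.concatenate(Ts)
    order = np.argsort(T_all)
    return StabilityBoundary(
        values=T_all[order], critical=np.concatenate(Ws)[order],
        frequency=np.concatenate(Fs)[order], method="analytic",
    )


def reduced_critical_wss(T: float,
                         rp: ReducedModelParams = ReducedModelParams(),
                         ) -> float:
    """Smallest w_SS on the analytic boundary at delay ``T`` (the first
    crossing when w_SS is increased from 0).

    Each parametric branch T_k(omega) is solved for T_k(omega) = T by
    bracketing along a dense omega grid and interpolating linearly; the
    minimum w_SS over all crossings is the first Hopf crossing.
    """
    b = rp.b
    omega = np.linspace(0.02, 14.0, 30001)
    w = np.sqrt(((omega ** 2 - b - 1.0) ** 2 + 4.0 * omega ** 2)
                / (1.0 + omega ** 2))
    r1 = (omega ** 2 - b - 1.0) / w
    r2 = -2.0 * omega / w
    denom = 1.0 + omega ** 2
    c = (r1 + omega * r2) / denom
    s = (omega * r1 - r2) / denom
    phi = np.mod(np.arctan2(s, c), 2.0 * np.pi)
    best = np.inf
    for k in range(6):
        Tk = (phi + 2.0 * np.pi * k) / omega
        g = Tk - T
        idx = np.nonzero(np.diff(np.sign(g)))[0]
        for i in idx:
            frac = g[i] / (g[i] - g[i + 1])
            w_cross = w[i] + frac * (w[i + 1] - w[i])
            best = min(best, w_cross)
    return float(best) if np.isfinite(best) else float("nan")


def reduced_simulate(rp: ReducedModelParams, duration: float = 300.0,
                     step: float = 0.01) -> Tuple[np.ndarray, np.ndarray, float]:
    """Integrate the reduced oscillator (dimensionless time) from a unit
    kick on s; returns (times, s, envelope growth rate per time unit)."""
    h = float(step)
    if h > rp.T_SS:
        raise ValueError("step must not exceed the delay")
    n_steps = int(round(duration / h))
    n_hist = int(math.ceil(rp.T_SS / h - 1e-12))
    Y = np.zeros((n_hist + n_steps + 1, 2))
    F = np.zeros_like(Y)
    Y[: n_hist + 1, 0] = 1.0
    done = _integrator.integrate_reduced(
        rp.w_GS, rp.w_SG, rp.w_SS, rp.T_SS, h, n_steps, n_hist, Y, F, 1e9,
    )
    sol = Y[n_hist: n_hist + done + 1]
    times = np.arange(done + 1) * h
    rate = growth_rate(times, sol[:, 0])
    return times, sol[:, 0], rate


def reduced_boundary_numeric(
    T_values: Sequence[float],
    rp: ReducedModelParams = ReducedModelParams(),
    wss_range: Tuple[float, float] = (0.0, 12.0),
    tol: float = 5e-3,
    duration: float = 400.0,
) -> StabilityBoundary:
    """Boundary located by bisection on simulations of the reduced model
    (the numerical counterpart of the analytic curve)."""
    T_values = np.asarray(T_values, float)
    crit = np.full(T_values.size, np.nan)
    freq = np.full(T_values.size, np.nan)
    for i, T in enumerate(T_values):
        lo, hi = wss_range

        def rate(w):
            return reduced_simulate(
                ReducedModelParams(rp.w_GS, rp.w_SG, w, T, rp.tau),
                duration=duration,
            )[2]

        if rate(lo) > 0:
            crit[i] = lo
            continue
        if rate(hi) <= 0:
            continue
        a, b_ = lo, hi
        while b_ - a > tol:
            m = 0.5 * (a + b_)
            if rate(m) > 0:
                b_ = m
            else:
                a = m
        crit[i] = 0.5 * (a + b_)
        t, s, _ = reduced_simulate(
            ReducedModelParams(rp.w_GS, rp.w_SG, crit[i] * 1.02 + 0.02, T,
                               rp.tau), duration=duration)
        x = s - s.mean()
        from scipy.signal import find_peaks

        pk, _ = find_peaks(x, prominence=0.01 * np.max(np.abs(x)))
        if len(pk) >= 3:
            per = float(np.median(np.diff(t[pk])))  # dimensionless time
            freq[i] = 1.0 / (per * rp.tau * 1e-3)  # Hz
    return StabilityBoundary(values=T_values, critical=crit,
                             frequency=freq, method="simulation")
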