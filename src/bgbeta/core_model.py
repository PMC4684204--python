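"""The four-population delay model and its lesion protocol.

The coupled delay differential equations are

.. math::

    \\tau_S S' &= F_S(w_{CS} E(t-T_{CS}) - w_{GS} G(t-T_{GS})) - S(t) \\\\
    \\tau_G G' &= F_G(w_{SG} S(t-T_{SG}) - w_{GG} G(t-T_{GG}) - Str) - G(t) \\\\
    \\tau_E E' &= F_E(-w_{SC} S(t-T_{SC}) - w_{CC} I(t-T_{CC}) + C) - E(t) \\\\
    \\tau_I I' &= F_I(w_{CC} E(t-T_{CC})) - I(t)

with sigmoid activations :math:`F` (see :class:`bgbeta.params.ActivationParams`).
``simulate`` integrates them by the method of steps (fixed-step RK4, cubic
Hermite interpolation of the stored past), ``apply_lesion`` implements the
blockade protocol including the ``C_adj`` compensation for the cortex->STN
cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

from . import _integrator
from .params import (
    ActivationParams,
    InvalidActivationError,
    LesionSpec,
    LesionTarget,
    ModelParameters,
    ProtocolError,
)

__all__ = [
    "sigmoid_response",
    "model_rhs",
    "simulate",
    "apply_lesion",
    "lesion_panel",
    "Trajectory",
    "IntegrationDivergedError",
    "ConfigError",
]


class IntegrationDivergedError(RuntimeError):
    """The state became non-finite or left the allowed box."""


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


def sigmoid_response(x: float, act: ActivationParams) -> float:
    """Population rate as a function of net synaptic input.

    ``F(x) = M / (1 + ((M-B)/B) exp(-4x/M))``: strictly increasing, bounded
    in (0, M), equal to B at x = 0, maximum slope 1 where F = M/2.
    """
    if not isinstance(act, ActivationParams):
        act = ActivationParams(*act)
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        out = act.M / (1.0 + ((act.M - act.B) / act.B) * np.exp(-4.0 * x / act.M))
    return float(out) if out.ndim == 0 else out


def model_rhs(
    state: Sequence[float],
    delayed: dict,
    params: ModelParameters,
    extra_stn_input: float = 0.0,
    linear: bool = False,
) -> np.ndarray:
    """Time derivatives (S', G', E', I') given the current state and the
    delayed rates.

    ``delayed`` must supply ``S_TSG`` = S(t-T_SG), ``S_TSC``, ``G_TGS``,
    ``G_TGG``, ``E_TCS``, ``E_TCC`` and ``I_TCC``.  ``extra_stn_input`` is
    added inside the STN activation argument (the ``C_adj`` compensation).
    """
    S, G, E, I = state
    x_S = params.w_CS * delayed["E_TCS"] - params.w_GS * delayed["G_TGS"] \
        + extra_stn_input
    x_G = params.w_SG * delayed["S_TSG"] - params.w_GG * delayed["G_TGG"] \
        - params.Str
    x_E = -params.w_SC * delayed["S_TSC"] - params.w_CC * delayed["I_TCC"] \
        + params.C
    x_I = params.w_CC * delayed["E_TCC"]
    if linear:
        f = (x_S, x_G, x_E, x_I)
    else:
        f = (
            sigmoid_response(x_S, params.act_S),
            sigmoid_response(x_G, params.act_G),
            sigmoid_response(x_E, params.act_E),
            sigmoid_response(x_I, params.act_I),
        )
    taus = (params.tau_S, params.tau_G, params.tau_E, params.tau_I)
    return np.array([(fi - yi) / ti for fi, yi, ti in zip(f, state, taus)])


@dataclass
class Trajectory:
    """Sampled firing-rate time series of one simulation."""

    times: np.ndarray  # ms, uniform, starting at 0
    S: np.ndarray
    G: np.ndarray
    E: np.ndarray
    I: np.ndarray
    params: ModelParameters
    lesion: LesionSpec
    step: float
    transient: float  # ms flagged as settling time (retained in the arrays)
    extra_stn_input: float = 0.0
    linear: bool = False

    def population(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def post_transient(self, name: str = "S") -> Tuple[np.ndarray, np.ndarray]:
        """(times, rates) restricted to t >= transient."""
        m = self.times >= self.transient
        return self.times[m], getattr(self, name)[m]

    def mean_rate(self, name: str) -> float:
        return float(np.mean(self.post_transient(name)[1]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ms": self.times, "S": self.S, "G": self.G,
             "E": self.E, "I": self.I}
        )


HistoryLike = Union[None, Sequence[float], Callable[[float], Sequence[float]]]


def _fill_history(history: HistoryLike, params: ModelParameters,
                  n_hist: int, h: float, linear: bool,
                  perturb_S: float) -> Tuple[np.ndarray, np.ndarray]:
    """History values/derivatives on the grid [-n_hist*h, 0]."""
    Yh = np.zeros((n_hist + 1, 4))
    Fh = np.zeros((n_hist + 1, 4))
    if history is None:
        base = np.zeros(4) if linear else params.baselines
        const = base + np.array([perturb_S, 0.0, 0.0, 0.0])
        Yh[:] = const
    elif callable(history):
        ts = (np.arange(n_hist + 1) - n_hist) * h
        for i, t in enumerate(ts):
            Yh[i] = np.asarray(history(t), dtype=float)
        # derivative of the supplied history by central differences
        Fh[1:-1] = (Yh[2:] - Yh[:-2]) / (2 * h)
        Fh[0] = (Yh[1] - Yh[0]) / h
        Fh[-1] = (Yh[-1] - Yh[-2]) / h
    else:
        Yh[:] = np.asarray(history, dtype=float)
    return Yh, Fh


def simulate(
    params: ModelParameters,
    lesion: Optional[LesionSpec] = None,
    duration: float = 5000.0,
    step: float = 0.05,
    history: HistoryLike = None,
    transient: float = 1000.0,
    record_dt: Optional[float] = 0.5,
    pre_lesion_mean_E: Optional[float] = None,
    linear: bool = False,
    history_perturbation: float = 1.0,
    blowup: float = 1e12,
) -> Trajectory:
    """Integrate the delay model and return the sampled trajectory.

    The default history is constant at each population's baseline rate with a
    +1 spk/s perturbation on S to break symmetry (for linear runs the history
    is zero plus the perturbation).  The first ``transient`` ms are flagged
    but kept in the output.  If a compensated cortex->STN lesion is requested
    without ``pre_lesion_mean_E``, an intact simulation with the same
    settings is run first to obtain it.
    """
    if lesion is None:
        lesion = LesionSpec()
    if duration <= params.max_delay:
        raise ConfigError("duration must exceed the largest delay")
    if step <= 0 or step > params.min_delay:
        raise ConfigError(
            f"step must lie in (0, min delay = {params.min_delay} ms]"
        )
    if record_dt is None:
        record_dt = step
    every = int(round(record_dt / step))
    if every < 1 or abs(every * step - record_dt) > 1e-9:
        raise ConfigError("step must divide record_dt")
    if transient >= duration:
        raise ConfigError("transient must be shorter than duration")

    if (lesion.target is LesionTarget.CTX_TO_STN and lesion.compensate
            and pre_lesion_mean_E is None):
        intact = simulate(
            params, LesionSpec(), duration=duration, step=step,
            history=history, transient=transient, record_dt=record_dt,
            linear=linear, history_perturbation=history_perturbation,
        )
        pre_lesion_mean_E = intact.mean_rate("E")

    sim_params, extra = apply_lesion(params, lesion, pre_lesion_mean_E)

    h = float(step)
    n_steps = int(round(duration / h))
    n_hist = int(math.ceil(sim_params.max_delay / h - 1e-12))
    Y = np.zeros((n_hist + n_steps + 1, 4))
    F = np.zeros_like(Y)
    Yh, Fh = _fill_history(history, sim_params, n_hist, h, linear,
                           history_perturbation)
    Y[: n_hist + 1] = Yh
    F[: n_hist + 1] = Fh

    done = _integrator.integrate_network(
        sim_params.pack(), h, n_steps, n_hist, Y, F, linear, float(extra),
        float(blowup),
    )
    if done < n_steps and not linear:
        raise IntegrationDivergedError(
            f"state non-finite after {done * h:.3f} ms"
        )

    sol = Y[n_hist: n_hist + done + 1]
    idx = np.arange(0, done + 1, every)
    times = idx * h
    return Trajectory(
        times=times, S=sol[idx, 0], G=sol[idx, 1], E=sol[idx, 2],
        I=sol[idx, 3], params=sim_params, lesion=lesion, step=h,
        transient=transient, extra_stn_input=float(extra), linear=linear,
    )


def apply_lesion(
    params: ModelParameters,
    lesion: LesionSpec,
    pre_lesion_mean_E: Optional[float] = None,
) -> Tuple[ModelParameters, float]:
    """Zero the blocked connection and compute the compensatory STN drive.

    Returns ``(lesioned_params, extra_stn_input)``.  For a compensated
    cortex->STN cut, ``extra_stn_input = w_CS * mean(E)`` with the original
    weight and the pre-blockade mean cortical rate, which keeps the average
    synaptic drive to the STN unchanged by the cut.
    """
    if lesion.target is LesionTarget.NONE:
        return params, 0.0
    extra = 0.0
    if lesion.target is LesionTarget.STR_TO_GPE:
        new = params.replace(Str=0.0)
    elif lesion.target is LesionTarget.CTX_TO_STN:
        if lesion.compensate:
            if pre_lesion_mean_E is None:
                raise ProtocolError(
                    "compensated Ctx->STN cut needs the pre-lesion mean E"
                )
            extra = params.w_CS * float(pre_lesion_mean_E)
        new = params.replace(w_CS=0.0)
    else:
        new = params.replace(**{lesion.target.value: 0.0})
    return new, extra


#: The blockade conditions of the experimental protocol, in panel order.
PANEL_CONDITIONS = (
    ("intact", LesionSpec()),
    ("cut_w_SG", LesionSpec(LesionTarget.STN_TO_GPE)),
    ("cut_w_GS", LesionSpec(LesionTarget.GPE_TO_STN)),
    ("cut_w_CS", LesionSpec(LesionTarget.CTX_TO_STN, compensate=True)),
    ("cut_Str", LesionSpec(LesionTarget.STR_TO_GPE)),
    ("cut_w_SC", LesionSpec(LesionTarget.STN_TO_CTX)),
)


def lesion_panel(params: ModelParameters, **sim_kw) -> dict:
    """Run the intact model plus the five blockade conditions.

    The compensated cortex->STN cut reuses the intact run's mean cortical
    rate.  Returns an ordered ``{condition_name: Trajectory}`` dict.
    """
    out = {}
    intact = simulate(params, **sim_kw)
    out["intact"] = intact
    mean_E = intact.mean_rate("E")
    for name, les in PANEL_CONDITIONS[1:]:
        out[name] = simulate(
            params, lesion=les, pre_lesion_mean_E=mean_E, **sim_kw
        )
    return out
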