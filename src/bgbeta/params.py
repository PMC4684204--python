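"""Parameter containers and published parameter presets.

The model describes four interacting neural populations: the subthalamic
nucleus (S, excitatory), the external globus pallidus (G, inhibitory) and an
excitatory/inhibitory pair (E, I) standing for the motor cortex.  Connection
weights ``w_ij`` are dimensionless gains from population *i* to population
*j*; ``T_ij`` are the corresponding axonal/synaptic transmission delays in
milliseconds; ``tau_*`` are membrane time constants in milliseconds; ``C``
and ``Str`` are constant excitatory (to cortex) and inhibitory (striatum to
GPe) drives.

Two model variants exist.  In the *resonance* variant the long
STN->GPi->thalamus->cortex->STN feedback loop is absent (``w_SC = 0``): the
cortex oscillates on its own and the STN-GPe circuit resonates with it.  In
the *feedback* variant ``w_SC`` may be positive, closing the long loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "ActivationParams",
    "ModelParameters",
    "LesionTarget",
    "LesionSpec",
    "FIXED",
    "preset",
    "PRESET_NAMES",
]


class InvalidActivationError(ValueError):
    """Raised when a sigmoid activation is parameterized inconsistently."""


@dataclass(frozen=True)
class ActivationParams:
    """Sigmoid input-output curve of one population.

    The curve is ``F(x) = M / (1 + ((M - B)/B) * exp(-4 x / M))``: bounded in
    (0, M), equal to the baseline ``B`` at zero input, with maximum slope
    fixed at 1 (attained where the output equals M/2) so that connection
    weights keep an interpretable unit.
    """

    M: float  # maximum firing rate, spk/s
    B: float  # baseline firing rate at zero input, spk/s

    def __post_init__(self) -> None:
        if not (self.M > self.B > 0):
            raise InvalidActivationError(
                f"need M > B > 0, got M={self.M}, B={self.B}"
            )


class LesionTarget(str, Enum):
    """Connections that can be pharmacologically blocked in the protocol."""

    STN_TO_GPE = "w_SG"
    GPE_TO_STN = "w_GS"
    CTX_TO_STN = "w_CS"
    STN_TO_CTX = "w_SC"
    STR_TO_GPE = "Str"
    NONE = "none"


@dataclass(frozen=True)
class LesionSpec:
    """A single blockade.

    ``compensate`` is meaningful only for the cortex->STN cut: when set, a
    constant input ``C_adj = w_CS * mean(E)`` (pre-blockade cortical drive)
    is injected into the STN so that the cut removes the rhythm without
    removing tonic excitation, mirroring the experimental observation that
    mean STN rate is unchanged by this blockade.
    """

    target: LesionTarget = LesionTarget.NONE
    compensate: bool = False

    def __post_init__(self) -> None:
        if self.compensate and self.target is not LesionTarget.CTX_TO_STN:
            raise ValueError("compensate is only meaningful for the Ctx->STN cut")


class ProtocolError(RuntimeError):
    """A lesion/fitting protocol was invoked with missing prerequisites."""


#: Fixed (non-fitted) constants: delays, STN/GPe time constants and
#: STN/GPe activation curves.  These are shared by every preset.
FIXED = {
    "T_SG": 6.0,
    "T_GS": 6.0,
    "T_GG": 4.0,
    "T_CS": 5.5,
    "T_SC": 21.5,
    "tau_S": 12.8,
    "tau_G": 20.0,
    "M_S": 300.0,
    "B_S": 10.0,
    "M_G": 400.0,
    "B_G": 20.0,
}


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameterization of the four-population delay model."""

    # connection weights (dimensionless)
    w_SG: float
    w_GS: float
    w_CS: float
    w_SC: float
    w_GG: float
    w_CC: float
    # constant inputs (spk/s-equivalent synaptic drive)
    C: float
    Str: float
    # transmission delays (ms)
    T_SG: float = FIXED["T_SG"]
    T_GS: float = FIXED["T_GS"]
    T_GG: float = FIXED["T_GG"]
    T_CS: float = FIXED["T_CS"]
    T_SC: float = FIXED["T_SC"]
    T_CC: float = 5.0
    # membrane time constants (ms)
    tau_S: float = FIXED["tau_S"]
    tau_G: float = FIXED["tau_G"]
    tau_E: float = 11.0
    tau_I: float = 11.0
    # activation curves
    act_S: ActivationParams = field(
        default=ActivationParams(FIXED["M_S"], FIXED["B_S"])
    )
    act_G: ActivationParams = field(
        default=ActivationParams(FIXED["M_G"], FIXED["B_G"])
    )
    act_E: ActivationParams = field(default=ActivationParams(75.0, 15.0))
    act_I: ActivationParams = field(default=ActivationParams(250.0, 10.0))
    variant: str = "feedback"

    def __post_init__(self) -> None:
        if self.variant not in ("resonance", "feedback"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("w_SG", "w_GS", "w_CS", "w_SC", "w_GG", "w_CC"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("T_SG", "T_GS", "T_GG", "T_CS", "T_SC", "T_CC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tau_S", "tau_G", "tau_E", "tau_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.variant == "resonance" and self.w_SC != 0.0:
            # the resonance model has no long-loop return path by definition
            object.__setattr__(self, "w_SC", 0.0)

    # -- convenience ----------------------------------------------------

    @property
    def max_delay(self) -> float:
        return max(self.T_SG, self.T_GS, self.T_GG, self.T_CS, self.T_SC, self.T_CC)

    @property
    def min_delay(self) -> float:
        return min(self.T_SG, self.T_GS, self.T_GG, self.T_CS, self.T_SC, self.T_CC)

    @property
    def baselines(self) -> np.ndarray:
        """Baseline rates (B_S, B_G, B_E, B_I): the fixed point of the
        uncoupled, undriven model."""
        return np.array(
            [self.act_S.B, self.act_G.B, self.act_E.B, self.act_I.B]
        )

    @property
    def max_rates(self) -> np.ndarray:
        return np.array(
            [self.act_S.M, self.act_G.M, self.act_E.M, self.act_I.M]
        )

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def pack(self) -> np.ndarray:
        """Flatten to the vector layout consumed by the integrator kernel."""
        return np.array(
            [
                self.w_SG, self.w_GS, self.w_CS, self.w_SC, self.w_GG,
                self.w_CC,
                self.T_SG, self.T_GS, self.T_GG, self.T_CS, self.T_SC,
                self.T_CC,
                self.tau_S, self.tau_G, self.tau_E, self.tau_I,
                self.C, self.Str,
                self.act_S.M, self.act_S.B,
                self.act_G.M, self.act_G.B,
                self.act_E.M, self.act_E.B,
                self.act_I.M, self.act_I.B,
            ],
            dtype=np.float64,
        )


def _make_preset(variant: str, **kw) -> ModelParameters:
    act = {
        "act_E": ActivationParams(kw.pop("M_E"), kw.pop("B_E")),
        "act_I": ActivationParams(kw.pop("M_I"), kw.pop("B_I")),
    }
    return ModelParameters(variant=variant, **kw, **act)


# Published best-fit parameter sets.  ``fig3A`` is the resonance model
# (w_SC is structurally zero there; the fitted-but-unused value 8.93 is kept
# in ``fig3A-feedback`` which reads the same numbers as a feedback model).
# ``fig3C`` is the feedback model exactly as printed, whose w_SC entry of
# 0.00 appears to have been swapped in print with the 8.93 of the other set;
# ``fig3C-swapped`` applies that correction.
_FIG3A = dict(
    w_SG=4.87, w_GS=1.33, w_CS=9.98, w_GG=0.53, w_CC=6.17,
    C=172.18, Str=8.46, T_CC=4.65, tau_E=11.59, tau_I=13.02,
    B_E=17.85, B_I=9.87, M_E=75.77, M_I=205.72,
)
_FIG3C = dict(
    w_SG=2.56, w_GS=3.22, w_CS=6.60, w_GG=0.90, w_CC=3.08,
    C=277.94, Str=40.51, T_CC=7.74, tau_E=11.69, tau_I=10.45,
    B_E=3.62, B_I=7.18, M_E=71.77, M_I=276.39,
)

_PRESETS = {
    "fig3A": lambda: _make_preset("resonance", w_SC=0.0, **_FIG3A),
    "fig3A-feedback": lambda: _make_preset("feedback", w_SC=8.93, **_FIG3A),
    "fig3C": lambda: _make_preset("feedback", w_SC=0.00, **_FIG3C),
    "fig3C-swapped": lambda: _make_preset("feedback", w_SC=8.93, **_FIG3C),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> ModelParameters:
    """Return a named published parameter set.

    ``fig3A`` -- resonance-model best fit; ``fig3C`` -- feedback-model best
    fit as printed; ``fig3C-swapped`` -- feedback fit with the apparently
    interchanged ``w_SC`` entry (8.93) restored, which is the reading under
    which the long loop actually sustains the oscillation.
    """
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
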