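"""Synthetic spike trains with a noisy sinusoidal rate, and their
auto-correlograms.

The firing-rate constraints used by the fitting protocol are reverse
engineered from published single-neuron auto-correlograms: a rate process

.. math::

    fr(t) = A \\sin\\theta + b, \\qquad d\\theta = 2\\pi f\\,dt + N\\,dw

(a sinusoid whose phase diffuses with Wiener noise of strength ``N``) drives
an inhomogeneous Bernoulli/Poisson spike generator (one 1 ms bin per draw,
spike probability ``fr(t) dt``).  Matching the auto-correlogram of such a
train to a recorded one yields ``(A, b, f, N)``, from which the rate
constraints follow as ``(b - A, b, b + A)``.

Inside the phase increment ``dt`` is in seconds, so ``f`` in Hz advances the
phase correctly and ``dw ~ Normal(0, dt)``; binning uses ``dt`` in ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "RateProcessParams",
    "SpikeTrain",
    "Autocorrelogram",
    "simulate_rate",
    "sample_spikes",
    "autocorrelogram",
    "match_autocorrelogram",
    "rate_constraints_from_fit",
    "STN_RATE_PROCESS",
    "GPE_RATE_PROCESS",
    "InvalidProcessError",
    "BinningResolutionError",
    "NoMatchError",
]


class InvalidProcessError(ValueError):
    """Rate-process parameters would produce negative rates."""


class BinningResolutionError(ValueError):
    """Per-bin spike probability exceeded 1; a smaller dt is required."""


class NoMatchError(RuntimeError):
    """The target correlogram is degenerate and cannot be matched."""


@dataclass(frozen=True)
class RateProcessParams:
    """Parameters of the noisy sinusoidal rate process."""

    A: float  # oscillation amplitude, spk/s
    b: float  # baseline rate, spk/s
    f: float  # oscillation frequency, Hz
    N: float  # phase-noise strength (multiplies the Wiener increment)
    duration: float = 40.0  # s
    dt: float = 1.0  # ms, bin width for both the rate trace and spikes

    def __post_init__(self) -> None:
        if not (self.b >= self.A >= 0):
            raise InvalidProcessError(
                f"need b >= A >= 0 for a non-negative rate, got "
                f"A={self.A}, b={self.b}"
            )
        if self.f <= 0 or self.N < 0 or self.dt <= 0 or self.duration <= 0:
            raise InvalidProcessError("need f > 0, N >= 0, dt > 0, duration > 0")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))


#: processes matched to the published STN and GPe auto-correlograms
STN_RATE_PROCESS = RateProcessParams(A=60.0, b=65.0, f=13.7, N=3.3)
GPE_RATE_PROCESS = RateProcessParams(A=55.0, b=100.0, f=14.6, N=3.9)


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (ms) of one synthetic neuron; at most one spike per bin."""

    times: np.ndarray  # ms, sorted
    duration: float  # ms
    dt: float  # ms

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        """Empirical rate, spk/s."""
        return self.n_spikes / (self.duration / 1000.0)


@dataclass(frozen=True)
class Autocorrelogram:
    """Histogram of pairwise spike-time differences (zero-lag pairs of a
    spike with itself excluded)."""

    edges: np.ndarray  # ms, symmetric about 0
    counts: np.ndarray
    bin_width: float
    max_lag: float
    normalized: bool = False  # counts divided by spike count (rate per bin)

    @property
    def lags(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def zero_bin(self) -> int:
        """Index of the bin containing lag 0 (self-pairs are excluded from
        it, but distinct near-coincident spikes still count)."""
        return int(np.searchsorted(self.edges, 0.0, side="right") - 1)


def simulate_rate(p: RateProcessParams, seed: int = 0,
                  theta0: float = 0.0) -> np.ndarray:
    """Rate trace fr(t) (spk/s), one value per dt bin.

    The phase advances by ``2*pi*f*dt_s + N*dw`` per bin with ``dt_s`` the
    bin width in seconds and ``dw ~ Normal(0, dt_s)``; for ``N = 0`` the
    trace is the exact sinusoid ``A sin(2 pi f t) + b``.
    """
    rng = np.random.default_rng(seed)
    n = p.n_bins
    dt_s = p.dt / 1000.0
    increments = 2.0 * np.pi * p.f * dt_s \
        + p.N * rng.normal(0.0, np.sqrt(dt_s), size=n)
    theta = theta0 + np.concatenate(([0.0], np.cumsum(increments[:-1])))
    return p.A * np.sin(theta) + p.b


def sample_spikes(rate: np.ndarray, dt: float = 1.0, seed: int = 0
                  ) -> SpikeTrain:
    """Bernoulli spike per bin with probability ``rate * dt`` (dt in ms,
    rate in spk/s)."""
    rate = np.asarray(rate, float)
    prob = rate * (dt / 1000.0)
    if np.any(prob > 1.0):
        raise BinningResolutionError(
            f"rate*dt reaches {prob.max():.3f} > 1; use a smaller dt"
        )
    rng = np.random.default_rng(seed)
    hits = rng.random(rate.size) < prob
    times = (np.nonzero(hits)[0] + 0.5) * dt
    return SpikeTrain(times=times, duration=rate.size * dt, dt=dt)


def generate_train(p: RateProcessParams, seed: int = 0) -> SpikeTrain:
    """Rate simulation + Bernoulli sampling with independent sub-seeds."""
    rate = simulate_rate(p, seed=seed)
    return sample_spikes(rate, dt=p.dt, seed=seed + 1_000_003)


def autocorrelogram(train: SpikeTrain, bin_width: float = 2.0,
                    max_lag: float = 200.0, normalize: bool = False
                    ) -> Autocorrelogram:
    """All pairwise spike-time differences within ±max_lag, binned.

    Self-pairs at lag 0 are excluded; counts are exactly symmetric by
    construction.  ``normalize`` divides by the spike count, giving the mean
    number of coincidences per reference spike per bin.
    """
    nbins = int(np.ceil(max_lag / bin_width))
    edges = np.arange(-nbins, nbins + 1) * bin_width
    t = np.sort(np.asarray(train.times, float))
    if t.size == 0:
        warnings.warn("empty spike train: all-zero correlogram")
        return Autocorrelogram(edges, np.zeros(2 * nbins), bin_width,
                               max_lag, normalize)
    diffs = []
    for i, ti in enumerate(t):
        j = np.searchsorted(t, ti + max_lag, side="left")
        diffs.append(t[i + 1: j] - ti)
    pos = np.concatenate(diffs) if diffs else np.empty(0)
    # each unordered pair contributes +d and -d: bin the positive side and
    # mirror it, which makes the symmetry exact by construction
    counts_pos, _ = np.histogram(pos, bins=np.arange(nbins + 1) * bin_width)
    counts = np.concatenate([counts_pos[::-1], counts_pos]).astype(float)
    if normalize:
        counts /= t.size
    return Autocorrelogram(edges, counts, bin_width, max_lag, normalize)


def _smooth(x: np.ndarray, width: int = 5) -> np.ndarray:
    pad = width // 2
    xp = np.pad(x, pad, mode="reflect")
    kernel = np.ones(width) / width
    return np.convolve(xp, kernel, mode="valid")


def _matching_profile(ac: Autocorrelogram) -> np.ndarray:
    """Lightly smoothed correlogram used by the matching objective.

    The zero-lag bin is masked to its neighbours' mean (the self-coincidence
    notch carries no rate information).  Counts are kept on their absolute
    scale: the overall level of an auto-correlogram grows with the squared
    firing rate, which is what identifies the baseline ``b``; min-max
    normalization would discard it.
    """
    c = ac.counts.astype(float).copy()
    if ac.normalized:
        raise ValueError("match on raw-count correlograms")
    z = ac.zero_bin
    if 1 < z < c.size - 1:
        # the central bin pair straddles lag 0 (self-pairs excluded and,
        # at 1 ms spike binning, only one attainable lag value per bin)
        c[z] = c[z + 1]
        c[z - 1] = c[z - 2]
    return _smooth(c)


def match_autocorrelogram(
    target: Autocorrelogram,
    search_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
    grid_shape: Tuple[int, int, int, int] = (4, 4, 9, 3),
    refine: bool = True,
    duration: float = 40.0,
) -> Tuple[RateProcessParams, float, bool]:
    """Find the rate-process parameters whose correlogram best matches
    ``target``.

    The objective is the L2 distance between smoothed, min-max-normalized
    correlograms (identical binning), evaluated with common random numbers
    so it is deterministic given ``seed``.  A coarse grid over
    ``(A, b, f, N)`` is followed by Nelder-Mead refinement.  Returns
    ``(params, objective value, frequency_identifiable)``; when the best
    amplitude is near zero the correlogram is flat and ``f`` is flagged as
    unidentifiable.
    """
    if np.all(target.counts == 0):
        raise NoMatchError("target correlogram is all zeros")
    ranges = {
        "A": (0.0, 80.0), "b": (20.0, 150.0), "f": (8.0, 20.0),
        "N": (0.5, 6.0),
    }
    if search_ranges:
        ranges.update(search_ranges)
    tgt = _matching_profile(target)

    # a target without a concentrated spectral peak pins down no frequency:
    # fit the baseline only and flag f as unidentifiable
    x = tgt - tgt.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    concentrated = power[1:].max() / max(power[1:].sum(), 1e-300) > 0.35
    if not concentrated:
        f_mid = 0.5 * (ranges["f"][0] + ranges["f"][1])

        def flat_objective(b):
            if not ranges["b"][0] <= b <= ranges["b"][1]:
                return 1e12
            train = generate_train(
                RateProcessParams(0.0, float(b), f_mid, 0.0,
                                  duration=duration), seed=seed)
            ac = autocorrelogram(train, bin_width=target.bin_width,
                                 max_lag=target.max_lag)
            return float(np.mean((_matching_profile(ac) - tgt) ** 2))

        bs = np.linspace(*ranges["b"], 30)
        vals = [flat_objective(b) for b in bs]
        b_best = float(bs[int(np.argmin(vals))])
        return (RateProcessParams(0.0, b_best, f_mid, 0.0,
                                  duration=duration),
                float(np.min(vals)), False)

    def make(A, b, f, N):
        return RateProcessParams(A=A, b=b, f=f, N=N, duration=duration)

    def objective(x):
        A, b, f, N = x
        if not (b >= A >= 0) or f <= 0 or N < 0:
            return 1e6
        for name, v in zip(("A", "b", "f", "N"), x):
            a, c = ranges[name]
            if not (a - 1e-9 <= v <= c + 1e-9):
                return 1e6
        try:
            train = generate_train(make(A, b, f, N), seed=seed)
        except (InvalidProcessError, BinningResolutionError):
            return 1e6
        ac = autocorrelogram(train, bin_width=target.bin_width,
                             max_lag=target.max_lag)
        resid = _matching_profile(ac) - tgt
        return float(np.mean(resid ** 2))

    grids = [np.linspace(*ranges[n], k) for n, k in
             zip(("A", "b", "f", "N"), grid_shape)]
    best_x, best_f = None, np.inf
    for A in grids[0]:
        for b in grids[1]:
            if b < A:
                continue
            for f in grids[2]:
                for N in grids[3]:
                    v = objective((A, b, f, N))
                    if v < best_f:
                        best_x, best_f = np.array([A, b, f, N]), v
    if best_x is None:
        raise NoMatchError("no feasible point in the search ranges")

    if refine:
        res = minimize(objective, best_x, method="Nelder-Mead",
                       options={"maxiter": 200, "xatol": 0.05,
                                "fatol": 1e-4})
        if res.fun < best_f:
            best_x, best_f = np.asarray(res.x), float(res.fun)

    A, b, f, N = map(float, best_x)
    f_identifiable = A > 2.0  # near-flat correlograms pin down no frequency
    return (RateProcessParams(A=max(A, 0.0), b=b, f=f, N=max(N, 0.0),
                              duration=duration),
            float(best_f), f_identifiable)


def rate_constraints_from_fit(b: float, A: float
                              ) -> Tuple[float, float, float]:
    """(minimum, mean, maximum) firing rate implied by the matched process:
    ``(b - A, b, b + A)``."""
    if not (b >= A >= 0):
        raise InvalidProcessError(f"need b >= A >= 0, got b={b}, A={A}")
    return (b - A, b, b + A)
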