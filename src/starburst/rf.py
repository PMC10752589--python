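"""Center-surround receptive-field model of bipolar-cell motion responses.

Each bipolar cell is a point neuron whose receptive field (RF) has two
Gaussian spatial components, center and surround, described by their full
widths at half maximum.  At every millisecond the fraction of each
component's mass covered by the stimulus drives a small recursion:

* the center low-passes its stimulated area (``center_rise``) and is
  multiplicatively gated by an adaptation state that only decreases within
  a trial (rate set by ``center_decay``);
* the surround low-passes its strength-scaled area (``surround_rise``);
* the two are combined in a conductance-divider,
  ``RF_full = A * (C + S * reversal) / (C + S + R_in)``, with
  ``R_in = 0.1 x`` the total center mass inside the arena, so surround
  activation shunts the response and ``surround_reversal`` sets how much of
  it also depolarizes.  ``RF_full`` is unitless in [0, 1].

A ``delay`` parameter shifts the response in time (pure transport lag);
the spatial position of the cell enters through the stimulus overlap, which
is what produces early responses of wide RFs to approaching bars.

Fluorescence reported by the glutamate sensor is the release waveform
convolved with a difference-of-exponentials kernel (10 ms rise, 50 ms
decay), peak-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
from scipy.special import erf

from ._kernels import bc_recursion
from .stimuli import StimulusSpec

#: FWHM of a Gaussian = FWHM_TO_SIGMA * sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class RFParams:
    """Nine-parameter presynaptic receptive field (one half of a genome).

    Widths in um (FWHM); rise/decay constants in 1-ms time steps; delay in
    ms.  ``amplitude``, ``surround_strength`` and ``surround_reversal`` are
    unitless in [0, 1].
    """

    amplitude: float = 1.0
    center_width: float = 60.0
    surround_width: float = 180.0
    center_rise: float = 30.0
    center_decay: float = 500.0
    surround_rise: float = 60.0
    surround_strength: float = 0.3
    surround_reversal: float = 0.2
    delay: float = 0.0

    def __post_init__(self):
        for name in ("amplitude", "surround_strength", "surround_reversal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("center_width", "surround_width", "center_rise",
                     "center_decay", "surround_rise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d) -> "RFParams":
        return cls(**d)


@dataclass
class ActivationTrace:
    """Time-resolved state of one RF simulation (all channels unitless)."""

    t: np.ndarray                 # ms
    area_center: np.ndarray
    area_surround: np.ndarray
    rf_center: np.ndarray
    adaptation: np.ndarray
    rf_surround: np.ndarray
    rf_full: np.ndarray
    params: Optional[RFParams] = None
    stim: Optional[StimulusSpec] = None
    rf_x: Optional[float] = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "t_ms": self.t, "area_center": self.area_center,
            "area_surround": self.area_surround, "rf_center": self.rf_center,
            "adaptation": self.adaptation, "rf_surround": self.rf_surround,
            "rf_full": self.rf_full,
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------- area terms

def _mass(width: float, rf_x, lo, hi):
    """Unit-normalized Gaussian mass of a component between lo and hi."""
    sigma = width / FWHM_PER_SIGMA
    z = sigma * _SQRT2
    return 0.5 * (erf((hi - rf_x) / z) - erf((lo - rf_x) / z))


def rf_area_fraction(width: float, rf_x: float, stim: StimulusSpec, t: float) -> float:
    """Fraction of a Gaussian RF component's mass covered by the stimulus.

    The component is a unit-mass Gaussian of FWHM ``width`` centered at
    ``rf_x``; the returned value integrates it over the instantaneous
    stimulus footprint (closed form via the error function).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    total = 0.0
    for a, b in stim.footprint(t):
        total += _mass(width, rf_x, a, b)
    return float(total)


def area_series(width: float, rf_x, stim: StimulusSpec) -> np.ndarray:
    """(T, n) array of area fractions for cells at positions ``rf_x``."""
    rf_x = np.atleast_1d(np.asarray(rf_x, dtype=float))
    T = stim.n_steps
    ts = np.arange(T) * stim.dt
    if stim.kind == "bar" and not stim.mask_intervals:
        # single-interval fast path
        lead = stim.speed * ts
        if stim.direction >= 0:
            lo = np.clip(lead - stim.bar_length, 0.0, stim.arena_width)
            hi = np.clip(lead, 0.0, stim.arena_width)
        else:
            hi = np.clip(stim.arena_width - lead + stim.bar_length, 0.0, stim.arena_width)
            lo = np.clip(stim.arena_width - lead, 0.0, stim.arena_width)
        return _mass(width, rf_x[None, :], lo[:, None], hi[:, None])
    out = np.zeros((T, rf_x.size))
    for i, t in enumerate(ts):
        for a, b in stim.footprint(t):
            out[i] += _mass(width, rf_x, a, b)
    return out


def total_center_mass(width: float, rf_x, arena_width: float) -> np.ndarray:
    """Center mass inside the arena (the ``area_center_inf`` term)."""
    return _mass(width, np.asarray(rf_x, dtype=float), 0.0, arena_width)


# ----------------------------------------------------------------- response

def bc_drive(params: RFParams, stim: StimulusSpec, rf_x) -> np.ndarray:
    """(T, n) RF_full waveforms for cells at positions ``rf_x`` (um).

    Vectorized core used by the circuit simulations; per-cell timing
    emerges from the stimulus overlap at each position, and ``delay`` is
    applied afterwards as a pure time shift.
    """
    rf_x = np.atleast_1d(np.asarray(rf_x, dtype=float))
    ac = area_series(params.center_width, rf_x, stim)
    as_ = area_series(params.surround_width, rf_x, stim)
    r_in = 0.1 * total_center_mass(params.center_width, rf_x, stim.arena_width)
    _, _, _, full = bc_recursion(
        ac, as_, params.center_rise, params.center_decay, params.surround_rise,
        params.surround_strength, params.surround_reversal, params.amplitude,
        np.atleast_1d(r_in))
    if params.delay > 0:
        full = shift_trace(full, params.delay / stim.dt, axis=0)
    return full


def simulate_bc_response(params: RFParams, stim: StimulusSpec,
                         rf_x: float = 500.0) -> ActivationTrace:
    """Full single-cell simulation returning every state channel.

    The response onset is set by when the stimulus reaches the RF at
    ``rf_x`` (equivalently a shift of RF_x / velocity for a bar) plus the
    ``delay`` parameter.
    """
    x = np.array([float(rf_x)])
    ac = area_series(params.center_width, x, stim)
    as_ = area_series(params.surround_width, x, stim)
    r_in = 0.1 * total_center_mass(params.center_width, x, stim.arena_width)
    rc, ad, rs, full = bc_recursion(
        ac, as_, params.center_rise, params.center_decay, params.surround_rise,
        params.surround_strength, params.surround_reversal, params.amplitude,
        np.atleast_1d(r_in))
    if not np.all(np.isfinite(full)):
        raise FloatingPointError(
            f"RF recursion diverged for params {params.to_dict()}")
    shift = params.delay / stim.dt
    if shift > 0:
        rc = shift_trace(rc, shift, axis=0)
        ad = shift_trace(ad, shift, axis=0, fill=1.0)
        rs = shift_trace(rs, shift, axis=0)
        full = shift_trace(full, shift, axis=0)
    T = ac.shape[0]
    return ActivationTrace(
        t=np.arange(T) * stim.dt,
        area_center=ac[:, 0], area_surround=as_[:, 0],
        rf_center=rc[:, 0], adaptation=ad[:, 0],
        rf_surround=rs[:, 0], rf_full=full[:, 0],
        params=params, stim=stim, rf_x=float(rf_x))


def shift_trace(x: np.ndarray, steps: float, axis: int = 0, fill: float = 0.0) -> np.ndarray:
    """Shift a sampled trace right by a (possibly fractional) step count,
    linearly interpolating between samples."""
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    idx = np.arange(n, dtype=float) - steps
    x0 = np.moveaxis(x, axis, 0)
    lo = np.clip(np.floor(idx).astype(int), -1, n - 1)
    w = idx - np.floor(idx)
    valid_lo = lo >= 0
    valid_hi = lo + 1 <= n - 1
    left = np.where(valid_lo[:, None] if x0.ndim > 1 else valid_lo,
                    x0[np.clip(lo, 0, n - 1)], fill)
    right = np.where(valid_hi[:, None] if x0.ndim > 1 else valid_hi,
                     x0[np.clip(lo + 1, 0, n - 1)], fill)
    out = left * (1 - w[(...,) + (None,) * (x0.ndim - 1)]) + \
        right * w[(...,) + (None,) * (x0.ndim - 1)]
    return np.moveaxis(out, 0, axis)


# ------------------------------------------------------------ sensor filter

def sensor_kernel(f_rise: float = 10.0, f_decay: float = 50.0,
                  dt: float = 1.0) -> np.ndarray:
    """Causal difference-of-exponentials kernel, peak-normalized.

    k(tau) = exp(-tau/f_decay) - exp(-tau/f_rise), tau >= 0.  Its analytic
    peak sits at tau* = ln(f_decay/f_rise) * f_rise * f_decay /
    (f_decay - f_rise), about 20.1 ms for the default 10/50 ms sensor.
    """
    if not 0 < f_rise < f_decay:
        raise ValueError("need f_decay > f_rise > 0")
    tau = np.arange(0.0, 10.0 * f_decay + dt, dt)
    k = np.exp(-tau / f_decay) - np.exp(-tau / f_rise)
    return k / k.max()


def apply_sensor_filter(trace, f_rise: float = 10.0, f_decay: float = 50.0,
                        dt: Optional[float] = None):
    """Convolve a release waveform with the glutamate-sensor kernel.

    Accepts a 1-D array (requires ``dt``; defaults to 1 ms) or an
    :class:`ActivationTrace`, in which case a copy with the filtered
    ``rf_full`` channel is returned.  Output length equals input length
    (causal convolution, truncated).
    """
    if isinstance(trace, ActivationTrace):
        k = sensor_kernel(f_rise, f_decay, trace.dt)
        filt = np.convolve(trace.rf_full, k)[: trace.rf_full.size]
        return replace(trace, rf_full=filt)
    x = np.asarray(trace, dtype=float)
    k = sensor_kernel(f_rise, f_decay, 1.0 if dt is None else dt)
    if x.ndim == 1:
        return np.convolve(x, k)[: x.size]
    from scipy.signal import fftconvolve
    return fftconvolve(x, k[:, None], axes=0)[: x.shape[0]]
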