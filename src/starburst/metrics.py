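"""Scalar descriptors of responses: direction selectivity, waveform shape,
onset lags, and the bidirectional alignment used before clustering.

The directional readout follows the standard peak-calcium convention:
``DSI = (R_out - R_in) / (R_out + R_in)`` on the peak signals for motion
away from / toward the soma, and the training objective damps extreme
calcium levels with a Gaussian factor centered on an optimal outward peak
(500 nM): ``metric = DSI * exp(-(R_out - Ca_opt)^2 / Ca_opt^2)``.

Onset ("initiation") of a response is defined throughout as the first
upward crossing of a threshold fraction (default 5%) of the peak after
baseline subtraction, linearly interpolated between samples.  The paper's
convention for onsets is not stated more precisely than "initiation of the
fluorescent response"; the threshold is configurable everywhere it is
used.
"""

from __future__ import annotations

import numpy as np

from .stimuli import StimulusSpec

#: Default onset threshold as a fraction of the peak.
ONSET_FRACTION = 0.05


def dsi(r_out: float, r_in: float) -> float:
    """Direction-selectivity index from outward/inward peak responses."""
    if r_out < 0 or r_in < 0:
        raise ValueError("peak responses must be non-negative")
    denom = r_out + r_in
    if denom == 0:
        raise ValueError("DSI undefined for two zero responses")
    return (r_out - r_in) / denom


def directional_metric(dsi_value: float, r_out: float,
                       ca_opt: float = 500.0) -> float:
    """DSI damped by distance of the outward peak from the optimum.

    Equals the DSI exactly when ``r_out == ca_opt``; decays with a
    Gaussian penalty of width ``ca_opt`` otherwise, discouraging the
    threshold-hugging solutions that maximize DSI at near-zero calcium.
    """
    if ca_opt <= 0:
        raise ValueError("ca_opt must be positive")
    return dsi_value * np.exp(-((r_out - ca_opt) ** 2) / ca_opt ** 2)


def fwhm_from_sigma(sigma: float) -> float:
    """Gaussian full width at half maximum, 2*sqrt(2 ln 2) * sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma


def transiency_index(trace: np.ndarray, window=None) -> float:
    """Shape descriptor in [0, 1): 1 - mean/peak within the window.

    A sustained plateau scores ~0; a single-sample transient approaches 1.
    """
    x = np.asarray(trace, dtype=float)
    if window is not None:
        x = x[window]
    if x.size == 0:
        raise ValueError("empty window")
    peak = x.max()
    if peak <= 0:
        raise ValueError("transiency undefined for non-positive peak")
    return float(1.0 - x.mean() / peak)


def half_max_rise_time(trace: np.ndarray, dt: float = 1.0,
                       baseline: float = 0.0) -> float:
    """Time of the first upward crossing of 50% of peak (interpolated)."""
    return onset_time(trace, dt=dt, fraction=0.5, baseline=baseline)


def onset_time(trace: np.ndarray, dt: float = 1.0,
               fraction: float = ONSET_FRACTION,
               baseline: float = 0.0) -> float:
    """First upward crossing of ``fraction`` x peak above baseline."""
    x = np.asarray(trace, dtype=float) - baseline
    peak = x.max()
    if peak <= 0:
        raise ValueError("no positive response; onset undefined")
    thr = fraction * peak
    above = x >= thr
    if not above.any():
        raise ValueError("trace never crosses threshold")
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    x0, x1 = x[i - 1], x[i]
    frac = (thr - x0) / (x1 - x0) if x1 != x0 else 0.0
    return (i - 1 + frac) * dt


def align_bidirectional(trace_l: np.ndarray, trace_r: np.ndarray,
                        dt: float = 1.0) -> np.ndarray:
    """Average the two motion-direction responses after centering both on
    the mean of their half-maximum rise times.

    Each trace is shifted so its half-rise lands on the common reference
    (the mean of the two rise times); the returned average therefore has a
    half-rise exactly in between the two, which removes the dependence on
    the RF's spatial position.
    """
    from .rf import shift_trace
    tl = half_max_rise_time(trace_l, dt)
    tr = half_max_rise_time(trace_r, dt)
    ref = 0.5 * (tl + tr)
    a = shift_trace(np.asarray(trace_l, dtype=float), (ref - tl) / dt)
    b = shift_trace(np.asarray(trace_r, dtype=float), (ref - tr) / dt)
    return 0.5 * (a + b)


def motion_onset_lag(trace: np.ndarray, stim: StimulusSpec, rf_x: float,
                     dt: float = 1.0, fraction: float = ONSET_FRACTION) -> float:
    """Response onset minus the arrival of the bar's leading edge at the
    cell position (ms).  Negative values mean the cell responds before the
    bar reaches it -- the signature of a wide receptive-field center.
    """
    if stim.kind == "flash":
        raise ValueError("motion lag requires a bar stimulus")
    if stim.direction >= 0:
        t_arrival = rf_x / stim.speed
    else:
        t_arrival = (stim.arena_width - rf_x) / stim.speed
    return onset_time(trace, dt=dt, fraction=fraction) - t_arrival


def flash_lag(trace: np.ndarray, stim_onset: float = 0.0, dt: float = 1.0,
              fraction: float = ONSET_FRACTION) -> float:
    """Interval between flash onset and response initiation (ms).

    A full-field flash engages the entire RF at once, so this lag is
    independent of RF width and reflects purely temporal parameters.
    """
    return onset_time(trace, dt=dt, fraction=fraction) - stim_onset


def peak_responses(result, direction: int) -> np.ndarray:
    """Per-site peak calcium from a :class:`~starburst.cable.SimResult`."""
    return result.ca.max(axis=1)


def directional_summary(res_lr, res_rl, ca_opt: float = 500.0):
    """Per-site DSI and directional metric from a left-to-right and a
    right-to-left trial over the same recording sites.

    Outward for a site on the right of the soma is the left-to-right
    direction, and vice versa.  Returns (dsi_array, metric_array).
    """
    peaks_lr = res_lr.ca.max(axis=1) - 0.0
    peaks_rl = res_rl.ca.max(axis=1) - 0.0
    ds, met = [], []
    for i, site in enumerate(res_lr.sites):
        if site.outward_sign >= 0:
            r_out, r_in = peaks_lr[i], peaks_rl[i]
        else:
            r_out, r_in = peaks_rl[i], peaks_lr[i]
        d = dsi(r_out, r_in) if (r_out + r_in) > 0 else 0.0
        ds.append(d)
        met.append(directional_metric(d, r_out, ca_opt))
    return np.asarray(ds), np.asarray(met)
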