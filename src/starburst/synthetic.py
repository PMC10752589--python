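"""Synthetic datasets emulating the glutamate-imaging experiments.

Real bipolar-release recordings are not bundled with the package; these
generators produce statistically analogous data with known ground truth so
every analysis stage can be exercised and validated end to end:

* cluster libraries -- small sets of RF parameterizations emulating the
  qualitative spectrum of bipolar release types seen around SAC dendrites:
  a gradient from transient to sustained kinetics (clusters are sorted by
  transiency, C1 most transient), mostly narrow RF centers (45-100 um)
  plus one or two wide-center clusters (hundreds of um) whose motion
  responses begin before the bar arrives;
* ROI datasets -- per-ROI fluorescence traces for the motion battery,
  generated from a library member at a random arena position, passed
  through the sensor filter, scaled, and corrupted by Gaussian noise;
* pixel movies -- ROI traces painted into a small field of view with a
  Gaussian point-spread blur and per-pixel noise;
* oriented-bar response tables for the back-projection RF mapping.

Every generator is deterministic for a fixed seed (numpy default_rng,
i.e. PCG64) and emits its settings in the returned metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .rf import RFParams, apply_sensor_filter, bc_drive
from .stimuli import make_bar_stimulus
from .metrics import transiency_index

#: imaging geometry defaults (two-photon field of view after 2x2 binning)
FOV_UM = 164.0
PIXEL_UM = 1.28 * 2
FRAME_RATE = 50.0


@dataclass
class ClusterLibrary:
    """Named RF parameterizations with prevalences (sums to 1)."""

    kind: str
    params: list            # RFParams per cluster, sorted by transiency
    prevalence: np.ndarray
    names: list = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.params) < 2:
            raise ValueError("a library needs at least 2 clusters")
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        self.prevalence /= self.prevalence.sum()
        if self.names is None:
            self.names = [f"C{i + 1}" for i in range(len(self.params))]

    @property
    def n_clusters(self) -> int:
        return len(self.params)


@dataclass
class NoiseModel:
    """Additive Gaussian noise in dF/F units plus optional gain jitter."""

    sd: float = 0.1                  # relative to unit peak -> SNR = 1/sd
    gain_jitter: float = 0.1         # multiplicative SD of per-ROI amplitude
    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")


# Template parameters: a transiency gradient (fast-adapting to plateau,
# realized by center decay constants from ~100 to ~5000 steps and a rising
# surround-reversal ladder that adds sustained plateaus) with distinct
# center widths; the 380 and ~200 um entries are the wide-center clusters
# that produce negative motion lags.  Surround FWHM is 1.8 x center + 30,
# surround rise 2 x center rise + 40.
_ON7 = [
    # width  rise  decay  s_str s_rev delay
    (380.0, 20.0, 100.0, 0.20, 0.00, 20.0),
    (95.0, 22.0, 130.0, 0.30, 0.02, 30.0),
    (78.0, 90.0, 600.0, 0.25, 0.12, 40.0),
    (198.0, 85.0, 550.0, 0.30, 0.15, 50.0),
    (64.0, 170.0, 1700.0, 0.30, 0.30, 60.0),
    (54.0, 260.0, 3600.0, 0.30, 0.55, 80.0),
    (45.0, 430.0, 5000.0, 0.30, 0.85, 110.0),
]
_ON7_PREV = (0.10, 0.20, 0.18, 0.10, 0.16, 0.14, 0.12)

_OFF6 = [
    (300.0, 22.0, 110.0, 0.20, 0.00, 25.0),
    (100.0, 25.0, 130.0, 0.30, 0.02, 35.0),
    (80.0, 125.0, 850.0, 0.25, 0.12, 45.0),
    (66.0, 200.0, 1900.0, 0.30, 0.30, 60.0),
    (55.0, 300.0, 3800.0, 0.30, 0.55, 80.0),
    (46.0, 430.0, 5000.0, 0.30, 0.85, 110.0),
]
_OFF6_PREV = (0.12, 0.20, 0.18, 0.18, 0.17, 0.15)


def _params_from_row(row) -> RFParams:
    w, r, d, ss, srev, delay = row
    return RFParams(amplitude=0.8, center_width=w,
                    surround_width=min(600.0, 1.8 * w + 30.0),
                    center_rise=r, center_decay=d,
                    surround_rise=2.0 * r + 40.0,
                    surround_strength=ss, surround_reversal=srev, delay=delay)


def gen_cluster_library(kind: str = "ON7", seed: int = 0,
                        custom: Optional[Sequence[RFParams]] = None,
                        custom_prevalence=None) -> ClusterLibrary:
    """Built-in ON7 (7 clusters) / OFF6 (6 clusters) libraries, or a
    custom list.  Clusters come sorted by transiency, C1 most transient;
    the seed only matters for custom jitter (templates are fixed so that
    tests are reproducible)."""
    if kind == "ON7":
        params = [_params_from_row(r) for r in _ON7]
        prev = _ON7_PREV
    elif kind == "OFF6":
        params = [_params_from_row(r) for r in _OFF6]
        prev = _OFF6_PREV
    elif kind == "custom":
        if custom is None:
            raise ValueError("custom library requires params")
        params = list(custom)
        prev = custom_prevalence if custom_prevalence is not None \
            else np.ones(len(params))
    else:
        raise ValueError(f"unknown library kind {kind!r}")
    ti = [cluster_transiency(p) for p in params]
    order = np.argsort(ti)[::-1]
    params = [params[i] for i in order]
    prev = np.asarray(prev, dtype=float)[order]
    lib = ClusterLibrary(kind, params, prev,
                         meta={"seed": seed, "rng": "PCG64",
                               "sorted_by": "transiency_desc"})
    return lib


def cluster_waveform(params: RFParams, velocity: float = 0.5,
                     direction: int = 1, rf_x: float = 500.0,
                     frame_rate: Optional[float] = None) -> np.ndarray:
    """Noise-free sensor-filtered release waveform of one cluster."""
    stim = make_bar_stimulus(velocity, direction)
    w = apply_sensor_filter(bc_drive(params, stim, rf_x)[:, 0])
    if frame_rate:
        step = 1000.0 / frame_rate
        t = np.arange(len(w))
        return np.interp(np.arange(0, len(w) - 1, step), t, w)
    return w


def cluster_transiency(params: RFParams, velocity: float = 0.5) -> float:
    """Transiency index of the template waveform at the reference speed."""
    w = cluster_waveform(params, velocity)
    # stimulation window: from response onset to bar exit
    nz = np.flatnonzero(w > 0.05 * w.max())
    return transiency_index(w[nz[0]: len(w)])


# --------------------------------------------------------------- ROI traces

@dataclass
class ROITrace:
    """One region of interest: traces per (velocity, direction) and
    bookkeeping used by the clustering pipeline."""

    traces: dict                    # (velocity mm/s, direction) -> array
    dt: float                       # ms between samples
    centroid: tuple = (0.0, 0.0)    # um within the field of view
    rf_x: float = 500.0             # um, arena position of the RF center
    label: Optional[int] = None     # ground-truth cluster id (synthetic)
    pixels: Optional[list] = None
    aligned: Optional[np.ndarray] = None


def gen_roi_dataset(library: ClusterLibrary, n_rois: int = 334,
                    velocities: Sequence[float] = (0.5,),
                    noise: NoiseModel = NoiseModel(),
                    seed: int = 0, frame_rate: float = FRAME_RATE,
                    rf_x_range=(380.0, 620.0)):
    """ROI traces drawn from the library with known labels.

    Each ROI samples a cluster (by prevalence) and an arena position; its
    trace per velocity and direction is the cluster's sensor-filtered
    motion response at that position, downsampled to the imaging frame
    rate, amplitude-jittered and noise-corrupted (SNR = 1/noise.sd at unit
    peak).  Returns (rois, labels).
    """
    if n_rois < library.n_clusters:
        raise ValueError("need at least one ROI per cluster")
    rng = np.random.default_rng(seed)
    labels = rng.choice(library.n_clusters, size=n_rois, p=library.prevalence)
    # guarantee every cluster appears
    for c in range(library.n_clusters):
        if not (labels == c).any():
            labels[rng.integers(n_rois)] = c
    dt = 1000.0 / frame_rate
    # template bank per (cluster, velocity, direction) on the 1 ms grid
    bank = {}
    for c, p in enumerate(library.params):
        for v in velocities:
            for d in (1, -1):
                stim = make_bar_stimulus(v, d)
                bank[(c, v, d)] = (stim, p)
    rois = []
    for i in range(n_rois):
        c = int(labels[i])
        x = rng.uniform(*rf_x_range)
        gain = max(0.1, 1.0 + rng.normal(0.0, noise.gain_jitter))
        traces = {}
        for v in velocities:
            for d in (1, -1):
                stim, p = bank[(c, v, d)]
                w = apply_sensor_filter(bc_drive(p, stim, x)[:, 0])
                w = w / w.max() if w.max() > 0 else w
                t = np.arange(len(w))
                ws = np.interp(np.arange(0.0, len(w) - 1, dt), t, w)
                ws = gain * ws + rng.normal(0.0, noise.sd, size=ws.size)
                traces[(v, d)] = ws
        rois.append(ROITrace(traces, dt, rf_x=x, label=c))
    return rois, labels


# -------------------------------------------------------------- pixel movie

def gen_roi_layout(n_rois: int, fov: float = FOV_UM, roi_radius: float = 3.0,
                   seed: int = 0, min_sep: Optional[float] = None) -> np.ndarray:
    """Non-overlapping ROI centers (um) inside the field of view."""
    rng = np.random.default_rng(seed)
    if min_sep is None:
        min_sep = 2.5 * roi_radius
    centers = []
    tries = 0
    while len(centers) < n_rois and tries < 20000:
        c = rng.uniform(roi_radius + 2, fov - roi_radius - 2, size=2)
        if all(np.hypot(*(c - o)) >= min_sep for o in centers):
            centers.append(c)
        tries += 1
    if len(centers) < n_rois:
        raise ValueError("could not place ROIs without overlap; reduce n_rois")
    return np.array(centers)


def gen_movie(centers: np.ndarray, traces: Sequence[np.ndarray],
              psf_sigma: float = 1.0, noise_sd: float = 0.05,
              seed: int = 0, fov: float = FOV_UM,
              pixel_size: float = PIXEL_UM, roi_radius: float = 3.0,
              frame_rate: float = FRAME_RATE):
    """Paint per-ROI traces into a (T, H, W) dF/F movie.

    Returns an :class:`~starburst.imaging.Movie` whose ``truth`` is the
    (H, W) int map of pixel -> ROI index (-1 outside all ROIs).
    """
    from .imaging import Movie
    n_px = int(round(fov / pixel_size))
    T = min(len(tr) for tr in traces)
    xs = (np.arange(n_px) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, xs)
    truth = np.full((n_px, n_px), -1, dtype=int)
    for i, c in enumerate(centers):
        mask = (X - c[0]) ** 2 + (Y - c[1]) ** 2 <= roi_radius ** 2
        truth[mask] = i
    data = np.zeros((T, n_px, n_px))
    for i in range(len(centers)):
        mask = truth == i
        if mask.any():
            data[:, mask] = np.asarray(traces[i])[:T, None]
    if psf_sigma > 0:
        from scipy.ndimage import gaussian_filter
        data = gaussian_filter(data, sigma=(0.0, psf_sigma / pixel_size,
                                            psf_sigma / pixel_size))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return Movie(data=data, pixel_size=pixel_size, frame_rate=frame_rate,
                 truth=truth,
                 meta={"psf_sigma_um": psf_sigma, "noise_sd": noise_sd,
                       "seed": seed, "rng": "PCG64"})


# ------------------------------------------------------- oriented-bar table

def gen_oriented_bar_responses(params: RFParams, seed: int = 0,
                               n_orientations: int = 5, n_positions: int = 32,
                               span: float = 300.0, bar_width: float = 10.0,
                               center=(0.0, 0.0), noise_sd: float = 0.0):
    """Peak responses to flashed oriented bars (the RF-mapping protocol).

    Bars of ``bar_width`` um are flashed at ``n_positions`` offsets along
    the axis perpendicular to each of ``n_orientations`` evenly spaced
    orientations (36 degrees apart for 5), spanning ``span`` um.  The
    response is the 2-D Gaussian center mass under the bar strip (an exact
    Radon projection of the RF) with optional Gaussian noise.

    Returns (responses (n_orientations, n_positions), orientations_deg,
    positions_um).
    """
    from scipy.special import erf
    sigma = params.center_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    thetas = np.arange(n_orientations) * (180.0 / n_orientations)
    # index-centered grid (position n//2 is exactly 0) so the table is a
    # sinogram in the convention expected by the back-projection step
    positions = (np.arange(n_positions) - n_positions // 2) * (span / n_positions)
    rng = np.random.default_rng(seed)
    out = np.empty((n_orientations, n_positions))
    for i, th in enumerate(np.deg2rad(thetas)):
        # signed distance of the RF center from each bar's axis
        c = center[0] * np.cos(th) - center[1] * np.sin(th)
        z = sigma * np.sqrt(2.0)
        hi = positions + bar_width / 2.0
        lo = positions - bar_width / 2.0
        out[i] = 0.5 * (erf((hi - c) / z) - erf((lo - c) / z)) * params.amplitude
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out, thetas, positions
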