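"""Receptive-field estimation from multi-velocity motion waveforms.

Glutamate release waveforms recorded during bar motion at several speeds
jointly constrain the underlying center-surround RF: the spatial extent
sets how response onset scales with 1/velocity, while rise/decay and delay
set velocity-independent shape features.  Fitting a single RF model to all
speeds at once therefore disentangles spatial from temporal parameters --
which a single flash response cannot do.

The fit runs the same elitist evolutionary engine used for the circuit
optimization, but the objective is the total mean-square error between
peak-normalized, sensor-filtered model waveforms and the target waveforms
across velocities.  Targets and model outputs are peak-normalized before
comparison, so the absolute release amplitude is unidentifiable by
construction and is flagged as such.  Flash responses, never part of the
objective, serve as held-out validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evolution import (RF_BOUNDS, RF_PARAM_NAMES, ParamBounds,
                        init_population, step_generation)
from .metrics import flash_lag, half_max_rise_time, onset_time
from .rf import RFParams, apply_sensor_filter, bc_drive
from .stimuli import make_bar_stimulus, make_flash_stimulus


def _rf_bounds() -> ParamBounds:
    lo = [RF_BOUNDS[n][0] for n in RF_PARAM_NAMES]
    hi = [RF_BOUNDS[n][1] for n in RF_PARAM_NAMES]
    return ParamBounds(tuple(RF_PARAM_NAMES), np.array(lo), np.array(hi))


@dataclass
class FitTask:
    """Targets and settings for one cluster's RF fit.

    ``waveforms`` maps velocity (mm/s) to a 1-ms-sampled target trace
    (single motion direction, left to right).  Traces are peak-normalized
    internally.
    """

    waveforms: dict
    f_rise: float = 10.0            # ms, sensor filter
    f_decay: float = 50.0           # ms
    rf_x: float = 500.0             # um, model cell position in the arena
    arena_width: float = 1000.0
    dwell_time: float = 2.0         # s
    n_repeats: int = 10
    seed: int = 0
    pop_size: int = 16
    generations: int = 120

    def __post_init__(self):
        if len(self.waveforms) < 2:
            raise ValueError("need waveforms for at least 2 velocities")
        for v, w in self.waveforms.items():
            w = np.asarray(w, dtype=float)
            if not np.all(np.isfinite(w)):
                raise ValueError(f"non-finite target waveform at {v} mm/s")
            self.waveforms[v] = w


@dataclass
class FitResult:
    params: list                    # RFParams per repeat
    mse: np.ndarray                 # per repeat
    param_mean: dict
    param_sd: dict
    unidentifiable: list = field(default_factory=list)

    @property
    def best(self) -> RFParams:
        return self.params[int(np.argmin(self.mse))]

    @property
    def best_mse(self) -> float:
        return float(self.mse.min())


def _normalize(x: np.ndarray) -> np.ndarray:
    p = x.max()
    return x / p if p > 0 else x


def simulate_motion_waveform(params: RFParams, velocity: float,
                             rf_x: float = 500.0, arena_width: float = 1000.0,
                             dwell_time: float = 2.0, f_rise: float = 10.0,
                             f_decay: float = 50.0) -> np.ndarray:
    """Sensor-filtered model release waveform for one bar velocity."""
    stim = make_bar_stimulus(velocity, 1, arena_width=arena_width,
                             dwell_time=dwell_time)
    drive = bc_drive(params, stim, rf_x)[:, 0]
    return apply_sensor_filter(drive, f_rise, f_decay)


def _task_mse(task: FitTask, genome: np.ndarray, targets_norm: dict) -> float:
    params = RFParams(**dict(zip(RF_PARAM_NAMES, genome)))
    total = 0.0
    for v, target in targets_norm.items():
        model = simulate_motion_waveform(params, v, task.rf_x,
                                         task.arena_width, task.dwell_time,
                                         task.f_rise, task.f_decay)
        n = min(len(model), len(target))
        total += float(np.mean((_normalize(model[:n]) - target[:n]) ** 2))
    return total / len(targets_norm)


def fit_rf_to_motion(task: FitTask) -> FitResult:
    """Evolve RF parameters to reproduce the target motion waveforms.

    Runs ``n_repeats`` independent fits (fresh seeds); per-parameter mean
    and SD across repeats quantify identifiability.  Parameters whose
    perturbation leaves the best fit's MSE essentially unchanged (e.g.
    surround shape when the fitted surround strength is ~0) are listed in
    ``unidentifiable`` rather than trusted.
    """
    bounds = _rf_bounds()
    targets_norm = {v: _normalize(np.asarray(w, dtype=float))
                    for v, w in task.waveforms.items()}
    all_zero = all(t.max() == 0 for t in targets_norm.values())
    params_out, mses = [], []
    for rep in range(task.n_repeats):
        seed = task.seed + 1000 * rep
        pop = init_population(bounds, n=task.pop_size, seed=seed)
        rng = np.random.default_rng(seed + 1)
        if all_zero:
            # degenerate target: zero drive fits exactly
            g = pop.genomes[0].copy()
            g[RF_PARAM_NAMES.index("amplitude")] = bounds.lo[0]
            params_out.append(RFParams(**dict(zip(RF_PARAM_NAMES, g))))
            mses.append(0.0)
            continue
        for gen in range(task.generations + 1):
            for i in range(pop.n):
                if np.isnan(pop.fitness[i]):
                    pop.fitness[i] = -_task_mse(task, pop.genomes[i],
                                                targets_norm)
            if gen < task.generations:
                pop = step_generation(pop, bounds, rng)
        b = pop.best_index()
        params_out.append(RFParams(**dict(zip(RF_PARAM_NAMES, pop.genomes[b]))))
        mses.append(-pop.fitness[b])
    mses = np.asarray(mses)
    arr = np.array([[getattr(p, n) for n in RF_PARAM_NAMES] for p in params_out])
    mean = dict(zip(RF_PARAM_NAMES, arr.mean(axis=0)))
    sd = dict(zip(RF_PARAM_NAMES, arr.std(axis=0)))
    result = FitResult(params_out, mses, mean, sd)
    if not all_zero:
        result.unidentifiable = _flag_unidentifiable(task, result, targets_norm)
    return result


def _flag_unidentifiable(task: FitTask, result: FitResult, targets_norm,
                         rel_perturb: float = 0.25,
                         tol: float = 1e-6) -> list:
    """Sensitivity screen: perturb each fitted parameter of the best fit
    by +/-25% (clipped to bounds); if the MSE moves by less than ``tol``
    the parameter does not constrain the targets (e.g. the absolute
    amplitude of peak-normalized targets changes the MSE by exactly 0)."""
    best = result.best
    base_genome = np.array([getattr(best, n) for n in RF_PARAM_NAMES])
    base_mse = _task_mse(task, base_genome, targets_norm)
    bounds = _rf_bounds()
    out = []
    for j, name in enumerate(RF_PARAM_NAMES):
        deltas = []
        for sgn in (1.0 - rel_perturb, 1.0 + rel_perturb):
            g = base_genome.copy()
            g[j] = np.clip(g[j] * sgn + (0.02 * (bounds.hi[j] - bounds.lo[j])
                                         if g[j] == 0 else 0.0),
                           bounds.lo[j], bounds.hi[j])
            deltas.append(abs(_task_mse(task, g, targets_norm) - base_mse))
        if max(deltas) < tol:
            out.append(name)
    return out


def predict_flash(params: RFParams, duration: float = 4.0,
                  rf_x: float = 500.0, arena_width: float = 1000.0,
                  f_rise: float = 10.0, f_decay: float = 50.0,
                  post_ms: float = 1000.0) -> np.ndarray:
    """Sensor-filtered model response to a full-field flash (held-out
    stimulus for validating motion-derived fits)."""
    stim = make_flash_stimulus(duration, arena_width=arena_width)
    drive = bc_drive(params, stim, rf_x)[:, 0]
    if post_ms > 0:
        drive = np.concatenate([drive, np.full(int(post_ms), drive[-1])])
    return apply_sensor_filter(drive, f_rise, f_decay)


def evaluate_fit(result: FitResult, validation_flash: np.ndarray,
                 flash_duration: float = 4.0, rf_x: float = 500.0,
                 onset_fraction: float = 0.05) -> dict:
    """Compare the fitted model against a held-out flash response.

    Returns flash rise time, flash lag and center FWHM for model and
    measurement, plus the flash MSE of the peak-normalized traces.
    """
    val = _normalize(np.asarray(validation_flash, dtype=float))
    pred = _normalize(predict_flash(result.best, flash_duration, rf_x))
    n = min(len(val), len(pred))
    report = {
        "model_flash_rise_ms": half_max_rise_time(pred),
        "measured_flash_rise_ms": half_max_rise_time(val),
        "model_flash_lag_ms": flash_lag(pred, 0.0, fraction=onset_fraction),
        "measured_flash_lag_ms": flash_lag(val, 0.0, fraction=onset_fraction),
        "model_center_fwhm_um": result.best.center_width,
        "flash_mse": float(np.mean((pred[:n] - val[:n]) ** 2)),
    }
    return report
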