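"""Evolutionary search over presynaptic receptive fields and postsynaptic
biophysics to maximize direction selectivity in the bipolar-SAC circuit.

The optimizer is a small elitist evolutionary algorithm: a population of
16 genomes, the two best retained verbatim each generation, every other
slot re-seeded from one of the two elites (fair coin) and mutated.
Mutation multiplies each parameter by a Gaussian factor (mean 1, SD 5%)
and adds a uniform perturbation of +/-1.5% of the parameter's bound range,
then clips to bounds.  The additive term acts on the normalized bound
range; a raw-unit addition of 0.015 would be invisible for parameters
like the axial resistance.

Genomes concatenate the presynaptic RF description(s) with five
postsynaptic parameters (leak conductance, axial resistance, N-type
conductance density and voltage offset, synaptic conductance).  The full
scenario has 9 x 2 + 5 = 23 free parameters; constrained scenarios share
or clamp RF parameters, and the annulus scenario replaces the RF genome
by a per-annulus choice among fitted waveform clusters, swapped with 5%
probability per bin per generation.

Fitness is the mean over stimulation speeds of the site-averaged
directional metric computed from peak dendritic calcium at distal
recording sites near the horizontal axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .cable import (CompartmentalModel, MembraneSpec, SimulationError,
                    perisomatic_modification, place_bipolar_synapses,
                    run_visual_trial)
from .metrics import directional_summary
from .morphology import Morphology
from .rf import RFParams, bc_drive, shift_trace
from .stimuli import make_bar_stimulus

RF_PARAM_NAMES = ("amplitude", "center_width", "surround_width",
                  "center_rise", "center_decay", "surround_rise",
                  "surround_strength", "surround_reversal", "delay")

#: presynaptic bounds: unitless terms in [0,1], widths/times positive with
#: documented upper limits wide enough to cover the evolved optima
RF_BOUNDS = {
    "amplitude": (0.05, 1.0),
    "center_width": (10.0, 300.0),
    "surround_width": (20.0, 600.0),
    "center_rise": (1.0, 300.0),
    "center_decay": (5.0, 5000.0),
    "surround_rise": (1.0, 500.0),
    "surround_strength": (0.0, 1.0),
    "surround_reversal": (0.0, 1.0),
    "delay": (0.0, 300.0),
}

POST_PARAM_NAMES = ("g_pas", "ra", "can_voffset", "g_can", "g_syn")

POST_BOUNDS = {
    "g_pas": (1e-5, 1e-3),       # S/cm^2
    "ra": (50.0, 300.0),         # Ohm*cm
    "can_voffset": (-30.0, 30.0),  # mV
    "g_can": (1e-6, 3e-5),       # S/cm^2 (upper limit is a package default)
    "g_syn": (0.01, 1.0),        # nS
}

#: positive scale-type parameters whose bounds span about a decade or more;
#: these are *initialized* log-uniformly (mutation is unaffected) so that
#: random populations start in physiologically responsive regimes
LOG_SCALE_PARAMS = frozenset({
    "center_width", "surround_width", "center_rise", "center_decay",
    "surround_rise", "g_can", "g_syn",
})
# g_pas is deliberately *not* log-initialized: the raw-uniform median
# (5e-4 S/cm^2) matches the default passive leak, keeping the membrane
# tight enough that typical random drive stays below saturation


@dataclass
class ParamBounds:
    names: tuple
    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def from_dicts(cls, *dicts_names):
        names, lo, hi = [], [], []
        for d, ns in dicts_names:
            for n in ns:
                names.append(n)
                lo.append(d[n][0])
                hi.append(d[n][1])
        return cls(tuple(names), np.array(lo), np.array(hi))

    def __post_init__(self):
        if not np.all(self.lo < self.hi):
            raise ValueError("bounds require lo < hi")

    @property
    def k(self):
        return len(self.names)


@dataclass
class Population:
    genomes: np.ndarray                 # (n, k)
    fitness: np.ndarray                 # (n,), NaN = not evaluated
    labels: Optional[np.ndarray] = None  # (n, n_annuli) for annulus mode

    @property
    def n(self):
        return self.genomes.shape[0]

    def best_index(self) -> int:
        return int(np.nanargmax(self.fitness))


# ------------------------------------------------------------------ engine

def init_population(bounds: ParamBounds, n: int = 16, seed: int = 0,
                    n_labels: int = 0, n_clusters: int = 0) -> Population:
    """Random genomes within bounds (deterministic per seed).

    Positive scale-type parameters (see ``LOG_SCALE_PARAMS``) are sampled
    log-uniformly over their bounds, everything else uniformly; a raw
    uniform draw over ranges spanning two decades starts virtually every
    model saturated or silent.
    """
    rng = np.random.default_rng(seed)
    g = rng.uniform(bounds.lo, bounds.hi, size=(n, bounds.k))
    for j, name in enumerate(bounds.names):
        base = name.split("_", 1)[1] if name.split("_", 1)[0] in \
            ("prox", "dist", "shared") else name
        if base in LOG_SCALE_PARAMS and bounds.lo[j] > 0:
            g[:, j] = np.exp(rng.uniform(np.log(bounds.lo[j]),
                                         np.log(bounds.hi[j]), size=n))
    labels = None
    if n_labels:
        labels = rng.integers(0, n_clusters, size=(n, n_labels))
    return Population(g, np.full(n, np.nan), labels)


def mutate_genome(genome: np.ndarray, bounds: ParamBounds,
                  rng: np.random.Generator, sigma: float = 0.05,
                  u_frac: float = 0.015) -> np.ndarray:
    """Gaussian scaling (mean 1, SD ``sigma``) plus a uniform perturbation
    of ``u_frac`` of the bound range, clipped to bounds."""
    scale = rng.normal(1.0, sigma, size=genome.shape)
    add = rng.uniform(-u_frac, u_frac, size=genome.shape) * (bounds.hi - bounds.lo)
    return np.clip(genome * scale + add, bounds.lo, bounds.hi)


def step_generation(pop: Population, bounds: ParamBounds,
                    rng: np.random.Generator, n_elite: int = 2,
                    swap_prob: float = 0.05, n_clusters: int = 0,
                    sigma: float = 0.05, u_frac: float = 0.015) -> Population:
    """Selection + mutation: elites verbatim, everyone else re-seeded from
    a fair-coin choice between the two best and mutated (and, in annulus
    mode, each bin's cluster identity swapped with ``swap_prob``)."""
    if np.isnan(pop.fitness).any():
        raise ValueError("population must be fully evaluated before stepping")
    order = np.argsort(-pop.fitness, kind="stable")
    elites = order[:n_elite]
    genomes = np.empty_like(pop.genomes)
    fitness = np.full(pop.n, np.nan)
    labels = None if pop.labels is None else np.empty_like(pop.labels)
    for j, e in enumerate(elites):
        genomes[j] = pop.genomes[e]
        fitness[j] = pop.fitness[e]
        if labels is not None:
            labels[j] = pop.labels[e]
    for j in range(n_elite, pop.n):
        parent = elites[rng.integers(0, n_elite)]
        genomes[j] = mutate_genome(pop.genomes[parent], bounds, rng,
                                   sigma=sigma, u_frac=u_frac)
        if labels is not None:
            lab = pop.labels[parent].copy()
            swap = rng.random(lab.size) < swap_prob
            lab[swap] = rng.integers(0, n_clusters, size=int(swap.sum()))
            labels[j] = lab
    return Population(genomes, fitness, labels)


# ---------------------------------------------------------------- scenario

@dataclass(frozen=True)
class ScenarioSpec:
    """What is free to evolve, and under which stimulus battery."""

    mode: str = "full"       # full | identical | single_free | cluster_pair | annuli
    free_param: Optional[str] = None      # for single_free
    velocities: tuple = (0.25, 0.5, 1.0, 2.0, 4.0)   # mm/s
    objective: str = "standard"           # standard | dsi_only
    ca_opt: float = 500.0                 # nM
    n_synapses: int = 200
    max_syn_dist: float = 110.0           # um
    dwell_time: float = 2.0               # s
    arena_width: float = 1000.0           # um
    dt: float = 0.1                       # ms, cable solver step
    dt_rf: float = 1.0                    # ms, RF drive grid
    ra_factor: float = 1.0                # perisomatic compartmentalization
    rm_factor: float = 1.0
    annulus_width: float = 10.0           # um, annuli mode bin width
    swap_prob: float = 0.05
    cluster_pair: Optional[tuple] = None  # (proximal id, distal id)

    def __post_init__(self):
        if self.mode not in ("full", "identical", "single_free",
                             "cluster_pair", "annuli"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        if self.mode == "single_free" and self.free_param not in RF_PARAM_NAMES:
            raise ValueError("single_free requires a valid free_param")
        if self.objective not in ("standard", "dsi_only"):
            raise ValueError("objective must be 'standard' or 'dsi_only'")


class BipolarSacProblem:
    """Binds a morphology, synapse placement and scenario into a fitness
    function over genome vectors.

    ``cluster_library`` (a list of RFParams or of pre-computed drive
    waveform factories) is required for the cluster_pair and annuli modes,
    where presynaptic waveforms are fixed cluster fits rather than free
    parameters.
    """

    def __init__(self, morph: Morphology, scenario: ScenarioSpec,
                 seed: int = 0, cluster_library: Optional[Sequence[RFParams]] = None,
                 membrane: MembraneSpec = MembraneSpec()):
        self.morph = morph
        self.scenario = scenario
        self.membrane = membrane
        self.cluster_library = list(cluster_library) if cluster_library else None
        base = CompartmentalModel(morph, membrane)
        if scenario.ra_factor != 1.0 or scenario.rm_factor != 1.0:
            base = perisomatic_modification(base, scenario.ra_factor,
                                            scenario.rm_factor)
        self.base_model = base
        self.synapses = place_bipolar_synapses(base, n=scenario.n_synapses,
                                               max_dist=scenario.max_syn_dist,
                                               seed=seed)
        self.record = base.recording_sites()
        if not self.record:
            raise ValueError("morphology yields no recording sites")
        sx = base.comp_xyz[0, 0]
        self.syn_x_arena = np.array([scenario.arena_width / 2.0 + s.x - sx
                                     for s in self.synapses])
        dists = np.array([s.path_dist for s in self.synapses])
        median = np.median(dists)
        self.proximal_mask = dists <= median
        self.syn_dists = dists
        self.stimuli = {}
        for v in scenario.velocities:
            for d in (1, -1):
                self.stimuli[(v, d)] = make_bar_stimulus(
                    v, d, arena_width=scenario.arena_width,
                    dwell_time=scenario.dwell_time, dt=scenario.dt_rf)
        self.bounds = self._make_bounds()
        if scenario.mode == "annuli":
            edges = np.arange(0.0, scenario.max_syn_dist + scenario.annulus_width,
                              scenario.annulus_width)
            self.annulus_of_syn = np.clip(
                np.digitize(dists, edges) - 1, 0, len(edges) - 2)
            self.n_annuli = len(edges) - 1

    # ------------------------------------------------------------- genome
    def _make_bounds(self) -> ParamBounds:
        s = self.scenario
        if s.mode == "full":
            names = [f"prox_{n}" for n in RF_PARAM_NAMES] + \
                    [f"dist_{n}" for n in RF_PARAM_NAMES]
            lo = [RF_BOUNDS[n][0] for n in RF_PARAM_NAMES] * 2
            hi = [RF_BOUNDS[n][1] for n in RF_PARAM_NAMES] * 2
        elif s.mode == "identical":
            names = [f"shared_{n}" for n in RF_PARAM_NAMES]
            lo = [RF_BOUNDS[n][0] for n in RF_PARAM_NAMES]
            hi = [RF_BOUNDS[n][1] for n in RF_PARAM_NAMES]
        elif s.mode == "single_free":
            names = [f"shared_{n}" for n in RF_PARAM_NAMES if n != s.free_param]
            lo = [RF_BOUNDS[n][0] for n in RF_PARAM_NAMES if n != s.free_param]
            hi = [RF_BOUNDS[n][1] for n in RF_PARAM_NAMES if n != s.free_param]
            names += [f"prox_{s.free_param}", f"dist_{s.free_param}"]
            lo += [RF_BOUNDS[s.free_param][0]] * 2
            hi += [RF_BOUNDS[s.free_param][1]] * 2
        else:  # cluster_pair, annuli: only postsynaptic parameters evolve
            names, lo, hi = [], [], []
        names += list(POST_PARAM_NAMES)
        lo += [POST_BOUNDS[n][0] for n in POST_PARAM_NAMES]
        hi += [POST_BOUNDS[n][1] for n in POST_PARAM_NAMES]
        return ParamBounds(tuple(names), np.array(lo), np.array(hi))

    def decode(self, genome: np.ndarray, labels: Optional[np.ndarray] = None):
        """Genome vector -> (proximal RFParams, distal RFParams | labels,
        postsynaptic dict)."""
        s = self.scenario
        post = dict(zip(POST_PARAM_NAMES, genome[-5:]))
        if s.mode == "full":
            prox = RFParams(**dict(zip(RF_PARAM_NAMES, genome[:9])))
            dist = RFParams(**dict(zip(RF_PARAM_NAMES, genome[9:18])))
        elif s.mode == "identical":
            prox = dist = RFParams(**dict(zip(RF_PARAM_NAMES, genome[:9])))
        elif s.mode == "single_free":
            shared_names = [n for n in RF_PARAM_NAMES if n != s.free_param]
            shared = dict(zip(shared_names, genome[:8]))
            prox = RFParams(**{**shared, s.free_param: genome[8]})
            dist = RFParams(**{**shared, s.free_param: genome[9]})
        elif s.mode == "cluster_pair":
            prox = self.cluster_library[s.cluster_pair[0]]
            dist = self.cluster_library[s.cluster_pair[1]]
        else:  # annuli
            prox = dist = None
        return prox, dist, post

    def _postsynaptic_model(self, post: dict) -> CompartmentalModel:
        spec = replace(self.membrane, g_pas=post["g_pas"], ra=post["ra"],
                       can_voffset=post["can_voffset"], g_can=post["g_can"])
        # same discretization as the base model so site indices stay valid
        # (perisomatic ra/rm scale factors are carried over by with_spec)
        return self.base_model.with_spec(spec)

    def _drive(self, prox: RFParams, dist: RFParams, stim,
               labels: Optional[np.ndarray]) -> np.ndarray:
        """(T, n_syn) RF_full release waveforms for one stimulus."""
        n = len(self.synapses)
        if self.scenario.mode == "annuli":
            T = stim.n_steps
            out = np.zeros((T, n))
            for cid in np.unique(labels):
                params = self.cluster_library[int(cid)]
                mask = labels[self.annulus_of_syn] == cid
                if mask.any():
                    out[:, mask] = bc_drive(params, stim, self.syn_x_arena[mask])
            return out
        out = np.zeros((stim.n_steps, n))
        pm = self.proximal_mask
        if pm.any():
            out[:, pm] = bc_drive(prox, stim, self.syn_x_arena[pm])
        if (~pm).any():
            out[:, ~pm] = bc_drive(dist, stim, self.syn_x_arena[~pm])
        return out

    # ------------------------------------------------------------- fitness
    def evaluate(self, genome: np.ndarray,
                 labels: Optional[np.ndarray] = None,
                 return_details: bool = False):
        """Mean directional metric over velocities (the training fitness).

        With ``return_details`` also returns per-velocity mean DSI and the
        final-trial calcium traces.
        """
        s = self.scenario
        prox, dist, post = self.decode(genome, labels)
        model = self._postsynaptic_model(post)
        synapses = [replace(sy, g_max=post["g_syn"]) for sy in self.synapses]
        per_v_metric, per_v_dsi = [], []
        details = {}
        try:
            for v in s.velocities:
                res = {}
                for d in (1, -1):
                    stim = self.stimuli[(v, d)]
                    drive = self._drive(prox, dist, stim, labels)
                    res[d] = run_visual_trial(model, synapses, drive,
                                              self.record, dt=s.dt,
                                              dt_rf=s.dt_rf)
                ds, met = directional_summary(res[1], res[-1], s.ca_opt)
                per_v_metric.append(met.mean())
                per_v_dsi.append(ds.mean())
                if return_details:
                    details[v] = res
        except SimulationError:
            return (-np.inf, None) if return_details else -np.inf
        fit = float(np.mean(per_v_dsi if s.objective == "dsi_only"
                            else per_v_metric))
        if return_details:
            return fit, {"per_velocity_dsi": np.array(per_v_dsi),
                         "per_velocity_metric": np.array(per_v_metric),
                         "results": details}
        return fit


@dataclass
class TrainResult:
    best_genome: np.ndarray
    best_labels: Optional[np.ndarray]
    best_fitness: float
    history: np.ndarray                 # best fitness per generation
    per_velocity_dsi: np.ndarray
    bounds: ParamBounds = None
    scenario: ScenarioSpec = None
    decoded: tuple = None

    def to_json(self, path):
        d = {"best_genome": self.best_genome.tolist(),
             "best_labels": None if self.best_labels is None
             else self.best_labels.tolist(),
             "best_fitness": self.best_fitness,
             "history": self.history.tolist(),
             "per_velocity_dsi": self.per_velocity_dsi.tolist(),
             "param_names": list(self.bounds.names) if self.bounds else None}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def train(problem: BipolarSacProblem, generations: int = 100,
          pop_size: int = 16, seed: int = 0,
          callback: Optional[Callable] = None) -> TrainResult:
    """Run the elitist EA on a bipolar-SAC problem.

    Deterministic per seed.  Reduced-scale runs (smaller population, fewer
    generations, a velocity subset, coarser solver step) use the same code
    path; pass the desired sizes here and in the scenario.
    """
    s = problem.scenario
    n_lab = getattr(problem, "n_annuli", 0) if s.mode == "annuli" else 0
    n_clu = len(problem.cluster_library) if problem.cluster_library else 0
    pop = init_population(problem.bounds, n=pop_size, seed=seed,
                          n_labels=n_lab, n_clusters=n_clu)
    rng = np.random.default_rng(seed + 1)
    history = []
    for gen in range(generations + 1):
        for i in range(pop.n):
            if np.isnan(pop.fitness[i]):
                lab = None if pop.labels is None else pop.labels[i]
                pop.fitness[i] = problem.evaluate(pop.genomes[i], lab)
        history.append(np.nanmax(pop.fitness))
        if callback:
            callback(gen, pop)
        if gen < generations:
            pop = step_generation(pop, problem.bounds, rng,
                                  swap_prob=s.swap_prob, n_clusters=n_clu)
    b = pop.best_index()
    lab = None if pop.labels is None else pop.labels[b]
    fit, det = problem.evaluate(pop.genomes[b], lab, return_details=True)
    return TrainResult(pop.genomes[b].copy(),
                       None if lab is None else lab.copy(),
                       float(fit), np.array(history),
                       det["per_velocity_dsi"] if det else np.full(len(s.velocities), np.nan),
                       problem.bounds, s, problem.decode(pop.genomes[b], lab))
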