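"""The core lineage-resolved population algorithm.

An asynchronously cycling Generation-1 population is built by heterogenizing
serum-starved cells, stimulating them with growth media for a 48 h window
(Generation 0) and sampling one uniformly random timepoint per cell as its
Gen-1 initial condition.  Per-generation single-cell simulations are then run
for the remaining experiment time; division and death events are detected on
each trajectory; daughters inherit the mother's exact state at division and
are simulated for the remaining time.  The loop terminates when a generation
produces no divisions.  Death halts a lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cellmodel import (DEFAULT_BURN_IN, DEFAULT_CV, DEFAULT_DT, CellState, simulate_cell,
                        starved_average_state, heterogenize_population,
                        stream_for)
from .events import DetectorConfig, resolve_fate
from .parallel import get_backend

GEN0_DURATION = 48.0  # hours of growth-media stimulation before sampling


def _model_hash(model):
    """Stable fingerprint of the model's declarative description."""
    import hashlib
    import json

    base = getattr(model, "base", model)
    if hasattr(base, "to_description"):
        payload = json.dumps(base.to_description(), sort_keys=True)
        drug = getattr(getattr(model, "spec", None), "name", "")
        return hashlib.sha1((payload + drug).encode()).hexdigest()[:12]
    return getattr(model, "name", "unknown")


@dataclass
class CellRecord:
    """One cell's bookkeeping entry in the lineage forest."""

    cell_id: str                  # "generation.index"
    parent_id: str | None
    generation: int
    index: int
    birth_time: float             # absolute hours
    fate: str                     # "divided" | "died" | "censored"
    fate_time: float              # absolute hours
    initial_state: np.ndarray | None = None
    param_scalings: dict = field(default_factory=dict)
    trajectory: object = None     # truncated Trajectory when stored

    @property
    def divided(self):
        return self.fate == "divided"

    @property
    def lifetime(self):
        return self.fate_time - self.birth_time


@dataclass
class PopulationResult:
    """The complete lineage record of one population run."""

    records: list
    n0: int
    exp_time: float
    dt: float
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self._by_id = {r.cell_id: r for r in self.records}

    def record(self, cell_id):
        try:
            return self._by_id[cell_id]
        except KeyError:
            raise KeyError(f"unknown cell id {cell_id!r}")

    def children(self, cell_id):
        return [r for r in self.records if r.parent_id == cell_id]

    def roots(self):
        return [r for r in self.records if r.parent_id is None]

    def generation(self, g):
        return [r for r in self.records if r.generation == g]

    @property
    def n_generations(self):
        return max(r.generation for r in self.records)

    def living_count(self, t):
        """Number of living cells at absolute time ``t``.

        A cell is alive on [birth, fate) if it divided or died, and on
        [birth, exp_time] if censored.
        """
        eps = 1e-6  # absorbs accumulated grid round-off in birth/fate times
        n = 0
        for r in self.records:
            if r.birth_time - eps <= t and (
                    t < r.fate_time - eps or
                    (r.fate == "censored" and t <= r.fate_time + eps)):
                n += 1
        return n

    def living_series(self, times=None):
        if times is None:
            times = np.arange(0.0, self.exp_time + self.dt / 2, self.dt)
        times = np.asarray(times, dtype=float)
        eps = 1e-6
        counts = np.zeros(len(times), dtype=int)
        for r in self.records:
            alive = (times >= r.birth_time - eps) & (
                (times < r.fate_time - eps) if r.fate != "censored"
                else (times <= r.fate_time + eps))
            counts += alive
        return times, counts

    def n_divisions(self, up_to=None):
        t = self.exp_time if up_to is None else up_to
        return sum(1 for r in self.records if r.divided and r.fate_time <= t)

    def n_deaths(self, up_to=None):
        t = self.exp_time if up_to is None else up_to
        return sum(1 for r in self.records if r.fate == "died" and r.fate_time <= t)


def living_count(result, t):
    """Module-level convenience mirroring :meth:`PopulationResult.living_count`."""
    return result.living_count(t)


def make_asynchronous_population(model, n0, media, seed=0, *, cv=DEFAULT_CV,
                                 burn_in=DEFAULT_BURN_IN,
                                 gen0_duration=GEN0_DURATION, dt=DEFAULT_DT,
                                 backend=None, return_sample_times=False):
    """Build Gen-1 initial conditions with uniformly sampled cycle phases.

    Heterogenized starved cells are stimulated with ``media`` (drug-free) for
    ``gen0_duration`` hours; for each cell a grid index is drawn uniformly at
    random and the state there becomes the Gen-1 initial condition with
    birth time 0.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    media = media.without_drug()
    base = starved_average_state(getattr(model, "base", model), dt)
    if hasattr(model, "extend_state"):
        base = CellState(species=model.extend_state(base.species),
                         cell_id=base.cell_id)
    cells = heterogenize_population(base, n0, cv, burn_in, model=model,
                                    seed=seed, dt=dt)
    bk = get_backend(backend)

    def _gen0(args):
        i, state = args
        traj = simulate_cell(state, media, gen0_duration, dt, model=model,
                             stochastic_death=False)
        return traj

    if cv == 0:
        shared = _gen0((0, cells[0]))
        trajs = [shared] * n0
    else:
        trajs = bk.map(_gen0, list(enumerate(cells)))

    out = []
    sample_times = []
    for i, (state, traj) in enumerate(zip(cells, trajs)):
        idx = int(state.rng.integers(0, len(traj.t)))
        sample_times.append(float(traj.t[idx]))
        out.append(CellState(
            species=traj.y[idx].copy(),
            param_scalings=dict(state.param_scalings),
            cell_id=f"1.{i}",
            rng=stream_for(seed, 1, i),
        ))
    if return_sample_times:
        return out, sample_times
    return out


def spawn_daughters(mother_record, mother_state, exp_time, seed):
    """Two daughters from the mother's state at division.

    Daughters receive identical copies of the mother's species vector and
    expression scalings, fresh independent random streams keyed by their
    lineage coordinates, birth time t_div, and remaining duration
    exp_time - t_div.  Mother index i yields daughter indices 2i and 2i+1 in
    generation g+1.
    """
    t_div = mother_record.fate_time
    if not mother_record.divided:
        raise ValueError(f"cell {mother_record.cell_id} did not divide")
    if t_div >= exp_time:
        return []
    g = mother_record.generation + 1
    daughters = []
    for k in range(2):
        idx = 2 * mother_record.index + k
        daughters.append((CellState(
            species=mother_state.copy(),
            param_scalings=dict(mother_record.param_scalings),
            cell_id=f"{g}.{idx}",
            rng=stream_for(seed, g, idx),
        ), t_div))
    return daughters


def run_population(model, n0, stimuli, exp_time=72.0, seed=0, *, cv=DEFAULT_CV,
                   dt=DEFAULT_DT, detector=None, backend=None,
                   store_trajectories=False, burn_in=DEFAULT_BURN_IN,
                   gen0_duration=GEN0_DURATION, gen1_states=None,
                   stochastic_death=True):
    """Run the full lineage-resolved population simulation.

    Generations are simulated until one produces no division events.  The
    result is reproducible given ``seed`` and independent of the parallel
    backend.  ``gen1_states`` may supply pre-built Gen-1 cells (e.g. to share
    one asynchronized population across doses).
    """
    if exp_time <= 0:
        raise ValueError("exp_time must be > 0")
    cfg = detector or DetectorConfig()
    bk = get_backend(backend)
    if gen1_states is None:
        gen1_states = make_asynchronous_population(
            model, n0, stimuli, seed, cv=cv, burn_in=burn_in,
            gen0_duration=gen0_duration, dt=dt, backend=backend)
    tasks = [(s, 0.0) for s in gen1_states]

    def _run_one(task):
        state, birth = task
        duration = exp_time - birth
        # durations are multiples of dt because divisions land on the grid
        traj = simulate_cell(state, stimuli, duration, dt, model=model,
                             stochastic_death=stochastic_death)
        if len(traj.t) < 3:
            # too short to contain a division pulse; only death can resolve
            from .events import Fate, detect_death
            t_death = detect_death(traj)
            if t_death is not None:
                return Fate("died", t_death, traj.truncate(t_death))
            return Fate("censored", float(traj.t[-1]), traj)
        return resolve_fate(traj, cfg)

    records = []
    generation = 1
    while tasks:
        fates = bk.map(_run_one, tasks)
        next_tasks = []
        any_division = False
        for (state, birth), fate in zip(tasks, fates):
            g, idx = state.cell_id.split(".")
            t_abs = birth + fate.time
            kind = fate.kind
            if kind == "divided" and t_abs >= exp_time - 1e-9:
                kind = "censored"  # a division on the final grid point leaves no time
            rec = CellRecord(
                cell_id=state.cell_id,
                parent_id=None if generation == 1 else f"{generation - 1}.{int(idx) // 2}",
                generation=int(g),
                index=int(idx),
                birth_time=birth,
                fate=kind,
                fate_time=t_abs,
                initial_state=state.species.copy(),
                param_scalings=dict(state.param_scalings),
                trajectory=fate.trajectory if store_trajectories else None,
            )
            records.append(rec)
            if kind == "divided":
                any_division = True
                next_tasks.extend(spawn_daughters(
                    rec, fate.trajectory.y[-1], exp_time, seed))
        tasks = next_tasks if any_division else []
        generation += 1

    return PopulationResult(
        records=records, n0=n0, exp_time=exp_time, dt=dt,
        config={
            "n0": n0, "exp_time": exp_time, "dt": dt, "seed": seed, "cv": cv,
            "drug": stimuli.drug, "dose_uM": stimuli.dose,
            "ligands_nM": {k: getattr(stimuli, k) for k in
                           ("egf", "ins", "hgf", "nrg", "pdgf", "igf", "fgf")},
            "model": getattr(model, "name", "unknown"),
            "model_hash": _model_hash(model),
            "species": list(getattr(model, "species_names", [])),
            "burn_in": burn_in, "gen0_duration": gen0_duration,
        },
    )
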