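"""Single-cell model contract: states, stimuli, trajectories, observables.

The unit of simulation is a :class:`CellState` (species vector + per-cell
expression scalings + a reproducible random stream).  :func:`simulate_cell`
integrates the attached model deterministically on a fixed output grid and
then resolves the stochastic death branch (caspase activation drawn from the
cell's hazard) analytically — the caspase/PARP block is strictly downstream of
the signaling state, so it never feeds back into the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint

from . import demo_model as dm

DEFAULT_DT = 0.05          # hours
DEFAULT_BURN_IN = 48.0     # hours of starved heterogenization
DEFAULT_CV = 0.18        # expression-noise coefficient of variation
GROWTH_MEDIA_EGF = 3.3     # nM
GROWTH_MEDIA_INS = 1721.0  # nM

LIGANDS = ("egf", "ins", "hgf", "nrg", "pdgf", "igf", "fgf")


class SimulationError(RuntimeError):
    """Integration failure, annotated with the failing cell."""


@dataclass
class Stimuli:
    """Ligand doses (nM) and at most one drug with its extracellular dose (uM).

    The demo model responds to EGF and insulin; the remaining ligand fields
    are accepted for protocol compatibility and ignored by models that do not
    include their receptors.
    """

    egf: float = 0.0
    ins: float = 0.0
    hgf: float = 0.0
    nrg: float = 0.0
    pdgf: float = 0.0
    igf: float = 0.0
    fgf: float = 0.0
    drug: str | None = None
    dose: float = 0.0  # uM

    def __post_init__(self):
        for name in LIGANDS + ("dose",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def dose_nM(self):
        return self.dose * 1000.0

    def without_drug(self):
        return replace(self, drug=None, dose=0.0)


def growth_media(drug=None, dose=0.0):
    """The default growth-media stimuli: EGF 3.3 nM + insulin 1721 nM."""
    return Stimuli(egf=GROWTH_MEDIA_EGF, ins=GROWTH_MEDIA_INS, drug=drug, dose=dose)


@dataclass
class CellState:
    """A single cell: species concentrations, expression scalings, identity."""

    species: np.ndarray
    param_scalings: dict = field(default_factory=dict)
    cell_id: str = "1.0"
    rng: np.random.Generator | None = None

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype=float)
        if np.any(self.species < 0):
            raise ValueError("species concentrations must be >= 0")
        if any(s <= 0 for s in self.param_scalings.values()):
            raise ValueError("param_scalings must be > 0")

    def copy(self, cell_id=None, rng=None):
        return CellState(
            species=self.species.copy(),
            param_scalings=dict(self.param_scalings),
            cell_id=self.cell_id if cell_id is None else cell_id,
            rng=rng,
        )


def stream_for(master_seed, generation, index):
    """Reproducible per-cell random stream keyed by (generation, index).

    Keying by lineage coordinates (not by scheduling order) makes population
    results invariant to the parallel worker count.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(generation, index))
    return np.random.default_rng(ss)


# --- observables -----------------------------------------------------------

DEFAULT_CHANNELS = {
    "cyclinB_cdk1": ("CycB",),
    "cyclinE_cdk2": ("CycE",),
    "cyclinA_cdk2": ("CycA",),
    "cyclinD": ("CycD", "CycD_CDK46"),
    "cyclinD_cdk46": ("CycD_CDK46",),
    "parp": ("PARP",),
    "cleaved_parp": ("cPARP",),
    "erk_activity": ("pERK",),
    "akt_activity": ("pAKT",),
    "pegfr": ("pEGFR",),
}


@dataclass
class ObservableSpec:
    """Named mappings from species to scalar trajectory channels.

    Each plain channel is the sum of the listed species; the derived channel
    ``cleaved_parp_fraction`` = cPARP / (PARP + cPARP) lies in [0, 1].
    """

    channels: dict = field(default_factory=lambda: dict(DEFAULT_CHANNELS))

    def validate(self, model):
        for name, species in self.channels.items():
            for sp in species:
                model.species_index(sp)  # raises on unknown species

    def restrict_to(self, model):
        """Keep only channels whose species all exist in ``model``."""
        kept = {}
        for name, species in self.channels.items():
            try:
                for sp in species:
                    model.species_index(sp)
            except KeyError:
                continue
            kept[name] = species
        return ObservableSpec(channels=kept)

    def names(self):
        return tuple(self.channels) + ("cleaved_parp_fraction",)


@dataclass
class Trajectory:
    """Uniform time grid (hours) plus the species matrix (time x species)."""

    t: np.ndarray
    y: np.ndarray
    model: object
    observables: ObservableSpec = field(default_factory=ObservableSpec)

    def __post_init__(self):
        if len(self.t) != self.y.shape[0]:
            raise ValueError("time grid and species matrix row count differ")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def dt(self):
        return float(self.t[1] - self.t[0])

    def channel(self, name):
        return get_observable(self, name)

    def truncate(self, t_stop):
        """Keep grid points with t <= t_stop (inclusive)."""
        keep = self.t <= t_stop + 1e-9
        return Trajectory(self.t[keep], self.y[keep], self.model, self.observables)

    def state_at_index(self, i):
        return self.y[i].copy()


def get_observable(traj, channel):
    """Evaluate a named observable channel over a trajectory."""
    spec = traj.observables
    if channel == "cleaved_parp_fraction":
        parp = get_observable(traj, "parp")
        cparp = get_observable(traj, "cleaved_parp")
        total = parp + cparp
        if np.any(total <= 0):
            raise ValueError("total PARP must be positive to form the cleaved fraction")
        return cparp / total
    if channel not in spec.channels:
        raise KeyError(
            f"unknown channel {channel!r}; valid channels: {sorted(spec.names())}"
        )
    cols = [traj.model.species_index(sp) for sp in spec.channels[channel]]
    return traj.y[:, cols].sum(axis=1)


# --- integration -----------------------------------------------------------

def _grid(duration, dt):
    n = int(round(duration / dt))
    if n < 1 or abs(n * dt - duration) > 1e-9:
        raise ValueError(f"duration {duration} must be a positive multiple of dt {dt}")
    return np.linspace(0.0, n * dt, n + 1)


def _integrate(model, y0, p, stimuli, grid, cell_id, rtol=1e-6, atol=1e-9):
    f = model.make_odeint_func(p, stimuli)
    y, info = odeint(f, y0, grid, rtol=rtol, atol=atol, mxstep=100000,
                     full_output=True)
    if info["message"] != "Integration successful.":
        t_fail = info["tcur"][-1] if len(info.get("tcur", [])) else float("nan")
        raise SimulationError(
            f"integration failed for cell {cell_id} near t={t_fail:.3f} h: "
            f"{info['message']}"
        )
    low = y.min()
    if low < -1e-6:
        raise SimulationError(
            f"cell {cell_id}: species went negative ({low:.3e}) beyond tolerance"
        )
    np.clip(y, 0.0, None, out=y)
    return y


def _apply_death_branch(model, y, grid, state, stochastic_death):
    """Resolve caspase activation and PARP cleavage on the finished grid.

    The hazard is h_basal plus an AKT-survival-loss term; the activation time
    is drawn by inverting the cumulative hazard with one exponential draw from
    the cell's stream.  Caspase and PARP columns are then filled analytically.
    """
    p = model.params
    h0 = p["h_basal"] * dm.S_PER_H
    h1 = p["h_akt"] * dm.S_PER_H
    kd = p["K_death"]
    kca = p["k_casp_act"] * dm.S_PER_H
    kcd = p["k_casp_dec"] * dm.S_PER_H
    kcl = p["k_cleave"] * dm.S_PER_H

    i_pakt = model.species_index("pAKT")
    i_casp = model.species_index("Casp")
    i_parp = model.species_index("PARP")
    i_cparp = model.species_index("cPARP")
    i_sig = model.species_index("DeathSig")

    pakt = y[:, i_pakt]
    if state.species[i_sig] >= 0.5:
        idx_act = 0
    elif stochastic_death:
        if state.rng is None:
            raise ValueError(f"cell {state.cell_id}: stochastic death needs an rng stream")
        hazard = h0 + h1 * kd**4 / (kd**4 + pakt**4)
        cum = np.concatenate(
            [[0.0], np.cumsum((hazard[1:] + hazard[:-1]) / 2.0 * np.diff(grid))]
        )
        draw = -np.log(state.rng.random())
        above = np.nonzero(cum >= draw)[0]
        idx_act = int(above[0]) if above.size else None
    else:
        idx_act = None

    casp0 = state.species[i_casp]
    parp0 = state.species[i_parp]
    cparp0 = state.species[i_cparp]

    casp = casp0 * np.exp(-kcd * grid)
    sig = np.full_like(grid, state.species[i_sig])
    if idx_act is not None:
        t_act = grid[idx_act]
        css = kca / kcd
        tail = grid[idx_act:] - t_act
        casp_at = casp0 * np.exp(-kcd * t_act)
        casp[idx_act:] = css + (casp_at - css) * np.exp(-kcd * tail)
        sig[idx_act:] = 1.0
    integral = np.concatenate(
        [[0.0], np.cumsum((casp[1:] + casp[:-1]) / 2.0 * np.diff(grid))]
    )
    frac_left = np.exp(-kcl * integral)
    y[:, i_casp] = casp
    y[:, i_parp] = parp0 * frac_left
    y[:, i_cparp] = cparp0 + parp0 * (1.0 - frac_left)
    y[:, i_sig] = sig


def simulate_cell(state, stimuli, duration, dt=DEFAULT_DT, *, model=None,
                  stochastic_death=True, observables=None):
    """Simulate one cell for one generation segment.

    The signaling/cell-cycle ODEs are deterministic; stochasticity enters only
    through the cell's caspase-activation hazard draw.  Given an identical
    (state, stimuli, rng stream) the output is bitwise reproducible.
    """
    if model is None:
        raise ValueError("a cell model must be attached (pass model=...)")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if stimuli.drug is not None and not getattr(model, "accepts_drug", lambda d: False)(stimuli.drug):
        raise ValueError(
            f"model {model.name!r} has no drug module for {stimuli.drug!r}; "
            "attach one with pharmacodynamics.attach_drug"
        )
    grid = _grid(duration, dt)
    p = model.param_vector(state.param_scalings)
    y = _integrate(model, state.species, p, stimuli, grid, state.cell_id)
    if getattr(model, "has_death", False):
        _apply_death_branch(model, y, grid, state, stochastic_death)
    if observables is None:
        obs = ObservableSpec().restrict_to(model)
    else:
        observables.validate(model)
        obs = observables
    return Trajectory(grid, y, model, obs)


# --- heterogenization ------------------------------------------------------

def lognormal_scalings(rng, names, cv):
    """Unit-mean lognormal scalings with coefficient of variation ``cv``."""
    if cv == 0:
        return {n: 1.0 for n in names}
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -sigma**2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=sigma, size=len(names))
    return dict(zip(names, draws))


def _scaled_initial_state(model, base, scalings):
    y = base.species.copy()
    for pool, s in scalings.items():
        if pool in dm.POOL_MEMBERS:
            for sp in dm.POOL_MEMBERS[pool]:
                y[model.species_index(sp)] *= s
    return y


_starved_cache = {}


def starved_average_state(model, dt=DEFAULT_DT):
    """The average serum-starved cell: the starved-condition fixed point.

    Computed once per parameterization by relaxing the naive state for 96 h
    with no ligands, then cached.
    """
    key = (model.name, tuple(sorted(model.params.items())))
    if key not in _starved_cache:
        grid = _grid(96.0, dt)
        p = model.param_vector()
        y = _integrate(model, model.naive_state(), p, Stimuli(), grid, "starved-ref")
        _starved_cache[key] = y[-1]
    state = _starved_cache[key].copy()
    return CellState(species=state, cell_id="starved-ref")


def heterogenize_population(base, n, cv=DEFAULT_CV, burn_in=DEFAULT_BURN_IN, *,
                            model=None, seed=0, dt=DEFAULT_DT):
    """Create ``n`` cells with lognormal expression variability from ``base``.

    Each cell's designated expression parameters (conserved signaling pools
    and the Cyclin D synthesis capacity) receive independent unit-mean
    lognormal scalings with coefficient of variation ``cv``; the scaled state
    is then relaxed for ``burn_in`` hours under serum-starved conditions so
    protein levels settle to each cell's own starved distribution.  Streams
    are seeded per cell from (master seed, cell index).
    """
    if model is None:
        raise ValueError("a cell model must be attached (pass model=...)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv < 0 or burn_in < 0:
        raise ValueError("cv and burn_in must be >= 0")

    starved = Stimuli()
    cells = []
    # with cv = 0 every cell relaxes identically; integrate once and share
    shared = None
    for i in range(n):
        rng = stream_for(seed, 0, i)
        scalings = lognormal_scalings(rng, dm.EXPRESSION_PARAMS, cv)
        state = CellState(
            species=_scaled_initial_state(model, base, scalings),
            param_scalings=scalings,
            cell_id=f"1.{i}",
            rng=rng,
        )
        if burn_in > 0:
            if cv == 0 and shared is not None:
                final = shared
            else:
                traj = simulate_cell(state, starved, burn_in, dt, model=model,
                                     stochastic_death=False)
                final = traj.y[-1]
                if cv == 0:
                    shared = final
            state = CellState(species=final, param_scalings=scalings,
                              cell_id=state.cell_id, rng=rng)
        cells.append(state)
    return cells
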