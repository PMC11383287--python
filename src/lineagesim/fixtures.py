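"""Synthetic fixture generators that carry their own ground truth.

Each generator returns (fixture, truth): oscillatory trajectories embed their
exact trough times, death trajectories the exact first grid point with a
cleaved-PARP fraction above one half, and toy populations a full expected
lineage table.  Fixtures are built programmatically at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cellmodel import ObservableSpec, Trajectory
from .population import CellRecord, PopulationResult


class _ChannelModel:
    """Minimal model stub backing a hand-built channel trajectory."""

    name = "fixture"
    has_death = False

    def __init__(self, species):
        self.species_names = tuple(species)
        self.compartments = {s: "cytoplasm" for s in species}

    def species_index(self, name):
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}")


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic fixture."""

    generator: str              # oscillatory_trajectory | death_trajectory | toy_population
    params: dict = field(default_factory=dict)
    seed: int = 0


def generate_fixture(spec):
    generators = {
        "oscillatory_trajectory": oscillatory_trajectory,
        "death_trajectory": death_trajectory,
        "toy_population": toy_population,
    }
    if spec.generator not in generators:
        raise KeyError(f"unknown fixture generator {spec.generator!r}; "
                       f"valid: {sorted(generators)}")
    return generators[spec.generator](seed=spec.seed, **spec.params)


def channel_trajectory(values, dt=0.05, channel="cyclinB_cdk1", extra=None):
    """Wrap a raw channel array (plus optional extra channels) as a Trajectory."""
    extra = extra or {}
    names = [channel, *extra]
    y = np.column_stack([np.asarray(values, dtype=float)]
                        + [np.asarray(v, dtype=float) for v in extra.values()])
    model = _ChannelModel(names)
    obs = ObservableSpec(channels={n: (n,) for n in names})
    t = np.arange(len(values)) * dt
    return Trajectory(t, y, model, obs)


def oscillatory_trajectory(trough_times=(12.0, 36.0, 60.0), duration=72.0,
                           dt=0.05, peak=1.0, baseline=0.25, seed=0):
    """Pulse train whose troughs fall exactly at ``trough_times``.

    Each trough is the V-shaped minimum between two raised-cosine pulses; the
    signal rests at ``baseline`` at the troughs (above the detector's
    post-peak crossing level, so the detected events are the troughs
    themselves).  Returns (trajectory, truth dict with the trough times and
    the interleaved peak times).
    """
    trough_times = np.asarray(sorted(trough_times), dtype=float)
    t = np.arange(0.0, duration + dt / 2, dt)
    # one raised-cosine pulse spanning each interval between consecutive
    # troughs (and the flanking ends), so adjacent pulses meet exactly at the
    # troughs and each trough is a genuine local minimum
    centers = []
    bounds = np.concatenate([[0.0], trough_times, [duration]])
    x = np.full_like(t, baseline)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a <= 2 * dt:
            continue
        c, width = (a + b) / 2, b - a
        centers.append(c)
        mask = (t >= a) & (t <= b)
        x[mask] += (peak - baseline) * 0.5 * (
            1 + np.cos(2 * np.pi * (t[mask] - c) / width))
    traj = channel_trajectory(x, dt)
    return traj, {"trough_times": trough_times, "peak_times": np.array(centers)}


def death_trajectory(crossing_time=30.0, duration=72.0, dt=0.05,
                     total_parp=100.0, rate=0.05, seed=0):
    """PARP-cleavage trajectory with a known first grid point above 1/2.

    The cleaved fraction rises smoothly through 0.5 between grid points
    around ``crossing_time``; the truth records the first grid time at which
    the fraction strictly exceeds one half.
    """
    from scipy.special import expit

    t = np.arange(0.0, duration + dt / 2, dt)
    frac = expit((t - crossing_time) / (rate * duration / 3.6))
    cleaved = total_parp * frac
    parp = total_parp - cleaved
    traj = channel_trajectory(parp, dt, channel="parp",
                              extra={"cleaved_parp": cleaved})
    above = np.nonzero(frac > 0.5)[0]
    truth = {"first_grid_time": float(t[above[0]]) if above.size else None}
    return traj, truth


def toy_population(shape="one_division", exp_time=72.0, dt=0.05, seed=0):
    """Hand-built lineage forests with their expected bookkeeping.

    Shapes: ``one_division`` (a root dividing at 10 h, one daughter dying at
    20 h, the other censored), ``censored`` (a single censored root), and
    ``three_generations`` (root and both daughters divide, grandchildren
    censored).
    """
    def rec(cid, parent, g, i, birth, fate, ft):
        return CellRecord(cell_id=cid, parent_id=parent, generation=g,
                          index=i, birth_time=birth, fate=fate, fate_time=ft)

    if shape == "censored":
        records = [rec("1.0", None, 1, 0, 0.0, "censored", exp_time)]
        truth = {"living": {0.0: 1, exp_time: 1}, "divisions": 0, "deaths": 0}
    elif shape == "one_division":
        records = [
            rec("1.0", None, 1, 0, 0.0, "divided", 10.0),
            rec("2.0", "1.0", 2, 0, 10.0, "died", 20.0),
            rec("2.1", "1.0", 2, 1, 10.0, "censored", exp_time),
        ]
        truth = {"living": {5.0: 1, 15.0: 2, 25.0: 1}, "divisions": 1,
                 "deaths": 1}
    elif shape == "three_generations":
        records = [
            rec("1.0", None, 1, 0, 0.0, "divided", 20.0),
            rec("2.0", "1.0", 2, 0, 20.0, "divided", 44.0),
            rec("2.1", "1.0", 2, 1, 20.0, "divided", 50.0),
            rec("3.0", "2.0", 3, 0, 44.0, "censored", exp_time),
            rec("3.1", "2.0", 3, 1, 44.0, "censored", exp_time),
            rec("3.2", "2.1", 3, 2, 50.0, "censored", exp_time),
            rec("3.3", "2.1", 3, 3, 50.0, "censored", exp_time),
        ]
        truth = {"living": {10.0: 1, 30.0: 2, 60.0: 4}, "divisions": 3,
                 "deaths": 0, "progeny_divisions": {"1.0": 3}}
    else:
        raise KeyError(f"unknown toy population shape {shape!r}")
    result = PopulationResult(records=records, n0=1, exp_time=exp_time, dt=dt,
                              config={"fixture": shape})
    return result, truth
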