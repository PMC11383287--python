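"""Portable population-result archives.

An archive is a directory with a JSON manifest, a lineage table (CSV), an
initial-state matrix (CSV) and, when trajectories were stored, an HDF5 file
of per-cell species matrices — documented open formats in place of
language-specific serialized objects.  Round trip: reading a written archive
reproduces the records and living counts exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cellmodel import ObservableSpec, Trajectory
from .population import CellRecord, PopulationResult

SCHEMA_VERSION = 2


class _SpeciesView:
    """Name->column resolver for trajectories read back from an archive."""

    name = "archived"
    has_death = False

    def __init__(self, species):
        self.species_names = tuple(species)

    def species_index(self, name):
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}")


def write_archive(result, path):
    """Write a PopulationResult to ``path`` (created as a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n0": result.n0,
        "exp_time": result.exp_time,
        "dt": result.dt,
        "config": _jsonable(result.config),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    rows = []
    for r in result.records:
        rows.append({
            "cell_id": r.cell_id, "parent_id": r.parent_id or "",
            "generation": r.generation, "index": r.index,
            "birth_time": r.birth_time, "fate": r.fate,
            "fate_time": r.fate_time,
            "param_scalings": json.dumps(r.param_scalings),
        })
    pd.DataFrame(rows).to_csv(path / "lineage.csv", index=False)

    states = [r for r in result.records if r.initial_state is not None]
    if states:
        species = result.config.get("species") or [
            f"s{i}" for i in range(len(states[0].initial_state))]
        df = pd.DataFrame(np.stack([r.initial_state for r in states]),
                          columns=species)
        df.insert(0, "cell_id", [r.cell_id for r in states])
        df.to_csv(path / "initial_states.csv", index=False)

    times, counts = result.living_series()
    pd.DataFrame({"time_h": times, "living": counts}).to_csv(
        path / "living_counts.csv", index=False)

    with_traj = [r for r in result.records if r.trajectory is not None]
    if with_traj:
        import h5py

        with h5py.File(path / "trajectories.h5", "w") as h5:
            h5.attrs["species"] = json.dumps(
                list(with_traj[0].trajectory.model.species_names))
            for r in with_traj:
                g = h5.create_group(r.cell_id)
                g.create_dataset("t", data=r.trajectory.t)
                g.create_dataset("y", data=r.trajectory.y)
    return path


def read_archive(path):
    """Read an archive written by :func:`write_archive`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"archive schema version {version} does not match reader "
            f"version {SCHEMA_VERSION}")

    lineage = pd.read_csv(path / "lineage.csv",
                          dtype={"cell_id": str, "parent_id": str},
                          keep_default_na=False)
    states = {}
    sp_file = path / "initial_states.csv"
    if sp_file.exists():
        df = pd.read_csv(sp_file, dtype={"cell_id": str})
        cols = [c for c in df.columns if c != "cell_id"]
        for _, row in df.iterrows():
            states[row.cell_id] = row[cols].to_numpy(dtype=float)

    trajs = {}
    h5_file = path / "trajectories.h5"
    if h5_file.exists():
        import h5py

        with h5py.File(h5_file, "r") as h5:
            species = json.loads(h5.attrs["species"])
            view = _SpeciesView(species)
            obs = ObservableSpec()
            try:
                obs.validate(view)
            except KeyError:
                obs = ObservableSpec(channels={
                    s: (s,) for s in species})
            for cid in h5:
                trajs[cid] = Trajectory(h5[cid]["t"][...], h5[cid]["y"][...],
                                        view, obs)

    records = []
    for _, row in lineage.iterrows():
        records.append(CellRecord(
            cell_id=row.cell_id,
            parent_id=row.parent_id or None,
            generation=int(row.generation),
            index=int(row["index"]),
            birth_time=float(row.birth_time),
            fate=row.fate,
            fate_time=float(row.fate_time),
            initial_state=states.get(row.cell_id),
            param_scalings=json.loads(row.param_scalings),
            trajectory=trajs.get(row.cell_id),
        ))
    return PopulationResult(
        records=records,
        n0=int(manifest["n0"]),
        exp_time=float(manifest["exp_time"]),
        dt=float(manifest["dt"]),
        config=manifest.get("config", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
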