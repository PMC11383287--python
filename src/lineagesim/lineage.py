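"""Lineage analytics: progeny counts, phenotype bins, trajectory stitching,
and dendrogram layout.

Division-count phenotype categories follow the low (0-6), moderate (6-16),
high (16+) bins; the overlapping printed bin edges are resolved as half-open
intervals [0, 6), [6, 16), [16, inf) with the boundary going to the upper
category.  A mother's progeny division count includes her own division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORY_EDGES = (6, 16)
CATEGORIES = ("low", "moderate", "high")


def progeny_division_count(result, mother_id):
    """Number of division events in the subtree rooted at a Gen-1 mother.

    Counts every divided record in the subtree, including the mother's own
    division if she divided.
    """
    root = result.record(mother_id)
    if root.generation != 1:
        raise ValueError(f"{mother_id!r} is not a Generation-1 record")
    count = 0
    stack = [root]
    while stack:
        rec = stack.pop()
        if rec.divided:
            count += 1
            stack.extend(result.children(rec.cell_id))
    return count


def division_count_table(result):
    """Per-mother progeny division counts with phenotype categories."""
    rows = []
    for rec in sorted(result.generation(1), key=lambda r: r.index):
        n = progeny_division_count(result, rec.cell_id)
        rows.append({"cell_id": rec.cell_id, "divisions": n,
                     "category": categorize_division_count(n)})
    return pd.DataFrame(rows)


def categorize_division_count(count):
    """Phenotype bin for one progeny division count."""
    if count < 0:
        raise ValueError("division count must be >= 0")
    if count < CATEGORY_EDGES[0]:
        return "low"
    if count < CATEGORY_EDGES[1]:
        return "moderate"
    return "high"


def categorize_division_counts(counts):
    return [categorize_division_count(c) for c in counts]


def ancestors_path(result, leaf_id):
    """Root-to-leaf list of records."""
    path = [result.record(leaf_id)]
    while path[0].parent_id is not None:
        path.insert(0, result.record(path[0].parent_id))
    return path


def stitch_trajectory(result, leaf_id, channel):
    """Concatenate an observable across all ancestors of a leaf.

    Returns (times, values, generations): absolute times, the channel values
    of each truncated ancestor segment in birth order, and the generation tag
    of every point.  Times are strictly increasing; junctions fall at the
    recorded division times.
    """
    path = ancestors_path(result, leaf_id)
    ts, vs, gs = [], [], []
    for rec in path:
        if rec.trajectory is None:
            raise ValueError(
                f"record {rec.cell_id} has no stored trajectory; rerun with "
                "store_trajectories=True")
        t = rec.trajectory.t + rec.birth_time
        v = rec.trajectory.channel(channel)
        if ts:
            # drop the duplicated junction point (division time)
            keep = t > ts[-1][-1] + 1e-9
            t, v = t[keep], v[keep]
        ts.append(t)
        vs.append(v)
        gs.append(np.full(len(t), rec.generation))
    return np.concatenate(ts), np.concatenate(vs), np.concatenate(gs)


@dataclass
class DendrogramLayout:
    """Segment-table layout of a lineage forest.

    ``segments`` has one row per cell: x0=birth, x1=fate time, y=lane, plus a
    connector table of vertical segments at divisions.  Death-terminated
    branches carry ``died=True`` for marker styling.
    """

    segments: pd.DataFrame
    connectors: pd.DataFrame

    @property
    def n_leaves(self):
        return int((~self.segments.cell_id.isin(
            self.connectors.parent_id)).sum())


def dendrogram_layout(result):
    """Deterministic depth-first layout: one horizontal lane per leaf."""
    lanes = {}
    next_lane = [0]

    def assign(rec):
        kids = sorted(result.children(rec.cell_id), key=lambda r: r.index)
        if not kids:
            lanes[rec.cell_id] = float(next_lane[0])
            next_lane[0] += 1
        else:
            for k in kids:
                assign(k)
            lanes[rec.cell_id] = float(np.mean([lanes[k.cell_id] for k in kids]))

    for root in sorted(result.roots(), key=lambda r: r.index):
        assign(root)

    seg_rows, conn_rows = [], []
    for rec in result.records:
        seg_rows.append({
            "cell_id": rec.cell_id, "generation": rec.generation,
            "x0": rec.birth_time, "x1": rec.fate_time,
            "y": lanes[rec.cell_id], "fate": rec.fate,
            "died": rec.fate == "died",
        })
        if rec.divided:
            kids = result.children(rec.cell_id)
            if kids:
                ys = [lanes[k.cell_id] for k in kids]
                conn_rows.append({
                    "parent_id": rec.cell_id, "x": rec.fate_time,
                    "y0": min(ys), "y1": max(ys),
                })
    return DendrogramLayout(
        segments=pd.DataFrame(seg_rows),
        connectors=pd.DataFrame(conn_rows) if conn_rows else
        pd.DataFrame(columns=["parent_id", "x", "y0", "y1"]),
    )
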