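"""Fractional cell-cycle progress estimation from a composite cyclin signal.

The composite signal is the pointwise mean of the peak-normalized CycE-CDK2,
CycA-CDK2 and CycB-CDK1 channels; its trough-to-trough distance is one full
cell cycle.  A reference composite comes from a deterministic (cv = 0,
hazard-free) simulation; a cell's progress at a query time is obtained by
aligning its composite to the reference by maximal cross-correlation over one
reference period and reading off the phase relative to the previous reference
trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .events import DetectorConfig, detect_division


@dataclass
class CompositeSignal:
    """Peak-normalized mean cyclin signal with its detected troughs."""

    t: np.ndarray
    value: np.ndarray
    troughs: np.ndarray = field(default_factory=lambda: np.array([]))
    channel_peaks: dict = field(default_factory=dict)

    @property
    def period(self):
        if len(self.troughs) < 2:
            raise ValueError(
                "fewer than 2 composite troughs; need >= 2 full cycles")
        # median: robust to the initial transient cycle and to a final cycle
        # truncated by the end of the simulation
        return float(np.median(np.diff(self.troughs)))


@dataclass
class ProgressEstimate:
    """Per-cell cycle-progress fraction in [0, 1) with a quality flag."""

    fraction: float
    offset: float
    correlation: float
    low_quality: bool
    time_scale: float = 1.0


#: candidate cell-cycle lengths relative to the reference period tried during
#: alignment; heterogenized cycle lengths span roughly a third to triple the
#: average cycle
TIME_SCALES = (0.5, 0.7, 1.0, 1.4, 2.0, 2.8)


COMPOSITE_CHANNELS = ("cyclinE_cdk2", "cyclinA_cdk2", "cyclinB_cdk1")

# composite is in [0, 1]; detector thresholds are scaled accordingly
# the composite anchor uses the division-event semantics (post-peak
# crossing): cycle boundaries then coincide with the recorded division times,
# which keeps progress estimates and division outcomes on one clock.  Pass a
# ``prefer="trough"`` detector to anchor at the exact interior minima instead.
COMPOSITE_DETECTOR = DetectorConfig(peak_min=0.3, prominence_frac=0.1,
                                    min_separation=4.0, terminal_frac=0.15)


def composite_cyclin_signal(traj, detector=None, peaks=None):
    """Mean of the peak-normalized cyclin channels, with troughs.

    With ``peaks`` (channel -> peak level) the channels are normalized by
    those reference peaks instead of the trajectory's own maxima; this keeps
    the composite on the reference scale for cells whose cycle is perturbed
    (e.g. arrested under drug), where a vanishing own-peak would blow noise
    up to order one.
    """
    parts = []
    used_peaks = {}
    for name in COMPOSITE_CHANNELS:
        x = traj.channel(name)
        peak = x.max() if peaks is None else peaks[name]
        if peak <= 0:
            raise ValueError(f"channel {name} has no positive peak")
        used_peaks[name] = float(peak)
        parts.append(x / peak)
    value = np.mean(parts, axis=0)

    class _View:
        t = traj.t
        dt = traj.dt

        def channel(self, _):
            return value

    cfg = detector or COMPOSITE_DETECTOR
    try:
        troughs = np.asarray(detect_division(_View(), cfg))
    except ValueError:
        troughs = np.array([])
    return CompositeSignal(t=traj.t, value=value, troughs=troughs,
                           channel_peaks=used_peaks)


def reference_signal(model, media, *, duration=200.0, dt=0.05,
                     detector=None):
    """Average composite trajectory from a deterministic simulation.

    Runs a single cv = 0, hazard-free cell under ``media`` long enough for at
    least two full cycles; trough-to-trough distance defines the reference
    period.
    """
    from .cellmodel import CellState, simulate_cell, starved_average_state

    base = starved_average_state(getattr(model, "base", model), dt)
    if hasattr(model, "extend_state"):
        base = CellState(species=model.extend_state(base.species),
                         cell_id="reference")
    traj = simulate_cell(base, media.without_drug(), duration, dt,
                         model=model, stochastic_death=False)
    sig = composite_cyclin_signal(traj, detector)
    if len(sig.troughs) < 2:
        raise ValueError(
            "reference simulation produced fewer than 2 composite troughs "
            "(is the model cycling under these stimuli?)")
    return sig


def _reference_cycle(reference):
    """One steady reference cycle sampled from trough to trough.

    The latest trough pair whose spacing matches the (median) period is
    used, so a final cycle truncated by the end of the run is skipped.
    """
    period = reference.period
    troughs = reference.troughs
    t0, t1 = troughs[-2], troughs[-1]
    for a, b in zip(troughs[-2::-1], troughs[:0:-1]):
        if abs((b - a) - period) <= 0.05 * period:
            t0, t1 = a, b
            break
    sel = (reference.t >= t0) & (reference.t < t1)
    return reference.t[sel] - t0, reference.value[sel]


def progress_at(cell_traj, reference, t_query, *, min_correlation=0.5,
                detector=None, time_scales=None):
    """Cycle progress of one cell at ``t_query`` (trajectory-local hours).

    The cell's composite (normalized by the reference channel peaks, so that
    levels are comparable) is aligned to the periodic reference by
    least-squares matching over phase offsets spanning one reference period,
    using a half-period window after ``t_query``; progress is the aligned
    phase of ``t_query`` relative to the previous reference trough.  The
    Pearson correlation at the chosen phase is reported; a poor correlation
    sets ``low_quality`` but an estimate is still returned (a cycle-arrested
    cell has a flat composite whose level, not shape, carries its phase).
    """
    if not (cell_traj.t[0] <= t_query <= cell_traj.t[-1]):
        raise ValueError("t_query outside the trajectory span")
    sig = composite_cyclin_signal(cell_traj, detector,
                                  peaks=reference.channel_peaks or None)
    tc, ref_cycle = _reference_cycle(reference)
    period = reference.period
    dt = float(cell_traj.t[1] - cell_traj.t[0])
    tc_ext = np.concatenate([tc, [period]])
    rv_ext = np.concatenate([ref_cycle, [ref_cycle[0]]])

    # half-period window: long enough to carry shape, short enough that the
    # level of a featureless (arrested or all-interphase) window still
    # constrains the phase
    n_half = max(2, int(round(period / dt)) // 2)
    w0 = np.searchsorted(cell_traj.t, t_query)
    w1 = min(len(sig.value), w0 + n_half)
    window = sig.value[w0:w1]
    n = len(window)
    wsq = float(np.sum(window ** 2))

    scales = time_scales if time_scales is not None else TIME_SCALES
    best = (np.inf, 0.0, 1.0, 0, None, None, None)
    for s in scales:
        # reference played at cycle length s * period, sampled on the grid
        period_s = s * period
        n_phase = max(1, int(round(period_s / dt)))
        grid = ((np.arange(n_phase + n) * dt) / s) % period
        ref_dense = np.interp(grid, tc_ext, rv_ext)
        xy = np.correlate(ref_dense, window, mode="valid")[:n_phase]
        csum = np.concatenate([[0.0], np.cumsum(ref_dense)])
        csq = np.concatenate([[0.0], np.cumsum(ref_dense ** 2)])
        rsum = csum[n:n + n_phase] - csum[:n_phase]
        rsq = csq[n:n + n_phase] - csq[:n_phase]
        # sliding mean squared error between window and stretched reference
        mse = (wsq - 2.0 * xy + rsq) / n
        k = int(np.argmin(mse))
        if mse[k] < best[0]:
            best = (float(mse[k]), (k * dt) / s % period, s, k, xy, rsum, rsq)
    _, phi, s, k, xy, rsum, rsq = best

    # correlation at the chosen alignment, as the quality measure
    rmean = rsum[k] / n
    rstd = np.sqrt(max(rsq[k] / n - rmean ** 2, 0.0))
    wstd = window.std()
    if wstd > 1e-12 and rstd > 1e-12:
        corr = float((xy[k] / n - window.mean() * rmean) / (wstd * rstd))
    else:
        corr = 0.0
    fraction = (phi % period) / period
    return ProgressEstimate(
        fraction=float(fraction), offset=float(phi),
        correlation=float(corr), low_quality=bool(corr < min_correlation),
        time_scale=float(s))


def population_progress(result, reference, *, t_query=0.0, generation=1,
                        min_correlation=0.5):
    """Progress estimates for every stored Generation-``generation`` record."""
    out = {}
    for rec in sorted(result.generation(generation), key=lambda r: r.index):
        if rec.trajectory is None:
            raise ValueError(
                f"record {rec.cell_id} has no stored trajectory; rerun with "
                "store_trajectories=True")
        out[rec.cell_id] = progress_at(
            rec.trajectory, reference, t_query,
            min_correlation=min_correlation)
    return out


def division_probability_vs_progress(progress, divided, bin_width=0.01,
                                     bw_method=None):
    """Binned division probability as a function of cycle progress.

    Gaussian KDE smooths the progress distributions of the divided and
    non-divided groups; expected group counts per bin give probability =
    dividing / (dividing + non-dividing).  Each group's bandwidth follows
    the robust Silverman rule, 0.9 min(sd, IQR/1.34) n^(-1/5), which keeps a
    group's main cluster sharp even when a few stragglers inflate its
    standard deviation; kernels are reflected at 0 and 1 so mass piled at
    the boundaries (e.g. arrested cells at progress 0) keeps its full
    density.  ``bw_method`` overrides the bandwidth factor.  A group with
    fewer than 2 members contributes exact histogram counts instead of a
    KDE.  Bins with zero expected total count are undefined (NaN).
    """
    progress = np.asarray(progress, dtype=float)
    divided = np.asarray(divided, dtype=bool)
    if len(progress) != len(divided):
        raise ValueError("progress and divided must have equal length")
    if len(progress) < 2:
        raise ValueError("need at least 2 cells to estimate probabilities")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2

    def expected_counts(values):
        if len(values) == 0:
            return np.zeros(len(centers))
        if len(values) < 2 or np.std(values) == 0:
            counts, _ = np.histogram(values, bins=edges)
            return counts.astype(float)
        if bw_method is not None:
            bw = bw_method
        else:
            std = float(np.std(values, ddof=1))
            q75, q25 = np.percentile(values, [75, 25])
            scale = min(std, (q75 - q25) / 1.34) or std
            h = 0.9 * scale * len(values) ** (-1.0 / 5.0)
            bw = h / std
        kde = gaussian_kde(values, bw_method=bw)
        density = kde(centers) + kde(-centers) + kde(2.0 - centers)
        return density * bin_width * len(values)

    n_div = expected_counts(progress[divided])
    n_not = expected_counts(progress[~divided])
    total = n_div + n_not
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(total > 1e-9, n_div / np.where(total > 0, total, 1.0),
                        np.nan)
    return pd.DataFrame({
        "progress": centers, "p_divide": prob,
        "expected_divided": n_div, "expected_total": total,
    })


def probability_crossing(table, level=0.5):
    """Smallest progress where the probability first exceeds ``level``."""
    valid = table.dropna(subset=["p_divide"])
    above = valid[valid.p_divide > level]
    if above.empty:
        return None
    return float(above.progress.iloc[0])
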