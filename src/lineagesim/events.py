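"""Division and death event detection on single-cell trajectories.

Division is marked by the post-mitotic minimum of the CycB-CDK1 pulse: the
detector finds qualifying pulses (peaks above an absolute height with a
minimum separation) and, for each, the earlier of (i) the following detected
trough and (ii) the first time the channel falls below a fraction of that
pulse's height.  Rule (ii) places the event at the end of mitosis even when
the channel then rests on a flat interphase baseline (where a local-minimum
search would be ambiguous), and also catches a terminal division that is not
followed by another pulse.

Death is marked the first time more than half of PARP has been cleaved
(strictly more; a fraction of exactly one half is not death).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks


@dataclass
class DetectorConfig:
    """Tunables of the division-trough detector.

    ``peak_min`` (nM) qualifies a pulse; ``prominence_frac`` is relative to
    the observed pulse amplitude; ``min_separation`` (h) applies to both
    pulses and troughs; ``terminal_frac`` sets the post-peak crossing level as
    a fraction of the pulse height.
    """

    channel: str = "cyclinB_cdk1"
    peak_min: float = 5.0
    prominence_frac: float = 0.1
    min_separation: float = 4.0
    terminal_frac: float = 0.1
    #: "crossing" places the event at the earlier of the detected trough and
    #: the post-peak crossing below terminal_frac (division semantics, robust
    #: to flat interphase baselines); "trough" prefers the interior local
    #: minimum and falls back to the crossing (phase-anchor semantics)
    prefer: str = "crossing"


def detect_division(traj, config=None):
    """Ordered division times (hours, trajectory-local) from CycB troughs."""
    cfg = config or DetectorConfig()
    x = traj.channel(cfg.channel)
    if len(x) < 3:
        raise ValueError("trajectory must have at least 3 points")
    dt = traj.dt
    dist = max(1, int(round(cfg.min_separation / dt)))
    peaks, _ = find_peaks(x, height=cfg.peak_min, distance=dist)
    if peaks.size == 0:
        return []
    amp = float(x[peaks].max() - x.min())
    troughs, _ = find_peaks(-x, prominence=cfg.prominence_frac * amp,
                            distance=dist)
    events = []
    last = -np.inf
    for k, ip in enumerate(peaks):
        end = peaks[k + 1] if k + 1 < len(peaks) else len(x)
        after = troughs[(troughs > ip) & (troughs < end)]
        i_trough = after[0] if after.size else None
        below = np.nonzero(x[ip:end] < cfg.terminal_frac * x[ip])[0]
        i_cross = ip + below[0] if below.size else None
        if cfg.prefer == "trough":
            i_ev = i_trough if i_trough is not None else i_cross
        else:
            candidates = [i for i in (i_trough, i_cross) if i is not None]
            i_ev = min(candidates) if candidates else None
        if i_ev is None:
            continue
        t_ev = traj.t[i_ev]
        if t_ev - last >= cfg.min_separation:
            events.append(float(t_ev))
            last = t_ev
    return events


def detect_death(traj):
    """First time (hours, trajectory-local) the cleaved-PARP fraction
    exceeds one half, or None."""
    frac = traj.channel("cleaved_parp_fraction")
    above = np.nonzero(frac > 0.5)[0]
    if above.size == 0:
        return None
    return float(traj.t[above[0]])


@dataclass
class Fate:
    """Resolved fate of one generation segment (times trajectory-local)."""

    kind: str          # "divided" | "died" | "censored"
    time: float
    trajectory: object  # truncated at the fate time

    @property
    def divided(self):
        return self.kind == "divided"


def resolve_fate(traj, config=None):
    """Earliest of division, death and censoring; ties go to death.

    The trajectory is truncated at the fate time (timepoints after a division
    or death are discarded).
    """
    divisions = detect_division(traj, config)
    death = detect_death(traj)
    t_div = divisions[0] if divisions else None
    if death is not None and (t_div is None or death <= t_div):
        return Fate("died", death, traj.truncate(death))
    if t_div is not None:
        return Fate("divided", t_div, traj.truncate(t_div))
    return Fate("censored", float(traj.t[-1]), traj)
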