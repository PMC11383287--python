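"""Growth-rate-inhibition (GR) scoring and dose-response tables.

The GR value normalizes treated growth to control growth on a log2 scale:

    GR(c) = 2 ** ( log2(x_c / x0) / log2(x_ctrl / x0) ) - 1

with x0 the living count at t = 0, x_c the endpoint count under dose c and
x_ctrl the endpoint count of the untreated control.  Landmarks: GR = 1 when
treatment matches control, GR = 0 at complete cytostasis (no net growth), and
GR -> -1 at complete killing.  GR is invariant to rescaling all three counts
by a common factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cellmodel import DEFAULT_CV


#: default half-log dose grid (uM): 10 dose levels spanning the published
#: assay range
DEFAULT_DOSE_GRID = tuple(round(10.0 ** (-4 + 0.5 * i), 6) for i in range(10))


class ControlGrowthError(ValueError):
    """The control did not grow (x_ctrl <= x0), so GR is undefined."""


@dataclass(frozen=True)
class GRInput:
    """Counts entering one GR evaluation."""

    x0: float
    x_c: float
    x_ctrl: float

    def __post_init__(self):
        if self.x0 <= 0:
            raise ValueError("x0 must be > 0")
        if self.x_c < 0:
            raise ValueError("x_c must be >= 0")
        if self.x_ctrl <= self.x0:
            raise ControlGrowthError(
                f"control endpoint {self.x_ctrl} must exceed x0 {self.x0} "
                "for GR to be defined")


def gr_value(inp):
    """GR score of one (x0, x_c, x_ctrl) triple; x_c = 0 maps to -1."""
    if inp.x_c == 0:
        return -1.0
    num = np.log2(inp.x_c / inp.x0)
    den = np.log2(inp.x_ctrl / inp.x0)
    return float(2.0 ** (num / den) - 1.0)


def dose_response_curve(results, endpoint=72.0, x0=None):
    """GR dose-response table from replicate population results.

    ``results`` maps dose (uM) -> list of PopulationResult replicates and
    must include dose 0.  The control endpoint count x_ctrl is the median
    over dose-0 replicates; each replicate of each dose is scored against it
    and summarized by the median and the standard error across replicates.
    Extinct replicates (endpoint count 0) score at the -1 limit and are
    flagged.
    """
    if 0.0 not in results:
        raise ValueError("dose-0 control replicates are required")
    x_ctrl = float(np.median([r.living_count(endpoint) for r in results[0.0]]))
    rows = []
    for dose in sorted(results):
        grs, extinct = [], 0
        for rep in results[dose]:
            xc = rep.living_count(endpoint)
            x0_rep = float(rep.n0 if x0 is None else x0)
            grs.append(gr_value(GRInput(x0=x0_rep, x_c=xc, x_ctrl=x_ctrl)))
            extinct += xc == 0
        grs = np.asarray(grs)
        sem = grs.std(ddof=1) / np.sqrt(len(grs)) if len(grs) > 1 else 0.0
        rows.append({
            "dose_uM": dose, "gr_median": float(np.median(grs)),
            "gr_sem": float(sem), "n_replicates": len(grs),
            "n_extinct": int(extinct),
            "gr_values": list(np.round(grs, 6)),
        })
    return pd.DataFrame(rows)


def run_dose_response(model_factory, doses, *, n0=100, exp_time=72.0,
                      replicates=10, seed=0, media=None, drug=None,
                      backend=None, cv=DEFAULT_CV, dt=None):
    """Run the full dose-response protocol and score it.

    ``model_factory(dose)`` returns the (drug-attached) model to use; each
    (dose, replicate) pair gets its own deterministic seed stream.  Returns
    (table, results dict).
    """
    from .cellmodel import DEFAULT_DT, growth_media
    from .population import run_population

    media = media or growth_media()
    dt = dt or DEFAULT_DT
    results = {}
    for di, dose in enumerate(sorted(set([0.0, *doses]))):
        model = model_factory(dose)
        reps = []
        for r in range(replicates):
            rep_seed = (seed * 100003 + di * 1009 + r) % (2**31 - 1)
            stim = media.without_drug() if dose == 0 else media.__class__(
                **{**media.__dict__, "drug": drug, "dose": dose})
            reps.append(run_population(
                model, n0, stim, exp_time, rep_seed, cv=cv, dt=dt,
                backend=backend))
        results[dose] = reps
    return dose_response_curve(results, endpoint=exp_time), results
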