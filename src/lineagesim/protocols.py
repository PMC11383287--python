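"""Canned study protocols on the demo model.

These reproduce the population-level analyses the simulator was built for:
the control doubling-time measurement, the restriction-point analysis under
saturating CDK4/6 inhibition, and the basal (tonic) Ras-activation sweep in
EGF-free media.
"""

from __future__ import annotations

import numpy as np

from .cellmodel import Stimuli, growth_media
from .cycle_progress import (division_probability_vs_progress,
                             population_progress, probability_crossing,
                             reference_signal)
from .demo_model import build_demo_model
from .pharmacodynamics import attach_drug, resolve_drug_spec
from .population import run_population


def time_to_double(result):
    """First time the living count reaches twice the starting population."""
    times, counts = result.living_series()
    hit = np.nonzero(counts >= 2 * result.n0)[0]
    return float(times[hit[0]]) if hit.size else None


def doubling_time_protocol(model=None, *, n0=100, replicates=10, seed=0,
                           exp_time=96.0, backend=None):
    """Control growth curves; the median time for n0 cells to reach 2 n0.

    Mirrors the control doubling-time measurement: replicates of an untreated
    population in full growth media, each scored by the first time the living
    count doubles; the median across replicates is the doubling time.
    """
    model = model or build_demo_model()
    media = growth_media()
    per_rep = []
    for r in range(replicates):
        rep_seed = (seed * 1000003 + r) % (2**31 - 1)
        res = run_population(model, n0, media, exp_time, rep_seed,
                             backend=backend)
        per_rep.append(time_to_double(res))
    finite = [t for t in per_rep if t is not None]
    return {
        "replicate_doubling_times": per_rep,
        "median_doubling_time": float(np.median(finite)) if finite else None,
        "n0": n0, "replicates": replicates,
    }


def restriction_point_protocol(model=None, *, dose=0.1, n0=100, seed=0,
                               exp_time=96.0, backend=None, bin_width=0.01,
                               bw_method=None):
    """Division probability vs cycle progress under saturating CDK4/6 inhibition.

    Palbociclib at ``dose`` uM is added at t = 0 to an asynchronized Gen-1
    population; each cell's cycle progress at drug addition is estimated from
    its composite cyclin signal, and the division outcome is recorded for
    Gen 1 and (per mother) Gen 2.  The observation window defaults to 96 h so
    that the outcome of the slowest committed cells is not censored.
    """
    base = model or build_demo_model()
    drugged = attach_drug(base, resolve_drug_spec("palbociclib"))
    ref = reference_signal(base, growth_media())
    res = run_population(
        drugged, n0, growth_media(drug="palbociclib", dose=dose), exp_time,
        seed, backend=backend, store_trajectories=True)
    prog = population_progress(res, ref)

    gen1 = sorted(res.generation(1), key=lambda r: r.index)
    fractions = np.array([prog[r.cell_id].fraction for r in gen1])
    divided1 = np.array([r.divided for r in gen1])
    table1 = division_probability_vs_progress(fractions, divided1, bin_width,
                                              bw_method=bw_method)

    mothers = [r for r in gen1 if r.divided]
    frac2 = np.array([prog[r.cell_id].fraction for r in mothers])
    div2 = np.array([any(k.divided for k in res.children(r.cell_id))
                     for r in mothers])
    table2 = (division_probability_vs_progress(frac2, div2, bin_width,
                                               bw_method=bw_method)
              if len(mothers) >= 2 else None)
    return {
        "result": res,
        "progress": fractions,
        "divided_gen1": divided1,
        "gen1_table": table1,
        "gen2_table": table2,
        "gen1_crossing": probability_crossing(table1),
        "gen2_max_probability": (float(np.nanmax(table2.p_divide.values))
                                 if table2 is not None and
                                 np.isfinite(table2.p_divide).any() else 0.0),
    }


def basal_ras_sweep(k_basal_values=(2e-4, 3.5e-4, 5e-4, 1e-3, 2e-3), *,
                    n0=100, seed=0, exp_time=72.0, ins=1721.0, backend=None):
    """Division probability in EGF-free media vs the tonic Ras exchange rate.

    For each basal Ras-GDP -> Ras-GTP rate constant (s^-1), an EGF-free
    population (insulin only) is run and the fraction of Gen-1 mothers that
    divide is recorded.  At 2e-4 s^-1 the division probability is near zero.
    """
    media = Stimuli(ins=ins)
    out = []
    for k in k_basal_values:
        model = build_demo_model(k_ras_basal=k)
        res = run_population(model, n0, media, exp_time, seed, backend=backend)
        gen1 = res.generation(1)
        out.append({
            "k_ras_basal": k,
            "division_probability": float(np.mean([r.divided for r in gen1])),
            "n_divisions": res.n_divisions(),
        })
    return out
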