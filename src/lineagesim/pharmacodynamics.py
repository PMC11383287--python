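"""Declarative drug modules: transport, target binding, and validation.

A :class:`DrugSpec` describes a drug's membrane transport and mass-action
binding mechanism.  :func:`attach_drug` extends any model satisfying the cell
model contract with the extra species and reactions: an extracellular
reservoir (held at the applied dose), first-order symmetric transport into the
cytoplasm (and into the nucleus when the target is nuclear), one binding
reaction per target, and drug-target complexes that participate in nothing but
dissociation (reversible specs) and first-order decay at the target's own
decay rate.  Because every downstream rate law in the base model reads the
*free* target concentration, sequestration into a complex is loss of function
by construction.

The four bundled specs carry the published rate constants: alpelisib and
palbociclib and trametinib bind reversibly with kon 1e-3 nM^-1 s^-1 and Kd of
2.4, 1.9 and 0.35 nM respectively; neratinib binds irreversibly with kon
1e-4 nM^-1 s^-1.  Transport is first-order at 0.01 s^-1 in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRANSPORT_RATE = 0.01      # s^-1, symmetric in/out (and nuclear import/export)
S_PER_H = 3600.0


@dataclass(frozen=True)
class DrugSpec:
    """Declarative description of one drug's mechanism.

    ``kon`` is in nM^-1 s^-1, ``koff`` in s^-1 (reversible only), transport in
    s^-1.  ``targets`` are free-species names in the attached model; a bound
    target loses all catalytic activity (the complex takes part in no other
    reaction) and the complex inherits the target's first-order decay rate.
    """

    name: str
    targets: tuple
    mechanism: str            # "reversible" | "irreversible"
    kon: float
    koff: float = 0.0
    transport_rate: float = TRANSPORT_RATE
    aliases: tuple = ()

    def __post_init__(self):
        if self.mechanism not in ("reversible", "irreversible"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.kon <= 0:
            raise ValueError("kon must be > 0")
        if self.mechanism == "reversible" and self.koff < 0:
            raise ValueError("koff must be >= 0 for a reversible spec")

    @property
    def kd(self):
        """Dissociation constant koff/kon in nM (reversible specs)."""
        if self.mechanism != "reversible":
            raise ValueError(f"{self.name} is irreversible; Kd is undefined")
        return self.koff / self.kon

    def matches(self, name):
        return name.lower() in {self.name.lower(), *[a.lower() for a in self.aliases]}


def builtin_drug_specs():
    """The four bundled drug modules with their published constants."""
    return {
        "alpelisib": DrugSpec(
            name="alpelisib", targets=("PI3K",), mechanism="reversible",
            kon=1.0e-3, koff=2.4e-3, aliases=("alpel", "alpel_EC"),
        ),
        "palbociclib": DrugSpec(
            name="palbociclib", targets=("CDK46",), mechanism="reversible",
            kon=1.0e-3, koff=1.9e-3, aliases=("palbo", "palbo_EC"),
        ),
        "trametinib": DrugSpec(
            name="trametinib", targets=("MEK",), mechanism="reversible",
            kon=1.0e-3, koff=3.5e-4, aliases=("trame", "trame_EC"),
        ),
        "neratinib": DrugSpec(
            name="neratinib", targets=("EGFR",), mechanism="irreversible",
            kon=1.0e-4, aliases=("nerat", "nerat_EC"),
        ),
    }


def resolve_drug_spec(name):
    for spec in builtin_drug_specs().values():
        if spec.matches(name):
            return spec
    options = sorted(builtin_drug_specs())
    raise KeyError(f"unknown drug {name!r}; available options: {options} "
                   "(short names alpel/nerat/trame/palbo and the *_EC species "
                   "names are accepted)")


def equilibrium_occupancy(spec, dose):
    """Equilibrium bound fraction of an isolated target, dose in nM.

    For a reversible drug in excess this is dose / (dose + Kd).
    """
    if spec.mechanism != "reversible":
        raise ValueError(
            f"{spec.name} is irreversible; equilibrium occupancy is undefined")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return dose / (dose + spec.kd)


class DrugModel:
    """A cell model extended with one drug module.

    Appends species [<drug>_cyto, (<drug>_nuc,) <target>:<drug> complexes] to
    the base model's state vector.  The extracellular compartment is treated
    as an infinite reservoir held at the applied dose (assay media volume is
    large compared to cell volume).  With dose 0 the extension is inert and
    trajectories match the base model to solver tolerance.
    """

    def __init__(self, base, spec):
        if isinstance(base, DrugModel):
            raise ValueError(
                f"model already has drug module {base.spec.name!r}; at most "
                "one drug per protocol run")
        for tgt in spec.targets:
            base.species_index(tgt)  # raises naming the missing species
        self.base = base
        self.spec = spec
        self.name = f"{base.name}+{spec.name}"
        self.has_death = getattr(base, "has_death", False)
        self.params = base.params

        nuclear = [
            t for t in spec.targets
            if base.compartments.get(t) == "nucleus"
        ]
        self.nuclear = bool(nuclear)
        self._n_base = base.n_species
        names = [f"{spec.name}_cyto"]
        comps = {f"{spec.name}_cyto": "cytoplasm"}
        if self.nuclear:
            names.append(f"{spec.name}_nuc")
            comps[f"{spec.name}_nuc"] = "nucleus"
        self.complex_names = tuple(f"{t}:{spec.name}" for t in spec.targets)
        for t, c in zip(spec.targets, self.complex_names):
            names.append(c)
            comps[c] = base.compartments.get(t, "cytoplasm")
        self.species_names = tuple(base.species_names) + tuple(names)
        self.compartments = {**base.compartments, **comps}
        self._index = {n: i for i, n in enumerate(self.species_names)}

        self._tgt_idx = np.array([base.species_index(t) for t in spec.targets])
        decay = getattr(base, "species_decay", {})
        self._cplx_decay = np.array(
            [decay.get(t, 0.0) * S_PER_H for t in spec.targets])
        # binding site: nuclear targets bind the nuclear drug pool
        self._tgt_nuclear = np.array(
            [base.compartments.get(t) == "nucleus" for t in spec.targets])

    # -- contract -----------------------------------------------------------
    @property
    def n_species(self):
        return len(self.species_names)

    def species_index(self, name):
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(
                f"unknown species {name!r} in model {self.name!r}")

    def accepts_drug(self, drug_name):
        return self.spec.matches(drug_name)

    def param_vector(self, scalings=None):
        return self.base.param_vector(scalings)

    def naive_state(self):
        return self.extend_state(self.base.naive_state())

    def extend_state(self, y_base):
        """Pad a base-model state with zero drug species."""
        y = np.zeros(self.n_species)
        y[: self._n_base] = y_base
        return y

    def make_odeint_func(self, p, stimuli):
        base_f = self.base.make_odeint_func(p, stimuli)
        nb = self._n_base
        dose_ec = stimuli.dose_nM if (
            stimuli.drug is not None and self.accepts_drug(stimuli.drug)) else 0.0
        kt = self.spec.transport_rate * S_PER_H
        kon = self.spec.kon * S_PER_H
        koff = (self.spec.koff if self.spec.mechanism == "reversible" else 0.0) * S_PER_H
        tgt = self._tgt_idx
        tgt_nuc = self._tgt_nuclear
        cdec = self._cplx_decay
        nuclear = self.nuclear
        i_cyto = nb
        i_nuc = nb + 1 if nuclear else nb
        i_cplx0 = i_nuc + 1 if nuclear else nb + 1

        def f(y, t):
            dy = np.empty_like(y)
            dy[:nb] = base_f(y[:nb], t)
            d_cyto = y[i_cyto]
            d_nuc = y[i_nuc] if nuclear else d_cyto
            dd_cyto = kt * (dose_ec - d_cyto)
            dd_nuc = 0.0
            if nuclear:
                v_imp = kt * (d_cyto - d_nuc)
                dd_cyto -= v_imp
                dd_nuc += v_imp
            for j in range(len(tgt)):
                loc = d_nuc if tgt_nuc[j] else d_cyto
                c = y[i_cplx0 + j]
                v = kon * loc * y[tgt[j]] - koff * c
                dy[tgt[j]] -= v
                dy[i_cplx0 + j] = v - cdec[j] * c
                if tgt_nuc[j]:
                    dd_nuc -= v
                else:
                    dd_cyto -= v
            dy[i_cyto] = dd_cyto
            if nuclear:
                dy[i_nuc] = dd_nuc
            return dy

        return f


def attach_drug(model, spec):
    """Extend ``model`` with the drug module described by ``spec``.

    The original model object is left untouched; with dose 0 the extended
    model reproduces it within solver tolerance.
    """
    return DrugModel(model, spec)


# --- validation harness ----------------------------------------------------

#: biomarkers named in the validation protocol (any observable channel is
#: accepted; these four are the documented standards)
STANDARD_BIOMARKERS = ("akt_activity", "erk_activity", "pegfr", "cyclinD")


@dataclass
class ValidationReport:
    """Outcome of the three-criterion drug-module check.

    Criteria: (i) intra/extracellular free drug equilibrates within minutes,
    (ii) target engagement reaches 90% of its equilibrium within minutes,
    (iii) the downstream biomarker changes substantially at 10 uM vs control.
    """

    drug: str
    biomarker: str
    equilibration_time: float   # minutes to 90% of extracellular level
    engagement_time: float      # minutes to 90% of equilibrium complex
    biomarker_effect: float     # fractional reduction vs control at endpoint
    max_minutes: float = 10.0
    min_effect: float = 0.5

    @property
    def equilibration_ok(self):
        return 0 <= self.equilibration_time <= self.max_minutes

    @property
    def engagement_ok(self):
        return 0 <= self.engagement_time <= self.max_minutes

    @property
    def biomarker_ok(self):
        return self.biomarker_effect >= self.min_effect

    @property
    def passed(self):
        return self.equilibration_ok and self.engagement_ok and self.biomarker_ok


def validate_drug_module(model, spec, dose=10.0, biomarker="erk_activity", *,
                         duration=24.0, dt=0.01, max_minutes=10.0,
                         min_effect=0.5):
    """Run the three-criterion validation protocol for one drug module.

    Two deterministic simulations of the average serum-starved cell under
    growth media (EGF + insulin), with and without drug at ``dose`` uM, are
    compared.  ``biomarker`` may be any observable channel; ppAKT, ppERK,
    receptor phosphorylation and Cyclin D are the documented choices.
    """
    from .cellmodel import (ObservableSpec, growth_media, simulate_cell,
                            starved_average_state)

    obs = ObservableSpec()
    if biomarker not in obs.names():
        raise KeyError(f"unknown biomarker channel {biomarker!r}; "
                       f"valid: {sorted(obs.names())}")
    drugged = model if isinstance(model, DrugModel) else attach_drug(model, spec)
    base_state = starved_average_state(drugged.base)
    state = drugged.extend_state(base_state.species)

    from .cellmodel import CellState
    ctrl = simulate_cell(
        CellState(species=state, cell_id="validate-ctrl"),
        growth_media(), duration, dt, model=drugged, stochastic_death=False)
    treated = simulate_cell(
        CellState(species=state, cell_id="validate-drug"),
        growth_media(drug=spec.name, dose=dose), duration, dt,
        model=drugged, stochastic_death=False)

    dose_nM = dose * 1000.0
    t_min = treated.t * 60.0
    d_cyto = treated.y[:, drugged.species_index(f"{spec.name}_cyto")]
    eq_idx = np.nonzero(d_cyto >= 0.9 * dose_nM)[0]
    equilibration = t_min[eq_idx[0]] if eq_idx.size else float("inf")

    cplx = treated.y[:, [drugged.species_index(c) for c in drugged.complex_names]].sum(axis=1)
    target_level = 0.9 * cplx[-1]
    en_idx = np.nonzero(cplx >= target_level)[0]
    engagement = t_min[en_idx[0]] if en_idx.size and cplx[-1] > 0 else float("inf")

    ref = ctrl.channel(biomarker)[-1]
    val = treated.channel(biomarker)[-1]
    effect = 0.0 if ref <= 0 else (ref - val) / ref

    return ValidationReport(
        drug=spec.name, biomarker=biomarker,
        equilibration_time=float(equilibration),
        engagement_time=float(engagement),
        biomarker_effect=float(effect),
        max_minutes=max_minutes, min_effect=min_effect,
    )
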