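"""Bundled reduced mechanistic proliferation/death model ("demo model").

A minimal single-cell signaling cascade wired so that every population-level
procedure of the package is exercised:

* EGF binds EGFR (neratinib target) and activates Ras-GTP exchange on top of a
  basal (tonic) exchange rate — the tonic/ligand balance knob.
* Insulin (plus active receptor) drives PI3K (alpelisib target) -> AKT, the
  survival branch.
* Ras-GTP activates MEK (trametinib binds free unphosphorylated MEK) -> ERK.
* ERK (with a smaller AKT contribution) drives Cyclin D synthesis; Cyclin D
  binds CDK4/6 (palbociclib target, nuclear) and the active complex gates a
  sequential CycE-CDK2 -> CycA-CDK2 -> CycB-CDK1 relaxation oscillator with
  APC/C-mediated Cyclin B degradation.  The trough of the CycB-CDK1 pulse is
  the division marker.
* A restriction-point memory latches the current CDK4/6 gate once CycE-CDK2
  crosses a commitment threshold early in the cycle, so a committed cell
  finishes its cycle even if CDK4/6 is inhibited afterwards; the latch is
  erased by the APC/C pulse at mitosis.
* A death branch: a small constant stochastic hazard plus a hazard term for
  loss of AKT survival signal activates caspase, which cleaves PARP.  A cell
  with more than half its PARP cleaved is dead.

Protocol times are in hours.  Rate constants are stored per second (and
nM^-1 s^-1 for second-order constants) as they would be printed, and converted
to per-hour once when the parameter vector is built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

S_PER_H = 3600.0

# --- species layout -------------------------------------------------------
SPECIES = (
    "EGFR", "pEGFR",
    "PI3K", "aPI3K",
    "AKT", "pAKT",
    "RasGDP", "RasGTP",
    "MEK", "pMEK",
    "ERK", "pERK",
    "CycD", "CDK46", "CycD_CDK46",
    "CycE", "CycA", "CycB", "APC",
    "RPmem",
    "Casp", "PARP", "cPARP", "DeathSig",
)
COMPARTMENTS = {name: "cytoplasm" for name in SPECIES}
COMPARTMENTS.update({"CDK46": "nucleus", "CycD_CDK46": "nucleus", "APC": "nucleus"})
IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

# indices used by the compiled right-hand side
(I_EGFR, I_PEGFR, I_PI3K, I_API3K, I_AKT, I_PAKT, I_RASGDP, I_RASGTP,
 I_MEK, I_PMEK, I_ERK, I_PERK, I_CYCD, I_CDK46, I_DK, I_CYCE, I_CYCA,
 I_CYCB, I_APC, I_RPMEM, I_CASP, I_PARP, I_CPARP, I_DEATHSIG) = range(N_SPECIES)

# --- parameters (printed units: s^-1, nM^-1 s^-1, nM s^-1, nM) ------------
# (name, value, unit) — unit tags drive the one-time hour conversion.
PARAM_TABLE = (
    ("k_egf_on", 1.0e-4, "per_nM_s"),     # EGF + EGFR association
    ("k_egf_off", 1.0e-3, "per_s"),       # active receptor decay to free
    ("k_pi3k_rtk", 1.5e-3, "per_s"),      # receptor-driven PI3K activation
    ("k_pi3k_ins", 4.0e-3, "per_s"),      # insulin-driven PI3K activation
    ("k_pi3k_basal", 2.5e-4, "per_s"),
    ("k_pi3k_off", 5.0e-3, "per_s"),
    ("K_ins", 300.0, "nM"),               # insulin half-saturation
    ("k_akt_on", 1.0e-2, "per_s"),
    ("k_akt_off", 5.0e-3, "per_s"),
    ("k_ras_basal", 5.0e-4, "per_s"),     # tonic Ras-GDP -> Ras-GTP exchange
    ("k_ras_lig", 1.25e-2, "per_s"),      # ligand-induced exchange (x active R frac)
    ("k_ras_gap", 2.5e-2, "per_s"),
    ("k_mek_on", 2.5e-2, "per_s"),
    ("k_mek_off", 1.0e-2, "per_s"),
    ("k_erk_on", 2.5e-2, "per_s"),
    ("k_erk_off", 1.0e-2, "per_s"),
    ("k_d_syn", 2.9e-2, "nM_per_s"),      # Cyclin D synthesis capacity
    ("w_erk", 1.0, "dimensionless"),
    ("w_akt", 0.12, "dimensionless"),
    ("k_d_dec", 4.0e-4, "per_s"),         # Cyclin D turnover (t1/2 ~ 29 min)
    ("k_dk_on", 1.0e-4, "per_nM_s"),      # CycD + CDK4/6 association
    ("k_dk_off", 1.0e-3, "per_s"),
    ("K_gate", 47.0, "nM"),               # CycD-CDK4/6 gate half-point
    ("n_gate", 4.0, "dimensionless"),
    ("g_floor", 0.028, "dimensionless"),  # CDK4/6-dependent minimum gate drive
    ("K_floor", 12.0, "nM"),              # complex level that saturates the floor
    ("k_e_syn", 2.78e-3, "nM_per_s"),     # CycE-CDK2 synthesis at open gate
    ("k_e_dec", 1.4e-6, "per_s"),
    ("k_e_apc", 1.11e-3, "per_s"),        # APC-driven CycE destruction at mitosis
    ("K_EA", 20.0, "nM"),                 # CycE level triggering CycA
    ("k_a_syn", 2.22e-3, "nM_per_s"),
    ("k_a_pos", 8.33e-3, "nM_per_s"),     # CycA autocatalytic (bistable) loop
    ("K_A_pos", 15.0, "nM"),
    ("k_a_dec", 2.78e-4, "per_s"),
    ("k_a_apc", 5.56e-3, "per_s"),        # APC-driven CycA degradation
    ("K_AB", 20.0, "nM"),                 # CycA level triggering CycB
    ("k_b_syn", 5.56e-3, "nM_per_s"),
    ("k_b_pos", 1.11e-2, "nM_per_s"),     # CycB-CDK1 autocatalytic loop
    ("K_B_pos", 10.0, "nM"),
    ("k_b_dec", 5.56e-5, "per_s"),
    ("k_b_apc", 1.67e-3, "per_s"),        # APC-mediated CycB degradation
    ("K_B", 15.0, "nM"),                  # CycB level activating APC
    ("k_apc_on", 1.11e-2, "per_s"),
    ("k_apc_off", 6.9e-5, "per_s"),
    ("E_commit", 2.7, "nM"),              # restriction-point CycE threshold
    ("k_rp_on", 5.6e-3, "per_s"),         # latch tracking rate
    ("k_rp_off", 2.8e-3, "per_s"),        # APC-driven latch reset
    ("EGFR_ref", 100.0, "nM"),
    ("PI3K_ref", 100.0, "nM"),
    ("AKT_ref", 100.0, "nM"),
    ("Ras_ref", 120.0, "nM"),
    ("MEK_ref", 200.0, "nM"),
    ("ERK_ref", 250.0, "nM"),
    # death branch
    ("h_basal", 1.4e-7, "per_s"),         # constant stochastic hazard
    ("h_akt", 5.6e-6, "per_s"),           # hazard at full AKT-survival loss
    ("K_death", 4.0, "nM"),               # pAKT below this drives the hazard
    ("k_casp_act", 2.8e-4, "nM_per_s"),
    ("k_casp_dec", 2.8e-4, "per_s"),
    ("k_cleave", 2.8e-4, "per_nM_s"),     # caspase-driven PARP cleavage
)
PARAM_NAMES = tuple(t[0] for t in PARAM_TABLE)
P_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}

#: initial totals of the conserved signaling pools (nM)
POOL_TOTALS = {
    "EGFR": 100.0, "PI3K": 100.0, "AKT": 100.0, "Ras": 120.0,
    "MEK": 200.0, "ERK": 250.0, "CDK46": 50.0, "PARP": 100.0,
}

#: expression parameters eligible for per-cell lognormal scaling.  Pool names
#: scale the corresponding conserved totals (all member species); ``k_d_syn``
#: scales the Cyclin D synthesis rate.
EXPRESSION_PARAMS = (
    "EGFR", "PI3K", "AKT", "Ras", "MEK", "ERK", "CDK46", "k_d_syn",
)

#: species belonging to each scalable pool (free + modified + complexed forms)
POOL_MEMBERS = {
    "EGFR": ("EGFR", "pEGFR"),
    "PI3K": ("PI3K", "aPI3K"),
    "AKT": ("AKT", "pAKT"),
    "Ras": ("RasGDP", "RasGTP"),
    "MEK": ("MEK", "pMEK"),
    "ERK": ("ERK", "pERK"),
    "CDK46": ("CDK46", "CycD_CDK46"),
    "PARP": ("PARP", "cPARP"),
}


# parameter-vector index constants (compiled into the jitted RHS as literals)
P_K_EGF_ON = P_IDX["k_egf_on"]; P_K_EGF_OFF = P_IDX["k_egf_off"]
P_K_PI3K_RTK = P_IDX["k_pi3k_rtk"]; P_K_PI3K_INS = P_IDX["k_pi3k_ins"]
P_K_PI3K_BASAL = P_IDX["k_pi3k_basal"]; P_K_PI3K_OFF = P_IDX["k_pi3k_off"]
P_K_INS = P_IDX["K_ins"]
P_K_AKT_ON = P_IDX["k_akt_on"]; P_K_AKT_OFF = P_IDX["k_akt_off"]
P_K_RAS_BASAL = P_IDX["k_ras_basal"]; P_K_RAS_LIG = P_IDX["k_ras_lig"]
P_K_RAS_GAP = P_IDX["k_ras_gap"]
P_K_MEK_ON = P_IDX["k_mek_on"]; P_K_MEK_OFF = P_IDX["k_mek_off"]
P_K_ERK_ON = P_IDX["k_erk_on"]; P_K_ERK_OFF = P_IDX["k_erk_off"]
P_K_D_SYN = P_IDX["k_d_syn"]; P_W_ERK = P_IDX["w_erk"]; P_W_AKT = P_IDX["w_akt"]
P_K_D_DEC = P_IDX["k_d_dec"]
P_K_DK_ON = P_IDX["k_dk_on"]; P_K_DK_OFF = P_IDX["k_dk_off"]
P_K_GATE = P_IDX["K_gate"]; P_N_GATE = P_IDX["n_gate"]
P_G_FLOOR = P_IDX["g_floor"]; P_K_FLOOR = P_IDX["K_floor"]
P_K_E_SYN = P_IDX["k_e_syn"]; P_K_E_DEC = P_IDX["k_e_dec"]
P_K_E_APC = P_IDX["k_e_apc"]; P_K_EA = P_IDX["K_EA"]
P_K_A_SYN = P_IDX["k_a_syn"]; P_K_A_DEC = P_IDX["k_a_dec"]
P_K_A_POS = P_IDX["k_a_pos"]; P_K_A_POS_K = P_IDX["K_A_pos"]
P_K_A_APC = P_IDX["k_a_apc"]; P_K_AB = P_IDX["K_AB"]
P_K_B_SYN = P_IDX["k_b_syn"]; P_K_B_DEC = P_IDX["k_b_dec"]
P_K_B_POS = P_IDX["k_b_pos"]; P_K_B_POS_K = P_IDX["K_B_pos"]
P_K_B_APC = P_IDX["k_b_apc"]; P_K_B = P_IDX["K_B"]
P_K_APC_ON = P_IDX["k_apc_on"]; P_K_APC_OFF = P_IDX["k_apc_off"]
P_E_COMMIT = P_IDX["E_commit"]
P_K_RP_ON = P_IDX["k_rp_on"]; P_K_RP_OFF = P_IDX["k_rp_off"]
P_EGFR_REF = P_IDX["EGFR_ref"]; P_PI3K_REF = P_IDX["PI3K_ref"]
P_AKT_REF = P_IDX["AKT_ref"]; P_RAS_REF = P_IDX["Ras_ref"]
P_MEK_REF = P_IDX["MEK_ref"]; P_ERK_REF = P_IDX["ERK_ref"]


def _demo_rhs(t, y, p, egf, ins):
    """Time derivative of the demo model state (hour units).

    ``p`` is the per-hour parameter vector; ligand doses are boundary
    conditions in nM.  The caspase/PARP block is feed-forward and handled
    analytically outside the integrator, so its derivatives are zero here.
    """
    dy = np.zeros(y.shape[0])

    egfr = y[I_EGFR]; pegfr = y[I_PEGFR]
    pi3k = y[I_PI3K]; api3k = y[I_API3K]
    akt = y[I_AKT]; pakt = y[I_PAKT]
    rasgdp = y[I_RASGDP]; rasgtp = y[I_RASGTP]
    mek = y[I_MEK]; pmek = y[I_PMEK]
    erk = y[I_ERK]; perk = y[I_PERK]
    cycd = y[I_CYCD]; cdk46 = y[I_CDK46]; dk = y[I_DK]
    e = y[I_CYCE]; a = y[I_CYCA]; b = y[I_CYCB]; apc = y[I_APC]
    rpmem = y[I_RPMEM]

    # receptor
    v_r = p[P_K_EGF_ON] * egf * egfr - p[P_K_EGF_OFF] * pegfr
    dy[I_EGFR] = -v_r
    dy[I_PEGFR] = v_r

    # PI3K / AKT
    ins_sig = ins / (ins + p[P_K_INS])
    act_p = (p[P_K_PI3K_RTK] * (pegfr / p[P_EGFR_REF])
             + p[P_K_PI3K_INS] * ins_sig + p[P_K_PI3K_BASAL])
    v_p = act_p * pi3k - p[P_K_PI3K_OFF] * api3k
    dy[I_PI3K] = -v_p
    dy[I_API3K] = v_p
    v_a = p[P_K_AKT_ON] * (api3k / p[P_PI3K_REF]) * akt - p[P_K_AKT_OFF] * pakt
    dy[I_AKT] = -v_a
    dy[I_PAKT] = v_a

    # Ras: tonic + ligand-induced exchange
    v_ras = ((p[P_K_RAS_BASAL] + p[P_K_RAS_LIG] * (pegfr / p[P_EGFR_REF]))
             * rasgdp - p[P_K_RAS_GAP] * rasgtp)
    dy[I_RASGDP] = -v_ras
    dy[I_RASGTP] = v_ras

    # MEK / ERK
    v_m = p[P_K_MEK_ON] * (rasgtp / p[P_RAS_REF]) * mek - p[P_K_MEK_OFF] * pmek
    dy[I_MEK] = -v_m
    dy[I_PMEK] = v_m
    v_e = p[P_K_ERK_ON] * (pmek / p[P_MEK_REF]) * erk - p[P_K_ERK_OFF] * perk
    dy[I_ERK] = -v_e
    dy[I_PERK] = v_e

    # Cyclin D synthesis, turnover, CDK4/6 binding
    syn_d = p[P_K_D_SYN] * (p[P_W_ERK] * perk / p[P_ERK_REF]
                            + p[P_W_AKT] * pakt / p[P_AKT_REF])
    v_bind = p[P_K_DK_ON] * cycd * cdk46 - p[P_K_DK_OFF] * dk
    dy[I_CYCD] = syn_d - p[P_K_D_DEC] * cycd - v_bind
    # complex decays at Cyclin D's rate, releasing CDK4/6
    dy[I_DK] = v_bind - p[P_K_D_DEC] * dk
    dy[I_CDK46] = -v_bind + p[P_K_D_DEC] * dk

    # CDK4/6 gate with restriction-point memory
    # the gate combines a steep main term with a low-threshold saturating
    # floor; both read the active CycD-CDK4/6 complex, so CDK4/6 inhibition
    # closes the gate entirely while moderate complex levels guarantee a
    # minimum cycle drive (caps the slowest cycles near ~100 h)
    gx = (dk / p[P_K_GATE]) ** p[P_N_GATE] if dk > 0.0 else 0.0
    fx = (dk / p[P_K_FLOOR]) ** 8.0 if dk > 0.0 else 0.0
    gate = gx / (1.0 + gx) + p[P_G_FLOOR] * fx / (1.0 + fx)
    ex = (e / p[P_E_COMMIT]) ** 6.0 if e > 0.0 else 0.0
    committed = ex / (1.0 + ex)
    # APC destruction machinery is ultrasensitive: substrates are degraded
    # only once the pulse commits (APC > ~0.5), giving all-or-none mitoses
    apx = (apc / 0.6) ** 8.0 if apc > 0.0 else 0.0
    apc_high = apx / (1.0 + apx)
    ratchet = gate - rpmem
    if ratchet < 0.0:
        ratchet = 0.0
    dy[I_RPMEM] = p[P_K_RP_ON] * committed * ratchet - p[P_K_RP_OFF] * apc_high * rpmem
    gate_eff = gate if gate > rpmem else rpmem

    # sequential cyclin relaxation oscillator; CycA is a bistable switch
    # (autocatalytic loop) triggered by the slow CycE integrator and reset by
    # the APC pulse each mitosis
    eax = (e / p[P_K_EA]) ** 6.0 if e > 0.0 else 0.0
    f_ea = eax / (1.0 + eax)
    aax = (a / p[P_K_A_POS_K]) ** 4.0 if a > 0.0 else 0.0
    f_aa = aax / (1.0 + aax)
    abx = (a / p[P_K_AB]) ** 6.0 if a > 0.0 else 0.0
    f_ab = abx / (1.0 + abx)
    bbx = (b / p[P_K_B_POS_K]) ** 4.0 if b > 0.0 else 0.0
    f_bb = bbx / (1.0 + bbx)
    bx = (b / p[P_K_B]) ** 8.0 if b > 0.0 else 0.0
    f_b = bx / (1.0 + bx)

    dy[I_CYCE] = p[P_K_E_SYN] * gate_eff - (p[P_K_E_DEC] + p[P_K_E_APC] * apc_high) * e
    dy[I_CYCA] = (p[P_K_A_SYN] * f_ea + p[P_K_A_POS] * f_aa
                  - (p[P_K_A_DEC] + p[P_K_A_APC] * apc_high) * a)
    dy[I_CYCB] = (p[P_K_B_SYN] * f_ab + p[P_K_B_POS] * f_bb
                  - (p[P_K_B_DEC] + p[P_K_B_APC] * apc_high) * b)
    dy[I_APC] = p[P_K_APC_ON] * f_b * (1.0 - apc) - p[P_K_APC_OFF] * apc
    return dy


try:  # numba keeps population-scale runs fast; plain python is the fallback
    from numba import njit

    _demo_rhs = njit(cache=True)(_demo_rhs)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


@dataclass
class DemoModel:
    """The bundled reduced proliferation/death model.

    Parameters are stored in printed units (per second / nM) in ``params``;
    the per-hour vector actually integrated is built once by
    :meth:`param_vector`.
    """

    params: dict = field(default_factory=lambda: {n: v for n, v, _ in PARAM_TABLE})
    species_names: tuple = SPECIES
    compartments: dict = field(default_factory=lambda: dict(COMPARTMENTS))
    name: str = "demo"
    has_death: bool = True

    def accepts_drug(self, drug_name):
        return False

    # -- parameter handling -------------------------------------------------
    def param_vector(self, scalings=None):
        """Per-hour parameter vector, with per-cell scalings applied."""
        p = np.empty(len(PARAM_TABLE))
        for i, (pname, _, unit) in enumerate(PARAM_TABLE):
            v = self.params[pname]
            if unit in ("per_s", "per_nM_s", "nM_per_s"):
                v *= S_PER_H
            p[i] = v
        if scalings:
            for pname, s in scalings.items():
                if pname in P_IDX:
                    p[P_IDX[pname]] *= s
        return p

    @property
    def n_species(self):
        return N_SPECIES

    def species_index(self, name):
        try:
            return IDX[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}; demo species: {SPECIES}")

    # -- right-hand side -----------------------------------------------------
    def rhs(self, t, y, p, stimuli):
        return _demo_rhs(t, y, p, stimuli.egf, stimuli.ins)

    def make_odeint_func(self, p, stimuli):
        """Bound ``f(y, t)`` for scipy.integrate.odeint."""
        egf = float(stimuli.egf)
        ins = float(stimuli.ins)

        def f(y, t):
            return _demo_rhs(t, y, p, egf, ins)

        return f

    # -- reference states ----------------------------------------------------
    def naive_state(self):
        """All-free, unsignaled species vector (pools at their totals)."""
        y = np.zeros(N_SPECIES)
        y[I_EGFR] = POOL_TOTALS["EGFR"]
        y[I_PI3K] = POOL_TOTALS["PI3K"]
        y[I_AKT] = POOL_TOTALS["AKT"]
        y[I_RASGDP] = POOL_TOTALS["Ras"]
        y[I_MEK] = POOL_TOTALS["MEK"]
        y[I_ERK] = POOL_TOTALS["ERK"]
        y[I_CDK46] = POOL_TOTALS["CDK46"]
        y[I_PARP] = POOL_TOTALS["PARP"]
        return y

    def to_description(self):
        """Plain-JSON description of species, compartments and parameters."""
        return {
            "name": self.name,
            "species": list(self.species_names),
            "compartments": dict(self.compartments),
            "parameters": [
                {"name": n, "value": self.params[n], "unit": u}
                for n, _, u in PARAM_TABLE
            ],
            "pool_totals": dict(POOL_TOTALS),
            "expression_params": list(EXPRESSION_PARAMS),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_description(), fh, indent=1)


def build_demo_model(**param_overrides):
    """Construct the demo model, optionally overriding printed-unit params.

    >>> m = build_demo_model(k_ras_basal=2e-4)   # tonic-signaling endpoint
    """
    model = DemoModel()
    for k, v in param_overrides.items():
        if k not in model.params:
            raise KeyError(f"unknown parameter {k!r}")
        model.params[k] = v
    return model
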