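# Methods

`lineagesim` turns a mechanistic single-cell proliferation/death model into
population-level viability predictions by simulating every cell in a lineage
forest: single-cell trajectories are integrated one generation at a time,
division and death events are detected on each trajectory, daughters inherit
the mother's exact state at division, and the loop continues until a
generation produces no divisions. This note records the model, the estimators,
the numerical choices, and what the bundled demo model does and does not
capture.

## The population algorithm

A run begins from the *average serum-starved cell*: the fixed point reached by
relaxing the model for 96 h with no ligands. **Heterogenization** draws, for
each of the `n0` starting cells, independent unit-mean lognormal scalings
(coefficient of variation `cv`, default 0.18) for the designated expression
parameters — the conserved totals of EGFR, PI3K, AKT, Ras, MEK, ERK and
CDK4/6, and the Cyclin D synthesis capacity — and relaxes each scaled cell for
48 h under starved conditions so protein levels settle to that cell's own
starved distribution. **Asynchronization** then stimulates every cell with
growth media (EGF 3.3 nM + insulin 1721 nM) for a 48 h "Generation 0" window
and samples one uniformly random grid time per cell; the state there becomes
the Generation-1 initial condition. Because the demo model's first stimulated
cycle completes in ≈48 h — the same length as the window — the sampled
cell-cycle phases are close to uniform.

Generation-1 cells are then simulated for the experiment time (default 72 h)
under the protocol stimuli (including any drug). For each trajectory:

* **Division** is marked on the CycB-CDK1 channel. Qualifying pulses are
  peaks above an absolute height (default 5 nM) with ≥4 h separation; the
  event is placed at the earlier of the detected trough and the first
  post-peak crossing below 10% of that pulse's height. The crossing rule puts
  the event at the end of mitosis even when the channel then rests on a flat
  interphase baseline, where a local-minimum search is ambiguous, and it also
  catches a terminal division not followed by another pulse. A
  `prefer="trough"` detector mode anchors at exact interior minima instead.
* **Death** is the first grid point at which *strictly more than half* of
  PARP has been cleaved. A cleaved fraction of exactly one half is not death.
* Ties on the same grid point resolve to death (conservative choice; the
  source protocol does not specify). The trajectory is truncated at the fate
  time; a divided mother's state there is copied bitwise to two daughters
  with remaining duration `exp_time − t_div` and indices `2i`, `2i+1` in the
  next generation. Daughters diverge only through their independent death
  hazards (an optional partition-noise hook exists and defaults off).

Randomness is confined to two places: the heterogenization scalings and one
caspase-activation draw per cell segment. Every cell's stream is keyed by
`(master seed, generation, index)`, so results are bitwise independent of the
parallel backend and worker count. The living count at `t` counts cells with
`birth ≤ t < fate` (censored cells through the experiment end inclusive) and
always equals `n0 + divisions(≤t) − deaths(≤t)`.

## The demo cell model

The bundled model is a 24-species mechanistic cascade — deliberately minimal,
not a reduction of any published large model — built so that every procedure
above is exercised:

* **Receptor layer.** EGF binds EGFR reversibly (association
  1e-4 nM⁻¹s⁻¹, dissociation 1e-3 s⁻¹; ~25% receptor occupancy at 3.3 nM).
  Ligands are boundary species (assay media ≫ cell volume).
* **Survival branch.** Insulin (half-saturation 300 nM) and active receptor
  drive PI3K activation; active PI3K phosphorylates AKT.
* **Proliferative branch.** Ras-GDP→Ras-GTP exchange proceeds at a tonic
  (ligand-independent) rate `k_ras_basal` (default 5e-4 s⁻¹) plus a
  ligand-induced term proportional to active-receptor fraction. Ras-GTP
  activates MEK; phospho-MEK activates ERK.
* **Cyclin D gate.** Cyclin D synthesis is proportional to ERK activity plus
  a smaller AKT term, with fast turnover (t½ ≈ 29 min, so the gate tracks
  signaling within the hour); Cyclin D binds CDK4/6 and the active complex
  opens the cell-cycle gate. The gate is the sum of a steep quartic Hill
  (half-point 47 nM) and a low-threshold saturating "floor" term (amplitude
  0.028, half-point 12 nM, eighth-order). Both terms read the same active
  complex, so CDK4/6 inhibition closes the gate entirely; the floor caps the
  slowest heterogenized cycles near ~100 h, without which the steep gate maps
  a sizable tail of cells onto cycles far longer than any assay window.
* **Cell-cycle oscillator.** CycE-CDK2 integrates the gate (synthesis 10 nM/h
  at a fully open gate, weak basal decay). When CycE crosses ~20 nM it flips
  a bistable CycA-CDK2 switch (autocatalytic positive feedback); CycA drives
  CycB-CDK1, which is itself autocatalytic (the classic mitotic trigger) and
  activates APC/C with an eighth-order switch. APC destruction of CycE, CycA
  and CycB is ultrasensitive in APC (engaging only once the pulse commits),
  which makes each mitosis all-or-none and resets the oscillator cleanly.
  Division is the post-pulse CycB trough. At the default calibration the
  deterministic cycle is 48.4 h with the first stimulated division at 47.7 h.
* **Restriction point.** A memory species ratchets up to the current gate
  value once CycE exceeds a commitment threshold (2.7 nM, crossed at ≈10.9%
  of the deterministic cycle) and is erased by the APC pulse at mitosis. The
  effective CycE synthesis drive is `max(gate, memory)`: a committed cell
  finishes its cycle at its own pace even if the drug closes the gate
  afterwards, while its daughters are born uncommitted and arrest.
* **Death branch.** The per-cell hazard is a small constant (5e-4 h⁻¹,
  ~3.5%/72 h) plus a term that engages when phospho-AKT falls below 4 nM —
  below the starved baseline, so only an active loss of survival signaling
  (e.g. PI3K inhibition) is lethal, at up to 0.02 h⁻¹. The activation time is
  drawn by inverting the cumulative hazard along the deterministic
  trajectory; the caspase→PARP block is strictly downstream of the signaling
  state and is therefore resolved analytically after the integration.
  Cleaved-PARP fraction above one half marks death.

Units: protocols are in hours; rate constants are stored per second (and
nM⁻¹s⁻¹) and converted to per-hour once when the parameter vector is built.
The drug transport constant is printed in its source as "0.01 nM⁻¹s⁻¹" for a
first-order process; it is treated as 0.01 s⁻¹.

### Calibration targets

The default constants were chosen against these population-level targets: a
~48 h control doubling time in full media; no cycling when starved (the CycB
amplitude over the last 24 h of a 96 h starved run is <1% of the stimulated
pulse); near-zero EGF-free division probability at the tonic-exchange
endpoint 2e-4 s⁻¹; heterogenized inter-division times covering at least
[16, 96] h at the default `cv` (measured span ≈ [14, 123] h, with ~3.6% of
cycles ≤16 h and ~2% ≥96 h); and restriction-point commitment at ~10% of the
cycle. The default `cv = 0.18` was chosen on distributional grounds: it sets
the log-spread of the gate to ≈0.87, wide enough to reach both tails of the
required inter-division range while keeping the mass of cells with cycles
beyond ~110 h under ~10%.

## Drug pharmacodynamics

A `DrugSpec` declares transport, mechanism and rate constants; `attach_drug`
extends any conforming model with an extracellular reservoir held at the
applied dose, symmetric first-order transport (0.01 s⁻¹) into the cytoplasm
(and into the nucleus for nuclear targets), one mass-action binding reaction
per free-target species, and drug-target complexes that take part in nothing
except dissociation (reversible specs) and first-order decay at the target's
own decay rate. Because every downstream rate law reads the *free* target,
sequestration is loss of function by construction; the extension is exactly
inert at dose 0. The four bundled drugs: alpelisib (PI3K, Kd 2.4 nM),
palbociclib (nuclear CDK4/6, Kd 1.9 nM), trametinib (free unphosphorylated
MEK, Kd 0.35 nM), all with kon 1e-3 nM⁻¹s⁻¹; neratinib (EGFR, irreversible,
kon 1e-4 nM⁻¹s⁻¹, no further receptor/ligand interactions for the complex).

The validation harness runs the average starved cell under growth media ±drug
(10 µM, deterministic) and checks: intracellular free drug reaches 90% of the
extracellular level within 10 min (first-order transport gives
ln(10)/0.01 s⁻¹ ≈ 230 s ≈ 3.8 min); target engagement reaches 90% of its
equilibrium within 10 min; and a downstream biomarker changes by ≥50%. The
thresholds quantify "rapidly" and "substantial", which the source protocol
leaves qualitative, and are configurable. Any observable channel is accepted
as the biomarker; phospho-AKT, phospho-ERK, receptor phosphorylation and
Cyclin D are the documented standards. For palbociclib the meaningful readout
is the active CycD-CDK4/6 complex — total Cyclin D is not reduced by CDK4/6
sequestration.

## GR dose-response scoring

GR(c) = 2^(log2(x_c/x0) / log2(x_ctrl/x0)) − 1, with x0 the count at t = 0,
x_c the 72 h count under dose c and x_ctrl the 72 h control count. The
landmarks are 1 (treated matches control), 0 (complete cytostasis) and −1
(complete killing); the score is invariant to rescaling all counts. The
control is aggregated as the *median* over dose-0 replicates (per-replicate
pairing is not defined by the protocol; mean vs median is an open choice and
median is robust to a single outlier replicate). Per dose, replicates are
summarized by the median and the standard error across replicates; extinct
replicates score at the −1 limit and are flagged. The default protocol is 10
dose levels × 10 replicates of 100 cells.

## Cycle-progress estimation

The composite cyclin signal is the pointwise mean of the peak-normalized
CycE-CDK2, CycA-CDK2 and CycB-CDK1 channels; trough-to-trough distance is one
cycle. The reference composite comes from a single deterministic, hazard-free
simulation long enough for ≥2 full cycles; its period is the median
trough-to-trough interval (robust to the initial transient and to a final
truncated cycle, which is also skipped when extracting the reference cycle).

`progress_at` estimates a cell's phase at a query time by matching its
composite — normalized by the *reference* channel peaks — against the
periodic reference. Two departures from a plain normalized cross-correlation
were necessary and are deliberate:

* **Reference-peak normalization.** A drug-arrested cell's own CycA/CycB
  peaks are near zero; dividing by them amplifies noise to order one and
  destroys the composite. Normalizing by the reference peaks keeps all cells
  on one scale.
* **Least-squares matching over phase × time-scale.** An arrested or
  all-interphase window is nearly flat: its *level*, not its shape, carries
  the phase, and correlation is blind to level. The estimator minimizes the
  mean squared error over phase offsets and a small grid of time-scale
  factors (0.5–2.8× the reference period, since heterogenized cycles span
  roughly that range), using a half-period window after the query time. The
  Pearson correlation at the chosen alignment is reported, with a
  low-quality flag below 0.5; an estimate is always returned.

On a uniformly phased deterministic population the estimates are uniform
(Kolmogorov–Smirnov distance ≈ 0.034 at n = 1000) and track the sampled phase
to a median error below 0.02.

`division_probability_vs_progress` smooths the progress distributions of the
divided and non-divided groups with Gaussian KDEs and reports, per 0.01-wide
bin, expected-dividing / expected-total. Two robustness choices, both
calibrated against a synthetic step-rule oracle (divide iff progress > 0.1),
where they recover the threshold with mean ≈0.09–0.10: the bandwidth follows
the robust Silverman rule 0.9·min(sd, IQR/1.34)·n^(−1/5) per group (plain
Scott over-smooths a small group whose mass piles at one point with a few
stragglers elsewhere — exactly the arrested-cell cluster at progress 0); and
kernels are reflected at the [0, 1] boundaries so edge mass keeps its full
density. A group with fewer than two members contributes exact histogram
counts instead of a KDE, so the saturating-inhibition analysis — whose
"divided in Generation 2" group is empty by design — remains well defined.
Bins with no expected mass are NaN, never 0.

The restriction-point protocol observes Generation-1 outcomes over a **96 h**
window rather than the 72 h dose-response default: a committed cell completes
its cycle at its own pace, and the slowest heterogenized cycles need more
than 72 h, so the shorter window censors their outcome and biases the
probability curve downward at mid progress.

## Initial-state PCA

The Generation-1 cell-by-species matrix is z-scored per column (constant
columns dropped and recorded — e.g. species that are identically zero at
sampling) and decomposed with PCA; scores, loadings and explained-variance
fractions are exposed, and component signs are fixed by making each
component's largest-magnitude loading positive. Projection of a new (e.g.
drug-treated) population always uses the control means, standard deviations
and components — never a re-fit. In the demo model the component that
correlates with progeny division count loads on the ERK branch (phospho-ERK,
phospho-MEK, Ras-GTP) together with the Cyclin D/CDK4/6 species directly
downstream, which is the planted ground truth: cycle speed is driven through
ERK-dependent Cyclin D synthesis.

## Numerical choices

* Integration: LSODA (via `scipy.integrate.odeint`) behind a fixed output
  grid, default dt = 0.05 h; rtol 1e-6, atol 1e-9. Concentrations are clipped
  at zero after integration; any excursion below −1e-6 nM is an error that
  names the cell. The right-hand side is compiled with numba when available,
  with a pure-Python fallback.
* The `cv = 0` path simulates heterogenization and Generation 0 once and
  shares the result (the cells are identical by construction).
* Heterogenization and Generation-0 runs are hazard-free; death applies from
  Generation 1 onward, matching the protocol in which fates are scored only
  during the experiment.
* A division landing on the final grid point leaves no time for daughters
  and is recorded as censoring.
* Daughter durations stay on the dt grid because divisions are detected at
  grid points; living counts use a 1e-6 h tolerance against accumulated
  round-off.

## Problem sizes

The test suite and the reproduction script use the protocol sizes the
package documents: 100-cell populations with 10 replicates for the doubling
time, 100 Generation-1 cells for the restriction-point analysis (five
replicates in the reproduction script, reported as the median), 1000 cells
for the phase-uniformity check, and 100–120-cell runs for the PCA analyses.
Example scripts use smaller populations (20–60 cells) purely for
responsiveness and say so.

## What the demo model does and does not show

Passing tests on the demo model demonstrate that the *framework* — lineage
bookkeeping, event detection, GR scoring, progress estimation, PCA analytics —
behaves correctly on a mechanistic model with realistic structure: a
signaling cascade with tonic and ligand-driven routes, a gated relaxation
oscillator with a restriction point, drug modules with published binding
constants, and expression heterogeneity that spreads cycle lengths several
fold. They do not validate any specific biological claim about real cells:
the demo model is not a published cell-line model, its kinetic constants
(other than the drug constants and media doses) are implementer-chosen, its
gene-expression noise is a static lognormal surrogate for a dynamic
stochastic-expression process, daughters inherit exact state copies (no
partition noise by default), and there is no cell volume, spatial structure
or resource competition. Sister cells that never draw a death event remain
identical forever — real lineages decorrelate faster. Dose-response curves
computed here characterize the demo model, not experimental viability data.

## Known limitations

* The progress estimator's accuracy degrades for cells whose cycle length
  lies far outside the time-scale grid, and near the 0/1 phase boundary,
  where estimation noise can wrap an almost-mitotic cell to phase ~0.
* The division detector assumes pulse-like CycB dynamics; a model with
  sustained high CycB plateaus would need a different marker or detector
  settings.
* `equilibrium_occupancy` assumes drug excess (no target depletion); the
  simulated equilibrium matches it to 1% only when the target pool is small
  against the dose.
* Archives store trajectories only when the run kept them; reading an
  archive reconstructs records and counts exactly, but trajectories only if
  present.
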