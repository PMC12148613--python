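# Methods

## The model

`endosig` implements a coarse-grained ordinary-differential-equation model
of the endothelial signaling network formed by the VEGF and
angiopoietin-Tie pathways, their crosstalk, and the shared downstream
kinase network. The state space is 77 species across seven compartments
(extracellular, cell surface, junctional, cytosol, ER, internalized
vesicles, Weibel-Palade bodies), coupled by 116 reaction rules compiled
into 138 irreversible reaction columns.

Mechanisms, by module:

**VEGF axis.** VEGF-A (treated as the 45 kDa dimer) binds VEGFR2; the
liganded receptor recruits a second VEGFR2 into a dimer that activates by
autophosphorylation. VEGFR1 acts as a decoy for VEGF and sequesters VEGFR2
in heterodimers; NRP1 binds VEGF, VEGFR1 and active VEGFR2; TSP1-bound
CD47 associates with VEGFR2 and blocks its dimerization. Receptors
internalize, recycle, are synthesized at a constant rate and degraded from
both the surface and the internalized pool; NRP1-associated internalized
active receptor has its own degradation constant
(`kdegvegfr2dpe2_nrp`).

**Tie axis.** Ang1 is a single tetrameric ligand; Ang2 enters as a
dimer/trimer/tetramer mixture (0.4/0.3/0.3 of monomer mass by default).
Tetrameric ligand seeds a Tie2 cluster that grows one receptor at a time
to the lumped size of four; only complete clusters phosphorylate. The
Ang2 tetramer clusters with a much smaller rate constant (weak agonist);
Ang2 dimers and trimers occupy Tie2 without clustering (competitive
antagonism). Tie1-Tie2 heterodimers block ligand access at the surface;
at the junction the heterodimer level slows VE-PTP dephosphorylation
through an inhibitory saturation gate (stabilization). Phospho-clusters
translocate first-order to the junctional compartment where VE-PTP
dephosphorylates and disassembles them. Every non-phosphorylated surface
Tie2 state sheds its ectodomain at the constitutive rate; soluble Tie2
traps Ang1 and the Ang2 tetramer.

**Crosstalk.** Active VEGFR2 multiplies the Tie2 shedding rate through a
saturating enhancement (calibrated to a 2-fold ceiling), drives S1P
production, and S1P releases the finite WPB-stored Ang2 pool into the
extracellular multimer mixture. Junctional pTie2 activates PI3K
independently of Src and loads RhoA with GTP; RhoA-GTP binds mDia and the
complex sequesters free Src. pSrc phosphorylates VE-cadherin, the
permeability proxy.

**Downstream.** Active VEGFR2 activates Src and, in parallel, Axl. Src,
Axl and junctional pTie2 converge on PI3K; active PI3K converts PIP2 to
PIP3, which drives Akt. Active PLCγ (produced on the active receptor)
hydrolyses the *same* PIP2 pool into DAG + IP3, so PLCγ abundance and
turnover compete with PI3K for lipid substrate and feed back on Akt
output. IP3 gates ER calcium release against a SERCA-style reuptake and a
passive leak; DAG feeds Raf with a joint S1P-and-calcium requirement,
followed by a linear Raf/MEK/Erk cascade; ppAkt plus calcium activate
eNOS.

### Rate laws

Three documented forms (v is the reaction rate, all species clamped at
zero inside the evaluation so the derivative is defined for slightly
negative integrator states):

* mass action: `v = k · Π[reactants]` (at most two reactants; reversible
  rules compile to two columns);
* Michaelis–Menten: `v = kcat · [E] · [S]/(Km + [S])`; without a modifier
  the form degenerates to `Vmax·[S]/(Km+[S])` (SERCA);
* saturating activation: `v = k · [S] · [M]/(K + [M])`, first-order in
  the optional substrate and saturating in the modifier (used for the
  VEGF-enhanced shedding, S1P production, WPB release, IP3-gated calcium
  release and the Tie2→PI3K input).

Rules may carry multiplicative gates `[G]/(Kg+[G])` (activating) or
`Kg/(Kg+[G])` (inhibitory), used for the Ca/S1P requirements of Raf and
eNOS and the Tie1 stabilization of junctional pTie2. One lumped rule (the
Ang2-tetramer cluster completion) consumes three Tie2 in a single bilinear
step; it is stoichiometrically balanced and documented as a lumping.

Pharmacological inhibitors are instantaneous activity scalings: a
fraction f applied to a target node multiplies the node's activation rule
and, for VEGFR2, every catalytic activity of the active receptor
(Src/Axl/PLCγ activation, S1P production, shedding enhancement) by
(1 − f) from the application time onward. Without the catalytic-activity
part a receptor kinase inhibitor would have almost no effect, because
autophosphorylation is not rate-controlling in the calibrated model.

### Units

Time is minutes. All concentrations are bath-effective nM: surface
receptor pools correspond to roughly 10⁴ copies per cell at an assumed
2×10⁵ cells/mL (`molecules_per_cell_to_nM` does the conversion), so
ligand depletion by binding and receptor-mediated consumption is captured
in a single consistent unit system, and surface-surface rate constants
absorb the conversion (hence their large per-nM-per-min values). Ligand
doses are ng/mL, converted with VEGF-A dimer 45 kDa, Ang1 tetramer
280 kDa, Ang2 monomer 66 kDa. Ang2 doses split into the multimer mixture
by monomer mass.

## Baseline parameters

The packaged baseline (`endosig.params.BASELINE_VALUES`) is the package's
calibrated set. Initial estimates follow typical endothelial receptor and
kinase abundances and kinetics; the crosstalk and downstream constants
were then tuned — manual tuning first, pattern-search refinement against
the packaged fixture suite second — so the model reproduces the headline
behaviours of this model family:

* VEGF-induced pSrc peaks ~5 min post-stimulus and decays;
* Ang1-induced Src sequestration reaches ~90 % and plateaus ~20 min
  post-stimulus (so chronic Ang1 protects, acute Ang1 does not);
* 25 min of Ang1 at 50 ng/mL reduces peak pSrc and pVE-cadherin after
  VEGF by ~80 %;
* VEGF enhances Tie2 shedding up to 2-fold with saturation near 7 ng/mL
  and suppresses Ang1-induced pTie2 by ~90 % at high dose;
* the WPB Ang2 pool releases with a saturation dose near 7 ng/mL VEGF.

The suppression of Ang1-induced Tie2 activation by VEGF emerges from two
mechanisms: the doubled shedding rate halves the surface Tie2 pool at
steady state, and the cluster-of-four activation makes pTie2 roughly
cubic in free Tie2, so a 2-fold receptor loss produces close to a 90 %
activation loss, reinforced by released Ang2 occupying Tie2
non-productively.

Parameter bounds default to a factor of 100 around the baseline; the
calibration module narrows them per fit.

## Simulation

Stiff integration uses LSODA with an analytic Jacobian assembled from the
closed-form derivatives of the rate laws (numba-compiled kernels with a
pure-Python fallback). Defaults: rtol 1e-8, atol 1e-10, output grid
0–120 min at 0.5-min resolution, peak refinement by local re-integration
at 0.1-min resolution. Ligand additions are instantaneous concentration
jumps; the bath is an infinite reservoir except for binding and
receptor-mediated consumption, which are modeled. Pre-equilibration
integrates the ligand-free system until max |dx/dt|/(|x|+1e-9) < 1e-8
(default), erroring after 5000 simulated minutes.

## Calibration

Experimental observations in this model family are relative signals, so
datasets declare a normalization (percent-of-max, fold-of-baseline or
absolute) and the objective is a weighted sum of squared errors between
identically normalized model predictions and data, with weights
defaulting to 1/(points per dataset) so each dataset counts equally.
The optimizer is a generalized pattern search in log10 parameter space:
2n coordinate polls in lexicographic key order, first improvement
accepted, mesh ×2 on success and ×0.5 on failure, stopping at mesh
< 1e-6 (log10 units) or 5000 evaluations. It is deterministic given the
initial point. An optional Hooke–Jeeves-style search step (a full
exploratory sweep followed by pattern moves along the net displacement,
doubled while they keep paying off) can be enabled per fit; the poll step
is untouched, so the method remains a generalized pattern search, and the
acceleration matters in the curved sum-of-squares valleys typical of
kinetic models. The recovery experiments enable it. Integration failures at a candidate contribute a large
finite penalty (1e9) and are logged. The ligand-free steady state is
recomputed once per candidate (warm-started from the baseline rest state)
and shared by all datasets of that evaluation.

Two recovery experiments are packaged. The noise-free, reduced-subsystem
experiment fits eight Tie-axis constants
(`endosig.synthetic.RECOVERY_KEYS`) on the Tie-only submodel, which
reproduces the full model's Tie fixtures exactly (no VEGF is present in
those protocols); the subset was chosen by a local sensitivity (Jacobian
eigenvalue) analysis so that the 1e-6 objective contour confines every
constant to within a few percent of truth — in particular it pairs each
binding constant with at most one member of a quasi-equilibrated
kon/koff pair. The noisy (CV 5 %) experiment fits eight shape- and
scale-constants (`NOISY_RECOVERY_KEYS`) on the full model against eight
dedicated fixtures; percent-of-max normalization deliberately discards
amplitude information, so that subset consists of decay/translocation
timescales, dose-response positions and the two absolutely-normalized
shedding/release constants.

## Synthetic data

The fixture suite emulates the sparse normalized panels this model family
is calibrated against: ten VEGF (50 ng/mL) phospho time-courses, Ang1 and
Ang2 dose-responses of pTie2, four Ang1 (50 ng/mL) time-courses, a
VEGF→S1P dose-response, an Ang2-release time-course and two soluble-Tie2
accumulation curves — 20 datasets, 5–12 points each. Noise is
multiplicative lognormal at CV 5 % by default (typical densitometry
variability), applied after normalization and re-anchored so
percent-of-max datasets have a maximum of exactly 100. Truth parameters
are the packaged baseline, so fixtures double as regression baselines.
What passing recovery tests show is that the designated constants are
identifiable from data of this sparsity and noise level *when the model
is correct*; they say nothing about structural misspecification against
real blots, digitization error, or batch effects, none of which the
generator emulates.

## Global sensitivity analysis

First-order (main-effect) Sobol indices use the Saltelli (A, B, AB_i)
design, N(d+2) model runs, with the estimator
S_i = mean(f(B)·(f(AB_i) − f(A)))/V(Y); second-order synergy indices use
the full (A, B, AB_i, BA_i) design, N(2d+2) runs, via the closed
pair-variance estimator. Percentile bootstrap over sample rows (B = 1000
by default, 95 % level) gives confidence intervals; intervals are
anchored to contain the point estimate. Parameters vary uniformly over
0.2-fold to 5-fold of baseline. The default varied set is every rate
constant and initial abundance (123 parameters); the capital-K saturation
constants of the lumped rate laws are structural coarse-graining
constants and stay fixed. Outputs are pVEGFR2, pTie2, pSrc and ppAkt at
5 min after a simultaneous stimulus of 10 ng/mL VEGF + 200 ng/mL Ang1 +
500 ng/mL Ang2 applied to a pre-equilibrated cell; the per-sample
pre-equilibration uses a fixed 600-min ligand-free settle at relaxed
tolerance (rtol 1e-6), which is robust across the sampled range. Failed
integrations yield NaN rows that the estimators drop.

Samplers: Latin hypercube (default, seeded) or a scrambled Sobol sequence
with configurable skip (default 10³) and leap (default 10²). Taking every
k-th point of a Sobol net with even k zeroes low-order generator bits and
collapses the first coordinate, so the implementation uses the next odd
stride for even leap values; with that correction the leaped sequence
retains lower star discrepancy than iid uniform sampling.

Raw index estimates may be slightly negative (estimator noise); reporting
preserves raw values. With ~10 influential multiplicative factors spanning
25-fold ranges, a large share of output variance is interaction variance,
so individual main effects are modest and their ranking carries
appreciable estimator noise at desk-scale N — the bootstrap intervals in
the results should be taken seriously.

## In-silico experiments

* Crosstalk sweep: VEGF 0–20 ng/mL, 41 points, from one shared
  pre-equilibrated baseline. Cumulative Ang2 release is read at 60 min;
  the Tie2-shedding fold (the instantaneous per-receptor shedding rate
  over the constitutive rate) and pTie2 are read at 180 min, long enough
  for receptor pools to re-equilibrate. pTie2 suppression uses 200 ng/mL
  Ang1 co-stimulation. Plateaus are the top-dose values; saturation doses
  are the smallest dose reaching 95 % of plateau.
* Protection: Ang1 at t = 0, VEGF at t = 25 min (chronic) or t = 0
  (simultaneous); peak pSrc/pVE-cadherin on the post-VEGF window versus a
  VEGF-only run from the same rest state. Src sequestration is
  1 − (free Src + pSrc)/total Src.
* Combination grids: simultaneous Ang1 + 50 ng/mL background VEGF
  (package default, configurable — the background dose is not printed in
  the source material for these grids), inhibitor applied at t = 0, four
  readouts at 15 min, levels {0 … 1} × Ang1 {0, 50, 200, 500} ng/mL.

## Numerical and design choices

* State ordering is the declaration order of the species table; reversible
  rules occupy adjacent forward/reverse reaction columns.
* Conservation accounting: monomer pools are computed from species
  compositions; flux through rules flagged non-conserving is integrated
  (trapezoid on the output grid) and credited before measuring drift.
* Dose-response saturation dose is measured from the zero-dose anchor
  (95 % of the plateau-minus-anchor span).
* Messenger species (S1P, IP3, Ca) carry empty or standalone compositions;
  their synthesis/decay rules are exempt from monomer balance.
* Akt activation is modeled as a single active state (`ppAkt`); whether
  this denotes dual-site phosphorylation is left open in the source
  material, and the package treats it as one species.
* Axl is wired downstream of active VEGFR2, feeding PI3K in parallel with
  Src. This placement is consistent with Axl inhibition failing to block
  Src activation; it is a package choice where the literature wiring is
  not settled.
* The pattern-search poll order and tie-breaks are fixed (lexicographic)
  so calibration runs are bit-reproducible.
* Problem sizes for the packaged analyses were chosen at desk scale:
  sensitivity runs at n_base 256 over the full 123-parameter set
  (256 x 125 = 32,000 model runs first-order); the noise-free recovery
  fits 8 Tie-axis parameters (about 5,000 objective evaluations) and the
  noisy recovery 8 full-model parameters (under 1,000 evaluations).

## Known limitations

* Cluster size is capped at four Tie2 per cluster; higher-oligomer
  combinatorics are out of scope.
* pTie2 versus Ang1 dose shows a mild hook above ~200 ng/mL (a few
  percent): at supersaturating ligand, seed complexes outcompete cluster
  completion for free Tie2 — the classic multivalent prozone. The
  dose-response is monotone over the 0-200 ng/mL agonist range.
* Inhibitors are activity scalings, not binding species; no
  pharmacokinetics.
* The junctional compartment has no geometry; translocation is a
  first-order rate.
* The extracellular bath is well mixed and infinite except for binding
  depletion; no autocrine gradients.
* The model is calibrated to its own synthetic fixture suite (the original
  digitized datasets are not redistributable), so agreement with the
  packaged targets demonstrates internal reproducibility of the model
  family's behaviour, not fidelity to any particular experiment.
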