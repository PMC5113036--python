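# Methods

## The model

Two adjacent endothelial cells compete for the migratory "tip" role
through VEGF-notch-DLL4 lateral inhibition.  Each cell carries eight
species: free VEGFR2 (`R2`), the active VEGF-receptor complex (`VR2`),
internal DLL4 (`DLL`), free notch, the DLL-bound notch complex
(`DLLnotch`), the cleaved NICD fragment (`nicd`), a lumped
Hes/Hey/Her repressor (`HE`), and filopodia (`filo`).  Mass-action and
Hill kinetics (cooperativity `n`, half-saturation at 1 c.u.) drive

* activation: VEGF binds R2; VR2 induces DLL expression
  (`theta*VR2^n/(1+VR2^n)`) and filopodia (`k5*VR2^n`), and filopodia in
  turn amplify perceived VEGF, `V_eff = V*(1 + k6*filo^n)` — a positive
  feedback that makes activation switch-like;
* inhibition: the *neighbour's* DLL plus any external DLL presented to
  this cell (`Dext_i`) binds this cell's notch; the cleaved NICD drives
  HE (`theta*nicd^n/(1+nicd^n)`), and HE removes free R2
  (`k3*R2*HE^n`), closing the mutually inhibitory loop.

All species share the turnover rate `phi` (filopodia: `phi_f`), except
NICD, which is turned over at `gamma*sirt1`.  R2, notch and filopodia
have constitutive production `gamma`; DLL and HE have basal expression
`beta`.  Concentrations are in dimensionless concentration units
(c.u.), time in seconds; the nominal parameter values are the
`ModelParams` defaults.  The default initial condition is the quiescent
cell: `R2 = notch = 1`, everything else 0.

Two scalar modulators act on the notch arm and are neutral at 1:
**Sirt1** multiplies the NICD turnover rate (deacetylation destabilises
NICD; high Sirt1 weakens inhibition) and **Lfng** multiplies the
DLL-notch association rate `k2` (glycosylation stabilises binding; high
Lfng strengthens inhibition).  Lfng scales association only, not
dissociation — a net affinity change.

### Bookkeeping choices in the coupling

Each cell's DLL balance carries `-v5 + v6` of the cell's *own* binding
reaction, whose ligand is dominated by the neighbour's DLL.  This "net
pool" bookkeeping means a cell facing a much stronger neighbour can
have its DLL pool overdrawn slightly below zero (bounded, at most a few
c.u.); the ligand actually presented to notch is clamped at zero, and
every other species stays non-negative.  The overdraw is what produces
the deeply inhibited inactive state (DLL well below the basal
`beta/phi = 1` c.u., hence below the 0.5 c.u. inactive threshold).  A
strictly mass-conserving alternative (debiting the neighbour's pool,
`DllDebit.NEIGHBOUR`) is provided for comparison: its inhibition debit
is bounded by the losing cell's own low DLL, which caps inhibition so
severely that the model loses bistability altogether.  A literal
variant of the external-DLL pool updates (`DextMode.PRINTED`) is also
kept for comparison; the default treats `Dext_i` as an unconsumed bath
presented to cell *i*'s notch.

The NICD turnover constant is `gamma` (0.005/s), not the global `phi`
(0.001/s).  This places the basal NICD level (from basal DLL-notch
engagement) at ~1 c.u. — exactly the Hill half-saturation — so lateral
inhibition retains dynamic range and the Sirt1 modulator is maximally
effective in both directions.  With `phi` instead, the `k4/phi`
amplification saturates the HE response everywhere, no parameter region
is bistable, and none of the phenomena this package analyses exist.

### What the quiescent state looks like

At zero VEGF the system is *not* decoupled: basal DLL (~1 c.u.) and
notch (~5 c.u.) sustain a basal NICD of ~1 c.u. and an HE tone of ~50
c.u., which quenches free R2 to ~4e-4 c.u.  The "quiescent" cell is
thus actively held down by basal notch signalling — which is also what
makes the intermediate (pI) states stable.

## Dynamical regimes and the default analysis conditions

The activation feedback makes the model's behaviour regime-dependent:

* **Autonomous activation** from the quiescent start requires VEGF
  above ~3.6 c.u.; below that a cell activates only if its neighbour is
  silenced for it (by VEGF contrast or external DLL).
* **Bistability**: for symmetric VEGF roughly between 1 and 5 c.u. the
  patterned states A:I and I:A coexist (with the unpatterned state),
  giving the hysteretic switches analysed throughout.
* **Invulnerability at high VEGF**: once VR2 is high, filopodia
  amplification outcompetes HE-mediated receptor removal, so an active
  cell at V >~ 1.5 c.u. cannot be switched off by any external DLL.
  The neighbour-overtaking analyses therefore run at low VEGF.

These regimes fix the package defaults, all chosen once and
configurable:

* **VEGF sweep grid**: 21 x 21 levels on [0, 10] c.u., horizon 20000 s.
  Patterning time is the earliest instant from which one cell's DLL
  stays above 13 c.u. while the other's stays below 0.5 c.u.
  (persistent crossing, refined on the dense solution to <= 1 s).
* **Modulator scan environments**: the scans need an environment where
  the unmodulated model patterns differentially and either modulator
  extreme breaks the pattern; such inputs are not derivable from first
  principles, so they are calibrated package choices and the thresholds
  the scans yield should be read together with them.  For Sirt1
  (`SIRT1_SCAN_BASE`): V = (3.52, 1.76) c.u. — a ~2:1 VEGF gradient
  straddling the activation threshold — plus a unit external-DLL bolus
  on cell2; it yields the differential window ~0.15 to ~8.5 c.u.  For
  Lfng (`LFNG_SCAN_BASE`): V = (3.6, 3.0) c.u., a shallower gradient
  bracketing the threshold, so halving Lfng releases both cells (A:A)
  and doubling it silences both.
* **Overtaking path** (`DextPath`): Dext1 = s*Dmax, Dext2 = (1-s)*Dmax,
  Dmax = 12 c.u., V = 1 c.u.  At smaller Dmax the second fold pair
  moves past the end of the path and the multistep A:I -> pI:pI -> I:A
  switch cannot complete; at V above ~1.5 the active cell is
  invulnerable (see above).  Position-switch schedules use the same
  geometry: abrupt = one step at half the window, gradual = linear ramp
  across it; the simulation horizon defaults to twice the window so the
  post-switch state can settle.
* **Sirt1 continuation** (`ModulatorPath`): Sirt1 on [0.1, 10] c.u. at
  fixed Dext = (1, 2) c.u., optionally at several Lfng levels.
* **Bistability screen**: symmetric-VEGF lattice of 21 values on
  [0, 10] c.u.; a set is bistable if some lattice value admits two
  distinct verified stable equilibria.  Candidates come from two
  integrations (quiescent start; cell1-ignited start), are polished by
  Newton iteration with the analytic Jacobian and verified to residual
  < 1e-9; an asymmetric stable state at symmetric inputs implies its
  mirror by exchange symmetry.
* **Robustness screen**: 200 Latin-hypercube parameter sets per
  perturbation fraction (10-50%), one design per fraction, sub-seeded
  deterministically; numerically failing sets are reported as
  indeterminate and excluded from the denominator.

## Numerics

Integration uses LSODA with the analytic 16 x 16 Jacobian
(rtol 1e-8, atol 1e-10); abrupt input switches are integrated
segment-wise.  Power-law bases are clamped at zero so that non-integer
Hill coefficients (which the robustness screen samples) remain defined
at the solver's marginal negative probes.  Halving the tolerances moves
reported patterning times by well under 1%.

Equilibria are found by multi-start root finding (Powell hybrid with
analytic Jacobian) from deterministic integration endpoints plus
random states, merged within a relative tolerance of 1e-4 and verified
to residual < 1e-9; stability is the sign of the leading Jacobian
eigenvalue.  Continuation is natural-parameter root tracking with
adaptive step halving; a fold is declared where tracking fails or jumps
at the minimum step (default 1e-3 of the span, giving a leading
eigenvalue within ~1e-4 of zero at the bracket) and the branch restarts
beyond it from a long-time integration.  Unstable segments between
folds are not traced; the analyses assert fold locations, stable
segments and hysteresis, none of which require them.

Cluster analysis standardises each species by asinh transform followed
by z-scoring: concentrations span several decades and the DLL pool can
be marginally negative, so a plain z-score would let the largest
species dominate while a log would be undefined.  Distance is
Euclidean, linkage is average (UPGMA), and the k = 4 cut is mapped to
classes by cluster means: the two high-DLL clusters are the active
side, pA being the one with more HE; the two low-DLL clusters are the
inactive side, pI being the one with more VR2.

## What the scenario generator does and does not emulate

Scenarios are idealised umwelts: constant or piecewise-linear VEGF and
external-DLL exposures, exact exchange symmetry between the cells, and
no stochasticity.  Real sprouts add molecular noise (which breaks
VEGF-symmetric ties that remain unresolved here), spatially graded and
fluctuating ligand fields, more than two interacting cells, and other
notch ligands (Jagged) and receptors (VEGFR1) that this model
deliberately omits.  Passing tests therefore show that the *mechanism*
— multistep bistable switching, partial states, modulator control of
their lifetime — is a robust property of the signalling topology, not
that the specific thresholds or times transfer quantitatively to
tissue.

## Known limitations

* The DLL pool overdraw (above) means the spec-level invariant "all
  concentrations stay non-negative" holds for 14 of the 16 state
  variables; the two DLL pools are instead bounded below by a small
  negative excursion.
* With exactly equal inputs the deterministic model never breaks
  symmetry; diagonal grid cells report "unresolved" rather than the
  noise-assisted slow patterning a stochastic system would show.
* Fold coordinates along the overtaking path depend on the unprinted
  path geometry (Dmax, V); the package asserts their existence, count,
  ordering and hysteresis, not their numeric positions.
* `modulator_scan` thresholds assume the outcome sequence is monotone
  along the scanned level (non-patterning -> differential -> A:A for
  Sirt1), which holds in the default environment but is not checked
  globally.
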