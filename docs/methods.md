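# Methods

## Model

The package simulates a genetic toggle switch — two genes whose protein
products homodimerize and each dimer fully represses the opposing gene's
promoter — inserted at two loci of the *E. coli* chromosome: one copy of
`G_ori` adjacent to the replication origin (L = 0) and, by default, two
identical copies of `G_ter` adjacent to the terminus (L = 1).  Replication
takes C ≈ 40 min and finishes D ≈ 20 min before division, so for doubling
times T < C + D rounds overlap and the cycle-averaged copy-number ratio of
the two loci is 2^(C/T): 2 at T = 40 min (where the default design is
exactly balanced), 4 at T = 20 min.  Growth rate therefore tilts the
toggle: short cycles favour the *ori*-proximal gene, long cycles the
*ter*-proximal one.

### Gene dosage (`cell_cycle`)

A locus at distance L (ori–ter = 1) is passed by a replication fork
x = C·(1−L) + D minutes before the division its round belongs to.  Within a
cycle of length T the locus carries `n·2^⌊x/T⌋` copies from birth and
doubles at age T − (x mod T); when x is an exact multiple of T the doubling
coincides with division and the count is constant.  This closed form is not
printed anywhere as such; it is validated in the test suite against an
independent fork-counting construction and against the known cycle
averages S_ori(T) (8 at T = 20, 120/T at T = 40) and S_ter(T) = 1 + 20/T,
which it reproduces exactly on a 1-minute grid of doubling times.
Cycle averages for intermediate loci use exact piecewise integration.

The balanced-design calculator inverts the dosage law: a gene inserted at
copy-number ratio R ∈ (0,1] relative to the ori gene is dosage-balanced at
L2 = −(T/C)·log2 R.  Among the eight candidate ratios
{1/4, 1/3, 2/5, 1/2, 3/5, 2/3, 3/4, 4/5} the design with the largest
admissible L2 ≤ 1 is selected (largest locus separation = highest
sensitivity), ties broken toward the smaller ratio.

### Rates (`model_params`)

All rates are per second; T, C, D are entered in minutes and converted
internally.  Defaults: k_g = 2e-3 (activation), r_g = {5, 20, 35}e-4 / V
(repressor–promoter binding; the three published settings are referred to
by their numerators), k_m = 5e-3 / S(T) (transcription per active copy,
inversely proportional to the DNA content per cell S(T)),
k_p = 2·V0(T)·(40/T)·1e-2 (translation, keeping protein concentration
growth-rate independent), k_d = 1e-3 / V (dimerization), r_d = 0.1
(dissociation), r_m = 3e-3 (mRNA decay), no protein degradation (dilution
only).  The scaled birth volume is V0(T) = (1/6)(40/T)² + 1/3 and
V(t) = V0·2^(t/T).  The sources for this parametrization state the birth
volume in two normalizations differing by a factor 2; we use the
(1/6)(40/T)² + 1/3 convention consistently in the volume law, the
bimolecular rates and k_p.  The published repression labels map to the
r_g numerators verbatim, and perturbations (`RateConstants.perturbed`)
multiply any raw numerator so that two-fold scans treat all parameters
uniformly.

### Deterministic approximation (`deterministic`)

Eight ODEs for gene activities G ∈ [0,1], mRNAs, monomers and dimers, with
cycle-averaged copy numbers (exact S_ori, S_ter — not the smooth
approximation, which would give 0.63 rather than the correct 0.643 for the
uncoupled ratio at T = 120 min), implicit division as dilution at ln2/T,
and a constant volume equal to the pre-division value 2·V0(T) in the
bimolecular rates.  The dimerization flux is ½·k_d·P².  Steady states are
found by BDF integration (rtol 1e-8, atol 1e-10, analytic Jacobian) in
chunks of 30 dilution times until every component satisfies
|dy/dt| ≤ 1e-9·max(|y|, 1); non-convergence within 3e7 s of model time is
flagged, never silent.

Bistability is detected by quasi-static continuation: sweep T across
[20, 120] min (default step 0.5 min; the classification is robust down to
2-min steps) upward from the ori-dominant extreme and downward from the
ter-dominant extreme, re-using each steady state as the next initial
condition.  A fold shows up as a jump of |Δlog2 R| > 1 between adjacent
grid points (the two branches differ by orders of magnitude, so the
threshold is uncritical); the bistable range is the ratio of the two fold
doubling-times.  With the default design this classifies r_g = 5e-4 as
monostable and 20e-4 / 35e-4 as bistable with range ratios ≈ 1.4 / 2.1.
The sweep step and protocol are a package choice; no reference protocol is
published.

### Stochastic model (`stochastic`, `_ssa`)

Exact Gillespie simulation of one daughter lineage over 14 channels
(activation, repression, transcription, mRNA decay, translation,
dimerization with the combinatorial propensity k_d·p(p−1), dissociation —
for each gene).  Scheduled events interrupt the SSA clock, which is
resampled afterwards because propensities change discontinuously:

* **Replication** of a locus at its fixed cell age doubles its copy count;
  any promoter-bound repressor dimer is stripped by the fork and returned
  to the free pool, and both arising copies are active.
* **Division** at age T splits every free molecule species binomially
  (p = ½) and keeps one copy of each replicated pair, chosen uniformly at
  random, with its activity state; a discarded repressed copy removes its
  bound dimer from the lineage.  A locus whose replication coincides with
  division is replicated (releasing repressors) and keeps a constant
  count.

The volume is re-evaluated after every step rather than integrated into
the waiting-time distribution; the volume changes on the cell-cycle
timescale, orders of magnitude slower than the fastest reaction, so the
error is negligible.  Free dimers and promoter-bound dimers are accounted
separately (bound dimers live implicitly in the repressed-copy count);
every simulation returns event counters from which the dimer ledgers can
be audited exactly, and the test suite does so.

The stochastic dimerization propensity k_d·p(p−1) and the deterministic
term ½·k_d·P² differ by a factor ≈ 2 — both forms are kept as printed in
the model definition; the discrepancy shifts the monomer/dimer split but
cancels in the total protein content P + 2D that all reported ratios use.

A reduced mode (frozen volume, no replication or division, translation
off) makes each gene's protein pool conserved and the state space finite;
the simulator's stationary distribution in this mode is compared against a
direct numerical solution of the chemical master equation (dense
null-space of the generator over ~900 states) and agrees within total
variation < 0.01.

### Estimators (`analysis`)

**R_protein** is the ratio of population means of total protein content
(P + 2D) of the two genes.  Two window estimators are provided: the
time-and-ensemble average over the post-burn-in window, and the
newborn-cell average (sampled just after each division).  They differ
because protein accumulates within the cycle: along a lineage, production
early in the cycle is weighted more strongly in the time average, so genes
replicating at different cell ages acquire a small (~2% at T = 120 min)
phase bias relative to the implicit-division ODE.  The newborn average has
no phase — the expected newborn content equals the protein produced over
one cycle, proportional to the cycle-averaged dosage — and is therefore
the estimator compared against the deterministic steady state; the plain
time average is the default reported R_protein.

**Switch detection** is conjunctive: the transition is the first instant
at which BOTH the monomer count and the free-dimer count of the initially
repressed gene strictly exceed those of the initially dominant gene.  The
summed reading (total contents crossing) is also implemented; on this
model the two give statistically indistinguishable first-passage times,
so the stricter conjunctive rule is the default.

**MFPT.**  First-passage durations from a prepared dominant state are
collected until at least `min_transitions` (default 100) uncensored
transitions exist.  Initial states are the deterministic dominant-branch
levels rounded to counts, with every copy of the suppressed gene repressed
— a reproducible preparation whose transient contributes only to the
shortest durations.  Because switching is a barrier escape, durations are
exponential except at short times (recrossings near the unstable saddle);
1/λ is estimated as the mean excess over a truncation threshold — the
bin-free maximum-likelihood fit of a·e^(−λx) to the tail — on a grid of
thresholds from 0 to the sample mean, and reported at the first threshold
where successive estimates change by < 5%.

**Response time** fits y(t) = y∞ + (y0 − y∞)·e^(−t/τ) to the
ensemble-mean log2 R_protein after a doubling-time shift (flat signals are
rejected as ill-defined); the scalar summary is the geometric mean of the
40→30 and 40→60 min shifts.  The shift is applied at a division: the
lineage equilibrates at the old T, divides once more, and the daughter is
re-seeded on the new replication schedule (copy counts set to the new
age-0 values; added copies active; dropped repressed copies release their
bound dimers).  No reference shift protocol is published; mid-cycle
remapping between different schedules would be ambiguous, which is why
the division boundary was chosen.

**Sensitivity scan.**  Each kinetic parameter is separately scaled ×2 and
×½ and four metrics are computed: switching time at T = 40 min,
deterministic bistability range, sensitivity R(30 min)/R(60 min), and the
response-time scalar.  Perturbations that destroy bistability are recorded
as not-applicable and excluded from the Pearson correlations, which are
computed on log10 metric values (the scale is a package choice).

## Problem sizes and runtime choices

The published switching-time statistics rest on 1e5 transitions; this
package's defaults target ≥100 transitions per estimate (batches of ~115
lineages, per-lineage seeds derived from the base seed), which resolves
1/λ to roughly ±10% (standard error) and keeps a full three-condition MFPT
study in the minutes range on one core.  Equilibrium ensembles default to
200 lineages; at doubling times where the disfavoured basin empties slowly
(residence times of hundreds of hours at T = 60 min), burn-in must span
several residence times — the suite uses up to 250 h of model time per
lineage at T = 60 min — or the occupancy, and with it R_protein, is still
relaxing.  The SSA kernel (numba) advances ~5e6 events/s, so one such
ensemble is a couple of minutes of wall time.

## What the simulations do and do not emulate

The generator *is* the study system: parameter sets, the replication
geometry and the 1:2 insertion design are the study conditions, not
fixtures.  Real-bacterium features outside scope: replication-fork
variability and D-period noise, volume fluctuations and unequal division,
locus-dependent promoter context, transcription–replication conflicts,
extrinsic noise in T, and population-level (both-daughter) bookkeeping —
a single daughter lineage is followed, so ensemble averages are lineage
averages, not growing-population snapshot averages (cells divide in phase
at fixed T; the newborn-phase estimator above sidesteps the resulting
cycle-phase effects).

## Known limitations

* Switching times are exponentially sensitive to the basin structure, so
  percent-level ambiguities in the printed parametrization (volume
  normalization, the dimerization factor 2) translate into tens of
  percent in MFPT.  The implementation follows the printed propensities
  and Table values verbatim; with them, the three reference switching
  times come out ≈ 30–45% above the published 25 h / 58 h / 10 h
  (measured 36.4 h / 82.4 h / 13.1 h at seed 11), a
  uniform offset consistent with a slightly different effective
  repression strength in the original (unpublished) simulation code.
  Variants tested and rejected (each moves the numbers further away or
  not at all): the doubled V0 normalization, halved dimerization, the
  summed switch criterion.
* The strongly-repressed equilibrium ratio at T = 20 min depends on the
  residual occupancy of the disfavoured basin and is therefore
  protocol-sensitive; see the ensemble notes above.
* The deterministic sweeps detect folds of stable branches only; unstable
  branches and formal bifurcation continuation are out of scope.
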