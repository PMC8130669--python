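# Methods

## Scope and purpose

`pbkra` implements a read-across workflow for human PBK modelling of
alkenylbenzenes: simulate a source chemical's model, re-parameterise it
for a target chemical at two levels of data availability, quantify which
parameters drive the predictions, and select defensible source analogues
by structural-similarity consensus plus model-availability criteria. The
outputs of interest are internal dose metrics of the parent (liver Cmax,
AUC, venous concentration) and of the genotoxicity-relevant 1′-hydroxy
metabolite and its conjugates.

## Model structure

The parent chemical is described by perfusion-limited (flow-limited)
compartments: gut lumen, fat, richly perfused tissue, slowly perfused
tissue, an optional kidney, and the metabolising liver. All amounts are in
µmol, volumes in L, flows in L/h, times in h.

- Gut lumen: `dAGI/dt = −ka·AGI`, with the absorbed flux `ka·AGI` entering
  the liver directly (oral first pass). `AGI(0) = dose·BW/MW·1000` µmol.
- Non-metabolising tissue t: `dA_t/dt = Q_t (CA − CV_t)`,
  `CV_t = A_t/(V_t·P_t)`.
- Liver: `dAL/dt = QL (CA − CVL) + ka·AGI − Σ_i v_i`, with every phase I
  route Michaelis–Menten in the venous-side liver concentration:
  `v_i = Vmax_i · CVL/(Km_i + CVL)`.
- Blood carries no state: mixed venous equals the flow-weighted mean of
  tissue venous concentrations, `CV = Σ Q_t CV_t / QC`, and arterial
  equals mixed venous (no lung compartment). The blood volume fraction
  (VBC = 0.079) only converts CV to a reported blood amount. This keeps
  the state minimal and matches the structure of the source models.
- 1′-hydroxy metabolite: formed by the flagged hydroxylation route,
  distributed between the liver (its own liver:blood partition
  coefficient) and a single lumped rest-of-body compartment with partition
  1 and volume `BW − V_liver`, exchanging at the liver blood flow:
  `dALM/dt = v_HE + QL (CAM − CVLM) − Σ_j w_j`,
  `dABM/dt = QL (CVLM − CAM)`, with phase II conjugation
  `w_j = Vmax_j · CVLM/(Km_j + CVLM)` acting as terminal sinks (urinary
  excretion of conjugates is not resolved in time).
- Every metabolic rate also integrates into a cumulative per-pathway
  tracker, which makes the mass balance checkable:
  dose = gut + parent compartments + Σ phase I trackers, and
  hydroxylation tracker = metabolite pools + Σ phase II trackers. The
  worst relative violation over the output grid is reported with every
  simulation and is ~1e−15 at the default tolerances.

### Scale-up of in vitro kinetics

In vitro maximal rates (nmol·min⁻¹·mg protein⁻¹) become whole-liver rates
(µmol/h) via `Vmax = vmax · yield · liver_g · 60/1000`, with
liver mass `VLC·BW·1000` g. Phase I P450 routes scale with the microsomal
protein yield (32 mg/g liver) and phase II conjugations of the
1′-hydroxy metabolite with the S9 yield (143 mg/g liver), matching the
incubation systems the kinetic constants were measured in; the basis is
overridable per pathway in the parameter files.

## Parameters

Transcribed physiology (60 kg human): cardiac output coefficient 15 with
allometric exponent 0.74 (`QC = 15·BW^0.74 ≈ 310 L/h`); flow fractions
fat 0.052, liver 0.227, richly 0.473, slowly 0.248; volume fractions
fat 0.214, liver 0.026, richly 0.050, slowly 0.517, blood 0.079. The
cardiac-output entry in the source table is printed with garbled units;
the allometric reading is adopted because it yields a physiologically
correct ~310 L/h at 60 kg where a linear reading would give 900 L/h. The
exponent is an ordinary configurable field.

Chemical parameter files (YAML, one per chemical, canonical field order so
rewrites are byte-stable) carry molecular weights of parent and
1′-hydroxy metabolite, log Kow, measured tissue:blood partition
coefficients, and the phase I/II Michaelis–Menten tables with standard
deviations stored but unused (reserved for future uncertainty
propagation). Safrole's log Kow is not reported alongside its kinetic
data; the fixture stores a typical estimated value (3.45), flagged in its
provenance string — it is never used by simulation and is overwritten by
the target's value in both substitution modes.

### Declared assumptions

- **ka = 1.0 h⁻¹** first-order oral absorption into the liver. The value
  is taken from the source model implementations rather than the
  parameter tables, is exposed as a `DoseRegimen` field, and appears in
  the assumptions register of every report. At 24 h more than 99.99 % of
  the dose is absorbed, so terminal cumulative amounts are insensitive to
  it; peak amounts are not, which is why the peak-amount comparisons carry
  a generous tolerance in the tests.
- **Kidney**: the transcribed physiology has no kidney flow/volume
  fractions, while the safrole set carries a kidney partition coefficient
  and the original safrole model metabolised in kidney (parameters not
  available). Default behaviour lumps kidney into the richly perfused
  compartment with a warning — numerically exact here because the safrole
  kidney and richly-perfused partition coefficients are both 6.65 — and
  kidney metabolism is not modelled. Passing `include_kidney=True`
  enforces an explicit kidney compartment and errors if the physiology
  cannot support it.
- **Metabolite distribution**: one lumped rest-of-body pool with
  partition 1 is the simplest structure that conserves mass and
  reproduces a liver pool that fills and is then conjugated away. Renal
  excretion of the free metabolite is neglected.

## Substitution modes

`MW_PC` replaces molecular weights, log Kow and all partition
coefficients with the target's, keeping the source's kinetics and pathway
topology — the minimal-data scenario. `ALL` additionally replaces every
Vmax/Km, at which point the pathway topology becomes the target's
(methyleugenol has six phase I routes against estragole's five and
safrole's four). Both operations are idempotent, and an ALL-mode
self-substitution reproduces the original simulation exactly (tested).

Fold differences between scenarios are symmetric, `max(x,y)/min(x,y)`.
Conjugate trackers are compared on terminal cumulative amounts (they are
non-decreasing, so terminal = peak). The free 1′-hydroxy liver amount is
a depletable pool — it rises and is then conjugated away — so it is
compared on its peak; its terminal value reflects only the late-time
trickle of parent released from fat and is not a meaningful summary of
formation. The terminal cumulative hydroxylation fold is reported
alongside for completeness. Comparison conditions default to
0.07 mg/kg bw and 24 h, the realistic-intake setting.

## Dose–response

The sweep simulates each dose independently; the default grid is
logarithmic from 0.0007 to 300 mg/kg bw plus zero, spanning dietary
intake to the bend of the Michaelis–Menten curves. Below 0.07 mg/kg every
route is linear in dose within 5 % (tested). At high doses the low-Km
routes saturate first and the branching shifts toward the high-Km
1′-hydroxylation route, so bioactivation grows superlinearly — the
expected behaviour for this chemical class.

## Sensitivity analysis

One-sided forward perturbation: each parameter individually to
(1 + δ)·P with δ = 0.05 by default, everything else at baseline, and
`SC = (C′ − C)/(P′ − P) · P/C`. SC is invariant to parameter rescaling
and converges to the analytic elasticity as δ → 0 (both tested on closed
forms). Parameters are addressed by dotted paths
(`chemical.phase1.HE.vmax_unscaled`). The default scan covers kinetic
constants, partition coefficients, protein yields, body weight, cardiac
output and ka. Molecular weights are excluded by default (they only
convert the external dose to µmol, giving a trivial elasticity of −1), as
are individual flow fractions (a lone perturbation would violate the
sum-to-one constraint; perturb the cardiac output coefficient instead).
On the estragole model the largest-magnitude chemical-specific
coefficients for metabolite formation are Vmax/Km values (asserted as a
ranking property; for sulfate formation the sulfotransferase Vmax and Km
have |SC| ≈ 1). Body weight also scores |SC| ≈ 1 for amount outputs
because the dose is specified per kg.

## Analogue ranking and selection

Nine RDKit fingerprint families with recorded parameterisation: Morgan
and feature Morgan (radius 2, 2048 bits), topological torsion, atom pair,
path-based RDKit, layered and pattern (2048 bits), Avalon (512 bits),
MACCS keys. The exact family parameterisation behind externally reported
consensus scores is generally unknown, so reported scores are treated as
approximate references; with these defaults the shipped pool gives
consensus averages of 0.65 (estragole) and 0.62 (safrole) against
reported values of 0.66 and 0.69. Candidates in the top-5 of at least
four families receive a consensus average over all nine; ties within a
family are broken by canonical-SMILES lexicographic order so rankings are
deterministic. Selection applies, in order: similarity ≥ cut-off (0.6);
human PBK model exists and is reproducible; validated against in vivo
data; similar ADME. Missing metadata excludes a candidate rather than
raising, and relaxing the cut-off can only ever select more candidates.
The similar-ADME flag is an input (e.g. from metabolism simulators or
expert judgement); the package does not simulate metabolic similarity.

## Partition-coefficient estimation (optional helper)

`PC_t = (f_lip,t·Kow^a + f_wat,t)/(f_lip,blood·Kow^a + f_wat,blood)` with
a bundled human tissue-composition table and lipid exponent a = 1 for all
tissues (overridable per tissue). With the adopted table this reproduces
the measured methyleugenol coefficients within 15 % (fat 114 vs 103,
liver 5.7 vs 6.2, slowly perfused 4.0 vs 3.9). The estimate is scale-free
in the composition units. The primary modelling path always uses the
measured, transcribed partition coefficients; the estimator exists for
chemicals without measured values.

## Numerical choices

- Solver: SciPy's LSODA (stiff-capable, switching Adams/BDF) with
  rel_tol 1e−8, abs_tol 1e−10 µmol, output grid 0.01 h. The specific
  stiff method is a solver detail, not part of the model contract;
  halving both tolerances moves every reported amount by far less than
  0.1 % (tested), and on a reduced gut-plus-liver instance the solver
  matches an independently hand-coded fixed-step RK4 integrator
  (step 1e−4 h) to better than 0.1 % (tested).
- Zero dose yields identically zero trajectories and a mass-balance error
  of 0 by convention.
- Degenerate inputs (negative dose, non-positive Km, missing fields,
  duplicate pathway ids, unknown fixtures/trackers/metric keys) raise
  typed validation errors; the CLI maps validation errors to exit code 2
  and integration failures to exit code 3.
- The package is entirely deterministic: no random numbers are used
  anywhere, which the report output records.

## Problem sizes

All shipped analyses are small: the largest ODE system has 17 states
(safrole template with methyleugenol topology: 6 parent + 2 metabolite
states + 9 trackers), one 24 h simulation takes ~40 ms, the full scenario
suite seven simulations, a full sensitivity scan ~30 simulations, and the
consensus ranking 9 × 9 fingerprint comparisons. The test suite and the
reproduction script each run in seconds.

## Known limitations

- Oral route only; no inhalation/dermal absorption, no enterohepatic
  recirculation, no population variability.
- Kidney metabolism of safrole is not parameterised (data unavailable);
  the kidney compartment is structural only.
- Conjugates are terminal sinks; urinary time courses are not produced.
- Measured Vmax/Km standard deviations are stored but not propagated.
- Analogue selection reports decisions and reasons; whether a read-across
  is acceptable for a regulatory purpose remains expert judgement.
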