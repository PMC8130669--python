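# pbkra — read-across PBK modelling of alkenylbenzenes

`pbkra` is a toolkit for deriving and exercising human physiologically
based kinetic (PBK) models of alkenylbenzenes — estragole, safrole and
methyleugenol — by **read-across**: re-using a data-rich *source*
chemical's validated model to predict internal dosimetry for a data-poor
*target* chemical. It is aimed at toxicokinetic modellers and risk
assessors who need to parameterise, compare and report PBK models when no
in vivo kinetic data exist for the chemical of interest.

The package covers four pieces of that workflow:

1. **PBK simulation** — a perfusion-limited compartmental model (gut lumen,
   fat, richly/slowly perfused tissue, metabolising liver, optional kidney)
   with Michaelis–Menten phase I metabolism of the parent and a
   liver + rest-of-body submodel for the bioactivated 1′-hydroxy metabolite
   and its phase II conjugation (glucuronidation, sulfation, oxidation).
   For each tissue `dA_t/dt = Q_t (CA − A_t/(V_t P_t))`; in liver every
   route contributes `v_i = Vmax_i · CVL/(Km_i + CVL)` with in vitro rates
   scaled to whole organ via the microsomal/S9 protein yields. Mass balance
   is verified on every run.
2. **Read-across substitution** — three labelled scenario modes:
   `ORIGINAL` (source model untouched), `MW_PC` (only molecular weights,
   log Kow and partition coefficients replaced by the target's) and `ALL`
   (additionally every Vmax/Km), e.g. `ES_ME_MW_PC`, `SA_ME_all`; plus
   dose–response sweeps and symmetric fold differences between scenarios.
3. **Sensitivity analysis** — normalized local sensitivity coefficients
   `SC = (C′ − C)/(P′ − P) · P/C` with one-at-a-time +5 % perturbations.
4. **Analogue selection** — nine-fingerprint Tanimoto consensus ranking
   (Morgan, feature Morgan, torsion, Avalon, layered, atom pair, RDKit,
   MACCS, pattern), top-5 membership in ≥ 4 families, a 0.6 similarity
   cut-off, and a decision tree over model-availability metadata
   (human PBK model exists / reproducible / validated in vivo /
   similar ADME).

The transcribed parameter sets for estragole, safrole and methyleugenol
ship as data files, together with a candidate analogue pool and a human
tissue-composition table for the optional log Kow-based partition
coefficient estimator.

## Worked example

Simulate the methyleugenol model at a realistic dietary intake
(0.07 mg/kg bw, 60 kg, 24 h):

```python
import pbkra

phys = pbkra.builtin_physiology()
me = pbkra.builtin_chemical("methyleugenol")
dose = pbkra.DoseRegimen(oral_dose=0.07, duration=24.0)
result = pbkra.simulate(pbkra.build_model(phys, me, dose))
m = pbkra.summary_metrics(result)
print(round(m["dose_total_umol"], 2))          # 23.57
print(round(m["cmax"]["liver"], 3))            # 1.05
print(round(m["tmax"]["liver"], 2))            # 0.17
print(round(m["terminal_trackers"]["HE"], 3))  # 1.652
print(m["mass_balance_error"] < 1e-9)          # True
```

The 0.07 mg/kg dose corresponds to 23.57 µmol in the gut lumen; the parent
peaks in the liver at 1.05 µmol about 10 minutes after dosing (absorption
is fast relative to distribution), and 1.65 µmol flows through the
1′-hydroxylation route — the bioactivation pathway — within 24 h, with the
remainder through the competing oxidative routes. The mass-balance check
confirms the dose is fully accounted for.

The read-across comparison (both sources against the target, all modes):

```python
comp = pbkra.run_scenarios(
    [pbkra.builtin_chemical("estragole"), pbkra.builtin_chemical("safrole")],
    me, ["ORIGINAL", "MW_PC", "ALL"], phys, dose)
_, _, a = comp.get("ES_ME_MW_PC")
_, _, b = comp.get("ES_ME_all")
print(round(a["cmax"]["liver"], 2))                              # 0.98
print(round(comp.get("SA_ME_MW_PC")[2]["cmax"]["liver"], 2))     # 2.1
print(round(pbkra.fold_difference(a, b, "HEG"), 2))              # 2.01
print(round(pbkra.fold_difference(a, b, "metabolite_liver"), 2)) # 3.71
```

With only MW and partition coefficients substituted, the safrole template
predicts roughly twice the peak liver amount of the estragole template
(2.1 vs 0.98 µmol); adding the target's metabolism data (mode `ALL`)
changes the phase II conjugate amounts about 2-fold and the free liver
1′-hydroxy pool about 4-fold — quantifying how much the target's own
metabolism data matter for the read-across.

The same functionality is exposed on the command line
(`pbkra simulate`, `pbkra readacross`, `pbkra dose-response`,
`pbkra sensitivity`, `pbkra analogues`, `pbkra report`); `pbkra report`
writes a complete OECD-style model report in markdown, including the
substitution audit trail and assumptions register.

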