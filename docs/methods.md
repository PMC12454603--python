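# Methods

This note documents the models implemented in `mbaptox`, the assumptions
behind them, the choices made where the underlying model family leaves the
design open, and what the synthetic-data generators do and do not emulate.

## The PBK model

### Structure

The kinetic model is a flow-limited (perfusion-limited) physiologically
based kinetic model of 8-methyl-benzo[a]pyrene (8-MBaP) in the rat with a
sub-model for its aromatic-ring oxidation metabolite 3-OH-8-MBaP. Blood
circulates venous blood → lung → arterial blood → {fat, liver, rapidly
perfused, slowly perfused} → venous blood; the lung receives the total
cardiac output `QC = QCc·BW^0.74` (interpreted in L/h — at BW = 0.245 kg
this gives 5.30 L/h, the right magnitude for a rat, whereas a literal
mL/s reading would be ~45-fold too high). Each tissue is flow-limited:
its venous outflow carries `C_tissue/P_tissue`.

Three single-bolus routes are modeled exactly as first-order depots:

* **intravenous** — needle depot → venous blood at `Kd = 1e6/h`
  (effectively instantaneous; the simulated peak equals the venous
  dilution limit `dose/(VVBc·BW)` to 0.3%);
* **intratracheal** — trachea depot → lung tissue at `Kt = 1/h`;
* **oral** — stomach → first intestinal lumen segment at `Ka = 1/h`;
  seven lumen segments, each absorbed into the liver (portal inflow) with
  clearance `kabin = Papp·SAin = 0.00268 L/h` acting on the segment
  concentration, and passing lumen content onward at `kin`; the seventh
  segment empties into feces.

Liver metabolism comprises four saturable Michaelis–Menten reactions
driven by the free (venous-equilibrated) liver concentration
`C_liver/P_liver`: hydroxylation of the parent to the 3-OH metabolite,
oxidation of the parent to the sum of other metabolites, and
glucuronidation and sulfation of the metabolite (terminal sinks). Formed
metabolite enters the metabolite sub-model's liver compartment 1:1 on a
molar basis. Both compounds undergo first-order biliary excretion from
liver to feces at `Kb = 1/h`.

### Metabolite blood-protein binding

3-OH-8-MBaP binds blood protein; without this the large fat:blood
partition coefficient (392.8) would drain the metabolite into fat.
Binding is implemented as an instantaneous equilibrium: arterial and
venous amounts are totals, and every flux out of a blood compartment is
driven by the free concentration `fub·C_total` with `fub = 0.004`. The
free:total ratio therefore equals `fub` identically, and the
protein-bound pool is `(1 − fub)` of the blood amount. The parent's
printed fraction unbound (0.003) plays no transport role — its tissue
partition coefficients already subsume binding — and is retained for
reporting only.

### Metabolic capacity convention

In vitro maximal rates (nmol/min/mg protein) are scaled to the whole
liver with 45 mg microsomal protein/g liver, 125 mg S9 protein/g liver
and a 9.1 g liver (`per-gram = Vmax·protein·60/1000`;
`whole-liver = per-gram·liver mass`). The ODE model then applies the
allometric capacity convention of the classic PBK template this model
family descends from (the same template that supplies `QC = QCc·BW^0.74`
and names the metabolic coefficients `Vmax1c…Vmax4c`):

    Vmax_in_vivo = (whole-liver capacity) · BW^a ,  a = 0.75 by default.

With `a = 0.75` the package reproduces the published model-family
predictions across all validation anchors (route-specific Cmax of parent
and metabolite at 10 mg/kg bw, and the 50 mg/kg bw IV metabolite peak)
to within ~3–25%, whereas the literal whole-liver reading (`a = 0`,
selectable in the configuration) leaves every slow anchor uniformly
about 2-fold low — including an intratracheal parent peak that is
unreachable under any clearance assumption. The exponent is therefore a
model-identification choice, exposed in `[metabolism]
allometric_exponent` and honestly documented as such.

The liver mass defaults to the fixed 9.1 g rather than `VLc·BW·1000`
(= 9.065 g, 0.4% apart); both are configuration values.

### Numerics

The system is linear except for the four Michaelis–Menten rates, so the
right-hand side is assembled as a constant transport matrix `L·y` plus
the saturable terms, and the analytic Jacobian reuses `L`. Every column
of `L` sums to zero, so mass conservation is structural: the ledger
(dose = depots + tissues + blood + cumulative metabolized + feces, and
metabolite formed = present + conjugated + feces) closes to ~1e-15
relative at any solver tolerance. Integration uses `scipy`'s BDF with
`rtol 1e-8 / atol 1e-10` by default (the IV needle transfer makes the
problem stiff); reverse-dosimetry inversions use `rtol 1e-6` over a 24 h
horizon, which is ample since all metabolite peaks occur within a few
hours. Dense output is evaluated on a grid with >2000 points inside the
first hour plus a logarithmic sweep down to 1e-8 h, and Cmax is refined
on the continuous interpolant (the IV peak occurs near 1e-5 h).

### Intestinal constants

`kin` (lumen transfer between segments) and the lumen segment volume are
inherited in the source model family from earlier intestinal models and
are not printed; the packaged defaults are one-time calibration choices:
`kin = 7/1.5 h⁻¹` (total small-intestinal residence ~1.5 h) and 1 mL per
segment, both exposed in the configuration. Oral predictions are the
most sensitive to these constants, which is why the oral anchors carry
the widest acceptance bands.

## In vitro kinetics

Velocities are `metabolite µM/(time·protein)` (µM ≡ nmol/mL). The
Michaelis–Menten fit is unweighted nonlinear least squares (the default
of the curve-fitting tools used for such data), initialized from a
Hanes–Woolf linearization; weighting and substrate-depletion corrections
are deliberately not applied (initial-rate conditions are assumed, as in
the incubation design: ≤20 min, 0.1 mg/mL S9 for glucuronidation; 70 min
for the slower sulfation).

## mEST analysis

Differentiation is scored as beating embryoid bodies out of 24 per
concentration, expressed as a percentage of the solvent control so the
curve top sits near 100 and IC50s are comparable across runs. Validity
requires strictly more than 21/24 control EBs beating (generalized
proportionally, beating/total > 87.5%, for other totals). Viability is
`100·mean(A440−A620)/mean(A440c−A620c)`. Curves are fitted with the
three-parameter log-inhibition model (top, bottom, IC50; Hill slope
fixed at 1 — the named three-parameter family); a free-slope
four-parameter variant sits behind a flag. Concentration-zero rows
evaluate exactly to `top` and need no exclusion.

## Reverse dosimetry

Unbound-concentration matching sets
`C_in_vivo = C_in_vitro·fub_in_vitro/fub_in_vivo`, with
`fub_in_vitro = fub_in_vivo/2` by default (7.5% protein in rat plasma vs
15% serum in the assay medium). The matched internal metric is the
metabolite's total blood Cmax — peak concentration, not AUC, is taken as
the relevant driver for developmental effects. Doses are recovered by
bracketed bisection on the monotone dose→Cmax map to 0.1% relative.

A whole in vitro curve is translated on a 32-point log-spaced grid
spanning 0.01–100 × IC50 (each point through the full PBK inversion,
since Michaelis–Menten saturation bends the mapping at high
concentrations; points whose matched Cmax exceeds the attainable range
are dropped with a warning). The (dose, effect) points are refitted with
a log-logistic curve constrained to bottom 0 and top 100, slope fixed at
1 to mirror the in vitro family (free-slope variant behind a flag; with
the default rat curve the free-slope ED50 differs by <5%). Effects are
oriented as rising toxicity, `100·(1 − R(c)/top)`, so the constrained
fit is meaningful. With the packaged parameters and the rat IC50 of
1.40 µM the oral ED50 computes to 8.8 mg/kg bw, 1.2-fold below the
published 10.5 mg/kg bw.

## Sensitivity analysis

One-sided +10% normalized coefficients
`SC = ((C′−C)/(P′−P))·(P/C)` on the metabolite blood Cmax, every scalar
parameter perturbed independently. Perturbing a fractional blood flow
rescales the remaining members of {liver, rapidly, slowly} so the four
flow fractions (including fat) keep summing to 1 exactly; perturbing the
fat flow rescales the whole trio. Perturbing the liver volume fraction
also carries the liver mass (hence metabolic capacity) with it —
without that pathway liver size could not be an influential parameter,
contradicting the published screen. A ±1% central-difference oracle
exists only in the tests.

## Synthetic data

The generators reproduce the statistical structure, not the chemistry,
of the study's raw data:

* **Incubation velocities** — exact Michaelis–Menten curves times
  `1 + cv·ε` multiplicative Gaussian noise (cv 0.1 by default, matching
  the visual scatter of triplicate S9 incubations), truncated at zero,
  on substrate grids within the experimental 0–100 µM range.
* **mEST plates** — binomial beating counts over 24 EBs on a slope-1
  log-inhibition curve `p(c) = top/(1 + c/IC50)`, with the solvent
  control drawn at `p = top` and a strongly inhibited 5-FU positive
  control (p = 0.05, a nominal choice). The discrete 24-EB readout is
  the dominant noise source: it alone carries ~20% median IC50
  estimation error at study scale (3 replicate plates), which is why
  end-to-end ED50 recovery is asserted on the median over seed batches.
* **Blood time courses** — PBK predictions sampled at the in vivo
  schedule (1 min, 0.5, 1, 2, 4, 8, 12, 24, 32, 48, 72 h; 3 animals)
  times lognormal noise (`sdlog` 0.3 by default, consistent with the
  large recovery scatter of highly lipophilic analytes).

What they do not emulate: inter-experiment drift, chromatographic
quantification error structure, substrate depletion, plate-position
effects, or animal-to-animal physiological variability. Tests passing on
these generators therefore demonstrate estimator and pipeline
correctness under the assumed noise models, not field performance on
real data.

## Known limitations

* The source model's ODEs are unpublished; the reconstruction is
  validated against its printed predictions. Two residual gaps are
  documented rather than absorbed: the intratracheal parent Cmax stays
  ~1.8-fold below the printed value (reproducing it would need an
  effective trachea→blood rate ~20/h, contradicting the printed
  Kt = 1/h), and the 50 mg/kg IV metabolite peak computes ~25% low
  (2.33 vs 3.1 µM). Both sit inside the 2-fold adequacy band customary
  for PBK evaluation.
* No pregnancy/fetal compartment (maternal and fetal blood are assumed
  equal), no repeated dosing, no inhalation aerosol physics, no
  enterohepatic recirculation.
* Partition coefficients and unbound fractions are consumed as
  configuration constants; the QSARs that produced them are out of
  scope.
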