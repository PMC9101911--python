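# Methods

## Model structure

`phthalpbpk` simulates the disposition of DEHP (di(2-ethylhexyl)
phthalate) and its primary hydrolysis metabolite MEHP (mono(2-ethylhexyl)
phthalate) in a whole-body physiologically based pharmacokinetic (PBPK)
model with sixteen compartments: lungs, heart, brain, muscle, skin,
liver, gut, spleen, pancreas, bone, kidney, thymus, a lumped
rest-of-body pool, arterial and venous blood, and a cumulative urine
accumulator (a fixed 1-mL bookkeeping compartment, not a perfused
tissue).

Every tissue is **flow-limited**: uptake is assumed fast relative to
perfusion, so the venous outflow of organ *i* leaves in equilibrium with
the tissue,

    V_i dC_i/dt = Q_i (C_art − C_i / Kp_i),

with Q_i the organ blood flow and Kp_i the tissue:plasma partition
coefficient. Systemic organs are perfused in parallel from the arterial
pool; the lungs sit in series on total cardiac output between venous and
arterial blood; gut, spleen and pancreas drain through the portal vein
into the liver, which also receives a hepatic arterial supply. Flow is
conserved exactly at every node by construction, and
`physiology.validate_topology` audits the venous, hepatic and pulmonary
junctions to 1e-9 of cardiac output.

Species-specific wiring:

- **DEHP** enters through three routes — gut lumen (oral), skin tissue
  (dermal) and lung tissue (inhalation) — and distributes into every
  perfused organ *except* the rest-of-body pool (that pool carries MEHP
  only; the flow it receives shunts arterial blood unchanged to the
  venous pool for DEHP). Gut-lumen DEHP is absorbed into gut tissue
  first-order at `kgut` (7 h⁻¹); unabsorbed lumen content is retained
  (no faecal loss).
- **MEHP** is formed in gut and liver tissue by saturable hydrolysis of
  DEHP and distributes into all perfused organs including rest-of-body.
  It is eliminated (i) by saturable oxidation in gut and liver into a
  pooled downstream-metabolite **sink** (5-OH MEHP, 5-cx MEPP,
  5-oxo MEHP, phthalic acid are not tracked individually) and (ii) into
  urine, first-order from venous blood at `kurine × fup` (0.35 h⁻¹ ×
  0.007 unbound fraction). A config option (`urine_source="kidney"`)
  drains kidney tissue instead.

Metabolism follows Michaelis–Menten kinetics, v = Vmax·C/(Km + C), on
the total tissue concentration in µg/L (no intracellular
sub-compartmentalisation). Hydrolysis converts mass with the molecular
weight ratio MW_MEHP/MW_DEHP so that **moles** are conserved;
`ode_core.mass_balance` audits molar conservation at every output time
and every shipped scenario closes to better than 1e-6 relative.

## Parameters

Chemical parameters (partition coefficients, fup, kgut, kurine, the
twelve Vmax/Km pairs) are tabulated medians with lognormal uncertainty
(geometric SD factor 1.1 or 1.5, draws truncated at ±1.5 geometric SDs).
Default runs use the medians; `chemistry.sample_parameters` provides
reproducible truncated-lognormal Monte Carlo draws (the truncation
reading of the "±1–1.5 SD" range is a modelling choice; the alternative
reading — dispersion only — is not used).

Choices made where the source tables are silent or inconsistent:

- **Blood flows are not part of the chemical parameter set** and no
  cardiac output is tabulated. We ship reference-human defaults:
  cardiac output 5200 mL/min (312 000 mL/h) and fractional flows
  heart 0.04, brain 0.12, muscle 0.17, skin 0.05, gut 0.15, spleen 0.03,
  pancreas 0.01, bone 0.05, kidney 0.19, thymus 0.0015, hepatic artery
  0.065, rest-of-body 0.1235 (remainder). All overridable.
- **Protein scaling.** Vmax values are per mg of microsomal (MSP) or
  cytosolic protein and are scaled to whole-organ capacity as
  Vmax × 60 × (mg protein / g tissue) × tissue mass (density 1 g/mL).
  Defaults: liver 40 mg MSP/g and 80.7 mg cytosolic protein/g; gut
  3 mg/g for both pools. These constants dominate total metabolic
  clearance and are the largest single source of quantitative
  uncertainty in the outputs.
- **Liver microsomal M1 Km** is not tabulated; the intestinal microsomal
  value (6956 µg/L) for the same DEHP→MEHP lipase reaction is used.
- **Gut M5 Vmax** (0.285) is printed with mg-scale units unlike every
  other capacity; it is read on the µg basis (assumed unit typo), with a
  flag to flip.
- **M4** nominally acts on the hydroxylated metabolite, which this model
  does not track; it is wired as a small additional MEHP→sink loss
  (<1% of total MEHP clearance), keeping the twelve-reaction table
  intact.
- **MEHP molecular weight** defaults to 278.3 g/mol; the single-dose
  benchmark uses the deuterium-labelled 281 g/mol, matching the analyte
  measured in that experiment.
- **Partition fallback.** Organs without a measured Kp (heart, brain,
  muscle, skin, spleen, pancreas, bone, kidney, thymus, lungs) use the
  rest-of-body Kp of the corresponding species (DEHP 6.24, MEHP 0.38).
  A direct consequence: at steady state under continuous dosing, lungs
  and spleen+pancreas concentrations coincide *exactly*, because every
  organ equilibrates to Kp × C_art and the lungs' series position does
  not change their equilibrium. Reported orderings between these organs
  are therefore ties up to solver precision.
- **Fat Kp values** (188 DEHP, 0.12 MEHP) are loaded but unused: the
  anatomy table has no adipose compartment. This removes the body's
  largest lipophilic depot and is a known structural limitation.
- **fup** multiplies the urinary elimination flux only (it is an
  elimination parameter in the source table); an option applies it to
  tissue-exchange driving concentrations instead.

## Dosing

- Oral: 1.95 mg/day split 0.5/0.8/0.65 mg at 8, 12 and 18 h, each
  infused into the gut lumen over 30 min (constant rate, half-open
  intervals). The stated per-kg rate (3.25 µg/kg/day × 60 kg) actually
  gives 0.195 mg/day; the 1.95 mg/day total is used because it matches
  the individual meal masses.
- Dermal: 0.68 mg/h continuous into skin tissue, 24 h/day (no
  stratum-corneum diffusion model).
- Inhalation: 0.53 mg/h continuous into lung tissue, 24 h/day (no
  respiratory-tract deposition model).
- Single-dose benchmark: 48.1 mg oral over 30 min, 75-kg subject.

## Numerics

The stiff system (32 states) is integrated with LSODA at rtol 1e-8 /
atol 1e-10 µg, restarting at every dose on/off boundary so the solver
never steps across a rate discontinuity. Output is a uniform grid of 20
points/h (0.05 h), fine enough to resolve post-meal peak timing. States
are validated non-negative to 1e-6 µg at output times. Simulation sizes:
the shipped analyses use 48-h (oral peaks), 120-h (equilibria and
day-over-day deltas) and 72-h (single-dose benchmark) horizons; each run
completes in about a second on one CPU.

Peaks are strict local maxima on the output grid; equilibrium values are
means over the final 12 h, flagged converged only when the window spread
is below 1% relative (periodic oral signals are reported not-converged).
Day-over-day convergence is measured on the whole-body burden (all
tissue amounts plus gut lumen, urine and sink excluded) at day
boundaries: δ_n = |B(24n) − B(24(n−1))| / B(24n) × 100.

## What the defaults do and do not reproduce

Structural behaviour reproduces the published qualitative picture at
median parameters: the liver dominates DEHP and MEHP peaks under oral
dosing (≥2× lungs/spleen/pancreas); continuous dermal and inhalation
exposure drive the endocrine organs and lungs to the highest DEHP
equilibria with the liver lowest, while the liver carries the highest
MEHP; day-over-day burden deltas decrease monotonically toward a
periodic steady state.

Quantitatively, liver MEHP equilibria under continuous dosing land
within ~30% of the published simulated values. Other published values
are more sensitive to the two unpublished constant groups: absolute
DEHP levels in liver scale inversely with the protein-scaled hepatic
intrinsic clearance, equilibrium concentrations in non-metabolising
organs scale inversely with hepatic blood flow, and the first-day
burden delta reflects the slowest tissue time constant (V·Kp/Q ≈ 8 h
for rest-of-body here). With the defaults above, liver DEHP runs ~4×
low, spleen+pancreas DEHP ~1.3× high and the 24–48 h delta ~1.5–2.3×
high relative to the published simulation; none of these constants were
adjusted to match.

The urinary output is structurally small in this wiring: elimination at
kurine × fup from venous blood gives a urinary clearance of ~0.008 L/h
against a hepatic MEHP metabolic clearance near 100 L/h, so well under
0.1% of a molar dose reaches urine as MEHP, versus the several percent
seen in human dosing data. Reproducing observed urinary recoveries
would require either a much larger effective urinary clearance or
routing a fraction of the oxidised-metabolite sink to urine, neither of
which the present parameterisation supports; the benchmark run reports
what the model computes.

## Synthetic conditions vs real exposure

The dose scenarios are idealised study conditions — constant 24 h/day
dermal/inhalation rates, a fixed three-meal diet — not measured personal
exposure. Passing tests demonstrate internal consistency (conservation,
limiting behaviour, orderings) and reproducibility of the model as
specified; they do not validate the parameterisation against human
biomonitoring beyond the qualitative single-dose comparison.
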