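# Methods

## Scope and model structure

`pedrenal` predicts total renal plasma clearance (CL_R, mL/min) as the sum
of glomerular filtration and active tubular secretion arranged in series:

    CL_R = f_u·GFR + (Q_R − GFR)·f_u·CL_int,sec / (Q_R + f_u·CL_int,sec/BP)

Only unbound drug in plasma is available for elimination. The second term
is a well-stirred kidney model for the secretion pathway: blood that has
already been filtered (fraction GFR/Q_R) is not available for secretion,
and the CL_int,sec/BP term converts the intrinsic (plasma-referenced)
secretion capacity to the blood side. Reabsorption, renal metabolism and
passive permeability are deliberately out of scope: the framework isolates
the filtration and secretion pathways so that the effect of transporter
ontogeny can be read off without confounding. No inter-individual
variability or parameter uncertainty is modelled — every output is the
deterministic prediction for a *typical* individual.

## System parameters and maturation

Nine typical individuals anchor the age range: 1 day, 1, 3 and 6 months, 1,
2, 5 and 15 years, and a 35-year adult, with tabulated weight, height, BSA
and hematocrit (`src/pedrenal/data/individuals.csv`). Conversions are fixed
at 1 y = 365.25 d = 52.18 wk; postmenstrual age assumes term birth
(PMA = PNA + 40 wk), the only neutral choice for typical individuals.

Maturation functions (each using the age unit of its source):

| Parameter | Form | Age unit |
|---|---|---|
| GFR | 112·(WT/70)^0.63 · PMA^3.3/(PMA^3.3+55.4^3.3) mL/min | PMA weeks |
| [HSA] | 1.1287·ln(AGE) + 33.746 g/L | days |
| [AGP] | 0.887·AGE^0.38/(8.89^0.38+AGE^0.38) g/L | days |
| CO | BSA·(110 + 184·(e^(−0.0378·AGE) − e^(−0.24477·AGE))) L/h | years |
| fr | mean of male/female sigmoids, 4.53% at birth → ~18% adult | years |
| hematocrit | mean of male/female curves, 53% at birth | years |
| KW | 1050·(4.214·WT^0.823 + 4.456·WT^0.795)/1000 g | — |

Unit conventions that required a decision:

* **Q_R = CO·fr.** Cardiac output is taken in L/h (the bracket is then a
  cardiac index of 110 L/h/m² at birth and ~159 in the adult, i.e.
  1.8–2.6 L/min/m², physiologic) with the 184 coefficient applied to the
  *difference* of the exponentials, and fr as percent/100. This yields an
  adult Q_R of ≈ 853 mL/min — inside the physiologic 600–1500 mL/min band
  and above GFR at every age. Q_R is converted to mL/min internally.
  Note the cardiac index peaks in adolescence, so Q_R(15 y) ≈ 1012 mL/min
  exceeds the adult value; Q_R is monotone over the pediatric ages only.
* **Protein concentrations are absolute.** Both binding-protein expressions
  evaluate to g/L-scale numbers (HSA ≈ 33.7 at birth, ≈ 44.4 in the adult),
  so they are treated as absolute concentrations and the pediatric/adult
  *ratio* is formed inside the unbound-fraction scaling
  f_u,ped = 1/(1 + (1−f_u,adult)·[P]_ped/([P]_adult·f_u,adult)), with the
  adult reference evaluated at 35 y. The same age-specific f_u feeds both
  the filtration term and BP.
* **Hematocrit of record.** The nine anchors use their tabulated hematocrit
  (the maturation formula disagrees slightly at 1 day and the adult);
  synthetic individuals at other ages fall back on the formula. Hematocrit
  enters BP = 1 + hemat·(f_u·Kp − 1) as a fraction.
* **CL_int,T units.** CL_int,T is carried in μL/min per 10⁶ proximal tubule
  cells, so CL_int,sec = CL_int,T·ont_T·PTCPGK·KW/1000 closes dimensionally
  (PTCPGK in 10⁶ cells/g at the fixed adult value 60, KW in g, the /1000
  converting μL to mL). This is the only reading under which the scaling
  chain is consistent with the mechanistic-kidney convention.

## Transporter ontogeny

`ont_T ∈ (0, 1]` multiplies the adult CL_int,T. Scenarios:

* `fixed_adult` — ont_T ≡ 1 (ontogeny ignored; the %PD reference).
* `constant:x` — ont_T held at x ∈ {0.05, 0.2, 0.5, 0.7} across the
  pediatric range (the adult keeps ont_T = 1 as the reference complement).
* `published:T` — six literature functions: sigmoids in postnatal weeks for
  P-gp (half-max 4.02 wk), OAT1 (19.71 wk), OAT3 (30.70 wk) and OCT2; a
  continuous aggregated weight/age function; and a step function over
  literature age groups with steps 20.3, 14.9, 31.3, 46.5, 44.2, 66.5,
  73.15, 73.15, 79.8 (relative to the adult 79.8) at the nine anchor ages.
  The step function is deliberately non-monotone (its source age groups
  are), so no monotonicity is asserted for it.

Two quirks are implemented exactly as published, with switches:

* The OCT2 sigmoid pairs a numerator exponent of 1 with a half-max constant
  raised to 0.51 (`PNA/(PNA + 4.38^0.51)`). The printed form is the
  default; `oct2_corrected=True` selects the internally consistent
  `PNA/(PNA + 4.38)` variant.
* The continuous aggregated function is normalized to its value at 12 y and
  treated as mature from that age on. Its 12-y reference weight is not in
  the anchor table; 43.45 kg, the linear interpolation between the 5-y
  (18.25 kg) and 15-y (54.25 kg) anchors, is used and is configurable.

## The drug grid (synthetic data)

The study conditions are a full Cartesian grid: binding protein ∈
{HSA, AGP} (exclusive binding), f_u,adult ∈ {0.05, 0.15, …, 0.95, 1},
Kp ∈ {0, 1, 2, 3, 4}, and 39 CL_int,T values log-spaced over
[2, 500] μL/min/10⁶ cells with the representative values {5, 50, 500}
snapped onto the grid (each anchor replaces its nearest log-spaced
neighbour, keeping 39 strictly increasing values; the source range is
stated but the 39 individual values are not, so log-spacing is the neutral
reconstruction). That yields 4290 drugs; the original analysis quotes 3800
combinations for the same value lists, a discrepancy we surface in the run
log rather than resolve by silent pruning. Grid generation is deterministic
and order-stable.

The retrograde mode inverts the clearance model algebraically:
CL_ATS = CL_R − f_u·GFR, then
CL_int,sec = CL_ATS·Q_R / (f_u·((Q_R−GFR) − CL_ATS/BP)), then unscale by
PTCPGK·KW. It refuses observations with no secretion component
(CL_R ≤ f_u·GFR) and flow-limited observations at or above the perfusion
ceiling (CL_ATS ≥ (Q_R−GFR)·BP), where the forward model is insensitive to
CL_int,T. On its valid domain the inversion round-trips through the forward
model to 1e-9 relative precision (property-tested).

## %PD and acceptability

%PD = 100·(CL_R[ont=1] − CL_R[ont])/CL_R[ont] ≥ 0 whenever ont_T ≤ 1.
Classification: < 30% acceptable, 30–50% (both bounds inclusive) reasonably
acceptable, > 50% unacceptable. Systematic acceptability of an
age × scenario cell is driven solely by the *maximum* %PD over the drug
grid; the heat-map summary reports min/median/max with the median
midpoint-interpolated for even counts. Pediatric summaries cover the eight
pediatric anchors; the adult row exists only as the ont = 1 reference.

## Averaging scopes for the headline aggregates

The report module computes the study's prose aggregates with explicit
scopes:

* Mean ATS contributions by CL_int,T stratum (5/50/500): all HSA grid
  drugs (11 f_u × 5 Kp) across all nine individuals, ont_T = 1.
* Mean CL_R by (CL_int,T, f_u,adult) stratum: the representative drug at
  Kp = 1, averaged over the **eight pediatric ages**. This is the scope of
  the age-profile figures the prose describes: with it the strata come out
  at 46.3, 129.7 and 235.6 mL/min for f_u,adult = 0.95 at CL_int,T = 5, 50
  and 500 — against reference values 46, 130 and 238 — whereas including
  the adult or averaging over Kp misses them by 30–50%. Both scope choices
  are keyword arguments, not hard-coded.
* %PD extrema: the nine representative drugs (HSA, Kp = 1,
  f_u ∈ {0.05, 0.55, 0.95} × CL_int,T ∈ {5, 50, 500}) under the constant
  ontogeny fractions.

One reference value is not reproducible from the model as published: the
maximum Kp 1→4 fold-change in CL_R (reference 1.25 at CL_int,T = 500,
f_u = 0.95). In the perfusion limit CL_ATS → (Q_R−GFR)·BP, so raising Kp
from 1 to 4 multiplies the secretion term by the BP ratio (≈ 2.2 at
f_u = 0.95), giving ≈ 1.8-fold in CL_R under every averaging scope we
tried; the companion value at CL_int,T = 50, f_u = 0.55 (1.15) reproduces
(1.16). The report prints the computed ratios next to the reference values
without adjustment.

## Numerical notes

* Everything is closed-form arithmetic; no solver, no randomness. The full
  default run (4290 drugs × 9 individuals × 11 scenarios) is vectorized
  over drugs with numpy and completes in a few seconds on one CPU.
* The scalar model (`clearance.renal_clearance`) and the vectorized grid
  evaluator (`study.evaluate_drug_frame`) are independent code paths,
  cross-checked row-by-row in the tests at 1e-12 relative tolerance.
* Degenerate inputs fail loudly: ages below one day (the HSA log diverges),
  non-positive weights or concentrations, BP ≤ 0, fu_adult = 0 and empty
  report strata all raise `ValueError`.
* Contribution sums and inverse round-trips are checked at 1e-9 relative
  tolerance — pure arithmetic, no stiffness.

## What the synthetic grid does and does not show

The drug grid spans realistic marginal ranges, but its Cartesian product
contains property combinations no real drug has (e.g. f_u = 1 with maximal
CL_int,T), and real drugs rarely use a single elimination pathway or bind a
single protein. Passing the acceptance checks therefore demonstrates that
the *model* reproduces the published sensitivity analysis, not that any
particular real drug's pediatric clearance is predicted accurately. The
transporter ontogeny functions come from sparse postmortem expression data
and two aggregated-literature compilations; their disagreement (the
continuous aggregated function is the slowest by far) is propagated, not
resolved.
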