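# pedrenal

Mechanistic prediction of **pediatric renal drug clearance** by glomerular
filtration (GF) and active tubular secretion (ATS), with explicit
renal-transporter ontogeny.

Renal excretion is a major elimination route for small-molecule drugs, but
while the maturation of glomerular filtration in children is well
characterized, the developmental trajectory of the secretion transporters in
the proximal tubule (OAT1, OAT3, OCT2, P-gp, …) is not. `pedrenal` is a
physiologically based (PBPK) simulation framework for asking, systematically:
*for which drug properties and at which ages does ignoring transporter
ontogeny bias a renal clearance prediction, and by how much?* It is aimed at
pharmacometricians and DMPK scientists doing pediatric extrapolation.

## The model

Total renal plasma clearance is a serial arrangement of filtration and
secretion with a well-stirred kidney term:

```
CL_R = CL_GF + CL_ATS
     = f_u · GFR  +  (Q_R − GFR) · f_u · CL_int,sec
                     ────────────────────────────────
                       Q_R + f_u · CL_int,sec / BP
```

where `f_u` is the (age-dependent) fraction unbound in plasma, `GFR` the
glomerular filtration rate, `Q_R` renal blood flow, `BP` the blood-to-plasma
ratio (`1 + hematocrit·(f_u·Kp − 1)`), and

```
CL_int,sec = CL_int,T · ont_T · PTCPGK · KW
```

scales a drug's transporter-mediated intrinsic clearance `CL_int,T`
(μL/min per 10⁶ proximal tubule cells) by the transporter ontogeny fraction
`ont_T ∈ (0, 1]`, the proximal-tubule cell density (60×10⁶ cells/g, all
ages) and kidney weight. Every system parameter carries a published
maturation function; nine typical individuals (1 day, 1/3/6 months,
1/2/5/15 years, adult) anchor the age range. Hypothetical drugs live on a
grid of 2 binding proteins × 11 `f_u,adult` × 5 `Kp` × 39 `CL_int,T`
values (4290 drugs).

The impact of ignoring ontogeny is the percentage prediction difference

```
%PD = 100 · (CL_R[ont_T = 1] − CL_R[ont_T]) / CL_R[ont_T]
```

classified as acceptable (< 30%), reasonably acceptable (30–50%) or
unacceptable (> 50%); an age/transporter scenario is *systematically
acceptable* only if the maximum %PD over the entire drug grid stays below
30%.

## Worked example

Clearance profile of an OAT1 substrate (HSA-bound, `f_u,adult` = 0.55,
`Kp` = 1, `CL_int,T` = 50 μL/min/10⁶ cells) across the nine ages:

```bash
$ pedrenal drug --fu 0.55 --clint 50 --kp 1 --scenario published:OAT1
individual  ont_t  fu_age  cl_gf  cl_ats    cl_r  ats_contribution   limitation
     1 day  0.107   0.617  2.710   2.886   5.596            51.575 permeability
   1 month  0.343   0.591  3.700   9.876  13.576            72.745        mixed
  3 months  0.456   0.583  6.277  17.631  23.908            73.746        mixed
  6 months  0.530   0.578 10.213  25.355  35.568            71.286        mixed
    1 year  0.603   0.573 15.785  36.549  52.333            69.838 permeability
   2 years  0.672   0.569 20.480  50.464  70.944            71.132 permeability
   5 years  0.752   0.563 26.910  82.188 109.098            75.334 permeability
  15 years  0.830   0.555 52.968 207.935 260.903            79.698 permeability
     Adult  0.875   0.550 59.641 217.571 277.212            78.486        mixed
```

Reading the columns: in the 1-day-old OAT1 activity is at ~11% of the adult
level, so secretion contributes only 2.9 of the 5.6 mL/min total clearance;
by 15 years the transporter is essentially mature and ATS carries ~80% of a
260 mL/min clearance. `limitation` classifies each prediction by
`CL_R/Q_R` (permeability-limited < 0.3, perfusion-limited > 0.7).

The full study — all 4290 drugs × 9 individuals × 11 ontogeny scenarios,
with %PD tables and the scenario × age acceptability heat map — runs in a
few seconds:

```bash
pedrenal run --out study_out/      # clearance, pd, heatmap, contributions CSVs
pedrenal report                    # headline aggregates vs reference values
```

Single observations invert too: `pedrenal retrograde obs.csv` recovers
`CL_int,T` from adult `CL_R` values (columns `drug_id, clr_adult, fu_adult,
kp`), the calculation used to set the realistic [2, 500] grid range.

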