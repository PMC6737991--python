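# Methods note

This note documents the models, parameters and numerical choices in
`ricessnm`, and what the synthetic-cohort generator does and does not try
to emulate.

Units throughout: nutrient rates in kg elemental nutrient/ha, yields in
Mg/ha at 14% grain moisture, timing in days after transplanting (DAT),
money in US$/ha.

## 1. Recommendation engine

### 1.1 Target yield

For an interview with recent (historical) yield `GY_R`, optional variety
ceiling `C`, and transplanting delay `d` days:

```
GY_T = clamp( min(GY_R + u, C) − p · d/7 ,  lo, hi )
```

Defaults: uplift `u = 0.5` Mg/ha, delay penalty `p = 0.25` Mg/ha per
week, bounds `[lo, hi] = [3.0, 6.5]` Mg/ha. The uplift encodes
"attainable improvement over recent performance"; the bounds keep the
downstream calibration inside its supported range. Results are rounded
to 0.1 Mg/ha.

### 1.2 Nitrogen rate and splits

Fertilizer N is piecewise-linear through calibration anchors, by default
`(3.0, 57)` and `(6.0, 123)` (target yield, kg N/ha), extrapolating the
terminal segments. With two anchors this is `FN = 57 + 22 (GY_T − 3)`.
The anchor form (rather than a slope/intercept) lets recalibration add
points without changing code. N is split by fractions
`(0.30, 0.30, 0.40)` across basal, mid-tillering and panicle initiation;
the last split absorbs any rounding residue so the splits always sum to
the rate.

### 1.3 Phenology

Panicle initiation is assumed at `duration − 60` days after sowing, so
`PI = duration − 60 − seedling_age` DAT. Mid-tillering is `round(PI/2)`.
The basal deadline interpolates linearly in growth duration between
(100 d → 5 DAT) and (160 d → 21 DAT), clamped at the ends. The schedule
must satisfy `basal < MT < PI` with `PI ≥ 1`; violations (e.g. very old
seedlings on a short-duration variety) raise `SchedulingError` rather
than emit an impossible plan.

### 1.4 Phosphorus: input–output balance

```
FP = max(0, rie_p · GY_T − credit)
credit = residue_fraction · straw_p_share · rie_p · GY_prev
```

Defaults: reciprocal internal efficiency `rie_p = 2.6` kg P per Mg grain;
grain holds 70% of plant P, so straw holds `straw_p_share = 0.30`;
`residue_fraction = 0.15` of residue biomass retained. P is all basal.

### 1.5 Potassium: yield-gain replacement

```
FK = f_k · GY_T · rie_k / re_k
```

Defaults: `f_k = 0.15` (fraction of target yield attributed to fertilizer
K), `rie_k = 14.5` kg K per Mg grain, recovery efficiency `re_k = 0.44`.
Rates up to the threshold 33 kg/ha (inclusive) are a single basal dose;
above it, 50/50 between basal and panicle initiation.

### 1.6 Product allocation

Grades convert to elemental content with `P = 0.4364 · P₂O₅`,
`K = 0.8301 · K₂O`. Allocation is a fixed priority rule: (1) zinc sulfate
at a flat 25 kg/ha; (2) the prescription's P from the highest-P product
available (usually DAP); (3) K from the highest-K product (MOP); (4) the
N delivered as a by-product of steps 1–3 is credited against the N splits
in stage order (basal first); (5) the residual N of each split is met
with the single-nutrient N product (urea). For the (urea, DAP, MOP)
basket this rule reproduces the exact solution of the 3×3 linear system —
a property verified in the tests against `numpy.linalg.solve`. "Unmet"
amounts (positive or negative) are reported when the basket cannot match
the prescription exactly.

### 1.7 Economics

`TFC` is the priced sum of allocated product amounts. Gross return above
fertilizer cost `GRF = 1000 · GY · price − TFC` with paddy price 0.21
US$/kg (0.22 for kharif 2015) and an accounting exchange rate of 65
INR/US$. Added net benefit between treatments A and B on the same field
is `ANB = GRF_A − GRF_B` (antisymmetric and additive across contrasts).
`PFP = 1000 · GY / FN` kg grain per kg N; undefined (reported as null)
when FN = 0. Exceedance curves use the inclusive event `P(ANB ≥ t)`.

## 2. Treatments

- **RCM**: the engine's full prescription, allocated to products.
- **BFR** (blanket recommendation): fixed 80/17/33 kg/ha N/P/K with N
  split 20/50/30 across the same three stages, K split 50/50
  basal/panicle initiation, plus 25 kg/ha zinc sulfate. Identical across
  fields by construction (the tests assert invariance), though its stage
  *dates* follow each field's phenology.
- **FFP** (farmer's practice): the farmer's reported product applications
  taken verbatim; zinc only if the farmer reports applying it.

Trial evaluation computes per-treatment economics and the three pairwise
ANB contrasts; cohort summaries aggregate means and exceedance curves.

## 3. Synthetic cohort generator

The generator (`CohortSpec`, seeded via `numpy.random.default_rng`)
emulates the *population structure* of a multi-location on-farm trial
cohort, not any particular real dataset:

- 209 trials by default, split 108 kharif (wet) / 101 rabi (dry) across
  10 districts and 6 agro-climatic zones; 24 named varieties with
  durations 105–160 d (long-duration varieties kharif-only; rabi all
  irrigated).
- Recent yield `GY_R` ~ truncated Normal(4.4, 0.7) on [1.7, 6.3] Mg/ha;
  previous-crop yield set equal to `GY_R`.
- Farmer practice: urea-N drawn U(10, 104) kharif / U(14, 135) rabi,
  applied in 1–3 splits with probabilities (0.05, 0.20, 0.75); P as basal
  DAP with its N riding on top of the drawn urea-N (the ranges are chosen
  so *delivered* N season means land near 75/98 kg/ha); P drawn U(0, 40)
  / U(0, 52); K as basal MOP, U(0, 86) / U(0, 92); zinc applied with
  probability 0.05. Uniform draws within sub-ranges are a deliberate
  simplification — real practice is lumpier (bag-size quantization,
  local norms).
- 12% of fields transplant late (delay U(15, 35) days).

Yield is simulated from a linear-plateau response:

```
GY = clip( base + AE · FN_effective − zinc_penalty + ε ,  0, potential )
```

with field-specific agronomic efficiency `AE ~ U(0.010, 0.025)` Mg grain
per kg N, `base = max(0.3, GY_R − AE · typical_N)` (typical N 75 kharif /
98 rabi), `potential = GY_R + headroom`, `headroom ~ U(0.5, 2.5)`, noise
`ε ~ N(0, 0.3)`. `FN_effective` discounts N applied later than PI + 10
DAT by 50% and applies a 0.85 factor when more than half the N goes in
the first application — a coarse stand-in for timing losses. 30% of
fields are zinc-responsive with a 0.4 Mg/ha penalty if no zinc is
applied; frequency and magnitude are assumptions, not calibrated values.
A zero-noise test recovers the programmed AE by least squares to 0.1%.

Not emulated: weather, water stress, pests, prices varying by market,
spatial correlation between neighbouring fields, and within-season price
or labour dynamics.

## 4. Numerical and I/O choices

- Rates rounded to 0.1 kg/ha at the reporting layer only; internal
  arithmetic is unrounded. Split-sum and GRF-identity invariants are
  enforced in the models at 1e-6 / exactly.
- All randomness flows from a single `default_rng(seed)`; the CLI's
  cohort output is byte-identical under a fixed seed.
- Flat files are CSV with `#`-prefixed metadata headers (package version,
  seed, a 12-hex-digit SHA-256 config hash); configs are YAML mapping
  1:1 onto `EngineConfig`. Schema errors name the offending column and
  row.

## 5. Known limitations

- The mean zinc-sulfate share of fertilizer cost over the default cohort
  computes to ≈34% (seed-to-seed 33.5–34.4 at n = 209). Field programmes
  report nearer 32%. The gap traces to the literature-default internal
  efficiencies (`rie_p`, `rie_k`), which put the engine's P and K rates
  1–3 kg/ha below typical observed trial means, lowering TFC by ~3–4
  US$/ha and inflating the flat zinc cost's share. Recalibrating the
  efficiencies to a specific trial dataset would close it; the defaults
  are kept as published literature values.
- The N calibration is linear between anchors; response saturation is
  handled only by the target-yield cap, not by the rate curve itself.
- Phenology uses a single duration-based rule; photoperiod-sensitive
  varieties are not modelled.
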