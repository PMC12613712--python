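# Methods

## Scope and model

`cucurgrow` implements the yield-component decomposition used in
greenhouse cucumber growth analysis, together with a stochastic generator
of synthetic trials whose parameters are calibrated so the full pipeline
reproduces a reference set of cultivar-level aggregates. The generator is
deliberately the *minimal statistical inverse* of the estimators — no
mechanistic photosynthesis, energy balance or fruit-growth ODEs — so that
every derived quantity has a known ground truth and estimator bias can be
measured by simulation.

### Phenology

Thermal time is accumulated daily mean air temperature from a reference
day (default 38 DAT, base temperature 0 °C; the base is exposed as a
parameter but the reference analysis accumulates the plain daily
averages). Latent node number per stem is linear in thermal time from
38 DAT with slope NFR; before 38 DAT a slower linear establishment phase
connects the transplant node number (4) to the 38-DAT count (9). Observed
counts are rounded latent values (rounding is the only node-observation
noise). The NFR estimator divides each plant's final baseline-subtracted
count by its final accumulated temperature and averages across plants;
a windowed variant returns inter-observation finite differences, whose
AT-weighted mean telescopes to the same value.

### Canopy and light

Single-leaf area follows the cucumber allometry
`0.8072·W·L − 1.6083` (cm²; negative outputs for tiny leaves are clamped
to zero, which prevents a negative LAI from the intercept). LAI at a
measurement date is the mean per-stem summed leaf area times the stem
density (4.44 stems m⁻²; leaves are recorded per stem, so the stem
density — not the plant density — is the correct multiplier). Daily LAI
interpolates linearly between weekly measurements, extrapolates linearly
from (0, 0) before the first one, and is held constant after the last.
Interception is Beer–Lambert with transmission 0.51, PAR fraction 0.5 and
extinction coefficient 0.9; `estimate_k` inverts the same law from paired
above/below-canopy PAR readings (through-origin least squares of
−ln transmittance on LAI), which is the standard field method when no
protocol details are available.

### Biomass and partitioning

TDM at a destructive sampling is standing organ dry mass plus the
harvested-fruit and trimmed-leaf ledgers. Interval DM production
subtracts the *mean* TDM at the earlier timepoint from each later-sampled
plant (the trial's stated convention; plant-paired differences would have
lower variance but are not what the protocol computes). Fruit partition
fractions divide the interval's fruit DM (harvested in the interval plus
the change in on-plant fruit DM) by the interval's DM production; on-plant
fruit at a sampling counts toward cumulative fruit DM. LUE is ordinary
least squares of (TDM − initial dry weight) on cumulative intercepted
PAR through the origin — subtracting the initial dry weight is only
coherent with a zero intercept; a free-intercept fit is available via a
flag. Per-area scaling multiplies per-plant masses by stems m⁻² / stems
per plant.

### Yield

Harvested fruits with fresh weight strictly below 3.0 g count as aborted:
excluded from yield and fruit number, included in the abortion ratio and
the female flowering rate (total fruits per final node per stem).
Dry yield is fresh yield × fruit DM content; DM content is a configurable
input (0.0189 g g⁻¹ for the packaged scenarios, see below), not something
the pipeline estimates.

### Statistics

Tukey HSD (statsmodels) with a hand-implemented insert-and-absorb compact
letter display; LUE slope contrasts from a joint OLS model with per-group
intercepts and slopes, adjusted with the studentized range over the
number of groups; Pearson (optionally Spearman) correlations among yield
components with Benjamini–Hochberg adjustment over the upper triangle,
pooled by default over per-plant rows (plant-level values where they
exist, cultivar-level values broadcast otherwise; a per-cultivar-mean
pooling is available).

## The synthetic generator

One seeded generator per trial, with sub-streams derived per table and
per plant, so output is byte-identical under a fixed seed and adding
plants does not perturb existing ones.

**Climate.** In-house daily mean temperature is a seasonal sinusoid
(centre 22 °C, amplitude 3 °C, minimum at the winter solstice ≈ DAT 67
for an October transplant) plus N(0, 1.2 °C) noise, clipped to the
15/28 °C setpoints. Outside global solar radiation is a seasonal sinusoid
with mean-preserving multiplicative log-normal noise (σ = 0.30),
representing day-to-day cloudiness while keeping radiation non-negative
and cumulative totals unbiased. The sinusoid's mean level (8.495 MJ m⁻²
d⁻¹) is calibrated so that cumulative intercepted PAR under the default
canopy equals (TDM₂₂₈ − initial DW)/LUE for the vigorous scenario
(≈350 MJ m⁻²): the dry-matter bookkeeping is kept internally consistent
in preference to matching any one site's insolation records, since the
printed TDM and LUE values jointly pin down cumulative interception.

**Canopy and dry matter.** The latent daily LAI is the piecewise-linear
interpolation of a ramp-to-plateau design (plateau 2.4 m² m⁻² for all
cultivars) through the weekly measurement grid — defined through the same
interpolation rule the estimator uses, so noise-free recovery is exact.
Each cultivar's ramp duration is solved (Brent) so its cumulative
interception matches (TDM₂₂₈ − initial DW)/LUE; slower cultivars build
leaf area more slowly. Latent per-area TDM is initial DW + LUE ×
cumulative interception under the *realized* (noisy) climate, so the LUE
estimator is exactly consistent while absolute TDM carries the season's
weather. Cumulative fruit DM applies the per-term partition schedule to
TDM increments; the trimmed-leaf ledger removes a fixed share (0.25) of
post-plateau vegetative DM; standing organs are the remainder, split
60/40 into leaf and stem. Mass is conserved exactly before observation
noise.

**Fruit set and fresh weights.** Nodes from position 3 (the lowest two
are deflowered, standard practice) set a fruit with the scenario's
flowering probability; a set fruit aborts (< 3 g) with the abortion
probability. A fruit is harvested a fixed 200 °C·d after its node forms,
but no earlier than 39 DAT, when commercial harvest begins (fruits
maturing earlier are picked on the first harvest day). Each kept fruit's
fresh weight is the increment of the per-stem cumulative fruit-DM curve
since the stem's previous kept harvest, divided by fruit DM content —
making fresh yield, the partition fractions and the cumulative fruit
fraction mutually consistent by construction — plus N(0, 15 g)
observation noise (floored at the 3 g threshold: a kept, marketable fruit
is at least threshold-weight by definition). The calibration adds the
expected post-final-harvest fruit-DM tail (about half an inter-harvest
interval) to the partition target so the expected realized yield equals
the target.

**Observation noise defaults** (all configurable per scenario): node
counts rounded; leaf dimensions CV 5 %; organ and trimmed-leaf dry
weights CV 10 %; fruit fresh weight SD 15 g. `scenario.noiseless()`
switches everything off (and disables rounding) for exactness tests.

## Scenario calibration

The packaged scenarios anchor to: NFR 0.022 ('josho') vs 0.015 (others);
LUE 4.26/4.08/4.07/3.86 g MJ⁻¹ ('s30'/'gflush'/'josho'/'yusho'); TDM₂₂₈
1484/1431/1329 g m⁻² ('s30'/'josho'/'yusho'); fresh yield 36.3 ('josho')
and 28.1 kg m⁻² ('yusho'); abortion 7.4 % ('josho') vs ≤ ~1 %; 'josho'
first-term partition 0.15 (0.20 for the others) and cumulative fruit
fraction 0.48. Unanchored cells are filled consistently: 's30'/'gflush'
fresh yields 31.5/30.0 kg m⁻² (preserving the cultivar ordering and
fruit numbers ≈300 m⁻² or fewer, 18–26 % below 'josho'); 'gflush' TDM
emerges from its LUE and the shared canopy (≈1434 g m⁻²); mean fruit
weights 100/115/110/104 g (the vigorous cultivar bears slightly smaller
fruit; the slower ones have higher per-fruit sink strength). Fruit DM
content is the algebraic consistency value 0.48 × 1431 / 36300 ≈
0.0189 g g⁻¹, shared by all cultivars. From these, the calibration solves
deterministically: the LAI ramp per cultivar, the late-term partition
fraction (≈0.52 'josho', ≈0.43 others), and the per-node flowering
probability (0.96–0.97), asserting all probabilities stay in (0, 1).

## Problem sizes and numerics

Default cohorts mirror the trial protocol: 9 harvest plants, 6
growth-analysis plants, 3 leaf-measurement plants, 3 destructive plants
at each of DAT 0/45/66/105/142 with the 9 harvest plants sampled at 228.
One full trial simulates and analyzes in well under a second; the test
suite's replicated-recovery study uses 100 replicates. Ties and
degenerate inputs: observations between climate days interpolate AT
linearly; a missing 38-DAT node baseline falls back to the nearest
observation within ±3 days, else the plant is dropped with a warning;
partition fractions with non-positive DM production are reported missing
rather than raising; a DAT-0 fruit fraction is 0 by convention; constant
columns yield missing correlations.

## What passing tests do and do not show

The generator reproduces the estimators' data-generating assumptions by
construction, plus realistic observation noise. Recovery therefore
demonstrates the pipeline's correctness and its sampling behaviour at
trial-realistic n — not robustness to model misspecification in real
data: real canopies violate the ramp-plateau LAI shape, real fruit growth
responds to source–sink dynamics and temperature rather than a fixed
partition schedule, harvest weights are not exchangeable increments of a
smooth DM curve, and real climates have autocorrelated weather. The
abortion and flowering processes are independent Bernoulli draws per
node, with no premature fruits (the event schema reserves the flag).
Within-cultivar plant-to-plant variation in latent growth is not
modelled; all biological spread comes from fruit set, observation noise
and (across seeds) weather.
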