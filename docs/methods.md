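# Methods

## Model

The package decomposes the change in sex-stratified hip-fracture counts
between a baseline year (BY) and an end year (EY) with a deterministic
comparative risk-assessment model. All calculations are made separately per
sex stratum and then summed; rates are carried per 10,000 person-denominator
throughout, prevalences as proportions in [0, 1] (sources that print
percentages are converted on transcription, and every run log notes the
convention).

**Expectation stage.** The baseline incidence rate `r(BY) = NO(BY)/pop(BY) ×
10,000` is applied to the end-year population to give the expected count
`NE = r(BY)·pop(EY)/10,000`, rounded half-away-from-zero per stratum and
summed (round-then-sum: with the packaged Romania scenario this reproduces
7391 + 4581 = 11,972 exactly). The excess to explain is `NO(EY) − NE`, signed.
A scenario may pin `r(BY)` to a published rounded value (the Romania fixture
pins 6.5 and 3.87; the recomputed ratios are 6.509 and 3.878) because the
published downstream numbers were produced from the printed rates.

**Attribution stage.** Each binary exposure contributes
`NX_i = NE·(PARF(EY) − PARF(BY))` with `PARF = P(RR−1)/(P(RR−1)+1)`. The sign
convention is *generated-positive*: a positive contribution means the
prevalence change generated fractures. The opposite orientation (difference
taken BY − EY, positive meaning prevented) appears in parts of the source
literature; this package standardises on the orientation used by the published
result tables and records the convention in every result and run log.

**Overlap adjustment.** Individual attributions overlap, so the component
subtotals are scaled by `AF = CR/AR`, `CR = 1 − Π(1−R_i)`, `AR = ΣR_i`. The
source model never defines `R_i` operationally; the default here is
`R_i = |PARF(EY) − PARF(BY)|` per factor — the magnitude that actually flows
through the attribution — pooled across strata by expected-count weighting.
That pooling gives the clean identity `AF·ΣNX_i = ΣNE·CR` whenever all
contributions share a sign. An alternative interpretation (`parf_ey`, the
end-year PARF magnitude) is selectable in the scenario options and recorded
in the output. AF is applied to the risk/preventive and drug-class subtotals,
never to the medication component. `CR` is computed via `log1p`/`expm1` so
that AF → 1 correctly for very small magnitudes, and AF is exactly 1 for a
single factor (where CR ≡ AR).

**Medication component.** `NX_med = −OM·ΔRR_OM·r_OP/10,000` per stratum with
`OM` the end-year treated-patient count and `r_OP` the end-year population
rate times the osteoporosis relative risk. The population rate used inside
this chain is unrounded; two-decimal rounding is applied only at the display
boundary (the medication CSV shows the rounded osteoporosis rates, e.g. 41.60
and 64.77 per 10,000 for Romanian women). Baseline user counts are carried in
the scenario for reporting but do not enter the default formula.

## Two aggregation tracks

Published national decompositions of this kind rest on internal age-stratified
expected counts and medication user counts that their summary tables do not
print. Per-row attributions recomputed from the printed sex-level inputs
therefore cannot match the published rows (back-calculation from the Romania
rows implies effective stratified expected counts roughly 4x the printed
sex-level NE). The pipeline handles this honestly with two tracks, both
reported when possible:

- **published** — aggregates the reported per-row values carried as
  annotations by an annotated scenario. For the Romania fixture this
  reproduces every printed total exactly: medication −733 (−15.4%), risk and
  preventive factors 4376, drug side effects 644, overall 4287 = 90.1% of the
  4760 excess. AF is computed and reported but not applied, since the
  reported rows already sum to their reported totals.
- **equations** — recomputes every row from prevalences and relative risks as
  described above. On the Romania fixture this gives a very different picture
  (net −654 explained), dominated by the protective relative risks printed
  for BMI (0.66/0.76) and physical activity (0.87) acting on *rising*
  prevalences — a sign structure the published rows do not follow. The
  divergence is a property of the published inputs, not of this
  implementation; noise-free synthetic scenarios are recovered exactly.

Scenarios without reported annotations (all synthetic ones) run the equations
track only; requesting both logs that the published track was skipped.

## Sensitivity analysis

Every parameter entering the model — per-sex prevalences at BY and EY,
relative risks (one parameter when shared across sexes), end-year medication
users, relative risk reduction, osteoporosis relative risks — receives bounds:
a supplied 95% CI where present, otherwise ±20% of the central value, with
proportion-valued parameters clipped to [0, 1]. Parameters are varied jointly
to their extremes (corner semantics), not one-at-a-time:

- *enumeration* evaluates all `2^k` corners, limited to `k ≤ 20`;
- *monotone* probes each parameter once against the central configuration to
  find its direction of effect on the modeled excess, then evaluates the
  joint maximising and minimising assignments (2k + 2 model evaluations).

Both modes include the central evaluation among the candidates, so the
reported bracket always contains the best estimate; on models where every
parameter acts monotonically the two modes coincide with pure corner extremes
(property-tested). Correlated bounds — e.g. the BY and EY prevalence of the
same factor — are varied independently, which can produce corners (BY above
EY) that a correlated treatment would exclude; this is a documented
limitation and one reason the monotone Romania bracket is wide. A
one-at-a-time tornado table is emitted as a diagnostic, and per-component
ranges are computed by enumerating each factor's own parameter corners with
all others held central.

## Uncertainty statistics

Expected counts carry Poisson intervals: exact Garwood inversion of the tail
probabilities via the chi-square quantile identity by default (verified in
tests against brute-force probability-mass summation), or the normal
approximation `mean ± z√mean` by option; the two agree within 2% relative
width for means ≥ 1000. A chi-square goodness-of-fit statistic
`Σ(O−E)²/E` with `df = strata − 1` compares observed and expected end-year
counts. The Romania strata give χ² ≈ 2386.9 (df = 1); the value printed in
the source (392.6) is not reconstructible from any printed cell combination
and is not forced. Likewise the printed expected-count confidence limits
match neither the exact nor the normal method and are not replicated
bit-for-bit, and the published extremes pair (3189/5902) is not a
reproduction target — the corner assignment behind it is unstated. These
quantities are covered instead by property-based checks (recovery, mode
agreement, analytic PARF/AF properties, interval-oracle agreement).

## Synthetic data

`generate_scenario(seed, n_factors, n_meds, pop_scale)` builds two-stratum
scenarios: populations near `pop_scale` (default 5 million per stratum, the
order of a national sex stratum), baseline rates uniform in [2, 12] per
10,000 (the range spanned by the fixture's strata), prevalences uniform in
[0.02, 0.8] with the end-year value shifted by a uniform delta in
[−0.15, 0.15] (clipped to [0, 1]), relative risks log-uniform in [0.5, 2.0]
(the span of the fixture's factor RRs), medication users uniform in
[1000, 50,000] with relative risk reduction in [0.2, 0.8] and osteoporosis
relative risks in [2, 8]. Every third factor is a drug class so both
component groups are exercised. All randomness flows through one
`numpy.random.Generator` seeded explicitly; no global state.

The end-year observed counts are constructed by the forward model itself:
`observed = (NE + AF·Σ injected)/(1 + k)` with
`k = Σ users_EY·rrr·osteo_RR/pop_EY`, the closed-form fixed point of the
medication term's dependence on the end-year rate. Because ground truth and
engine share the same equations, noise-free recovery (exact per-factor
contributions, percent explained = 100% to 1e−9 relative, over 100 seeds)
tests plumbing, sign conventions and the adjustment pathway — not the
epidemiological validity of the model on real data. Real scenarios add
transcription error, non-binary and correlated exposures, lag between
exposure change and event change, and age structure, none of which the
generator emulates. `add_poisson_noise` replaces the noise-free counts with
Poisson draws; the recovered percent explained is then unbiased with spread
`√(total counts)/excess`, which the suite checks on a signal-dominant
scenario (injected excess ≥ 10% of total counts, selected by that input-side
criterion) at 200 replicates.

## Numerical choices and degenerate inputs

- Rounding is half-away-from-zero everywhere a value is displayed (rates 2
  decimals, percentages 1); internal arithmetic is unrounded except the
  per-stratum integer rounding of NE, which is part of the model definition.
- `PARF` rejects inputs where `P(RR−1)+1 ≤ 0` (reachable only by float
  underflow at P = 1, RR → 0) as invalid rather than returning a value past
  the pole.
- `AF` with all-zero magnitudes is defined as 1 by continuity and logged.
- A zero total excess makes percent-explained undefined; the decomposition
  still returns all counts, flags the situation, and percent is NaN.
- Scenario totals are computed from the scenario's own strata. Published
  summary rows are not always self-consistent (the Romania source prints a
  total end-year population that is not the sum of its printed stratum
  populations); the fixture keeps the stratum values its own row-level
  numbers require, and the pipeline's total row reports the self-consistent
  sums.
- Problem sizes in the test suite (3-factor synthetic scenarios, 100 recovery
  seeds, 200 noise replicates, ≤ 9-parameter enumeration toys) keep the whole
  suite within a few seconds while exercising every code path; they are the
  package's own choice of test scale.

## Known limitations

- The model is deterministic and additive at the component level; no Monte
  Carlo propagation, no lag-time modelling, no age standardisation, no
  mediation (e.g. bone mineral density) modelling.
- `R_i` pooling across strata and the AF application scope are necessarily
  design choices where the source model is silent; both are recorded in every
  result and switchable where alternatives are plausible.
- Extremes analysis treats parameters as independent at their bounds; the
  monotone mode is exact only for monotone response, otherwise it is a
  heuristic bracket (the enumeration mode is exact but exponential).
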