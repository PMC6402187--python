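# Methods

## Model

trialflow is a closed-form decision-analytic model of staged efficacy
testing. Each candidate treatment is either truly effective or truly
ineffective; each development phase is a hypothesis test that an
effective treatment passes with the phase's composite power and an
ineffective one passes with its composite type-I error rate. A phase
with `k` independent confirmatory trials that must all succeed has
composite α = α_trial^k and composite power = power_trial^k; phase III
defaults to k = 2 at α = 5% / power 90% per trial (composite 0.25% /
81%). Failures exit permanently — there is no re-testing — and safety,
pharmacokinetics and strategic attrition are deliberately outside the
model: it isolates efficacy testing as the driver of attrition.

Expected counts are continuous reals. All derived quantities (false
negatives, productivity = true positives / effective entrants, and so
on) are deterministic functions of (α₂, 1−β₂, p_eff, N) given the fixed
phase III design.

### Printed-rounding convention

Published tables of this kind round expected counts half-up to one
decimal and then form percentages *from the rounded counts*
(e.g. productivity 10.1/25 = 40.4% rather than the exact
10.125/25 = 40.5%). `mode="printed"` reproduces that convention
end-to-end; `mode="exact"` (the computational default) never rounds.
One derived figure cannot be reproduced under any rounding direction we
tested (the status-quo share of phase III entrants passing phase III:
10.1/16.3 = 61.96% prints as 62.0 here); we treat that as a display
artefact, not model content.

## Power and sample size

The two-arm normal approximation: power = 1 − Φ(z_crit − ES·√(n/2))
with per-arm sample size n, standardized effect size ES and z_crit the
per-trial critical value (z_{1−α/2} two-sided by default; one-sided is a
flag). The vanishing far-tail term of the two-sided test is ignored, as
usual in design calculations (the test suite bounds the discrepancy
against an independent solver at <10⁻³). The reference calibration is a
200-participant (100/arm) phase II study with 50% power at α = 5%
two-sided, i.e. ES ≈ 0.277.

Because ES cancels in sample-size ratios, cost scaling across phase II
designs needs no effect-size input:
ratio = ((z_{1−α/2} + z_{1−β}) / (1.96 + 0))². Quantiles are rounded to
two decimals by default (`z_rounding="two_decimals"`), the convention
that makes the high-power scenario's phase II program cost come out at
4000 × (1.96+0.84)²/1.96² = $8,163M; full precision is a flag.

## Economics

* Phase II: all N candidates are tested; program cost =
  N × $40M × (cost_per_participant / $200,000) × cost multiplier, where
  the multiplier applies the economies-of-scale factor `e` to the
  incremental part of the sample-size ratio: `1 + e·(ratio − 1)` for
  ratio > 1.
* Phase III: $163M per entrant, scenario-invariant (the phase III design
  never changes), scaled by the same unit participant cost.
* Return: $2,500M per treatment passing phase III, either class, using
  exact unrounded expected counts — this reproduces the published
  returns to the $M ($40,523M / $25,317M / $48,188M).
* "Adjusted" analyses: a phase II effect-size multiplier m ≥ 1
  (surrogate endpoints, enriched populations) divides the phase II
  sample-size ratio by m²; m = √2 exactly halves the phase II bill.

### The economies-of-scale inconsistency

The source analyses state an 80% economies-of-scale correction, yet the
printed high-power phase II cost ($8,163M) equals the *uncorrected*
ratio times $4,000M, while the grid-search optimum (α = 20%, power 95%)
and the dominance of that scenario across participant costs are
reproduced **only with** the 0.8 correction (under e = 1 the optimum
moves to α = 30% and the high-power scenario overtakes at high unit
costs). The two layers evidently used different conventions. trialflow
therefore defaults the tabulated economics to e = 1 (reproducing the
printed cost) and the search grid and sweep helpers to e = 0.8
(reproducing the optimum and the dominance pattern). Both are plain
`CostModel` fields; every output bundle records the values used.

## Grid search and sweeps

The default grid crosses α₂ ∈ {1, 5, 10, 20, 30}% — the plotted
profit-vs-power line set — with power 50–99% in 1% steps. The optimum is
the grid cell with maximal expected profit; ties break to the lowest
alpha, then the lowest power. The optimum is grid-restricted; no claim
of a continuous maximum is made. (A finer alpha axis shifts the argmax
to neighbouring cells — e.g. α = 25% edges out 20% by ~0.1% of profit —
so the reported optimum should be read at the resolution of the grid.)

Sweeps vary one parameter: cost-per-participant (default $100k–$400k,
the unit cost scaling both phase program costs, so profit → expected
return as the unit cost → 0) or p_eff. Phase III per-trial power is
selectable (0.80/0.90) for the cost sweep.

## Probabilistic sensitivity analysis

`run_psa` samples, per Monte Carlo draw: an effect-size multiplier,
p_eff, cost-per-participant and return-on-success, holding each
scenario's α/β fixed, and pushes every draw through flow + economics for
every scenario. Defaults (10,000 draws, portfolios of 100):

| input | distribution | rationale |
|---|---|---|
| effect multiplier | Normal(1, 0.15) truncated > 0.5 | ±15% design-stage uncertainty about ES |
| p_eff | Beta(5, 15) | mean 0.25, mass on 10–45% |
| cost/participant | Uniform($100k, $400k) | the swept cost range |
| return/success | LogNormal(median $2,500M, CV 0.5) | right-skewed commercial value |

These emulate parameter uncertainty only; the upstream provenance of any
particular published interval is not reproducible, so PSA conclusions
here are property-level (profit ordering, overlap, correlation signs),
never interval-matching. The effect multiplier m rescales required
sample sizes — hence both phase program costs — by 1/m² (a global
true-effect perturbation; the deterministic "adjusted" multiplier, by
contrast, is phase-II-only by construction).

By default each draw uses the *expected-count* flow, so point-mass
inputs collapse the PSA exactly onto the deterministic profits (a
degeneracy check the suite enforces at 10⁻⁶). `portfolio_sampling=True`
additionally realizes each draw as binomial pass/fail counts of a
finite 100-candidate cohort (first-order noise); the binomial sampler is
validated against expected counts at 10⁵ replicates. Scenario
comparisons are paired through the shared input draws (the dominant
variance component); portfolio noise, when enabled, uses per-scenario
`SeedSequence` children of the root seed, so results are bit-reproducible
for a given seed. Associations between inputs and paired profit
differences use Spearman rank correlation (several inputs are skewed);
degenerate inputs yield NaN rather than an error.

## Numerical choices

* Half-up decimal rounding via `decimal.Decimal` on the float's shortest
  repr (banker's rounding would print 16.25 as 16.2, breaking the table
  convention).
* Sample-size inversion uses the closed form with a one-step minimality
  correction, guarding against float slop at exact-integer solutions.
* Comparisons against a zero baseline return NaN, flagged not raised.
* Expected-count conservation identities hold exactly by construction
  (failures are stored as differences, not separately).

## What the simulations do and do not show

The generator emulates idealized efficacy-only attrition with a
homogeneous effect size, independent trials and a two-class (effective /
ineffective) world. Real portfolios have graded effect sizes, correlated
endpoints between phases, safety- and strategy-driven stops, and
per-area heterogeneity in p_eff and costs — none of which are modelled.
Passing tests therefore demonstrate internal consistency of the
decision-analytic arithmetic and robustness to the sampled parameter
ranges, not predictive validity for any particular development program.
Cost figures are stylized sector averages; the profit surface should be
read comparatively (which designs beat which), not as absolute forecasts.
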