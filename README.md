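# trialflow

**trialflow** simulates the passage of candidate treatments through staged
clinical development (phase II → phase III) to quantify the burden of
*false negatives* — effective treatments wrongly screened out by
underpowered early-phase trials — and its economic consequences. It is
aimed at quantitative scientists in drug development, health economics and
meta-research who want to explore how the choice of type-I error (α) and
power (1−β) at phase II shapes portfolio productivity and profit.

## The model

A portfolio of `N` candidates (default 100) enters phase II; a fraction
`p_eff` (default 25%) is truly effective. Phase II is a single trial with
thresholds (α₂, 1−β₂); phase III requires two independent confirmatory
trials, each at α = 5% and power 90%, so its composite operating
characteristics are α₃ = 0.05² = 0.25% and power 0.9² = 81%. Expected
counts propagate as

```
effective passers   = N·p_eff·(1−β₂)·(1−β₃)
ineffective passers = N·(1−p_eff)·α₂·α₃
```

and classify into true/false positives/negatives. Power follows the
two-arm normal approximation

```
power = 1 − Φ( z_{1−α/2} − ES·√(n/2) ),    n/arm = 2 (z_{1−α/2} + z_{1−β})² / ES²
```

with ES the standardized effect size (μ₁−μ₀)/σ. Because ES cancels in
sample-size *ratios*, phase II program costs scale across designs as
`((z_{1−α/2}+z_{1−β}) / (z_ref_α+z_ref_β))²` relative to the reference
design (α = 5%, power 50%; a $40M, 200-participant program at $200,000 per
participant). Phase III costs $163M per entrant; every phase III passer
returns $2,500M. On top of the deterministic layer sit a grid search over
phase II (α, power) and a Monte Carlo probabilistic sensitivity analysis
that samples effect size, `p_eff`, participant cost and return on success.

## Worked example

```python
from trialflow import default_scenarios, run_flow, productivity_metrics, classify_outcomes

flows = {s.name: run_flow(s) for s in default_scenarios()}
base = flows["Scenario 1"]                      # phase II: alpha 5%, power 50%
m1 = productivity_metrics(base, mode="printed")
m2 = productivity_metrics(flows["Scenario 2"], baseline=base, mode="printed")
print(m1.productivity_pct, classify_outcomes(base, mode="printed").false_negatives)
print(m2.productivity_pct, m2.productivity_change_pct)
```

prints

```
40.4 14.9
64.8 60.4
```

Under the status-quo design only 40.4% of the 25 truly effective
candidates survive both phases — 14.9 effective treatments are lost as
false negatives. Raising phase II power to 80% (Scenario 2) lifts
productivity to 64.8%, a 60.4% relative gain. The economic layer prices
that gain: `trialflow econ` tabulates, per scenario, phase II/III costs,
expected return and profit ($M):

```
  scenario  pass_phase2_pct  productivity_pct  false_negatives  cost_phase2  cost_phase3  expected_return       profit
Scenario 1             16.3              40.4             14.9  4000.000000      2648.75       25335.9375 18687.187500
Scenario 2             23.8              64.8              8.8  8163.265306      3871.25       40523.4375 28488.922194
Scenario 3             13.3              40.4             14.9  6930.862141      2159.75       25317.1875 16226.575359
Scenario 4             38.8              76.8              5.8  8877.967514      6316.25       48187.5000 32993.282486
```

(columns abridged; the command also prints the share of phase III
entrants that are effective and the changes vs Scenario 1)

Scenario 2's doubled phase II bill ($8,163M) buys $40,523M of expected
return. The grid search (`trialflow surface`) locates the most profitable
phase II design at α = 20%, power = 95% (Scenario 4), and
`trialflow psa` propagates input uncertainty through all four scenarios,
reporting profit distributions and the rank correlations of each
scenario's profit advantage with the sampled inputs. See
`docs/methods.md` for the model's assumptions, conventions and
limitations.

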