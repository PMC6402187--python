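"""Expected-count pipeline propagation and outcome classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialflow import (
    Scenario,
    StageDesign,
    classify_outcomes,
    productivity_metrics,
    run_flow,
)
from trialflow.rounding import round_half_up


def _printed_cells(flow):
    r = round_half_up
    return {
        "eff_pass2": r(flow.eff_pass2),
        "eff_fail2": r(flow.eff_fail2),
        "eff_pass3": r(flow.eff_pass3),
        "eff_fail3": r(flow.eff_fail3),
        "ineff_pass2": r(flow.ineff_pass2),
        "ineff_fail2": r(flow.ineff_fail2),
        "ineff_pass3": r(flow.ineff_pass3),
        "ineff_fail3": r(flow.ineff_fail3),
    }


class TestRunFlow:
    def test_status_quo_phase2(self, flows):
        f = flows["Scenario 1"]
        assert f.eff_pass2 == pytest.approx(12.5)
        assert f.ineff_pass2 == pytest.approx(3.75)
        assert round_half_up(f.ineff_pass2) == 3.8

    def test_status_quo_phase3(self, flows):
        f = flows["Scenario 1"]
        assert f.eff_pass3 == pytest.approx(10.125)
        assert round_half_up(f.eff_pass3) == 10.1
        assert round_half_up(f.eff_fail3) == 2.4

    def test_certainty_case_all_pass(self):
        scen = Scenario(
            "sure thing",
            phase2=StageDesign(0.05, 0.999999),
            phase3=StageDesign(0.05, 0.999999, n_trials=2),
            p_eff=1.0,
            n_candidates=50,
        )
        f = run_flow(scen)
        assert f.eff_pass3 == pytest.approx(50.0, abs=1e-3)

    def test_printed_table_all_scenarios(self, flows):
        # the published passage-through-the-pipeline grid
        expected = {
            "Scenario 1": dict(
                eff_pass2=12.5, eff_fail2=12.5, eff_pass3=10.1, eff_fail3=2.4,
                ineff_pass2=3.8, ineff_fail2=71.3, ineff_pass3=0.0, ineff_fail3=3.7,
            ),
            "Scenario 2": dict(
                eff_pass2=20.0, eff_fail2=5.0, eff_pass3=16.2, eff_fail3=3.8,
                ineff_pass2=3.8, ineff_fail2=71.3, ineff_pass3=0.0, ineff_fail3=3.7,
            ),
            "Scenario 3": dict(
                eff_pass2=12.5, eff_fail2=12.5, eff_pass3=10.1, eff_fail3=2.4,
                ineff_pass2=0.8, ineff_fail2=74.3, ineff_pass3=0.0, ineff_fail3=0.7,
            ),
            "Scenario 4": dict(
                eff_pass2=23.8, eff_fail2=1.3, eff_pass3=19.2, eff_fail3=4.5,
                ineff_pass2=15.0, ineff_fail2=60.0, ineff_pass3=0.0, ineff_fail3=15.0,
            ),
        }
        for name, cells in expected.items():
            assert _printed_cells(flows[name]) == cells, name


class TestClassification:
    def test_status_quo_printed_confusion(self, flows):
        c = classify_outcomes(flows["Scenario 1"], mode="printed")
        assert c.true_positives == 10.1
        assert c.false_negatives == 14.9
        assert c.false_positives == 0.0
        assert c.true_negatives == 75.0

    def test_high_power_false_negative_total(self, flows):
        # 5.0 lost at phase II + 3.8 at phase III
        c = classify_outcomes(flows["Scenario 2"], mode="printed")
        assert c.false_negatives == pytest.approx(8.8)

    def test_partition_sums_to_portfolio(self, flows):
        for f in flows.values():
            c = classify_outcomes(f)
            assert c.total == pytest.approx(100.0, abs=1e-9)


class TestProductivityMetrics:
    def test_high_power_productivity_exact(self, flows):
        m = productivity_metrics(flows["Scenario 2"])
        assert m.productivity_pct == pytest.approx(64.8, abs=1e-9)

    def test_change_vs_status_quo_printed(self, flows):
        m = productivity_metrics(
            flows["Scenario 2"], baseline=flows["Scenario 1"], mode="printed"
        )
        assert m.productivity_change_pct == 60.4

    def test_self_baseline_is_zero_change(self, flows):
        f = flows["Scenario 1"]
        assert productivity_metrics(f, baseline=f).productivity_change_pct == pytest.approx(0.0)

    def test_mismatched_candidate_mix_rejected(self, flows):
        other = run_flow(
            Scenario("odd", StageDesign(0.05, 0.5), p_eff=0.10, n_candidates=100)
        )
        with pytest.raises(ValueError, match="candidate mix"):
            productivity_metrics(flows["Scenario 1"], baseline=other)

    def test_productivity_increasing_in_power_and_alpha_free(self):
        base = dict(phase3=StageDesign(0.05, 0.9, 2), p_eff=0.25, n_candidates=100)
        prods, fps = [], []
        for power in (0.5, 0.6, 0.7, 0.8, 0.9):
            for alpha in (0.01, 0.05, 0.2):
                f = run_flow(Scenario("g", StageDesign(alpha, power), **base))
                prods.append((power, alpha, productivity_metrics(f).productivity_pct))
                fps.append((power, alpha, f.ineff_pass3))
        # same power, different alpha -> same productivity
        by_power = {}
        for power, alpha, p in prods:
            by_power.setdefault(power, set()).add(round(p, 12))
        assert all(len(v) == 1 for v in by_power.values())
        # strictly increasing in power
        seq = sorted(by_power)
        vals = [next(iter(by_power[p])) for p in seq]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        # false-positive count independent of phase II power
        by_alpha = {}
        for power, alpha, fp in fps:
            by_alpha.setdefault(alpha, set()).add(round(fp, 12))
        assert all(len(v) == 1 for v in by_alpha.values())


@st.composite
def random_scenarios(draw):
    return Scenario(
        name="random",
        phase2=StageDesign(
            draw(st.floats(min_value=0.001, max_value=0.5)),
            draw(st.floats(min_value=0.05, max_value=0.99)),
        ),
        phase3=StageDesign(
            draw(st.floats(min_value=0.001, max_value=0.5)),
            draw(st.floats(min_value=0.05, max_value=0.99)),
            n_trials=draw(st.integers(min_value=1, max_value=3)),
        ),
        p_eff=draw(st.floats(min_value=0.0, max_value=1.0)),
        n_candidates=draw(st.integers(min_value=1, max_value=1000)),
    )


class TestConservationProperties:
    @given(random_scenarios())
    @settings(derandomize=True, max_examples=1000, deadline=None)
    def test_flow_and_classification_conservation(self, scen):
        f = run_flow(scen)
        n = scen.n_candidates
        assert f.eff_enter + f.ineff_enter == pytest.approx(n, abs=1e-9)
        for enter, p, fail in (
            (f.eff_enter, f.eff_pass2, f.eff_fail2),
            (f.eff_pass2, f.eff_pass3, f.eff_fail3),
            (f.ineff_enter, f.ineff_pass2, f.ineff_fail2),
            (f.ineff_pass2, f.ineff_pass3, f.ineff_fail3),
        ):
            assert p + fail == pytest.approx(enter, abs=1e-9)
            assert p >= 0 and fail >= -1e-12
        c = classify_outcomes(f)
        assert c.true_positives + c.false_negatives == pytest.approx(
            scen.p_eff * n, abs=1e-9
        )
        assert c.false_positives + c.true_negatives == pytest.approx(
            (1 - scen.p_eff) * n, abs=1e-9
        )


class TestMonteCarloOracle:
    def test_million_candidate_simulation_matches_expectation(self, scenarios):
        # independent per-candidate Bernoulli simulation, not the package's
        # portfolio sampler
        rng = np.random.default_rng(20170704)
        n = 1_000_000
        for scen in scenarios:
            f = run_flow(scen)
            eff = rng.random(n) < scen.p_eff
            pw2, a2 = scen.phase2.power_composite, scen.phase2.alpha_composite
            pw3, a3 = scen.phase3.power_composite, scen.phase3.alpha_composite
            p2 = np.where(eff, pw2, a2) > rng.random(n)
            p3 = p2 & (np.where(eff, pw3, a3) > rng.random(n))
            scale = n / scen.n_candidates
            for observed, expected in (
                ((eff & p2).sum(), f.eff_pass2 * scale),
                ((eff & p3).sum(), f.eff_pass3 * scale),
                ((~eff & p2).sum(), f.ineff_pass2 * scale),
                ((~eff & p3).sum(), f.ineff_pass3 * scale),
            ):
                se = np.sqrt(expected * max(1e-12, 1 - expected / n))
                assert abs(observed - expected) <= 3 * max(se, 1.0), scen.name
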