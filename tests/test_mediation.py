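"""Joint-significance mediation framework: path evidence, precedence grading
and the combined verdict."""

import numpy as np
import pytest

from scedmed import (CrossLagResult, MediationConfig, PathEvidence, SCEDDataset,
                     SynthConfig, ValidationError, assess_temporal_precedence,
                     combine_verdict, evaluate_a_path, evaluate_b_path,
                     fit_piecewise, generate_sced, mediation_report)
from scedmed.mediation import PathTest

from conftest import make_series


DIRS = {"mediator": +1, "outcome": -1}


def shifted_dataset(shift_sign=+1, seed=0, n=20, noise=0.3):
    """Mediator with a clean level shift at the boundary; outcome flat noise."""
    rng = np.random.default_rng(seed)
    phase = np.array(["B"] * n + ["C"] * n, dtype=object)
    med = np.concatenate([rng.normal(2, noise, n),
                          rng.normal(2 + 3 * shift_sign, noise, n)])
    out = rng.normal(5, noise, 2 * n)
    return SCEDDataset(make_series(med, phase, name="m"),
                       make_series(out, phase, name="y"),
                       hypothesized_direction=dict(DIRS))


def make_crosslag(sig_lags, r_sign=-1, max_lag=5):
    lags = list(range(-max_lag, max_lag + 1))
    r = {k: (0.6 * r_sign if k in sig_lags else 0.05) for k in lags}
    p = {k: (0.001 if k in sig_lags else 0.8) for k in lags}
    return CrossLagResult(lags, r, {k: 40 for k in lags}, p=dict(p),
                          p_adjusted=dict(p), reps=1000)


class TestAPath:
    def test_clean_level_shift_detected(self):
        ev = evaluate_a_path(shifted_dataset(+1, seed=1))
        assert ev.significant and ev.direction_ok

    def test_detection_rate_high_over_replicates(self):
        hits = sum(evaluate_a_path(shifted_dataset(+1, seed=s)).significant
                   for s in range(300))
        assert hits / 300 >= 0.95

    def test_opposite_shift_fails_direction_gate(self):
        ev = evaluate_a_path(shifted_dataset(-1, seed=2))
        # the level change is large and its p tiny, but the sign is wrong
        assert any(t.p_value < 0.05 for t in ev.tests)
        assert not ev.significant

    def test_corrected_tau_added_only_with_significant_baseline_trend(self):
        rng = np.random.default_rng(3)
        phase = np.array(["B"] * 15 + ["C"] * 15, dtype=object)
        med = np.concatenate([np.arange(15) * 0.4 + rng.normal(0, 0.2, 15),
                              rng.normal(9, 0.2, 15)])
        out = rng.normal(5, 0.3, 30)
        ds = SCEDDataset(make_series(med, phase, name="m"),
                         make_series(out, phase, name="y"),
                         hypothesized_direction=dict(DIRS))
        names = [t.name for t in evaluate_a_path(ds).tests]
        assert any(n.startswith("tau_between_corrected") for n in names)
        names_flat = [t.name for t in
                      evaluate_a_path(shifted_dataset(+1, seed=4)).tests]
        assert not any(n.startswith("tau_between_corrected")
                       for n in names_flat)


class TestBPath:
    def test_lagged_negative_effect_gives_leading_support(self):
        cfg = SynthConfig(a_level=0, a_trend=0, b=-0.8, lag=3,
                          sd_m=1.0, sd_y=0.3, phi_m=0.0, phi_y=0.0,
                          phase_lengths=(30, 30), seed=11)
        ds, _ = generate_sced(cfg)
        ev = evaluate_b_path(ds, reps=500, seed=12)
        assert ev.significant
        assert any("leading support" in n for n in ev.notes)

    def test_wrong_sign_association_gated_out(self):
        cfg = SynthConfig(a_level=0, a_trend=0, b=-0.8, lag=0,
                          sd_m=1.0, sd_y=0.3, phi_m=0.0, phi_y=0.0,
                          phase_lengths=(25, 25), seed=13)
        ds, _ = generate_sced(cfg)
        # flip the hypothesis: improvement in outcome now expected positive
        ds.hypothesized_direction["outcome"] = +1
        ev = evaluate_b_path(ds, reps=500, seed=14)
        assert not ev.significant


class TestPrecedence:
    def test_mediator_first_then_outcome_trend(self):
        rng = np.random.default_rng(20)
        t = np.arange(1, 41)
        phase = np.array(["B"] * 20 + ["C"] * 20, dtype=object)
        on = (t >= 21).astype(float)
        med = 2 + 3 * on + rng.normal(0, 0.3, 40)
        out = 6 - 0.2 * (t - 21) * on + rng.normal(0, 0.3, 40)
        fit_m = fit_piecewise(make_series(med, phase, time=t))
        fit_y = fit_piecewise(make_series(out, phase, time=t))
        flag, why = assess_temporal_precedence(fit_m, fit_y, None, 0.05, DIRS)
        assert flag == "supported"
        assert "boundary-onset" in why

    def test_contiguous_leading_lags_support(self):
        clr = make_crosslag({-2, -1})
        flag, _ = assess_temporal_precedence(None, None, clr, 0.05, DIRS)
        assert flag == "supported"

    def test_noncontiguous_lags_only_caveats(self):
        # the pattern: -4 and -3 significant, -2/-1 not, 0 significant
        clr = make_crosslag({-4, -3, 0})
        flag, why = assess_temporal_precedence(None, None, clr, 0.05, DIRS)
        assert flag == "supported_with_caveats"
        assert "non-contiguous" in why

    def test_concurrent_only_caveats(self):
        clr = make_crosslag({0})
        flag, _ = assess_temporal_precedence(None, None, clr, 0.05, DIRS)
        assert flag == "supported_with_caveats"

    def test_outcome_changes_but_mediator_flat(self):
        rng = np.random.default_rng(21)
        t = np.arange(1, 41)
        phase = np.array(["B"] * 20 + ["C"] * 20, dtype=object)
        med = rng.normal(2, 0.3, 40)
        out = 6 - 3 * (t >= 21) + rng.normal(0, 0.3, 40)
        fit_m = fit_piecewise(make_series(med, phase, time=t))
        fit_y = fit_piecewise(make_series(out, phase, time=t))
        flag, _ = assess_temporal_precedence(fit_m, fit_y, None, 0.05, DIRS)
        assert flag == "not_supported"


class TestVerdict:
    @staticmethod
    def _ev(path, sig):
        t = PathTest("t", -0.5 if path == "b" else 0.5,
                     0.01 if sig else 0.5, sig)
        return PathEvidence(path=path, tests=[t], significant=sig,
                            direction_ok=sig)

    def test_joint_significance_rule(self):
        a_sig, b_sig = self._ev("a", True), self._ev("b", True)
        a_ns, b_ns = self._ev("a", False), self._ev("b", False)
        assert combine_verdict(a_sig, b_sig, "supported") \
            == "consistent_with_mediation"
        assert combine_verdict(a_sig, b_sig, "supported_with_caveats") \
            == "consistent_with_mediation"
        assert combine_verdict(a_sig, b_sig, "not_supported") == "inconclusive"
        assert combine_verdict(a_sig, b_ns, "supported") == "inconclusive"
        assert combine_verdict(a_ns, b_ns, "supported") == "no_evidence"

    def test_c_path_never_gates(self):
        # the decision rule does not even receive the c path
        import inspect
        params = inspect.signature(combine_verdict).parameters
        assert "c" not in params

    def test_unevaluable_path_forces_inconclusive(self):
        a = self._ev("a", True)
        b = self._ev("b", True)
        b.evaluable = False
        assert combine_verdict(a, b, "supported") == "inconclusive"


class TestReport:
    def test_full_mediation_scenario(self):
        ds, _ = generate_sced(SynthConfig(seed=42))
        ev = mediation_report(ds, MediationConfig(seed=7, reps=500))
        assert ev.verdict == "consistent_with_mediation"
        assert ev.a.significant and ev.b.significant
        assert ev.temporal_precedence != "not_supported"

    def test_single_phase_rejected(self):
        phase = np.array(["B"] * 12, dtype=object)
        vals = np.arange(12, dtype=float)
        ds = SCEDDataset(make_series(vals, phase, name="m"),
                         make_series(vals, phase, name="y"))
        with pytest.raises(ValidationError):
            mediation_report(ds, MediationConfig(seed=1, reps=200))

    def test_byte_identical_json_under_same_seed(self):
        ds, _ = generate_sced(SynthConfig(seed=3))
        cfg = MediationConfig(seed=9, reps=300)
        j1 = mediation_report(ds, cfg).to_json()
        j2 = mediation_report(ds, cfg).to_json()
        assert j1 == j2

    def test_listwise_policy_compresses_before_analysis(self):
        ds, _ = generate_sced(SynthConfig(missing_rate=0.145, seed=8))
        cfg = MediationConfig(seed=2, reps=300, missing="listwise")
        ev = mediation_report(ds, cfg)
        assert ev.verdict in {"consistent_with_mediation", "inconclusive",
                              "no_evidence"}
        # report is still deterministic with the policy applied
        assert ev.to_json() == mediation_report(ds, cfg).to_json()

    def test_report_json_is_valid(self):
        import json
        ds, _ = generate_sced(SynthConfig(seed=5))
        ev = mediation_report(ds, MediationConfig(seed=4, reps=300))
        parsed = json.loads(ev.to_json())
        assert parsed["verdict"] == ev.verdict
        assert set(parsed["piecewise"]) == {"mediator", "outcome"}
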