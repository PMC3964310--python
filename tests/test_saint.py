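import math

import numpy as np
import pytest

from apms.countmatrix import identity_normalized, zero_bait_self_counts
from apms.errors import ConfigError, DataError
from apms.saint import (
    SaintConfig,
    SaintResult,
    ThresholdPolicy,
    apply_thresholds,
    combine_iprobs,
    fit_background,
    score_bait,
    score_replicate,
)


# Independent oracle: Bayes posterior from hand-coded factorial Poisson masses.
def poisson_mass(k: int, lam: float) -> float:
    return math.exp(-lam) * lam**k / math.factorial(k)


def bayes_posterior(k: int, lam_false: float, lam_true: float, pi: float) -> float:
    num = pi * poisson_mass(k, lam_true)
    return num / (num + (1 - pi) * poisson_mass(k, lam_false))


class TestFitBackground:
    def test_smoothed_all_zero_controls(self, sim_data):
        matrix, _ = sim_data
        norm = identity_normalized(matrix)
        # a prey absent from the matrix has zero counts in all 7 controls
        assert fit_background(norm, "NOT_A_PREY", 0.1) == pytest.approx(0.1 / 7)

    @pytest.mark.parametrize(
        "counts, pc, expected",
        [([7] * 7, 0.0, 7.0), ([3], 0.1, 3.1), ([0] * 7, 0.1, 0.1 / 7)],
    )
    def test_hand_arithmetic(self, counts, pc, expected, tiny_matrix):
        import pandas as pd

        from apms.countmatrix import CountMatrix, Run

        runs = [Run(f"CONTROL_r{i+1}", None, i + 1) for i in range(len(counts))]
        m = CountMatrix(
            counts=pd.DataFrame(
                {r.run_id: [c] for r, c in zip(runs, counts)}, index=["P"]
            ),
            preys=pd.DataFrame({"accession": ["A"], "length": [100]}, index=["P"]),
            runs=runs,
        )
        assert fit_background(identity_normalized(m), "P", pc) == pytest.approx(
            expected
        )

    def test_no_controls_is_config_error(self, tiny_matrix):
        norm = identity_normalized(tiny_matrix)
        norm.runs = [r for r in norm.runs if not r.is_control]
        norm.counts = norm.counts[[r.run_id for r in norm.runs]]
        with pytest.raises(ConfigError):
            fit_background(norm, "PREYA")


class TestScoreReplicate:
    def test_equal_rates_return_prior(self):
        assert score_replicate(5, 2.0, 2.0, 0.1) == pytest.approx(0.1)

    def test_zero_count_under_high_specific_rate_is_near_zero(self):
        assert score_replicate(0, 0.1, 20.0, 0.1) < 0.01

    def test_large_count_is_near_one(self):
        assert score_replicate(50, 0.5, 40.0, 0.1) > 0.999

    @pytest.mark.parametrize("lam_false, lam_true", [(0.1, 15.0), (0.5, 5.0), (2.0, 40.0)])
    @pytest.mark.parametrize("pi", [0.05, 0.1, 0.5])
    def test_matches_brute_force_bayes_on_count_grid(self, lam_false, lam_true, pi):
        for k in range(101):
            expected = bayes_posterior(k, lam_false, lam_true, pi)
            assert score_replicate(float(k), lam_false, lam_true, pi) == pytest.approx(
                expected, abs=1e-12
            )

    @pytest.mark.parametrize("lam_false, lam_true", [(0.1, 15.0), (1.0, 3.0)])
    def test_monotone_in_count(self, lam_false, lam_true):
        probs = [score_replicate(k, lam_false, lam_true, 0.1) for k in range(101)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_nonfinite_input_raises(self):
        with pytest.raises(DataError):
            score_replicate(float("nan"), 0.1, 1.0, 0.1)


class TestCombineIprobs:
    def test_mean_of_two_highest(self):
        assert combine_iprobs([0.99, 0.95, 0.20]) == pytest.approx(0.97)

    def test_single_replicate_passes_through(self):
        assert combine_iprobs([0.80]) == pytest.approx(0.80)

    def test_empty_raises(self):
        with pytest.raises(DataError):
            combine_iprobs([])


class TestScoreBait:
    def test_uninformative_prey_scores_near_prior_and_fails(self, sim_data):
        matrix, truth = sim_data
        norm = identity_normalized(zero_bait_self_counts(matrix))
        results = {r.prey: r for r in score_bait(norm, "BAIT1")}
        background = truth.index[truth["role"] == "background"]
        scored_bg = [results[p] for p in background if p in results]
        assert scored_bg, "some background preys must be observed"
        near_prior = [r for r in scored_bg if abs(r.score - 0.1) < 0.35]
        assert len(near_prior) / len(scored_bg) > 0.8

    def test_prey_only_in_controls_not_scored(self, sim_data):
        matrix, _ = sim_data
        norm = identity_normalized(zero_bait_self_counts(matrix))
        bait_cols = [r.run_id for r in norm.runs_for("BAIT1")]
        unseen = norm.counts.index[(norm.counts[bait_cols] == 0).all(axis=1)]
        scored = {r.prey for r in score_bait(norm, "BAIT1")}
        assert scored.isdisjoint(set(unseen))

    def test_invariant_to_other_baits_runs(self, sim_data):
        matrix, _ = sim_data
        full = identity_normalized(zero_bait_self_counts(matrix))
        keep = [r for r in full.runs if r.is_control or r.bait == "BAIT1"]
        sub = identity_normalized(zero_bait_self_counts(matrix))
        sub.runs = keep
        sub.counts = sub.counts[[r.run_id for r in keep]]
        full_scores = {r.prey: r.score for r in score_bait(full, "BAIT1")}
        sub_scores = {r.prey: r.score for r in score_bait(sub, "BAIT1")}
        assert full_scores == sub_scores

    def test_recovers_planted_specific_preys(self, sim_data, scored_default):
        """>=90% of planted specific preys pass at 0.75; <=5% of background."""
        _, truth = sim_data
        background = set(truth.index[truth["role"] == "background"])
        for bait, results in scored_default.items():
            specific = {
                p
                for p, row in truth[truth["role"] == "specific"].iterrows()
                if bait in row["baits"].split(";")
            }
            passing = {r.prey for r in results if r.passes}
            assert len(passing & specific) / len(specific) >= 0.90
            assert len(passing & background) / len(background) <= 0.05


class TestApplyThresholds:
    def _result(self, score, bait="BAITX", prey="P1"):
        return SaintResult(bait=bait, prey=prey, iprobs=[score], score=score)

    def test_at_threshold_passes_non_strict(self):
        r = self._result(0.75)
        out = apply_thresholds([r], ThresholdPolicy(default=0.75))
        assert r.passes and out == [r]

    def test_at_threshold_fails_strict(self):
        r = self._result(0.95)
        policy = ThresholdPolicy(
            default=0.75, thresholds={"BAITX": 0.95}, strict=frozenset({"BAITX"})
        )
        assert apply_thresholds([r], policy) == [] and not r.passes

    def test_manual_include_retained_and_flagged(self):
        r = self._result(0.3, prey="MEF2C")
        policy = ThresholdPolicy(manual_include=frozenset({("BAITX", "MEF2C")}))
        out = apply_thresholds([r], policy)
        assert out == [r] and r.passes and r.manual


def test_config_validation():
    with pytest.raises(ConfigError):
        SaintConfig(pi_true=0.0)
    with pytest.raises(ConfigError):
        SaintConfig(pseudocount=-1)
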