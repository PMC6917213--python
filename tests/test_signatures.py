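"""Signature scoring, normalization, risk calls, consensus and hazard ratios."""

import numpy as np
import pandas as pd
import pytest

from angiosig import signatures, syndata
from angiosig.errors import EstimationError, InputError, ScoringError
from angiosig.signatures import GeneSignature

from conftest import simulate_surv


def _sig(name="s", members=(("gA", 1), ("gB", -1)), tag=None):
    return GeneSignature(name=name, members=tuple(members), tag=tag)


class TestGeneSignature:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(InputError):
            _sig(members=(("gA", 1), ("gA", 1)))

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            _sig(members=())

    def test_bad_weight_rejected(self):
        with pytest.raises(InputError):
            _sig(members=(("gA", 2),))


class TestGMT:
    def test_round_trip_with_down_weights(self, tmp_path):
        sigs = [
            _sig("up_only", (("gA", 1), ("gB", 1)), tag="angiogenesis"),
            _sig("mixed", (("gC", 1), ("gD", -1)), tag="hypoxia"),
        ]
        path = tmp_path / "sigs.gmt"
        signatures.write_gmt(sigs, path)
        back = signatures.read_gmt(path)
        assert back == sigs

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(InputError):
            signatures.read_gmt(path)


class TestScoring:
    def test_two_gene_hand_computation(self):
        # z-values supplied directly: weights (+1, -1) on z = (2, 0.5) -> 1.5
        expr = pd.DataFrame({"s1": [2.0, 0.5]}, index=["gA", "gB"])
        score = signatures.score_samples(_sig(), expr, standardize=False)
        assert score["s1"] == pytest.approx(1.5)

    def test_sample_at_plus_one_sd_scores_signature_size(self):
        z = pd.DataFrame(np.ones((4, 3)), index=list("abcd"),
                         columns=["s1", "s2", "s3"])
        sig = GeneSignature("all_up", tuple((g, 1) for g in "abcd"))
        score = signatures.score_samples(sig, z, standardize=False)
        assert (score == len(sig)).all()

    def test_weight_negation_negates_scores(self, rng):
        expr = pd.DataFrame(rng.standard_normal((5, 20)),
                            index=list("abcde"))
        sig = GeneSignature("s", tuple((g, 1) for g in "abcde"))
        neg = GeneSignature("s", tuple((g, -1) for g in "abcde"))
        np.testing.assert_allclose(
            signatures.score_samples(sig, expr),
            -signatures.score_samples(neg, expr),
        )

    def test_gene_order_invariance(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 10)), index=list("abcd"))
        s1 = GeneSignature("s", (("a", 1), ("b", -1), ("c", 1)))
        s2 = GeneSignature("s", (("c", 1), ("a", 1), ("b", -1)))
        np.testing.assert_allclose(
            signatures.score_samples(s1, expr), signatures.score_samples(s2, expr)
        )

    def test_missing_genes_warn_and_skip(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 8)), index=["a", "b"])
        sig = GeneSignature("s", (("a", 1), ("b", 1), ("zz", 1)))
        with pytest.warns(UserWarning, match="absent"):
            score = signatures.score_samples(sig, expr)
        ref = signatures.score_samples(GeneSignature("s", (("a", 1), ("b", 1))), expr)
        np.testing.assert_allclose(score, ref)

    def test_no_genes_present_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 4)), index=["a", "b"])
        with pytest.raises(ScoringError):
            signatures.score_samples(GeneSignature("s", (("zz", 1),)), expr)


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        raw = pd.Series([0.0, 5.0, 10.0])
        np.testing.assert_allclose(signatures.normalize_scores(raw), [-1, 0, 1])

    def test_degenerate_maps_to_zero(self):
        raw = pd.Series([3.0, 3.0, 3.0])
        np.testing.assert_allclose(signatures.normalize_scores(raw), 0.0)

    def test_rank_order_preserved(self, rng):
        raw = pd.Series(rng.standard_normal(50))
        norm = signatures.normalize_scores(raw)
        assert (np.argsort(norm.to_numpy()) == np.argsort(raw.to_numpy())).all()


class TestDichotomize:
    def test_event_fraction_determines_high_count(self, rng):
        scores = pd.Series(rng.permutation(10).astype(float))
        events = np.r_[np.ones(3), np.zeros(7)]
        calls = signatures.dichotomize_by_event_percentile(scores, events)
        assert (calls == "high").sum() == 3

    def test_all_events_all_high(self):
        scores = pd.Series([1.0, 2.0, 3.0])
        calls = signatures.dichotomize_by_event_percentile(scores, [1, 1, 1])
        assert (calls == "high").all()

    def test_no_events_all_low(self):
        scores = pd.Series([1.0, 2.0, 3.0])
        calls = signatures.dichotomize_by_event_percentile(scores, [0, 0, 0])
        assert (calls == "low").all()


class TestCorrelation:
    def test_duplicate_signature_correlates_perfectly(self, rng):
        expr = pd.DataFrame(rng.standard_normal((6, 40)),
                            index=[f"g{i}" for i in range(6)])
        sig = GeneSignature("s1", tuple((f"g{i}", 1) for i in range(4)))
        dup = GeneSignature("s2", tuple((f"g{i}", 1) for i in range(4)))
        corr = signatures.signature_correlation([sig, dup], expr)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)

    def test_sign_flip_anticorrelates(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 30)),
                            index=[f"g{i}" for i in range(4)])
        sig = GeneSignature("s1", tuple((f"g{i}", 1) for i in range(4)))
        neg = GeneSignature("s2", tuple((f"g{i}", -1) for i in range(4)))
        corr = signatures.signature_correlation([sig, neg], expr)
        assert corr.loc["s1", "s2"] == pytest.approx(-1.0)

    def test_disjoint_random_signatures_uncorrelated(self, rng):
        expr = pd.DataFrame(rng.standard_normal((20, 2000)),
                            index=[f"g{i}" for i in range(20)])
        a = GeneSignature("a", tuple((f"g{i}", 1) for i in range(10)))
        b = GeneSignature("b", tuple((f"g{i}", 1) for i in range(10, 20)))
        corr = signatures.signature_correlation([a, b], expr)
        assert abs(corr.loc["a", "b"]) < 0.1


class TestConsensus:
    def test_majority_high(self):
        calls = pd.DataFrame([["high"] * 5 + ["low"] * 4], index=["p1"])
        assert signatures.consensus_call(calls)["p1"] == "high"

    def test_unanimous_low(self):
        calls = pd.DataFrame([["low"] * 9], index=["p1"])
        assert signatures.consensus_call(calls)["p1"] == "low"

    def test_tie_goes_high(self):
        calls = pd.DataFrame([["high"] * 4 + ["low"] * 4], index=["p1"])
        assert signatures.consensus_call(calls)["p1"] == "high"

    def test_single_signature_consensus_is_identity(self, rng):
        scores = pd.Series(rng.standard_normal(30))
        events = rng.integers(0, 2, 30)
        own = signatures.dichotomize_by_event_percentile(scores, events)
        consensus = signatures.consensus_call(own.to_frame("s"))
        assert (consensus == own).all()


class TestGroupHazardRatio:
    def test_identical_survival_hr_near_one(self, rng):
        _, t, e = simulate_surv(rng, 300)
        t2 = np.r_[t, t]
        e2 = np.r_[e, e]
        calls = pd.Series(["high"] * 300 + ["low"] * 300)
        res = signatures.group_hazard_ratio(calls, t2, e2)
        assert res.ci_low < 1.0 < res.ci_high

    def test_planted_hr_two_recovered(self, rng):
        n = 500
        t_lo = rng.exponential(10.0, n)
        t_hi = rng.exponential(5.0, n)  # hazard ratio 2
        cens = rng.uniform(0, 30, 2 * n)
        t = np.minimum(np.r_[t_hi, t_lo], cens)
        e = (np.r_[t_hi, t_lo] <= cens).astype(int)
        calls = pd.Series(["high"] * n + ["low"] * n)
        res = signatures.group_hazard_ratio(calls, t, e)
        assert 1.6 <= res.hazard_ratio <= 2.5
        assert res.p_logrank < 1e-6

    def test_label_swap_inverts_hr(self, rng):
        x, t, e = simulate_surv(rng, 400, beta=0.5)
        calls = pd.Series(np.where(x > 0, "high", "low"))
        swapped = pd.Series(np.where(x > 0, "low", "high"))
        a = signatures.group_hazard_ratio(calls, t, e)
        b = signatures.group_hazard_ratio(swapped, t, e)
        assert a.hazard_ratio == pytest.approx(1.0 / b.hazard_ratio, rel=1e-6)

    def test_single_group_rejected(self, rng):
        _, t, e = simulate_surv(rng, 20)
        with pytest.raises(EstimationError):
            signatures.group_hazard_ratio(pd.Series(["high"] * 20), t, e)

    def test_prognostic_signature_from_cohort_truth(self):
        genes = tuple(f"HGENE{i:04d}" for i in range(30))
        prog = tuple((g, 0.5) for g in genes[:6])
        cfg = syndata.CohortSimConfig(
            n_patients=1000, n_genes=30, genes=genes, prognostic_genes=prog,
            train_fraction=0.999, seed=21,
        )
        train, _, _ = syndata.gen_cohort(cfg)
        sig = GeneSignature("planted", tuple((g, 1) for g in genes[:6]))
        raw = signatures.score_samples(sig, train.expr)
        calls = signatures.dichotomize_by_event_percentile(raw, train.event)
        res = signatures.group_hazard_ratio(calls, train.time, train.event)
        assert res.hazard_ratio > 1.0
        assert res.p_cox < 0.01
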