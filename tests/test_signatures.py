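"""Moderated testing, FDR control and signature set algebra."""

import numpy as np
import pytest
from scipy import stats

from cascadeomics.datasets import FoldChangeTensor
from cascadeomics.signatures import (
    SignatureSets,
    bh_fdr,
    build_signature_sets,
    estimate_variance_prior,
    magnitude_signature,
    match_pairs,
    overlap_from_counts,
    proliferative_signature,
    response_signature,
    signature_from_tests,
    temporal_signature,
    temporal_tests,
    two_group_tests,
)


def make_fc(arr, groups=None, modality="transcript"):
    arr = np.asarray(arr, dtype=float)
    F, T, P = arr.shape
    return FoldChangeTensor(
        modality=modality, log2fc=arr,
        features=[f"G{i}" for i in range(F)],
        time_hours=tuple(range(1, T + 1)),
        individuals=[f"I{p}" for p in range(P)],
        groups=groups or ["proliferative"] * P,
    )


class TestModeratedTest:
    def test_all_zero_feature_gives_statistic_zero_p_one(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(0, 0.3, size=(20, 4, 3))
        arr[0] = 0.0
        tests = temporal_tests(make_fc(arr), "proliferative")
        row = tests[(tests.feature == "G0") & (tests.time == 1)].iloc[0]
        assert row.statistic == 0.0 and row.p_value == 1.0

    def test_fully_pooled_limit_uses_prior_scale(self):
        # equal sample variances across all cells -> d0 -> inf and the
        # statistic reduces to mean * sqrt(n) / s0
        s2 = np.full(50, 0.04)
        d0, s0 = estimate_variance_prior(s2, np.full(50, 2.0))
        assert np.isinf(d0)
        # chi-square bias correction on log variances (d = 2)
        from scipy.special import digamma

        assert s0 == pytest.approx(0.04 * np.exp(-digamma(1.0)), rel=1e-6)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(42)
        arr = rng.normal(0.0, 0.25, size=(200, 8, 3))
        tests = temporal_tests(make_fc(arr), "proliferative")
        ks = stats.kstest(tests.p_value.to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_untestable_cells_flagged_and_outside_family(self):
        arr = np.random.default_rng(1).normal(0, 0.2, size=(5, 3, 3))
        arr[2, 1, :] = np.nan
        arr[2, 1, 0] = 0.1  # single observation: untestable
        tests = temporal_tests(make_fc(arr, modality="protein"), "proliferative")
        row = tests[(tests.feature == "G2") & (tests.time == 2)].iloc[0]
        assert not row.testable and np.isnan(row.q_value)


class TestTwoGroupTest:
    def groups(self):
        return ["proliferative"] * 3 + ["nonproliferative"] * 3

    def test_identical_groups_give_zero_statistic(self):
        rng = np.random.default_rng(2)
        half = rng.normal(0, 0.3, size=(10, 4, 3))
        arr = np.concatenate([half, half], axis=2)
        tests = two_group_tests(make_fc(arr, groups=self.groups()))
        assert np.allclose(tests.statistic, 0.0)
        assert np.allclose(tests.p_value, 1.0)

    def test_swapping_groups_negates_statistic(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(0, 0.3, size=(10, 4, 6))
        fc = make_fc(arr, groups=self.groups())
        fwd = two_group_tests(fc, "proliferative", "nonproliferative")
        rev = two_group_tests(fc, "nonproliferative", "proliferative")
        assert np.allclose(fwd.statistic, -rev.statistic)
        assert np.allclose(fwd.p_value, rev.p_value)

    def test_power_on_planted_two_log2_shift(self):
        # 100 seeded replicates of one shifted feature among nulls
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            arr = rng.normal(0, 0.1, size=(50, 1, 6))
            arr[0, :, :3] += 2.0
            tests = two_group_tests(make_fc(arr, groups=self.groups()))
            hits += tests[tests.feature == "G0"].p_value.iloc[0] < 0.001
        assert hits >= 95


class TestBH:
    def test_step_up_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_fdr([]).size == 0
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p_ranking(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([-0.1, 0.5])


class TestSignatureSets:
    def planted(self, seed=0, n=300, k=30, effect=3.0, sd=0.2):
        rng = np.random.default_rng(seed)
        arr = rng.normal(0, sd, size=(n, 8, 3))
        arr[:k, 3:, :] += effect
        return make_fc(arr), set(f"G{i}" for i in range(k))

    def test_union_semantics_and_direction(self):
        arr = np.zeros((3, 8, 3))
        arr[1, 4, :] = 2.0   # significant only at T5
        arr += np.random.default_rng(5).normal(0, 0.05, arr.shape)
        sig = temporal_signature(temporal_tests(make_fc(arr), "proliferative"), 0.01)
        assert "G1" in sig and sig["G1"][5] == 1

    def test_alpha_zero_empty(self):
        fc, _ = self.planted()
        assert temporal_signature(temporal_tests(fc, "proliferative"), 0.0) == {}

    def test_planted_responders_recovered_with_fdr_control(self):
        fps, fns = [], []
        for seed in range(10):
            fc, truth = self.planted(seed)
            sig = temporal_signature(temporal_tests(fc, "proliferative"), 0.01)
            found = set(sig)
            fns.append(len(truth - found))
            fps.append(len(found - truth) / max(len(found), 1))
        assert sum(fns) == 0          # every planted responder recovered
        assert np.mean(fps) <= 0.05   # empirical FDR within tolerance

    def test_proliferative_is_exact_intersection(self):
        assert proliferative_signature({"A": {}, "B": {}}, {"C": {}}) == set()
        assert proliferative_signature({"A": {}, "B": {}}, {"B": {}}) == {"B"}
        with pytest.raises(ValueError):
            SignatureSets(
                temporal={("proliferative", "transcript"): {"A": {1: 1}}},
                response={"transcript": {"A": {1: 1}}},
                proliferative={"transcript": set()},
            )

    def test_match_pairs_uppercases(self):
        assert match_pairs({"A", "B"}, {"B", "C"}) == ["B"]
        assert match_pairs({"EGR1"}, {"Egr1"}) == ["EGR1"]
        assert match_pairs({"A", "B"}, {"a", "b"}) == ["A", "B"]

    def test_shared_symbols_from_printed_counts(self):
        assert overlap_from_counts(430, 374, 779) == 25

    def test_magnitude_signature_thresholds_mean(self):
        arr = np.zeros((2, 3, 2))
        arr[0, 1, :] = [0.5, 0.7]
        sig = magnitude_signature(make_fc(arr), "proliferative", 0.1)
        assert sig == {"G0": {2: 1}}

    def test_build_signature_sets_end_to_end(self):
        rng = np.random.default_rng(7)
        groups = ["proliferative"] * 3 + ["nonproliferative"] * 3
        gene = rng.normal(0, 0.2, size=(40, 8, 6))
        prot = rng.normal(0, 0.2, size=(40, 8, 6))
        gene[:5, 2:, :3] += 3.0   # responders in the proliferative group only
        prot[:5, 4:, :3] += 3.0
        sig = build_signature_sets(make_fc(gene, groups),
                                   make_fc(prot, groups, "protein"))
        for modality in ("transcript", "protein"):
            assert sig.proliferative[modality] == proliferative_signature(
                sig.temporal[("proliferative", modality)], sig.response[modality]
            )
        assert set(sig.matched_pairs) >= {"G0", "G1", "G2", "G3", "G4"}
        summary = sig.summary()
        assert summary["proliferative"]["shared_symbols"] == len(
            set(sig.proliferative["transcript"]) & set(sig.proliferative["protein"])
        )
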