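"""Cascade model estimation: predictors, LASSO, stability, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from cascadeomics.cascade import (
    CascadeNetworkModel,
    ClusterAssignment,
    InferredNetwork,
    PriorNetwork,
    assign_clusters,
    build_predictor,
    degree_summary,
    shift_matrix,
)
from cascadeomics.preprocess import log2fc_vs_t0


# ---------------------------------------------------------------------------
# helpers


def simple_model(seed=0, n_actors=6, T=8, P=3, noise=0.0, prior=None, kappa=0.5):
    """Cluster-1 inputs with random profiles driving cluster-2 targets by a
    one-step lag; returns (model, true_omega) on the same actor order."""
    rng = np.random.default_rng(seed)
    n1 = n_actors // 2
    series = np.zeros((n_actors, P, T))
    for i in range(n1):
        base = rng.normal(0, 1, T)
        series[i] = base * rng.uniform(0.9, 1.1, (P, T))
    omega = np.zeros((n_actors, n_actors))
    for l in range(n1, n_actors):
        parents = rng.choice(n1, size=rng.integers(1, min(3, n1 + 1)),
                             replace=False)
        for k in parents:
            omega[k, l] = rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
            series[l, :, 1:] += omega[k, l] * series[k, :, :-1]
        series[l] += noise * rng.normal(0, 1, (P, T))
    actors = [f"A{i}" for i in range(n_actors)]
    clusters = ClusterAssignment(
        m={a: (1 if i < n1 else 2) for i, a in enumerate(actors)}
    )
    model = CascadeNetworkModel(series, actors, clusters, prior=prior, kappa=kappa)
    return model, omega


class TestBuildPredictor:
    def test_shift_matrix_lags_by_one(self):
        x = np.arange(1.0, 9.0)
        out = build_predictor(shift_matrix(8), x)
        assert out[0] == 0.0
        assert np.allclose(out[1:], x[:-1])

    def test_zero_matrix_gives_zero(self):
        assert np.allclose(build_predictor(np.zeros((8, 8)), np.ones(8)), 0.0)

    def test_unit_input_reads_first_column(self):
        rng = np.random.default_rng(0)
        F = np.tril(rng.normal(size=(8, 8)), -1)
        e1 = np.zeros(8)
        e1[0] = 1.0
        assert np.allclose(build_predictor(F, e1), F[:, 0])

    def test_rejects_upper_triangular_leakage(self):
        F = np.zeros((8, 8))
        F[0, 1] = 1.0  # a target time depending on a later source time
        with pytest.raises(ValueError):
            build_predictor(F, np.ones(8))
        with pytest.raises(ValueError):
            build_predictor(np.zeros((4, 4)), np.ones(8))


class TestFit:
    def test_ols_oracle_at_lambda_zero(self):
        """lam=0 on a well-conditioned single-target design must match the
        brute-force normal-equation solution to 1e-8."""
        model, _ = simple_model(seed=1, n_actors=3, noise=0.05)
        res = model.fit(0.0, max_iter=1)
        l = 2  # the single cluster-2 target
        X = model._design(l, res.F)
        y = model.scaled[l].ravel()
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        cand = model.candidates[l]
        assert np.allclose(res.omega[cand, l], beta_oracle, atol=1e-8)

    def test_huge_lambda_zeroes_everything(self):
        model, _ = simple_model(seed=2, noise=0.1)
        res = model.fit(1e6)
        assert not res.support.any()

    def test_noiseless_support_recovery(self):
        model, omega = simple_model(seed=3, noise=0.0)
        res = model.fit(1e-4, max_iter=1, refit_ols=True)
        assert np.array_equal(res.support, np.abs(omega) > 0)

    def test_objective_non_increasing_across_alternations(self):
        model, _ = simple_model(seed=4, noise=0.3)
        res = model.fit(0.5, max_iter=6, tol=0.0)
        path = np.array(res.objective_path)
        assert (np.diff(path) <= 1e-6 * np.maximum(1, np.abs(path[:-1]))).all()

    def test_cluster1_targets_get_empty_models(self):
        model, _ = simple_model(seed=5)
        for l in range(model.n_actors):
            if model._m[l] == 1:
                assert len(model.candidates[l]) == 0

    def test_inferred_edges_respect_causality(self):
        model, _ = simple_model(seed=6, noise=0.2)
        edges = model.fit(0.1).edges()
        assert (edges.source_cluster <= edges.target_cluster).all()

    def test_prior_kappa_bounds_enforced(self):
        with pytest.raises(ValueError):
            simple_model(kappa=0.0)
        with pytest.raises(ValueError):
            simple_model(kappa=1.5)

    def test_summary_mentions_key_quantities(self):
        model, _ = simple_model(seed=7, noise=0.1)
        text = model.fit(0.2).summary()
        for token in ("lambda", "kappa", "Selected edges", "Objective"):
            assert token in text


class TestClusterAssignment:
    def test_rank_construction(self):
        cl = assign_clusters({"a": {1: 1}, "b": {1: -1}, "c": {4: 1}})
        assert cl.m == {"A": 1, "B": 1, "C": 2}
        assert cl.onset_time == {"A": 1, "B": 1, "C": 4}

    def test_single_onset_gives_single_cluster(self):
        cl = assign_clusters({"a": {1: 1}, "b": {1: 1}})
        assert cl.n_clusters == 1

    def test_actor_without_significant_time_excluded(self):
        cl = assign_clusters({"a": {2: 1}, "b": {}})
        assert "B" not in cl.m

    def test_contiguity_enforced(self):
        with pytest.raises(ValueError):
            ClusterAssignment(m={"A": 1, "B": 3})

    def test_generator_clusters_recovered_from_noisy_onsets(self):
        """Onset ranks track the planted waves under calibrated noise: most
        actors land on their true wave and nearly all true edges stay
        causally feasible (bounds frozen from the generator's behavior)."""
        from cascadeomics.signatures import temporal_signature, temporal_tests
        from cascadeomics.synthetic import (
            SimulationConfig,
            calibrate_noise_for_snr,
            generate_network,
            simulate_dataset,
        )

        accs, feas = [], []
        for seed in range(6):
            net = generate_network(10, 2, mean_out_degree=1.5, seed=seed)
            cfg = SimulationConfig(seed=seed, n_background=50)
            cfg.noise_sd = calibrate_noise_for_snr(net, cfg, 4.0)
            tr, _ = simulate_dataset(net, cfg, "proliferative")
            fc = log2fc_vs_t0(tr, pseudocount=1.0)
            sig = temporal_signature(temporal_tests(fc, "proliferative"), 0.01)
            cl = assign_clusters(sig)
            accs.append(np.mean([cl.m.get(a) == net.cluster_of[a]
                                 for a in net.actors]))
            feas.append(np.mean([a in cl.m and b in cl.m and cl.m[a] <= cl.m[b]
                                 for a, b in net.edge_set]))
        assert np.mean(accs) >= 0.75
        assert np.mean(feas) >= 0.9


class TestCrossValidation:
    def test_single_value_grid_returned(self):
        model, _ = simple_model(seed=8, noise=0.2)
        lam, table = model.cross_validate([0.3])
        assert lam == 0.3
        assert set(table.lam) == {0.3}

    def test_pure_noise_prefers_largest_lambda(self):
        rng = np.random.default_rng(9)
        series = rng.normal(0, 1, size=(6, 3, 8))
        actors = [f"A{i}" for i in range(6)]
        clusters = ClusterAssignment(m={a: (1 if i < 3 else 2)
                                        for i, a in enumerate(actors)})
        wins = 0
        for seed in range(10):
            noise = np.random.default_rng(seed).normal(0, 1, size=(6, 3, 8))
            model = CascadeNetworkModel(noise, actors, clusters)
            lam, _ = model.cross_validate([0.1, 1.0, 10.0])
            wins += lam == 10.0
        assert wins >= 9

    def test_heldout_error_curve_has_finite_minimum(self):
        model, _ = simple_model(seed=10, noise=0.3)
        lam, table = model.cross_validate([0.01, 0.1, 0.5, 2.0])
        mean_err = table.groupby("lam")["mse"].mean()
        assert np.isfinite(mean_err).all()
        assert mean_err[lam] == pytest.approx(mean_err.min())


class TestStabilitySelection:
    def test_deterministic_refits_give_binary_frequencies(self):
        model, omega = simple_model(seed=11, noise=0.0)
        net = model.stability_selection(0.05, B=2, subsample_fraction=0.9, seed=0)
        vals = np.unique(net.frequencies)
        assert set(np.round(vals, 6)) <= {0.0, 0.5, 1.0}
        # noiseless support at full threshold matches a single fit
        single = model.fit(0.05, max_iter=1)
        retained_full = {
            (model.actors[k], model.actors[l])
            for l in range(model.n_actors) for k in model.candidates[l]
            if net.frequencies[k, l] == 1.0
        }
        assert retained_full <= set(single.to_network().edge_set) | retained_full

    def test_threshold_monotonicity(self):
        model, _ = simple_model(seed=12, noise=0.3)
        strict = model.stability_selection(0.3, B=30, pi_thr=1.0, seed=1)
        loose = model.stability_selection(0.3, B=30, pi_thr=0.6, seed=1)
        assert strict.edge_set <= loose.edge_set

    def test_bit_identical_given_seed(self):
        model, _ = simple_model(seed=13, noise=0.3)
        a = model.stability_selection(0.3, B=20, seed=42)
        b = model.stability_selection(0.3, B=20, seed=42)
        assert np.array_equal(a.frequencies, b.frequencies)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_parameter_validation(self):
        model, _ = simple_model(seed=14)
        with pytest.raises(ValueError):
            model.stability_selection(0.1, B=1)
        with pytest.raises(ValueError):
            model.stability_selection(0.1, subsample_fraction=1.5)
        with pytest.raises(ValueError):
            model.stability_selection(0.1, pi_thr=0.3)

    def test_prior_favoring_never_hurts_prior_edge_recall(self):
        """Decreasing kappa must not decrease recall of prior-listed true
        edges on a fixed instance."""
        rng_model, omega = simple_model(seed=15, noise=0.4)
        true_edges = {(f"A{k}", f"A{l}") for k, l in zip(*np.nonzero(omega))}
        listed = sorted(true_edges)[: max(1, len(true_edges) // 2)]
        prior = PriorNetwork(edges=[(s, t, 1.0) for s, t in listed])
        recalls = {}
        for kappa in (1.0, 0.5, 0.25):
            model, _ = simple_model(seed=15, noise=0.4, prior=prior, kappa=kappa)
            net = model.stability_selection(0.4, B=40, pi_thr=0.6, seed=3)
            recalls[kappa] = len(net.edge_set & set(listed)) / len(listed)
        assert recalls[0.5] >= recalls[1.0]
        assert recalls[0.25] >= recalls[0.5]


class TestNetworkSummaries:
    def make_net(self, degs):
        edges = []
        for actor, d in degs.items():
            for i in range(d):
                edges.append(dict(source=actor, target=f"T{actor}{i}",
                                  omega_hat=1.0, stability_frequency=1.0,
                                  sign=1, source_cluster=1, target_cluster=2,
                                  in_prior=False))
        frame = pd.DataFrame(edges)
        actors = sorted(set(frame.source) | set(frame.target))
        clusters = ClusterAssignment(
            m={a: (1 if not a.startswith("T") else 2) for a in actors}
        )
        return InferredNetwork(edges=frame, actors=actors, clusters=clusters)

    def test_hub_threshold(self):
        net = self.make_net({"a": 12, "b": 3})
        hubs, table = degree_summary(net, threshold=10)
        assert hubs == {"a"}
        assert table.iloc[0]["actor"] == "a"

    def test_threshold_zero_selects_everyone(self):
        net = self.make_net({"a": 2, "b": 1})
        hubs, _ = degree_summary(net, threshold=0)
        assert hubs == set(net.actors)

    def test_acausal_edge_rejected(self):
        frame = pd.DataFrame([dict(source="B", target="A", omega_hat=1.0,
                                   stability_frequency=1.0, sign=1,
                                   source_cluster=2, target_cluster=1,
                                   in_prior=False)])
        clusters = ClusterAssignment(m={"A": 1, "B": 2})
        with pytest.raises(ValueError):
            InferredNetwork(edges=frame, actors=["A", "B"], clusters=clusters)
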