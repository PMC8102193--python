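"""Seeded subnetwork extraction, layering, comparison, and term counts."""

import numpy as np
import pandas as pd
import pytest

from cascadeomics.cascade import ClusterAssignment, InferredNetwork
from cascadeomics.subnetwork import (
    AnnotationMap,
    compare_networks,
    extract_subnetwork,
    select_seeding_proteins,
    temporal_function_counts,
)


def build_network(edges, protein_actors=(), extra_actors=()):
    """Directed network over symbols; actors in ``protein_actors`` are
    tagged as proteins (ids get the :P suffix convention stripped off by
    symbol matching)."""
    rows = []
    actors = set(extra_actors)
    for s, t in edges:
        actors |= {s, t}
        rows.append(dict(source=s, target=t, omega_hat=1.0,
                         stability_frequency=1.0, sign=1,
                         source_cluster=1, target_cluster=1, in_prior=False))
    frame = pd.DataFrame(rows, columns=["source", "target", "omega_hat",
                                        "stability_frequency", "sign",
                                        "source_cluster", "target_cluster",
                                        "in_prior"])
    clusters = ClusterAssignment(m={a: 1 for a in actors})
    modality = {a: ("protein" if a in protein_actors else "transcript")
                for a in actors}
    return InferredNetwork(edges=frame, actors=sorted(actors),
                           clusters=clusters, actor_modality=modality)


class TestSeedSelection:
    def test_annotated_protein_in_network_selected(self):
        ann = AnnotationMap(terms={"proliferation": {"P1", "P2"}})
        net = build_network([("P1:P", "X")], protein_actors={"P1:P"})
        # the network's protein actor P1:P carries symbol P1
        net.actor_modality["P1:P"] = "protein"
        assert select_seeding_proteins(ann, ["proliferation"], net) == {"P1:P"}

    def test_empty_terms_give_empty_seeds(self):
        ann = AnnotationMap(terms={"proliferation": {"P1"}})
        net = build_network([("P1:P", "X")], protein_actors={"P1:P"})
        assert select_seeding_proteins(ann, [], net) == set()

    def test_missing_term_logged_not_fatal(self):
        ann = AnnotationMap(terms={"proliferation": {"P1"}})
        net = build_network([("P1:P", "X")], protein_actors={"P1:P"})
        out = select_seeding_proteins(ann, ["no such process"], net)
        assert out == set()

    def test_symbols_uppercased(self):
        ann = AnnotationMap(terms={"Proliferation": {"p1"}})
        assert ann.terms == {"PROLIFERATION": {"P1"}}


class TestExtraction:
    def test_star_network(self):
        net = build_network([("S", "A"), ("S", "B"), ("S", "C")],
                            protein_actors={"S"})
        layers = extract_subnetwork(net, {"S"})
        assert layers.actors == {"S", "A", "B", "C"}
        assert len(layers.induced_edges) == 3
        assert layers.layer1 == {"S"}

    def test_isolated_seed_dropped(self):
        net = build_network([("A", "B")], protein_actors={"S"},
                            extra_actors={"S"})
        layers = extract_subnetwork(net, {"S"})
        assert layers.actors == set()

    def test_gene_encoding_seed_protein_lands_in_layer2(self):
        net = build_network([("X:P", "X"), ("X:P", "Y")],
                            protein_actors={"X:P"})
        layers = extract_subnetwork(net, {"X:P"})
        assert layers.layer1 == {"X:P"}
        assert layers.layer2 == {"X"}
        assert layers.layer3 == {"Y"}

    def test_layers_partition_exactly(self):
        rng = np.random.default_rng(0)
        actors = [f"A{i}" for i in range(12)]
        edges = {(actors[rng.integers(12)], actors[rng.integers(12)])
                 for _ in range(20)}
        edges = [(s, t) for s, t in edges if s != t]
        proteins = set(actors[:4])
        net = build_network(edges, protein_actors=proteins)
        layers = extract_subnetwork(net, proteins)
        assert layers.layer1 | layers.layer2 | layers.layer3 == layers.actors
        assert not (layers.layer1 & layers.layer2)
        assert not (layers.layer1 & layers.layer3)
        assert not (layers.layer2 & layers.layer3)
        # every actor is a seed or adjacent to one
        adj = {a: set() for a in net.actors}
        for s, t in edges:
            adj[s].add(t)
            adj[t].add(s)
        for a in layers.actors:
            assert a in layers.layer1 or adj[a] & layers.layer1

    def test_monotone_in_seed_set(self):
        net = build_network([("A", "B"), ("C", "D"), ("B", "C")],
                            protein_actors={"A", "C"})
        small = extract_subnetwork(net, {"A"})
        large = extract_subnetwork(net, {"A", "C"})
        assert small.actors <= large.actors

    def test_undirected_neighborhood(self):
        # the seed is a pure target; its regulator still joins the subnetwork
        net = build_network([("U", "S")], protein_actors={"S"})
        layers = extract_subnetwork(net, {"S"})
        assert layers.actors == {"S", "U"}


class TestComparison:
    def test_reported_fractions_match_known_worked_example(self):
        # 388- and 114-actor networks sharing 60 actors: ~15% and ~52%
        assert abs(60 / 388 - 0.15) < 0.005
        assert abs(60 / 114 - 0.52) < 0.01

    def test_identical_networks_full_overlap(self):
        net = build_network([("S", "A"), ("S", "B")], protein_actors={"S"})
        layers = extract_subnetwork(net, {"S"})
        report = compare_networks(layers, layers)
        assert report["fraction_of_a"] == 1.0
        assert report["fraction_of_b"] == 1.0
        assert report["n_common"] == len(layers.actors)

    def test_disjoint_networks_share_nothing(self):
        a = extract_subnetwork(build_network([("S", "A")],
                                             protein_actors={"S"}), {"S"})
        b = extract_subnetwork(build_network([("T", "B")],
                                             protein_actors={"T"}), {"T"})
        report = compare_networks(a, b)
        assert report["n_common"] == 0
        assert report["shared_edges"] == []

    def test_symmetric_common_set(self):
        net1 = build_network([("S", "A"), ("S", "B")], protein_actors={"S"})
        net2 = build_network([("S", "A"), ("A", "C")], protein_actors={"S"})
        la, lb = extract_subnetwork(net1, {"S"}), extract_subnetwork(net2, {"S"})
        ab = compare_networks(la, lb)
        ba = compare_networks(lb, la)
        assert ab["common_actors"] == ba["common_actors"]


class TestTemporalFunctionCounts:
    def test_unannotated_term_gives_zero_row(self):
        ann = AnnotationMap(terms={"proliferation": {"Z"}})
        counts = temporal_function_counts({"A": {7: 1}}, ann)
        assert (counts["count"] == 0).all()

    def test_single_upregulated_protein_counted(self):
        ann = AnnotationMap(terms={"cell cycle regulation": {"A"}})
        counts = temporal_function_counts({"A": {7: 1}}, ann)
        hit = counts[(counts.time == 7) & (counts.direction == "up")]
        assert hit["count"].iloc[0] == 1
        assert counts[(counts.time == 7) & (counts.direction == "down")][
            "count"].iloc[0] == 0

    def test_late_responders_concentrate_late(self, small_net):
        """Planted late-wave responders annotated to proliferation produce
        counts that peak at the late time points."""
        from cascadeomics.preprocess import log2fc_vs_t0
        from cascadeomics.signatures import magnitude_signature
        from cascadeomics.synthetic import (
            SimulationConfig,
            generate_annotations,
            simulate_dataset,
        )

        cfg = SimulationConfig(seed=7, deterministic=True, noise_sd=0.0,
                               n_background=0, protein_missing_rate=0.0,
                               translation_delay_steps=2)
        _tr, pr = simulate_dataset(small_net, cfg, "proliferative")
        sig = magnitude_signature(log2fc_vs_t0(pr, 0.0), "proliferative", 0.05)
        ann = AnnotationMap(terms=generate_annotations(small_net, seed=7))
        counts = temporal_function_counts(sig, ann)
        prolif = counts[counts.term == "PROLIFERATION"]
        by_time = prolif.groupby("time")["count"].sum()
        # late-wave proteins lag twice (cascade + translation): nothing
        # annotated shows up before the late indices
        assert by_time.loc[[1, 2]].sum() == 0
        assert by_time.loc[[4, 5, 6]].sum() > 0
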