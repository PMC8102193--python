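"""Seeded subnetwork extraction and network comparison.

Proteins annotated to nucleating biological processes (by default
"cell cycle regulation" and "proliferation") seed a nested subnetwork:
seeds with at least one link plus their direct neighbors (adjacency taken
undirected), stratified into three layers - the seed proteins, the genes
encoding them, and everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .cascade import InferredNetwork

logger = logging.getLogger(__name__)

DEFAULT_SEED_TERMS = ("CELL CYCLE REGULATION", "PROLIFERATION")


@dataclass
class AnnotationMap:
    """Biological-process term -> set of (uppercase) symbols, GMT-derived."""

    terms: dict

    def __post_init__(self):
        self.terms = {
            str(t).upper(): {str(s).upper() for s in syms}
            for t, syms in self.terms.items()
        }

    def symbols_for(self, terms) -> set:
        out = set()
        for term in terms:
            term = str(term).upper()
            if term not in self.terms:
                logger.warning("annotation term %r not found", term)
                continue
            out |= self.terms[term]
        return out


@dataclass
class SubnetworkLayers:
    """Three-layer stratification of a seeded subnetwork.

    layer1: seed proteins retained (>= 1 link); layer2: genes encoding a
    layer-1 protein; layer3: the remaining actors.  The layers partition
    the subnetwork actor set exactly.
    """

    layer1: set
    layer2: set
    layer3: set
    induced_edges: pd.DataFrame
    symbol_of: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.layer1 & self.layer2) or (self.layer1 & self.layer3) or (self.layer2 & self.layer3):
            raise ValueError("subnetwork layers must be pairwise disjoint")

    @property
    def actors(self) -> set:
        return self.layer1 | self.layer2 | self.layer3

    @property
    def edge_set(self):
        return set(zip(self.induced_edges["source"], self.induced_edges["target"]))

    def layer_of(self, actor):
        for i, layer in enumerate((self.layer1, self.layer2, self.layer3), start=1):
            if actor in layer:
                return i
        raise KeyError(actor)


def _modality_of(net: InferredNetwork):
    """Actor -> modality; networks without tags are treated as transcript."""
    if net.actor_modality:
        return net.actor_modality
    return {a: "transcript" for a in net.actors}


def _symbol_of(net: InferredNetwork):
    return {a: a.split(":")[0] for a in net.actors}


def select_seeding_proteins(ann: AnnotationMap, terms, net: InferredNetwork) -> set:
    """Protein actors annotated with any listed term and present in the network."""
    symbols = ann.symbols_for(terms)
    modality = _modality_of(net)
    symbol = _symbol_of(net)
    return {
        a for a in net.actors
        if modality.get(a) == "protein" and symbol[a] in symbols
    }


def extract_subnetwork(net: InferredNetwork, seeds: set) -> SubnetworkLayers:
    """Seeds with >= 1 link plus their direct (undirected) neighbors.

    Induced edges keep both endpoints inside the subnetwork.  Isolated
    seeds are dropped; an empty seed set yields an empty subnetwork.
    """
    seeds = {s for s in seeds if s in set(net.actors)}
    g = nx.Graph()
    g.add_nodes_from(net.actors)
    for row in net.edges.itertuples():
        g.add_edge(row.source, row.target)
    connected_seeds = {s for s in seeds if g.degree(s) > 0}
    actors = set(connected_seeds)
    for s in connected_seeds:
        actors |= set(g.neighbors(s))
    induced = net.edges[
        net.edges["source"].isin(actors) & net.edges["target"].isin(actors)
    ].reset_index(drop=True)
    symbol = _symbol_of(net)
    modality = _modality_of(net)
    layer1 = connected_seeds
    layer1_symbols = {symbol[a] for a in layer1}
    layer2 = {
        a for a in actors - layer1
        if modality.get(a) == "transcript" and symbol[a] in layer1_symbols
    }
    layer3 = actors - layer1 - layer2
    return SubnetworkLayers(
        layer1=layer1, layer2=layer2, layer3=layer3, induced_edges=induced,
        symbol_of={a: symbol[a] for a in actors},
    )


def compare_networks(a: SubnetworkLayers, b: SubnetworkLayers) -> dict:
    """Overlap report between two subnetworks (symmetric common set)."""
    common = a.actors & b.actors
    report = {
        "common_actors": sorted(common),
        "n_common": len(common),
        "n_a": len(a.actors),
        "n_b": len(b.actors),
        "fraction_of_a": len(common) / len(a.actors) if a.actors else 0.0,
        "fraction_of_b": len(common) / len(b.actors) if b.actors else 0.0,
        "per_layer": {},
        "shared_edges": sorted(a.edge_set & b.edge_set),
    }
    for i, (la, lb) in enumerate(
        ((a.layer1, b.layer1), (a.layer2, b.layer2), (a.layer3, b.layer3)), start=1
    ):
        report["per_layer"][f"layer{i}"] = len(la & lb)
    return report


def temporal_function_counts(protein_directions: dict, ann: AnnotationMap,
                             n_times: int = 8) -> pd.DataFrame:
    """Count signature proteins per process x time x direction.

    ``protein_directions`` maps symbol -> {time: +1/-1} (a protein temporal
    signature); returns a tidy table (term, time, direction, count) with
    all-zero rows kept so unrepresented terms stay visible.
    """
    rows = []
    for term in sorted(ann.terms):
        members = ann.terms[term]
        for t in range(1, n_times + 1):
            up = down = 0
            for sym, times in protein_directions.items():
                if sym not in members or t not in times:
                    continue
                if times[t] > 0:
                    up += 1
                elif times[t] < 0:
                    down += 1
            rows.append(dict(term=term, time=t, direction="up", count=up))
            rows.append(dict(term=term, time=t, direction="down", count=down))
    return pd.DataFrame(rows, columns=["term", "time", "direction", "count"])
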