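"""Readers and writers for the interchange formats.

TSV (tab-delimited, UTF-8, '.' decimal) is the interchange dialect:
expression matrices (rows = feature symbols, columns = sample ids), sample
metadata, edge tables, and signature tables.  Annotations travel as GMT,
networks additionally as SIF and GraphML (Cytoscape-compatible).  Symbols
are uppercased once at ingestion; time is carried both as index (T0..T8)
and nominal hours, and joins use the index.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cascade import InferredNetwork, PriorNetwork
from .datasets import (
    GROUPS,
    PROTEIN,
    TRANSCRIPT,
    FoldChangeTensor,
    TemporalOmicsDataset,
)
from .subnetwork import AnnotationMap


# ---------------------------------------------------------------------------
# expression + metadata


def sample_id(individual: str, time_index: int, modality: str) -> str:
    return f"{individual}.T{time_index}.{modality}"


def write_expression(ds: TemporalOmicsDataset, matrix_path, metadata_path, mode="w"):
    """Write one modality as a matrix TSV plus sample-metadata TSV rows."""
    cols, meta = [], []
    F, T1, P = ds.values.shape
    data = {}
    for p, ind in enumerate(ds.individuals):
        for t in range(T1):
            sid = sample_id(ind, t, ds.modality)
            cols.append(sid)
            data[sid] = ds.values[:, t, p]
            meta.append(
                dict(sample_id=sid, individual=ind, group=ds.groups[p],
                     time_index=t, time_hours=ds.time_hours[t], modality=ds.modality)
            )
    frame = pd.DataFrame(data, index=pd.Index(ds.features, name="symbol"))
    frame.to_csv(matrix_path, sep="\t", na_rep="NA")
    meta_frame = pd.DataFrame(meta)
    write_header = mode == "w" or not Path(metadata_path).exists()
    meta_frame.to_csv(metadata_path, sep="\t", index=False, mode=mode,
                      header=write_header)


def read_expression(matrix_path, metadata_path) -> dict:
    """Assemble TemporalOmicsDataset objects per modality from TSVs.

    Every matrix column must be described by a metadata row; duplicate
    (individual, time, modality) combinations and unknown labels are hard
    errors.  Missing values are allowed only in the protein modality.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
    matrix.index = matrix.index.astype(str).str.upper()
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate feature row {dup!r}")
    meta = pd.read_csv(metadata_path, sep="\t")
    meta_by_sample, seen_keys = {}, set()
    for row in meta.itertuples():
        key = (row.individual, int(row.time_index), row.modality)
        if key in seen_keys:
            raise ValueError(f"duplicate sample for {key}")
        seen_keys.add(key)
        meta_by_sample[row.sample_id] = row
    missing = [c for c in matrix.columns if c not in meta_by_sample]
    if missing:
        raise ValueError(f"matrix column without metadata: {missing[0]!r}")
    out = {}
    for modality in (TRANSCRIPT, PROTEIN):
        rows = [r for r in meta_by_sample.values() if r.modality == modality
                and r.sample_id in set(matrix.columns)]
        if not rows:
            continue
        individuals = sorted({r.individual for r in rows},
                             key=lambda i: [r.individual for r in rows].index(i))
        times = sorted({int(r.time_index) for r in rows})
        if times != list(range(len(times))):
            raise ValueError("time indices must be contiguous from 0")
        groups, hours = {}, {}
        for r in rows:
            if r.group not in GROUPS:
                raise ValueError(f"unknown group label {r.group!r}")
            groups[r.individual] = r.group
            hours[int(r.time_index)] = float(r.time_hours)
        values = np.full((len(matrix), len(times), len(individuals)), np.nan)
        for r in rows:
            p = individuals.index(r.individual)
            values[:, int(r.time_index), p] = matrix[r.sample_id].to_numpy()
        if modality == TRANSCRIPT and np.isnan(values).any():
            raise ValueError("transcript matrix has missing cells")
        out[modality] = TemporalOmicsDataset(
            modality=modality, values=values, features=list(matrix.index),
            time_hours=tuple(hours[t] for t in times),
            individuals=individuals, groups=[groups[i] for i in individuals],
        )
    return out


def write_fold_changes(fc: FoldChangeTensor, path, mode="w"):
    """Tidy fold-change TSV: modality, symbol, individual, group, time, log2fc."""
    rows = []
    for f, sym in enumerate(fc.features):
        abundance = fc.abundance[f] if fc.abundance is not None else np.nan
        for t in range(fc.n_times):
            for p, ind in enumerate(fc.individuals):
                rows.append(
                    dict(modality=fc.modality, symbol=sym, individual=ind,
                         group=fc.groups[p], time=t + 1,
                         time_hours=fc.time_hours[t],
                         log2fc=fc.log2fc[f, t, p], abundance=abundance)
                )
    frame = pd.DataFrame(rows)
    header = mode == "w" or not Path(path).exists()
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", mode=mode, header=header)


def read_fold_changes(path) -> dict:
    """Rebuild FoldChangeTensor objects per modality from the tidy TSV."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    out = {}
    for modality, sub in frame.groupby("modality"):
        features = list(dict.fromkeys(sub["symbol"]))
        individuals = list(dict.fromkeys(sub["individual"]))
        times = sorted(sub["time"].unique())
        groups = {r.individual: r.group for r in sub.itertuples()}
        hours = {int(r.time): float(r.time_hours) for r in sub.itertuples()}
        fidx = {s: i for i, s in enumerate(features)}
        pidx = {s: i for i, s in enumerate(individuals)}
        arr = np.full((len(features), len(times), len(individuals)), np.nan)
        abund = np.full(len(features), np.nan)
        has_abund = "abundance" in sub.columns
        for r in sub.itertuples():
            arr[fidx[r.symbol], int(r.time) - 1, pidx[r.individual]] = r.log2fc
            if has_abund:
                abund[fidx[r.symbol]] = r.abundance
        out[modality] = FoldChangeTensor(
            modality=modality, log2fc=arr, features=features,
            time_hours=tuple(hours[t] for t in times),
            individuals=individuals, groups=[groups[i] for i in individuals],
            abundance=abund if has_abund and np.isfinite(abund).any() else None,
        )
    return out


# ---------------------------------------------------------------------------
# edges, priors, annotations


def write_edges(edges, path):
    """Edge TSV: either truth (source, target, weight) or prior
    (source, target, confidence) three-column tables."""
    pd.DataFrame(edges, columns=["source", "target", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_edges(path) -> PriorNetwork:
    """Read a 2-3 column edge TSV as a prior network (uppercased symbols).

    A missing third column defaults to confidence 1; duplicate edges merge
    at the maximum confidence.
    """
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError("edge table needs at least source and target columns")
    src, tgt = frame.columns[:2]
    conf = frame.columns[2] if frame.shape[1] > 2 else None
    edges = [
        (str(r[src]).upper(), str(r[tgt]).upper(),
         float(r[conf]) if conf else 1.0)
        for _, r in frame.iterrows()
    ]
    return PriorNetwork(edges=edges)


def read_truth_edges(path):
    """(source, target, weight) triples from a truth edge TSV."""
    frame = pd.read_csv(path, sep="\t")
    src, tgt, val = frame.columns[:3]
    return [
        (str(r[src]).upper(), str(r[tgt]).upper(), float(r[val]))
        for _, r in frame.iterrows()
    ]


def write_gmt(ann: AnnotationMap, path):
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(ann.terms):
            symbols = "\t".join(sorted(ann.terms[term]))
            fh.write(f"{term}\tna\t{symbols}\n")


def read_gmt(path) -> AnnotationMap:
    """Standard GMT: term <tab> description <tab> symbol...; malformed lines
    raise with their line number."""
    terms = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: {line!r}")
            terms[parts[0]] = set(parts[2:])
    return AnnotationMap(terms=terms)


# ---------------------------------------------------------------------------
# network exports


def write_sif(net: InferredNetwork, path, relation="regulates"):
    with open(path, "w", encoding="utf-8") as fh:
        for row in net.edges.itertuples():
            fh.write(f"{row.source}\t{relation}\t{row.target}\n")


def read_sif(path):
    """Edge multiset [(source, target)] from a SIF file."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 3:
                out.append((parts[0], parts[2]))
    return out


def to_graph(net: InferredNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    modality = net.actor_modality or {}
    for a in net.actors:
        g.add_node(a, cluster=int(net.clusters.m[a]),
                   modality=modality.get(a, "transcript"))
    for row in net.edges.itertuples():
        g.add_edge(row.source, row.target, omega=float(row.omega_hat),
                   stability_frequency=float(row.stability_frequency),
                   sign=int(row.sign), in_prior=bool(row.in_prior))
    return g


def write_graphml(net: InferredNetwork, path, layers=None):
    """GraphML with omega, stability_frequency, cluster and (optionally)
    subnetwork layer attributes, loadable in Cytoscape."""
    g = to_graph(net)
    if layers is not None:
        for a in g.nodes:
            if a in layers.actors:
                g.nodes[a]["layer"] = layers.layer_of(a)
    nx.write_graphml(g, path)


def write_network_tables(net: InferredNetwork, outdir, stem="network"):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net.edges.to_csv(outdir / f"{stem}_edges.tsv", sep="\t", index=False)
    write_sif(net, outdir / f"{stem}.sif")
    write_graphml(net, outdir / f"{stem}.graphml")


def write_model_json(results, path):
    """Fitted-model dump: transfer matrices, hyperparameters, diagnostics."""
    payload = {
        "lambda": results.lam,
        "kappa": results.kappa,
        "converged": bool(results.converged),
        "n_iter": int(results.n_iter),
        "objective_path": [float(v) for v in results.objective_path],
        "n_edges": int(results.support.sum()),
        "F": {f"{i},{j}": results.F[(i, j)].tolist() for (i, j) in sorted(results.F)},
        "residual_scale": {a: float(s) for a, s in
                           zip(results.model.actors, results.residual_scale)},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
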