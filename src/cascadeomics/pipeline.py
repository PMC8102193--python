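"""Pipeline configuration and the stage orchestrator.

Every stage reads its inputs from, and writes its outputs to, the run's
output directory, so a run is resumable from any intermediate: rerunning a
later stage only needs the files of the earlier ones.  The resolved
configuration is written next to the outputs of every run and the global
seed threads every stochastic stage.

Joint network inference treats a gene and its protein as distinct actors:
gene actors keep their plain symbol, protein actors carry a ``:P`` suffix,
and temporal clusters are onset ranks computed over both modalities at
once.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .benchmark import score_recovery
from .cascade import CascadeNetworkModel, InferredNetwork, assign_clusters, degree_summary
from .concordance import build_pairs, correlation_profile, delay_summary, sign_concordance
from .datasets import PROTEIN, TRANSCRIPT
from .preprocess import (
    filter_low_expression,
    log2fc_vs_t0,
    normalize_median_ratios,
    quantile_normalize,
)
from .signatures import build_signature_sets
from .subnetwork import (
    DEFAULT_SEED_TERMS,
    compare_networks,
    extract_subnetwork,
    select_seeding_proteins,
    temporal_function_counts,
)
from .synthetic import (
    SimulationConfig,
    generate_annotations,
    generate_network,
    generate_prior,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

PROTEIN_SUFFIX = ":P"

STAGES = ("simulate", "preprocess", "signatures", "concordance",
          "infer", "subnet", "benchmark")


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run (unknown keys are rejected)."""

    outdir: str = "cascadeomics_run"
    seed: int = 0
    # input paths (filled by the simulate stage when simulation is on)
    expression: str = ""
    metadata: str = ""
    prior: str = ""
    annotations: str = ""
    truth: str = ""
    # simulate
    simulate: bool = True
    n_actors: int = 30
    n_clusters: int = 3
    mean_out_degree: float = 1.5
    attachment_exponent: float = 1.0
    knockout_fraction: float = 0.5
    snr: float = 4.0
    n_background: int = 100
    prior_coverage: float = 0.5
    prior_false_edges: int = 20
    # preprocess
    min_cpm: float = 1.0
    min_samples: int = 1
    pseudocount: float = 1.0
    # signatures
    alpha_temporal: float = 0.01
    alpha_response: float = 0.05
    # concordance
    max_lag: int = 3
    min_points: int = 3
    # inference
    lam: str = "auto"          # "auto" (grouped CV) or a number as string
    lam_grid: tuple = (1e-4, 1e-3, 0.01, 0.1, 0.3, 0.6, 1.2, 2.4)
    kappa: float = 0.5
    B: int = 100
    subsample_fraction: float = 0.5
    pi_thr: float = 0.6
    refit_ols: bool = False
    # subnetwork
    terms: tuple = DEFAULT_SEED_TERMS
    hub_threshold: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("lam_grid", "terms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def write(self, path):
        payload = dataclasses.asdict(self)
        payload["lam_grid"] = list(self.lam_grid)
        payload["terms"] = list(self.terms)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _out(config) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig):
    out = _out(config)
    net = generate_network(
        config.n_actors, config.n_clusters,
        mean_out_degree=config.mean_out_degree,
        attachment_exponent=config.attachment_exponent,
        knockout_fraction_of_cluster1=config.knockout_fraction,
        seed=config.seed,
    )
    sim = SimulationConfig(seed=config.seed, n_background=config.n_background)
    if config.snr:
        from .synthetic import calibrate_noise_for_snr

        sim.noise_sd = calibrate_noise_for_snr(net, sim, config.snr)
    matrix, metadata = out / "expression.tsv", out / "samples.tsv"
    frames, meta_rows = [], []
    for group in ("proliferative", "nonproliferative"):
        tr, pr = simulate_dataset(net, sim, group)
        for ds in (tr, pr):
            for p, ind in enumerate(ds.individuals):
                for t in range(ds.n_times):
                    sid = cio.sample_id(ind, t, ds.modality)
                    frames.append(pd.Series(ds.values[:, t, p],
                                            index=ds.features, name=sid))
                    meta_rows.append(
                        dict(sample_id=sid, individual=ind, group=group,
                             time_index=t, time_hours=ds.time_hours[t],
                             modality=ds.modality)
                    )
    pd.concat(frames, axis=1).rename_axis("symbol").to_csv(
        matrix, sep="\t", na_rep="NA"
    )
    pd.DataFrame(meta_rows).to_csv(metadata, sep="\t", index=False)
    cio.write_edges(net.edges, out / "truth_edges.tsv")
    prior = generate_prior(net, config.prior_coverage, config.prior_false_edges,
                           seed=config.seed)
    cio.write_edges(prior.edges, out / "prior_edges.tsv")
    from .subnetwork import AnnotationMap

    cio.write_gmt(AnnotationMap(terms=generate_annotations(net, config.seed)),
                  out / "annotations.gmt")
    config.expression = str(matrix)
    config.metadata = str(metadata)
    config.prior = str(out / "prior_edges.tsv")
    config.annotations = str(out / "annotations.gmt")
    config.truth = str(out / "truth_edges.tsv")
    logger.info("simulate: %d actors, %d true edges", config.n_actors,
                len(net.edges))


def stage_preprocess(config: PipelineConfig):
    out = _out(config)
    datasets = cio.read_expression(config.expression, config.metadata)
    fc_path = out / "fold_changes.tsv"
    mode = "w"
    if TRANSCRIPT in datasets:
        ds = filter_low_expression(datasets[TRANSCRIPT], config.min_cpm,
                                   config.min_samples)
        ds = normalize_median_ratios(ds)
        fc = log2fc_vs_t0(ds, pseudocount=config.pseudocount)
        cio.write_fold_changes(fc, fc_path, mode=mode)
        mode = "a"
    if PROTEIN in datasets:
        ds = quantile_normalize(datasets[PROTEIN])
        fc = log2fc_vs_t0(ds, pseudocount=0.0)
        cio.write_fold_changes(fc, fc_path, mode=mode)
    logger.info("preprocess: fold changes at %s", fc_path)


def _load_fold_changes(config):
    return cio.read_fold_changes(Path(config.outdir) / "fold_changes.tsv")


def stage_signatures(config: PipelineConfig):
    out = _out(config)
    fcs = _load_fold_changes(config)
    sig = build_signature_sets(fcs[TRANSCRIPT], fcs[PROTEIN],
                               alpha_temporal=config.alpha_temporal,
                               alpha_response=config.alpha_response)
    rows = []
    for (group, modality), members in sig.temporal.items():
        for sym, times in members.items():
            rows.append(dict(symbol=sym, modality=modality, set="temporal",
                             group=group, first_significant_time=min(times),
                             directions=";".join(f"{t}:{d:+d}"
                                                 for t, d in sorted(times.items()))))
    for modality, members in sig.response.items():
        for sym, times in members.items():
            rows.append(dict(symbol=sym, modality=modality, set="response",
                             group="", first_significant_time=min(times),
                             directions=";".join(f"{t}:{d:+d}"
                                                 for t, d in sorted(times.items()))))
    for modality, members in sig.proliferative.items():
        for sym in sorted(members):
            rows.append(dict(symbol=sym, modality=modality, set="proliferative",
                             group="", first_significant_time=-1, directions=""))
    pd.DataFrame(rows).to_csv(out / "signatures.tsv", sep="\t", index=False)
    with open(out / "signature_summary.json", "w", encoding="utf-8") as fh:
        json.dump(sig.summary(), fh, indent=1)
    logger.info("signatures: %s", sig.summary())


def _load_signatures(config):
    frame = pd.read_csv(Path(config.outdir) / "signatures.tsv", sep="\t",
                        keep_default_na=False)
    temporal, response, prolif = {}, {}, {}
    for row in frame.itertuples():
        times = {}
        if row.directions:
            for part in str(row.directions).split(";"):
                t, d = part.split(":")
                times[int(t)] = int(d)
        if row.set == "temporal":
            temporal.setdefault((row.group, row.modality), {})[row.symbol] = times
        elif row.set == "response":
            response.setdefault(row.modality, {})[row.symbol] = times
        else:
            prolif.setdefault(row.modality, set()).add(row.symbol)
    return temporal, response, prolif


def stage_concordance(config: PipelineConfig):
    out = _out(config)
    fcs = _load_fold_changes(config)
    temporal, _response, _prolif = _load_signatures(config)
    gene_sig = temporal.get(("proliferative", TRANSCRIPT), {})
    prot_sig = temporal.get(("proliferative", PROTEIN), {})
    shared = sorted(set(gene_sig) & set(prot_sig))
    if not shared:
        logger.warning("concordance: no matched gene/protein pairs")
        return
    pairs = build_pairs(fcs[TRANSCRIPT], fcs[PROTEIN], shared, "proliferative")
    correlation_profile(pairs, config.min_points).to_csv(
        out / "correlation_by_time.tsv", sep="\t", index=False
    )
    summary = delay_summary(pairs, max_lag=config.max_lag,
                            protein_hours=(0,) + tuple(fcs[PROTEIN].time_hours))
    summary["sign_concordance"] = sign_concordance(pairs, gene_sig, prot_sig)
    summary["n_matched_symbols"] = len(shared)
    with open(out / "concordance_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    logger.info("concordance: %s", summary)


def _joint_model(config, fcs, temporal, group):
    """Gene + protein actors of one group's temporal signature, one model."""
    gene_sig = temporal.get((group, TRANSCRIPT), {})
    prot_sig = temporal.get((group, PROTEIN), {})
    merged = {sym: times for sym, times in gene_sig.items()}
    merged.update({sym + PROTEIN_SUFFIX: times for sym, times in prot_sig.items()})
    clusters = assign_clusters(merged)
    if not clusters.m:
        return None
    series, actors = [], []
    keep = [i for i, g in enumerate(fcs[TRANSCRIPT].groups) if g == group]
    for sym in gene_sig:
        series.append(fcs[TRANSCRIPT].series(sym)[:, keep].T)
        actors.append(sym)
    keep_p = [i for i, g in enumerate(fcs[PROTEIN].groups) if g == group]
    for sym in prot_sig:
        series.append(fcs[PROTEIN].series(sym)[:, keep_p].T)
        actors.append(sym + PROTEIN_SUFFIX)
    prior = None
    if config.prior:
        base = cio.read_edges(config.prior)
        # prior edges name plain symbols; apply to gene actors and mirror
        # onto the protein actors of the same symbols
        mirrored = list(base.edges)
        mirrored += [(s + PROTEIN_SUFFIX, t + PROTEIN_SUFFIX, c)
                     for s, t, c in base.edges]
        mirrored += [(s, t + PROTEIN_SUFFIX, c) for s, t, c in base.edges]
        from .cascade import PriorNetwork

        prior = PriorNetwork(edges=mirrored)
    model = CascadeNetworkModel(np.asarray(series), actors, clusters,
                                prior=prior, kappa=config.kappa)
    return model


def stage_infer(config: PipelineConfig):
    out = _out(config)
    fcs = _load_fold_changes(config)
    temporal, _r, _p = _load_signatures(config)
    for group, stem in (("proliferative", "network_P"),
                        ("nonproliferative", "network_NP")):
        model = _joint_model(config, fcs, temporal, group)
        if model is None:
            logger.warning("infer: no actors for group %s", group)
            continue
        if config.lam == "auto":
            lam, cv_table = model.cross_validate(config.lam_grid)
            cv_table.to_csv(out / f"{stem}_cv.tsv", sep="\t", index=False)
        else:
            lam = float(config.lam)
        net = model.stability_selection(
            lam, B=config.B, subsample_fraction=config.subsample_fraction,
            pi_thr=config.pi_thr, seed=config.seed,
        )
        net.actor_modality = {
            a: ("protein" if a.endswith(PROTEIN_SUFFIX) else "transcript")
            for a in net.actors
        }
        cio.write_network_tables(net, out, stem=stem)
        res = model.fit(lam, max_iter=1, refit_ols=config.refit_ols)
        cio.write_model_json(res, out / f"{stem}_model.json")
        hubs, table = degree_summary(net, config.hub_threshold)
        table.to_csv(out / f"{stem}_degrees.tsv", sep="\t", index=False)
        logger.info("infer %s: lambda %.4g, %d edges, %d hubs",
                    group, lam, len(net.edges), len(hubs))


def _load_network(config, stem) -> InferredNetwork:
    out = Path(config.outdir)
    edges = pd.read_csv(out / f"{stem}_edges.tsv", sep="\t")
    if edges.empty:
        edges = edges.reindex(columns=["source", "target", "omega_hat",
                                       "stability_frequency", "sign",
                                       "source_cluster", "target_cluster",
                                       "in_prior"])
    temporal, _r, _p = _load_signatures(config)
    group = "proliferative" if stem.endswith("_P") else "nonproliferative"
    gene_sig = temporal.get((group, TRANSCRIPT), {})
    prot_sig = temporal.get((group, PROTEIN), {})
    merged = {sym: times for sym, times in gene_sig.items()}
    merged.update({s + PROTEIN_SUFFIX: t for s, t in prot_sig.items()})
    clusters = assign_clusters(merged)
    actors = list(clusters.m)
    modality = {a: ("protein" if a.endswith(PROTEIN_SUFFIX) else "transcript")
                for a in actors}
    return InferredNetwork(edges=edges, actors=actors, clusters=clusters,
                           pi_thr=0.0, actor_modality=modality)


def stage_subnet(config: PipelineConfig):
    out = _out(config)
    ann = cio.read_gmt(config.annotations)
    layer_objects = {}
    for stem in ("network_P", "network_NP"):
        if not (out / f"{stem}_edges.tsv").exists():
            continue
        net = _load_network(config, stem)
        seeds = select_seeding_proteins(ann, config.terms, net)
        layers = extract_subnetwork(net, seeds)
        layer_objects[stem] = layers
        rows = [dict(actor=a, symbol=layers.symbol_of[a],
                     layer=layers.layer_of(a)) for a in sorted(layers.actors)]
        pd.DataFrame(rows, columns=["actor", "symbol", "layer"]).to_csv(
            out / f"{stem}_subnetwork.tsv", sep="\t", index=False
        )
        cio.write_graphml(net, out / f"{stem}_subnetwork.graphml", layers=layers)
    if len(layer_objects) == 2:
        report = compare_networks(layer_objects["network_P"],
                                  layer_objects["network_NP"])
        report["shared_edges"] = [list(e) for e in report["shared_edges"]]
        with open(out / "network_overlap.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1)
    temporal, _r, _p = _load_signatures(config)
    prot_sig = temporal.get(("proliferative", PROTEIN), {})
    counts = temporal_function_counts(prot_sig, ann)
    counts.to_csv(out / "temporal_function_counts.tsv", sep="\t", index=False)
    logger.info("subnet: layers %s",
                {k: (len(v.layer1), len(v.layer2), len(v.layer3))
                 for k, v in layer_objects.items()})


def stage_benchmark(config: PipelineConfig):
    out = _out(config)
    if not config.truth:
        logger.info("benchmark: no ground truth available, skipped")
        return
    truth_edges = {(s, t) for s, t, _w in cio.read_truth_edges(config.truth)}
    net = _load_network(config, "network_P")
    gene_edges = {(s, t) for s, t in net.edge_set
                  if not s.endswith(PROTEIN_SUFFIX)
                  and not t.endswith(PROTEIN_SUFFIX)}

    class _Truth:  # minimal edge_set carrier for the scorer
        edge_set = truth_edges

    metrics = score_recovery(gene_edges, _Truth, directed=True)
    with open(out / "benchmark.json", "w", encoding="utf-8") as fh:
        json.dump(metrics.as_dict(), fh, indent=1)
    logger.info("benchmark: %s", metrics.as_dict())


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "signatures": stage_signatures,
    "concordance": stage_concordance,
    "infer": stage_infer,
    "subnet": stage_subnet,
    "benchmark": stage_benchmark,
}


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Execute the pipeline stages in order; any failure raises with the
    stage name.  Returns the artifact directory."""
    out = _out(config)
    todo = list(stages) if stages else [
        s for s in STAGES if s != "simulate" or config.simulate
    ]
    unknown = [s for s in todo if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    for stage in STAGES:
        if stage not in todo:
            continue
        try:
            _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    config.write(out / "resolved_config.yaml")
    return out
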