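# cascadeomics

Temporal multi-omic cascade network inference for short stimulation time
courses.

When primary cells are stimulated — the motivating case is B-cell
receptor engagement of chronic lymphocytic leukemia lymphocytes — the
response unfolds as a cascade: a handful of early transcripts switch on
within the first hour, relay through successive waves of genes and, with
a translation delay of a few hours, proteins, until proliferation
machinery dominates days later. Measuring that cascade yields paired
transcript and protein abundance matrices over ~9 time points for only a
few individuals per condition: thousands of features, almost no
replicates, and a directed temporal structure that ordinary differential
expression tools ignore.

`cascadeomics` is for computational biologists who want to analyse such
designs end to end:

* **Signatures** — moderated-t differential testing of both modalities on
  per-individual log2 fold changes; a *temporal* signature (any T vs T0,
  FDR < 1%), a *response* signature (condition vs control, FDR < 5%),
  and their exact intersection, the *proliferative* signature.
* **Concordance** — median gene/protein correlations over growing time
  windows, per-pair translation-delay estimation by lagged correlation,
  and sign concordance of matched pairs.
* **Cascade inference** — the core. Actors (genes and proteins, by
  symbol) are ordered into temporal clusters m(·) by response onset, and
  every actor profile is regressed on same-or-earlier-cluster candidates
  through strictly time-triangular transfer matrices:

      x_l[p,·] = Σ_k ω_{kl} · F_{m(k) m(l)} · x_k[p,·] + ε_l[p,·]

  Sparse ω is estimated by LASSO with a *weighted stability selection*:
  B refits on row subsamples, edges kept at selection frequency ≥ π, and
  known interactions favored by a multiplicative penalty factor κ < 1.
  λ is chosen by leave-one-individual-out cross-validation.
* **Subnetworks** — seeding proteins picked by biological-process
  annotation ("cell cycle regulation", "proliferation"), their connected
  neighborhood, a three-layer stratification (seed proteins / the genes
  encoding them / the rest), and overlap reports between condition-
  specific networks.
* **Benchmark** — a first-class synthetic generator planting a
  scale-free, wave-structured cascade with negative-binomial transcript
  counts, lagged Gaussian protein intensities, left-censored missingness
  and a silenced-input control group, plus sensitivity / precision /
  F-score recovery scoring against the planted truth.

The inference core follows the statsmodels idiom:
`CascadeNetworkModel(...).fit(lam)` returns a `CascadeResults` with
coefficients, transfer matrices, an objective trajectory and a
`summary()`; stability selection and cross-validation are methods of the
model.

## Worked example

Plant a 30-actor, 3-wave cascade, simulate a proliferative group at a
4:1 signal-to-noise ratio, and reverse-engineer it:

```python
from cascadeomics import (generate_network, generate_prior, SimulationConfig,
                          simulate_dataset, CascadeNetworkModel, assign_clusters,
                          calibrate_noise_for_snr, degree_summary)
from cascadeomics.preprocess import log2fc_vs_t0
from cascadeomics.signatures import temporal_tests, temporal_signature
from cascadeomics.benchmark import score_recovery

net = generate_network(n_actors=30, n_clusters=3, mean_out_degree=1.5, seed=42)
config = SimulationConfig(seed=42, n_background=100)
config.noise_sd = calibrate_noise_for_snr(net, config, snr=4.0)
transcript, protein = simulate_dataset(net, config, "proliferative")

fc = log2fc_vs_t0(transcript, pseudocount=1.0)
signature = temporal_signature(temporal_tests(fc, "proliferative"), alpha=0.01)
clusters = assign_clusters(signature)

prior = generate_prior(net, coverage=0.5, false_edge_count=20, seed=42)
model = CascadeNetworkModel.from_fold_changes(fc, clusters, prior=prior, kappa=0.5)
lam, _cv = model.cross_validate((1e-3, 0.01, 0.1, 0.3, 0.6, 1.2))
network = model.stability_selection(lam, B=100, pi_thr=0.6, seed=42)
m = score_recovery(network, net)
print(f"{len(network.edges)} edges; sensitivity {m.sensitivity:.2f}, "
      f"precision {m.precision:.2f}, F {m.f_score:.2f}")
```

which prints:

```
54 edges; sensitivity 0.84, precision 0.70, F 0.77
```

All 30 planted actors (and none of the 100 flat background features) land
in the temporal signature; cross-validation picks λ = 0.6; stability
selection keeps 54 of the 138 edges a single LASSO fit would report,
recovering 38 of the 45 planted links at 70% precision. `degree_summary`
then lists the hub actors and `cascadeomics.io.write_graphml` exports the
network with stability frequencies and cluster annotations for Cytoscape.

The same flow runs from the shell against TSV/GMT inputs:

```bash
cascadeomics run --outdir demo --seed 42      # simulate + full pipeline
cascadeomics infer --config demo/resolved_config.yaml --lambda auto --kappa 0.5
```

A pipeline run writes expression and metadata TSVs, fold changes,
signature tables, concordance summaries, edge tables / SIF / GraphML for
both condition networks, the layered subnetworks with their overlap
report, and the resolved configuration.

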