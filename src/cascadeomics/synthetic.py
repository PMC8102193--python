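"""Synthetic paired transcript/protein time courses with a planted cascade.

The generator plays the role of the deposited stimulation experiments: two
groups of individuals (proliferative / nonproliferative), nine shared time
indices T0..T8 whose nominal hours differ between modalities, count-like
transcript observations, log-intensity protein observations lagged by a
translation delay, and a planted directed cascade network whose edges run
from earlier temporal clusters to later ones.

Design of the latent dynamics
-----------------------------
Cluster-1 actors are exogenous stimulus inputs: each trajectory is a
decaying envelope times a signed per-time modulation, shared across
individuals up to a small multiplicative jitter, so that input profiles
are linearly well separated (see docs/methods.md).  Every other actor
evolves by a linear lag-``delay_steps`` recursion

    latent(a, t) = sum_parents omega * latent(parent, t - delay) + N(0, sigma)

which is exactly the forward direction of the transfer-matrix regression
model the inference module estimates, with pure delay matrices as transfer
operators.  Planted edges connect adjacent waves (cluster c drives
cluster c+1) and every non-input actor has at least one upstream parent,
so the first-response order of actors is the cluster order itself.

In the nonproliferative group a configured subset of cluster-1 actors is
silenced (flat zero latent); all random draws are shared between the two
groups through per-feature substreams, so the groups differ only at the
silenced actors and their network descendants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import (
    PROTEIN,
    PROTEIN_HOURS,
    TRANSCRIPT,
    TRANSCRIPT_HOURS,
    TemporalOmicsDataset,
)
from .cascade import PriorNetwork

LOG2E = math.log2(math.e)

logger = logging.getLogger(__name__)


@dataclass
class GroundTruthNetwork:
    """Planted cascade: the benchmark oracle.

    ``edges`` are (source, target, weight) with cluster(source) <=
    cluster(target); ``delay_steps`` is the index lag of the propagation;
    ``knockout_set`` lists cluster-1 actors silenced in the
    nonproliferative group.
    """

    actors: list
    cluster_of: dict
    edges: list
    delay_steps: int = 1
    knockout_set: set = field(default_factory=set)

    def __post_init__(self):
        seen = set()
        for s, t, _w in self.edges:
            if s == t:
                raise ValueError(f"self-loop on {s}")
            if (s, t) in seen:
                raise ValueError(f"duplicate edge {s}->{t}")
            seen.add((s, t))
            if self.cluster_of[s] > self.cluster_of[t]:
                raise ValueError(f"acausal edge {s}->{t}")
        if self.delay_steps < 1:
            raise ValueError("delay_steps must be >= 1")

    @property
    def edge_set(self):
        return {(s, t) for s, t, _ in self.edges}

    @property
    def n_clusters(self):
        return max(self.cluster_of.values())

    def parents_of(self):
        out = {a: [] for a in self.actors}
        for s, t, w in self.edges:
            out[t].append((s, w))
        return out

    def descendants(self, seeds):
        """All actors reachable from ``seeds`` (seeds included)."""
        children = {a: [] for a in self.actors}
        for s, t, _ in self.edges:
            children[s].append(t)
        todo, seen = list(seeds), set(seeds)
        while todo:
            for c in children[todo.pop()]:
                if c not in seen:
                    seen.add(c)
                    todo.append(c)
        return seen

    def out_degrees(self):
        deg = {a: 0 for a in self.actors}
        for s, _t, _w in self.edges:
            deg[s] += 1
        return deg


@dataclass
class SimulationConfig:
    """Study-design parameters of the emulated experiment.

    Defaults mirror the design the package targets: 3 individuals per
    group, nine time indices with transcript hours
    (0, 1, 1.5, 3.5, 6.5, 12, 24, 48, 96) and protein hours
    (0, 1, 2, 4, 7, 12, 24, 48, 96), negative-binomial transcript counts,
    Gaussian log2-intensity protein noise, a one-index translation delay
    and 5% left-censored protein missingness.
    """

    n_individuals_per_group: int = 3
    time_grid_transcript_hours: tuple = TRANSCRIPT_HOURS
    time_grid_protein_hours: tuple = PROTEIN_HOURS
    noise_sd: float = 0.2              # latent process noise sigma
    # technical NB dispersion (var = mu + phi mu^2); biological variability
    # is modeled in the latent layer (impulse jitter + process noise)
    count_dispersion: float = 0.005
    translation_delay_steps: int = 1
    protein_missing_rate: float = 0.05
    protein_noise_sd: float = 0.3      # log2 intensity units
    n_background: int = 200            # flat, non-network filler features
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.0
    protein_baseline_mean: float = 22.0
    protein_baseline_sd: float = 1.5
    impulse_amplitude: tuple = (1.0, 2.0)
    impulse_tau: tuple = (2.0, 5.0)    # envelope decay constants, index units
    individual_jitter: float = 0.1     # relative spread of impulse params across individuals
    deterministic: bool = False        # phi -> 0 switch: observations = noiseless means
    seed: int = 0

    def __post_init__(self):
        if len(self.time_grid_transcript_hours) != len(self.time_grid_protein_hours):
            raise ValueError("modality grids must share the index length")
        for grid in (self.time_grid_transcript_hours, self.time_grid_protein_hours):
            if grid[0] != 0:
                raise ValueError("grids must start at 0 h")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if not 0 <= self.protein_missing_rate < 1:
            raise ValueError("protein_missing_rate must be in [0, 1)")

    @property
    def n_times(self):
        return len(self.time_grid_transcript_hours)


def generate_network(
    n_actors: int,
    n_clusters: int,
    mean_out_degree: float = 2.0,
    attachment_exponent: float = 1.0,
    knockout_fraction_of_cluster1: float = 0.5,
    seed: int = 0,
    delay_steps: int = 1,
) -> GroundTruthNetwork:
    """Plant a scale-free-ish cascade across temporal clusters.

    Actors are partitioned into ``n_clusters`` non-empty clusters; edges are
    drawn by preferential attachment on the current out-degree (propensity
    ``(deg + 1) ** attachment_exponent``) and relay from each temporal wave
    to the next (cluster c drives cluster c+1).  Every non-cluster-1 actor
    is guaranteed one upstream parent so no actor is silent.  Weights are
    uniform in +/-[0.5, 1.5].
    """
    if n_clusters > n_actors:
        raise ValueError("n_clusters may not exceed n_actors")
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if mean_out_degree <= 0:
        raise ValueError("mean_out_degree must be > 0")
    if knockout_fraction_of_cluster1 < 0 or knockout_fraction_of_cluster1 > 1:
        raise ValueError("knockout fraction must be in [0, 1]")

    rng = np.random.default_rng([seed, 101])
    width = max(3, len(str(n_actors)))
    actors = [f"A{i:0{width}d}" for i in range(1, n_actors + 1)]
    order = list(rng.permutation(n_actors))
    # near-equal contiguous chunks, each non-empty
    bounds = np.linspace(0, n_actors, n_clusters + 1).round().astype(int)
    cluster_of = {}
    for c in range(n_clusters):
        for i in order[bounds[c]:bounds[c + 1]]:
            cluster_of[actors[i]] = c + 1

    by_cluster = {c: [a for a in actors if cluster_of[a] == c] for c in range(1, n_clusters + 1)}
    edge_set = set()
    out_deg = {a: 0 for a in actors}

    def draw_weight():
        return float(rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0]))

    edges = []
    # relay cascade: every wave-c actor is driven by at least one wave-(c-1)
    # actor, so each cluster responds exactly one delay step after the
    # previous one and the cluster label is the actor's temporal wave
    for c in range(2, n_clusters + 1):
        upstream = by_cluster[c - 1]
        for target in by_cluster[c]:
            source = upstream[int(rng.integers(len(upstream)))]
            edge_set.add((source, target))
            out_deg[source] += 1
            edges.append((source, target, draw_weight()))

    n_edges = max(len(edges), int(round(mean_out_degree * n_actors)))
    eligible_sources = [a for a in actors if cluster_of[a] < n_clusters]
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        w = np.array(
            [(out_deg[a] + 1.0) ** attachment_exponent for a in eligible_sources]
        )
        source = eligible_sources[int(rng.choice(len(eligible_sources), p=w / w.sum()))]
        targets = [
            t for t in by_cluster[cluster_of[source] + 1] if (source, t) not in edge_set
        ]
        if not targets:
            continue
        target = targets[int(rng.integers(len(targets)))]
        edge_set.add((source, target))
        out_deg[source] += 1
        edges.append((source, target, draw_weight()))

    c1 = by_cluster[1]
    n_ko = int(round(knockout_fraction_of_cluster1 * len(c1)))
    knockout = set(rng.choice(c1, size=n_ko, replace=False)) if n_ko else set()

    return GroundTruthNetwork(
        actors=actors,
        cluster_of=cluster_of,
        edges=edges,
        delay_steps=delay_steps,
        knockout_set={str(a) for a in knockout},
    )


def _impulse_params(net, config):
    """Per cluster-1 actor x individual impulse amplitude and decay constant.

    Drawn from a stream independent of group so both groups share them.
    """
    rng = np.random.default_rng([config.seed, 555])
    c1 = [a for a in net.actors if net.cluster_of[a] == 1]
    p = config.n_individuals_per_group
    lo_a, hi_a = config.impulse_amplitude
    lo_t, hi_t = config.impulse_tau
    # each actor has its own response trajectory; individuals share it up to
    # a small multiplicative jitter (inter-individual biological variation).
    # The trajectory is a decaying envelope times a signed per-time
    # modulation: early-response genes swing up and down idiosyncratically,
    # which also keeps the input profiles linearly well separated (pure
    # same-shape decays would leave regulators unidentifiable).
    amp_actor = rng.uniform(lo_a, hi_a, size=len(c1))
    tau_actor = rng.uniform(lo_t, hi_t, size=len(c1))
    T = config.n_times - 1
    modulation = rng.normal(0.0, 1.0, size=(len(c1), T))
    j = config.individual_jitter
    amp = amp_actor[:, None] * rng.uniform(1 - j, 1 + j, size=(len(c1), p))
    tau = tau_actor[:, None] * rng.uniform(1 - j, 1 + j, size=(len(c1), p))
    return c1, amp, tau, modulation


def latent_trajectories(
    net: GroundTruthNetwork, config: SimulationConfig, group: str, noise_sd=None
) -> np.ndarray:
    """Latent (n_actors, T+1, P) trajectories for one group.

    ``noise_sd=None`` uses ``config.noise_sd``; pass 0.0 for the noiseless
    signal (used e.g. to calibrate a signal-to-noise ratio).
    """
    if group not in ("proliferative", "nonproliferative"):
        raise ValueError(f"unknown group {group!r}")
    T1 = config.n_times
    d = net.delay_steps
    if d >= T1 - 1:
        raise ValueError("delay_steps >= T leaves no room for propagation")
    sigma = config.noise_sd if noise_sd is None else noise_sd
    P = config.n_individuals_per_group
    A = len(net.actors)
    idx = {a: i for i, a in enumerate(net.actors)}
    parents = net.parents_of()

    c1, amp, tau, modulation = _impulse_params(net, config)
    noise = np.random.default_rng([config.seed, 999]).normal(0.0, 1.0, size=(A, T1, P))

    silenced = net.knockout_set if group == "nonproliferative" else set()
    latent = np.zeros((A, T1, P))
    for j, a in enumerate(c1):
        if a in silenced:
            continue
        i = idx[a]
        for t in range(1, T1):
            latent[i, t, :] = amp[j] * np.exp(-(t - 1) / tau[j]) * modulation[j, t - 1]
    downstream = [a for a in net.actors if net.cluster_of[a] > 1]
    for t in range(1, T1):
        for a in downstream:
            i = idx[a]
            val = np.zeros(P)
            if t - d >= 0:
                for s, w in parents[a]:
                    val += w * latent[idx[s], t - d, :]
            if sigma > 0:
                val = val + sigma * noise[i, t, :]
            latent[i, t, :] = val
    return latent


def latent_signal_sd(net: GroundTruthNetwork, config: SimulationConfig) -> float:
    """Median per-actor temporal sd of the noiseless proliferative latents.

    Convenience for expressing the process-noise level as a signal-to-noise
    ratio: ``noise_sd = latent_signal_sd(...) / snr``.
    """
    latent = latent_trajectories(net, config, "proliferative", noise_sd=0.0)
    sds = latent.std(axis=1).ravel()
    sds = sds[sds > 0]
    return float(np.median(sds)) if sds.size else 0.0


def calibrate_noise_for_snr(net: GroundTruthNetwork, config: SimulationConfig,
                            snr: float) -> float:
    """Latent process-noise sd delivering a fold-change signal-to-noise ratio.

    The ratio is defined on the observed transcript log2 fold changes:
    (median per-actor signal sd) / (total observation noise sd), where the
    total combines the latent process noise with the count-sampling noise
    measured empirically on a zero-process-noise run.  If count noise alone
    already exceeds the budget the returned sd is 0 (the ratio then cannot
    be reached and the residual gap is count-driven).
    """
    from .preprocess import log2fc_vs_t0  # local import: avoid module cycle

    base = dict(vars(config))
    base.update(deterministic=True, noise_sd=0.0, protein_missing_rate=0.0)
    noiseless = SimulationConfig(**base)
    tr0, _ = simulate_dataset(net, noiseless, "proliferative")
    fc0 = log2fc_vs_t0(tr0, pseudocount=0.0)
    n = len(net.actors)
    signal_sd = float(np.median(fc0.log2fc[:n].std(axis=1)))
    base = dict(vars(config))
    base.update(deterministic=False, noise_sd=0.0)
    counts_only = SimulationConfig(**base)
    trc, _ = simulate_dataset(net, counts_only, "proliferative")
    fcc = log2fc_vs_t0(trc, pseudocount=1.0)
    count_sd = float(np.median((fcc.log2fc[:n] - fc0.log2fc[:n]).std(axis=1)))
    budget = (signal_sd / snr) ** 2 - count_sd ** 2
    if budget <= 0:
        logger.warning(
            "count noise sd %.3g alone exceeds the SNR %.3g budget "
            "(signal sd %.3g); using zero latent noise", count_sd, snr, signal_sd,
        )
        return 0.0
    return float(np.sqrt(budget) / LOG2E)


def simulate_dataset(net: GroundTruthNetwork, config: SimulationConfig, group: str):
    """Forward-simulate one group's paired transcript/protein datasets.

    Returns ``(transcript_ds, protein_ds)``.  Transcript observations are
    negative-binomial counts with mean ``baseline * exp(latent)`` and
    dispersion ``count_dispersion``; protein observations are the latent
    lagged by ``translation_delay_steps`` index steps on the log2 scale,
    plus Gaussian noise, left-censored at each feature's lowest-intensity
    quantile.  With ``config.deterministic`` observations equal their
    noiseless means (the dispersion -> 0 limit).  Identical seeds give
    bit-identical output, and all observation substreams are keyed per
    feature so the two groups differ only at knockout actors and their
    descendants.
    """
    latent = latent_trajectories(net, config, group)
    A, T1, P = latent.shape
    d = config.translation_delay_steps
    if d >= T1 - 1:
        raise ValueError("translation_delay_steps >= T leaves no observable lag")

    nb = config.n_background
    width = max(3, len(str(nb))) if nb else 3
    background = [f"BG{i:0{width}d}" for i in range(1, nb + 1)]
    features = list(net.actors) + background
    F = len(features)
    full_latent = np.zeros((F, T1, P))
    full_latent[:A] = latent

    base_rng = np.random.default_rng([config.seed, 111])
    baseline = np.exp(base_rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=F))
    prot_rng = np.random.default_rng([config.seed, 222])
    prot_baseline = prot_rng.normal(config.protein_baseline_mean, config.protein_baseline_sd, size=F)

    prefix = "P" if group == "proliferative" else "NP"
    individuals = [f"{prefix}{i}" for i in range(1, P + 1)]
    groups = [group] * P

    # transcript counts
    mean = baseline[:, None, None] * np.exp(full_latent)
    if config.deterministic:
        counts = mean
    else:
        phi = config.count_dispersion
        r = 1.0 / phi
        counts = np.empty_like(mean)
        for f in range(F):
            frng = np.random.default_rng([config.seed, 777, f])
            p_nb = r / (r + mean[f])
            counts[f] = frng.negative_binomial(r, p_nb)
    transcript = TemporalOmicsDataset(
        modality=TRANSCRIPT,
        values=counts,
        features=features,
        time_hours=config.time_grid_transcript_hours,
        individuals=individuals,
        groups=groups,
    )

    # protein log2 intensities: latent lagged by d on the index grid
    lagged = np.zeros_like(full_latent)
    lagged[:, d:, :] = full_latent[:, : T1 - d, :]
    prot = prot_baseline[:, None, None] + LOG2E * lagged
    if not config.deterministic and config.protein_noise_sd > 0:
        for f in range(F):
            frng = np.random.default_rng([config.seed, 888, f])
            prot[f] = prot[f] + frng.normal(0.0, config.protein_noise_sd, size=(T1, P))
    if config.protein_missing_rate > 0:
        for f in range(F):
            thr = np.quantile(prot[f], config.protein_missing_rate)
            prot[f][prot[f] < thr] = np.nan
    protein = TemporalOmicsDataset(
        modality=PROTEIN,
        values=prot,
        features=features,
        time_hours=config.time_grid_protein_hours,
        individuals=individuals,
        groups=groups,
    )
    return transcript, protein


def generate_annotations(net: GroundTruthNetwork, seed: int = 0) -> dict:
    """Planted biological-process term memberships (term -> symbol set).

    The last temporal wave carries the proliferation program: its actors
    are annotated "PROLIFERATION", and a random half of the last two waves
    "CELL CYCLE REGULATION"; earlier waves get generic signaling /
    transcription terms.  Returned as a plain dict suitable for GMT export.
    """
    rng = np.random.default_rng([seed, 202])
    M = net.n_clusters
    by_cluster = {c: sorted(a for a, cc in net.cluster_of.items() if cc == c)
                  for c in range(1, M + 1)}
    late = by_cluster[M]
    last_two = sorted(set(by_cluster[M]) | set(by_cluster.get(M - 1, [])))
    half = sorted(
        str(a) for a in rng.choice(last_two, size=max(1, len(last_two) // 2),
                                   replace=False)
    ) if last_two else []
    terms = {
        "PROLIFERATION": set(late),
        "CELL CYCLE REGULATION": set(half),
        "TRANSCRIPTION REGULATION": set(by_cluster[1]),
    }
    if M >= 2:
        terms["SIGNALING"] = set(by_cluster[2])
    return terms


def generate_prior(
    net: GroundTruthNetwork, coverage: float, false_edge_count: int, seed: int = 0
) -> PriorNetwork:
    """A partial, partly wrong stand-in for a curated interaction database.

    Contains ``round(coverage * |true edges|)`` true edges plus
    ``false_edge_count`` ordered pairs absent from the truth, each with a
    confidence in (0, 1].
    """
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    true_edges = sorted(net.edge_set)
    n = len(net.actors)
    n_possible_false = n * (n - 1) - len(true_edges)
    if false_edge_count < 0 or false_edge_count > n_possible_false:
        raise ValueError("false_edge_count exceeds the available non-true pairs")
    rng = np.random.default_rng([seed, 303])
    n_true = int(round(coverage * len(true_edges)))
    chosen = [true_edges[i] for i in rng.choice(len(true_edges), size=n_true, replace=False)] if n_true else []
    false_edges = []
    seen = set(true_edges)
    while len(false_edges) < false_edge_count:
        s, t = rng.choice(net.actors, size=2, replace=False)
        if (s, t) not in seen:
            seen.add((s, t))
            false_edges.append((str(s), str(t)))
    edges = [(s, t, float(1.0 - rng.random())) for s, t in chosen + false_edges]
    return PriorNetwork(edges=edges)
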