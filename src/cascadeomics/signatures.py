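"""Differential expression/abundance testing and signature set algebra.

One moderated-t scheme serves both modalities, applied to per-individual
log2 fold changes: per feature x time cell the sample variance is shrunk
toward a pooled prior variance estimated across all cells by a method of
moments on log variances (an empirical-Bayes scheme in the limma family),
and two-sided p-values come from a t distribution with augmented degrees
of freedom.  Benjamini-Hochberg FDR is controlled per modality across the
full feature x time grid of one contrast type.

Three feature sets are derived per modality:

* temporal signature  - features differential at any T1..T8 vs T0 within a
  group (default FDR < 1%), with an up/down direction per significant time;
* response signature  - features differential between the proliferative and
  nonproliferative groups at any time (default FDR < 5%);
* proliferative signature - the exact intersection of the proliferative
  group's temporal signature with the response signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .datasets import GROUPS, FoldChangeTensor

logger = logging.getLogger(__name__)

_MAX_DF = 1e6


# ---------------------------------------------------------------------------
# variance moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray, covariate=None):
    """Method-of-moments fit of (d0, s0^2) from log sample variances.

    Cells with zero variance or zero residual df are excluded from the
    moment equations.  Returns ``(d0, s0_sq)``; ``d0`` may be ``inf``
    (fully pooled variances).

    With ``covariate`` (one abundance value per cell) the prior scale
    follows a lowess trend of the bias-corrected log variances on the
    covariate — count data have strongly mean-dependent fold-change
    variance, and a constant prior over-moderates low-abundance features.
    ``s0_sq`` is then an array aligned with the input cells.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (df >= 1) & (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    trend_all = None
    if covariate is not None:
        a = np.asarray(covariate, dtype=float)
        if np.isfinite(a[ok]).all() and np.ptp(a[ok]) > 0 and ok.sum() >= 30:
            fit = sm_lowess(e, a[ok], frac=0.5, return_sorted=True)
            xs, ys = fit[:, 0], fit[:, 1]
            trend = np.interp(a[ok], xs, ys)
            # extend the fitted trend to every cell (including s2 == 0 ones)
            trend_all = np.interp(a, xs, ys)
            e = e - trend
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, d / 2.0))
    if evar <= 0:
        d0 = np.inf
        offset = float(np.mean(e))
    else:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        offset = float(np.mean(e) - special.digamma(half_d0) + np.log(half_d0))
    if trend_all is None:
        return d0, float(np.exp(offset))
    return d0, np.exp(trend_all + offset)


def _spread_prior(s0, shape, testable):
    """Lay a scalar or per-testable-cell prior scale onto the cell grid."""
    grid = np.full(shape, np.nan)
    if np.ndim(s0) == 0:
        grid[:] = s0
    else:
        grid[testable] = s0
    return grid


def _moderated_stat(mean, s2, df, scale, d0, s0_sq):
    """t statistic and two-sided p for one cell.

    ``scale`` multiplies the posterior sd in the denominator (1/sqrt(n) for
    a one-sample test, sqrt(1/n1 + 1/n2) for two samples).
    """
    if np.isinf(d0):
        s2_post = s0_sq
        dof = _MAX_DF
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        dof = d0 + df
    denom = np.sqrt(s2_post) * scale
    if denom == 0:
        stat = 0.0 if mean == 0 else np.sign(mean) * np.inf
        p = 1.0 if mean == 0 else 0.0
    else:
        stat = mean / denom
        p = 2.0 * stats.t.sf(abs(stat), df=min(dof, _MAX_DF))
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# test frames


def temporal_tests(fc: FoldChangeTensor, group: str) -> pd.DataFrame:
    """One-sample moderated t of log2fc vs 0, per feature x time, one group.

    Untestable cells (< 2 non-missing individuals) carry NaN statistics and
    are excluded from the BH family downstream.
    """
    idx = [i for i, g in enumerate(fc.groups) if g == group]
    if not idx:
        raise ValueError(f"no individuals in group {group!r}")
    x = fc.log2fc[:, :, idx]
    n = (~np.isnan(x)).sum(axis=2)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=2)
        s2 = np.nanvar(x, axis=2, ddof=1)
    testable = n >= 2
    cov = (np.broadcast_to(fc.abundance[:, None], s2.shape)[testable]
           if fc.abundance is not None else None)
    d0, s0 = estimate_variance_prior(s2[testable], (n - 1)[testable], covariate=cov)
    s0_grid = _spread_prior(s0, s2.shape, testable)
    rows = []
    for f in range(fc.n_features):
        for t in range(fc.n_times):
            if testable[f, t]:
                stat, p = _moderated_stat(
                    mean[f, t], s2[f, t], n[f, t] - 1, 1.0 / np.sqrt(n[f, t]),
                    d0, s0_grid[f, t]
                )
            else:
                stat, p = np.nan, np.nan
            rows.append(
                dict(feature=fc.features[f], time=t + 1, n=int(n[f, t]),
                     log2fc_mean=float(mean[f, t]) if n[f, t] else np.nan,
                     statistic=stat, p_value=p, testable=bool(testable[f, t]))
            )
    out = pd.DataFrame(rows)
    out.attrs["contrast"] = f"T_t vs T0 ({group})"
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0 if np.ndim(s0) == 0 else float(np.median(s0))
    return add_q_values(out)


def two_group_tests(fc: FoldChangeTensor, group_a: str = "proliferative",
                    group_b: str = "nonproliferative") -> pd.DataFrame:
    """Two-sample moderated t of log2fc between groups, per feature x time."""
    ia = [i for i, g in enumerate(fc.groups) if g == group_a]
    ib = [i for i, g in enumerate(fc.groups) if g == group_b]
    if not ia or not ib:
        raise ValueError("both groups need at least one individual")
    xa, xb = fc.log2fc[:, :, ia], fc.log2fc[:, :, ib]
    na = (~np.isnan(xa)).sum(axis=2)
    nb = (~np.isnan(xb)).sum(axis=2)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(xa, axis=2)
        mb = np.nanmean(xb, axis=2)
        va = np.nanvar(xa, axis=2, ddof=1)
        vb = np.nanvar(xb, axis=2, ddof=1)
    testable = (na >= 2) & (nb >= 2)
    df = na + nb - 2
    with np.errstate(invalid="ignore"):
        s2 = ((na - 1) * va + (nb - 1) * vb) / df
    cov = (np.broadcast_to(fc.abundance[:, None], s2.shape)[testable]
           if fc.abundance is not None else None)
    d0, s0 = estimate_variance_prior(s2[testable], df[testable], covariate=cov)
    s0_grid = _spread_prior(s0, s2.shape, testable)
    rows = []
    for f in range(fc.n_features):
        for t in range(fc.n_times):
            if testable[f, t]:
                scale = np.sqrt(1.0 / na[f, t] + 1.0 / nb[f, t])
                stat, p = _moderated_stat(
                    ma[f, t] - mb[f, t], s2[f, t], df[f, t], scale,
                    d0, s0_grid[f, t]
                )
            else:
                stat, p = np.nan, np.nan
            rows.append(
                dict(feature=fc.features[f], time=t + 1,
                     n=int(na[f, t] + nb[f, t]),
                     log2fc_mean=float(ma[f, t] - mb[f, t])
                     if na[f, t] and nb[f, t] else np.nan,
                     statistic=stat, p_value=p, testable=bool(testable[f, t]))
            )
    out = pd.DataFrame(rows)
    out.attrs["contrast"] = f"{group_a} vs {group_b}"
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0 if np.ndim(s0) == 0 else float(np.median(s0))
    return add_q_values(out)


def moderated_paired_test(fc: FoldChangeTensor, feature: str, t: int, group: str):
    """(statistic, p_value) of the one-sample moderated t for one cell."""
    frame = temporal_tests(fc, group)
    row = frame[(frame.feature == str(feature).upper()) & (frame.time == t)]
    if row.empty:
        raise KeyError(f"{feature} at T{t} not in the test frame")
    return float(row.statistic.iloc[0]), float(row.p_value.iloc[0])


def two_group_test(fc: FoldChangeTensor, feature: str, t: int):
    frame = two_group_tests(fc)
    row = frame[(frame.feature == str(feature).upper()) & (frame.time == t)]
    if row.empty:
        raise KeyError(f"{feature} at T{t} not in the test frame")
    return float(row.statistic.iloc[0]), float(row.p_value.iloc[0])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_q_values(frame: pd.DataFrame) -> pd.DataFrame:
    """BH q-values over the testable cells of one contrast family."""
    frame = frame.copy()
    q = np.full(len(frame), np.nan)
    mask = frame["testable"].to_numpy()
    if mask.any():
        q[mask] = bh_fdr(frame.loc[mask, "p_value"])
    frame["q_value"] = q
    return frame


# ---------------------------------------------------------------------------
# signature set algebra


def signature_from_tests(tests: pd.DataFrame, alpha: float) -> dict:
    """{feature: {time: +1/-1}} for cells with q <= alpha."""
    sig = {}
    hit = tests[(tests["testable"]) & (tests["q_value"] <= alpha)]
    for row in hit.itertuples():
        direction = 1 if row.log2fc_mean > 0 else (-1 if row.log2fc_mean < 0 else 0)
        sig.setdefault(row.feature, {})[row.time] = direction
    return sig


def temporal_signature(tests: pd.DataFrame, alpha: float = 0.01) -> dict:
    """Features differential vs T0 at any post-stimulation time (union over t)."""
    return signature_from_tests(tests, alpha)


def response_signature(tests: pd.DataFrame, alpha: float = 0.05) -> dict:
    return signature_from_tests(tests, alpha)


def magnitude_signature(fc: FoldChangeTensor, group: str,
                        min_abs_log2fc: float = 1e-6) -> dict:
    """{feature: {time: sign}} by mean |log2fc| threshold, no testing.

    The responder rule for noise-free data, where any nonzero fold change
    is a real response and a significance test against inter-individual
    spread is ill-posed.
    """
    idx = [i for i, g in enumerate(fc.groups) if g == group]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(fc.log2fc[:, :, idx], axis=2)
    sig = {}
    for f in range(fc.n_features):
        for t in range(fc.n_times):
            v = mean[f, t]
            if np.isfinite(v) and abs(v) > min_abs_log2fc:
                sig.setdefault(fc.features[f], {})[t + 1] = int(np.sign(v))
    return sig


def proliferative_signature(temporal_p, response) -> set:
    """Exact intersection of the two signatures (same modality)."""
    return set(temporal_p) & set(response)


def match_pairs(gene_set, protein_set) -> list:
    """Sorted symbols present in both modality sets (uppercase exact match)."""
    genes = {str(s).upper() for s in gene_set}
    prots = {str(s).upper() for s in protein_set}
    return sorted(genes & prots)


def overlap_from_counts(n_genes: int, n_proteins: int, n_unique: int) -> int:
    """Shared symbols implied by two modality set sizes and their union size."""
    shared = n_genes + n_proteins - n_unique
    if shared < 0:
        raise ValueError("union larger than the two sets combined")
    return shared


@dataclass
class SignatureSets:
    """Temporal / response / proliferative feature sets per modality.

    ``temporal`` maps (group, modality) and ``response`` maps modality to
    {feature: {time: direction}}; ``proliferative`` maps modality to the
    exact temporal(proliferative) & response intersection.
    """

    temporal: dict
    response: dict
    proliferative: dict
    matched_pairs: list = field(default_factory=list)

    def __post_init__(self):
        for modality, members in self.proliferative.items():
            expect = proliferative_signature(
                self.temporal[("proliferative", modality)], self.response[modality]
            )
            if set(members) != expect:
                raise ValueError(
                    f"proliferative signature for {modality} is not the exact "
                    "temporal & response intersection"
                )

    def summary(self) -> dict:
        """Set sizes and cross-modality overlap, mirroring the signature
        counting scheme of the study design."""
        out = {"temporal": {}, "response": {}, "proliferative": {}}
        for (group, modality), sig in sorted(self.temporal.items()):
            out["temporal"][f"{group}/{modality}"] = len(sig)
        for modality, sig in sorted(self.response.items()):
            out["response"][modality] = len(sig)
        sizes = {}
        for modality, members in sorted(self.proliferative.items()):
            out["proliferative"][modality] = len(members)
            sizes[modality] = set(members)
        if len(sizes) == 2:
            union = set.union(*sizes.values())
            out["proliferative"]["unique_symbols"] = len(union)
            out["proliferative"]["shared_symbols"] = overlap_from_counts(
                *(len(s) for s in sizes.values()), len(union)
            )
        out["matched_pairs"] = len(self.matched_pairs)
        return out


def build_signature_sets(transcript_fc: FoldChangeTensor, protein_fc: FoldChangeTensor,
                         alpha_temporal: float = 0.01,
                         alpha_response: float = 0.05) -> SignatureSets:
    """Run both contrast families on both modalities and intersect.

    ``matched_pairs`` lists the symbols shared between the proliferative
    group's temporal gene and protein signatures (the gene/protein pair set
    the concordance analysis consumes).
    """
    temporal, response, prolif = {}, {}, {}
    for modality, fc in (("transcript", transcript_fc), ("protein", protein_fc)):
        for group in GROUPS:
            tests = temporal_tests(fc, group)
            temporal[(group, modality)] = temporal_signature(tests, alpha_temporal)
        resp_tests = two_group_tests(fc)
        response[modality] = response_signature(resp_tests, alpha_response)
        prolif[modality] = proliferative_signature(
            temporal[("proliferative", modality)], response[modality]
        )
    pairs = match_pairs(
        temporal[("proliferative", "transcript")], temporal[("proliferative", "protein")]
    )
    return SignatureSets(
        temporal=temporal, response=response, proliferative=prolif, matched_pairs=pairs
    )
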