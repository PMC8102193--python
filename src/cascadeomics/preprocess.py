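"""Filtering, normalization and fold-change computation.

Transcript counts are filtered on a counts-per-million rule and library-size
normalized; protein log2 intensities are quantile normalized with missing
values left in place; both modalities end as per-individual log2 fold
changes of T1..T8 against T0.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .datasets import PROTEIN, TRANSCRIPT, FoldChangeTensor, TemporalOmicsDataset

logger = logging.getLogger(__name__)


def _cpm(values):
    """Counts-per-million per sample column; columns are (time, individual)."""
    totals = values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("all-zero sample column: cannot normalize library size")
    return values / totals * 1e6


def filter_low_expression(ds: TemporalOmicsDataset, min_norm_count: float = 1.0,
                          min_samples: int = 1) -> TemporalOmicsDataset:
    """Keep transcripts with CPM >= ``min_norm_count`` in >= ``min_samples`` samples.

    An explicit, deterministic replacement for data-driven low-count filters;
    feature order is preserved.
    """
    if ds.modality != TRANSCRIPT:
        raise ValueError("low-expression filtering applies to transcript counts")
    if min_norm_count <= 0:
        return ds.subset_features(np.ones(ds.n_features, dtype=bool))
    cpm = _cpm(ds.values)
    keep = (cpm >= min_norm_count).sum(axis=(1, 2)) >= min_samples
    if not keep.any():
        logger.warning("low-expression filter removed every feature")
    return ds.subset_features(keep)


def normalize_library_size(ds: TemporalOmicsDataset) -> TemporalOmicsDataset:
    """Scale every sample column to counts per million."""
    if ds.modality != TRANSCRIPT:
        raise ValueError("library-size normalization applies to transcript counts")
    return replace(ds, values=_cpm(ds.values))


def normalize_median_ratios(ds: TemporalOmicsDataset) -> TemporalOmicsDataset:
    """Composition-robust library scaling (median-of-ratios size factors).

    Plain per-million scaling transfers strong responders' signal onto
    every other feature as a per-sample offset; dividing instead by the
    median ratio to a geometric-mean reference (computed over features
    observed in every sample) cancels that compositional shift.  Columns
    are then rescaled so the median library equals one million.
    """
    if ds.modality != TRANSCRIPT:
        raise ValueError("library-size normalization applies to transcript counts")
    F, T1, P = ds.values.shape
    cols = ds.values.reshape(F, T1 * P)
    positive = (cols > 0).all(axis=1)
    if positive.sum() < 10:
        logger.warning(
            "median-ratio normalization: only %d all-positive features; "
            "falling back to counts per million", int(positive.sum()),
        )
        return normalize_library_size(ds)
    ref = np.exp(np.log(cols[positive]).mean(axis=1))
    factors = np.median(cols[positive] / ref[:, None], axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor")
    scaled = cols / factors
    scaled *= 1e6 / np.median(scaled.sum(axis=0))
    return replace(ds, values=scaled.reshape(F, T1, P))


def quantile_normalize(ds: TemporalOmicsDataset) -> TemporalOmicsDataset:
    """Force every sample column onto the mean quantile profile.

    Missing entries stay missing and do not contribute to the reference
    distribution; ties share the average-rank quantile.  Columns with fewer
    than two observed values are rejected.
    """
    if ds.modality != PROTEIN:
        raise ValueError("quantile normalization applies to protein intensities")
    F, T1, P = ds.values.shape
    cols = ds.values.reshape(F, T1 * P)
    grid = np.linspace(0.0, 1.0, F)
    profiles = []
    for c in range(cols.shape[1]):
        obs = np.sort(cols[~np.isnan(cols[:, c]), c])
        if obs.size < 2:
            raise ValueError(f"sample column {c} has fewer than 2 observed values")
        q = np.linspace(0.0, 1.0, obs.size)
        profiles.append(np.interp(grid, q, obs))
    reference = np.mean(profiles, axis=0)
    out = np.full_like(cols, np.nan)
    for c in range(cols.shape[1]):
        mask = ~np.isnan(cols[:, c])
        vals = cols[mask, c]
        order = np.argsort(vals, kind="mergesort")
        ranks = np.empty(vals.size)
        ranks[order] = np.arange(vals.size, dtype=float)
        # average ranks over ties so tied entries get equal normalized values
        for v in np.unique(vals):
            tie = vals == v
            ranks[tie] = ranks[tie].mean()
        q = ranks / max(vals.size - 1, 1)
        out[mask, c] = np.interp(q, grid, reference)
    return replace(ds, values=out.reshape(F, T1, P))


def log2fc_vs_t0(ds: TemporalOmicsDataset, pseudocount: float = 1.0) -> FoldChangeTensor:
    """Per-individual log2 fold changes of T1..T8 against T0.

    Transcript: ``log2((v_t + pc) / (v_0 + pc))`` on normalized counts.
    Protein: intensities are already log2-scale, so the plain difference
    ``v_t - v_0``; missing entries propagate (a missing T0 voids the whole
    profile for that feature x individual).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    v0 = ds.values[:, :1, :]
    vt = ds.values[:, 1:, :]
    if ds.modality == TRANSCRIPT:
        fc = np.log2(vt + pseudocount) - np.log2(v0 + pseudocount)
        abundance = np.log2(ds.values.mean(axis=(1, 2)) + pseudocount + 0.5)
    else:
        fc = vt - v0
        with np.errstate(invalid="ignore"):
            abundance = np.nanmean(ds.values, axis=(1, 2))
    return FoldChangeTensor(
        abundance=abundance,
        modality=ds.modality,
        log2fc=fc,
        features=list(ds.features),
        time_hours=tuple(ds.time_hours[1:]),
        individuals=list(ds.individuals),
        groups=list(ds.groups),
        pseudocount=pseudocount,
    )
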