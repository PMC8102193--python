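"""Gene-to-protein temporal coupling: correlation, delay, sign concordance.

Correlations between a gene's and its protein's fold-change profiles are
computed per individual over cumulative windows T1..Tt (with only a few
individuals a cross-sectional correlation at one time point is degenerate;
the cumulative window reproduces the characteristic rise of gene/protein
agreement over the time course).  Translation delays are estimated per
pair as the index lag maximizing the lagged Pearson correlation, and
reported in nominal hours through the protein sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import PROTEIN_HOURS, FoldChangeTensor


@dataclass
class PairTimecourse:
    """One gene/protein pair's fold-change profiles for one individual."""

    symbol: str
    gene_log2fc: np.ndarray
    protein_log2fc: np.ndarray
    individual: str = ""

    def __post_init__(self):
        self.symbol = str(self.symbol).upper()
        self.gene_log2fc = np.asarray(self.gene_log2fc, dtype=float)
        self.protein_log2fc = np.asarray(self.protein_log2fc, dtype=float)
        if self.gene_log2fc.shape != self.protein_log2fc.shape:
            raise ValueError("gene and protein series must share the index grid")


def build_pairs(gene_fc: FoldChangeTensor, protein_fc: FoldChangeTensor,
                symbols, group: str = "proliferative") -> list:
    """PairTimecourse list for matched symbols, one entry per individual."""
    pairs = []
    idx = [i for i, g in enumerate(gene_fc.groups) if g == group]
    for sym in sorted({str(s).upper() for s in symbols}):
        g = gene_fc.series(sym)
        p = protein_fc.series(sym)
        for i in idx:
            pairs.append(
                PairTimecourse(sym, g[:, i], p[:, i], gene_fc.individuals[i])
            )
    return pairs


def _pearson(x, y):
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return np.nan
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlation_by_time(pairs, t: int, min_points: int = 3):
    """Median pair x individual Pearson correlation over the window T1..Tt.

    Windows with undefined correlation (zero variance, too few overlapping
    points) are dropped; if no window is valid the result is NaN (flagged
    undefined).
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    if t < min_points:
        raise ValueError(f"cumulative window T1..T{t} holds fewer than {min_points} points")
    vals = []
    for pair in pairs:
        g = pair.gene_log2fc[:t]
        p = pair.protein_log2fc[:t]
        if (~(np.isnan(g) | np.isnan(p))).sum() < min_points:
            continue
        r = _pearson(g, p)
        if not np.isnan(r):
            vals.append(r)
    return float(np.median(vals)) if vals else np.nan


def correlation_profile(pairs, min_points: int = 3) -> pd.DataFrame:
    """Median cumulative-window correlation at every admissible t."""
    T = len(pairs[0].gene_log2fc)
    rows = [
        dict(time=t, median_correlation=correlation_by_time(pairs, t, min_points))
        for t in range(min_points, T + 1)
    ]
    return pd.DataFrame(rows)


def estimate_delay(pair: PairTimecourse, max_lag: int) -> int:
    """Index lag in [0, max_lag] maximizing corr(gene[.-lag], protein[.]).

    Overlapping support only; ties break toward the smaller lag.  Returns
    -1 (flagged undefined) when every lag gives an undefined correlation,
    e.g. for all-constant series.
    """
    T = len(pair.gene_log2fc)
    if max_lag >= T - 2:
        raise ValueError("max_lag must be < T - 2")
    best_lag, best_r = -1, -np.inf
    for lag in range(max_lag + 1):
        g = pair.gene_log2fc[: T - lag]
        p = pair.protein_log2fc[lag:]
        r = _pearson(g, p)
        if not np.isnan(r) and r > best_r + 1e-12:
            best_lag, best_r = lag, r
    return best_lag


def delay_summary(pairs, max_lag: int = 3,
                  protein_hours=PROTEIN_HOURS) -> dict:
    """Cohort-level translation delay: median index lag and hour equivalent.

    The hour equivalent of a lag of L index steps is the median spacing
    ``hours[t] - hours[t - L]`` over the post-stimulation protein grid.
    """
    lags = [estimate_delay(p, max_lag) for p in pairs]
    lags = [l for l in lags if l >= 0]
    if not lags:
        return dict(median_lag_steps=np.nan, median_lag_hours=np.nan, n_pairs=0)
    med = float(np.median(lags))
    lag_int = int(round(med))
    post = list(protein_hours[1:])
    if lag_int == 0:
        hours = 0.0
    else:
        spac = [post[t] - post[t - lag_int] for t in range(lag_int, len(post))]
        hours = float(np.median(spac))
    return dict(median_lag_steps=med, median_lag_hours=hours, n_pairs=len(lags))


def _dominant_direction(directions, series):
    """Sign of the largest-|log2fc| significant time; 0 if undefined."""
    best_t, best_mag = None, -np.inf
    for t in directions:
        v = series[t - 1]
        if np.isnan(v):
            continue
        if abs(v) > best_mag:
            best_t, best_mag = t, abs(v)
    if best_t is None:
        return 0
    return int(np.sign(series[best_t - 1]))


def sign_concordance(pairs, gene_directions: dict, protein_directions: dict) -> float:
    """Fraction of pairs whose dominant gene and protein directions agree.

    ``gene_directions`` / ``protein_directions`` map symbol to
    {time: direction} (significant times from the signature analysis).
    Pairs with an undefined direction on either side leave the denominator.
    """
    if not pairs:
        raise ValueError("empty pair list")
    agree = total = 0
    for pair in pairs:
        gd = gene_directions.get(pair.symbol)
        pdir = protein_directions.get(pair.symbol)
        if not gd or not pdir:
            continue
        g = _dominant_direction(gd, pair.gene_log2fc)
        p = _dominant_direction(pdir, pair.protein_log2fc)
        if g == 0 or p == 0:
            continue
        total += 1
        agree += int(g == p)
    if total == 0:
        return np.nan
    return agree / total
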