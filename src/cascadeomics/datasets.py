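"""In-memory containers for temporal omics data.

A :class:`TemporalOmicsDataset` holds one modality (transcript counts or
log2 protein intensities) as a dense ``feature x time x individual`` tensor
over a shared time-index grid T0..T8 (nominal hours differ per modality).
A :class:`FoldChangeTensor` holds per-individual log2 fold changes of the
post-stimulation points T1..T8 against T0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

TRANSCRIPT = "transcript"
PROTEIN = "protein"
GROUPS = ("proliferative", "nonproliferative")

#: nominal sampling hours used by the study design this package emulates
TRANSCRIPT_HOURS = (0.0, 1.0, 1.5, 3.5, 6.5, 12.0, 24.0, 48.0, 96.0)
PROTEIN_HOURS = (0.0, 1.0, 2.0, 4.0, 7.0, 12.0, 24.0, 48.0, 96.0)


@dataclass
class TemporalOmicsDataset:
    """One modality's feature x time x individual tensor.

    Parameters
    ----------
    modality : {"transcript", "protein"}
        Transcript entries are non-negative counts; protein entries are
        log2 intensities and may be NaN (missing).
    values : ndarray, shape (n_features, T+1, n_individuals)
    features : list of str
        Unique feature symbols (uppercased at ingestion).
    time_hours : sequence of float
        Nominal hours for indices T0..T{T}; must start at 0.
    individuals : list of str
    groups : list of str
        Group label per individual, each in ``GROUPS``.
    """

    modality: str
    values: np.ndarray
    features: list
    time_hours: tuple
    individuals: list
    groups: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.features = [str(f).upper() for f in self.features]
        self.time_hours = tuple(float(h) for h in self.time_hours)
        if self.modality not in (TRANSCRIPT, PROTEIN):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.ndim != 3:
            raise ValueError("values must be feature x time x individual")
        nf, nt, ni = self.values.shape
        if nf != len(self.features):
            raise ValueError("feature list does not match tensor")
        if nt != len(self.time_hours):
            raise ValueError("time grid does not match tensor")
        if ni != len(self.individuals) or ni != len(self.groups):
            raise ValueError("individual list does not match tensor")
        if self.time_hours and self.time_hours[0] != 0.0:
            raise ValueError("time grid must start at T0 = 0 h")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature symbols must be unique within a modality")
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        if self.modality == TRANSCRIPT:
            if np.isnan(self.values).any():
                raise ValueError("transcript values may not be missing")
            if (self.values < 0).any():
                raise ValueError("transcript counts must be non-negative")

    @property
    def n_features(self):
        return self.values.shape[0]

    @property
    def n_times(self):
        return self.values.shape[1]

    @property
    def n_individuals(self):
        return self.values.shape[2]

    @property
    def time_labels(self):
        return [f"T{i}" for i in range(self.n_times)]

    def subset_features(self, keep) -> "TemporalOmicsDataset":
        """Return a dataset restricted to ``keep`` (bool mask or index array),
        preserving feature order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            values=self.values[idx].copy(),
            features=[self.features[i] for i in idx],
        )

    def individual_indices(self, group=None):
        if group is None:
            return list(range(self.n_individuals))
        return [i for i, g in enumerate(self.groups) if g == group]


@dataclass
class FoldChangeTensor:
    """Per-individual log2 fold changes T1..T8 vs T0.

    ``log2fc`` has shape (n_features, T, n_individuals); NaN entries mark
    propagated protein missingness.
    """

    modality: str
    log2fc: np.ndarray
    features: list
    time_hours: tuple  # post-stimulation hours, length T
    individuals: list
    groups: list
    pseudocount: float = 0.0
    #: per-feature mean log2 expression level; lets the variance moderation
    #: follow the count-driven mean-variance trend
    abundance: np.ndarray = None

    def __post_init__(self):
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        if self.log2fc.ndim != 3:
            raise ValueError("log2fc must be feature x time x individual")
        if self.abundance is not None:
            self.abundance = np.asarray(self.abundance, dtype=float)
            if self.abundance.shape != (self.log2fc.shape[0],):
                raise ValueError("abundance must be one value per feature")

    @property
    def n_features(self):
        return self.log2fc.shape[0]

    @property
    def n_times(self):
        return self.log2fc.shape[1]

    @property
    def n_individuals(self):
        return self.log2fc.shape[2]

    @property
    def time_labels(self):
        return [f"T{i}" for i in range(1, self.n_times + 1)]

    def series(self, feature):
        """(T, n_individuals) fold-change matrix for one feature symbol."""
        i = self.features.index(str(feature).upper())
        return self.log2fc[i]
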