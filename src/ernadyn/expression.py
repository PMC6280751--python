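"""Expression matrices on a shared time grid and derived quantities.

An :class:`ExpressionMatrix` is a thin wrapper over a pandas DataFrame
(loci x time points) that carries the :class:`TimeGrid`, and — for count
matrices — per-locus lengths and per-time-point library sizes so that RPKM
normalisation is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: sampling times (hours post-infection) of the viral-induction time course;
#: 0 h is the untreated control.
DEFAULT_HOURS = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 12.0, 18.0, 24.0, 48.0, 72.0)

#: pseudocount (RPKM) added to numerator and denominator of fold changes;
#: most eRNAs are silent at baseline so ratios to e(0) need regularising.
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sampling times in hours, starting at 0."""

    hours: tuple[float, ...] = DEFAULT_HOURS
    labels: tuple[str, ...] = field(default=None)

    def __post_init__(self):
        hours = tuple(float(h) for h in self.hours)
        object.__setattr__(self, "hours", hours)
        if hours[0] != 0:
            raise ValueError("time grid must start at the 0 h control")
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("time grid must be strictly increasing")
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(f"{h:g}h" for h in hours)
            )
        elif len(self.labels) != len(hours):
            raise ValueError("labels/hours length mismatch")

    def __len__(self):
        return len(self.hours)

    @classmethod
    def from_labels(cls, labels) -> "TimeGrid":
        hours = tuple(float(str(l).rstrip("h")) for l in labels)
        return cls(hours, tuple(str(l) for l in labels))


@dataclass
class ExpressionMatrix:
    """Loci x time-point values (raw counts or RPKM) on a TimeGrid."""

    values: pd.DataFrame
    timegrid: TimeGrid
    lengths: pd.Series | None = None       # bp, for count matrices
    library_sizes: pd.Series | None = None  # total mapped signal per time point
    unit: str = "counts"

    def __post_init__(self):
        if self.values.shape[1] != len(self.timegrid):
            raise ValueError("matrix columns must match the time grid")
        self.values = self.values.astype(float)
        self.values.columns = list(self.timegrid.labels)
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def loci(self) -> pd.Index:
        return self.values.index


def rpkm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Reads (signal) per kilobase of locus per million library reads.

    value = count * 1e9 / (length_bp * library_size).
    """
    if m.lengths is None or m.library_sizes is None:
        raise ValueError("count matrix must carry lengths and library sizes")
    lengths = m.lengths.reindex(m.values.index)
    lib = pd.Series(m.library_sizes).reindex(m.values.columns).astype(float)
    if (lengths <= 0).any():
        raise ValueError("locus lengths must be positive")
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    vals = m.values.mul(1e9).div(lengths, axis=0).div(lib, axis=1)
    return ExpressionMatrix(vals, m.timegrid, m.lengths, m.library_sizes, unit="rpkm")


def detection_call(
    m: ExpressionMatrix, threshold: float = 0.5, scope: str = "mean"
) -> pd.Series:
    """Expressed-locus call: mean RPKM > threshold, or the 0 h value alone.

    ``scope="time0"`` supports the fraction-undetected-at-baseline statistic.
    """
    if scope == "mean":
        stat = m.values.mean(axis=1)
    elif scope == "time0":
        stat = m.values.iloc[:, 0]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return stat > threshold


def log_fold_change(
    m: ExpressionMatrix,
    reference: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """log2 (e(t)+eps) / (e(ref)+eps) per locus; the reference column is 0."""
    ref = m.values.iloc[:, reference] + pseudocount
    return np.log2(m.values.add(pseudocount).div(ref, axis=0))


def pca_coordinates(
    m: ExpressionMatrix,
    n_components: int = 2,
    min_mean_rpkm: float = 0.5,
) -> pd.DataFrame:
    """Sample (time point) scores on the first principal components.

    Loci are filtered to expressed ones (mean > ``min_mean_rpkm``), features
    (loci) are centered, and each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    keep = m.values.mean(axis=1) > min_mean_rpkm
    X = m.values.loc[keep].T.values  # samples x loci
    if X.shape[1] < n_components:
        raise ValueError("fewer loci than components after filtering")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores,
        index=m.values.columns,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
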