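"""Core genomic data model: stranded intervals, gene models, PWMs, coverage.

All coordinates are 0-based half-open (BED dialect) everywhere inside the
package; GTF input is shifted on read. Strand is one of ``+``, ``-``, ``.``,
where ``.`` matches both strands in stranded queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: sentinel returned by :func:`nearest_distance` for trans (different
#: chromosome) interval pairs.
UNLINKED = None


@dataclass(frozen=True)
class GenomicInterval:
    """A located, stranded locus in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"{self.id or self.chrom}: start {self.start} < 0")
        if self.end <= self.start:
            raise ValueError(
                f"{self.id or self.chrom}: empty/inverted interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware transcription start and termination sites.

    ``tss`` is the 5' base of the gene (``start`` on plus strand, ``end - 1``
    on minus strand) and ``tts`` the 3' base.
    """

    interval: GenomicInterval
    name: str
    biotype: str = "protein_coding"

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand != "-" else iv.end - 1

    @property
    def tts(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand != "-" else iv.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class PWM:
    """A position weight matrix over A, C, G, T.

    ``matrix`` holds one row of four nonnegative counts/weights per motif
    position (columns ordered A, C, G, T).
    """

    name: str
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: matrix must be L x 4")
        if len(self.matrix) < 1:
            raise ValueError(f"PWM {self.name}: zero-length matrix")
        if np.any(self.matrix < 0):
            raise ValueError(f"PWM {self.name}: negative weights")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=1))


class CoverageTrack:
    """Base-resolution, strand-split nonnegative signal over a genome.

    Values are stored per (chromosome, strand) as dense float arrays;
    ``library_size`` is the total signal over all chromosomes and strands.
    """

    def __init__(self, chrom_sizes: dict[str, int], dtype=np.float32):
        self.chrom_sizes = dict(chrom_sizes)
        self._data: dict[tuple[str, str], np.ndarray] = {}
        self._dtype = dtype

    def _arr(self, chrom: str, strand: str, create: bool = False):
        key = (chrom, strand)
        if key not in self._data:
            if not create:
                return None
            if chrom not in self.chrom_sizes:
                raise KeyError(f"unknown chromosome {chrom!r}")
            self._data[key] = np.zeros(self.chrom_sizes[chrom], dtype=self._dtype)
        return self._data[key]

    def add(self, chrom: str, start: int, end: int, value: float, strand: str = "+"):
        if value < 0:
            raise ValueError("coverage values must be nonnegative")
        self._arr(chrom, strand, create=True)[start:end] += value

    def values(self, chrom: str, strand: str) -> np.ndarray | None:
        return self._arr(chrom, strand)

    @property
    def library_size(self) -> float:
        return float(sum(a.sum() for a in self._data.values()))

    def items(self):
        return self._data.items()


def point_distance(iv: GenomicInterval, pos: int) -> int:
    """Unsigned distance in bp from an interval to a base position.

    Zero when the position lies inside the interval, otherwise the distance
    to the nearest contained base.
    """
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - (iv.end - 1)
    return 0


def nearest_distance(a: GenomicInterval, b: GenomicInterval):
    """Gap in bp between two intervals; 0 if they overlap.

    Returns :data:`UNLINKED` (``None``) when the intervals lie on different
    chromosomes.
    """
    if a.chrom != b.chrom:
        return UNLINKED
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def interval_counts(
    track: CoverageTrack,
    intervals: list[GenomicInterval],
    stranded: bool = True,
) -> np.ndarray:
    """Sum track signal over each interval.

    With ``stranded`` the matching strand is used (``.`` intervals sum both
    strands); otherwise both strands are always summed. A chromosome absent
    from the track yields 0 with a logged warning.
    """
    out = np.zeros(len(intervals), dtype=float)
    warned: set[str] = set()
    for i, iv in enumerate(intervals):
        if stranded and iv.strand in ("+", "-"):
            strands = (iv.strand,)
        else:
            strands = ("+", "-")
        total = 0.0
        seen = False
        for s in strands:
            arr = track.values(iv.chrom, s)
            if arr is None:
                continue
            seen = True
            total += float(arr[iv.start : iv.end].sum())
        if not seen and iv.chrom not in track.chrom_sizes and iv.chrom not in warned:
            log.warning("chromosome %s absent from coverage track", iv.chrom)
            warned.add(iv.chrom)
        out[i] = total
    return out
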