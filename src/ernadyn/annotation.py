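"""Annotation of eRNA-producing enhancers from called transcript intervals.

Candidate eRNAs are intergenic transcripts — farther than 1 kb from every
gene 5' end and 10 kb from every gene 3' end, and not overlapping any gene
body — that overlap at least one enhancer-mark (H3K4me1/H3K27ac) peak.
Distances are measured from the transcript interval edges to each gene's
strand-aware end coordinate (the stricter of the plausible readings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .intervals import CoverageTrack, GeneModel, GenomicInterval, point_distance

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErnaLocus:
    """An annotated eRNA-producing enhancer locus."""

    interval: GenomicInterval
    has_marks: bool = True
    source_transcript: str = ""

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand != "-" else iv.end - 1

    @property
    def tts(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand != "-" else iv.start

    @property
    def id(self) -> str:
        return self.interval.id


def merge_same_strand(transcripts: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge transcripts overlapping on the same strand into single loci."""
    out = []
    for key in sorted({(t.chrom, t.strand) for t in transcripts}):
        group = sorted(
            (t for t in transcripts if (t.chrom, t.strand) == key),
            key=lambda t: (t.start, t.end),
        )
        cur = None
        for t in group:
            if cur is None:
                cur = t
            elif t.start < cur.end:
                if t.end > cur.end:
                    cur = GenomicInterval(cur.chrom, cur.start, t.end, cur.strand, cur.id)
            else:
                out.append(cur)
                cur = t
        if cur is not None:
            out.append(cur)
    return out


def classify_intergenic(
    transcripts: list[GenomicInterval],
    genes: list[GeneModel],
    d5: int = 1000,
    d3: int = 10000,
) -> list[GenomicInterval]:
    """Keep transcripts >``d5`` bp from every gene 5' end, >``d3`` bp from
    every gene 3' end, and not overlapping any gene body."""
    if not genes:
        log.warning("empty gene set: returning all transcripts as intergenic")
        return list(transcripts)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for t in transcripts:
        keep = True
        for g in by_chrom.get(t.chrom, ()):
            if t.start < g.interval.end and g.interval.start < t.end:
                keep = False
                break
            if point_distance(t, g.tss) <= d5 or point_distance(t, g.tts) <= d3:
                keep = False
                break
        if keep:
            out.append(t)
    return out


def filter_by_marks(
    candidates: list[GenomicInterval],
    mark_peaksets: list[list[GenomicInterval]],
) -> tuple[list[ErnaLocus], list[ErnaLocus]]:
    """Split candidates by >=1 bp overlap with the union of mark peak sets.

    Returns ``(marked, unmarked)``; the unmarked class corresponds to
    transcribed regions lacking canonical enhancer marks.
    """
    if not mark_peaksets:
        raise ValueError("need at least one peak set")
    peaks: dict[str, list[tuple[int, int]]] = {}
    for ps in mark_peaksets:
        for p in ps:
            peaks.setdefault(p.chrom, []).append((p.start, p.end))
    starts_ends = {
        c: (np.array([s for s, _ in sorted(v)]), np.array([e for _, e in sorted(v)]))
        for c, v in peaks.items()
    }
    marked, unmarked = [], []
    for t in candidates:
        hit = False
        if t.chrom in starts_ends:
            s, e = starts_ends[t.chrom]
            hit = bool(np.any((s < t.end) & (e > t.start)))
        locus = ErnaLocus(t, has_marks=hit, source_transcript=t.id)
        (marked if hit else unmarked).append(locus)
    return marked, unmarked


def threshold_transcript_caller(
    track: CoverageTrack,
    min_signal: float = 1.0,
    min_length: int = 200,
    merge_gap: int = 100,
) -> list[GenomicInterval]:
    """Minimal coverage-threshold transcript caller (experimental).

    Exists only to exercise the synthetic pipeline end-to-end from coverage;
    real nascent-transcription data should come with externally called
    transcript intervals.
    """
    out = []
    n = 0
    for (chrom, strand), arr in sorted(track.items()):
        above = arr >= min_signal
        if not above.any():
            continue
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > merge_gap)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
        for s, e in zip(starts, ends):
            if e - s >= min_length:
                out.append(GenomicInterval(chrom, int(s), int(e), strand, f"tx{n}"))
                n += 1
    return out


def tss_metaprofile(
    track: CoverageTrack,
    loci: list[ErnaLocus],
    upstream: int = 1000,
    downstream: int = 2000,
    binsize: int = 50,
    missing=np.nan,
) -> tuple[np.ndarray, np.ndarray]:
    """Signal matrix around locus TSSs, oriented 5'->3' by strand.

    Returns ``(matrix, mean_profile)`` with one row per locus and
    ``(upstream+downstream)/binsize`` columns; positions beyond chromosome
    edges are filled with ``missing``.
    """
    window = upstream + downstream
    if window % binsize:
        raise ValueError("binsize must divide the window")
    nbins = window // binsize
    mat = np.full((len(loci), nbins), missing, dtype=float)
    for i, locus in enumerate(loci):
        iv = locus.interval
        tss = locus.tss
        if iv.strand == "-":
            lo, hi = tss - downstream + 1, tss + upstream + 1
        else:
            lo, hi = tss - upstream, tss + downstream
        size = track.chrom_sizes.get(iv.chrom)
        if size is None:
            continue
        row = np.full(window, missing, dtype=float)
        clo, chi = max(lo, 0), min(hi, size)
        if chi > clo:
            strands = (iv.strand,) if iv.strand in "+-" else ("+", "-")
            seg = np.zeros(chi - clo)
            for s in strands:
                arr = track.values(iv.chrom, s)
                if arr is not None:
                    seg = seg + arr[clo:chi]
            row[clo - lo : chi - lo] = seg
        if iv.strand == "-":
            row = row[::-1]
        mat[i] = row.reshape(nbins, binsize).sum(axis=1)
    mean = np.nanmean(mat, axis=0) if len(loci) else np.full(nbins, missing)
    return mat, mean
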