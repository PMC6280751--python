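"""Readers and writers for the on-disk formats the pipeline touches.

BED (3 or 6 column), GTF gene/transcript features, strand-split bedGraph,
FASTA (via Biopython), a JASPAR-like plain-text PWM block format, and TSV
expression matrices with a time-label header.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import PWM, CoverageTrack, GeneModel, GenomicInterval

log = logging.getLogger(__name__)


class BedParseError(ValueError):
    pass


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; missing strand becomes ``.``."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from e
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(f[0], start, end, strand, name))
            except ValueError as e:
                raise BedParseError(f"{path}:{lineno}: {e}") from e
    return out


def write_bed(path, intervals: list[GenomicInterval], score: int = 0):
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t{score}\t{iv.strand}\n"
            )


def read_gtf_genes(path) -> list[GeneModel]:
    """Read gene features from a GTF file (1-based start converted to 0-based).

    Only ``gene`` features are used when present; otherwise transcript
    features are unioned per gene_id.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("gene", "transcript"):
                continue
            attrs = {}
            for item in f[8].strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                k, _, v = item.partition(" ")
                attrs[k] = v.strip().strip('"')
            rows.append(
                dict(
                    chrom=f[0],
                    feature=f[2],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6] if f[6] in ("+", "-") else ".",
                    gene_id=attrs.get("gene_id", ""),
                    gene_name=attrs.get("gene_name", attrs.get("gene_id", "")),
                    biotype=attrs.get("gene_biotype", attrs.get("biotype", "protein_coding")),
                )
            )
    if not rows:
        return []
    df = pd.DataFrame(rows)
    feats = df[df.feature == "gene"]
    if feats.empty:
        feats = (
            df[df.feature == "transcript"]
            .groupby("gene_id", sort=False)
            .agg(
                chrom=("chrom", "first"),
                start=("start", "min"),
                end=("end", "max"),
                strand=("strand", "first"),
                gene_name=("gene_name", "first"),
                biotype=("biotype", "first"),
            )
            .reset_index()
        )
    genes = []
    for r in feats.itertuples():
        genes.append(
            GeneModel(
                GenomicInterval(r.chrom, r.start, r.end, r.strand, r.gene_id),
                name=r.gene_name,
                biotype=r.biotype,
            )
        )
    return genes


def write_gtf_genes(path, genes: list[GeneModel], source: str = "ernadyn"):
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = (
                f'gene_id "{iv.id}"; gene_name "{g.name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# -- strand-split bedGraph ---------------------------------------------------

def write_bedgraph_pair(prefix, track: CoverageTrack):
    """Write ``<prefix>.plus.bedGraph`` / ``<prefix>.minus.bedGraph``."""
    for strand, tag in (("+", "plus"), ("-", "minus")):
        with open(f"{prefix}.{tag}.bedGraph", "w") as fh:
            for (chrom, s), arr in sorted(track.items()):
                if s != strand:
                    continue
                _write_runs(fh, chrom, arr)


def _write_runs(fh, chrom, arr):
    # run-length encode nonzero stretches
    nz = np.flatnonzero(arr)
    if nz.size == 0:
        return
    changes = np.flatnonzero(np.diff(arr) != 0)
    starts = np.concatenate([[0], changes + 1])
    ends = np.concatenate([changes + 1, [len(arr)]])
    for s, e in zip(starts, ends):
        v = arr[s]
        if v != 0:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph_pair(prefix, chrom_sizes: dict[str, int]) -> CoverageTrack:
    track = CoverageTrack(chrom_sizes)
    for strand, tag in (("+", "plus"), ("-", "minus")):
        p = Path(f"{prefix}.{tag}.bedGraph")
        if not p.exists():
            continue
        with open(p) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")
                track.add(chrom, int(s), int(e), float(v), strand)
    return track


# -- FASTA -------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]):
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


# -- PWM text blocks ---------------------------------------------------------

def read_pwms(path) -> list[PWM]:
    """Read ``>name`` blocks of one whitespace-separated A C G T row per
    position (JASPAR-like orientation with positions as rows)."""
    pwms = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(PWM(name, np.array(rows, dtype=float)))
                name, rows = line[1:].split()[0], []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: PWM row must have 4 values, got {len(vals)}")
                rows.append(vals)
    if name is not None:
        pwms.append(PWM(name, np.array(rows, dtype=float)))
    return pwms


def write_pwms(path, pwms: list[PWM]):
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for row in p.matrix:
                fh.write("\t".join(f"{x:g}" for x in row) + "\n")


# -- expression matrices -----------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    """Loci x time-point matrix; first column = locus id, header = time labels."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix_tsv(path, df: pd.DataFrame, header_comments: list[str] | None = None):
    with open(path, "w") as fh:
        for c in header_comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t")
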