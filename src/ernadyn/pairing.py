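"""Enhancer-promoter pairing and concordance classification.

Each inducible enhancer is assigned the nearest inducible gene whose TSS
lies within 200 kb (distance = unsigned gap from the enhancer interval to
the gene TSS, 0 if the TSS falls inside the enhancer). Pairs are then ranked
by the Spearman correlation of their eRNA and mRNA time courses; the top
30% are concordant, the bottom 30% discordant (the latter typified by
persistent eRNA transcription after the target gene shuts off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, point_distance

log = logging.getLogger(__name__)

PAIRING_WINDOW = 200_000
DISTANCE_BINSIZE = 100_000


@dataclass
class EPPair:
    enhancer: str
    gene: str
    distance: int
    scc: float = np.nan
    concordance: str = "intermediate"


def pair_nearest(
    enhancers: list[GenomicInterval],
    genes: list[GeneModel],
    inducible_genes: set[str],
    window: int = PAIRING_WINDOW,
    coding_only: bool = True,
) -> list[EPPair]:
    """Nearest-inducible-gene assignment within the pairing window.

    Enhancer-anchored: every enhancer gets at most one gene; a gene may
    serve several enhancers. Equal distances break to the lexicographically
    smallest gene id. Noncoding genes are excluded when biotypes are present
    and ``coding_only`` is set.
    """
    cands: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        if g.interval.id not in inducible_genes:
            continue
        if coding_only and g.biotype not in ("protein_coding", "", None):
            continue
        cands.setdefault(g.chrom, []).append((g.tss, g.interval.id))
    pairs = []
    for enh in enhancers:
        best = None
        for tss, gid in cands.get(enh.chrom, ()):
            d = point_distance(enh, tss)
            if d > window:
                continue
            if best is None or d < best[0] or (d == best[0] and gid < best[1]):
                best = (d, gid)
        if best is not None:
            pairs.append(EPPair(enh.id, best[1], best[0]))
    return pairs


def distance_enrichment(
    inducible_enhancers: list[GenomicInterval],
    genes: list[GeneModel],
    inducible_genes: set[str],
    binsize: int = DISTANCE_BINSIZE,
    max_dist: int = 1_000_000,
) -> pd.DataFrame:
    """Distance-binned gene counts around inducible enhancers.

    For the inducible-gene set and the all-gene control, counts genes whose
    distance to the nearest inducible enhancer falls in each ``binsize`` bin;
    each curve is normalised by its maximum for comparison.
    """
    if not inducible_enhancers or not genes:
        raise ValueError("need nonempty enhancer and gene sets")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in inducible_enhancers:
        by_chrom.setdefault(e.chrom, []).append(e)
    nbins = max_dist // binsize
    counts = {"inducible": np.zeros(nbins), "all": np.zeros(nbins)}
    for g in genes:
        ds = [point_distance(e, g.tss) for e in by_chrom.get(g.chrom, ())]
        if not ds:
            continue
        d = min(ds)
        if d >= max_dist:
            continue
        b = d // binsize
        counts["all"][b] += 1
        if g.interval.id in inducible_genes:
            counts["inducible"][b] += 1
    out = pd.DataFrame(
        {
            "bin_start": np.arange(nbins) * binsize,
            "inducible_genes": counts["inducible"],
            "all_genes": counts["all"],
        }
    )
    for col in ("inducible_genes", "all_genes"):
        m = out[col].max()
        out[col + "_norm"] = out[col] / m if m > 0 else np.nan
    return out


def concordance_classes(
    pairs: list[EPPair],
    erna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    top_frac: float = 0.3,
    bottom_frac: float = 0.3,
) -> list[EPPair]:
    """Spearman-rank concordance labels for EP pairs.

    Pairs are ranked by the Spearman correlation (average ranks on ties) of
    the enhancer and gene series across time points, descending. The top
    ``floor(top_frac*n)`` become ``concordant``, the bottom
    ``floor(bottom_frac*n)`` ``discordant``, the rest ``intermediate``.
    Pairs with a constant series have undefined correlation and are labelled
    intermediate outside the ranking.
    """
    scorable = []
    for p in pairs:
        e = erna_expr.loc[p.enhancer].values
        g = gene_expr.loc[p.gene].values
        if np.std(e) == 0 or np.std(g) == 0:
            p.scc = np.nan
            p.concordance = "intermediate"
            log.info("pair %s-%s has a constant series; labelled intermediate",
                     p.enhancer, p.gene)
            continue
        p.scc = float(stats.spearmanr(e, g).statistic)
        scorable.append(p)
    n = len(scorable)
    n_top = int(np.floor(top_frac * n))
    n_bot = int(np.floor(bottom_frac * n))
    order = sorted(range(n), key=lambda i: (-scorable[i].scc, scorable[i].enhancer))
    for rank, i in enumerate(order):
        if rank < n_top:
            scorable[i].concordance = "concordant"
        elif rank >= n - n_bot:
            scorable[i].concordance = "discordant"
        else:
            scorable[i].concordance = "intermediate"
    return pairs


def pairs_to_frame(pairs: list[EPPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "enhancer": p.enhancer,
                "gene": p.gene,
                "distance": p.distance,
                "scc": p.scc,
                "concordance": p.concordance,
            }
            for p in pairs
        ]
    )
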