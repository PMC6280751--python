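"""Cross-species colocalization of enhancer-promoter pairs.

Given an ortholog map (reference anchor -> target-genome interval per
species), an EP pair is conserved when both members map and land on the
same target chromosome — optionally also within 500 kb. Significance is
judged against a background of random promoter/intergenic pairs drawn to
follow the distance distribution of the inducible pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

PROXIMITY = 500_000
N_BACKGROUND = 10_000
DISTANCE_TOLERANCE = 0.10


@dataclass
class OrthologMap:
    """Per-species mapping of reference anchors to target coordinates."""

    species: str
    records: pd.DataFrame  # src_chrom, src_start, src_end, tgt_chrom, tgt_start, tgt_end, tgt_strand

    def lookup(self, chrom: str, start: int, end: int):
        """Target location of the anchor overlapping [start, end), or None."""
        r = self.records
        m = (r.src_chrom == chrom) & (r.src_start < end) & (r.src_end > start)
        if not m.any():
            return None
        row = r[m].iloc[0]
        return (row.tgt_chrom, int(row.tgt_start), int(row.tgt_end))

    @classmethod
    def read_tsv(cls, path) -> dict[str, "OrthologMap"]:
        df = pd.read_csv(path, sep="\t")
        return {
            sp: cls(sp, g.drop(columns="tgt_species").reset_index(drop=True))
            for sp, g in df.groupby("tgt_species")
        }


@dataclass
class SyntenyResult:
    species: str
    rate_same_chrom: float
    rate_proximal: float
    n_mapped_pairs: int


def colocalization_rate(
    pair_anchors: list[tuple[GenomicInterval, GenomicInterval]],
    omap: OrthologMap,
    proximity: int | None = PROXIMITY,
) -> SyntenyResult:
    """Fraction of mapped pairs on the same target chromosome (and within
    ``proximity`` bp when given). Pairs with an unmapped member are skipped;
    an empty mapped set yields NaN rates."""
    n_mapped = n_same = n_prox = 0
    for enh, prom in pair_anchors:
        te = omap.lookup(enh.chrom, enh.start, enh.end)
        tp = omap.lookup(prom.chrom, prom.start, prom.end)
        if te is None or tp is None:
            continue
        n_mapped += 1
        if te[0] == tp[0]:
            n_same += 1
            d = max(te[1], tp[1]) - min(te[2], tp[2])
            if proximity is not None and max(d, 0) < proximity:
                n_prox += 1
    if n_mapped == 0:
        return SyntenyResult(omap.species, np.nan, np.nan, 0)
    return SyntenyResult(
        omap.species,
        n_same / n_mapped,
        (n_prox / n_mapped) if proximity is not None else np.nan,
        n_mapped,
    )


def matched_background(
    promoters: list[GenomicInterval],
    intergenic: list[GenomicInterval],
    target_distances,
    n: int = N_BACKGROUND,
    seed: int = 0,
    tolerance: float = DISTANCE_TOLERANCE,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Random promoter/intergenic pairs following a target distance
    distribution.

    For each background pair a distance is drawn with replacement from the
    empirical target distances, a promoter is drawn uniformly, and an
    intergenic interval whose midpoint lies within ±``tolerance`` of the
    drawn distance from the promoter midpoint is selected at random. When a
    stratum is empty the tolerance is widened stepwise (with a warning)
    before giving up.
    """
    rng = np.random.default_rng(seed)
    target = np.asarray(list(target_distances), dtype=float)
    if target.size == 0:
        raise ValueError("no target distances")
    by_chrom: dict[str, tuple[np.ndarray, list[GenomicInterval]]] = {}
    for chrom in {iv.chrom for iv in intergenic}:
        cands = sorted(
            (iv for iv in intergenic if iv.chrom == chrom),
            key=lambda iv: (iv.start + iv.end) // 2,
        )
        mids = np.array([(iv.start + iv.end) // 2 for iv in cands], dtype=float)
        by_chrom[chrom] = (mids, cands)
    out = []
    warned = False
    for _ in range(n):
        d = float(rng.choice(target))
        found = None
        for attempt, tol in enumerate((tolerance, 2 * tolerance, 4 * tolerance, 8 * tolerance)):
            for _try in range(25):
                prom = promoters[int(rng.integers(len(promoters)))]
                if prom.chrom not in by_chrom:
                    continue
                mids, cands = by_chrom[prom.chrom]
                p = (prom.start + prom.end) / 2
                lo, hi = d * (1 - tol), d * (1 + tol)
                left = np.searchsorted(mids, [p - hi, p - lo])
                right = np.searchsorted(mids, [p + lo, p + hi])
                idxs = np.concatenate(
                    [np.arange(left[0], left[1]), np.arange(right[0], right[1])]
                )
                if idxs.size:
                    found = (prom, cands[int(rng.choice(idxs))])
                    break
            if found is not None:
                if attempt > 0 and not warned:
                    log.warning("matched_background widened distance tolerance")
                    warned = True
                break
        if found is None:
            raise ValueError(
                f"no intergenic candidate near distance {d:.0f} after widening tolerance"
            )
        out.append(found)
    return out


def intergenic_candidates(
    genes,
    chrom_sizes: dict[str, int],
    width: int = 1000,
    step: int = 2000,
    clearance: int = 2000,
) -> list[GenomicInterval]:
    """Tile the intergenic space into candidate background regions.

    Windows of ``width`` bp every ``step`` bp that keep ``clearance`` bp
    from every gene interval.
    """
    blocked: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        iv = g.interval if hasattr(g, "interval") else g
        blocked.setdefault(iv.chrom, []).append(
            (iv.start - clearance, iv.end + clearance)
        )
    for c in blocked:
        blocked[c].sort()
    out = []
    i = 0
    for chrom, size in sorted(chrom_sizes.items()):
        bl = blocked.get(chrom, [])
        starts = np.arange(0, size - width, step)
        for s in starts:
            e = s + width
            if any(s < be and bs < e for bs, be in bl):
                continue
            out.append(GenomicInterval(chrom, int(s), int(e), ".", f"ig{i:06d}"))
            i += 1
    return out


def background_self_check(
    background_pairs: list[tuple[GenomicInterval, GenomicInterval]],
    target_distances,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Two-sample KS test of achieved background distances vs the target
    distribution; returns (D, p, passed)."""
    achieved = [
        abs(((a.start + a.end) / 2) - ((b.start + b.end) / 2))
        for a, b in background_pairs
    ]
    res = stats.ks_2samp(achieved, np.asarray(list(target_distances), dtype=float))
    return float(res.statistic), float(res.pvalue), bool(res.pvalue > alpha)


def synteny_table(
    pair_anchors: list[tuple[GenomicInterval, GenomicInterval]],
    background_anchors: list[tuple[GenomicInterval, GenomicInterval]],
    maps: dict[str, OrthologMap],
    proximity: int = PROXIMITY,
) -> pd.DataFrame:
    """Observed vs background colocalization rates per species."""
    rows = []
    for sp, omap in sorted(maps.items()):
        obs = colocalization_rate(pair_anchors, omap, proximity)
        bgr = colocalization_rate(background_anchors, omap, proximity)
        rows.append(
            {
                "species": sp,
                "rate_same_chrom": obs.rate_same_chrom,
                "rate_proximal": obs.rate_proximal,
                "bg_rate_same_chrom": bgr.rate_same_chrom,
                "bg_rate_proximal": bgr.rate_proximal,
                "n_mapped_pairs": obs.n_mapped_pairs,
            }
        )
    return pd.DataFrame(rows)
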