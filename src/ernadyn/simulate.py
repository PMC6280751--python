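"""Synthetic genomes, time courses and assay tables with planted truth.

The generator emulates a viral-induction nascent-transcription experiment:
a small genome carries non-overlapping genes and intergenic enhancers; each
induced enhancer is planted within 200 kb of a designated inducible gene
(several enhancers may share a gene, as multi-enhancer loci do in vivo).
Locus time courses follow piecewise-linear log2-fold-change templates over
the 0–72 h grid in four classes — flat, early-induced (peak 12 h),
late-induced (peak 48 h) and repressed — scaled so a noiseless run measures
exactly the planted amplitude index. Counts are drawn negative-binomially
(gamma-Poisson) around the template means; dispersion 0 gives the exact
noiseless means. Enhancer-mark peaks, ortholog maps with a controlled
broken fraction, transient 12-h 3C interaction tables and siRNA knockdown
tables are generated from the same truth so every downstream stage has an
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import DEFAULT_PSEUDOCOUNT, ExpressionMatrix, TimeGrid
from .intervals import PWM, CoverageTrack, GeneModel, GenomicInterval, point_distance


class ConfigError(ValueError):
    pass


def default_pwm() -> PWM:
    """Default planted motif: a synthetic ISRE-like interferon-response
    element (GAAAGTGAAA core, 85% consensus base per position)."""
    consensus = "GAAAGTGAAA"
    mat = np.full((len(consensus), 4), 1.0)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 17.0
    return PWM("ISRE_synth", mat)


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 100
    n_enhancers: int = 300
    class_fractions: dict = field(
        default_factory=lambda: {"flat": 0.40, "early": 0.25, "late": 0.15, "repressed": 0.20}
    )
    timegrid: TimeGrid = field(default_factory=TimeGrid)
    noise_dispersion: float = 0.1
    planted_ai: float = 3.0
    discordant_fraction: float = 0.3
    concordant_fraction: float = 0.3
    motif_pwm: PWM = field(default_factory=default_pwm)
    bg_composition: tuple = (0.3, 0.2, 0.2, 0.3)  # A C G T
    library_size: float = 2.0e7
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    max_enhancers_per_gene: int = 3
    min_ep_distance: int = 6_000
    max_ep_distance: int = 100_000
    cassette_gap: int = 120_000   # trailing gap after a gene+enhancer cassette
    lone_gap: int = 15_000        # trailing gap after lone genes/enhancers

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class fractions sum to {total}, not 1")
        if set(self.class_fractions) != {"flat", "early", "late", "repressed"}:
            raise ConfigError("class_fractions must cover flat/early/late/repressed")
        if self.planted_ai <= 1:
            raise ConfigError("planted_ai must exceed 1 for induced classes")
        hours = tuple(self.timegrid.hours)
        if hours[0] != 0 or any(b <= a for a, b in zip(hours, hours[1:])):
            raise ConfigError("timegrid must start at 0 and increase strictly")


# log2-fold-change templates as (hours, fraction-of-amplitude) knots.
# Early peaks at 12 h and returns toward baseline; late starts after 6 h and
# peaks at 48 h (reaching 2/3 of the amplitude by 24 h, so late loci still
# clear the AI>1 gate); repressed declines to -A. The persistent variant
# keeps eRNA output high through 72 h (the discordant-pair eRNA shape) while
# the shutoff variant returns below baseline (its gene partner); the shifted
# variants give intermediate pairs a high but imperfect rank correlation.
TEMPLATES = {
    "flat": ([0.0, 72.0], [0.0, 0.0]),
    "early": (
        [0.0, 1.0, 2.0, 4.0, 6.0, 12.0, 24.0, 48.0, 72.0],
        [0.0, 0.10, 0.25, 0.50, 0.80, 1.00, 0.80, 0.25, 0.10],
    ),
    "early_shifted": (
        [0.0, 2.0, 4.0, 6.0, 12.0, 18.0, 24.0, 48.0, 72.0],
        [0.0, 0.10, 0.25, 0.50, 0.80, 1.00, 0.80, 0.30, 0.15],
    ),
    "early_persistent": (
        [0.0, 1.0, 2.0, 4.0, 6.0, 12.0, 72.0],
        [0.0, 0.10, 0.25, 0.50, 0.80, 1.00, 1.05],
    ),
    "early_shutoff": (
        [0.0, 1.0, 2.0, 4.0, 6.0, 12.0, 18.0, 24.0, 48.0, 72.0],
        [0.0, 0.10, 0.25, 0.50, 0.80, 1.00, 0.60, 0.20, -0.20, -0.30],
    ),
    "late": (
        [0.0, 6.0, 12.0, 18.0, 24.0, 48.0, 72.0],
        [0.0, 0.0, 0.20, 0.45, 0.6667, 1.00, 0.90],
    ),
    "late_shifted": (
        [0.0, 6.0, 12.0, 18.0, 24.0, 48.0, 72.0],
        [0.0, 0.05, 0.30, 0.55, 0.75, 0.95, 1.00],
    ),
    "repressed": (
        [0.0, 2.0, 6.0, 12.0, 24.0, 72.0],
        [0.0, -0.30, -0.70, -1.00, -1.00, -0.80],
    ),
}


def template_lfc(shape: str, amplitude: float, hours) -> np.ndarray:
    kt, kv = TEMPLATES[shape]
    return amplitude * np.interp(np.asarray(hours, dtype=float), kt, kv)


def template_rpkm(shape, amplitude, baseline, hours, pseudocount=DEFAULT_PSEUDOCOUNT):
    """Noiseless RPKM trajectory whose measured amplitude index (with the
    same pseudocount) equals ``amplitude`` for induced shapes."""
    lfc = template_lfc(shape, amplitude, hours)
    return np.maximum((baseline + pseudocount) * 2.0 ** lfc - pseudocount, 0.0)


@dataclass
class TruthTable:
    """Planted ground truth: per-locus table, EP-pair table, motif sites."""

    loci: pd.DataFrame    # id kind chrom start end strand class shape baseline paired_gene tier
    pairs: pd.DataFrame   # enhancer gene distance concordance interaction_amplitude
    motif_sites: pd.DataFrame  # locus position offset
    config: SimConfig

    @property
    def genes(self) -> pd.DataFrame:
        return self.loci[self.loci.kind == "gene"]

    @property
    def enhancers(self) -> pd.DataFrame:
        return self.loci[self.loci.kind == "enhancer"]

    def inducible_ids(self, kind: str) -> set[str]:
        sub = self.loci[self.loci.kind == kind]
        return set(sub[sub["class"].isin(["early", "late"])]["id"])

    def gene_models(self) -> list[GeneModel]:
        return [
            GeneModel(GenomicInterval(r.chrom, r.start, r.end, r.strand, r.id), name=r.id)
            for r in self.genes.itertuples()
        ]

    def enhancer_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, r.start, r.end, r.strand, r.id)
            for r in self.enhancers.itertuples()
        ]

    def write(self, outdir):
        from pathlib import Path

        d = Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        self.loci.to_csv(d / "loci.tsv", sep="\t", index=False)
        self.pairs.to_csv(d / "pairs.tsv", sep="\t", index=False)
        self.motif_sites.to_csv(d / "motif_sites.tsv", sep="\t", index=False)


def _enhancer_lengths(rng, n):
    # lognormal around the ~1.7 kb scale typical of called eRNA loci
    lens = rng.lognormal(mean=np.log(1500.0), sigma=0.45, size=n)
    return np.clip(lens, 500, 6000).astype(int)


def simulate_genome(config: SimConfig):
    """Lay out genes and enhancers, plant motif sites, and emit the truth.

    Returns ``(genes, enhancers, sequences, truth)`` where ``sequences`` is
    a dict chrom -> str. Gene/enhancer cassettes guarantee by construction
    that every induced enhancer's nearest inducible gene TSS is its
    designated partner within the 200-kb pairing window, and that every
    enhancer passes the intergenic distance filters (>1 kb from 5' ends,
    >10 kb from 3' ends, no gene-body overlap).
    """
    rng = np.random.default_rng(config.seed)
    cf = config.class_fractions
    n_enh = config.n_enhancers
    n_early = int(round(cf["early"] * n_enh))
    n_late = int(round(cf["late"] * n_enh))
    n_repressed = int(round(cf["repressed"] * n_enh))
    n_flat = n_enh - n_early - n_late - n_repressed
    if min(n_flat, n_early, n_late, n_repressed) < 0:
        raise ConfigError("class fractions produce negative counts")

    enh_classes = ["early"] * n_early + ["late"] * n_late
    n_induced = len(enh_classes)

    # concordance tiers with exact floor-rule counts; discordant pairs are
    # early-class (gene shutoff under persistent eRNA is an early phenomenon)
    n_disc = int(np.floor(config.discordant_fraction * n_induced))
    n_conc = int(np.floor(config.concordant_fraction * n_induced))
    if n_disc > n_early:
        raise ConfigError("discordant_fraction exceeds the early-class supply")
    tiers = np.array(["intermediate"] * n_induced, dtype=object)
    early_idx = np.array([i for i, c in enumerate(enh_classes) if c == "early"])
    if n_disc:
        tiers[rng.choice(early_idx, size=n_disc, replace=False)] = "discordant"
    remaining = np.array([i for i in range(n_induced) if tiers[i] == "intermediate"])
    if n_conc:
        tiers[rng.choice(remaining, size=min(n_conc, len(remaining)), replace=False)] = "concordant"

    # cassette partition: discordant enhancers get singleton cassettes (their
    # gene must shut off, which cannot be shared); the rest chunk by class so
    # concordant eRNAs share their gene's template exactly
    per_gene = config.max_enhancers_per_gene
    cassettes: list[list[int]] = [[i] for i in range(n_induced) if tiers[i] == "discordant"]
    for cls in ("early", "late"):
        pool = [i for i in range(n_induced)
                if enh_classes[i] == cls and tiers[i] != "discordant"]
        pool = [pool[j] for j in rng.permutation(len(pool))]
        cassettes += [pool[i : i + per_gene] for i in range(0, len(pool), per_gene)]
    n_lone_genes = config.n_genes - len(cassettes)
    if n_lone_genes < 0:
        raise ConfigError("too few genes for the induced-enhancer cassettes")

    enh_lens = _enhancer_lengths(rng, n_enh)
    enh_cursor = 0
    # cassette distances must clear the largest enhancer length
    min_sep = (int(enh_lens.max()) if n_enh else 0) + 500

    units = []  # (kind, span, trailing_gap, payload)
    for cas in cassettes:
        gene_len = int(rng.integers(5000, 15001))
        slots = np.arange(config.min_ep_distance, config.max_ep_distance, min_sep)
        if len(cas) > len(slots):
            raise ConfigError("EP distance range too narrow for cassette size")
        dists = np.sort(rng.choice(slots, size=len(cas), replace=False))
        members = []
        for j, enh_i in enumerate(cas):
            members.append((int(enh_i), int(dists[j]), int(enh_lens[enh_cursor])))
            enh_cursor += 1
        span = int(dists[-1]) + max(m[2] for m in members) + gene_len + 2000
        units.append(("cassette", span, config.cassette_gap, (gene_len, members)))
    for _ in range(n_lone_genes):
        gene_len = int(rng.integers(5000, 15001))
        units.append(("gene", gene_len, config.lone_gap, gene_len))
    for cls in ["flat"] * n_flat + ["repressed"] * n_repressed:
        ln = int(enh_lens[enh_cursor])
        enh_cursor += 1
        units.append(("enhancer", ln, config.lone_gap, (cls, ln)))

    rng.shuffle(units)

    # first-fit sequential packing across chromosomes
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    margin = 60_000
    placements = []
    ci, cursor = 0, margin
    for kind, span, gap, payload in units:
        while ci < len(chroms) and cursor + span + margin > config.chrom_length:
            ci += 1
            cursor = margin
        if ci >= len(chroms):
            raise ConfigError("locus counts do not fit the genome with the required spacing")
        placements.append((kind, chroms[ci], cursor, payload))
        cursor += span + gap

    loci_rows, pair_rows, motif_rows = [], [], []
    gene_counter = enh_counter = 0
    induced_enh_ids: list[str] = []
    lone_gene_classes = rng.choice(["flat", "repressed"],
                                   size=n_lone_genes, p=[0.75, 0.25])
    lone_gi = 0

    for kind, chrom, start, payload in placements:
        if kind == "cassette":
            gene_len, members = payload
            strand = "+" if rng.random() < 0.5 else "-"
            max_reach = max(d + ln for _, d, ln in members)
            if strand == "+":
                # enhancers left of the TSS, gene body to the right
                tss = start + max_reach + 1000
                g_start, g_end = tss, tss + gene_len
            else:
                # gene body first, TSS at its right edge, enhancers to the right
                g_start, g_end = start, start + gene_len
                tss = g_end - 1
            gene_id = f"G{gene_counter:04d}"
            gene_counter += 1
            gene_class = "late" if all(enh_classes[m[0]] == "late" for m in members) else "early"
            # singleton discordant cassette: the gene shuts off post-induction
            discordant_cassette = len(members) == 1 and tiers[members[0][0]] == "discordant"
            gene_shape = "early_shutoff" if discordant_cassette else gene_class
            loci_rows.append(
                dict(id=gene_id, kind="gene", chrom=chrom, start=g_start, end=g_end,
                     strand=strand, **{"class": gene_class}, shape=gene_shape,
                     baseline=float(rng.uniform(0.8, 3.0)), paired_gene="", tier="")
            )
            for enh_i, dist, ln in members:
                cls = enh_classes[enh_i]
                tier = str(tiers[enh_i])
                if strand == "+":
                    e_end = tss - dist + 1
                    e_start = e_end - ln
                else:
                    e_start = tss + dist
                    e_end = e_start + ln
                e_strand = "+" if rng.random() < 0.5 else "-"
                eid = f"E{enh_counter:04d}"
                enh_counter += 1
                induced_enh_ids.append(eid)
                if tier == "discordant":
                    eshape = "early_persistent"
                elif tier == "intermediate":
                    eshape = f"{cls}_shifted"
                else:
                    eshape = gene_class
                loci_rows.append(
                    dict(id=eid, kind="enhancer", chrom=chrom, start=e_start,
                         end=e_end, strand=e_strand, **{"class": cls}, shape=eshape,
                         baseline=float(rng.uniform(0.05, 0.15)),
                         paired_gene=gene_id, tier=tier)
                )
                pair_rows.append(
                    dict(enhancer=eid, gene=gene_id, distance=int(dist),
                         concordance=tier, interaction_amplitude=4.0)
                )
        elif kind == "gene":
            gene_len = payload
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{gene_counter:04d}"
            gene_counter += 1
            cls = str(lone_gene_classes[lone_gi])
            lone_gi += 1
            loci_rows.append(
                dict(id=gene_id, kind="gene", chrom=chrom, start=start,
                     end=start + gene_len, strand=strand, **{"class": cls},
                     shape=cls, baseline=float(rng.uniform(1.0, 10.0)),
                     paired_gene="", tier="")
            )
        else:
            cls, ln = payload
            strand = "+" if rng.random() < 0.5 else "-"
            eid = f"E{enh_counter:04d}"
            enh_counter += 1
            if cls == "flat":
                base = (float(rng.uniform(0.05, 0.3)) if rng.random() < 0.4
                        else float(rng.uniform(0.8, 3.0)))
            else:
                base = float(rng.uniform(1.5, 4.0))
            loci_rows.append(
                dict(id=eid, kind="enhancer", chrom=chrom, start=start,
                     end=start + ln, strand=strand, **{"class": cls}, shape=cls,
                     baseline=base, paired_gene="", tier="")
            )

    loci = pd.DataFrame(loci_rows)
    pairs = pd.DataFrame(
        pair_rows,
        columns=["enhancer", "gene", "distance", "concordance", "interaction_amplitude"],
    )

    # genome sequence + planted motif sites near induced-enhancer TSSs
    bg = np.asarray(config.bg_composition, dtype=float)
    bg = bg / bg.sum()
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {c: rng.choice(alphabet, size=config.chrom_length, p=bg) for c in chroms}
    consensus = config.motif_pwm.consensus
    L = len(consensus)
    enh_rows = {r.id: r for r in loci[loci.kind == "enhancer"].itertuples()}
    for eid in induced_enh_ids:
        r = enh_rows[eid]
        tss = r.start if r.strand != "-" else r.end - 1
        offset = int(rng.integers(-100, 101 - L))
        pos = tss + offset
        seqs[r.chrom][pos : pos + L] = np.frombuffer(consensus.encode(), dtype="S1")
        motif_rows.append(dict(locus=eid, position=pos, offset=offset))
    sequences = {c: arr.tobytes().decode() for c, arr in seqs.items()}
    motif_sites = pd.DataFrame(motif_rows, columns=["locus", "position", "offset"])

    truth = TruthTable(loci, pairs, motif_sites, config)
    return truth.gene_models(), truth.enhancer_intervals(), sequences, truth


def simulate_timecourse(
    truth: TruthTable,
    config: SimConfig | None = None,
    emit_coverage: bool = False,
):
    """Counts matrices (genes and enhancers) on the time grid, optionally
    with strand-split coverage tracks per time point.

    Counts are gamma-Poisson (negative binomial) with mean
    ``RPKM * length * library_size / 1e9`` and variance ``mu + disp*mu^2``;
    dispersion 0 returns the exact noiseless means. Enhancer transcription
    is bidirectional: the two strands draw independent noise and the locus
    count is their sum.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    hours = np.asarray(config.timegrid.hours)
    disp = config.noise_dispersion

    def draw(mu):
        mu = np.asarray(mu, dtype=float)
        if disp <= 0:
            return mu.copy()
        lam = rng.gamma(shape=1.0 / disp, scale=np.maximum(mu, 1e-12) * disp)
        return rng.poisson(lam).astype(float)

    frames = {}
    strand_counts = {}
    for kind in ("gene", "enhancer"):
        sub = truth.loci[truth.loci.kind == kind]
        ids = list(sub["id"])
        mat = np.zeros((len(sub), len(hours)))
        halves = np.zeros((len(sub), len(hours), 2))
        for i, r in enumerate(sub.itertuples()):
            rp = template_rpkm(r.shape, config.planted_ai, r.baseline, hours,
                               config.pseudocount)
            mu = rp * (r.end - r.start) * config.library_size / 1e9
            if kind == "enhancer":
                a, b = draw(mu / 2), draw(mu / 2)
                mat[i] = a + b
                halves[i, :, 0], halves[i, :, 1] = a, b
            else:
                mat[i] = draw(mu)
                halves[i, :, 0] = mat[i]
        frames[kind] = pd.DataFrame(mat, index=ids, columns=list(config.timegrid.labels))
        strand_counts[kind] = (ids, halves)

    lengths = pd.Series((truth.loci.end - truth.loci.start).values,
                        index=list(truth.loci["id"]))
    lib = pd.Series(config.library_size, index=list(config.timegrid.labels))
    gene_em = ExpressionMatrix(frames["gene"], config.timegrid,
                               lengths.loc[frames["gene"].index], lib, unit="counts")
    enh_em = ExpressionMatrix(frames["enhancer"], config.timegrid,
                              lengths.loc[frames["enhancer"].index], lib, unit="counts")
    if not emit_coverage:
        return gene_em, enh_em, None

    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)}
    locs = {r.id: r for r in truth.loci.itertuples()}
    tracks = []
    for ti in range(len(hours)):
        track = CoverageTrack(sizes)
        for kind in ("gene", "enhancer"):
            ids, halves = strand_counts[kind]
            for li, lid in enumerate(ids):
                r = locs[lid]
                ln = r.end - r.start
                s = r.strand if r.strand in "+-" else "+"
                if kind == "gene":
                    v = halves[li, ti, 0] / ln
                    if v > 0:
                        track.add(r.chrom, r.start, r.end, v, s)
                else:
                    other = "-" if s == "+" else "+"
                    for half, st in ((0, s), (1, other)):
                        v = halves[li, ti, half] / ln
                        if v > 0:
                            track.add(r.chrom, r.start, r.end, v, st)
        tracks.append(track)
    return gene_em, enh_em, tracks


def simulate_marks(
    truth: TruthTable,
    n_decoys: int = 50,
    pad: int = 200,
    seed_offset: int = 2,
) -> list[GenomicInterval]:
    """H3K4me1/H3K27ac-style peaks covering every true enhancer, plus decoy
    peaks placed clear of genes and enhancers."""
    config = truth.config
    rng = np.random.default_rng(config.seed + seed_offset)
    peaks = [
        GenomicInterval(r.chrom, max(r.start - pad, 0), r.end + pad, ".", f"peak{i:04d}")
        for i, r in enumerate(truth.enhancers.itertuples())
    ]
    occupied: dict[str, list[tuple[int, int]]] = {}
    for r in truth.loci.itertuples():
        occupied.setdefault(r.chrom, []).append((r.start - 2000, r.end + 2000))
    chroms = sorted(occupied)
    made = 0
    while made < n_decoys:
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(10_000, config.chrom_length - 12_000))
        e = s + int(rng.integers(500, 2000))
        if any(s < oe and os_ < e for os_, oe in occupied[c]):
            continue
        peaks.append(GenomicInterval(c, s, e, ".", f"decoy{made:04d}"))
        made += 1
    return peaks


def simulate_orthomap(
    truth: TruthTable,
    n_species: int = 3,
    break_fraction: float = 0.1,
    bg_break_fraction: float = 0.25,
    unmapped_fraction: float = 0.05,
    seed_offset: int = 3,
) -> pd.DataFrame:
    """Anchor-level ortholog maps (long TSV, one block per species).

    Gene promoters (TSS ± 1 kb) and enhancer TSS anchors (± 500 bp) map to
    target chromosomes mirroring the source; per species, ``break_fraction``
    of EP-pair anchors and a larger ``bg_break_fraction`` of all other
    anchors relocate to a different target chromosome, so planted pairs
    co-localize more often than a distance-matched background.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + seed_offset)
    paired = set(truth.pairs.enhancer) | set(truth.pairs.gene)
    n_tgt = config.n_chrom + 2
    src_index = {f"chr{i + 1}": i for i in range(config.n_chrom)}
    anchors = []
    for r in truth.genes.itertuples():
        tss = r.start if r.strand != "-" else r.end - 1
        anchors.append((r.id, r.chrom, max(tss - 1000, 0), tss + 1000, "promoter"))
    for r in truth.enhancers.itertuples():
        tss = r.start if r.strand != "-" else r.end - 1
        anchors.append((r.id, r.chrom, max(tss - 500, 0), tss + 500, "enhancer"))
    # background intergenic tiles must be liftable too, else matched random
    # pairs could not be scored against the map
    from .synteny import intergenic_candidates

    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)}
    for iv in intergenic_candidates(truth.gene_models(), sizes):
        anchors.append((iv.id, iv.chrom, iv.start, iv.end, "intergenic"))
    rows = []
    for sp_i in range(n_species):
        sp = f"species{sp_i + 1}"
        shift = int(rng.integers(0, 500_000))
        for aid, chrom, s, e, kind in anchors:
            if rng.random() < unmapped_fraction:
                continue
            broken_p = break_fraction if aid in paired else bg_break_fraction
            home = src_index[chrom]
            if rng.random() < broken_p:
                tgt_i = int(rng.choice([i for i in range(n_tgt) if i != home]))
                tgt_s = int(rng.integers(0, config.chrom_length))
            else:
                tgt_i = home
                tgt_s = s + shift
            rows.append(
                dict(src_chrom=chrom, src_start=s, src_end=e, tgt_species=sp,
                     tgt_chrom=f"{sp}_chr{tgt_i + 1}", tgt_start=tgt_s,
                     tgt_end=tgt_s + (e - s), tgt_strand="+")
            )
    return pd.DataFrame(rows)


def simulate_3c(
    truth: TruthTable | None,
    n_induced: int = 18,
    n_control: int = 18,
    amplitude: float | None = None,
    ct_noise: float = 0.25,
    times=(0.0, 6.0, 12.0, 18.0, 24.0),
    n_replicates: int = 3,
    seed: int | None = None,
    seed_offset: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct tables encoding transient 12-h interaction peaks for induced EP
    pairs and flat but variable trajectories for control pairs.

    Ct values are written on the assay convention in which the interaction
    frequency is ``2^(dCt_sample - dCt_control)``. Returns
    ``(ct_table, pair_truth)``.
    """
    if seed is None:
        seed = (truth.config.seed if truth is not None else 0) + seed_offset
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    base_ct = 22.0

    def tent(t, amp):
        return float(np.interp(t, [0, 6, 12, 18, 24],
                               [1.0, amp / 2, amp, (amp + 1) / 2, 1.2]))

    for group, n in (("induced", n_induced), ("control", n_control)):
        for i in range(n):
            pid = f"{group}_{i:02d}"
            if group == "induced":
                amp = amplitude if amplitude is not None else float(rng.uniform(3.0, 6.0))
                traj = {t: tent(t, amp) for t in times}
            else:
                amp = 1.0
                traj = {t: float(2.0 ** w) for t, w in zip(times, rng.normal(0, 0.4, len(times)))}
            truth_rows.append(dict(pair_id=pid, group=group, amplitude=amp))
            for t in times:
                for rep in range(n_replicates):
                    ctc = base_ct + float(rng.normal(0, ct_noise))
                    cts = base_ct + float(np.log2(traj[t])) + float(rng.normal(0, ct_noise))
                    rows.append(dict(pair_id=pid, time_h=t, library="sample",
                                     replicate=rep, ct=round(cts, 3)))
                    rows.append(dict(pair_id=pid, time_h=t, library="control_BAC",
                                     replicate=rep, ct=round(ctc, 3)))
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_kd(
    truth: TruthTable,
    efficacy: float = 0.4,
    n_inducible: int = 11,
    n_control: int = 12,
    seed_offset: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """siRNA knockdown fold-change tables.

    Effective knockdowns (eFold around ``efficacy``) of inducible-pair
    eRNAs repress the target mRNA; control pairs split between unchanged,
    repressed and activated targets. Each inducible pair also gets one
    ineffective siRNA (eFold near 1). Returns ``(kd_table, kd_truth)``.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + seed_offset)
    ind = truth.pairs.head(n_inducible)
    rows, truth_rows = [], []
    si = 0

    def add(enh, gene, efold, mfold, planted):
        nonlocal si
        rows.append(dict(sirna_id=f"si{si:03d}", enhancer_id=enh, gene_id=gene,
                         efold=round(efold, 3), mfold=round(mfold, 3)))
        truth_rows.append(dict(sirna_id=f"si{si:03d}", enhancer_id=enh,
                               gene_id=gene, planted_effect=planted))
        si += 1

    for r in ind.itertuples():
        eff = float(np.clip(efficacy * rng.lognormal(0, 0.2), 0.05, 0.65))
        add(r.enhancer, r.gene, eff, float(rng.uniform(0.3, 0.7)), "repressed")
        add(r.enhancer, r.gene, float(rng.uniform(0.75, 1.1)),
            float(rng.uniform(0.9, 1.1)), "ineffective")
    for i in range(n_control):
        enh, gene = f"CE{i:02d}", f"CG{i:02d}"
        eff = float(np.clip(efficacy * rng.lognormal(0, 0.2), 0.05, 0.65))
        u = rng.random()
        if u < 0.5:
            add(enh, gene, eff, float(rng.uniform(0.92, 1.08)), "unchanged")
        elif u < 0.75:
            add(enh, gene, eff, float(rng.uniform(0.4, 0.8)), "repressed")
        else:
            add(enh, gene, eff, float(rng.uniform(1.2, 1.8)), "activated")
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
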