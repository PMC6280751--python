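import numpy as np
import pandas as pd
import pytest

from ernadyn.intervals import GenomicInterval
from ernadyn.synteny import (OrthologMap, background_self_check,
                             colocalization_rate, intergenic_candidates,
                             matched_background)


def make_map(records):
    return OrthologMap("sp", pd.DataFrame(
        records, columns=["src_chrom", "src_start", "src_end", "tgt_chrom",
                          "tgt_start", "tgt_end", "tgt_strand"]))


def anchor(chrom, start, end, name=""):
    return GenomicInterval(chrom, start, end, ".", name)


class TestColocalizationRate:
    def _pairs(self, n=10):
        out = []
        for i in range(n):
            s = 100_000 * (i + 1)
            out.append((anchor("chr1", s, s + 1000, f"e{i}"),
                        anchor("chr1", s + 50_000, s + 52_000, f"g{i}")))
        return out

    def test_identity_like_map_gives_rate_one(self):
        pairs = self._pairs()
        recs = []
        for e, g in pairs:
            recs.append((e.chrom, e.start, e.end, "t1", e.start, e.end, "+"))
            recs.append((g.chrom, g.start, g.end, "t1", g.start, g.end, "+"))
        res = colocalization_rate(pairs, make_map(recs))
        assert res.rate_same_chrom == 1.0
        assert res.rate_proximal == 1.0
        assert res.n_mapped_pairs == 10

    def test_translocated_enhancers_give_zero(self):
        pairs = self._pairs()
        recs = []
        for e, g in pairs:
            recs.append((e.chrom, e.start, e.end, "t9", e.start, e.end, "+"))
            recs.append((g.chrom, g.start, g.end, "t1", g.start, g.end, "+"))
        assert colocalization_rate(pairs, make_map(recs)).rate_same_chrom == 0.0

    def test_unmapped_pairs_skipped_and_empty_is_nan(self):
        pairs = self._pairs(3)
        recs = [(pairs[0][0].chrom, pairs[0][0].start, pairs[0][0].end,
                 "t1", 0, 1000, "+")]  # only one enhancer maps
        res = colocalization_rate(pairs, make_map(recs))
        assert res.n_mapped_pairs == 0 and np.isnan(res.rate_same_chrom)

    def test_invariant_to_pair_order(self):
        pairs = self._pairs()
        recs = []
        for i, (e, g) in enumerate(pairs):
            tgt = "t1" if i % 2 else "t2"
            recs.append((e.chrom, e.start, e.end, tgt, e.start, e.end, "+"))
            recs.append((g.chrom, g.start, g.end, "t1", g.start, g.end, "+"))
        omap = make_map(recs)
        r1 = colocalization_rate(pairs, omap)
        r2 = colocalization_rate(list(reversed(pairs)), omap)
        assert r1.rate_same_chrom == r2.rate_same_chrom


class TestMatchedBackground:
    def _setup(self):
        proms = [anchor("chr1", s, s + 2000, f"p{i}")
                 for i, s in enumerate(range(100_000, 2_000_000, 100_000))]
        cands = [anchor("chr1", s, s + 1000, f"c{i}")
                 for i, s in enumerate(range(0, 2_000_000, 2000))]
        return proms, cands

    def test_single_distance_target_respected(self):
        proms, cands = self._setup()
        bg = matched_background(proms, cands, [50_000], n=200, seed=0)
        for p, c in bg:
            d = abs((p.start + p.end) / 2 - (c.start + c.end) / 2)
            assert 50_000 * 0.9 <= d <= 50_000 * 1.1

    def test_seeded_determinism(self):
        proms, cands = self._setup()
        t = [20_000, 50_000, 80_000]
        bg1 = matched_background(proms, cands, t, n=100, seed=7)
        bg2 = matched_background(proms, cands, t, n=100, seed=7)
        assert [(p.id, c.id) for p, c in bg1] == [(p.id, c.id) for p, c in bg2]

    def test_distance_distribution_passes_ks_self_check(self):
        proms, cands = self._setup()
        rng = np.random.default_rng(1)
        target = rng.uniform(10_000, 150_000, 100)
        bg = matched_background(proms, cands, target, n=1000, seed=3)
        D, p, ok = background_self_check(bg, target)
        assert ok, f"KS D={D:.3f} p={p:.4f}"

    def test_no_targets_rejected(self):
        proms, cands = self._setup()
        with pytest.raises(ValueError):
            matched_background(proms, cands, [], n=10, seed=0)


class TestIntergenicCandidates:
    def test_tiles_avoid_genes(self, small_truth):
        genes, enhancers, seqs, truth = small_truth
        sizes = {"chr1": truth.config.chrom_length}
        cands = intergenic_candidates(genes, sizes, clearance=2000)
        for g in genes:
            for c in cands:
                if c.chrom != g.chrom:
                    continue
                assert not (c.start < g.interval.end + 2000
                            and g.interval.start - 2000 < c.end)


class TestSynthOrthomapRates:
    def test_break_fraction_controls_rate(self, small_truth):
        from ernadyn.simulate import simulate_orthomap

        genes, enhancers, seqs, truth = small_truth
        df = simulate_orthomap(truth, n_species=1, break_fraction=0.0,
                               bg_break_fraction=0.0, unmapped_fraction=0.0)
        omap = OrthologMap("species1", df.drop(columns="tgt_species"))
        enh_rows = {r.id: r for r in truth.enhancers.itertuples()}
        gene_rows = {r.id: r for r in truth.genes.itertuples()}
        pairs = []
        for r in truth.pairs.itertuples():
            e, g = enh_rows[r.enhancer], gene_rows[r.gene]
            etss = e.start if e.strand != "-" else e.end - 1
            gtss = g.start if g.strand != "-" else g.end - 1
            pairs.append((anchor(e.chrom, etss - 500, etss + 500, e.id),
                          anchor(g.chrom, gtss - 1000, gtss + 1000, g.id)))
        res = colocalization_rate(pairs, omap)
        assert res.rate_same_chrom == 1.0

    def test_background_rate_below_pair_rate(self, small_truth):
        from ernadyn.simulate import simulate_orthomap

        genes, enhancers, seqs, truth = small_truth
        df = simulate_orthomap(truth, n_species=1, break_fraction=0.05,
                               bg_break_fraction=0.5, unmapped_fraction=0.0)
        omap = OrthologMap("species1", df.drop(columns="tgt_species"))
        enh_rows = {r.id: r for r in truth.enhancers.itertuples()}
        gene_rows = {r.id: r for r in truth.genes.itertuples()}
        pairs, bg = [], []
        paired_genes = set(truth.pairs.gene)
        for r in truth.pairs.itertuples():
            e, g = enh_rows[r.enhancer], gene_rows[r.gene]
            etss = e.start if e.strand != "-" else e.end - 1
            gtss = g.start if g.strand != "-" else g.end - 1
            pairs.append((anchor(e.chrom, etss - 500, etss + 500, e.id),
                          anchor(g.chrom, gtss - 1000, gtss + 1000, g.id)))
        # background: unpaired enhancers vs unpaired gene promoters
        unpaired_e = [r for r in truth.enhancers.itertuples()
                      if r.id not in set(truth.pairs.enhancer)]
        unpaired_g = [r for r in truth.genes.itertuples()
                      if r.id not in paired_genes]
        for e, g in zip(unpaired_e, unpaired_g):
            etss = e.start if e.strand != "-" else e.end - 1
            gtss = g.start if g.strand != "-" else g.end - 1
            bg.append((anchor(e.chrom, etss - 500, etss + 500, e.id),
                       anchor(g.chrom, gtss - 1000, gtss + 1000, g.id)))
        r_pairs = colocalization_rate(pairs, omap)
        r_bg = colocalization_rate(bg, omap)
        assert r_bg.rate_same_chrom <= r_pairs.rate_same_chrom
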