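import numpy as np
import pandas as pd
import pytest

from ernadyn.expression import TimeGrid
from ernadyn.intervals import GeneModel, GenomicInterval
from ernadyn.pairing import (EPPair, concordance_classes, distance_enrichment,
                             pair_nearest)


def gene(name, chrom, start, end, strand="+", biotype="protein_coding"):
    return GeneModel(GenomicInterval(chrom, start, end, strand, name),
                     name=name, biotype=biotype)


def enh(name, chrom, start, end):
    return GenomicInterval(chrom, start, end, "+", name)


class TestPairNearest:
    def test_inducibility_precedes_proximity(self):
        e = enh("e", "chr1", 100_000, 101_000)
        near = gene("gA", "chr1", 111_000, 120_000)          # 10 kb, not inducible
        far = gene("gB", "chr1", 151_000, 160_000)           # 50 kb, inducible
        pairs = pair_nearest([e], [near, far], {"gB"})
        assert len(pairs) == 1 and pairs[0].gene == "gB"
        # gap from the enhancer's last base (100_999) to the TSS (151_000)
        assert pairs[0].distance == 50_001

    def test_window_excludes_distant_genes(self):
        e = enh("e", "chr1", 0, 1000)
        g = gene("g", "chr1", 251_000, 260_000)
        assert pair_nearest([e], [g], {"g"}, window=200_000) == []

    def test_tie_breaks_to_lexicographically_smallest(self):
        e = enh("e", "chr1", 100_000, 101_000)
        left = gene("gA", "chr1", 42_000, 51_000, "-")  # TSS at 50_999
        d_left = 100_000 - 50_999
        # a right-side gene whose TSS sits at exactly the same distance
        right = gene("gC", "chr1", 100_999 + d_left, 160_000)
        pairs = pair_nearest([e], [left, right], {"gA", "gC"})
        assert pairs[0].distance == d_left
        assert pairs[0].gene == "gA"

    def test_order_invariance_and_function_property(self, small_truth):
        genes, enhancers, seqs, truth = small_truth
        ind_g = truth.inducible_ids("gene")
        fwd = pair_nearest(enhancers, genes, ind_g)
        rev = pair_nearest(list(reversed(enhancers)), list(reversed(genes)), ind_g)
        assert {(p.enhancer, p.gene) for p in fwd} == {(p.enhancer, p.gene) for p in rev}
        assert len({p.enhancer for p in fwd}) == len(fwd)  # one gene per enhancer

    def test_noncoding_targets_excluded(self):
        e = enh("e", "chr1", 100_000, 101_000)
        nc = gene("gN", "chr1", 111_000, 120_000, biotype="lincRNA")
        pc = gene("gP", "chr1", 151_000, 160_000)
        pairs = pair_nearest([e], [nc, pc], {"gN", "gP"})
        assert pairs[0].gene == "gP"


class TestDistanceEnrichment:
    def test_identical_sets_coincide(self):
        rng = np.random.default_rng(0)
        enhs = [enh(f"e{i}", "chr1", int(s), int(s) + 1000)
                for i, s in enumerate(rng.integers(0, 5_000_000, 20))]
        genes = [gene(f"g{i}", "chr1", int(s), int(s) + 10_000)
                 for i, s in enumerate(rng.integers(0, 5_000_000, 40))]
        out = distance_enrichment(enhs, genes, {g.interval.id for g in genes})
        assert np.allclose(out.inducible_genes_norm, out.all_genes_norm)

    def test_matches_per_gene_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        enhs = [enh(f"e{i}", "chr1", int(s), int(s) + 500)
                for i, s in enumerate(rng.integers(0, 3_000_000, 15))]
        genes = [gene(f"g{i}", "chr1", int(s), int(s) + 5000,
                      rng.choice(["+", "-"]))
                 for i, s in enumerate(rng.integers(0, 3_000_000, 30))]
        inducible = {g.interval.id for g in genes[:10]}
        out = distance_enrichment(enhs, genes, inducible, binsize=100_000,
                                  max_dist=1_000_000)
        raw_all = np.zeros(10)
        raw_ind = np.zeros(10)
        for g in genes:
            ds = []
            for e in enhs:
                tss = g.tss
                if tss < e.start:
                    ds.append(e.start - tss)
                elif tss >= e.end:
                    ds.append(tss - (e.end - 1))
                else:
                    ds.append(0)
            d = min(ds)
            if d < 1_000_000:
                raw_all[d // 100_000] += 1
                if g.interval.id in inducible:
                    raw_ind[d // 100_000] += 1
        assert np.allclose(out.all_genes, raw_all)
        assert np.allclose(out.inducible_genes, raw_ind)


class TestConcordance:
    def _expr(self, rows, ids):
        return pd.DataFrame(rows, index=ids)

    def test_identical_trajectories_rank_top(self):
        # floor(0.3*4) = 1 concordant and 1 discordant label
        e = self._expr([[0, 1, 5, 2], [5, 4, 1, 0], [1, 2, 1, 2], [0, 2, 3, 5]],
                       ["e1", "e2", "e3", "e4"])
        g = self._expr([[0, 1, 5, 2], [0, 1, 4, 5], [1, 2, 2, 2], [0, 3, 2, 5]],
                       ["g1", "g2", "g3", "g4"])
        pairs = [EPPair(f"e{i}", f"g{i}", 0) for i in (1, 2, 3, 4)]
        out = concordance_classes(pairs, e, g)
        by = {p.enhancer: p for p in out}
        assert by["e1"].scc == pytest.approx(1.0)
        assert by["e1"].concordance == "concordant"
        assert by["e2"].concordance == "discordant"  # anti-correlated

    def test_hand_built_ranking_boundaries(self):
        # 10 pairs with scc = 1.0, 0.9, ... strictly decreasing:
        # floor(0.3*10)=3 concordant at the top, 3 discordant at the bottom
        n = 10
        base = np.arange(8.0)
        erna = self._expr([base] * n, [f"e{i}" for i in range(n)])
        rows = []
        for i in range(n):
            series = base.copy()
            series[:i] = series[:i][::-1]  # progressively scramble ranks
            rows.append(series)
        genes = self._expr(rows, [f"g{i}" for i in range(n)])
        pairs = [EPPair(f"e{i}", f"g{i}", 0) for i in range(n)]
        out = concordance_classes(pairs, erna, genes)
        sccs = sorted(((p.scc, p.enhancer, p.concordance) for p in out), reverse=True)
        labels = [c for _, _, c in sccs]
        assert labels == (["concordant"] * 3 + ["intermediate"] * 4
                          + ["discordant"] * 3)

    def test_constant_series_labelled_intermediate(self):
        e = self._expr([[1, 1, 1, 1], [0, 1, 2, 3], [3, 2, 1, 0], [0, 2, 1, 3]],
                       ["e1", "e2", "e3", "e4"])
        g = self._expr([[0, 1, 2, 3]] * 4, ["g1", "g2", "g3", "g4"])
        pairs = [EPPair(f"e{i}", f"g{i}", 0) for i in (1, 2, 3, 4)]
        out = concordance_classes(pairs, e, g)
        by = {p.enhancer: p for p in out}
        assert by["e1"].concordance == "intermediate"
        assert np.isnan(by["e1"].scc)
        # counts over scorable pairs respect the floor rule (floor(.3*3)=0)
        assert [p.concordance for p in out if p.enhancer != "e1"] == ["intermediate"] * 3

    def test_persistent_erna_after_gene_shutoff_is_discordant(self, timegrid):
        from ernadyn.simulate import template_rpkm

        hours = timegrid.hours
        n = 10
        ids_e = [f"e{i}" for i in range(n)]
        ids_g = [f"g{i}" for i in range(n)]
        erna_rows, gene_rows = [], []
        rng = np.random.default_rng(0)
        for i in range(n):
            if i < 3:  # persistent eRNA, shutoff gene
                erna_rows.append(template_rpkm("early_persistent", 3, 0.1, hours))
                gene_rows.append(template_rpkm("early_shutoff", 3, 1.0, hours))
            else:
                amp = 2.0 + 0.2 * i
                erna_rows.append(template_rpkm("early", amp, 0.1, hours))
                gene_rows.append(template_rpkm("early", amp, 1.0, hours))
        pairs = [EPPair(e, g, 0) for e, g in zip(ids_e, ids_g)]
        out = concordance_classes(pairs, pd.DataFrame(erna_rows, index=ids_e),
                                  pd.DataFrame(gene_rows, index=ids_g))
        by = {p.enhancer: p.concordance for p in out}
        assert all(by[f"e{i}"] == "discordant" for i in range(3))
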