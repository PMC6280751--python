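import numpy as np
import pytest

from ernadyn.expression import TimeGrid
from ernadyn.simulate import SimConfig, simulate_genome, simulate_timecourse


@pytest.fixture(scope="session")
def timegrid():
    return TimeGrid()


@pytest.fixture(scope="session")
def small_config():
    """A tiny genome that still exercises every locus class."""
    return SimConfig(
        seed=11, n_chrom=1, chrom_length=3_000_000, n_genes=12, n_enhancers=40
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    genes, enhancers, seqs, truth = simulate_genome(small_config)
    return genes, enhancers, seqs, truth


@pytest.fixture(scope="session")
def study_scale_run():
    """One simulation at the default study scale (2 x 10 Mb, 100 genes,
    300 enhancers, NB dispersion 0.1), shared across tests."""
    cfg = SimConfig(seed=1)
    genes, enhancers, seqs, truth = simulate_genome(cfg)
    gene_em, enh_em, _ = simulate_timecourse(truth, cfg)
    return cfg, genes, enhancers, seqs, truth, gene_em, enh_em


def brute_force_intergenic(transcripts, genes, d5=1000, d3=10_000):
    """Independent all-pairs oracle for the intergenic filter."""
    kept = []
    for t in transcripts:
        ok = True
        for g in genes:
            if g.chrom != t.chrom:
                continue
            if t.start < g.interval.end and g.interval.start < t.end:
                ok = False
                break

            def pdist(pos):
                if pos < t.start:
                    return t.start - pos
                if pos >= t.end:
                    return pos - (t.end - 1)
                return 0

            if pdist(g.tss) <= d5 or pdist(g.tts) <= d3:
                ok = False
                break
        if ok:
            kept.append(t)
    return kept
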