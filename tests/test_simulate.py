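from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ernadyn.annotation import classify_intergenic, filter_by_marks
from ernadyn.expression import rpkm
from ernadyn.inducibility import amplitude_index
from ernadyn.simulate import (ConfigError, SimConfig, TEMPLATES, simulate_3c,
                              simulate_genome, simulate_kd, simulate_marks,
                              simulate_timecourse, template_rpkm)


class TestSimConfig:
    def test_fraction_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(class_fractions={"flat": 0.5, "early": 0.5, "late": 0.5,
                                       "repressed": 0.5})
        with pytest.raises(ConfigError):
            SimConfig(class_fractions={"flat": 1.0})

    def test_planted_ai_must_exceed_one(self):
        with pytest.raises(ConfigError):
            SimConfig(planted_ai=0.5)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ConfigError):
            simulate_genome(SimConfig(n_chrom=1, chrom_length=500_000,
                                      n_genes=50, n_enhancers=200))


class TestSimulateGenome:
    def test_seeded_determinism(self, small_config):
        g1, e1, s1, t1 = simulate_genome(small_config)
        g2, e2, s2, t2 = simulate_genome(small_config)
        assert g1 == g2 and e1 == e2 and s1 == s2
        pd.testing.assert_frame_equal(t1.loci, t2.loci)
        pd.testing.assert_frame_equal(t1.pairs, t2.pairs)

    def test_no_enhancers_means_no_pairs(self):
        cfg = SimConfig(seed=5, n_chrom=1, chrom_length=2_000_000,
                        n_genes=10, n_enhancers=0)
        genes, enh, seqs, truth = simulate_genome(cfg)
        assert enh == [] and len(truth.pairs) == 0

    def test_all_enhancers_pass_intergenic_filter(self, small_truth):
        genes, enhancers, seqs, truth = small_truth
        kept = classify_intergenic(enhancers, genes)
        assert len(kept) == len(enhancers)

    def test_pairs_within_window_and_unique_designation(self, small_truth):
        genes, enhancers, seqs, truth = small_truth
        assert (truth.pairs.distance <= 200_000).all()
        assert truth.pairs.enhancer.is_unique
        induced = truth.inducible_ids("enhancer")
        assert set(truth.pairs.enhancer) == induced

    def test_motif_sites_near_induced_tss(self, small_truth):
        genes, enhancers, seqs, truth = small_truth
        pwm_len = len(truth.config.motif_pwm)
        assert set(truth.motif_sites.locus) == truth.inducible_ids("enhancer")
        assert (truth.motif_sites.offset.abs() <= 100).all()
        consensus = truth.config.motif_pwm.consensus
        enh_rows = {r.id: r for r in truth.enhancers.itertuples()}
        for r in truth.motif_sites.itertuples():
            chrom = enh_rows[r.locus].chrom
            assert seqs[chrom][r.position : r.position + pwm_len] == consensus


class TestSimulateTimecourse:
    def test_noiseless_flat_is_constant_with_zero_ai(self, timegrid):
        rp = template_rpkm("flat", 3.0, 2.0, timegrid.hours)
        assert np.allclose(rp, 2.0)
        assert amplitude_index(rp, timegrid) == pytest.approx(0.0)

    def test_noiseless_early_attains_planted_ai(self, timegrid):
        rp = template_rpkm("early", 3.0, 0.1, timegrid.hours)
        assert amplitude_index(rp, timegrid, pseudocount=0.5) == pytest.approx(3.0)

    def test_noiseless_counts_recover_rpkm(self, small_config, small_truth):
        genes, enhancers, seqs, truth = small_truth
        cfg0 = replace(small_config, noise_dispersion=0.0)
        gene_em, enh_em, _ = simulate_timecourse(truth, cfg0)
        gr = rpkm(gene_em)
        for r in truth.genes.itertuples():
            expect = template_rpkm(r.shape, cfg0.planted_ai, r.baseline,
                                   cfg0.timegrid.hours)
            assert np.allclose(gr.values.loc[r.id], expect, atol=1e-9)

    def test_replicate_mean_recovers_template(self):
        """Monte-Carlo oracle: the NB mean matches the template trajectory."""
        cfg = SimConfig(seed=0, n_chrom=1, chrom_length=1_500_000, n_genes=5,
                        n_enhancers=10, noise_dispersion=0.1)
        genes, enh, seqs, truth = simulate_genome(cfg)
        hours = np.asarray(cfg.timegrid.hours)
        sums = None
        n_rep = 200
        for i in range(n_rep):
            cfg_i = replace(cfg, seed=1000 + i)
            ge, ee, _ = simulate_timecourse(truth, cfg_i)
            vals = ee.values.values
            sums = vals if sums is None else sums + vals
        mean = sums / n_rep
        lengths = (truth.enhancers.end - truth.enhancers.start).values
        for i, r in enumerate(truth.enhancers.itertuples()):
            mu = (template_rpkm(r.shape, cfg.planted_ai, r.baseline, hours)
                  * lengths[i] * cfg.library_size / 1e9)
            se = np.sqrt((mu + 0.1 * mu ** 2) / n_rep)
            assert np.all(np.abs(mean[i] - mu) <= 3 * se + 1e-9)

    def test_coverage_tracks_sum_to_counts(self, small_config, small_truth):
        from ernadyn.intervals import interval_counts

        genes, enhancers, seqs, truth = small_truth
        cfg0 = replace(small_config, noise_dispersion=0.0)
        gene_em, enh_em, tracks = simulate_timecourse(truth, cfg0,
                                                      emit_coverage=True)
        t0 = tracks[0]
        got = interval_counts(t0, enhancers, stranded=False)
        assert np.allclose(got, enh_em.values.iloc[:, 0].values, rtol=1e-5)


class TestSimulateMarks:
    def test_every_enhancer_covered(self, small_truth):
        genes, enhancers, seqs, truth = small_truth
        peaks = simulate_marks(truth, n_decoys=10)
        marked, unmarked = filter_by_marks(enhancers, [peaks])
        assert len(unmarked) == 0

    def test_decoys_only_retain_nothing(self, small_truth):
        genes, enhancers, seqs, truth = small_truth
        peaks = simulate_marks(truth, n_decoys=10)
        decoys = [p for p in peaks if p.id.startswith("decoy")]
        marked, unmarked = filter_by_marks(enhancers, [decoys])
        assert len(marked) == 0


class TestSimulate3c:
    def test_noiseless_construction_gives_planted_amplitude(self):
        from ernadyn.chromatin import frequency_trajectory

        ct, truth = simulate_3c(None, n_induced=2, n_control=0, amplitude=4.0,
                                ct_noise=0.0, seed=0)
        f = frequency_trajectory(ct, "induced_00")
        assert f[12.0] / f[0.0] == pytest.approx(4.0, rel=1e-3)

    def test_induced_folds_exceed_control(self):
        from ernadyn.chromatin import frequency_trajectory, interaction_fold_change

        ct, truth = simulate_3c(None, amplitude=4.0, seed=1)
        ind, ctl = [], []
        for r in truth.itertuples():
            lfc = interaction_fold_change(frequency_trajectory(ct, r.pair_id))
            (ind if r.group == "induced" else ctl).append(lfc)
        assert np.median(ind) > np.median(ctl)


class TestSimulateKd:
    def test_planted_rules_respected(self, small_truth):
        genes, enhancers, seqs, truth = small_truth
        kd, kd_truth = simulate_kd(truth, efficacy=0.4, n_inducible=5)
        merged = kd.merge(kd_truth, on="sirna_id")
        eff = merged[merged.planted_effect == "repressed"]
        assert (eff.efold < 0.7).all() and (eff.mfold < 1).all()
        ineff = merged[merged.planted_effect == "ineffective"]
        assert (ineff.efold >= 0.75).all()
        act = merged[merged.planted_effect == "activated"]
        assert (act.mfold > 1).all()


class TestTemplates:
    def test_all_templates_defined_on_full_course(self, timegrid):
        for name, (kt, kv) in TEMPLATES.items():
            assert kt[0] == 0.0 and kt[-1] == 72.0
            assert len(kt) == len(kv)

    def test_late_class_clears_ai_gate(self, timegrid):
        rp = template_rpkm("late", 3.0, 0.1, timegrid.hours)
        ai = amplitude_index(rp, timegrid, pseudocount=0.5)
        assert 1.5 < ai < 3.0
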