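# ernadyn

Time-resolved discovery of virus-inducible enhancer RNAs (eRNAs) and their
target genes from nascent-transcription time courses.

Active enhancers transcribe short-lived noncoding RNAs. When a cell mounts
an antiviral response, a subset of enhancers is induced together with the
genes they regulate, and this co-inducibility is a strong signal for linking
an enhancer to its functional target — steady-state correlation alone is
not. `ernadyn` implements that analysis as a reusable pipeline for
strand-specific nascent-transcription (GRO-seq-style) time courses:

1. **eRNA annotation** — intergenic transcripts (>1 kb from every gene
   5′ end, >10 kb from every 3′ end, no gene-body overlap) that overlap
   H3K4me1/H3K27ac enhancer-mark peaks.
2. **Inducibility scoring** — per locus, with expression e(t) in RPKM:
   - amplitude index `AI = log2[ max_{t≤24h} (e(t)+ε)/(e(0)+ε) ]`
   - continuity index `CI = corr([e(t1)…e(t_{n−1})], [e(t2)…e(t_n)])`
     (lag-1 autocorrelation, a noise filter)

   A locus is inducible when `AI > 1` and `CI > 0.2`. Responsive profiles
   are grouped into inducible-early / inducible-late / repressed classes by
   PAM (k-medoids) clustering.
3. **EP pairing** — each inducible enhancer is assigned its nearest
   inducible gene TSS within 200 kb; pairs are ranked by the Spearman
   correlation of their eRNA/mRNA trajectories, the top 30% called
   concordant and the bottom 30% discordant (persistent eRNA after target
   shutdown).
4. **Motif enrichment** — PWM scanning of ±500 bp around eRNA TSSs;
   sites-per-base-per-peak (SBP) profiles with absolute (max) and relative
   (center ±100 bp over flanks) enrichment, plus TF half-induction times.
5. **Synteny** — cross-species co-localization (same chromosome, <500 kb)
   of EP pairs against a background of random promoter–intergenic pairs
   drawn to match the EP distance distribution.
6. **3C / knockdown** — qPCR interaction frequencies
   `2^(ΔCt_sample − ΔCt_control)`, 12 h vs 0 h interaction fold changes with
   a two-sample KS comparison of induced vs control pairs, and siRNA
   knockdown classification (effective when eRNA fold < 0.7).

A first-class synthetic-data generator plants ground truth for every stage
(locus classes, EP pairs, concordance tiers, motif sites, synteny breaks,
transient 12-h 3C peaks), so the full pipeline is testable end to end
without any downloads.

## Worked example

```python
from ernadyn.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(run_dir="run1", seed=1)
summary = run_pipeline(cfg)
print(summary.to_string(index=False))
```

which prints (abridged):

```
                      metric      value
frac_enhancers_undetected_0h       0.53
            mean_erna_length    1579.01
                n_concordant         36
                n_discordant         36
                  n_ep_pairs        122
       n_inducible_enhancers        122
           n_inducible_genes         65
                n_intergenic        300
                     ks_p_3c        0.0
                sbp_relative  69.367448
  synteny_bg_rate_same_chrom   0.663795
     synteny_rate_same_chrom   0.815631
```

Reading: of 300 simulated intergenic transcripts, all carry enhancer marks;
53% are undetectable before induction; 122 enhancers pass the AI/CI gate and
each is paired to an inducible gene within 200 kb (122 EP pairs, of which 36
concordant and 36 discordant by Spearman rank). The planted interferon-like
motif is ~69× denser at eRNA TSS centers than in the flanks, EP pairs stay
on the same chromosome across species ~15 percentage points more often than
the distance-matched background, and induced 3C interaction fold changes
(12 h vs 0 h) separate from controls at a vanishing KS p-value.

The same stages are available as a CLI:

```sh
ernadyn run-all --run-dir run1 --seed 1
ernadyn simulate --run-dir run2 --config my.yaml
```

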