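# Methods

## Scope and model

`ernadyn` analyses a dense time course of strand-specific nascent
transcription (0, 0.5, 1, 2, 4, 6, 12, 18, 24, 48, 72 h post-stimulus; the
0 h sample is the untreated control) to find stimulus-inducible enhancer
RNAs and link them to target genes. The package consumes transcript
intervals (BED), gene models (GTF), enhancer-mark peaks (BED), count or
coverage matrices (TSV/bedGraph), genome FASTA plus plain-text PWMs,
ortholog interval maps (TSV) and qPCR tables (TSV). De novo transcript
calling, read alignment, peak calling and differential-expression testing
are out of scope: transcripts, peaks and counts are inputs (only a trivial
coverage-threshold caller exists, for synthetic coverage).

All coordinates are 0-based half-open internally (GTF is shifted on read).
Enhancer–promoter distance is the unsigned gap from the enhancer interval
to the gene's TSS base (0 if the TSS lies inside the enhancer); the 5′/3′
exclusion distances of the intergenic filter are measured from transcript
interval edges to each gene's strand-aware end coordinates, the stricter of
the plausible readings.

## Inducibility indices

With e(t) the RPKM of a locus (RPKM = count·10⁹ / (length·library size)):

- `AI = log2[ max_{t≤24h} (e(t)+ε)/(e(0)+ε) ]`. The 24 h sample is included
  (the 4–24 h interval behaves as one response stage). The pseudocount ε
  (default 0.5 RPKM) is unavoidable because a majority of eRNAs are silent
  at baseline; it is configurable and echoed into all output headers.
- `CI` is the lag-1 Pearson autocorrelation of the series. Pearson is used
  (the index is affine-invariant, so raw vs log input matters only through
  noise shape, and raw RPKM is used). A zero-variance lagged vector gives
  CI = 0 by definition, which fails the CI filter — consistent with CI's
  purpose of rejecting non-signals.
- Inducible ⇔ AI > 1 and CI > 0.2, strict inequalities.

Responsive loci (CI above threshold and max |log2 fold change| > 1) are
clustered on their log-fold-change profiles by PAM (k-medoids, k = 3) under
Euclidean distance: deterministic greedy BUILD, then steepest-descent SWAP
with a stable scan order; optional seeded random restarts guard against
local optima on small inputs. Cluster names come from the medoid shape:
dominant negative excursion → repressed; otherwise peak ≤ 24 h → early,
else late.

## Pairing and concordance

Each inducible enhancer is assigned the nearest inducible gene TSS within
200 kb (enhancer-anchored; a gene may serve several enhancers; equal
distances break to the lexicographically smallest gene id; noncoding
biotypes are excluded when annotated). Pairs are ranked by the Spearman
correlation (average ranks on ties) of eRNA vs mRNA trajectories; the top
floor(0.3·n) are concordant and the bottom floor(0.3·n) discordant — the
floor rule is stated explicitly because only percentages are conventional.
Constant series have undefined correlation and are labelled intermediate
outside the ranking. Distance enrichment curves count genes per 100-kb bin
of distance to the nearest inducible enhancer, max-normalised separately
for inducible and all genes.

## Motif enrichment

PWMs are pseudocounted (0.8, split by background base frequencies) and
scanned as log2-odds on both strands of ±500 bp windows anchored at eRNA
TSSs. The default hit threshold is the score whose tail probability under
the background is ≈1e-4, computed by exact convolution of the per-position
score distribution on a 0.01-bit grid (deterministic, no sampling). SBP
(sites per base per peak) is the per-offset expected site density per
anchor; by default a hit contributes at every base it covers (a per-base
density), with a start-only switch. Absolute enrichment is the profile
maximum; relative enrichment is mean SBP in the ±100 bp center over the
±100–500 bp flanks (infinite when all density is central; undefined with no
hits). TF timing uses the first time point reaching half of maximal
induction; a never-induced series maps to the last time point.

## Synteny

A pair is conserved in a species when both anchors (enhancer TSS ±500 bp,
promoter TSS ±1 kb — short anchors lift over more stably than whole loci)
map and land on the same target chromosome, optionally within 500 kb. The
background draws random promoter/intergenic pairs following the empirical
EP distance distribution: a distance is drawn with replacement, a promoter
at random, and an intergenic tile within ±10% of that distance (the
tolerance widens stepwise with a warning when a stratum is empty; the
matcher retries promoters before widening). A two-sample KS self-check
(α = 0.05) verifies the achieved distances match the target distribution.
Rates are reported per species; the cross-species mean difference is
labelled an aggregate.

## 3C and knockdown

Interaction frequency is `2^(ΔCt_sample − ΔCt_control)` against the
BAC-library control, exactly as the assay convention states. Note the sign
runs opposite to standard qPCR algebra (a larger Ct means less product);
the formula is implemented verbatim with a `negate_exponent` switch for the
standard `2^−ΔΔCt` form, and users supply ΔCt on the stated convention.
Replicate frequencies combine by geometric mean (equivalently, mean ΔCt
difference before exponentiation). Interaction fold change is log2 of the
12 h/0 h frequency ratio. Group comparison uses the two-sample KS test,
exact when n_a·n_b ≤ 100 and asymptotic otherwise. Knockdowns with eRNA
fold ≥ 0.7 are excluded as ineffective; effective records aggregate per EP
pair by the lowest eRNA fold and classify the target by mRNA fold (<1
repressed, >1 activated, with a configurable dead zone). Combinatorial
knockdowns are analysed by the same contract with multi-siRNA condition
ids.

## Synthetic data

The generator is the package's study-condition definition, not a test
fixture. Defaults: 2 chromosomes × 10 Mb, 100 genes, 300 enhancers; class
fractions flat 0.40 / early 0.25 / late 0.15 / repressed 0.20; planted
amplitude 3 (log2); library size 2×10⁷; negative-binomial dispersion 0.1
(nascent-transcription counts are overdispersed; counts are gamma-Poisson
with variance μ + 0.1μ², and dispersion 0 returns exact means for
noiseless oracles).

Loci are laid out in cassettes: each inducible gene carries 1–3 upstream
enhancers at 6–100 kb from its TSS, with inter-unit gaps (120 kb after
cassettes, 15 kb after lone loci) chosen so that, by construction, every
enhancer passes the intergenic filter and every induced enhancer's nearest
inducible gene is its designated partner. Discordant pairs occupy
singleton cassettes because their gene must shut off while the eRNA
persists. Trajectories are piecewise-linear log2-fold-change templates:
early peaks at 12 h and returns; late starts after 6 h, reaches 2/3 of its
amplitude by 24 h (so late loci still clear the AI gate) and peaks at
48 h; repressed falls to −amplitude; the persistent/shutoff/shifted
variants realise discordant and intermediate pair tiers with exact
floor-rule counts so that noiseless runs recover concordance labels
exactly. Enhancer transcription is bidirectional (independent noise per
strand). Baselines make roughly half of eRNAs undetectable at 0 h.

Marks cover every true enhancer (±200 bp) plus decoys clear of all loci.
Ortholog maps mirror source chromosomes, relocating 10% of EP-pair anchors
and 25% of background anchors (and leaving 5% unmapped); intergenic tiles
are mapped too so distance-matched background pairs are scorable. 3C
tables encode tent-shaped frequency trajectories peaking at 12 h
(amplitude ~3–6×, Ct noise 0.25 cycles, triplicate) against flat but
variable controls; knockdown tables give inducible pairs an effective
siRNA (eFold ≈ 0.4, repressed target) plus an ineffective one, and split
control pairs between unchanged, repressed and activated targets.

What the generator does not emulate: read-level sampling and mapping
artefacts, fragmented or merged transcript calls, chromatin-state
heterogeneity, genome-wide distance structure of real gene deserts, and
correlated noise across time points. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
performance on real sequencing data.

## Numerical choices and limitations

- PCA centers loci (features), uses a full SVD and fixes each component's
  sign so the largest-magnitude loading is positive.
- PAM restarts are off by default in the pipeline (BUILD+SWAP is already
  deterministic); tests use 10 restarts when comparing with exhaustive
  enumeration.
- The background KS self-check uses midpoint-to-midpoint distances.
- Problem sizes: the test suite and the acceptance script run the default
  study scale (300 enhancers / 100 genes / 11 time points) once, 20 small
  genomes for motif discrimination, 100 seeded background-matching runs
  (n = 1000–2000 pairs), and 50 seeded 3C cohorts of 18 + 18 pairs.
- The strict floor-rule concordance boundaries mean ties in Spearman rank
  at a boundary resolve by enhancer id; real data rarely ties, synthetic
  data is constructed not to straddle boundaries.
- One printed-convention ambiguity is preserved deliberately: the 3C
  exponent sign (see above).
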