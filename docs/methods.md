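# Methods

This note records the statistical models, parameter defaults, numerical
choices and known limitations of meripkit. It documents what the code
computes; every number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Coordinate conventions

All internal coordinates are 0-based half-open. GTF is read as 1-based
closed and converted on input; BED and bedGraph are written 0-based
half-open. Exons of a transcript model are stored in transcript
orientation (5′→3′ of the mRNA). When a gene has several isoforms the
longest is analyzed; ties break on the lexicographically smallest
transcript id so results are order-independent. Non-coding transcripts are
scanned for peaks but skipped (with a warning) by the metagene and
segment profiles, whose coordinate system requires a 5′UTR/CDS/3′UTR
architecture; transcripts with an empty segment are skipped for the same
reason.

## Peak calling

Windows of W = 100 nt advance in s = 10 nt steps from position 0 while
`start + W ≤ length`; a transcript shorter than W contributes one
whole-transcript window. Note that when `length − W` is not a multiple of
s the final `< s` bases are not covered — a direct consequence of the
start rule.

The exclusion rule computes, per transcript, thresholds `f·max(IP)` and
`f·max(input)` (f = 1/20, replicates summed within assay) and drops a
window only when it is strictly below threshold in *both* assays; a
window exactly at a threshold is retained, and an `either` mode is
available as a configuration switch. Transcripts whose counts are all
zero lose all windows with a warning.

The window test is the one-sided Fisher exact test of the window's pooled
IP count against the pooled input count given the library totals,
computed as the upper hypergeometric tail (vectorized); the unit tests
verify exact agreement with `scipy.stats.fisher_exact` and with an
integer brute-force enumeration over all 2×2 tables with margins ≤ 50.
Library totals are the column sums of the full (unfiltered) window table;
because windows overlap, these totals over-count physical reads by a
constant factor ≈ W/s, which cancels in the enrichment ratio and acts as
a uniform scale on the test margins. The 0.5 pseudocount appears only in
the reported log2 enrichment, never inside the exact test. BH correction
runs across all tested windows of the run; significant (q ≤ 0.05)
overlapping or bookended windows merge into peaks. Peak p and q are the
minima over merged windows; the summit is the midpoint of the minimum-p
window (first on ties); the identities of the merged windows are kept
(`member_starts`) because downstream differential analysis sums exactly
those windows.

## Differential methylation

Per peak, member-window counts are summed per genotype (replicates
pooled) and tested with the two-sided Fisher exact test on
`[[IP_alt, input_alt], [IP_ref, input_ref]]`, BH-corrected across peaks.
The effect estimate is the log2 ratio of depth-normalized IP/input odds
with a 0.5 pseudocount, positive when methylation is higher in the
alternative (knockout) genotype; swapping the genotype labels negates it
exactly.

Depths are estimated from the background — the column sums over windows
outside every peak — rather than from raw library totals. With raw
totals, true differential signal inflates the IP total of the genotype
that carries it and deflates the estimated effect (a composition bias of
about −0.04 log2 units under the default simulation conditions, analogous
to the composition effects handled by background normalization in
differential ChIP-seq analysis). With background depths and member-window
counting, a planted 2× knockout effect is recovered with mean log2 ratio
1.00 (Monte-Carlo over 200 studies; see the acceptance suite).

## Methylation landscape

The metagene profile maps each peak summit to the segment-normalized
coordinate (position within segment ÷ segment length, offset by 0, 1 or 2
for 5′UTR, CDS, 3′UTR) and histograms it in 33 bins per segment (99
total); densities are normalized so the profile integrates to exactly 1.
The summit, not the peak footprint, is the default unit to avoid
double-counting wide peaks; a footprint mode distributes one unit of mass
uniformly over the covered bases. The segment distribution is the
summit-count fraction per segment and is exactly consistent with the
metagene mass per segment.

The motif test counts summit ± 50 nt windows containing at least one
DRACH match and compares the rate with ≥ 10,000 width-matched windows
drawn uniformly (seeded) over all eligible start positions of the same
transcriptome, via a one-sided exact binomial test. This is a calibrated
occurrence test, not motif discovery: DRACH is degenerate enough that
random coding-scale sequence hits it in ~80–85% of 101-nt windows, so
discrimination comes from the gap to 100%, and p-values are conservative
at small peak counts. De novo motif discovery and position-weight-matrix
learning are out of scope.

## RNA decay and qPCR

A decay series is normalized per replicate to the reference species and
then to t = 0, so the residual fraction at t = 0 is 1 by construction.
The fit is ordinary least squares of ln(fraction) on time with a free
intercept — the intercept absorbs multiplicative noise in the t = 0
measurement instead of forcing it into the slope — with replicates pooled
into one regression by default (per-replicate fits by flag). k = −slope;
t½ = ln2/k; a non-decaying series (slope ≥ 0) is reported with k ≤ 0 and
infinite half-life rather than raising. On noise-free exponentials the
fit is exact to machine precision. Genotype comparison runs a two-tailed
Welch t test per post-zero timepoint and bootstraps the half-life
difference by resampling replicate series within genotype (2000 resamples
by default, seeded, percentile 95% CI); negative differences mean
destabilization in the knockout.

ΔΔCt relative expression is `2^−((Ct_t − Ct_r)_sample − (Ct_t −
Ct_r)_calibrator)`; the table-level analysis uses the reference-group
mean ΔCt as calibrator and a Welch t test on per-sample ΔCt values.

## Expression

TPM divides counts by kilobase gene length and rescales each sample to
10⁶. Size factors follow the median-of-ratios scheme over genes detected
in every sample. The differential test is a per-gene two-sided Welch t
test on `log2(count/size_factor + 0.5)` with BH correction. This is a
deliberately transparent stand-in, not a negative-binomial GLM: it has no
dispersion shrinkage and less power at low replication, and its claims
are calibrated only against its own simulations (null type-I error 0.03–
0.05 at α = 0.05 with 3 replicates per condition), never against external
tool output. DEG classes apply the literal thresholds — raw p ≤ 0.05 and
log2 fold-change ≥ 1 or ≤ −1, boundaries inclusive — with a q-value mode
available by flag; the contrast direction defaults to the condition of
the first sample column as reference. Gene-set enrichment is the
one-sided hypergeometric tail per set, BH-corrected across sets.

## Synthetic data generator

All generators are pure functions of a `SimConfig` whose seed is
mandatory; each stage draws from an independent substream so any table
can be regenerated alone. Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_targets | 50 / 5 | genes; knockout-responsive targets |
| utr5/cds/utr3 ranges | 100–300 / 300–1200 / 200–800 nt | uniform segment lengths (CDS codon-rounded) |
| n_sites_per_gene | 1 | planted DRACH-centered sites |
| frac_stop_proximal | 0.8 | sites drawn near the stop codon (±20% of CDS/3′UTR length), the canonical m⁶A topology |
| site_enrichment | 4 | IP mean multiplier at site windows |
| ko_effect | 2 | extra IP multiplier at target sites in the knockout |
| window_depth | 30 | mean input reads per 100-nt window |
| expr_log_sd | 0.5 | lognormal spread of per-gene expression weights |
| nb_dispersion | 0.005 | residual per-window NB dispersion |
| merip_replicates | 2 | IP+input replicates per genotype |
| decay timepoints | 0, 3, 6, 9 h | actinomycin-D chase |
| decay_noise_cv / ref cv | 0.10 / 0.02 | lognormal CV of target / reference |
| halflife WT / KO | 4 / 2 h | target transcript half-lives |
| qpcr fold / sd / n | 4 / 0.1 / 5 | planted qPCR effect |
| expr genes / reps / DE | 2000 / 3 / 5% at |log2FC| = 2 | expression matrix |

Counts are negative binomial (variance m + φm²; Poisson at φ = 0).
Between-gene biological variability is carried by the lognormal
expression weights; the per-window residual dispersion is kept near
Poisson (φ = 0.005, a variance-to-mean ratio of ~1.15 at the default
depth), the regime in which exact conditional tests on pooled counts are
properly calibrated: under these conditions null simulations call peaks
on < 1% of transcripts and the planted-site false-discovery proportion
stays below the nominal q. This is the decomposition the pipeline's own
FDR guarantees presume, and it is also the generator's main
idealization: real MeRIP replicates show stronger extra-Poisson
variation between biological replicates, under which any pooled-count
exact test becomes anticonservative (already at φ = 0.02 null
simulations call spurious peaks on ~19% of transcripts, and at φ = 0.1
the realized peak-level FDP reaches ≈ 0.5 at nominal q = 0.05).
Passing recovery tests therefore demonstrate correctness of
the procedure under its sampling model, not robustness to biological
overdispersion — replicate-aware GLM testing is an explicit non-goal.

Other simplifications: methylation is planted as a window-level
enrichment multiplier, not read-level fragment placement; windows are
counted independently, so adjacent windows do not share reads as they
would after fragmentation; the knockout acts only through IP enrichment
at target sites; decay noise is lognormal and i.i.d. across timepoints.

The decay design was chosen so the chase spans at least two half-lives of
the slowest (4 h) transcript — timepoints 0/3/6/9 h — and the reference
species carries a much smaller CV (0.02) than the targets, reflecting the
abundance and stability of rRNA references; under a 0–6 h design, the
slow transcript's slope is too poorly determined for reliable 10%-level
recovery at CV 0.1.

## Problem sizes

Monte-Carlo experiments in the test suite use 200 repeated studies for
peak/differential/half-life recovery and 10⁴ null genes for test
calibration; `scripts/acceptance.py` uses 50 studies for the
peak/differential experiment and 200 for decay. These sizes give
Monte-Carlo standard errors well below the tolerances being checked.

## Known limitations

* Exact proportion tests on pooled counts are anticonservative under
  strong biological overdispersion (see above).
* The 1/20 exclusion rule and all thresholds operate on replicate-summed
  counts; per-replicate concordance is not modelled.
* Half-life fitting is log-linear least squares; it is optimal for
  single-exponential decay with multiplicative noise but has no concept
  of plateaus or biphasic decay.
* The DEG thresholds use the raw p-value, which controls no multiplicity;
  this mirrors the stated classification criteria rather than best
  practice, and a q-value mode is provided.
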