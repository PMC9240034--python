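# meripkit

Desk-scale analysis of N6-methyladenosine (m⁶A) epitranscriptomics
experiments of the kind used to dissect RNA-demethylase (e.g. ALKBH5)
knockout phenotypes: MeRIP-seq peak calling, methylation landscape
profiling, genotype differential methylation, actinomycin-D RNA decay
analysis, ΔΔCt quantification, and TPM/DEG expression analysis — together
with a synthetic-data generator that plants methylation sites, stability
effects and expression changes so that every stage can be verified against
known ground truth.

The package is aimed at method developers and analysts who want a small,
fully tested, plain-text-formats implementation of this analysis stack:
counts in, peaks/fits/tables out, no alignment step (the pipeline starts
from window-level read counts).

## Methods at a glance

**Peak calling.** The longest isoform of each gene is scanned with a
100-nt sliding window advanced in 10-nt steps. Windows whose
replicate-summed read count falls below 1/20 of the transcript's top
window *in both* the IP and the input library are excluded. Each remaining
window is tested for IP-over-input enrichment with a one-sided Fisher
exact test on the 2×2 table

```
[[ ip_count,     ip_total − ip_count    ],
 [ input_count,  input_total − input_count ]]
```

equivalently the upper hypergeometric tail; Benjamini–Hochberg correction
runs across all tested windows and overlapping or bookended significant
windows (q ≤ 0.05) merge into peaks whose summit is the midpoint of the
minimum-p window.

**Landscape.** Peak summits are mapped onto the segment-normalized
transcript coordinate (5′UTR → [0,1), CDS → [1,2), 3′UTR → [2,3]) to form
a unit-area metagene density, and onto the three-segment distribution.
DRACH ([AGT][AG]AC[ACT]) occurrence in summit ± 50 nt windows is compared
with width-matched windows sampled from the same transcriptome (exact
binomial test).

**Differential methylation.** Per peak, IP/input counts of the merged
member windows are summed per genotype and tested with a two-sided Fisher
exact test on `[[IP_KO, input_KO], [IP_WT, input_WT]]`; the effect size is
the log2 ratio of depth-normalized IP/input odds (0.5 pseudocount),
positive when methylation is higher in the knockout. Depths are estimated
from non-peak background windows to keep the signal out of its own
normalization.

**RNA decay.** Abundances are normalized to a stable reference species
(18S rRNA stand-in) and to the t = 0 h point; ln(residual fraction) is
regressed on time (free intercept, replicates pooled), giving decay rate
k, half-life t½ = ln2 / k, and a genotype half-life difference with a
bootstrap CI plus per-timepoint Welch t tests.

**qPCR.** Relative expression follows 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_calibrator.

**Expression.** TPM (`count/(length/1000)`, columns scaled to 10⁶),
median-of-ratios size factors, a deliberately simple stand-in
differential test (per-gene Welch t on log2 normalized counts + BH — *not*
a negative-binomial GLM), literal DEG thresholds (p ≤ 0.05 and
|log2 fold-change| ≥ 1), and hypergeometric gene-set enrichment.

## Worked example

Simulate a 50-gene study (5 knockout-responsive target genes, one planted
DRACH site per gene, 4× IP enrichment, 2× knockout effect, ~30 reads per
window) and run every stage:

```sh
meripkit all --out-dir demo --seed 7
```

which logs

```
INFO meripkit: 50 peaks (7315 windows tested)
INFO meripkit: metagene mode at 1.89; DRACH rate 1.00 vs 0.83 expected
INFO meripkit: differential methylation for 50 peaks
INFO meripkit: ddCt folds for 50 genes
INFO meripkit: fits for 10 gene x genotype series
INFO meripkit: 46 up, 47 down of 2000 genes
```

Reading the outputs:

* `peaks/peaks.tsv` — 50 peaks for 50 planted sites; the metagene mode at
  normalized coordinate 1.89 (CDS end ≈ 2.0) and the segment split
  (CDS 0.60 / 3′UTR 0.38, `landscape/segments.tsv`) reproduce the
  stop-codon-proximal m⁶A topology.
* `landscape/motif.json` — all 50 summit windows contain a DRACH 5-mer
  against an expected background rate of 0.83 (binomial p ≈ 1e-4).
* `diffmeth.tsv` — target-site peaks show log2 ratios near 1 (the planted
  2× knockout effect); non-target peaks sit near 0.
* `decay/stability.tsv` — target half-lives fit at ≈ 4 h (WT) vs ≈ 2 h
  (KO); e.g. gene G0030: 4.03 h vs 2.02 h, difference −2.01 h with 95% CI
  (−2.27, −1.75), per-timepoint Welch p ≤ 3e-5.
* `qpcr_folds.tsv` — ΔΔCt fold changes per gene with Welch t p-values.
* `dge/de.tsv` — 46 up / 47 down of 2000 genes against 50 + 50 planted.

The library mirrors the CLI one-to-one, e.g.:

```python
import meripkit as mk

cfg = mk.SimConfig(seed=7)
tr = mk.simulate_transcriptome(cfg)
wt = mk.simulate_merip_counts(tr, cfg)
peaks = mk.call_peaks(wt, q_threshold=0.05)
profile = mk.metagene_profile(peaks, tr.models)
```

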