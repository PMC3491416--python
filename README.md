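# deltadnase

Quantitative analysis of chromatin-accessibility changes upon nuclear-receptor
activation, from per-base DNase I cleavage counts: DNase I hypersensitive
site (DHS) peak calling, differential DNase-seq signal (ΔDNase) detection over
adaptively tiled windows, permutation-based association of ΔDNase regions
with differentially expressed genes, first-order log-likelihood motif
scanning, and base-pair-resolution footprint clustering with a cross-run
stability statistic. A first-class synthetic-data module generates replicate
cut profiles, sequence, gene models and expression counts with the
statistical structure the analysis assumes, so every stage is testable
without any sequencing data.

Intended users: computational biologists analysing DNase-seq (or similar
cleavage-based accessibility) experiments with a two-condition design, and
methods developers who need a transparent, reproducible reimplementation of
this analysis chain.

## The statistics at the core

**Peaks.** Cut counts are smoothed with a Gaussian kernel (σ = 60 bp). The
positive signal values are fit to a gamma distribution by maximum
likelihood, and peaks are maximal runs of bases with signal above the
upper-tail quantile at *P* < 0.05.

**ΔDNase.** The union of both conditions' DHS peaks is tiled with 300-bp
windows (default stride 150 bp; regions shorter than 300 bp are expanded,
and when the default stride would discard ≥ 10% of a region's bases on an
edge, one extra window is added and the stride shrunk for exact coverage).
Windows with fewer than five total tags are dropped. Per-window replicate
counts are tested with a two-sided conditional negative-binomial exact
test — TMM (trimmed mean of M-values) effective library sizes, a common
dispersion φ estimated by conditional maximum likelihood, and the
conditional split *Z₁ | Z₁+Z₂* of group sums — thresholded at strict
(Benjamini–Hochberg FDR < 0.05) and loose (raw *p* < 0.05) levels, and
neighboring significant windows of the same direction are merged into
ΔDNase regions. Each union region also receives a normalized differential
tag score: counts per condition scaled by the mean over regions, induced
minus untreated.

**Association.** Forward: ΔDNase regions map to the nearest gene
(midpoint→TSS), and the overlap of those genes with the differentially
expressed (DE) set is compared against 100,000 random gene sets of the same
size. Reverse: the number of DE genes with a ΔDNase region within ±20 kb of
the merged gene span is compared against 1,000 random gene sets. Both
p-values carry the +1 permutation correction.

**Motif and footprints.** Sequences are scanned with
score = Σⱼ log P_pwm(bⱼ) − log P_bg(b₁…b_w) under a strand-symmetric
first-order (dinucleotide) background; matches below the 90th percentile of
all window scores are discarded, and the stronger strand wins when both
pass. Per-match 31-bp cut vectors (motif center ± 15 bp) are clustered with
k-means (k = 3, 100 runs, one seeded k-means++ initialization per run);
centers from every pair of runs are matched one-to-one by maximum Pearson
correlation, and the matched-correlation distribution measures cluster
reproducibility. Distributions from two conditions are compared with a
two-sided Mann–Whitney U test.

## Worked example

```bash
deltadnase run-all --seed 1 --outdir run1
```

simulates the packaged scenario — a 2-Mb genome with 500 DHS, 50 of them
planted with a 3-fold accessibility increase upon induction, 600 motif
instances carrying one of three footprint protection shapes (left
half-site, right half-site, full dimer site with an exposed 3-bp spacer),
and 200 genes of which 40 are 4-fold upregulated near planted increases —
then runs every stage. Key lines of the printed summary (seed 1):

```
"n_peaks_untreated": 492,     "n_peaks_induced": 460,
"n_strict_increase": 51,      "n_strict_decrease": 7,
"n_loose_increase": 67,       "n_loose_decrease": 38,
"n_de_up": 40,                "n_de_down": 7,
"association": { "forward_p_enrich": 1.0e-05, "reverse_p_enrich": 9.99e-04 },
"motif_site_recovery": 1.0,
"footprint": { "untreated": { "median_matched_correlation": 0.428 },
               "induced":   { "median_matched_correlation": 0.998 },
               "mannwhitney_p": 0.0, "higher_condition": "induced",
               "selected_k": 3 }
```

Reading this: peak calling recovers essentially all 500 simulated DHS in
both conditions; the differential stage finds the 50 planted increases
(51 strict increase regions) with a strong increase/decrease asymmetry;
all 40 upregulated genes are detected and are significantly associated
with ΔDNase increases in both test directions; every planted motif
instance is recovered by the scan; and footprint clustering is highly
reproducible only in the induced condition (median matched correlation
0.998 vs 0.428), with k = 3 recovering the three planted protection
shapes. Result tables (BED/TSV/JSON) are written to `run1/` and are
byte-identical across reruns with the same seed.

The same stages are available as library functions
(`deltadnase.peaks`, `.delta_dnase`, `.expression`, `.association`,
`.motif`, `.footprint`) and as individual subcommands
(`simulate`, `callpeaks`, `delta`, `express`, `associate`, `scan`,
`footprint`).

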