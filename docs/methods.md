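# Methods

This note documents the models, defaults and numerical choices behind
`deltadnase`, and what the synthetic data do and do not establish.

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention) throughout; 1-based
presentation would happen only at an output layer, and none currently does.
A "tag" or "cut" is the 5' base of a sequenced fragment and belongs to
exactly one bp, so a window's count is the sum of per-bp counts it covers;
overlapping windows may count the same cut more than once, which is why
library sizes are whole-profile totals rather than window column sums.
Strand `.` is treated as `+` wherever sequence orientation matters, since
DNase cleavage itself is unstranded.

## Signal and peak calling

The accessibility signal is a Gaussian kernel density of cut counts
evaluated at every bp (`scipy.ndimage.gaussian_filter1d`, truncation 6σ),
which conserves total cut mass away from chromosome edges. The default
bandwidth is σ = 60 bp — roughly one-tenth of a typical ~600-bp
hypersensitive feature — and is configurable.

Peaks are thresholded at the upper-tail quantile of a gamma distribution
fit by maximum likelihood (`scipy.stats.gamma.fit`, location fixed at 0) to
the positive signal values only; the zeros are structural (unsequenced
deserts), not part of the noise law. Runs of above-threshold bases closer
than `min_gap` = 50 bp merge into one peak, preventing a single
nucleosome-depleted region from fragmenting.

The gamma law is an approximation to the smoothed-count distribution that
becomes accurate as the expected kernel mass grows. Quantitatively, with
λ·σ ≳ 6 expected cuts per kernel width (e.g. pooled replicates at
0.1 cuts/bp with σ = 60), the realized exceedance of the fitted P < 0.05
threshold on homogeneous background is 0.04–0.05; at sparser coverage the
fitted tail is heavier than the true one and the threshold becomes
conservative (exceedance ~0.01–0.035), i.e. fewer false peaks, never more.
The calibration test therefore runs in the pooled-intensity regime, and
sparse-coverage behavior errs on the safe side.

## Window tiling

Union DHS regions are tiled with fixed-width windows (W = 300 bp).
Regions ≤ W are expanded to W, centered (placement is a package choice).
Longer regions are tiled from the region start at the default stride
(150 bp, i.e. 50% overlap — the stride is a package default, configurable,
not an inherited constant); all discarded bases then lie on the right
edge. If the uncovered bases on an edge reach 10% of the region length,
one extra window is added and the stride recomputed as (len − W)/n with
per-window offsets floored and the last window pinned to the region end,
which guarantees exact coverage. A brute-force restatement of this rule
cross-checks the implementation over random lengths in the tests.

## Differential testing

The two-group count test is a reimplementation of the classic exact
negative-binomial workflow:

* **Normalization.** Effective library sizes are raw totals times TMM
  factors (30% two-sided trim on M, 5% on A, inverse-asymptotic-variance
  weights, reference column chosen by the 75th count percentile, factors
  scaled to geometric mean 1). On a held fixture the factors, common
  dispersion and p-values agree with the Bioconductor reference
  implementation (log-p correlation > 0.99; dispersion within a few
  percent), which is kept as an independent cross-check in the test suite,
  never called by the package.
* **Dispersion.** A single common dispersion φ (variance μ + φμ²) is
  maximized by conditional likelihood on counts scaled to the
  geometric-mean effective library size and rounded; this shortcut to
  full quantile adjustment is accurate when effective sizes are within a
  few tens of percent of each other, as replicate designs are. Tagwise or
  trended dispersion is out of scope.
* **Exact test.** Conditional on a window's total z, the first group's sum
  follows P(Z₁ = x) ∝ NB(n₁μ, φ/n₁)(x) · NB(n₂μ, φ/n₂)(z − x); the
  two-sided p-value sums the probabilities of all outcomes no more likely
  than the observed one. φ → 0 reduces to the binomial split, which the
  tests verify in closed form. BH adjustment runs over all tested windows.

Two intrinsic limitations are documented rather than patched, with the
numbers reproduced by the test suite:

1. **Discreteness.** Exact-test p-values live on the conditional lattice;
   at ~20 counts/window with 3v3 replicates the largest pmf atom is ~0.04,
   so the p-value distribution under the null has KS distance ~0.06 from
   the continuous uniform (an atom at p = 1) no matter which two-sided
   convention is used. Type-I error at p < 0.05 is calibrated (0.042–0.044);
   super-uniformity F(t) ≤ t holds up to discreteness.
2. **Composition bias.** Percentile- or trimmed-mean-based normalization
   under-corrects a one-sided composition shift. In the packaged scenario
   ~6% of tested windows carry a genuine 3-fold increase, which leaves a
   ~2–3% downward bias on null windows and a handful of spurious strict
   decrease windows (2–11 across seeds, vs ~5 expected from the FDR). The
   Bioconductor reference produces the identical calls on the identical
   matrix, so this is a property of the method at this planted fraction,
   not of the implementation; at genome scale, where changed regions are
   ~1% of windows, the bias is negligible.

## Expression

Tags are assigned to genes when their 5' bp falls in an exon; a tag inside
several genes' exons counts for each (simplest defensible rule for
overlapping models). RPKM uses exonic length excluding the annotated 3'UTR
and excludes 3'UTR tags from its numerator; the DE test runs on plain
exonic counts. DE calling is literally the window-level exact test applied
to a gene-shaped count matrix — one code path, verified by a shared-path
test — with DE = BH FDR < 0.05 split by fold-change sign. With 20% of a
200-gene universe planted 4-fold up, the TMM composition effect described
above produces a few spurious down calls (~4% of null genes); real
transcriptomes with ≲2% DE do not show this.

## Association

Regions are annotated by midpoint with precedence promoter (2 kb upstream
of TSS) > first exon/intron > other intragenic > 3'-proximal (2 kb
downstream) > intergenic. Nearest genes are by |midpoint − TSS| with
lexicographic tie-break for determinism. Both permutation tests draw gene
sets uniformly without replacement and use p = (#{null ≥ obs} + 1)/(N + 1),
so p is never exactly 0 and is exactly hypergeometric in the forward case
(verified by χ² against the closed form on a small universe). The reverse
test's "surrounding 20 kb window" is the merged isoform span ± 20 kb.
One-sided enrichment and depletion p-values are both reported; no doubling
is applied. Calibration of the forward test is checked where the overlap
statistic has wide support (universe 2,000, |DE| = 500): with small
universes the overlap lattice is coarse and the +1-corrected p-values are
visibly super-uniform — a property of any tie-conservative permutation p,
not an error.

## Motif scanning

Window score = Σⱼ log P_pwm(bⱼ | column j) − [log π(b₁) +
Σ log T(bⱼ | bⱼ₋₁)] with a first-order background estimated from both
strands of the scanned sequence (dinucleotide pseudocount 1). The
symmetrized estimate makes P_bg(w) = P_bg(revcomp(w)) exactly, hence the
scan is strand-symmetric to machine precision. The percentile threshold
(default 90) is computed over all window scores of the scanned space —
mask-restricted when a mask is given — minus a 1e-9 tolerance so exact
ties with the threshold (e.g. the degenerate PWM-equals-background case,
where every window scores 0) are kept. Windows containing N are skipped.
Where both strands pass, the stronger is reported, `+` on ties; note that
for a palindromic dimer motif both strands score identically and the
reported strand is arbitrary. All overlapping above-threshold matches are
reported; deduplication (strongest match per locus) is a pipeline step so
the footprint stage sees one site per locus.

The relative enrichment score of a match set between region sets A and B is
(fraction of A with ≥ 1 match)/(fraction of B with ≥ 1 match). Because a
percentile threshold keeps the top decile of windows regardless of their
absolute quality, region-level contrasts are only informative with a
sparse match set; the pipeline uses matches scoring at least half the best
observed score for its host-vs-other DHS contrast.

## Footprint clustering and stability

Each deduplicated match contributes its per-bp cuts over motif
center ± 15 (31 columns), reversed for minus-strand sites so all rows read
in motif orientation; rows are clustered as raw counts (a row-normalize
option exists, off by default). Each of R runs (default 100) is one Lloyd
run from a seeded k-means++ initialization; per-run seeds derive from one
SeedSequence so results are reproducible. Plain random-row initialization
was rejected: with one init per run it sticks in degenerate merge/split
optima in a double-digit percentage of runs even on well-separated
clusters (three random rows hit three clusters with probability 2/9),
flooring the stability statistic for reasons unrelated to the data.

Centers of every unordered pair of runs are matched one-to-one by the
assignment maximizing total Pearson correlation (Hungarian algorithm,
verified against exhaustive permutation search for k ≤ 4); all k matched
correlations per pair are recorded, giving k·R(R−1)/2 values.
Zero-variance centers get correlation 0 with a logged warning. Condition
comparisons use a two-sided Mann–Whitney U with tie correction.

k selection reports the median matched correlation per k and recommends
the smallest k within 0.01 of the best median, provided that best is at
least 0.9. Caveat: matching is by shape correlation, so data holding a
single pattern saturate stability at every k (all centers inherit the
pattern's shape); the recommendation is meaningful only when candidate
patterns differ in shape. Pure noise yields no recommendation. The
recommendation is also coverage-dependent: at ~30 cuts/site the three
planted shapes give a decisive k = 3, while at a few cuts/site k = 2 can
tie within tolerance.

## Synthetic data

The generator emulates the structure the analysis assumes, not real
genomes:

* One 2-Mb chromosome; 500 non-overlapping DHS placed one per 4-kb slot:
  250 motif-host DHS (500–700 bp, rate multiplier 20) and 250 plain DHS
  (250–450 bp, multiplier 12) over background λ_bg = 0.01 cuts/bp/replicate,
  so a plain DHS window carries ~36 tags per replicate. 50 plain DHS are
  planted with a 3-fold induced increase. Multipliers were chosen so the
  fitted gamma threshold falls between background and the weakest DHS
  plateau; a much hotter host class (e.g. 100×) drags the fitted tail above
  the plain plateau and peak recall collapses — a real failure mode of
  threshold-by-global-fit worth knowing about.
* Counts are NB per bp (variance μ + φμ², φ = 0.05; φ = 0 is Poisson) with
  per-replicate lognormal depth factors (sd 0.15) to exercise
  normalization. Because per-bp noise is independent, window-level counts
  are nearly Poisson — biological replicate dispersion correlated across a
  region is not modeled, so the exact test's power here is an upper bound
  for real data.
* 600 motif sites, two per host DHS, 200 per footprint template, random
  strand. Templates protect the 31-bp core (multiplier 0.15 on the
  protected bp: left half 1–14, right half 18–31, full dimer both with the
  central bp 15–17 exposed) and elevate the surrounding ±100 bp by 1.15,
  reflecting how a bound factor shields its core while its neighborhood
  gains accessibility; the flank value is set so footprint planting is
  approximately window-count-neutral and does not masquerade as a ΔDNase
  decrease. Footprints apply to the induced condition only by default.
* The planted sequence draws background bases i.i.d. from the PWM's
  stationary background and samples each site's bases per PWM column
  (reverse-complemented on minus sites). The packaged PWM is a synthetic
  15-bp palindromic hormone-response-element-like dimer (two 6-bp
  half-sites, 3-bp degenerate spacer), constructed in code, not taken from
  any database.
* 200 genes (3 exons, 5 kb, 300-bp 3'UTR, random strand): 40 DE genes with
  TSS within 2 kb of a planted increase (4-fold up upon induction), the
  rest kept ≥ 6 kb away so the nearest-gene map separates groups — the
  association tests' alternative hypothesis is true by construction.
  Expression counts are NB (φ = 0.1) around lognormal baseline levels.
* The default replicate design is 3 + 3; unbalanced designs (e.g. 3 + 2,
  as arises when a discordant replicate is dropped) are supported and
  tested through the group-size-aware exact test.

Everything is bit-reproducible given the scenario seed; independent
streams are derived via `SeedSequence` spawn keys per purpose and
replicate.

What passing tests show: the pipeline recovers planted structure at
realistic desk-scale coverage, its statistics are calibrated where their
assumptions hold, and every stage is deterministic. What they do not show:
robustness to mappability artifacts, fragment-length effects,
sequence-composition cleavage bias, correlated biological replicate noise,
or genome-scale multiple-testing regimes — none of which the generator
models.

## Problem sizes

Defaults were sized so a full pipeline run (2-Mb genome, six replicate
profiles, ~1,200 windows, 100,000 forward permutations, 100 k-means runs
for each of two conditions and four candidate k) completes in well under a
minute on one CPU, and the whole test suite in a couple of minutes; these
are the package's reference problem sizes, and all scale linearly with
genome length and run counts.
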