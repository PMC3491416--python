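"""Differential DNase-seq signal (ΔDNase) over adaptively tiled windows.

The union of DHS peaks from both conditions is tiled with fixed-width
(default 300 bp) overlapping windows.  Regions smaller than the window are
expanded to window width; larger regions are tiled at a default stride, and
when that stride would discard 10% or more of the bases on an edge, an
extra window is added and the stride shrunk so the windows exactly cover
the region.  Replicate tag counts per window are tested with a two-group
negative-binomial exact test (trimmed-mean-of-M-values effective library
sizes, common dispersion by conditional maximum likelihood), thresholded at
strict (BH FDR < 0.05) and loose (raw p < 0.05) levels, and significant
windows sharing a direction are merged into ΔDNase regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .core_io import CutProfile, GenomicInterval, merge_intervals
from .peaks import PeakSet

WINDOW = 300
DEFAULT_STEP = 150  # 50% overlap
EDGE_FRAC = 0.10
MIN_SUM = 5


@dataclass(frozen=True)
class Window:
    interval: GenomicInterval
    parent: int  # index of the union region this window tiles

    def __post_init__(self) -> None:
        pass


@dataclass
class CountMatrix:
    """Windows x replicates tag counts with condition labels."""

    counts: np.ndarray  # (n_windows, n_replicates) non-negative ints
    windows: list[Window]
    conditions: list[str]
    lib_sizes: np.ndarray
    replicate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if np.any(self.lib_sizes <= 0):
            raise ValueError("library sizes must be positive")
        if not self.replicate_names:
            self.replicate_names = [
                f"{c}_{i}" for i, c in enumerate(self.conditions)
            ]

    def group_columns(self) -> tuple[np.ndarray, np.ndarray, str, str]:
        """Baseline = condition of the first column; fold-changes are
        treatment over baseline."""
        labels = list(dict.fromkeys(self.conditions))
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 conditions, got {labels}")
        g1 = np.array([i for i, c in enumerate(self.conditions) if c == labels[0]])
        g2 = np.array([i for i, c in enumerate(self.conditions) if c == labels[1]])
        return g1, g2, labels[0], labels[1]


@dataclass
class DiffResult:
    """Per-window exact-test results (direction: induced vs untreated)."""

    windows: list[Window]
    log2fc: np.ndarray
    pvalue: np.ndarray
    fdr: np.ndarray
    baseline_condition: str
    treatment_condition: str

    @property
    def direction(self) -> np.ndarray:
        return np.sign(self.log2fc)


@dataclass
class DeltaRegionSets:
    """Merged ΔDNase regions at strict (FDR) and loose (raw p) thresholds.

    Region score = min window p in the merged run; strict sets are always
    contained in the corresponding loose sets.
    """

    strict_increase: list[GenomicInterval]
    loose_increase: list[GenomicInterval]
    strict_decrease: list[GenomicInterval]
    loose_decrease: list[GenomicInterval]
    strict_fdr: float
    loose_p: float


# ---------------------------------------------------------------------------
# union + tiling


def union_regions(a: PeakSet | list, b: PeakSet | list) -> list[GenomicInterval]:
    """Sorted, non-overlapping union of two peak sets."""
    a_list = list(a.peaks) if isinstance(a, PeakSet) else list(a)
    b_list = list(b.peaks) if isinstance(b, PeakSet) else list(b)
    return merge_intervals(a_list + b_list, book_ended=False)


def tile_region(
    region: GenomicInterval,
    width: int = WINDOW,
    default_step: int = DEFAULT_STEP,
    edge_frac: float = EDGE_FRAC,
    parent: int = 0,
    chrom_size: int | None = None,
) -> list[Window]:
    """Tile one union region with fixed-width windows.

    Regions at most ``width`` long yield a single window of exactly
    ``width`` bp centered on the region.  Longer regions are tiled at
    ``default_step`` from the region start; if the bases left uncovered on
    an edge amount to ``edge_frac`` of the region or more, one more window
    is added and the stride recomputed (floored, last window pinned to the
    region end) so the windows cover every base.
    """
    if width <= 0 or not 0 < default_step <= width:
        raise ValueError("need width > 0 and 0 < default_step <= width")
    if chrom_size is not None and width > chrom_size:
        raise ValueError("window wider than chromosome")
    n_bp = len(region)
    if n_bp <= width:
        start = region.start - (width - n_bp) // 2
        if chrom_size is not None:
            start = min(max(start, 0), chrom_size - width)
        else:
            start = max(start, 0)
        iv = GenomicInterval(region.chrom, start, start + width)
        return [Window(iv, parent)]
    n = (n_bp - width) // default_step + 1
    starts = [region.start + i * default_step for i in range(n)]
    uncovered_right = region.end - (starts[-1] + width)
    if uncovered_right < edge_frac * n_bp:
        offsets = starts
    else:
        # add a window and shrink the stride for exact coverage
        stride = (n_bp - width) / n
        offsets = [region.start + int(np.floor(i * stride)) for i in range(n + 1)]
        offsets[-1] = region.end - width
    return [
        Window(GenomicInterval(region.chrom, s, s + width), parent)
        for s in offsets
    ]


def tile_regions(
    regions: list[GenomicInterval],
    width: int = WINDOW,
    default_step: int = DEFAULT_STEP,
    edge_frac: float = EDGE_FRAC,
    chrom_sizes: dict[str, int] | None = None,
) -> list[Window]:
    out: list[Window] = []
    for i, region in enumerate(regions):
        size = chrom_sizes.get(region.chrom) if chrom_sizes else None
        out.extend(
            tile_region(region, width, default_step, edge_frac, i, size)
        )
    return out


# ---------------------------------------------------------------------------
# counting


def count_and_filter(
    windows: list[Window],
    profiles: list[CutProfile],
    min_sum: int = MIN_SUM,
) -> CountMatrix:
    """Tag counts per window per replicate; windows whose total over all
    replicates is below ``min_sum`` are eliminated (strictly fewer)."""
    if min_sum < 0:
        raise ValueError("min_sum must be >= 0")
    cumsums = []
    for p in profiles:
        cumsums.append(
            {c: np.concatenate(([0], np.cumsum(v))) for c, v in p.counts.items()}
        )
    counts = np.zeros((len(windows), len(profiles)), dtype=np.int64)
    for wi, w in enumerate(windows):
        iv = w.interval
        for pi, cs in enumerate(cumsums):
            if iv.chrom not in cs or iv.end > cs[iv.chrom].size - 1:
                raise ValueError(f"window {iv} outside profile {pi}")
            counts[wi, pi] = cs[iv.chrom][iv.end] - cs[iv.chrom][iv.start]
    keep = counts.sum(axis=1) >= min_sum
    return CountMatrix(
        counts[keep],
        [w for w, k in zip(windows, keep) if k],
        [p.condition for p in profiles],
        np.array([p.total() for p in profiles], dtype=float),
        [p.replicate for p in profiles],
    )


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors, normalized to geometric mean 1.

    The reference column is the one whose 75th count percentile (relative
    to library size) is closest to the across-sample mean.
    """
    counts = np.asarray(counts, dtype=float)
    lib = np.asarray(lib_sizes, dtype=float)
    q75 = np.array(
        [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(counts.shape[1])
    yr = counts[:, ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        y = counts[:, j]
        ok = (y > 0) & (yr > 0)
        if not ok.any():
            continue
        p, pr = y[ok] / lib[j], yr[ok] / lib[ref]
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        w = (lib[j] - y[ok]) / (lib[j] * y[ok]) + (lib[ref] - yr[ok]) / (
            lib[ref] * yr[ok]
        )
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [sum_trim, 1 - sum_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.any() and w[keep].sum() > 0:
            factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# common dispersion (conditional maximum likelihood)


def _conditional_loglik(phi: float, scaled: np.ndarray, groups: list[np.ndarray]) -> float:
    r = 1.0 / phi
    total = 0.0
    for g in groups:
        y = scaled[:, g]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(special.gammaln(y + r))
            - y.shape[0] * n * special.gammaln(r)
            + y.shape[0] * special.gammaln(n * r)
            - np.sum(special.gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(matrix: CountMatrix,
                               eff_lib: np.ndarray | None = None) -> float:
    """Common NB dispersion by conditional ML on counts scaled to a common
    library size (accurate when effective library sizes are comparable)."""
    if eff_lib is None:
        eff_lib = matrix.lib_sizes * tmm_factors(matrix.counts, matrix.lib_sizes)
    g1, g2, _, _ = matrix.group_columns()
    common = np.exp(np.mean(np.log(eff_lib)))
    scaled = np.rint(matrix.counts * (common / eff_lib)).astype(np.int64)
    groups = [g1, g2]
    res = optimize.minimize_scalar(
        lambda lg: -_conditional_loglik(10**lg, scaled, groups),
        bounds=(-6.0, 1.0),
        method="bounded",
    )
    return float(10**res.x)


# ---------------------------------------------------------------------------
# exact test


def exact_nb_pvalue(z1: int, n1: int, z2: int, n2: int, dispersion: float,
                    mu: float | None = None) -> float:
    """Two-sided exact NB test on a two-group split of a window total.

    Conditional on z = z1 + z2, the first group's sum follows the
    distribution proportional to NB(n1*mu, phi/n1) x NB(n2*mu, phi/n2);
    the p-value sums the probabilities of all outcomes no more likely than
    the observed one.  dispersion 0 reduces to the binomial split.
    """
    z = z1 + z2
    if z == 0:
        return 1.0
    if mu is None:
        mu = z / (n1 + n2)
    x = np.arange(z + 1)
    if dispersion <= 0:
        logp1 = stats.poisson.logpmf(x, n1 * mu)
        logp2 = stats.poisson.logpmf(z - x, n2 * mu)
    else:
        r1, r2 = n1 / dispersion, n2 / dispersion
        m1, m2 = n1 * mu, n2 * mu
        logp1 = stats.nbinom.logpmf(x, r1, r1 / (r1 + m1))
        logp2 = stats.nbinom.logpmf(z - x, r2, r2 / (r2 + m2))
    logf = logp1 + logp2
    logf -= special.logsumexp(logf)
    f = np.exp(logf)
    p = float(f[f <= f[z1] * (1 + 1e-12)].sum())
    if p >= 1.0 - 1e-9:
        return 1.0
    return min(max(p, f[z1]), 1.0)


def nb_exact_test(
    matrix: CountMatrix, dispersion: float | None = None
) -> DiffResult:
    """TMM-normalized two-group exact NB test per window with BH adjustment.

    Counts are scaled to the geometric-mean effective library size before
    forming group sums; log2 fold-changes use a 0.5 prior count.
    """
    g1, g2, cond1, cond2 = matrix.group_columns()
    colsums = matrix.counts.sum(axis=0)
    if colsums[g1].sum() == 0 or colsums[g2].sum() == 0:
        raise ValueError("one condition has no counts at all")
    eff_lib = matrix.lib_sizes * tmm_factors(matrix.counts, matrix.lib_sizes)
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix, eff_lib)
    common = np.exp(np.mean(np.log(eff_lib)))
    scaled = np.rint(matrix.counts * (common / eff_lib)).astype(np.int64)
    n1, n2 = len(g1), len(g2)
    z1 = scaled[:, g1].sum(axis=1)
    z2 = scaled[:, g2].sum(axis=1)
    pvals = np.array(
        [
            exact_nb_pvalue(int(a), n1, int(b), n2, dispersion)
            for a, b in zip(z1, z2)
        ]
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    log2fc = np.log2((z2 / n2 + 0.5) / (z1 / n1 + 0.5))
    return DiffResult(matrix.windows, log2fc, pvals, fdr, cond1, cond2)


# ---------------------------------------------------------------------------
# classification + merging


def _merge_scored(ivs: list[tuple[GenomicInterval, float]]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended windows; region score = min window p."""
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda t: (t[0].chrom, t[0].start))
    out = []
    chrom, start, end, best = (
        ivs[0][0].chrom,
        ivs[0][0].start,
        ivs[0][0].end,
        ivs[0][1],
    )
    for iv, p in ivs[1:]:
        if iv.chrom == chrom and iv.start <= end:
            end = max(end, iv.end)
            best = min(best, p)
        else:
            out.append(GenomicInterval(chrom, start, end, score=best))
            chrom, start, end, best = iv.chrom, iv.start, iv.end, p
    out.append(GenomicInterval(chrom, start, end, score=best))
    return out


def classify_and_merge(
    results: DiffResult, strict_fdr: float = 0.05, loose_p: float = 0.05
) -> DeltaRegionSets:
    """Threshold windows at strict (FDR) and loose (raw p) levels, split by
    direction, and merge neighboring significant windows."""

    def pick(mask: np.ndarray) -> list[tuple[GenomicInterval, float]]:
        return [
            (results.windows[i].interval, float(results.pvalue[i]))
            for i in np.flatnonzero(mask)
        ]

    up = results.log2fc > 0
    down = results.log2fc < 0
    strict = results.fdr < strict_fdr
    loose = results.pvalue < loose_p
    return DeltaRegionSets(
        strict_increase=_merge_scored(pick(strict & up)),
        loose_increase=_merge_scored(pick(loose & up)),
        strict_decrease=_merge_scored(pick(strict & down)),
        loose_decrease=_merge_scored(pick(loose & down)),
        strict_fdr=strict_fdr,
        loose_p=loose_p,
    )


# ---------------------------------------------------------------------------
# normalized differential tag score


def normalized_differential_score(
    union: list[GenomicInterval],
    untreated: list[CutProfile],
    induced: list[CutProfile],
) -> np.ndarray:
    """Per-region differential tag score.

    Tags per region are pooled within each condition, normalized to the
    mean tag count over all union regions in that condition, and the
    normalized untreated value is subtracted from the normalized induced
    value.  The scores average to zero over regions by construction.
    """
    if not union:
        raise ValueError("no union regions")

    def region_counts(profiles: list[CutProfile]) -> np.ndarray:
        c = np.zeros(len(union))
        for p in profiles:
            c += np.array([p.count_in(r) for r in union], dtype=float)
        return c

    cu = region_counts(untreated)
    ci = region_counts(induced)
    if cu.mean() == 0 or ci.mean() == 0:
        raise ValueError("zero mean tag count in a condition")
    return ci / ci.mean() - cu / cu.mean()
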