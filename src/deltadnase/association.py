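"""Genic annotation of regions and permutation tests linking ΔDNase
regions to differentially expressed genes.

Two directions are tested.  Forward: map each ΔDNase region to its nearest
gene (midpoint-to-TSS distance) and ask whether those genes overlap the DE
set more than random gene sets of the same size (default 100,000 draws).
Reverse: ask whether DE genes have a ΔDNase region within a surrounding
window (default 20 kb around the merged gene span) more often than random
gene sets (default 1,000 draws).  Permutation p-values carry the +1
correction and are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GeneModel, GenomicInterval

PROMOTER_BP = 2000
ASSOC_WINDOW = 20_000

CATEGORIES = (
    "promoter",
    "first_exon_intron",
    "other_intragenic",
    "three_prime_proximal",
    "intergenic",
)


@dataclass
class CategoryDistribution:
    """Region counts and fractions over gene-relative categories."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()} if t else {}


@dataclass
class PermutationResult:
    """Observed overlap against an empirical permutation null."""

    observed: int
    null: np.ndarray
    n_permutations: int

    @property
    def p_enrich(self) -> float:
        return (np.sum(self.null >= self.observed) + 1) / (self.n_permutations + 1)

    @property
    def p_deplete(self) -> float:
        return (np.sum(self.null <= self.observed) + 1) / (self.n_permutations + 1)


def annotate_regions(
    regions: list[GenomicInterval],
    genes: list[GeneModel],
    promoter_bp: int = PROMOTER_BP,
) -> CategoryDistribution:
    """Assign each region one category by its midpoint with fixed
    precedence: promoter (within ``promoter_bp`` upstream of a TSS) >
    first exon/intron > other intragenic > 3'-proximal (within
    ``promoter_bp`` downstream of a gene end) > intergenic."""
    counts = {c: 0 for c in CATEGORIES}
    rank = {c: i for i, c in enumerate(CATEGORIES)}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for region in regions:
        mid = region.midpoint
        cat = "intergenic"
        for g in by_chrom.get(region.chrom, []):
            span = g.span
            if g.strand == "-":
                promoter = span[1] <= mid < span[1] + promoter_bp
                downstream = span[0] - promoter_bp <= mid < span[0]
            else:
                promoter = g.tss - promoter_bp <= mid < g.tss
                downstream = span[1] <= mid < span[1] + promoter_bp
            if promoter:
                gcat = "promoter"
            elif span[0] <= mid < span[1]:
                if len(g.exons) == 1:
                    in_first = True
                elif g.strand == "-":
                    in_first = mid >= g.exons[-2][1]
                else:
                    in_first = mid < g.exons[1][0]
                gcat = "first_exon_intron" if in_first else "other_intragenic"
            elif downstream:
                gcat = "three_prime_proximal"
            else:
                continue
            if rank[gcat] < rank[cat]:
                cat = gcat
            if cat == "promoter":
                break
        counts[cat] += 1
    return CategoryDistribution(counts)


def nearest_gene(
    regions: list[GenomicInterval], genes: list[GeneModel]
) -> dict[GenomicInterval, GeneModel]:
    """Nearest gene by |region midpoint - TSS|; ties go to the
    lexicographically smaller gene id."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    missing = sorted({r.chrom for r in regions} - set(by_chrom))
    if missing:
        raise ValueError(f"no genes on chromosome(s) with regions: {missing}")
    out: dict[GenomicInterval, GeneModel] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
    for region in regions:
        gs = by_chrom[region.chrom]
        mid = region.midpoint
        best = min(gs, key=lambda g: (abs(g.tss - mid), g.gene_id))
        out[region] = best
    return out


def permutation_enrichment(
    region_genes: set[str],
    de_set: set[str],
    universe: set[str],
    n_permutations: int = 100_000,
    seed: int = 0,
) -> PermutationResult:
    """Forward test: overlap of region-associated genes with the DE set
    versus random gene sets of size |de_set| drawn from the universe."""
    universe_list = sorted(universe)
    if not de_set <= universe:
        raise ValueError("de_set must be a subset of the universe")
    if not region_genes <= universe:
        raise ValueError("region_genes must be a subset of the universe")
    observed = len(region_genes & de_set)
    member = np.array([g in region_genes for g in universe_list])
    rng = np.random.default_rng(seed)
    k = len(de_set)
    n_u = len(universe_list)
    null = np.empty(n_permutations, dtype=np.int64)
    # draw k distinct indices per permutation via random-key partial sort
    chunk = max(1, min(n_permutations, 20_000_000 // max(n_u, 1)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        keys = rng.random((m, n_u))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[done : done + m] = member[idx].sum(axis=1)
        done += m
    return PermutationResult(observed, null, n_permutations)


def merged_gene_spans(genes: list[GeneModel]) -> dict[str, GenomicInterval]:
    """One interval per gene id covering all of its isoform spans."""
    spans: dict[str, tuple[str, int, int]] = {}
    for g in genes:
        s, e = g.span
        if g.gene_id in spans:
            c, s0, e0 = spans[g.gene_id]
            if c != g.chrom:
                raise ValueError(f"{g.gene_id}: isoforms on different chroms")
            spans[g.gene_id] = (c, min(s0, s), max(e0, e))
        else:
            spans[g.gene_id] = (g.chrom, s, e)
    return {
        gid: GenomicInterval(c, s, e, name=gid)
        for gid, (c, s, e) in spans.items()
    }


def reverse_association(
    de_set: set[str],
    regions: list[GenomicInterval],
    genes: list[GeneModel],
    window: int = ASSOC_WINDOW,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Reverse test: number of DE genes with a ΔDNase region within
    ``window`` bp of the merged gene span, versus random gene sets."""
    spans = merged_gene_spans(genes)
    if not de_set <= set(spans):
        raise ValueError("de_set contains unknown gene ids")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in regions}:
        ivs = sorted(
            (r for r in regions if r.chrom == chrom), key=lambda r: r.start
        )
        starts = np.array([r.start for r in ivs])
        ends = np.maximum.accumulate(np.array([r.end for r in ivs]))
        by_chrom[chrom] = (starts, ends)

    def has_region(gid: str) -> bool:
        span = spans[gid]
        if span.chrom not in by_chrom:
            return False
        starts, ends = by_chrom[span.chrom]
        lo, hi = span.start - window, span.end + window
        i = np.searchsorted(starts, hi, side="left")
        return i > 0 and ends[i - 1] > lo

    gene_ids = sorted(spans)
    match = np.array([has_region(g) for g in gene_ids])
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    observed = int(match[[idx_of[g] for g in sorted(de_set)]].sum())
    rng = np.random.default_rng(seed)
    k = len(de_set)
    null = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        pick = rng.choice(len(gene_ids), size=k, replace=False)
        null[i] = match[pick].sum()
    return PermutationResult(observed, null, n_permutations)
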