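"""Gene-level expression quantification and differential-expression calls.

Tags are assigned to a gene when their 5' base falls inside one of its
exons (a tag in the exons of several genes counts for each).  RPKM uses
the exonic length excluding the 3'UTR, and tags in the 3'UTR are excluded
from the RPKM numerator; the differential test itself runs on plain exonic
counts.  DE calling reuses the window-level negative-binomial exact test,
so windows and genes go through one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomicInterval
from .delta_dnase import CountMatrix, DiffResult, Window, nb_exact_test


@dataclass
class ExpressionResult:
    """DE calls (FDR < 0.05 by default) split by fold-change sign."""

    table: pd.DataFrame  # gene_id, log2fc, pvalue, fdr
    upregulated: list[str]
    downregulated: list[str]
    diff: DiffResult


def gene_counts(
    genes: list[GeneModel],
    tags: list[GenomicInterval],
    exclude_utr3: bool = False,
) -> np.ndarray:
    """Number of tags whose 5' bp lies within each gene's exons.

    The 5' bp of a tag is its start for '+'/'.' tags and end-1 for '-'
    tags.  With ``exclude_utr3``, tags falling in the annotated 3'UTR are
    not counted.
    """
    counts = np.zeros(len(genes), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for gi, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(gi)
    for tag in tags:
        five_prime = tag.end - 1 if tag.strand == "-" else tag.start
        for gi in by_chrom.get(tag.chrom, []):
            g = genes[gi]
            if exclude_utr3 and g.utr3 and g.utr3[0] <= five_prime < g.utr3[1]:
                continue
            if any(s <= five_prime < e for s, e in g.exons):
                counts[gi] += 1
    return counts


def rpkm(
    counts: np.ndarray | list, genes: list[GeneModel], library_size: float
) -> np.ndarray:
    """Reads per kilobase of non-3'UTR exon model per million mapped reads.

    Callers wanting the matching numerator should compute counts with
    ``gene_counts(..., exclude_utr3=True)``.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    counts = np.asarray(counts, dtype=float)
    lengths = np.array([g.exonic_length(exclude_utr3=True) for g in genes])
    if np.any(lengths <= 0):
        bad = [g.gene_id for g, n in zip(genes, lengths) if n <= 0]
        raise ValueError(f"zero effective exonic length: {bad}")
    return counts * 1e9 / (library_size * lengths)


def _gene_matrix(
    counts: pd.DataFrame, conditions: list[str]
) -> CountMatrix:
    """Wrap a gene x replicate count table as a CountMatrix.

    Genes are carried as unit-width placeholder windows so the window-level
    machinery applies unchanged; library size = column total.
    """
    windows = [
        Window(GenomicInterval("gene", i, i + 1, name=g), parent=i)
        for i, g in enumerate(counts.index)
    ]
    mat = counts.to_numpy()
    return CountMatrix(
        mat,
        windows,
        list(conditions),
        mat.sum(axis=0).astype(float),
        list(counts.columns),
    )


def de_genes(
    counts: pd.DataFrame,
    conditions: list[str],
    fdr: float = 0.05,
    dispersion: float | None = None,
) -> ExpressionResult:
    """Differential expression between two conditions at the given FDR."""
    matrix = _gene_matrix(counts, conditions)
    diff = nb_exact_test(matrix, dispersion=dispersion)
    gene_ids = list(counts.index)
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": diff.log2fc,
            "pvalue": diff.pvalue,
            "fdr": diff.fdr,
        }
    )
    sig = diff.fdr < fdr
    up = [g for g, s, f in zip(gene_ids, sig, diff.log2fc) if s and f > 0]
    down = [g for g, s, f in zip(gene_ids, sig, diff.log2fc) if s and f < 0]
    return ExpressionResult(table, up, down, diff)
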