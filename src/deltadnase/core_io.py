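"""Domain types and on-disk formats.

All coordinates throughout the package are 0-based half-open (BED
convention).  A "tag" or "cut" is the 5' base of a sequenced fragment and is
assigned to the single bp it occupies, so window counts are unambiguous even
for overlapping windows.  Strand ``.`` is permitted and treated as ``+`` for
sequence extraction (DNase cuts are unstranded).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``score`` is optional payload (peak height, motif score, ...); ``name``
    is an optional identifier carried through BED columns.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(
    intervals: list[GenomicInterval], book_ended: bool = True
) -> list[GenomicInterval]:
    """Merge overlapping (and, by default, book-ended) intervals.

    Returns a sorted, non-overlapping list.  Scores/names are dropped.
    """
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda r: (r.chrom, r.start, r.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        joined = iv.chrom == cur_chrom and (
            iv.start < cur_end or (book_ended and iv.start == cur_end)
        )
        if joined:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def total_length(intervals: list[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


# ---------------------------------------------------------------------------
# cut profiles


@dataclass
class CutProfile:
    """Per-chromosome dense vectors of DNase I 5'-cut counts (one per bp)."""

    counts: dict[str, np.ndarray]
    replicate: str = "rep1"
    condition: str = "untreated"

    def __post_init__(self) -> None:
        for chrom, vec in self.counts.items():
            vec = np.asarray(vec)
            if not np.issubdtype(vec.dtype, np.integer):
                if not np.all(vec == np.floor(vec)):
                    raise ValueError(f"non-integer counts on {chrom}")
                vec = vec.astype(np.int64)
            if np.any(vec < 0):
                raise ValueError(f"negative counts on {chrom}")
            self.counts[chrom] = vec

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.counts.items()}

    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def count_in(self, interval: GenomicInterval) -> int:
        vec = self.counts[interval.chrom]
        return int(vec[interval.start : interval.end].sum())


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """A gene with TSS, exons and an optional 3'UTR interval."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if not (self.span[0] <= self.tss < self.span[1]):
            raise ValueError(f"{self.gene_id}: TSS outside gene span")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exonic_length(self, exclude_utr3: bool = False) -> int:
        n = 0
        for s, e in self.exons:
            n += e - s
            if exclude_utr3 and self.utr3 is not None:
                u0, u1 = self.utr3
                n -= max(0, min(e, u1) - max(s, u0))
        return n


# ---------------------------------------------------------------------------
# position weight matrices


@dataclass
class PWM:
    """Base-probability motif model with a first-order background.

    ``probs`` is 4 x w (rows A,C,G,T, columns summing to 1).  The background
    is a stationary start distribution plus a 4 x 4 dinucleotide transition
    matrix; both are needed by the first-order log-likelihood scanner.
    """

    probs: np.ndarray
    background_stationary: np.ndarray | None = None
    background_transition: np.ndarray | None = None
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A,C,G,T)")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if self.background_stationary is not None:
            pi = np.asarray(self.background_stationary, dtype=float)
            if not np.isclose(pi.sum(), 1.0, atol=1e-9):
                raise ValueError("stationary background must sum to 1")
            self.background_stationary = pi
        if self.background_transition is not None:
            tr = np.asarray(self.background_transition, dtype=float)
            if not np.allclose(tr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("background transition rows must sum to 1")
            self.background_transition = tr

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.probs[::-1, ::-1].copy(),
            self.background_stationary,
            self.background_transition,
            name=self.name + "_rc",
        )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving file order."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, strand, score, name)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path: str, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                cols += [
                    iv.name if iv.name is not None else ".",
                    format(iv.score, "g") if iv.score is not None else "0",
                    iv.strand,
                ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# bedGraph cut profiles


def read_bedgraph_cuts(
    path: str,
    chrom_sizes: dict[str, int],
    replicate: str = "rep1",
    condition: str = "untreated",
) -> CutProfile:
    """Expand a 4-column bedGraph into dense per-bp cut counts.

    Positions not covered by any record are zero.  Overlapping records and
    records outside the declared chromosome are errors.
    """
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: need 4 columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chrom {chrom}")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if end > chrom_sizes[chrom] or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: record outside {chrom} "
                    f"(size {chrom_sizes[chrom]})"
                )
            if value < 0 or value != int(value):
                raise FormatError(
                    f"{path}:{lineno}: value must be a non-negative integer"
                )
            if covered[chrom][start:end].any():
                raise FormatError(f"{path}:{lineno}: overlapping records")
            covered[chrom][start:end] = True
            counts[chrom][start:end] = int(value)
    return CutProfile(counts, replicate=replicate, condition=condition)


def write_bedgraph(path: str, profile: CutProfile) -> None:
    """Write nonzero runs of a cut profile as bedGraph records."""
    with open(path, "w") as fh:
        for chrom in sorted(profile.counts):
            vec = profile.counts[chrom]
            if vec.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


def write_fasta(path: str, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# JASPAR PWMs


def read_jaspar_pwm(path: str, pseudocount: float = 0.0) -> PWM:
    """Read a JASPAR count matrix and normalize to column probabilities.

    ``pseudocount`` is added to every count before normalization.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        motif = bio_motifs.read(io.StringIO(text), "jaspar")
    except Exception:
        try:
            motif = bio_motifs.read(io.StringIO(text), "pfm")
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse as JASPAR/PFM") from exc
    counts = np.array([list(motif.counts[b]) for b in BASES], dtype=float)
    counts += pseudocount
    colsums = counts.sum(axis=0)
    if np.any(colsums <= 0):
        raise FormatError(f"{path}: column with zero total count")
    name = getattr(motif, "matrix_id", None) or motif.name or "pwm"
    return PWM(counts / colsums, name=str(name))


# ---------------------------------------------------------------------------
# gene model TSV


GENE_TSV_HEADER = [
    "gene_id",
    "chrom",
    "strand",
    "tss",
    "exon_starts",
    "exon_ends",
    "utr3_start",
    "utr3_end",
]


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from the package's TSV schema (see write_gene_models)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GENE_TSV_HEADER:
            raise FormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            starts = [int(x) for x in f[4].split(",") if x]
            ends = [int(x) for x in f[5].split(",") if x]
            if len(starts) != len(ends):
                raise FormatError(f"{path}:{lineno}: exon column mismatch")
            utr3 = None
            if f[6] != "." and f[7] != ".":
                utr3 = (int(f[6]), int(f[7]))
            genes.append(
                GeneModel(f[0], f[1], f[2], int(f[3]),
                          list(zip(starts, ends)), utr3)
            )
    return genes


def write_gene_models(path: str, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TSV_HEADER) + "\n")
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            u0, u1 = (str(g.utr3[0]), str(g.utr3[1])) if g.utr3 else (".", ".")
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{starts}\t{ends}\t{u0}\t{u1}\n"
            )
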