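"""DHS peak calling from cut profiles.

Cut counts are smoothed into a continuous accessibility signal with a
Gaussian kernel, the positive signal values are fit to a gamma distribution
by maximum likelihood, and discrete peaks are the maximal runs of bases
whose signal exceeds the fitted upper-tail quantile (default P < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core_io import CutProfile, GenomicInterval

DEFAULT_BANDWIDTH = 60  # bp, Gaussian sigma
DEFAULT_MIN_GAP = 50  # bp: runs closer than this merge into one peak


@dataclass
class SignalTrack:
    """Smoothed per-bp accessibility signal."""

    values: dict[str, np.ndarray]
    bandwidth: float

    def __post_init__(self) -> None:
        for chrom, vec in self.values.items():
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValueError(f"signal on {chrom} must be finite and >= 0")

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def positive_values(self) -> np.ndarray:
        parts = [v[v > 0] for v in self.values.values()]
        return np.concatenate(parts) if parts else np.array([])


@dataclass
class PeakSet:
    """Sorted, non-overlapping peaks with max-signal scores."""

    peaks: list[GenomicInterval]
    threshold: float
    p_cutoff: float | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start))
        for a, b in zip(self.peaks, self.peaks[1:]):
            if a.overlaps(b):
                raise ValueError("peaks must be non-overlapping")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def kde_signal(profile: CutProfile, bandwidth: float = DEFAULT_BANDWIDTH) -> SignalTrack:
    """Gaussian-kernel density of cuts evaluated at every bp.

    Mass-conserving away from chromosome edges: sum(signal) equals the cut
    total up to edge loss.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    values = {
        chrom: ndimage.gaussian_filter1d(
            vec.astype(float), sigma=bandwidth, mode="constant", truncate=6.0
        )
        for chrom, vec in profile.counts.items()
    }
    return SignalTrack(values, bandwidth)


def pooled_profile(profiles: list[CutProfile]) -> CutProfile:
    """Sum replicate cut profiles base-by-base."""
    if not profiles:
        raise ValueError("no profiles to pool")
    counts = {c: v.copy() for c, v in profiles[0].counts.items()}
    for p in profiles[1:]:
        for c, v in p.counts.items():
            counts[c] = counts.get(c, 0) + v
    return CutProfile(counts, replicate="pooled",
                      condition=profiles[0].condition)


def gamma_threshold(track: SignalTrack, p: float = 0.05) -> float:
    """Signal value whose upper-tail probability is ``p`` under a gamma
    distribution fit by MLE to the positive signal values."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    x = track.positive_values()
    if x.size == 0:
        raise ValueError("track has no positive signal")
    if np.ptp(x) == 0:
        raise ValueError("degenerate all-equal signal; gamma fit undefined")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return float(stats.gamma.isf(p, shape, scale=scale))


def call_peaks(
    track: SignalTrack, threshold: float, min_gap: int = DEFAULT_MIN_GAP
) -> PeakSet:
    """Maximal runs of bp with signal >= threshold; runs separated by fewer
    than ``min_gap`` bp are merged.  Peak score = max signal in the run."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    peaks: list[GenomicInterval] = []
    for chrom, vec in track.values.items():
        above = vec >= threshold
        if not above.any():
            continue
        diff = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(diff == 1) + 1)
        ends = list(np.flatnonzero(diff == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(vec.size)
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] < min_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            peaks.append(
                GenomicInterval(chrom, s, e, score=float(vec[s:e].max()))
            )
    return PeakSet(peaks, threshold=threshold)


@dataclass(frozen=True)
class OverlapSummary:
    """Counts and fractions of intervals overlapping the other set, in both
    directions (a site overlaps if it intersects >= 1 bp of the other set)."""

    n_a: int
    n_b: int
    a_overlapping: int
    b_overlapping: int

    @property
    def frac_a(self) -> float:
        return self.a_overlapping / self.n_a if self.n_a else 0.0

    @property
    def frac_b(self) -> float:
        return self.b_overlapping / self.n_b if self.n_b else 0.0


def _count_overlapping(
    query: list[GenomicInterval], subject: list[GenomicInterval]
) -> int:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    subj = sorted(subject, key=lambda r: (r.chrom, r.start))
    for iv in subj:
        by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    for chrom in by_chrom:
        ivs = [r for r in subj if r.chrom == chrom]
        by_chrom[chrom] = (
            np.array([r.start for r in ivs]),
            np.array([r.end for r in ivs]),
        )
    n = 0
    for q in query:
        if q.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[q.chrom]
        i = np.searchsorted(starts, q.end, side="left")
        # any subject starting before q.end with end beyond q.start
        if i > 0 and np.max(ends[:i]) > q.start:
            n += 1
    return n


def overlap_fraction(a: PeakSet | list, b: PeakSet | list) -> OverlapSummary:
    """Overlap summary between two peak/region sets, both directions."""
    a_list = list(a.peaks) if isinstance(a, PeakSet) else list(a)
    b_list = list(b.peaks) if isinstance(b, PeakSet) else list(b)
    return OverlapSummary(
        n_a=len(a_list),
        n_b=len(b_list),
        a_overlapping=_count_overlapping(a_list, b_list),
        b_overlapping=_count_overlapping(b_list, a_list),
    )
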