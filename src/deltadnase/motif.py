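"""PWM trimming, first-order log-likelihood scanning, relative enrichment.

Windows are scored as sum(log P_pwm(base_j)) minus the log-probability of
the window under a first-order (dinucleotide) background model; the first
base uses the background's stationary distribution.  Matches below the
90th percentile of all window scores in the scanned space are discarded,
and where both strands pass only the stronger is kept.  The background is
estimated from both strands of the scanned sequence, which makes the scan
exactly strand-symmetric.
"""

from __future__ import annotations

import numpy as np

from .core_io import BASES, GenomicInterval, PWM

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        codes[arr == ord(b)] = i
    return codes


def estimate_background(
    seq: str, pseudocount: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-symmetric first-order background from a sequence.

    Dinucleotide counts are accumulated from the sequence and its reverse
    complement (plus a pseudocount), so the estimated model assigns equal
    probability to a window and its reverse complement.  Returns
    (stationary 4-vector, 4x4 transition matrix).
    """
    codes = _encode(seq)
    valid = codes >= 0
    pair_ok = valid[:-1] & valid[1:]
    di = np.full((4, 4), pseudocount, dtype=float)
    np.add.at(di, (codes[:-1][pair_ok], codes[1:][pair_ok]), 1.0)
    di += di[::-1, ::-1].T  # reverse-complement symmetrization
    transition = di / di.sum(axis=1, keepdims=True)
    mono = np.full(4, pseudocount, dtype=float)
    np.add.at(mono, codes[valid], 1.0)
    mono += mono[::-1]
    stationary = mono / mono.sum()
    return stationary, transition


def with_background(pwm: PWM, seq: str, pseudocount: float = 1.0) -> PWM:
    pi, tr = estimate_background(seq, pseudocount)
    return PWM(pwm.probs, pi, tr, name=pwm.name)


def trim_pwm(pwm: PWM, keep_start: int, keep_end: int) -> PWM:
    """Keep columns ``keep_start``..``keep_end`` (1-based, inclusive)."""
    if not 1 <= keep_start <= keep_end <= pwm.width:
        raise ValueError(
            f"columns {keep_start}..{keep_end} out of range for width {pwm.width}"
        )
    return PWM(
        pwm.probs[:, keep_start - 1 : keep_end].copy(),
        pwm.background_stationary,
        pwm.background_transition,
        name=f"{pwm.name}[{keep_start}:{keep_end}]",
    )


def _window_scores(
    codes: np.ndarray, pwm: PWM, logpi: np.ndarray, logtr: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward/reverse log-likelihood-ratio scores for every window start,
    plus a validity mask (windows containing N are invalid)."""
    w = pwm.width
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0), np.empty(0, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    with np.errstate(divide="ignore"):
        logp = np.log(pwm.probs)
        logp_rc = np.log(pwm.probs[::-1, ::-1])
    fwd = np.zeros(n)
    rev = np.zeros(n)
    for j in range(w):
        fwd += logp[safe[j : j + n], j]
        rev += logp_rc[safe[j : j + n], j]
    # background of the forward window
    trans = logtr[safe[:-1], safe[1:]]
    ctrans = np.concatenate(([0.0], np.cumsum(trans)))
    bg_fwd = logpi[safe[:n]] + ctrans[w - 1 : w - 1 + n] - ctrans[:n]
    # background of the reverse-complement window
    rtrans = logtr[3 - safe[1:], 3 - safe[:-1]]
    crtrans = np.concatenate(([0.0], np.cumsum(rtrans)))
    bg_rev = logpi[3 - safe[w - 1 : w - 1 + n]] + crtrans[w - 1 : w - 1 + n] - crtrans[:n]
    bad = np.concatenate(([0], np.cumsum((codes < 0).astype(np.int64))))
    valid = (bad[w:] - bad[:-w]) == 0
    return fwd - bg_fwd, rev - bg_rev, valid


def scan_sequence(
    seq: str,
    pwm: PWM,
    chrom: str = "chr1",
    percentile: float = 90.0,
    regions: list[GenomicInterval] | None = None,
    pseudocount: float = 1.0,
) -> list[GenomicInterval]:
    """First-order log-likelihood scan of one sequence.

    Returns matches (width = PWM width) whose score reaches the given
    percentile of all window scores in the scanned space; where both
    strands reach it, only the stronger strand is reported ('+' on a tie).
    ``regions`` restricts scanning to windows fully inside the mask.  If
    the PWM carries no background, a strand-symmetric first-order model is
    estimated from ``seq``.
    """
    if pwm.background_stationary is None or pwm.background_transition is None:
        pwm = with_background(pwm, seq, pseudocount)
    codes = _encode(seq)
    w = pwm.width
    with np.errstate(divide="ignore"):
        logpi = np.log(pwm.background_stationary)
        logtr = np.log(pwm.background_transition)
    fwd, rev, valid = _window_scores(codes, pwm, logpi, logtr)
    if fwd.size == 0:
        return []
    if regions is not None:
        allowed = np.zeros(fwd.size, dtype=bool)
        for r in regions:
            if r.chrom != chrom:
                continue
            lo = max(r.start, 0)
            hi = min(r.end - w + 1, fwd.size)
            if hi > lo:
                allowed[lo:hi] = True
        valid = valid & allowed
    if not valid.any():
        return []
    pool = np.concatenate([fwd[valid], rev[valid]])
    # tiny tolerance keeps exact ties with the threshold (e.g. the
    # degenerate all-equal case) despite float rounding
    threshold = float(np.percentile(pool, percentile)) - 1e-9
    matches: list[GenomicInterval] = []
    idx = np.flatnonzero(valid & ((fwd >= threshold) | (rev >= threshold)))
    for i in idx:
        if fwd[i] >= threshold and (fwd[i] >= rev[i] or rev[i] < threshold):
            strand, score = "+", fwd[i]
        else:
            strand, score = "-", rev[i]
        matches.append(
            GenomicInterval(chrom, int(i), int(i) + w, strand, float(score))
        )
    return matches


def relative_enrichment(
    matches: list[GenomicInterval],
    set_a: list[GenomicInterval],
    set_b: list[GenomicInterval],
) -> float:
    """(fraction of A regions containing >= 1 match) over the same fraction
    for B.  Regions count as containing a match on >= 1 bp of overlap."""
    from .peaks import _count_overlapping

    if not set_a or not set_b:
        raise ValueError("both region sets must be non-empty")
    frac_a = _count_overlapping(set_a, matches) / len(set_a)
    frac_b = _count_overlapping(set_b, matches) / len(set_b)
    if frac_b == 0:
        raise ValueError(
            "no B region contains a match; relative enrichment undefined"
        )
    return frac_a / frac_b
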