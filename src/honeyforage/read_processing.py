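"""Quality trimming, mate-pair merging and the >450 bp length filter.

Amplicon pairs (2 x 300 bp dialect) are merged into full-length
amplicons: mate 2 is reverse-complemented, every admissible overlap
length is scanned, and the overlap maximizing matches minus mismatches
wins. Disagreements inside the overlap resolve to the higher-quality
base. Only merged sequences strictly longer than 450 bp are kept
downstream.

Trimming is a 3' non-overlapping mean-quality window trim (window 4,
threshold Q20 by default): the read is cut after the last window whose
mean quality reaches the threshold. The defaults are configurable; they
follow common amplicon practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import ReadPairBatch
from .synthetic_data import reverse_complement

DEFAULT_TRIM_Q = 20
DEFAULT_TRIM_WINDOW = 4
DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH_FRACTION = 0.1
DEFAULT_MIN_LENGTH = 450  # keep strictly greater than this


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    quality: list[int]
    overlap_length: int
    mismatches_in_overlap: int


@dataclass
class MergeRejection:
    read_id: str
    reason: str  # empty_read | no_overlap | too_many_mismatches


def quality_trim(
    seq: str,
    qual: Sequence[int],
    threshold_q: int = DEFAULT_TRIM_Q,
    window: int = DEFAULT_TRIM_WINDOW,
) -> tuple[str, list[int]]:
    """Trim low-quality 3' tails using non-overlapping mean-quality windows.

    The read is partitioned into consecutive windows of *window* bases
    (the final window may be partial); everything after the last window
    whose mean quality is >= *threshold_q* is removed. If no window
    reaches the threshold the whole read is trimmed away.
    """
    if threshold_q < 0 or window < 1:
        raise ValueError("threshold_q must be >= 0 and window >= 1")
    if not seq:
        return "", []
    q = np.asarray(qual, dtype=float)
    keep_end = 0
    for start in range(0, len(seq), window):
        chunk = q[start : start + window]
        if chunk.mean() >= threshold_q:
            keep_end = min(start + window, len(seq))
    return seq[:keep_end], list(qual[:keep_end])


_CODE = {ch: i for i, ch in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


def merge_pair(
    seq1: str,
    qual1: Sequence[int],
    seq2: str,
    qual2: Sequence[int],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    read_id: str = "",
) -> MergedRead | MergeRejection:
    """Merge a mate pair into one amplicon sequence.

    Mate 2 is supplied in sequencing orientation and reverse-complemented
    here. All overlap lengths from *min_overlap* to min(len1, len2) are
    scanned; the overlap maximizing (matches - mismatches) is selected,
    with ties broken toward the longer overlap. The merge is rejected if
    the best overlap's mismatch fraction exceeds *max_mismatch_fraction*.

    Disagreeing overlap positions take the base with higher quality; on a
    quality tie mate 1's base wins and the position's quality is set to
    the minimum of the two. Agreeing positions take the maximum quality.
    """
    if not seq1 or not seq2:
        return MergeRejection(read_id, "empty_read")
    rc2 = reverse_complement(seq2)
    rq2 = list(qual2)[::-1]
    n1, n2 = len(seq1), len(rc2)
    max_l = min(n1, n2)
    if max_l < min_overlap:
        return MergeRejection(read_id, "no_overlap")
    a1 = _encode(seq1)
    a2 = _encode(rc2)
    best_l, best_score, best_mm = -1, -(10**9), 0
    for length in range(min_overlap, max_l + 1):
        mm = int(np.count_nonzero(a1[n1 - length :] != a2[:length]))
        score = length - 2 * mm  # matches - mismatches
        if score > best_score or (score == best_score and length > best_l):
            best_l, best_score, best_mm = length, score, mm
    if best_mm / best_l > max_mismatch_fraction:
        return MergeRejection(read_id, "too_many_mismatches")

    left = seq1[: n1 - best_l]
    left_q = list(qual1[: n1 - best_l])
    right = rc2[best_l:]
    right_q = rq2[best_l:]
    ov_chars: list[str] = []
    ov_q: list[int] = []
    for k in range(best_l):
        c1, q1 = seq1[n1 - best_l + k], qual1[n1 - best_l + k]
        c2, q2 = rc2[k], rq2[k]
        if c1 == c2:
            ov_chars.append(c1)
            ov_q.append(max(q1, q2))
        elif q2 > q1:
            ov_chars.append(c2)
            ov_q.append(q2)
        elif q1 > q2:
            ov_chars.append(c1)
            ov_q.append(q1)
        else:
            ov_chars.append(c1)
            ov_q.append(min(q1, q2))
    merged = left + "".join(ov_chars) + right
    return MergedRead(
        read_id=read_id,
        sequence=merged,
        quality=left_q + ov_q + right_q,
        overlap_length=best_l,
        mismatches_in_overlap=best_mm,
    )


def length_filter(merged: MergedRead, min_exclusive: int = DEFAULT_MIN_LENGTH) -> bool:
    """Keep a merged read iff its length is strictly greater than the cutoff."""
    return len(merged.sequence) > min_exclusive


@dataclass
class BatchAccounting:
    """Per-sample read accounting: pairs_in = merged + rejected and
    merged = kept + length_filtered, so no read is silently dropped."""

    pairs_in: int = 0
    merged: int = 0
    rejected: int = 0
    kept: int = 0
    length_filtered: int = 0

    def check(self) -> None:
        assert self.pairs_in == self.merged + self.rejected
        assert self.merged == self.kept + self.length_filtered


def process_batch(
    batch: ReadPairBatch,
    threshold_q: int = DEFAULT_TRIM_Q,
    window: int = DEFAULT_TRIM_WINDOW,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[MergedRead], list[MergeRejection], BatchAccounting]:
    """Trim, merge and length-filter a batch of read pairs."""
    kept: list[MergedRead] = []
    rejections: list[MergeRejection] = []
    acct = BatchAccounting()
    for read_id, s1, q1, s2, q2 in batch.pairs:
        acct.pairs_in += 1
        ts1, tq1 = quality_trim(s1, q1, threshold_q, window)
        ts2, tq2 = quality_trim(s2, q2, threshold_q, window)
        result = merge_pair(
            ts1, tq1, ts2, tq2, min_overlap, max_mismatch_fraction, read_id=read_id
        )
        if isinstance(result, MergeRejection):
            acct.rejected += 1
            rejections.append(result)
            continue
        acct.merged += 1
        if length_filter(result, min_length):
            acct.kept += 1
            kept.append(result)
        else:
            acct.length_filtered += 1
    acct.check()
    return kept, rejections, acct
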