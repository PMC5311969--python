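"""Top-hit search of merged reads against the reference library.

Each read is scored against reference sequences by optimal local
alignment (Smith-Waterman, affine gaps) with a megablast-style scheme:
match +1, mismatch -2, gap open -2, gap extend -2. The "top hit set" is
every reference attaining the maximum raw score; ties are exact integer
ties on the raw score, and because the bit-score transform

    S' = (lambda * S - ln K) / ln 2

is strictly monotone in S, the tie structure is identical on either
scale. The Karlin-Altschul parameters default to published ungapped
values for +1/-2 (lambda = 1.28, K = 0.46) and are configuration, not
results-critical.

Two engines share this scoring (Biopython's C PairwiseAligner):

* :func:`top_hits` — exhaustive: aligns against every reference; the
  default engine and the oracle.
* :func:`seeded_top_hits` — a k-mer-seeded accelerator: only references
  sharing at least one exact k-mer with the read are aligned. It equals
  the exhaustive result whenever the true top alignment contains an
  exact k-mer match, which holds at the error rates simulated here; its
  results are flagged "heuristic".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from Bio import Align

from .formats_io import ReferenceLibrary

DEFAULT_KMER_SIZE = 11
DEFAULT_MIN_QUERY_LENGTH = 20


@dataclass(frozen=True)
class AlignmentParams:
    match_reward: float = 1.0
    mismatch_penalty: float = -2.0
    gap_open: float = -2.0  # score of a gap's first base
    gap_extend: float = -2.0  # score of each further gap base
    lam: float = 1.28
    K: float = 0.46
    # optional post-alignment filters, off by default
    min_identity: float | None = None  # fraction of aligned columns matching
    min_query_coverage: float | None = None  # fraction of query aligned

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        for name in ("min_identity", "min_query_coverage"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


class Hit(NamedTuple):
    seq_id: str
    raw_score: float
    bit_score: float


@dataclass
class HitSet:
    """All scored hits for one read, with the tied-top subset exposed."""

    read_id: str
    hits: list[Hit] = field(default_factory=list)
    reason: str | None = None  # set when the read was skipped, not searched
    heuristic: bool = False

    @property
    def top_score(self) -> float | None:
        return max((h.raw_score for h in self.hits), default=None)

    @property
    def top_hit_ids(self) -> list[str]:
        """seq_ids tied at the maximum raw score, in library order."""
        top = self.top_score
        if top is None:
            return []
        by_raw = [h.seq_id for h in self.hits if h.raw_score == top]
        top_bit = max(h.bit_score for h in self.hits)
        by_bit = [h.seq_id for h in self.hits if h.bit_score == top_bit]
        # monotone transform => identical tie structure on either scale
        assert by_raw == by_bit
        return by_raw


def make_aligner(params: AlignmentParams = AlignmentParams()) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_reward
    aligner.mismatch_score = params.mismatch_penalty
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def local_align_score(
    query: str,
    subject: str,
    params: AlignmentParams = AlignmentParams(),
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Optimal local alignment score; 0 is the empty-alignment floor."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if aligner is None:
        aligner = make_aligner(params)
    return max(0.0, float(aligner.score(query, subject)))


def bit_score(raw_score: float, params: AlignmentParams = AlignmentParams()) -> float:
    """Karlin-Altschul bit score S' = (lambda*S - ln K) / ln 2."""
    if not math.isfinite(raw_score):
        raise ValueError("raw score must be finite")
    return (params.lam * raw_score - math.log(params.K)) / math.log(2.0)


def _passes_optional_filters(
    aligner: Align.PairwiseAligner, query: str, subject: str, params: AlignmentParams
) -> bool:
    """Apply the optional identity/coverage cut-offs to the best alignment."""
    if params.min_identity is None and params.min_query_coverage is None:
        return True
    alignment = aligner.align(query, subject)[0]
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    if aligned_cols == 0:
        return False
    if params.min_identity is not None:
        if counts.identities / aligned_cols < params.min_identity:
            return False
    if params.min_query_coverage is not None:
        q_start, q_end = alignment.aligned[0][0][0], alignment.aligned[0][-1][1]
        if (q_end - q_start) / len(query) < params.min_query_coverage:
            return False
    return True


def _score_candidates(
    read_id: str,
    sequence: str,
    library: ReferenceLibrary,
    indices: list[int],
    params: AlignmentParams,
) -> list[Hit]:
    aligner = make_aligner(params)
    hits = []
    for i in indices:
        seq_id, subject, _ = library.entries[i]
        s = local_align_score(sequence, subject, params, aligner=aligner)
        if s > 0 and not _passes_optional_filters(aligner, sequence, subject, params):
            continue
        hits.append(Hit(seq_id, s, bit_score(s, params)))
    return hits


def top_hits(
    read_id: str,
    sequence: str,
    library: ReferenceLibrary,
    params: AlignmentParams = AlignmentParams(),
    min_query_length: int = DEFAULT_MIN_QUERY_LENGTH,
) -> HitSet:
    """Exhaustively score a read against every reference sequence."""
    if len(library) == 0:
        raise ValueError("reference library is empty")
    if len(sequence) < min_query_length:
        return HitSet(read_id, reason="query_too_short")
    hits = _score_candidates(
        read_id, sequence, library, list(range(len(library))), params
    )
    return HitSet(read_id, hits=hits)


class KmerIndex:
    """Exact k-mer -> reference-index lookup for the seeded engine."""

    def __init__(self, library: ReferenceLibrary, k: int = DEFAULT_KMER_SIZE):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.library = library
        self._index: dict[str, set[int]] = {}
        for i, (_, seq, _) in enumerate(library.entries):
            for j in range(len(seq) - k + 1):
                self._index.setdefault(seq[j : j + k], set()).add(i)

    def candidates(self, sequence: str) -> list[int]:
        found: set[int] = set()
        k = self.k
        for j in range(len(sequence) - k + 1):
            hit = self._index.get(sequence[j : j + k])
            if hit:
                found |= hit
        return sorted(found)


def seeded_top_hits(
    read_id: str,
    sequence: str,
    library: ReferenceLibrary,
    params: AlignmentParams = AlignmentParams(),
    k: int = DEFAULT_KMER_SIZE,
    index: KmerIndex | None = None,
    min_query_length: int = DEFAULT_MIN_QUERY_LENGTH,
) -> HitSet:
    """Seeded accelerator: align only references sharing >= 1 exact k-mer.

    A read sharing no k-mer with any reference yields an empty HitSet
    (reason ``no_kmer_match``) and stays unassigned.
    """
    if index is None:
        index = KmerIndex(library, k)
    elif index.k != k or index.library is not library:
        raise ValueError("supplied index does not match library/k")
    if len(sequence) < min_query_length:
        return HitSet(read_id, reason="query_too_short", heuristic=True)
    cand = index.candidates(sequence)
    if not cand:
        return HitSet(read_id, reason="no_kmer_match", heuristic=True)
    hits = _score_candidates(read_id, sequence, library, cand, params)
    return HitSet(read_id, hits=hits, heuristic=True)


class SearchEngine:
    """Engine facade used by the pipeline: ``exhaustive`` or ``seeded``."""

    def __init__(
        self,
        library: ReferenceLibrary,
        params: AlignmentParams = AlignmentParams(),
        engine: str = "exhaustive",
        k: int = DEFAULT_KMER_SIZE,
        min_query_length: int = DEFAULT_MIN_QUERY_LENGTH,
    ):
        if engine not in ("exhaustive", "seeded"):
            raise ValueError(f"unknown engine {engine!r}")
        self.library = library
        self.params = params
        self.engine = engine
        self.min_query_length = min_query_length
        self._index = KmerIndex(library, k) if engine == "seeded" else None

    def search(self, read_id: str, sequence: str) -> HitSet:
        if self.engine == "seeded":
            assert self._index is not None
            return seeded_top_hits(
                read_id,
                sequence,
                self.library,
                self.params,
                k=self._index.k,
                index=self._index,
                min_query_length=self.min_query_length,
            )
        return top_hits(
            read_id,
            sequence,
            self.library,
            self.params,
            min_query_length=self.min_query_length,
        )
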