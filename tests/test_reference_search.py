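"""Alignment scoring, bit scores and top-hit search (both engines)."""

import math

import numpy as np
import pytest

from honeyforage.formats_io import ReferenceLibrary, Taxon
from honeyforage.reference_search import (
    AlignmentParams,
    KmerIndex,
    SearchEngine,
    bit_score,
    local_align_score,
    seeded_top_hits,
    top_hits,
)
from honeyforage.synthetic_data import (
    SimulationConfig,
    TruthMixture,
    simulate_reads,
    simulate_reference,
)


def sw_oracle(a: str, b: str) -> float:
    """Independent Smith-Waterman DP (match +1, mismatch -2, gap -2/base)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = 1.0 if a[i - 1] == b[j - 1] else -2.0
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, H[i - 1, j] - 2.0,
                          H[i, j - 1] - 2.0)
            best = max(best, H[i, j])
    return best


class TestLocalAlignScore:
    def test_perfect_match_scores_length(self):
        seq = "ACGT" * 25
        assert local_align_score(seq, seq) == 100.0

    def test_trailing_mismatch_trimmed_by_local_alignment(self):
        # best local alignment keeps the first three matching bases
        assert local_align_score("ACGT", "ACGA") == 3.0

    def test_disjoint_alphabets_floor_at_zero(self):
        assert local_align_score("AAAA", "GGGG") == 0.0

    def test_agrees_with_independent_dp_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            a = "".join(rng.choice(list("ACGT"), rng.integers(5, 40)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(5, 40)))
            assert local_align_score(a, b) == sw_oracle(a, b)

    def test_score_is_symmetric(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 30))
            b = "".join(rng.choice(list("ACGT"), 25))
            assert local_align_score(a, b) == local_align_score(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align_score("", "ACGT")


class TestBitScore:
    def test_unit_transform(self):
        params = AlignmentParams(lam=math.log(2.0), K=1.0)
        assert bit_score(10, params) == pytest.approx(10.0)

    def test_default_formula(self):
        p = AlignmentParams()
        expected = (1.28 * 100 - math.log(0.46)) / math.log(2)
        assert bit_score(100, p) == pytest.approx(expected)

    def test_strictly_monotone(self):
        p = AlignmentParams()
        scores = [0, 1, 5, 50, 500]
        bits = [bit_score(s, p) for s in scores]
        assert bits == sorted(bits)
        assert len(set(bits)) == len(bits)


def tiny_library():
    return ReferenceLibrary(
        [
            ("r1", "ACGTACGTACGTACGTACGTACGT", Taxon("A a", "A", "Aceae")),
            ("r2", "ACGTACGTACGTACGTACGTACGT", Taxon("A b", "A", "Aceae")),
            ("r3", "TTTTGGGGCCCCAAAATTTTGGGG", Taxon("B b", "B", "Bceae")),
        ]
    )


class TestTopHits:
    def test_single_top_hit_when_one_reference_matches(self):
        lib = tiny_library()
        hits = top_hits("q", "TTTTGGGGCCCCAAAATTTTGGGG", lib)
        assert hits.top_hit_ids == ["r3"]

    def test_identical_references_tie(self):
        lib = tiny_library()
        hits = top_hits("q", "ACGTACGTACGTACGTACGTACGT", lib)
        assert hits.top_hit_ids == ["r1", "r2"]

    def test_short_query_skipped_with_reason(self):
        hits = top_hits("q", "ACG", tiny_library())
        assert hits.top_hit_ids == []
        assert hits.reason == "query_too_short"

    def test_unrelated_sequence_never_changes_top_set(self):
        """Adding a reference changes an existing top-hit set only if it
        reaches the current top score."""
        rng = np.random.default_rng(10)
        lib = simulate_reference(
            SimulationConfig(n_families=2, genera_per_family=2, species_per_genus=1,
                             amplicon_length=80, read_length=40, seed=2)
        )
        query = lib.entries[0][1]
        base = top_hits("q", query, lib)
        for _ in range(5):
            extra = "".join(rng.choice(list("ACGT"), 80))
            bigger = ReferenceLibrary(
                lib.entries + [("extra", extra, Taxon("X x", "X", "Xceae"))]
            )
            new = top_hits("q", query, bigger)
            extra_score = local_align_score(query, extra)
            if extra_score < base.top_score:
                assert new.top_hit_ids == base.top_hit_ids
            else:
                assert set(base.top_hit_ids) <= set(new.top_hit_ids)


class TestOptionalFilters:
    def test_coverage_filter_drops_partial_matches(self):
        lib = ReferenceLibrary(
            [
                ("full", "ACGTACGTACGTACGTACGTACGT", Taxon("A a", "A", "Aceae")),
                ("half", "ACGTACGTACGTTTTTCCCCGGGG", Taxon("B b", "B", "Bceae")),
            ]
        )
        query = "ACGTACGTACGTACGTACGTACGT"
        default = top_hits("q", query, lib)
        assert {h.seq_id for h in default.hits} == {"full", "half"}
        params = AlignmentParams(min_query_coverage=0.9)
        filtered = top_hits("q", query, lib, params=params)
        assert {h.seq_id for h in filtered.hits} == {"full"}

    def test_identity_filter_drops_divergent_matches(self):
        lib = ReferenceLibrary(
            [
                ("exact", "ACGTACGTACGTACGTACGTACGT", Taxon("A a", "A", "Aceae")),
                ("noisy", "ACGTACGAACGTACCTACGTAGGT", Taxon("B b", "B", "Bceae")),
            ]
        )
        query = "ACGTACGTACGTACGTACGTACGT"
        params = AlignmentParams(min_identity=0.99)
        filtered = top_hits("q", query, lib, params=params)
        assert {h.seq_id for h in filtered.hits} == {"exact"}

    def test_invalid_filter_range_rejected(self):
        with pytest.raises(ValueError, match="min_identity"):
            AlignmentParams(min_identity=1.5)


class TestSeededTopHits:
    def test_error_free_read_matches_exhaustive(self, small_reference):
        query = small_reference.entries[3][1]
        exact = top_hits("q", query, small_reference)
        seeded = seeded_top_hits("q", query, small_reference)
        assert seeded.top_hit_ids == exact.top_hit_ids
        assert seeded.heuristic

    def test_no_shared_kmer_gives_empty_hitset(self):
        lib = tiny_library()
        index = KmerIndex(lib, k=11)
        hits = seeded_top_hits("q", "A" * 30, lib, k=11, index=index)
        assert hits.top_hit_ids == []
        assert hits.reason == "no_kmer_match"

    def test_agreement_with_exhaustive_on_noisy_reads(self, small_reference):
        """Seeded and exhaustive engines return identical top-hit sets on
        reads simulated at 0.5% per-base error."""
        taxa = sorted({t.species for t in small_reference.taxonomy.values()})[:4]
        mix = {t: 0.25 for t in taxa}
        truth = TruthMixture("s", mix, n_read_pairs=30, error_rate=0.005, seed=21)
        batch, _ = simulate_reads(small_reference, truth)
        exhaustive = SearchEngine(small_reference, engine="exhaustive")
        seeded = SearchEngine(small_reference, engine="seeded", k=11)
        for read_id, s1, _, _, _ in batch.pairs:
            assert (
                seeded.search(read_id, s1).top_hit_ids
                == exhaustive.search(read_id, s1).top_hit_ids
            )

    def test_mismatched_index_rejected(self, small_reference):
        index = KmerIndex(small_reference, k=11)
        with pytest.raises(ValueError, match="does not match"):
            seeded_top_hits("q", "ACGT" * 10, small_reference, k=13, index=index)
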