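"""Generator properties: hierarchy, determinism, truth recovery."""

from itertools import combinations

import numpy as np
import pytest

from honeyforage.formats_io import SurveyZone
from honeyforage.read_processing import merge_pair
from honeyforage.survey_analysis import density_per_area
from honeyforage.synthetic_data import (
    SimulationConfig,
    TruthMixture,
    default_study,
    geometric_mixture,
    simulate_reads,
    simulate_reference,
    simulate_survey,
)


def pairwise_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestSimulateReference:
    def test_counts(self):
        lib = simulate_reference(
            SimulationConfig(n_families=2, genera_per_family=2, species_per_genus=2)
        )
        assert len(lib) == 8
        assert len({t.family for t in lib.taxonomy.values()}) == 2
        assert len({t.genus for t in lib.taxonomy.values()}) == 4

    def test_zero_species_divergence_gives_identical_congeners(self):
        lib = simulate_reference(
            SimulationConfig(
                n_families=2, genera_per_family=2, species_per_genus=3, d_species=0.0
            )
        )
        by_genus = {}
        for _, seq, tax in lib.entries:
            by_genus.setdefault(tax.genus, []).append(seq)
        for seqs in by_genus.values():
            assert len(set(seqs)) == 1

    def test_hierarchical_identity_structure(self):
        """Congeneric pairs are more similar than confamilial pairs, which
        beat cross-family pairs (brute-force identity over all pairs)."""
        lib = simulate_reference(SimulationConfig(seed=3))
        within_genus, within_family, between = [], [], []
        for (_, s1, t1), (_, s2, t2) in combinations(lib.entries, 2):
            ident = pairwise_identity(s1, s2)
            if t1.genus == t2.genus:
                within_genus.append(ident)
            elif t1.family == t2.family:
                within_family.append(ident)
            else:
                between.append(ident)
        assert np.mean(within_genus) > np.mean(within_family) > np.mean(between)

    def test_invalid_divergence_ordering_rejected(self):
        with pytest.raises(ValueError, match="d_family > d_genus"):
            SimulationConfig(d_family=0.05, d_genus=0.08)

    def test_deterministic_given_seed(self):
        a = simulate_reference(SimulationConfig(seed=5))
        b = simulate_reference(SimulationConfig(seed=5))
        assert a.entries == b.entries


class TestSimulateReads:
    def test_error_free_pairs_reconstruct_amplicons(self, small_reference):
        truth = TruthMixture(
            "s", {"Genus01a sp1": 1.0}, n_read_pairs=20, error_rate=0.0, seed=1
        )
        batch, _ = simulate_reads(small_reference, truth)
        amplicons = {
            seq
            for _, seq, tax in small_reference.entries
            if tax.species == "Genus01a sp1"
        }
        for read_id, s1, q1, s2, q2 in batch.pairs:
            merged = merge_pair(s1, q1, s2, q2, read_id=read_id)
            assert merged.sequence in amplicons
            assert merged.mismatches_in_overlap == 0

    def test_realized_counts_match_independent_replay(self, small_reference):
        taxa = {"Genus01a sp1": 0.6, "Genus02a sp1": 0.4}
        truth = TruthMixture("s", taxa, n_read_pairs=1000, error_rate=0.005, seed=42)
        _, table = simulate_reads(small_reference, truth)
        # replay the taxon draw with the same seed, independently
        rng = np.random.default_rng(42)
        labels = sorted(taxa)
        probs = np.array([taxa[t] for t in labels])
        draws = rng.choice(len(labels), size=1000, p=probs / probs.sum())
        expected = {t: int((draws == i).sum()) for i, t in enumerate(labels)}
        realized = dict(zip(table["taxon"], table["realized_pairs"]))
        assert realized == expected

    def test_unresolvable_taxon_rejected(self, small_reference):
        truth = TruthMixture("s", {"Nosuchus plantus": 1.0}, n_read_pairs=10)
        with pytest.raises(ValueError, match="absent from reference"):
            simulate_reads(small_reference, truth)

    def test_same_seed_byte_identical(self, small_reference):
        truth = TruthMixture("s", {"Genus01a sp1": 1.0}, n_read_pairs=30, seed=9)
        b1, _ = simulate_reads(small_reference, truth)
        b2, _ = simulate_reads(small_reference, truth)
        assert b1.pairs == b2.pairs

    def test_realized_mixture_converges_to_truth(self, small_reference):
        """At 10,000 pairs the realized mixture deviates < 2 percentage
        points from the truth (binomial bound, seeded)."""
        taxa = geometric_mixture(
            ["Genus01a sp1", "Genus01b sp1", "Genus02a sp1", "Genus03a sp1"], r=0.5
        )
        truth = TruthMixture("s", taxa, n_read_pairs=10_000, error_rate=0.0, seed=13)
        _, table = simulate_reads(small_reference, truth)
        realized = table["realized_pairs"] / table["realized_pairs"].sum()
        dev = np.abs(realized - table["true_proportion"])
        assert dev.max() < 0.02


class TestTruthMixture:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            TruthMixture("s", {"A": 0.5, "B": 0.4})

    def test_geometric_mixture_profile(self):
        mix = geometric_mixture(["a", "b", "c"], r=0.5)
        assert mix["a"] == pytest.approx(4 / 7)
        assert sum(mix.values()) == pytest.approx(1.0)


class TestSimulateSurvey:
    ZONES = [
        SurveyZone("Z1", 100.0, "G"),
        SurveyZone("Z2", 250.0, "W"),
        SurveyZone("Z3", 400.0, "H"),
    ]

    def test_flowering_window_respected(self):
        windows = {"Early plant": {"April"}, "Late plant": {"May"}}
        survey = simulate_survey(self.ZONES, windows, occupancy=1.0, seed=1)
        april = set().union(
            *(survey.records.get((z.zone_id, "April"), set()) for z in self.ZONES)
        )
        may = set().union(
            *(survey.records.get((z.zone_id, "May"), set()) for z in self.ZONES)
        )
        assert april == {"early plant"}
        assert may == {"late plant"}

    def test_full_occupancy_covers_total_area(self):
        windows = {"Everywhere plant": {"April", "May"}}
        survey = simulate_survey(self.ZONES, windows, occupancy=1.0, seed=1)
        assert survey.total_area == 750.0
        for month in ("April", "May"):
            zones_with = {
                z for (z, m), taxa in survey.records.items() if m == month and taxa
            }
            assert zones_with == {"Z1", "Z2", "Z3"}

    def test_density_equals_hand_recount(self):
        rng_windows = {
            f"Plant {i} sp": ({"April"} if i % 2 else {"April", "May"})
            for i in range(12)
        }
        survey = simulate_survey(self.ZONES, rng_windows, occupancy=0.5, seed=4)
        density = density_per_area(survey, "April")
        for zone in self.ZONES:
            taxa = survey.records.get((zone.zone_id, "April"), set())
            genera = {t.split()[0] for t in taxa}
            assert density[zone.zone_id] == pytest.approx(len(genera) / zone.area_m2)


class TestDefaultStudy:
    def test_study_shape(self, small_study):
        assert len(small_study.mixtures) == 6  # 3 hives x 2 months
        assert {m.sample_id.split("_")[0] for m in small_study.mixtures} == {
            "A",
            "B",
            "C",
        }
        for mixture in small_study.mixtures:
            assert len(mixture.proportions) == 7  # taxa in flower that month
            assert sum(mixture.proportions.values()) == pytest.approx(1.0)

    def test_honey_taxa_on_checklist_and_in_survey(self, small_study):
        for mixture in small_study.mixtures:
            for taxon in mixture.proportions:
                genus = taxon.split()[0]
                assert small_study.checklist.contains_genus(genus)
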