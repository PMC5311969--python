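"""Synthetic reference libraries, floral surveys and honey read sets.

The generator emulates the statistical structure the analysis assumes so
the whole pipeline runs and validates with known ground truth:

* a *hierarchical* reference library — congeneric sequences are more
  similar than confamilial ones, which are more similar than sequences
  from different families (per-site substitution from a common ancestor
  at rank-specific rates ``d_family > d_genus > d_species``);
* honey samples as known mixtures of reference taxa: per read pair a
  taxon is drawn by its true proportion, the full amplicon is taken from
  one of its reference sequences, and the pair is emitted as the first
  ``read_length`` bases plus the reverse complement of the last
  ``read_length`` bases, with independent per-base substitution errors;
* a two-month floral survey over zones with areas and habitat classes,
  where each taxon flowers only inside its flowering window.

Everything is deterministic given the seed; rerunning with the same seed
produces byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    ChecklistRow,
    FloralSurvey,
    ReadPairBatch,
    ReferenceLibrary,
    RegionalChecklist,
    SurveyZone,
    Taxon,
    normalize_label,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimulationConfig:
    """Geometry and divergence structure of a simulated reference library.

    ``d_family``/``d_genus``/``d_species`` are per-site substitution
    probabilities applied when deriving, respectively, each family
    ancestor from the root, each genus ancestor from its family ancestor,
    and each species from its genus ancestor. They must be strictly
    ordered ``d_family > d_genus > d_species`` and lie in (0, 0.5) so the
    library is hierarchical: within-genus identity > within-family
    identity > between-family identity.

    The amplicon default (550 bp) exceeds the pipeline's >450 bp merged
    length filter, so perfect merges of 2 x ``read_length`` reads pass it.
    """

    n_families: int = 6
    genera_per_family: int = 2
    species_per_genus: int = 2
    amplicon_length: int = 550
    read_length: int = 300
    d_family: float = 0.20
    d_genus: float = 0.08
    d_species: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.genera_per_family, self.species_per_genus) < 1:
            raise ValueError("library dimensions must be >= 1")
        for name in ("d_family", "d_genus"):
            v = getattr(self, name)
            if not 0.0 < v < 0.5:
                raise ValueError(f"{name}={v} outside (0, 0.5)")
        if not 0.0 <= self.d_species < 0.5:
            # zero is the limit case of identical congeneric species
            raise ValueError(f"d_species={self.d_species} outside [0, 0.5)")
        if not self.d_family > self.d_genus > self.d_species:
            raise ValueError("divergences must satisfy d_family > d_genus > d_species")
        if self.amplicon_length < self.read_length:
            raise ValueError("amplicon shorter than read length")


@dataclass
class TruthMixture:
    """Known composition of one simulated honey sample."""

    sample_id: str
    proportions: dict[str, float]  # taxon label -> true fraction
    n_read_pairs: int = 10_000
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_read_pairs < 1:
            raise ValueError("n_read_pairs must be >= 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate outside [0, 1)")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, p: float) -> np.ndarray:
    """Substitute each site with probability *p*, uniformly over the 3 others."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size:
        # shift by 1..3 mod 4 guarantees a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_reference(config: SimulationConfig) -> ReferenceLibrary:
    """Simulate a hierarchical barcode reference library.

    One root sequence is drawn uniformly over {A,C,G,T}; each family
    ancestor derives from it at rate ``d_family``, each genus ancestor
    from its family ancestor at ``d_genus``, and each species sequence
    from its genus ancestor at ``d_species``. Names follow a transparent
    scheme (``Family01``, ``Genus01a``, ``Genus01a sp1``).
    """
    rng = np.random.default_rng(config.seed)
    root = _random_sequence(rng, config.amplicon_length)
    entries: list[tuple[str, str, Taxon]] = []
    ref_idx = 0
    for f in range(config.n_families):
        family = f"Family{f + 1:02d}"
        fam_seq = _mutate(rng, root, config.d_family)
        for g in range(config.genera_per_family):
            genus = f"Genus{f + 1:02d}{chr(ord('a') + g)}"
            gen_seq = _mutate(rng, fam_seq, config.d_genus)
            for s in range(config.species_per_genus):
                species = f"{genus} sp{s + 1}"
                sp_seq = _mutate(rng, gen_seq, config.d_species)
                ref_idx += 1
                entries.append(
                    (f"ref{ref_idx:03d}", _to_str(sp_seq), Taxon(species, genus, family))
                )
    return ReferenceLibrary(entries)


def simulate_survey(
    zones: Sequence[SurveyZone],
    flowering_windows: Mapping[str, set[str]],
    months: Sequence[str] = ("April", "May"),
    zone_assignment: Mapping[str, set[str]] | None = None,
    occupancy: float = 0.4,
    seed: int = 0,
) -> FloralSurvey:
    """Simulate a floral survey.

    A taxon appears in a zone-month record iff the month is in its
    flowering window and the zone is in its assigned zone set. Zone sets
    may be supplied explicitly; otherwise each zone is included
    independently with probability *occupancy* (at least one zone is
    always assigned).
    """
    rng = np.random.default_rng(seed)
    zone_ids = [z.zone_id for z in zones]
    assignment: dict[str, set[str]] = {}
    for taxon in flowering_windows:
        if zone_assignment is not None and taxon in zone_assignment:
            assignment[taxon] = set(zone_assignment[taxon])
        else:
            mask = rng.random(len(zone_ids)) < occupancy
            chosen = {zid for zid, m in zip(zone_ids, mask) if m}
            if not chosen:
                chosen = {zone_ids[int(rng.integers(len(zone_ids)))]}
            assignment[taxon] = chosen
    records: dict[tuple[str, str], set[str]] = {}
    for taxon, window in flowering_windows.items():
        for month in months:
            if month not in window:
                continue
            for zid in assignment[taxon]:
                records.setdefault((zid, month), set()).add(normalize_label(taxon))
    return FloralSurvey(
        zones={z.zone_id: z for z in zones},
        records=records,
        months=tuple(months),
    )


def make_zones(
    n_zones: int = 20,
    total_area_m2: float = 342_000.0,
    habitat_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[SurveyZone]:
    """Draw survey zones with Dirichlet-distributed areas summing exactly
    to *total_area_m2* and habitat classes in the given proportions.

    Defaults mirror a garden-scale site: 34.2 ha split into 20 zones over
    grassland (G), woodland/hedgerow (W) and horticultural planting (H).
    """
    if habitat_fractions is None:
        habitat_fractions = {"G": 0.55, "W": 0.20, "H": 0.25}
    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.full(n_zones, 5.0))
    areas = np.round(shares * total_area_m2, 1)
    areas[-1] = round(total_area_m2 - areas[:-1].sum(), 1)
    habitats = list(habitat_fractions)
    counts = [int(round(habitat_fractions[h] * n_zones)) for h in habitats]
    while sum(counts) < n_zones:
        counts[0] += 1
    while sum(counts) > n_zones:
        counts[int(np.argmax(counts))] -= 1
    habitat_list = [h for h, c in zip(habitats, counts) for _ in range(c)]
    rng.shuffle(habitat_list)
    return [
        SurveyZone(f"Z{i + 1:02d}", float(a), h)
        for i, (a, h) in enumerate(zip(areas, habitat_list))
    ]


def _resolve_taxon(reference: ReferenceLibrary, taxon: str) -> list[int]:
    """Indices of reference entries matching a species or genus label."""
    norm = normalize_label(taxon)
    idx = [
        i
        for i, (_, _, tax) in enumerate(reference.entries)
        if normalize_label(tax.species) == norm or normalize_label(tax.genus) == norm
    ]
    return idx


def quality_for_error_rate(error_rate: float) -> int:
    """Constant Phred score whose implied error probability matches
    *error_rate* (capped at Q40 for error-free simulation)."""
    if error_rate <= 0:
        return 40
    return int(min(40, max(2, round(-10.0 * math.log10(error_rate)))))


def simulate_reads(
    reference: ReferenceLibrary,
    truth: TruthMixture,
    read_length: int = 300,
) -> tuple[ReadPairBatch, pd.DataFrame]:
    """Simulate one sample's paired reads from a truth mixture.

    Returns the batch plus a realized-count table (taxon, true_proportion,
    realized_pairs). Mate 1 is the amplicon's first ``read_length`` bases,
    mate 2 the reverse complement of its last ``read_length`` bases; each
    base is substituted independently with probability ``error_rate``
    (uniform over the three alternatives). Per-base qualities are the
    constant Phred score matching the error rate in expectation.
    """
    taxa = sorted(truth.proportions)
    resolved = {t: _resolve_taxon(reference, t) for t in taxa}
    unresolved = [t for t in taxa if not resolved[t]]
    if unresolved:
        raise ValueError(f"truth taxa absent from reference: {unresolved}")
    for _, seq, _ in reference.entries:
        if len(seq) < read_length:
            raise ValueError(
                f"amplicon length {len(seq)} shorter than read length {read_length}"
            )
    rng = np.random.default_rng(truth.seed)
    probs = np.array([truth.proportions[t] for t in taxa])
    probs = probs / probs.sum()
    draws = rng.choice(len(taxa), size=truth.n_read_pairs, p=probs)
    qual = quality_for_error_rate(truth.error_rate)
    pairs = []
    realized = dict.fromkeys(taxa, 0)
    for i, ti in enumerate(draws):
        taxon = taxa[ti]
        realized[taxon] += 1
        ref_i = resolved[taxon][int(rng.integers(len(resolved[taxon])))]
        amplicon = reference.entries[ref_i][1]
        mate1 = amplicon[:read_length]
        mate2 = reverse_complement(amplicon[-read_length:])
        if truth.error_rate > 0:
            mate1 = _apply_errors(rng, mate1, truth.error_rate)
            mate2 = _apply_errors(rng, mate2, truth.error_rate)
        read_id = f"{truth.sample_id}.{i + 1}"
        pairs.append((read_id, mate1, [qual] * read_length, mate2, [qual] * read_length))
    table = pd.DataFrame(
        {
            "sample_id": truth.sample_id,
            "taxon": taxa,
            "true_proportion": [truth.proportions[t] for t in taxa],
            "realized_pairs": [realized[t] for t in taxa],
        }
    )
    return ReadPairBatch(pairs), table


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    codes = np.frombuffer(seq.encode(), dtype="S1")
    lookup = {b: i for i, b in enumerate(_BASES)}
    arr = np.array([lookup.get(b, 0) for b in codes], dtype=np.int64)
    return _to_str(_mutate(rng, arr, rate))


def geometric_mixture(taxa: Sequence[str], r: float = 0.5) -> dict[str, float]:
    """Few-dominant-taxa profile: p_i proportional to r**i, normalized.

    Mimics honey compositions where most reads come from a handful of
    taxa and a long tail contributes the rest.
    """
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    weights = np.array([r**i for i in range(len(taxa))])
    weights = weights / weights.sum()
    return {t: float(w) for t, w in zip(taxa, weights)}


# ---------------------------------------------------------------------------
# Bundled demonstration study (3 hives x 2 months)
# ---------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """A complete simulated foraging study with known ground truth."""

    config: SimulationConfig
    reference: ReferenceLibrary
    checklist: RegionalChecklist
    survey: FloralSurvey
    mixtures: list[TruthMixture]
    flowering_windows: dict[str, set[str]]
    hives: tuple[str, ...]
    months: tuple[str, ...]
    truth_by_month: dict[str, dict[str, float]] = field(default_factory=dict)


def default_study(
    seed: int = 0,
    n_read_pairs: int = 10_000,
    error_rate: float = 0.005,
    n_taxa: int = 10,
    mixture_ratio: float = 0.5,
    config: SimulationConfig | None = None,
) -> StudyDesign:
    """Build the default simulated study: 3 hives sampled in April and May.

    Ten honey taxa (one species per genus) follow a geometric abundance
    profile; per month only the taxa inside their flowering window occur
    in the honey (4 flower in both months, 3 in April only, 3 in May
    only), so phenology concordance holds by construction. All hives in a
    month share the same true mixture; sampling noise alone separates
    them. A background flora of survey-only genera makes availability far
    exceed use, as in real landscapes.
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    if config is None:
        config = SimulationConfig(seed=child[0])
    reference = simulate_reference(config)
    genera = sorted({t.genus for t in reference.taxonomy.values()})
    if n_taxa > len(genera):
        raise ValueError("not enough genera in the reference for the mixture")
    honey_taxa = [f"{g} sp1" for g in genera[:n_taxa]]

    months = ("April", "May")
    windows: dict[str, set[str]] = {}
    for i, taxon in enumerate(honey_taxa):
        if i < 4:
            windows[taxon] = {"April", "May"}
        elif i < 7:
            windows[taxon] = {"April"}
        else:
            windows[taxon] = {"May"}
    # reference genera not used in honey still flower (available, unused)
    for g in genera[n_taxa:]:
        windows[f"{g} sp1"] = {"April", "May"}
    # background flora: survey-only genera, split across windows
    rng = np.random.default_rng(child[1])
    for b in range(40):
        label = f"Background{b + 1:02d} flora"
        windows[label] = {months[int(rng.integers(2))]} if b % 2 else set(months)

    zones = make_zones(seed=child[2])
    survey = simulate_survey(zones, windows, months=months, seed=child[3])

    # checklist covers every honey taxon (genus level) + background flora;
    # majors lean native/both, minors horticultural, mirroring hedgerow-vs-
    # garden structure
    rows: dict[str, ChecklistRow] = {}
    for i, g in enumerate(genera):
        status = "native" if i % 2 == 0 else "both"
        if i >= n_taxa:
            status = "horticulture"
        rows[normalize_label(g)] = ChecklistRow(
            status=status,
            habitat="W" if i % 3 == 0 else ("G" if i % 3 == 1 else "H"),
            growth_form="W" if i % 2 == 0 else "H",
            use=frozenset("NP"),
        )
    for b in range(40):
        rows[normalize_label(f"Background{b + 1:02d}")] = ChecklistRow(
            status="horticulture", habitat="H", growth_form="H", use=frozenset("N")
        )
    checklist = RegionalChecklist(rows)

    hives = ("A", "B", "C")
    mixtures: list[TruthMixture] = []
    truth_by_month: dict[str, dict[str, float]] = {}
    for m_i, month in enumerate(months):
        in_flower = [t for t in honey_taxa if month in windows[t]]
        mix = geometric_mixture(in_flower, r=mixture_ratio)
        truth_by_month[month] = mix
        for h_i, hive in enumerate(hives):
            mixtures.append(
                TruthMixture(
                    sample_id=f"{hive}_{month}",
                    proportions=mix,
                    n_read_pairs=n_read_pairs,
                    error_rate=error_rate,
                    seed=(child[4] + 97 * h_i + 31 * m_i) % (2**31),
                )
            )
    return StudyDesign(
        config=config,
        reference=reference,
        checklist=checklist,
        survey=survey,
        mixtures=mixtures,
        flowering_windows=windows,
        hives=hives,
        months=months,
        truth_by_month=truth_by_month,
    )


def write_truth_table(path: str | Path, mixtures: Sequence[TruthMixture]) -> None:
    rows = [
        (m.sample_id, taxon, prop)
        for m in mixtures
        for taxon, prop in sorted(m.proportions.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "taxon", "true_proportion"]).to_csv(
        path, sep="\t", index=False
    )
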