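"""Lowest-common-rank taxonomic assignment and the regional checklist filter.

The tied top hits of a read are collapsed to distinct (species, genus,
family) triples and assigned at the finest rank they all share:

* one species            -> rank ``species`` (that species)
* several species, one genus  -> rank ``genus``
* several genera, one family  -> rank ``family``; the contributing genera
  are recorded and rendered as a sorted slash-joined group label (e.g.
  ``Cotoneaster/Crataegus/Malus``), the way multi-genus rosaceous groups
  appear in honey metabarcoding results
* several families       -> ``unknown``

Reads with no hits at all also count as ``unknown`` in the identifiable
fraction. After assignment, taxa absent from the regional checklist are
removed (a family-rank group is retained if *any* constituent genus is
on the checklist) and their reads leave the downstream denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats_io import RegionalChecklist, Taxon, genus_of
from .reference_search import HitSet

RANKS = ("species", "genus", "family", "unknown")


@dataclass
class Assignment:
    read_id: str
    rank: str  # species | genus | family | unknown
    label: str
    family: str = ""  # family name when rank is species/genus/family
    genus_group: frozenset[str] = field(default_factory=frozenset)

    @property
    def identifiable(self) -> bool:
        return self.rank != "unknown"


def group_label(genera: Iterable[str]) -> str:
    """Canonical label for a multi-genus family group: sorted, slash-joined."""
    return "/".join(sorted(genera))


def assign(hit_set: HitSet, taxonomy: Mapping[str, Taxon]) -> Assignment:
    """Assign one read from its tied top hits.

    Raises :class:`KeyError` if a hit's seq_id is missing from the
    taxonomy (library and taxonomy are desynchronized — a hard error).
    """
    top = hit_set.top_hit_ids
    if not top:
        return Assignment(hit_set.read_id, "unknown", "unassigned")
    missing = [sid for sid in top if sid not in taxonomy]
    if missing:
        raise KeyError(
            f"seq_ids {missing} in hits for read {hit_set.read_id!r} "
            "are absent from the taxonomy table"
        )
    triples = {taxonomy[sid] for sid in top}
    families = {t.family for t in triples}
    if len(families) > 1:
        return Assignment(hit_set.read_id, "unknown", "unknown")
    family = next(iter(families))
    genera = {t.genus for t in triples}
    if len(genera) > 1:
        return Assignment(
            hit_set.read_id,
            "family",
            group_label(genera),
            family=family,
            genus_group=frozenset(genera),
        )
    genus = next(iter(genera))
    species = {t.species for t in triples}
    if len(species) == 1 and next(iter(species)):
        return Assignment(
            hit_set.read_id,
            "species",
            next(iter(species)),
            family=family,
            genus_group=frozenset({genus}),
        )
    # several species of one genus, or a genus-level reference
    return Assignment(
        hit_set.read_id, "genus", genus, family=family, genus_group=frozenset({genus})
    )


def identifiable_fraction(assignments: Iterable[Assignment]) -> float:
    """Percentage of reads identifiable to family, genus or species level."""
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no assignments")
    ok = sum(1 for a in assignments if a.identifiable)
    return 100.0 * ok / len(assignments)


def taxon_counts(assignments: Iterable[Assignment]) -> dict[str, int]:
    """Read counts per assigned taxon label, excluding unknown reads."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.identifiable:
            counts[a.label] = counts.get(a.label, 0) + 1
    return counts


def _constituent_genera(label: str) -> list[str]:
    """Genera named by a taxon label (family groups list every genus)."""
    return [genus_of(part) for part in label.split("/") if part.strip()]


def on_checklist(label: str, checklist: RegionalChecklist) -> bool:
    """Whether a honey taxon label is covered by the regional checklist.

    Species labels match their own entry or their genus entry; a
    family-rank group is retained if any constituent genus appears.
    """
    if label in checklist:
        return True
    return any(checklist.contains_genus(g) for g in _constituent_genera(label))


def regional_filter(
    counts: Mapping[str, int], checklist: RegionalChecklist
) -> tuple[dict[str, int], dict[str, int]]:
    """Split taxon counts into checklist-retained and removed.

    Removed taxa leave the downstream denominators entirely; the removed
    mapping (label -> read count) serves as the removal log.
    """
    retained: dict[str, int] = {}
    removed: dict[str, int] = {}
    for label, n in counts.items():
        if on_checklist(label, checklist):
            retained[label] = n
        else:
            removed[label] = n
    return retained, removed
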