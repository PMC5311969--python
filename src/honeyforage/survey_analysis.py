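"""Floral availability and use-versus-availability analysis.

From the zone x month survey records this module derives:

* availability — the deduplicated sets of genera and families in flower
  per month (and for the months combined);
* flowering density — distinct genera in flower per m² of each zone;
* use versus availability — how many of the available genera/families
  the honey taxa represent, as integer percentages rounded half away
  from zero (the rule that reproduces published count/percent pairs such
  as 18/80 -> 23% and 45/360 -> 13%);
* area of occurrence — summed area of the zones where a taxon flowered
  in a month, an approximate distribution measure;
* phenology concordance — whether each honey taxon was detected only in
  months when it was in flower (detections outside the window are
  flagged as carry-over, e.g. autumn-flowering ivy in spring honey).

Honey labels and survey lists are matched at genus level after
normalization: species-level honey labels match their genus's survey
records and multi-genus family groups contribute every constituent
genus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import FloralSurvey, genus_of, normalize_label
from .composition import SampleComposition

COMBINED = "combined"


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, halves away from zero (12.5 -> 13)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(n_used: int, n_available: int) -> int:
    """Integer use percentage with half-away-from-zero rounding."""
    if n_available == 0:
        raise ValueError("n_available is zero")
    return round_half_away_from_zero(100.0 * n_used / n_available)


@dataclass
class Availability:
    """Per month (and combined), the sets of genera/families in flower.

    ``genus_to_family`` maps normalized genus -> family for the taxa the
    reference or checklist knows; survey genera without a mapping count
    as their own singleton family so family availability stays a
    complete count.
    """

    genera: dict[str, set[str]] = field(default_factory=dict)
    families: dict[str, set[str]] = field(default_factory=dict)
    genus_to_family: dict[str, str] = field(default_factory=dict)

    def in_flower(self, rank: str, month: str) -> set[str]:
        table = {"genus": self.genera, "family": self.families}[rank]
        return table[month]

    def family_of(self, genus: str) -> str:
        norm = normalize_label(genus)
        return self.genus_to_family.get(norm, norm)


def availability(
    survey: FloralSurvey, genus_to_family: Mapping[str, str] | None = None
) -> Availability:
    """Deduplicated genera and families in flower per month and combined."""
    g2f = {
        normalize_label(g): f for g, f in (genus_to_family or {}).items()
    }
    avail = Availability(genus_to_family=g2f)
    for month in survey.months + (COMBINED,):
        avail.genera[month] = set()
        avail.families[month] = set()
    for (_, month), taxa in survey.records.items():
        for taxon in taxa:
            genus = genus_of(taxon)
            family = g2f.get(genus, genus)
            for key in (month, COMBINED):
                avail.genera[key].add(genus)
                avail.families[key].add(family)
    return avail


def density_per_area(survey: FloralSurvey, month: str) -> dict[str, float]:
    """Distinct genera in flower per m² for every zone in one month."""
    out: dict[str, float] = {}
    for zone_id, zone in survey.zones.items():
        if zone.area_m2 <= 0:
            raise ValueError(f"zone {zone_id!r} has non-positive area")
        taxa = survey.records.get((zone_id, month), set())
        genera = {genus_of(t) for t in taxa}
        out[zone_id] = len(genera) / zone.area_m2
    return out


def expand_honey_genera(honey_labels: Iterable[str]) -> set[str]:
    """Normalized genera named by honey taxon labels (groups expand)."""
    genera: set[str] = set()
    for label in honey_labels:
        for part in label.split("/"):
            g = genus_of(normalize_label(part))
            if g:
                genera.add(g)
    return genera


def use_vs_availability(
    honey_labels: Iterable[str],
    avail: Availability,
    rank: str,
    month: str,
) -> tuple[int, int, int]:
    """(n_used, n_available, rounded %) at genus or family rank.

    Honey labels are expanded to the requested rank: family groups
    contribute each constituent genus at genus rank and their (mapped)
    families at family rank. n_used is the deduplicated count of
    expanded honey taxa at that rank.
    """
    if rank not in ("genus", "family"):
        raise ValueError(f"rank must be 'genus' or 'family', got {rank!r}")
    genera = expand_honey_genera(honey_labels)
    used = genera if rank == "genus" else {avail.family_of(g) for g in genera}
    n_available = len(avail.in_flower(rank, month))
    n_used = len(used)
    return n_used, n_available, percent(n_used, n_available)


def area_of_occurrence(survey: FloralSurvey, taxon: str, month: str) -> float:
    """Summed area (m²) of zones where the taxon flowered that month.

    Matching is at genus level; a multi-genus group label uses the union
    of its constituent genera's zones.
    """
    genera = expand_honey_genera([taxon])
    total = 0.0
    for zone_id, zone in survey.zones.items():
        recorded = survey.records.get((zone_id, month), set())
        if any(genus_of(t) in genera for t in recorded):
            total += zone.area_m2
    return total


def phenology_concordance(
    compositions_by_month: Mapping[str, SampleComposition],
    avail: Availability,
    detection_threshold_pct: float = 0.0,
) -> pd.DataFrame:
    """Compare per-month honey detections with flowering windows.

    A taxon is *concordant* when every month it was detected in honey
    (proportion > threshold) is a month its genus was recorded in
    flower; otherwise it is flagged as a carry-over candidate.
    """
    months = sorted(compositions_by_month)
    if len(months) < 2:
        raise ValueError("need at least two months to assess phenology")
    all_labels = sorted(
        {t for comp in compositions_by_month.values() for t in comp.proportions}
    )
    rows = []
    for label in all_labels:
        genera = expand_honey_genera([label])
        row: dict[str, object] = {"taxon": label}
        concordant = True
        for month in months:
            flowering = bool(genera & avail.in_flower("genus", month))
            prop = compositions_by_month[month].proportions.get(label, 0.0)
            detected = prop > detection_threshold_pct
            row[f"in_flower_{month}"] = flowering
            row[f"prop_{month}"] = prop
            if detected and not flowering:
                concordant = False
        row["concordant"] = concordant
        row["carry_over"] = not concordant
        rows.append(row)
    return pd.DataFrame(rows)


def availability_table(
    avail: Availability,
    honey_labels_by_month: Mapping[str, Iterable[str]],
    months: Sequence[str],
) -> pd.DataFrame:
    """Use-versus-availability table over months plus the combined column."""
    combined_labels = sorted(
        {t for labels in honey_labels_by_month.values() for t in labels}
    )
    rows = []
    for rank in ("family", "genus"):
        for month in list(months) + [COMBINED]:
            labels = (
                combined_labels
                if month == COMBINED
                else honey_labels_by_month.get(month, [])
            )
            n_used, n_avail, pct = use_vs_availability(labels, avail, rank, month)
            rows.append((rank, month, n_avail, n_used, pct))
    return pd.DataFrame(
        rows, columns=["rank", "month", "n_in_flower", "n_in_honey", "pct_used"]
    )
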