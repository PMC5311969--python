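"""Per-sample plant composition: proportions, major/minor forage classes,
taxon richness and Simpson's diversity.

Read counts per taxon (checklist-retained, identifiable reads only) are
converted to percentages of the sample's retained reads — the study's
semi-quantitative measure of DNA abundance. Taxa above 1% of reads are
*major* forage, the rest *minor*. Diversity is the Gini-Simpson
complement D = 1 - sum(p_i^2) over taxon fractions, which is 0 for a
single taxon and approaches 1 - 1/k for k evenly used taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

MAJOR_THRESHOLD_PCT = 1.0
POOL_MODES = ("pooled-counts", "mean-of-proportions")


@dataclass
class SampleComposition:
    """Taxon -> (read count, proportion %) for one hive x month sample.

    Pooled compositions use ``hive_id="all"``; mean-of-proportions pooling
    has no meaningful read counts and leaves ``counts`` empty.
    """

    hive_id: str
    month: str
    counts: dict[str, int] = field(default_factory=dict)
    _proportions: dict[str, float] | None = None

    @property
    def proportions(self) -> dict[str, float]:
        """Taxon -> percentage of retained reads (sums to 100)."""
        if self._proportions is not None:
            return self._proportions
        total = sum(self.counts.values())
        if total == 0:
            raise ValueError(
                f"sample {self.hive_id}/{self.month}: zero retained reads"
            )
        return {t: 100.0 * n / total for t, n in self.counts.items()}

    @property
    def fractions(self) -> dict[str, float]:
        return {t: p / 100.0 for t, p in self.proportions.items()}

    @property
    def taxa(self) -> set[str]:
        return {t for t, p in self.proportions.items() if p > 0}


def proportions(
    taxon_counts: Mapping[str, int], hive_id: str = "", month: str = ""
) -> SampleComposition:
    """Build a composition from retained per-taxon read counts."""
    if sum(taxon_counts.values()) == 0:
        raise ValueError(f"sample {hive_id}/{month}: zero retained reads")
    return SampleComposition(hive_id, month, counts=dict(taxon_counts))


def pool_samples(
    compositions: Sequence[SampleComposition], mode: str = "pooled-counts"
) -> SampleComposition:
    """Pool several samples into one composition.

    ``pooled-counts`` (default) sums read counts and recomputes
    proportions — each read weighs the same, as in pooled "% of all DNA
    reads" summaries. ``mean-of-proportions`` averages the per-sample
    percentages unweighted, so each sample weighs the same.
    """
    if not compositions:
        raise ValueError("no compositions to pool")
    if mode not in POOL_MODES:
        raise ValueError(f"unknown pooling mode {mode!r}")
    months = {c.month for c in compositions}
    month = next(iter(months)) if len(months) == 1 else "combined"
    if mode == "pooled-counts":
        counts: dict[str, int] = {}
        for c in compositions:
            for t, n in c.counts.items():
                counts[t] = counts.get(t, 0) + n
        return SampleComposition("all", month, counts=counts)
    taxa = sorted({t for c in compositions for t in c.proportions})
    mean = {
        t: sum(c.proportions.get(t, 0.0) for c in compositions) / len(compositions)
        for t in taxa
    }
    return SampleComposition("all", month, counts={}, _proportions=mean)


def classify_major_minor(
    composition: SampleComposition, threshold: float = MAJOR_THRESHOLD_PCT
) -> dict[str, str]:
    """Partition taxa into major (> threshold %) and minor forage."""
    return {
        t: "major" if p > threshold else "minor"
        for t, p in composition.proportions.items()
    }


def richness(composition: SampleComposition) -> int:
    """Number of taxa present (non-zero proportion)."""
    return len(composition.taxa)


def simpson_diversity(composition: SampleComposition) -> float:
    """Gini-Simpson diversity D = 1 - sum(p_i^2), p_i as fractions."""
    fr = composition.fractions
    total = sum(fr.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {100 * total}%, expected 100%")
    return 1.0 - sum(p * p for p in fr.values())


def composition_table(
    compositions: Iterable[SampleComposition],
    major_threshold: float = MAJOR_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Long-format table (hive, month, taxon, count, proportion, class)."""
    rows = []
    for comp in compositions:
        classes = classify_major_minor(comp, major_threshold)
        for taxon in sorted(comp.proportions):
            rows.append(
                (
                    comp.hive_id,
                    comp.month,
                    taxon,
                    comp.counts.get(taxon, pd.NA),
                    comp.proportions[taxon],
                    classes[taxon],
                )
            )
    return pd.DataFrame(
        rows, columns=["hive", "month", "taxon", "count", "proportion", "class"]
    )
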