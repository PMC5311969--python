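"""Readers and writers for every file the pipeline touches.

All downstream modules operate on the in-memory types defined here:
a :class:`ReferenceLibrary` (rbcL-style barcode sequences with three-rank
taxonomy), a :class:`RegionalChecklist` (which taxa occur in the study
region, with status/habitat/growth-form/use codes), a
:class:`ReadPairBatch` (paired-end amplicon reads) and a
:class:`FloralSurvey` (zone x month lists of taxa in flower).

On-disk formats are the plain-text formats of the field: FASTA and paired
FASTQ (Phred+33 by default) via Biopython, and tab-separated UTF-8 tables
with a header row for taxonomy, checklist, survey and result tables.
Loading is order-stable and writers round-trip exactly.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

#: Survey months recognised by default (the study season).
DEFAULT_MONTHS = ("April", "May")

STATUS_CODES = frozenset({"native", "both", "horticulture"})
HABITAT_CODES = frozenset({"W", "G", "H"})
GROWTH_CODES = frozenset({"W", "H", "B"})
USE_CODES = frozenset({"N", "P"})


class FormatError(ValueError):
    """A file failed syntactic or semantic validation."""


class Taxon(NamedTuple):
    """Three-rank taxonomy of a reference sequence.

    ``species`` may be empty for a genus-level reference; ``genus`` and
    ``family`` are always non-empty.
    """

    species: str
    genus: str
    family: str


def normalize_label(label: str) -> str:
    """Canonical form for taxon-label matching: collapse whitespace, casefold.

    Survey lists and checklists are hand-curated, so matching is
    case-insensitive after whitespace normalization.
    """
    return " ".join(label.split()).casefold()


def genus_of(label: str) -> str:
    """First whitespace-delimited token of a taxon label (its genus)."""
    parts = label.split()
    return parts[0] if parts else ""


@dataclass
class ReferenceLibrary:
    """Barcode reference sequences plus their taxonomy.

    Invariants: seq_ids unique; sequences non-empty over {A,C,G,T,N};
    every entry has non-empty genus and family.
    """

    entries: list[tuple[str, str, Taxon]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq_id, seq, tax in self.entries:
            if seq_id in seen:
                raise FormatError(f"duplicate reference seq_id {seq_id!r}")
            seen.add(seq_id)
            if not seq:
                raise FormatError(f"empty sequence for {seq_id!r}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"illegal characters {sorted(bad)} in sequence {seq_id!r}"
                )
            if not tax.genus or not tax.family:
                raise FormatError(f"{seq_id!r}: genus and family must be non-empty")

    @property
    def seq_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def taxonomy(self) -> dict[str, Taxon]:
        return {seq_id: tax for seq_id, _, tax in self.entries}

    def sequence(self, seq_id: str) -> str:
        for sid, seq, _ in self.entries:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ChecklistRow:
    status: str  # native | both | horticulture
    habitat: str  # W | G | H
    growth_form: str  # W | H | B
    use: frozenset[str]  # subset of {N, P}


@dataclass
class RegionalChecklist:
    """Regional plant checklist used to filter honey identifications.

    Keys are normalized taxon labels; genus-level membership is exposed via
    :meth:`contains_genus` so species-level honey labels match their genus.
    """

    rows: dict[str, ChecklistRow] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, row in self.rows.items():
            if row.status not in STATUS_CODES:
                raise FormatError(f"{label!r}: bad status {row.status!r}")
            if row.habitat not in HABITAT_CODES:
                raise FormatError(f"{label!r}: bad habitat {row.habitat!r}")
            if row.growth_form not in GROWTH_CODES:
                raise FormatError(f"{label!r}: bad growth form {row.growth_form!r}")
            if not set(row.use) <= USE_CODES:
                raise FormatError(f"{label!r}: bad use codes {sorted(row.use)}")
        self._genera = {genus_of(label) for label in self.rows}

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in self.rows

    def contains_genus(self, genus: str) -> bool:
        return normalize_label(genus) in self._genera

    def lookup(self, label: str) -> ChecklistRow | None:
        norm = normalize_label(label)
        if norm in self.rows:
            return self.rows[norm]
        # species-level label falls back to its genus entry
        return self.rows.get(genus_of(norm))


@dataclass
class ReadPairBatch:
    """Paired-end reads; qualities are per-base integer Phred scores."""

    pairs: list[tuple[str, str, list[int], str, list[int]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for read_id, s1, q1, s2, q2 in self.pairs:
            if len(s1) != len(q1) or len(s2) != len(q2):
                raise FormatError(f"{read_id!r}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SurveyZone:
    zone_id: str
    area_m2: float
    habitat: str


@dataclass
class FloralSurvey:
    """Floral survey: per zone x month, the set of taxa recorded in flower."""

    zones: dict[str, SurveyZone]
    records: dict[tuple[str, str], set[str]]  # (zone_id, month) -> taxa
    months: tuple[str, ...] = DEFAULT_MONTHS

    @property
    def total_area(self) -> float:
        return sum(z.area_m2 for z in self.zones.values())


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ordered ``(seq_id, uppercase sequence)`` pairs.

    The seq_id is the first whitespace-delimited token of the header.
    Raises :class:`FormatError` (naming the offending line) on empty
    sequences or characters outside {A,C,G,T,N}.
    """
    records: list[tuple[str, str]] = []
    header_line: dict[str, int] = {}
    with _open_text(path) as handle:
        text = handle.read()
    lineno = 0
    current: str | None = None
    for line in text.splitlines():
        lineno += 1
        if line.startswith(">"):
            current = line[1:].split()[0] if line[1:].split() else ""
            if not current:
                raise FormatError(f"{path}: malformed FASTA header at line {lineno}")
            header_line[current] = lineno
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        line = header_line.get(rec.id, 0)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r} (line {line})")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: illegal characters {sorted(bad)} in record "
                f"{rec.id!r} starting at line {line}"
            )
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in records
    ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(seqrecords, handle, "fasta")


def _id_stem(read_id: str) -> str:
    """Strip a trailing mate tag (``/1``, ``/2``) from a read id."""
    if len(read_id) > 1 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path, quality_offset: int = 33
) -> ReadPairBatch:
    """Load paired FASTQ files, pairing mates by position.

    Mate ids must share a stem (ignoring ``/1`` / ``/2`` suffixes) and the
    files must contain the same number of records.
    """
    fmt = {33: "fastq", 64: "fastq-illumina"}.get(quality_offset)
    if fmt is None:
        raise ValueError(f"unsupported quality offset {quality_offset}")
    with _open_text(path_r1) as h1, _open_text(path_r2) as h2:
        recs1 = list(SeqIO.parse(h1, fmt))
        recs2 = list(SeqIO.parse(h2, fmt))
    if len(recs1) != len(recs2):
        raise FormatError(
            f"record-count mismatch: {path_r1} has {len(recs1)} records, "
            f"{path_r2} has {len(recs2)}"
        )
    pairs = []
    for i, (r1, r2) in enumerate(zip(recs1, recs2)):
        if _id_stem(r1.id) != _id_stem(r2.id):
            raise FormatError(
                f"read id mismatch at record {i}: {r1.id!r} vs {r2.id!r}"
            )
        pairs.append(
            (
                _id_stem(r1.id),
                str(r1.seq).upper(),
                list(r1.letter_annotations["phred_quality"]),
                str(r2.seq).upper(),
                list(r2.letter_annotations["phred_quality"]),
            )
        )
    return ReadPairBatch(pairs)


def write_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path, batch: ReadPairBatch
) -> None:
    recs1, recs2 = [], []
    for read_id, s1, q1, s2, q2 in batch.pairs:
        r1 = SeqRecord(Seq(s1), id=f"{read_id}/1", description="")
        r1.letter_annotations["phred_quality"] = list(q1)
        r2 = SeqRecord(Seq(s2), id=f"{read_id}/2", description="")
        r2.letter_annotations["phred_quality"] = list(q2)
        recs1.append(r1)
        recs2.append(r2)
    with _open_text(path_r1, "wt") as h1:
        SeqIO.write(recs1, h1, "fastq")
    with _open_text(path_r2, "wt") as h2:
        SeqIO.write(recs2, h2, "fastq")


# ---------------------------------------------------------------------------
# Tabular formats (TSV, UTF-8, header row)
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_taxonomy_table(path: str | Path) -> dict[str, Taxon]:
    """Read a seq_id -> (species, genus, family) table.

    Columns: ``seq_id``, ``species``, ``genus``, ``family``. Species may be
    empty (genus-level reference); genus and family may not. Duplicate
    seq_ids are rejected.
    """
    df = _read_tsv(path, ["seq_id", "species", "genus", "family"])
    mapping: dict[str, Taxon] = {}
    for i, row in df.iterrows():
        seq_id = row["seq_id"].strip()
        if seq_id in mapping:
            raise FormatError(f"{path}: duplicate seq_id {seq_id!r} at row {i}")
        tax = Taxon(row["species"].strip(), row["genus"].strip(), row["family"].strip())
        if not tax.genus or not tax.family:
            raise FormatError(
                f"{path}: row {i} ({seq_id!r}): genus and family are required"
            )
        mapping[seq_id] = tax
    return mapping


def write_taxonomy_table(path: str | Path, taxonomy: Mapping[str, Taxon]) -> None:
    df = pd.DataFrame(
        [(sid, t.species, t.genus, t.family) for sid, t in taxonomy.items()],
        columns=["seq_id", "species", "genus", "family"],
    )
    df.to_csv(path, sep="\t", index=False)


def load_reference(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> ReferenceLibrary:
    """Load and cross-validate a reference FASTA plus its taxonomy table."""
    records = read_fasta(fasta_path)
    taxonomy = read_taxonomy_table(taxonomy_path)
    missing = [sid for sid, _ in records if sid not in taxonomy]
    if missing:
        raise FormatError(
            f"seq_ids present in {fasta_path} but absent from "
            f"{taxonomy_path}: {missing}"
        )
    return ReferenceLibrary(
        [(sid, seq, taxonomy[sid]) for sid, seq in records]
    )


def read_checklist(path: str | Path) -> RegionalChecklist:
    """Read the regional checklist.

    Columns: ``taxon``, ``status``, ``habitat``, ``growth_form``, ``use``
    (use is a string over {N,P}, e.g. ``NP`` or ``P``).
    """
    df = _read_tsv(path, ["taxon", "status", "habitat", "growth_form", "use"])
    rows: dict[str, ChecklistRow] = {}
    for i, row in df.iterrows():
        label = normalize_label(row["taxon"])
        if not label:
            raise FormatError(f"{path}: empty taxon label at row {i}")
        if label in rows:
            raise FormatError(f"{path}: duplicate taxon {row['taxon']!r} at row {i}")
        rows[label] = ChecklistRow(
            status=row["status"].strip(),
            habitat=row["habitat"].strip(),
            growth_form=row["growth_form"].strip(),
            use=frozenset(row["use"].strip()),
        )
    return RegionalChecklist(rows)


def write_checklist(path: str | Path, checklist: RegionalChecklist) -> None:
    df = pd.DataFrame(
        [
            (label, r.status, r.habitat, r.growth_form, "".join(sorted(r.use)))
            for label, r in checklist.rows.items()
        ],
        columns=["taxon", "status", "habitat", "growth_form", "use"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_survey_tables(
    path: str | Path, months: Sequence[str] = DEFAULT_MONTHS
) -> FloralSurvey:
    """Read the floral survey table.

    Columns: ``zone_id``, ``area_m2``, ``habitat_class``, ``month``,
    ``taxon``. Zones are deduplicated and must have a consistent area and
    habitat wherever they appear; months outside *months* are rejected;
    taxa repeated within one zone-month are stored once (set semantics).
    """
    df = _read_tsv(path, ["zone_id", "area_m2", "habitat_class", "month", "taxon"])
    zones: dict[str, SurveyZone] = {}
    records: dict[tuple[str, str], set[str]] = {}
    for i, row in df.iterrows():
        zone_id = row["zone_id"].strip()
        try:
            area = float(row["area_m2"])
        except ValueError as exc:
            raise FormatError(f"{path}: bad area at row {i}: {row['area_m2']!r}") from exc
        habitat = row["habitat_class"].strip()
        month = row["month"].strip()
        if month not in months:
            raise FormatError(
                f"{path}: unknown month {month!r} at row {i} (expected {list(months)})"
            )
        zone = SurveyZone(zone_id, area, habitat)
        if zone_id in zones and zones[zone_id] != zone:
            raise FormatError(
                f"{path}: zone {zone_id!r} listed with conflicting "
                f"area/habitat ({zones[zone_id]} vs {zone})"
            )
        zones[zone_id] = zone
        taxon = normalize_label(row["taxon"])
        if taxon:
            records.setdefault((zone_id, month), set()).add(taxon)
    return FloralSurvey(zones=zones, records=records, months=tuple(months))


def write_survey_table(path: str | Path, survey: FloralSurvey) -> None:
    rows = []
    for (zone_id, month), taxa in sorted(survey.records.items()):
        zone = survey.zones[zone_id]
        for taxon in sorted(taxa):
            rows.append((zone_id, zone.area_m2, zone.habitat, month, taxon))
    df = pd.DataFrame(
        rows, columns=["zone_id", "area_m2", "habitat_class", "month", "taxon"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_proportion_table(path: str | Path) -> pd.DataFrame:
    """Read a per-hive proportion table (long format).

    Columns: ``hive``, ``month``, ``taxon``, ``proportion`` (percent).
    Used to feed externally published per-sample compositions (e.g. a
    study's supplementary table) into the diversity/concordance statistics.
    """
    df = _read_tsv(path, ["hive", "month", "taxon", "proportion"])
    df["proportion"] = df["proportion"].astype(float)
    return df
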