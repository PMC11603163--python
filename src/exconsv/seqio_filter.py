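"""Sequence I/O, dataset quality control, and reference coordinate mapping.

The analysis starts from candidate RNA-polymerase largest subunits (NRPB1 /
NRPD1 / NRPE1 homologs) gathered by similarity search.  Genuine largest
subunits are long (> 900 aa) and carry the invariant catalytic metal-A
aspartate motif DFDGD; :func:`qc_filter` applies exactly those two criteria.

Downstream conservation work happens on a single master multiple sequence
alignment that contains every family, with one designated reference row (the
Arabidopsis NRPD1 ortholog in the original study).  Per-position results are
reported in *reference residue coordinates*, so :func:`build_column_map`
provides the bidirectional map between reference residue numbers (1-based,
counting non-gap characters of the reference row) and alignment columns
(1-based).

FASTA header dialect: ``>id key=value key=value``.  Recognised keys are
``species=``, ``group=`` (one of B1, D1, E1, DE_like, unknown) and
``clade=``; unknown keys are kept in :attr:`ProteinRecord.tags`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

#: The 20 standard amino acids.
AA20 = "ARNDCQEGHILKMFPSTWYV"

#: Characters allowed in an ungapped protein sequence (X = unknown residue).
VALID_RESIDUES = frozenset(AA20) | {"X"}

#: Gap character used in alignments.
GAP = "-"

#: Recognised paralog-group labels (B1 = Pol II, D1 = Pol IV, E1 = Pol V,
#: DE_like = the bryophyte NRPD1/NRPE1-like fourth cluster).
GROUP_LABELS = ("B1", "D1", "E1", "DE_like", "unknown")


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate subunit sequence with identity and provenance."""

    id: str
    sequence: str
    species: str = ""
    group_hint: Optional[str] = None
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if GAP in self.sequence:
            raise ValueError(f"record {self.id!r}: sequence contains gap characters")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)}"
            )
        if self.group_hint is not None and self.group_hint not in GROUP_LABELS:
            raise ValueError(
                f"record {self.id!r}: unknown group hint {self.group_hint!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_bryophyte(self) -> bool:
        """Whether this record is flagged as bryophyte-derived.

        Taken from a ``clade=bryophyte`` header tag, or implied by a DE_like
        group hint (the bryophyte NRPD1/NRPE1-like cluster).
        """
        return self.tags.get("clade") == "bryophyte" or self.group_hint == "DE_like"


@dataclass(frozen=True)
class QCReport:
    """Outcome of the dataset QC filter for one record."""

    record_id: str
    passed: bool
    length: int
    has_metal_a: bool
    fail_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.fail_reasons) == 0):
            raise ValueError("passed must be true iff fail_reasons is empty")


@dataclass
class AlignmentSet:
    """A master MSA with per-row group labels and a designated reference row."""

    rows: list[tuple[str, str]]
    group_of: dict[str, str]
    reference_id: str
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate row id {dup!r} in alignment")
        first_id, first_seq = self.rows[0]
        self.n_columns = len(first_seq)
        for rid, seq in self.rows:
            if len(seq) != self.n_columns:
                raise ValueError(
                    "ragged alignment: row "
                    f"{rid!r} has length {len(seq)}, expected {self.n_columns} "
                    f"(length of {first_id!r})"
                )
        if self.reference_id not in ids:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")
        for rid in ids:
            if rid not in self.group_of:
                raise ValueError(f"row {rid!r} has no group label")

    def row(self, record_id: str) -> str:
        for rid, seq in self.rows:
            if rid == record_id:
                return seq
        raise KeyError(record_id)

    def group_rows(self, group: str) -> list[str]:
        """Gapped sequences of all rows labelled ``group`` (row order)."""
        return [seq for rid, seq in self.rows if self.group_of[rid] == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for rid, _ in self.rows:
            g = self.group_of[rid]
            if g not in seen:
                seen.append(g)
        return seen


@dataclass(frozen=True)
class ColumnMap:
    """Bidirectional map between reference residues and alignment columns.

    ``ref_to_col[i]`` is the alignment column (1-based) holding the i-th
    non-gap character of the reference row; columns where the reference row
    holds a gap are absent from ``col_to_ref``.
    """

    ref_to_col: dict[int, int]
    col_to_ref: dict[int, int]
    ref_length: int


@dataclass(frozen=True)
class MaskSpec:
    """Masked intervals in reference coordinates, 1-based inclusive."""

    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.intervals))
        for a, b in ivs:
            if a < 1 or b < a:
                raise ValueError(f"invalid mask interval ({a}, {b})")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 <= b0:
                raise ValueError("mask intervals overlap")
        object.__setattr__(self, "intervals", ivs)

    def validate(self, ref_length: int) -> None:
        for a, b in self.intervals:
            if b > ref_length:
                raise ValueError(
                    f"mask interval ({a}, {b}) exceeds reference length {ref_length}"
                )

    def covers(self, ref_pos: int) -> bool:
        return any(a <= ref_pos <= b for a, b in self.intervals)


def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    parts = description.split()
    rid = parts[0]
    tags: dict[str, str] = {}
    for token in parts[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            tags[key] = value
    return rid, tags


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an unaligned protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased and terminal ``*`` stop characters stripped.
    Duplicate ids, an empty file, gaps, or residue characters outside the
    standard 20 + X are hard errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid, tags = _parse_header(entry.description)
        if rid in seen:
            raise ValueError(f"duplicate sequence id {rid!r} in {path}")
        seen.add(rid)
        seq = str(entry.seq).upper().rstrip("*")
        bad = sorted(set(seq) - VALID_RESIDUES)
        if bad:
            raise ValueError(
                f"record {rid!r} in {path}: non-amino-acid characters {bad}"
            )
        records.append(
            ProteinRecord(
                id=rid,
                sequence=seq,
                species=tags.pop("species", ""),
                group_hint=tags.pop("group", None),
                tags=tags,
            )
        )
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def qc_filter(
    records: Sequence[ProteinRecord],
    min_length: int = 900,
    metal_a_motif: str = "DFDGD",
) -> tuple[list[ProteinRecord], list[QCReport]]:
    """Apply the dataset QC criteria: length strictly over ``min_length``
    amino acids and presence of the catalytic metal-A motif.

    Returns the passing records (input order preserved) and one
    :class:`QCReport` per input record.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    passing: list[ProteinRecord] = []
    reports: list[QCReport] = []
    for rec in records:
        reasons: list[str] = []
        if len(rec) <= min_length:
            reasons.append("length")
        has_metal = metal_a_motif in rec.sequence
        if not has_metal:
            reasons.append("metal_a")
        passed = not reasons
        if passed:
            passing.append(rec)
        reports.append(
            QCReport(
                record_id=rec.id,
                passed=passed,
                length=len(rec),
                has_metal_a=has_metal,
                fail_reasons=tuple(reasons),
            )
        )
    return passing, reports


def read_aligned_fasta(
    path: str | Path,
    groups: Optional[Mapping[str, str]] = None,
    reference_id: str = "",
) -> AlignmentSet:
    """Read a gapped FASTA into an :class:`AlignmentSet`.

    ``groups`` maps row id to group label; when omitted, ``group=`` header
    tags must be present on every row.  The reference row must be present.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    tag_groups: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rid, tags = _parse_header(entry.description)
        rows.append((rid, str(entry.seq).upper()))
        if "group" in tags:
            tag_groups[rid] = tags["group"]
    if not rows:
        raise ValueError(f"no FASTA entries found in {path}")
    group_of = dict(groups) if groups is not None else tag_groups
    return AlignmentSet(rows=rows, group_of=group_of, reference_id=reference_id)


def build_column_map(aln: AlignmentSet) -> ColumnMap:
    """Map reference residue numbers to alignment columns (both 1-based)."""
    ref_row = aln.row(aln.reference_id)
    ref_to_col: dict[int, int] = {}
    col_to_ref: dict[int, int] = {}
    i = 0
    for col, ch in enumerate(ref_row, start=1):
        if ch != GAP:
            i += 1
            ref_to_col[i] = col
            col_to_ref[col] = i
    if i == 0:
        raise ValueError(f"reference row {aln.reference_id!r} is entirely gaps")
    return ColumnMap(ref_to_col=ref_to_col, col_to_ref=col_to_ref, ref_length=i)


def ungapped_reference(aln: AlignmentSet) -> str:
    """The reference sequence with gaps removed."""
    return aln.row(aln.reference_id).replace(GAP, "")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (id, group label) into a mapping."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"group map {path}: malformed line {row!r}")
            out[row[0]] = row[1]
    return out


def read_mask(path: str | Path) -> MaskSpec:
    """Read a 2-column TSV of (start, end) intervals, 1-based inclusive."""
    intervals: list[tuple[int, int]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"mask file {path}: malformed line {row!r}")
            intervals.append((int(row[0]), int(row[1])))
    return MaskSpec(intervals=tuple(intervals))


def alignment_from_records(
    records: Iterable[ProteinRecord],
    group_of: Mapping[str, str],
    reference_id: str,
) -> AlignmentSet:
    """Build an AlignmentSet from equal-length ungapped records.

    Convenience for pre-aligned inputs such as simulator output.
    """
    rows = [(rec.id, rec.sequence) for rec in records]
    return AlignmentSet(rows=rows, group_of=dict(group_of), reference_id=reference_id)
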