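"""Sequence/annotation input-output and validated glycoprotein records.

External files use UniProt-style 1-based inclusive coordinates; everything
internal is 0-based half-open.  A :class:`GlycoproteinRecord` merges a protein
sequence with its experimentally annotated N-glycosite positions and its
(externally predicted) disorder intervals, and derives a per-residue locale
label in {ORDERED, DISORDERED}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: Canonical amino-acid alphabet, alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: 'X' (unknown residue) is tolerated in sequences but excluded from
#: composition counts downstream.
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class Locale(str, Enum):
    """Structural locale of a residue position."""

    ORDERED = "ORDERED"
    DISORDERED = "DISORDERED"


class AnnotationError(ValueError):
    """Raised when sequences or annotation tables violate the input contract."""


@dataclass(frozen=True)
class GlycoproteinRecord:
    """One glycoprotein: sequence + glycosites + disorder intervals.

    Parameters
    ----------
    protein_id
        Unique identifier (FASTA header token).
    sequence
        Upper-case amino-acid sequence over the 20-letter alphabet plus 'X'.
    glycosites
        0-based positions of experimentally annotated N-glycosites; each must
        point at an asparagine.
    disorder_intervals
        Sorted, pairwise-disjoint 0-based half-open ``(start, end)`` intervals.
    """

    protein_id: str
    sequence: str
    glycosites: frozenset[int] = frozenset()
    disorder_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise AnnotationError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise AnnotationError(
                f"{self.protein_id}: illegal residue(s) {sorted(bad)}"
            )
        for p in self.glycosites:
            if not 0 <= p < n:
                raise AnnotationError(
                    f"{self.protein_id}: glycosite position {p + 1} out of bounds "
                    f"(length {n})"
                )
            if self.sequence[p] != "N":
                raise AnnotationError(
                    f"{self.protein_id}: glycosite at position {p + 1} is "
                    f"'{self.sequence[p]}', not 'N'"
                )
        prev_end = -1
        for s, e in self.disorder_intervals:
            if not (0 <= s < e <= n):
                raise AnnotationError(
                    f"{self.protein_id}: disorder interval [{s}, {e}) out of bounds"
                )
            if s <= prev_end:
                raise AnnotationError(
                    f"{self.protein_id}: disorder intervals not sorted/disjoint"
                )
            prev_end = e - 1

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def disorder_mask(self) -> np.ndarray:
        """Boolean array, True where the residue lies in a disorder interval."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for s, e in self.disorder_intervals:
            mask[s:e] = True
        mask.flags.writeable = False
        return mask

    @property
    def locale_labels(self) -> list[Locale]:
        return [
            Locale.DISORDERED if d else Locale.ORDERED for d in self.disorder_mask
        ]

    def region_positions(self, region: Locale) -> np.ndarray:
        """0-based positions belonging to ``region``."""
        want = self.disorder_mask if region is Locale.DISORDERED else ~self.disorder_mask
        return np.flatnonzero(want)


@dataclass
class AnnotationTables:
    """Raw annotation rows as read from disk (1-based, verbatim)."""

    glycosite_rows: list[tuple[str, int]] = field(default_factory=list)
    disorder_rows: list[tuple[str, int, int]] = field(default_factory=list)


def locale_of(record: GlycoproteinRecord, position: int) -> Locale:
    """Locale of a 0-based residue position."""
    if not 0 <= position < len(record.sequence):
        raise AnnotationError(
            f"{record.protein_id}: position {position} out of bounds"
        )
    return Locale.DISORDERED if record.disorder_mask[position] else Locale.ORDERED


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``, order preserved.

    Sequences are upper-cased; a single terminal '*' (stop) is stripped.
    Empty files, duplicate ids and illegal residue characters are errors.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AnnotationError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        for i, ch in enumerate(seq):
            if ch not in VALID_RESIDUES:
                raise AnnotationError(
                    f"{rec.id}: illegal residue {ch!r} at position {i + 1}"
                )
        out.append((rec.id, seq))
    if not out:
        raise AnnotationError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | Path, sequences: list[tuple[str, str]]) -> None:
    """Write ``[(id, sequence), ...]`` as FASTA (inverse of :func:`read_fasta`)."""
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_tsv_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Return (header, [(line_number, fields), ...]) skipping '#' comments."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None:
        raise AnnotationError(f"{path}: empty table (no header)")
    return header, rows


def _int_field(value: str, path: str | Path, lineno: int, name: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise AnnotationError(
            f"{path}, line {lineno}: non-integer {name} {value!r}"
        ) from None


def read_annotation_tables(
    glyco_path: str | Path, disorder_path: str | Path
) -> AnnotationTables:
    """Read the glycosite and disorder TSV tables (1-based coordinates).

    Expected headers: ``protein_id<TAB>position`` and
    ``protein_id<TAB>start<TAB>end`` (end inclusive).  An empty disorder table
    (header only) is valid and means fully ordered proteins.
    """
    tables = AnnotationTables()

    header, rows = _read_tsv_rows(glyco_path)
    if header[:2] != ["protein_id", "position"]:
        raise AnnotationError(
            f"{glyco_path}: expected header 'protein_id\\tposition', got {header}"
        )
    for lineno, fields in rows:
        if len(fields) < 2:
            raise AnnotationError(f"{glyco_path}, line {lineno}: too few columns")
        pos = _int_field(fields[1], glyco_path, lineno, "position")
        if pos < 1:
            raise AnnotationError(
                f"{glyco_path}, line {lineno}: position must be >= 1 (1-based)"
            )
        tables.glycosite_rows.append((fields[0], pos))

    header, rows = _read_tsv_rows(disorder_path)
    if header[:3] != ["protein_id", "start", "end"]:
        raise AnnotationError(
            f"{disorder_path}: expected header 'protein_id\\tstart\\tend', got {header}"
        )
    for lineno, fields in rows:
        if len(fields) < 3:
            raise AnnotationError(f"{disorder_path}, line {lineno}: too few columns")
        start = _int_field(fields[1], disorder_path, lineno, "start")
        end = _int_field(fields[2], disorder_path, lineno, "end")
        if start < 1:
            raise AnnotationError(
                f"{disorder_path}, line {lineno}: start must be >= 1 (1-based)"
            )
        if start > end:
            raise AnnotationError(
                f"{disorder_path}, line {lineno}: start {start} > end {end}"
            )
        tables.disorder_rows.append((fields[0], start, end))

    return tables


def merge_intervals(
    intervals: list[tuple[int, int]], protein_id: str = ""
) -> tuple[tuple[int, int], ...]:
    """Merge overlapping/adjacent 0-based half-open intervals, sorted.

    Overlap is common in meta-predictor exports; merging is logged as a
    warning rather than rejected.
    """
    if not intervals:
        return ()
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    n_merged = 0
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:  # overlapping or adjacent
            merged[-1][1] = max(merged[-1][1], e)
            n_merged += 1
        else:
            merged.append([s, e])
    if n_merged:
        log.warning(
            "%s: merged %d overlapping/adjacent disorder interval(s)",
            protein_id or "<intervals>",
            n_merged,
        )
    return tuple((s, e) for s, e in merged)


def assemble_records(
    sequences: list[tuple[str, str]], tables: AnnotationTables
) -> list[GlycoproteinRecord]:
    """Merge sequences and annotation tables into validated records.

    1-based inclusive table coordinates are converted to 0-based half-open.
    Output order follows the FASTA order; assembly is independent of table
    row order.
    """
    seq_by_id = dict(sequences)
    glyco: dict[str, set[int]] = {}
    for pid, pos1 in tables.glycosite_rows:
        if pid not in seq_by_id:
            raise AnnotationError(f"glycosite table id {pid!r} absent from FASTA")
        glyco.setdefault(pid, set()).add(pos1 - 1)
    dis: dict[str, list[tuple[int, int]]] = {}
    for pid, start1, end1 in tables.disorder_rows:
        if pid not in seq_by_id:
            raise AnnotationError(f"disorder table id {pid!r} absent from FASTA")
        dis.setdefault(pid, []).append((start1 - 1, end1))  # 1-based incl -> 0-based half-open

    records = []
    for pid, seq in sequences:
        intervals = merge_intervals(sorted(dis.get(pid, [])), pid)
        records.append(
            GlycoproteinRecord(
                protein_id=pid,
                sequence=seq,
                glycosites=frozenset(glyco.get(pid, set())),
                disorder_intervals=intervals,
            )
        )
    return records


def write_annotation_tables(
    records: list[GlycoproteinRecord],
    glyco_path: str | Path,
    disorder_path: str | Path,
) -> None:
    """Write records back to the 1-based TSV formats (inverse of assembly)."""
    with open(glyco_path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tposition\n")
        for rec in records:
            for p in sorted(rec.glycosites):
                fh.write(f"{rec.protein_id}\t{p + 1}\n")
    with open(disorder_path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tstart\tend\n")
        for rec in records:
            for s, e in rec.disorder_intervals:
                fh.write(f"{rec.protein_id}\t{s + 1}\t{e}\n")


def load_records(
    fasta_path: str | Path,
    glyco_path: str | Path,
    disorder_path: str | Path,
) -> list[GlycoproteinRecord]:
    """Convenience: read all three input files and assemble records."""
    return assemble_records(
        read_fasta(fasta_path), read_annotation_tables(glyco_path, disorder_path)
    )
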