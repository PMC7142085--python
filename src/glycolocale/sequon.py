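"""N-linked glycosylation sequon detection and X-residue classification.

The sequon is the tripeptide N-X-S/T with X any residue except proline
(proline kinks the backbone and abolishes glycan transfer).  Every overlapping
match is reported.  The X position is additionally classified into
(possibly overlapping) property classes — acidic, basic, hydrophobic,
hydrophilic, bulky, small — from an editable YAML table, since the identity
of X modulates glycosylation efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .io_annotation import AMINO_ACIDS, GlycoproteinRecord, Locale, locale_of

log = logging.getLogger(__name__)

X_CLASS_NAMES = ("acidic", "basic", "hydrophobic", "hydrophilic", "bulky", "small")


@dataclass(frozen=True)
class Sequon:
    """One N(X-P)S/T match within a protein."""

    protein_id: str
    n_position: int  # 0-based position of the Asn
    x_residue: str
    third_residue: str  # 'S' or 'T'
    locale: Locale  # locale of the Asn
    is_glycosite: bool
    spans_boundary: bool = False  # sequon straddles an order/disorder boundary


def load_x_classes(path=None) -> dict[str, frozenset[str]]:
    """Load the X-residue class definitions (default: packaged YAML config)."""
    if path is None:
        text = (
            resources.files("glycolocale.data")
            .joinpath("residue_classes.yaml")
            .read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    classes = {name: frozenset(raw[name]) for name in raw}
    for name, members in classes.items():
        unknown = members - set(AMINO_ACIDS)
        if unknown:
            raise ValueError(f"class {name!r} has non-standard residues {unknown}")
    return classes


_DEFAULT_CLASSES: dict[str, frozenset[str]] | None = None


def default_x_classes() -> dict[str, frozenset[str]]:
    global _DEFAULT_CLASSES
    if _DEFAULT_CLASSES is None:
        _DEFAULT_CLASSES = load_x_classes()
    return _DEFAULT_CLASSES


def classify_x(
    residue: str, classes: dict[str, frozenset[str]] | None = None
) -> set[str]:
    """Property classes of an X residue; empty set (logged) for non-standard."""
    if classes is None:
        classes = default_x_classes()
    if residue not in AMINO_ACIDS:
        log.debug("non-standard X residue %r: no class assigned", residue)
        return set()
    return {name for name, members in classes.items() if residue in members}


def scan_sequons(record: GlycoproteinRecord) -> list[Sequon]:
    """All N(X-P)S/T sequons of a record, sorted by Asn position.

    Overlapping sequons are all reported.  The sequon's locale is the locale
    of its Asn; a sequon whose three residues do not share one locale is
    flagged ``spans_boundary``.
    """
    seq = record.sequence
    mask = record.disorder_mask
    out: list[Sequon] = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST":
            out.append(
                Sequon(
                    protein_id=record.protein_id,
                    n_position=i,
                    x_residue=seq[i + 1],
                    third_residue=seq[i + 2],
                    locale=locale_of(record, i),
                    is_glycosite=i in record.glycosites,
                    spans_boundary=bool(
                        mask[i] != mask[i + 1] or mask[i] != mask[i + 2]
                    ),
                )
            )
    return out


def x_class_profile(
    records: list[GlycoproteinRecord],
    classes: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Per-region proportions of sequons whose X falls in each property class.

    Returns a DataFrame indexed by region (ORDERED, DISORDERED) with one
    column per class plus ``n_sequons``.  Classes overlap, so rows need not
    sum to 1.  A region with zero sequons yields an all-NA row (logged);
    zero sequons overall is an error.
    """
    if classes is None:
        classes = default_x_classes()
    sequons = [s for rec in records for s in scan_sequons(rec)]
    if not sequons:
        raise ValueError("no sequons in the cohort")
    rows = {}
    for region in (Locale.ORDERED, Locale.DISORDERED):
        in_region = [s for s in sequons if s.locale is region]
        if not in_region:
            log.warning("no sequons in %s region: NA profile row", region.value)
            rows[region.value] = {name: float("nan") for name in classes} | {
                "n_sequons": 0
            }
            continue
        row = {
            name: sum(s.x_residue in members for s in in_region) / len(in_region)
            for name, members in classes.items()
        }
        row["n_sequons"] = len(in_region)
        rows[region.value] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def sequon_asn_fraction(record: GlycoproteinRecord, region: Locale) -> float:
    """Fraction of a region's asparagines that start a sequon; NaN if none.

    Measures how often an Asn in ordered vs disordered sequence carries the
    minimal signature required for N-glycan conjugation.
    """
    positions = record.region_positions(region)
    asn = [p for p in positions if record.sequence[p] == "N"]
    if not asn:
        return float("nan")
    sequon_starts = {s.n_position for s in scan_sequons(record)}
    return sum(p in sequon_starts for p in asn) / len(asn)


def glycosite_sequon_report(records: list[GlycoproteinRecord]) -> dict[str, float]:
    """QC summary: how many annotated glycosites sit at a sequon Asn.

    Experimental annotations can contain non-canonical glycosites; these are
    retained in locale analyses but counted here separately.
    """
    n_glyco = 0
    n_at_sequon = 0
    for rec in records:
        starts = {s.n_position for s in scan_sequons(rec)}
        for g in rec.glycosites:
            n_glyco += 1
            n_at_sequon += g in starts
    return {
        "n_glycosites": n_glyco,
        "n_glycosites_at_sequon": n_at_sequon,
        "n_glycosites_non_sequon": n_glyco - n_at_sequon,
        "fraction_at_sequon": n_at_sequon / n_glyco if n_glyco else float("nan"),
    }


def sequon_table(records: list[GlycoproteinRecord]) -> pd.DataFrame:
    """One row per sequon across the cohort (positions 1-based for output)."""
    classes = default_x_classes()
    rows = []
    for rec in records:
        for s in scan_sequons(rec):
            rows.append(
                {
                    "protein_id": s.protein_id,
                    "n_position": s.n_position + 1,
                    "x_residue": s.x_residue,
                    "third_residue": s.third_residue,
                    "locale": s.locale.value,
                    "is_glycosite": s.is_glycosite,
                    "spans_boundary": s.spans_boundary,
                    "x_classes": ";".join(sorted(classify_x(s.x_residue, classes))),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "n_position",
            "x_residue",
            "third_residue",
            "locale",
            "is_glycosite",
            "spans_boundary",
            "x_classes",
        ],
    )
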