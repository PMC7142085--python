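"""Synthetic glycoprotein cohorts with known ground truth.

Generates proteins as alternating ordered/disordered segments with distinct
residue compositions, plants N-X-S/T sequons carrying glycosites with a
controllable bias toward ordered segments, and derives 4-taxon ortholog
alignments by region-specific substitution rates on a fixed
(((human, chimp), mouse), chicken) topology.  Every emitted cohort passes the
annotation-module validations and ships a truth table, so each pipeline stage
can be checked against planted ground truth without any external data.

All randomness flows from a single cohort seed: protein ``i`` uses the
``i``-th child of ``numpy.random.SeedSequence(seed)`` and its ortholog set
uses that child's own first spawn, so any single protein is reproducible in
isolation via :func:`protein_rng`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_annotation import (
    AMINO_ACIDS,
    GlycoproteinRecord,
    Locale,
    write_annotation_tables,
    write_fasta,
)
from .conservation import OrthologAlignment
from .regions import FLANK

log = logging.getLogger(__name__)

_AA = np.array(list(AMINO_ACIDS))
_P_INDEX = AMINO_ACIDS.index("P")


class GenerationError(RuntimeError):
    """Raised when a cohort cannot satisfy its placement constraints."""


def default_compositions() -> tuple[np.ndarray, np.ndarray]:
    """Default (ordered, disordered) residue compositions.

    Starting from uniform 1/20 weights, the disordered composition up-weights
    the disorder-associated residues P, E, S, R, Q (x2.5) and N, M (x1.8) and
    down-weights the hydrophobic/aromatic core set W, F, Y, I, L, V, C (x0.3);
    the ordered composition applies the mirrored multipliers (x2.0 for the
    core set, x0.6 for the disorder set).  Both are renormalized to sum to 1.
    """
    disorder_strong = [AMINO_ACIDS.index(a) for a in "PESRQ"]
    disorder_mild = [AMINO_ACIDS.index(a) for a in "NM"]
    order_set = [AMINO_ACIDS.index(a) for a in "WFYILVC"]

    disordered = np.full(20, 0.05)
    disordered[disorder_strong] *= 2.5
    disordered[disorder_mild] *= 1.8
    disordered[order_set] *= 0.3
    disordered /= disordered.sum()

    ordered = np.full(20, 0.05)
    ordered[order_set] *= 2.0
    ordered[disorder_strong + disorder_mild] *= 0.6
    ordered /= ordered.sum()
    return ordered, disordered


@dataclass
class GeneratorParams:
    """Study conditions for one synthetic cohort."""

    n_proteins: int = 200
    length_min: int = 300
    length_max: int = 600
    disordered_fraction: float = 0.3
    segment_length_min: int = 15  # disordered segment draw; ordered scaled
    segment_length_max: int = 45
    ordered_composition: np.ndarray = field(
        default_factory=lambda: default_compositions()[0]
    )
    disordered_composition: np.ndarray = field(
        default_factory=lambda: default_compositions()[1]
    )
    glycosites_min: int = 1
    glycosites_max: int = 4
    p_glycosite_ordered: float = 0.8
    rate_neighborhood: float = 0.02  # substitutions / site / lineage unit
    rate_ordered: float = 0.05
    rate_disordered: float = 0.2
    taxa: tuple = (
        ("human", 0.0),
        ("chimp", 0.15),
        ("mouse", 1.0),
        ("chicken", 2.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ordered_composition", "disordered_composition"):
            comp = np.asarray(getattr(self, name), dtype=float)
            if comp.shape != (20,) or (comp < 0).any():
                raise ValueError(f"{name} must be a non-negative 20-vector")
            if abs(comp.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            setattr(self, name, comp)
        if not 0.0 <= self.p_glycosite_ordered <= 1.0:
            raise ValueError("p_glycosite_ordered must be in [0, 1]")
        if not 0.0 < self.disordered_fraction < 1.0:
            raise ValueError("disordered_fraction must be in (0, 1)")
        if len(self.taxa) != 4 or self.taxa[0][1] != 0.0:
            raise ValueError("taxa must be 4 (name, branch factor) pairs, "
                             "reference first with factor 0")

    def manifest(self) -> dict:
        d = asdict(self)
        d["ordered_composition"] = [round(float(x), 10) for x in self.ordered_composition]
        d["disordered_composition"] = [
            round(float(x), 10) for x in self.disordered_composition
        ]
        d["taxa"] = [list(t) for t in self.taxa]
        return d


def protein_rng(seed: int, index: int) -> np.random.Generator:
    """The generator stream of protein ``index`` within cohort ``seed``."""
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return np.random.default_rng(child)


def _sample_segments(
    params: GeneratorParams, length: int, rng: np.random.Generator
) -> list[tuple[Locale, int, int]]:
    """Alternating (locale, start, end) segments covering [0, length).

    Disordered segment lengths are U(seg_min, seg_max); ordered lengths are
    the same draw scaled by (1-f)/f so the expected disordered fraction is
    the target f.  The starting class is a fair coin flip; the final segment
    is trimmed to the protein length.
    """
    f = params.disordered_fraction
    scale = (1.0 - f) / f
    segs: list[tuple[Locale, int, int]] = []
    pos = 0
    disordered = bool(rng.integers(2))
    while pos < length:
        draw = int(rng.integers(params.segment_length_min, params.segment_length_max + 1))
        seg_len = draw if disordered else max(1, int(round(draw * scale)))
        end = min(length, pos + seg_len)
        segs.append((Locale.DISORDERED if disordered else Locale.ORDERED, pos, end))
        pos = end
        disordered = not disordered
    return segs


def _candidate_positions(
    segs: list[tuple[Locale, int, int]], length: int
) -> dict[Locale, set[int]]:
    """Sequon-start candidates per class: i..i+2 inside one segment, >= 5
    residues from either terminus."""
    out: dict[Locale, set[int]] = {Locale.ORDERED: set(), Locale.DISORDERED: set()}
    for locale, s, e in segs:
        lo = max(FLANK, s)
        hi = min(length - FLANK - 3, e - 3)  # i+2 <= length-6 and within segment
        out[locale].update(range(lo, hi + 1))
    return out


def gen_protein(
    params: GeneratorParams, rng: np.random.Generator, index: int = 0
) -> tuple[GlycoproteinRecord, list[dict]]:
    """One synthetic glycoprotein plus its truth rows.

    Residues are drawn iid from the segment's composition; each planted
    glycosite rewrites an eligible interior position to an N-X-S/T sequon
    (X != P drawn from the segment composition) in an ordered segment with
    probability ``p_glycosite_ordered``.  Raises :class:`GenerationError`
    when a forced placement (bias 0 or 1) is infeasible.
    """
    length = int(rng.integers(params.length_min, params.length_max + 1))
    segs = _sample_segments(params, length, rng)
    seq = np.empty(length, dtype="U1")
    for locale, s, e in segs:
        comp = (
            params.disordered_composition
            if locale is Locale.DISORDERED
            else params.ordered_composition
        )
        seq[s:e] = _AA[rng.choice(20, size=e - s, p=comp)]

    candidates = _candidate_positions(segs, length)
    comp_of = {
        Locale.ORDERED: params.ordered_composition,
        Locale.DISORDERED: params.disordered_composition,
    }
    n_sites = int(rng.integers(params.glycosites_min, params.glycosites_max + 1))
    glycosites: list[int] = []
    truth_rows: list[dict] = []
    pid = f"syn{index:05d}"
    for _ in range(n_sites):
        want_ordered = rng.random() < params.p_glycosite_ordered
        locale = Locale.ORDERED if want_ordered else Locale.DISORDERED
        if not candidates[locale]:
            other = (
                Locale.DISORDERED if locale is Locale.ORDERED else Locale.ORDERED
            )
            if params.p_glycosite_ordered in (0.0, 1.0) or not candidates[other]:
                raise GenerationError(
                    f"{pid}: no eligible {locale.value} position for a glycosite"
                )
            log.debug("%s: %s placement infeasible; fell back to %s",
                      pid, locale.value, other.value)
            locale = other
        cand = sorted(candidates[locale])
        i = cand[int(rng.integers(len(cand)))]
        comp = comp_of[locale]
        x_comp = comp.copy()
        x_comp[_P_INDEX] = 0.0
        x_comp /= x_comp.sum()
        seq[i] = "N"
        seq[i + 1] = _AA[rng.choice(20, p=x_comp)]
        seq[i + 2] = "S" if rng.random() < 0.5 else "T"
        glycosites.append(i)
        truth_rows.append(
            {
                "protein_id": pid,
                "position": i + 1,  # 1-based in truth output
                "locale": locale.value,
                "sequon_third": seq[i + 2],
            }
        )
        # later placements may not touch i-2..i+2 (would clobber this sequon)
        for cls in candidates.values():
            cls.difference_update(range(i - 2, i + 3))

    intervals = tuple(
        (s, e) for locale, s, e in segs if locale is Locale.DISORDERED
    )
    record = GlycoproteinRecord(
        protein_id=pid,
        sequence="".join(seq),
        glycosites=frozenset(glycosites),
        disorder_intervals=intervals,
    )
    return record, truth_rows


@dataclass
class Cohort:
    """A generated cohort: validated records plus the planted truth."""

    records: list[GlycoproteinRecord]
    truth: pd.DataFrame
    params: GeneratorParams

    @property
    def realized_ordered_fraction(self) -> float:
        """Fraction of all planted glycosites whose locale is ORDERED."""
        if self.truth.empty:
            return float("nan")
        return float((self.truth["locale"] == Locale.ORDERED.value).mean())


def gen_cohort(params: GeneratorParams, outdir: str | Path | None = None) -> Cohort:
    """Generate a cohort; optionally write the annotation-module file formats.

    Writes ``sequences.fasta``, ``glycosites.tsv``, ``disorder.tsv``,
    ``truth.tsv`` and ``manifest.json`` into ``outdir`` when given.
    """
    children = np.random.SeedSequence(params.seed).spawn(max(params.n_proteins, 1))
    records = []
    truth_rows: list[dict] = []
    for i in range(params.n_proteins):
        rng = np.random.default_rng(children[i])
        rec, rows = gen_protein(params, rng, index=i)
        records.append(rec)
        truth_rows.extend(rows)
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "position", "locale", "sequon_third"]
    )
    cohort = Cohort(records=records, truth=truth, params=params)
    if params.n_proteins == 0:
        log.warning("empty cohort requested (n_proteins=0)")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            outdir / "sequences.fasta",
            [(r.protein_id, r.sequence) for r in records],
        )
        write_annotation_tables(
            records, outdir / "glycosites.tsv", outdir / "disorder.tsv"
        )
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(params.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return cohort


# ---------------------------------------------------------------------------
# ortholog simulation
# ---------------------------------------------------------------------------


def _region_rates(record: GlycoproteinRecord, params: GeneratorParams) -> np.ndarray:
    """Per-site substitution rate: neighborhood overrides the segment class."""
    rates = np.where(
        record.disorder_mask, params.rate_disordered, params.rate_ordered
    )
    n = len(record.sequence)
    for g in record.glycosites:
        lo = max(0, g - FLANK)
        hi = min(n, g + FLANK + 1)
        rates[lo:hi] = params.rate_neighborhood
    return rates


def newick_tree(params: GeneratorParams) -> str:
    """Fixed rooted 4-taxon topology with branch lengths from the factors."""
    (t0, _), (t1, f1), (t2, f2), (t3, f3) = params.taxa
    return (
        f"((({t0}:0.05,{t1}:{f1}):0.5,{t2}:{f2}):0.5,{t3}:{f3});"
    )


def gen_orthologs(
    record: GlycoproteinRecord,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> tuple[OrthologAlignment, str]:
    """Simulate a gapless 4-row ortholog alignment for one record.

    Each non-reference row substitutes site ``i`` with probability
    ``min(rate_i * branch_factor, 0.95)``; the replacement is drawn from the
    site's segment-class composition excluding the current residue.  With no
    indels the alignment is trivially gapless and ``ref_map`` is the
    identity.  Returns the alignment and the cohort's newick tree string.
    """
    n = len(record.sequence)
    rates = _region_rates(record, params)
    comp_matrix = np.where(
        record.disorder_mask[:, None],
        params.disordered_composition[None, :],
        params.ordered_composition[None, :],
    )
    human = np.array(list(record.sequence))
    rows = [(params.taxa[0][0], record.sequence)]
    for name, factor in params.taxa[1:]:
        p_sub = np.clip(rates * factor, 0.0, 0.95)
        derived = human.copy()
        for i in np.flatnonzero(rng.random(n) < p_sub):
            comp = comp_matrix[i].copy()
            cur = AMINO_ACIDS.find(derived[i])
            if cur >= 0:
                comp[cur] = 0.0
            if comp.sum() == 0:
                continue
            comp /= comp.sum()
            derived[i] = _AA[rng.choice(20, p=comp)]
        rows.append((name, "".join(derived)))
    alignment = OrthologAlignment(rows=tuple(rows), reference_taxon=params.taxa[0][0])
    return alignment, newick_tree(params)


def ortholog_rng(seed: int, index: int) -> np.random.Generator:
    """Dedicated stream for protein ``index``'s ortholog simulation."""
    child = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return np.random.default_rng(child.spawn(1)[0])
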