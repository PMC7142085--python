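"""Glycosite neighborhoods, control windows, and paired region metrics.

An N-glycosite neighborhood is the 11-residue window centered on a
glycosylated Asn (5 residues each side).  Ordered/disordered control windows
are glycosite-free 11-mers lying entirely within one locale class, sampled
uniformly (one per class per protein by default).  Per-protein metrics over
the two locales are compared with the Wilcoxon matched-pairs signed-rank
test: exact null distribution for small untied samples, normal approximation
with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_annotation import GlycoproteinRecord, Locale, locale_of
from .sequon import scan_sequons

log = logging.getLogger(__name__)

WINDOW_LENGTH = 11
FLANK = WINDOW_LENGTH // 2  # 5 residues each side of the central Asn

NEIGHBORHOOD = "NEIGHBORHOOD"
ORDERED_CONTROL = "ORDERED_CONTROL"
DISORDERED_CONTROL = "DISORDERED_CONTROL"


@dataclass(frozen=True)
class ResidueWindow:
    """An 11-residue stretch with provenance."""

    protein_id: str
    kind: str  # NEIGHBORHOOD / ORDERED_CONTROL / DISORDERED_CONTROL
    start: int  # 0-based
    residues: str
    center_locale: Locale | None  # neighborhoods only
    locale_purity: float  # fraction of residues sharing the window's class

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_LENGTH:
            raise ValueError(f"window must have length {WINDOW_LENGTH}")


def extract_neighborhoods(record: GlycoproteinRecord) -> list[ResidueWindow]:
    """One 11-mer window per glycosite at least 5 residues from each terminus.

    Glycosites nearer a terminus are skipped (logged) rather than truncated so
    all windows stay comparable.  Windows spanning an order/disorder boundary
    are kept; their purity (fraction of residues matching the central Asn's
    locale) is recorded.
    """
    n = len(record.sequence)
    windows = []
    n_skipped = 0
    for g in sorted(record.glycosites):
        if g < FLANK or g > n - FLANK - 1:
            n_skipped += 1
            continue
        start = g - FLANK
        center = locale_of(record, g)
        mask = record.disorder_mask[start : start + WINDOW_LENGTH]
        purity = float(np.mean(mask == (center is Locale.DISORDERED)))
        windows.append(
            ResidueWindow(
                protein_id=record.protein_id,
                kind=NEIGHBORHOOD,
                start=start,
                residues=record.sequence[start : start + WINDOW_LENGTH],
                center_locale=center,
                locale_purity=purity,
            )
        )
    if n_skipped:
        log.info(
            "%s: skipped %d terminal glycosite(s) (< %d residues of flank)",
            record.protein_id,
            n_skipped,
            FLANK,
        )
    return windows


def eligible_control_starts(record: GlycoproteinRecord, region: Locale) -> np.ndarray:
    """All starts of valid 11-mer control windows of a locale class.

    A start ``s`` is eligible when every residue of ``[s, s+11)`` has the
    class locale and the window does not contain, or lie within 5 residues
    of, any glycosite (i.e. it never intersects a glycosite neighborhood).
    """
    n = len(record.sequence)
    if n < WINDOW_LENGTH:
        return np.array([], dtype=int)
    want = record.disorder_mask if region is Locale.DISORDERED else ~record.disorder_mask
    # window all in class <=> rolling sum of `want` over 11 positions == 11
    csum = np.concatenate([[0], np.cumsum(want)])
    all_in_class = (csum[WINDOW_LENGTH:] - csum[:-WINDOW_LENGTH]) == WINDOW_LENGTH
    forbidden = np.zeros(n, dtype=bool)
    for g in record.glycosites:
        lo = max(0, g - FLANK)
        hi = min(n, g + FLANK + 1)
        forbidden[lo:hi] = True
    fsum = np.concatenate([[0], np.cumsum(forbidden)])
    touches_neighborhood = (fsum[WINDOW_LENGTH:] - fsum[:-WINDOW_LENGTH]) > 0
    return np.flatnonzero(all_in_class & ~touches_neighborhood)


def sample_control_windows(
    record: GlycoproteinRecord,
    rng: np.random.Generator,
    controls_per_class: int = 1,
) -> dict[str, list[ResidueWindow]]:
    """Uniformly sample control windows per locale class (deterministic per rng).

    Returns ``{ORDERED_CONTROL: [...], DISORDERED_CONTROL: [...]}``; a class
    with no eligible window gets an empty list (NA downstream).  When k > 1,
    distinct starts are drawn without replacement (fewer if not enough).
    """
    out: dict[str, list[ResidueWindow]] = {ORDERED_CONTROL: [], DISORDERED_CONTROL: []}
    for region, kind in (
        (Locale.ORDERED, ORDERED_CONTROL),
        (Locale.DISORDERED, DISORDERED_CONTROL),
    ):
        starts = eligible_control_starts(record, region)
        if starts.size == 0:
            continue
        k = min(controls_per_class, starts.size)
        chosen = rng.choice(starts, size=k, replace=False)
        for s in sorted(int(s) for s in np.atleast_1d(chosen)):
            out[kind].append(
                ResidueWindow(
                    protein_id=record.protein_id,
                    kind=kind,
                    start=s,
                    residues=record.sequence[s : s + WINDOW_LENGTH],
                    center_locale=None,
                    locale_purity=1.0,
                )
            )
    return out


# ---------------------------------------------------------------------------
# per-protein metrics
# ---------------------------------------------------------------------------


def metric_glycosite_ordered_fraction(record: GlycoproteinRecord) -> float:
    """Fraction of a protein's glycosites lying in ordered sequence.

    The disordered fraction is the complement.  NaN when the protein has no
    glycosite.
    """
    if not record.glycosites:
        return float("nan")
    ordered = sum(
        locale_of(record, g) is Locale.ORDERED for g in record.glycosites
    )
    return ordered / len(record.glycosites)


def metric_residue_percent(
    record: GlycoproteinRecord, residue_set: Iterable[str], region: Locale
) -> float:
    """Percent of a region's residues belonging to ``residue_set``; NaN if empty."""
    positions = record.region_positions(region)
    if positions.size == 0:
        return float("nan")
    residue_set = set(residue_set)
    hits = sum(record.sequence[p] in residue_set for p in positions)
    return 100.0 * hits / positions.size


def metric_sequon_density(record: GlycoproteinRecord, region: Locale) -> float:
    """Sequons (by Asn locale) per 100 residues of the region; NaN if < 3 long."""
    positions = record.region_positions(region)
    if positions.size < 3:
        return float("nan")
    n_sequons = sum(1 for s in scan_sequons(record) if s.locale is region)
    return 100.0 * n_sequons / positions.size


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    n_effective: int  # pairs with non-zero difference
    statistic: float  # W+ = sum of ranks of positive differences
    p_two_sided: float
    method: str  # 'exact' | 'normal_approx' | 'na'
    n_dropped_na: int = 0
    n_dropped_zero: int = 0


def _exact_signed_rank_p(ranks_sum: float, n: int) -> float:
    """Two-sided exact p for W+ with distinct integer ranks 1..n.

    Dynamic programme over the 2^n equiprobable sign assignments: counts[w]
    = number of subsets of {1..n} with rank sum w.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: total - r + 1].copy()
    w = int(round(ranks_sum))
    denom = 2.0**n
    p_le = counts[: w + 1].sum() / denom
    p_ge = counts[w:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    NA pairs are dropped (count logged); zero differences are dropped per the
    classic convention.  Exact null distribution when the effective n is at
    most 25 with no ties in |difference|; otherwise a normal approximation
    with tie correction and continuity correction.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array-like")
    ok = ~np.isnan(arr).any(axis=1)
    n_na = int((~ok).sum())
    if n_na:
        log.info("wilcoxon: dropped %d pair(s) with NA", n_na)
    d = arr[ok, 0] - arr[ok, 1]
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        log.warning("wilcoxon: no non-zero differences; NA result")
        return WilcoxonResult(0, float("nan"), float("nan"), "na", n_na, n_zero)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        p = _exact_signed_rank_p(w_plus, n)
        method = "exact"
    else:
        res = stats.wilcoxon(
            d,
            zero_method="wilcox",
            correction=True,
            alternative="two-sided",
            method="approx",
        )
        p = float(res.pvalue)
        method = "normal_approx"
    return WilcoxonResult(n, w_plus, p, method, n_na, n_zero)


def summarize_metric(values: Sequence[float]) -> tuple[float, float, float]:
    """NA-aware (mean, median, SEM) of one metric column.

    SEM uses the sample standard deviation (n-1 denominator); NaN when fewer
    than two non-NA values.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return (float("nan"),) * 3
    mean = float(np.mean(v))
    median = float(np.median(v))
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
    return mean, median, sem


def paired_metric_table(
    records: list[GlycoproteinRecord],
    metric,
    name: str,
) -> pd.DataFrame:
    """Per-protein (value_ordered, value_disordered) rows for a region metric.

    ``metric(record, region)`` must return a float (NaN allowed).
    """
    rows = [
        {
            "protein_id": rec.protein_id,
            f"{name}_ordered": metric(rec, Locale.ORDERED),
            f"{name}_disordered": metric(rec, Locale.DISORDERED),
        }
        for rec in records
    ]
    return pd.DataFrame(rows)


def windows_table(windows: Iterable[ResidueWindow]) -> pd.DataFrame:
    """Serialize windows to a DataFrame (start 1-based for output)."""
    rows = [
        {
            "protein_id": w.protein_id,
            "kind": w.kind,
            "start": w.start + 1,
            "residues": w.residues,
            "center_locale": w.center_locale.value if w.center_locale else "",
            "locale_purity": w.locale_purity,
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "kind",
            "start",
            "residues",
            "center_locale",
            "locale_purity",
        ],
    )
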