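"""Composition enrichment between residue pools with bootstrap significance.

Compares amino-acid frequencies (and composition-weighted property scores)
between a query pool and a background pool of residues — typically glycosite
neighborhoods vs ordered or disordered control windows.  The statistic is the
fractional difference D(a) = (Cq(a) - Cb(a)) / Cb(a).  Significance comes
from a bootstrap of D: each iteration resamples Nq residues from the query
and Nb from the background with replacement and recomputes D; the observed D
is tested against a standard normal via z = D / SE_bootstrap, two-sided, with
Bonferroni correction over the 20 amino acids (or over the property scales
in a property run).

Resampling a pool of N residues with replacement is implemented as a single
multinomial draw over the 20 amino-acid counts, which is distributionally
identical and vectorizes across iterations.  A label-permutation p-value is
available as an independent cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io_annotation import AMINO_ACIDS

log = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)


@dataclass(frozen=True)
class CompositionProfile:
    """Amino-acid counts and fractions of a residue pool."""

    counts: np.ndarray  # shape (20,), order AMINO_ACIDS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_AA,) or (counts < 0).any():
            raise ValueError("counts must be a non-negative 20-vector")
        if counts.sum() < 1:
            raise ValueError("empty residue pool")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.total


def pool_residues(windows: Iterable) -> CompositionProfile:
    """Concatenate window residues into one composition profile.

    Accepts `ResidueWindow` objects or plain strings.  'X' (unknown) residues
    are dropped with a logged count.
    """
    counts = np.zeros(N_AA, dtype=np.int64)
    n_x = 0
    n_windows = 0
    for w in windows:
        n_windows += 1
        residues = getattr(w, "residues", w)
        for ch in residues:
            idx = AA_INDEX.get(ch)
            if idx is None:
                n_x += 1
            else:
                counts[idx] += 1
    if n_windows == 0:
        raise ValueError("no windows to pool")
    if n_x:
        log.info("pool_residues: dropped %d unknown ('X') residue(s)", n_x)
    return CompositionProfile(counts)


def fractional_difference(cq: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """D(a) = (Cq(a) - Cb(a)) / Cb(a); NaN where Cb==0<Cq, 0 where both 0."""
    cq = np.asarray(cq, dtype=float)
    cb = np.asarray(cb, dtype=float)
    d = np.full_like(cq, np.nan)
    ok = cb > 0
    d[ok] = (cq[ok] - cb[ok]) / cb[ok]
    d[(cb == 0) & (cq == 0)] = 0.0
    return d


def _resample_fractions(
    profile: CompositionProfile, iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """(iterations, 20) bootstrap fraction matrix for one pool."""
    draws = rng.multinomial(profile.total, profile.fractions, size=iterations)
    return draws / profile.total


def bootstrap_enrichment(
    query_pool: CompositionProfile,
    background_pool: CompositionProfile,
    iterations: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-amino-acid fractional enrichment with bootstrap z-test.

    Returns a DataFrame indexed by amino acid with columns
    ``Cq, Cb, D, SE, p, significant, direction``.  ``significant`` applies the
    Bonferroni divisor 20 (or none); direction is enriched/depleted/ns.
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if rng is None:
        rng = np.random.default_rng()
    if min(query_pool.total, background_pool.total) < 20:
        log.warning("pool smaller than 20 residues: bootstrap SEs are unstable")

    cq = query_pool.fractions
    cb = background_pool.fractions
    d_obs = fractional_difference(cq, cb)

    q_boot = _resample_fractions(query_pool, iterations, rng)
    b_boot = _resample_fractions(background_pool, iterations, rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_boot = np.where(b_boot > 0, (q_boot - b_boot) / b_boot, np.nan)
    with warnings.catch_warnings():
        # amino acids absent from the background yield all-NaN bootstrap columns
        warnings.simplefilter("ignore", category=RuntimeWarning)
        se = np.nanstd(d_boot, axis=0, ddof=1)

    p = np.ones(N_AA)
    for i in range(N_AA):
        if np.isnan(d_obs[i]):
            p[i] = np.nan
        elif se[i] == 0 or np.isnan(se[i]):
            p[i] = 1.0 if d_obs[i] == 0 else 0.0
        else:
            p[i] = 2.0 * stats.norm.sf(abs(d_obs[i]) / se[i])

    threshold = alpha / N_AA if correction == "bonferroni" else alpha
    significant = (p <= threshold) & ~np.isnan(p)
    direction = np.where(
        significant, np.where(d_obs > 0, "enriched", "depleted"), "ns"
    )
    return pd.DataFrame(
        {
            "Cq": cq,
            "Cb": cb,
            "D": d_obs,
            "SE": se,
            "p": p,
            "significant": significant,
            "direction": direction,
        },
        index=list(AMINO_ACIDS),
    )


def permutation_enrichment(
    query_pool: CompositionProfile,
    background_pool: CompositionProfile,
    iterations: int = 1_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Label-permutation p-values for D(a), an independent cross-check.

    Residues of both pools are combined; each iteration reassigns Nq of them
    to the query without replacement (multivariate hypergeometric) and
    recomputes D.  p(a) = (1 + #{|D_perm| >= |D_obs|}) / (iterations + 1).
    """
    if rng is None:
        rng = np.random.default_rng()
    nq, nb = query_pool.total, background_pool.total
    combined = query_pool.counts + background_pool.counts
    d_obs = fractional_difference(query_pool.fractions, background_pool.fractions)
    exceed = np.zeros(N_AA)
    valid = np.zeros(N_AA)
    for _ in range(iterations):
        q_counts = rng.multivariate_hypergeometric(combined, nq)
        b_counts = combined - q_counts
        with np.errstate(divide="ignore", invalid="ignore"):
            d_perm = np.where(
                b_counts > 0, (q_counts / nq - b_counts / nb) / (b_counts / nb), np.nan
            )
        ok = ~np.isnan(d_perm) & ~np.isnan(d_obs)
        exceed[ok] += np.abs(d_perm[ok]) >= np.abs(d_obs[ok])
        valid[ok] += 1
    p = (1.0 + exceed) / (1.0 + valid)
    p[np.isnan(d_obs)] = np.nan
    return p


# ---------------------------------------------------------------------------
# property scales
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropertyScale:
    """A named per-residue numeric scale with a provenance note."""

    name: str
    values: dict[str, float]
    provenance: str

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {missing}")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.values[aa] for aa in AMINO_ACIDS], dtype=float)


def builtin_scales(path=None) -> list[PropertyScale]:
    """Load the packaged property scales (editable YAML; >= 10 scales).

    Covers aromaticity, polarity, net charge, hydrophobicity, flexibility,
    surface exposure, beta-structure frequency, coil frequency, disorder and
    order propensity, and bulkiness; each documents the literature scale it
    mirrors.
    """
    if path is None:
        text = (
            resources.files("glycolocale.data")
            .joinpath("property_scales.yaml")
            .read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return [
        PropertyScale(
            name=name,
            values={k: float(v) for k, v in entry["values"].items()},
            provenance=entry["provenance"],
        )
        for name, entry in raw.items()
    ]


def property_enrichment(
    query_pool: CompositionProfile,
    background_pool: CompositionProfile,
    scales: list[PropertyScale] | None = None,
    iterations: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Composition-weighted mean property scores with bootstrap significance.

    For each scale, S = sum_a scale(a) * C(a) per pool; the difference
    S_q - S_b is bootstrapped exactly like the per-residue enrichment.  The
    Bonferroni divisor is the number of scales tested in this run.
    """
    if scales is None:
        scales = builtin_scales()
    if rng is None:
        rng = np.random.default_rng()
    if iterations < 100:
        raise ValueError("iterations must be >= 100")

    q_boot = _resample_fractions(query_pool, iterations, rng)
    b_boot = _resample_fractions(background_pool, iterations, rng)
    threshold = alpha / len(scales) if correction == "bonferroni" else alpha

    rows = []
    for scale in scales:
        vec = scale.vector
        s_q = float(query_pool.fractions @ vec)
        s_b = float(background_pool.fractions @ vec)
        diff = s_q - s_b
        diff_boot = q_boot @ vec - b_boot @ vec
        se = float(np.std(diff_boot, ddof=1))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(diff) / se))
        significant = p <= threshold
        rows.append(
            {
                "scale": scale.name,
                "S_q": s_q,
                "S_b": s_b,
                "difference": diff,
                "SE": se,
                "p": p,
                "significant": significant,
                "direction": ("enriched" if diff > 0 else "depleted")
                if significant
                else "ns",
                "provenance": scale.provenance,
            }
        )
    return pd.DataFrame(rows).set_index("scale")
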