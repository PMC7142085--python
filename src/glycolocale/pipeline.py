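"""End-to-end orchestration: simulate, annotate, metrics, enrich, conserve, report.

Stages communicate through TSV files in the run's output directory so each
one is independently runnable and resumable.  All configuration comes from a
strict YAML file (unknown keys are errors); every stage derives its
randomness from the single run seed, so a full re-run with the same config
and seed reproduces every table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conservation import (
    ETRankResult,
    et_rank,
    link_alignment,
    read_msa,
    region_mean_entropy,
)
from .enrichment import (
    bootstrap_enrichment,
    builtin_scales,
    pool_residues,
    property_enrichment,
)
from .io_annotation import GlycoproteinRecord, Locale, load_records, locale_of
from .regions import (
    DISORDERED_CONTROL,
    FLANK,
    NEIGHBORHOOD,
    ORDERED_CONTROL,
    WINDOW_LENGTH,
    extract_neighborhoods,
    metric_glycosite_ordered_fraction,
    metric_residue_percent,
    metric_sequon_density,
    sample_control_windows,
    summarize_metric,
    wilcoxon_signed_rank,
    windows_table,
)
from .sequon import glycosite_sequon_report, sequon_asn_fraction, sequon_table
from .synthetic import GeneratorParams, gen_cohort, gen_orthologs, ortholog_rng

log = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration keys."""


_SIMULATE_KEYS = {
    "n_proteins", "length_min", "length_max", "disordered_fraction",
    "segment_length_min", "segment_length_max", "glycosites_min",
    "glycosites_max", "p_glycosite_ordered", "rate_neighborhood",
    "rate_ordered", "rate_disordered", "orthologs",
}
_INPUT_KEYS = {"fasta", "glycosites", "disorder", "msa_dir", "tree", "reference_taxon"}
_WINDOW_KEYS = {"controls_per_protein"}
_ENRICH_KEYS = {"iterations", "alpha", "correction"}
_CONSERVE_KEYS = {"gap_policy"}
_TOP_KEYS = {
    "seed", "outdir", "log_level", "simulate", "inputs", "windows",
    "enrichment", "conservation",
}


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int = 0
    outdir: Path = Path("glycolocale_run")
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    windows: dict = field(default_factory=lambda: {"controls_per_protein": 1})
    enrichment: dict = field(
        default_factory=lambda: {
            "iterations": 10_000,
            "alpha": 0.05,
            "correction": "bonferroni",
        }
    )
    conservation: dict = field(default_factory=lambda: {"gap_policy": "gap_as_symbol"})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def check(section: dict, allowed: set[str], prefix: str) -> None:
            for key in section:
                if key not in allowed:
                    raise ConfigError(f"unknown config key: {prefix}{key}")

        check(raw, _TOP_KEYS, "")
        check(raw.get("simulate", {}) or {}, _SIMULATE_KEYS, "simulate.")
        check(raw.get("inputs", {}) or {}, _INPUT_KEYS, "inputs.")
        check(raw.get("windows", {}) or {}, _WINDOW_KEYS, "windows.")
        check(raw.get("enrichment", {}) or {}, _ENRICH_KEYS, "enrichment.")
        check(raw.get("conservation", {}) or {}, _CONSERVE_KEYS, "conservation.")
        cfg = cls()
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.outdir = Path(raw.get("outdir", cfg.outdir))
        cfg.log_level = str(raw.get("log_level", cfg.log_level))
        cfg.simulate = dict(raw.get("simulate", {}) or {})
        cfg.inputs = dict(raw.get("inputs", {}) or {})
        cfg.windows = {**cfg.windows, **(raw.get("windows", {}) or {})}
        cfg.enrichment = {**cfg.enrichment, **(raw.get("enrichment", {}) or {})}
        cfg.conservation = {**cfg.conservation, **(raw.get("conservation", {}) or {})}
        if not cfg.simulate and not cfg.inputs:
            raise ConfigError("config needs either a 'simulate' or an 'inputs' block")
        return cfg

    def generator_params(self) -> GeneratorParams:
        kwargs = {k: v for k, v in self.simulate.items() if k != "orthologs"}
        return GeneratorParams(seed=self.seed, **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "simulate": self.simulate,
                "inputs": {k: str(v) for k, v in self.inputs.items()},
                "windows": self.windows,
                "enrichment": self.enrichment,
                "conservation": self.conservation,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def _input_paths(cfg: RunConfig) -> dict:
    """Resolve annotation inputs: explicit paths, else the simulated cohort."""
    if cfg.inputs:
        return dict(cfg.inputs)
    cohort_dir = cfg.outdir / "cohort"
    paths = {
        "fasta": cohort_dir / "sequences.fasta",
        "glycosites": cohort_dir / "glycosites.tsv",
        "disorder": cohort_dir / "disorder.tsv",
        "reference_taxon": "human",
    }
    if (cohort_dir / "msa").is_dir():
        paths["msa_dir"] = cohort_dir / "msa"
    if (cohort_dir / "tree.nwk").exists():
        paths["tree"] = cohort_dir / "tree.nwk"
    return paths


def _load_input_records(cfg: RunConfig) -> list[GlycoproteinRecord]:
    paths = _input_paths(cfg)
    for key in ("fasta", "glycosites", "disorder"):
        if key not in paths or not Path(paths[key]).exists():
            raise FileNotFoundError(
                f"missing input {key!r}: run 'simulate' first or set inputs.{key}"
            )
    return load_records(paths["fasta"], paths["glycosites"], paths["disorder"])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def cmd_simulate(cfg: RunConfig) -> Path:
    """Generate a synthetic cohort (and orthologs when enabled) under outdir."""
    params = cfg.generator_params()
    cohort_dir = cfg.outdir / "cohort"
    cohort = gen_cohort(params, outdir=cohort_dir)
    if cfg.simulate.get("orthologs", False):
        msa_dir = cohort_dir / "msa"
        msa_dir.mkdir(parents=True, exist_ok=True)
        tree = None
        for i, rec in enumerate(cohort.records):
            aln, tree = gen_orthologs(rec, params, ortholog_rng(params.seed, i))
            with open(msa_dir / f"{rec.protein_id}.fasta", "w") as fh:
                for taxon, seq in aln.rows:
                    fh.write(f">{taxon}\n{seq}\n")
        if tree is not None:
            (cohort_dir / "tree.nwk").write_text(tree + "\n")
    log.info(
        "simulated %d proteins (realized ordered glycosite fraction %.3f)",
        len(cohort.records),
        cohort.realized_ordered_fraction,
    )
    return cohort_dir


def cmd_annotate(cfg: RunConfig) -> None:
    """Assemble records; emit QC, sequon and window tables."""
    records = _load_input_records(cfg)
    if not any(rec.glycosites for rec in records):
        raise ValueError("no glycosites in the input cohort")

    qc = glycosite_sequon_report(records)
    n_by_locale = {"ORDERED": 0, "DISORDERED": 0}
    n_terminal_skipped = 0
    for rec in records:
        n = len(rec.sequence)
        for g in rec.glycosites:
            n_by_locale[locale_of(rec, g).value] += 1
            if g < FLANK or g > n - FLANK - 1:
                n_terminal_skipped += 1
    qc_df = pd.DataFrame(
        [
            {"key": "n_proteins", "value": len(records)},
            {"key": "n_glycosites", "value": qc["n_glycosites"]},
            {"key": "n_glycosites_ordered", "value": n_by_locale["ORDERED"]},
            {"key": "n_glycosites_disordered", "value": n_by_locale["DISORDERED"]},
            {"key": "n_glycosites_at_sequon", "value": qc["n_glycosites_at_sequon"]},
            {"key": "n_glycosites_non_sequon", "value": qc["n_glycosites_non_sequon"]},
            {"key": "n_glycosites_terminal_skipped", "value": n_terminal_skipped},
        ]
    )
    _write(qc_df, cfg.outdir / "qc.tsv")
    _write(sequon_table(records), cfg.outdir / "sequons.tsv")

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    windows = []
    for rec in records:
        windows.extend(extract_neighborhoods(rec))
        controls = sample_control_windows(
            rec, rng, controls_per_class=int(cfg.windows["controls_per_protein"])
        )
        windows.extend(controls[ORDERED_CONTROL])
        windows.extend(controls[DISORDERED_CONTROL])
    _write(windows_table(windows), cfg.outdir / "windows.tsv")


def cmd_metrics(cfg: RunConfig) -> None:
    """Per-protein paired metrics, Wilcoxon tests and the summary table."""
    records = _load_input_records(cfg)
    metric_fns = {
        "asn_percent": lambda r, reg: metric_residue_percent(r, {"N"}, reg),
        "ser_percent": lambda r, reg: metric_residue_percent(r, {"S"}, reg),
        "thr_percent": lambda r, reg: metric_residue_percent(r, {"T"}, reg),
        "sequon_density": metric_sequon_density,
        "sequon_asn_fraction": sequon_asn_fraction,
    }
    rows = []
    for rec in records:
        f_ord = metric_glycosite_ordered_fraction(rec)
        row = {
            "protein_id": rec.protein_id,
            "glycosite_fraction_ordered": f_ord,
            "glycosite_fraction_disordered": 1.0 - f_ord
            if not np.isnan(f_ord)
            else float("nan"),
        }
        for name, fn in metric_fns.items():
            row[f"{name}_ordered"] = fn(rec, Locale.ORDERED)
            row[f"{name}_disordered"] = fn(rec, Locale.DISORDERED)
        rows.append(row)
    table = pd.DataFrame(rows)
    _write(table, cfg.outdir / "metrics_per_protein.tsv")

    test_rows = []
    metric_names = ["glycosite_fraction"] + list(metric_fns)
    for name in metric_names:
        pairs = table[[f"{name}_ordered", f"{name}_disordered"]].to_numpy()
        res = wilcoxon_signed_rank(pairs)
        test_rows.append(
            {
                "metric": name,
                "n_effective": res.n_effective,
                "W": res.statistic,
                "p": res.p_two_sided,
                "method": res.method,
                "n_dropped_na": res.n_dropped_na,
                "n_dropped_zero": res.n_dropped_zero,
            }
        )
    _write(pd.DataFrame(test_rows), cfg.outdir / "metrics_tests.tsv")

    summary_rows = []
    for name in metric_names:
        for region in ("ordered", "disordered"):
            mean, median, sem = summarize_metric(table[f"{name}_{region}"])
            summary_rows.append(
                {
                    "metric": name,
                    "region": region,
                    "mean": mean,
                    "median": median,
                    "sem": sem,
                }
            )
    _write(pd.DataFrame(summary_rows), cfg.outdir / "metrics_summary.tsv")


_COMPARISONS = (
    ("neighborhood_vs_disordered_control", NEIGHBORHOOD, DISORDERED_CONTROL),
    ("neighborhood_vs_ordered_control", NEIGHBORHOOD, ORDERED_CONTROL),
    ("ordered_vs_disordered_control", ORDERED_CONTROL, DISORDERED_CONTROL),
)


def cmd_enrich(cfg: RunConfig) -> None:
    """Amino-acid and property enrichment for the three pairwise comparisons."""
    windows_path = cfg.outdir / "windows.tsv"
    if not windows_path.exists():
        raise FileNotFoundError("windows.tsv missing: run 'annotate' first")
    windows = pd.read_csv(windows_path, sep="\t")
    pools = {}
    for kind in (NEIGHBORHOOD, ORDERED_CONTROL, DISORDERED_CONTROL):
        residues = windows.loc[windows["kind"] == kind, "residues"].tolist()
        pools[kind] = pool_residues(residues) if residues else None

    scales = builtin_scales()
    iterations = int(cfg.enrichment["iterations"])
    alpha = float(cfg.enrichment["alpha"])
    correction = str(cfg.enrichment["correction"])
    for i, (label, query_kind, background_kind) in enumerate(_COMPARISONS):
        query, background = pools[query_kind], pools[background_kind]
        if query is None or background is None:
            log.warning("%s: empty pool, comparison skipped", label)
            continue
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2, i)))
        aa = bootstrap_enrichment(
            query, background, iterations=iterations, alpha=alpha, rng=rng,
            correction=correction,
        )
        _write(
            aa.reset_index(names="amino_acid"),
            cfg.outdir / f"enrichment_{label}_aa.tsv",
        )
        props = property_enrichment(
            query, background, scales=scales, iterations=iterations, alpha=alpha,
            rng=rng, correction=correction,
        )
        _write(
            props.reset_index(),
            cfg.outdir / f"enrichment_{label}_properties.tsv",
        )


def _region_positions_for_conservation(
    rec: GlycoproteinRecord, windows: pd.DataFrame
) -> dict[str, np.ndarray]:
    """0-based reference positions per region for one protein."""
    mine = windows[windows["protein_id"] == rec.protein_id]
    out = {}
    for kind, key in (
        (NEIGHBORHOOD, "neighborhood"),
        (ORDERED_CONTROL, "ordered_control"),
        (DISORDERED_CONTROL, "disordered_control"),
    ):
        starts = mine.loc[mine["kind"] == kind, "start"].to_numpy() - 1
        positions = sorted(
            {int(p) for s in starts for p in range(s, s + WINDOW_LENGTH)}
        )
        out[key] = np.array(positions, dtype=int)
    out["full_length"] = np.arange(len(rec.sequence))
    return out


def cmd_conserve(cfg: RunConfig) -> None:
    """Per-region entropy means (+ trace ranks when a tree is given)."""
    paths = _input_paths(cfg)
    msa_dir = paths.get("msa_dir")
    if msa_dir is None or not Path(msa_dir).is_dir():
        raise FileNotFoundError(
            "no MSA directory: enable simulate.orthologs or set inputs.msa_dir"
        )
    records = _load_input_records(cfg)
    windows_path = cfg.outdir / "windows.tsv"
    if not windows_path.exists():
        raise FileNotFoundError("windows.tsv missing: run 'annotate' first")
    windows = pd.read_csv(windows_path, sep="\t")
    reference = str(paths.get("reference_taxon", "human"))
    gap_policy = str(cfg.conservation["gap_policy"])
    tree_path = paths.get("tree")
    tree = Path(tree_path).read_text().strip() if tree_path else None

    region_keys = ("neighborhood", "ordered_control", "disordered_control", "full_length")
    entropy_rows = []
    rank_rows = []
    for rec in records:
        msa_path = Path(msa_dir) / f"{rec.protein_id}.fasta"
        if not msa_path.exists():
            log.warning("%s: no MSA file, skipped", rec.protein_id)
            continue
        aln = read_msa(msa_path, reference)
        try:
            link_alignment(aln, rec)
        except ValueError as err:
            raise ValueError(f"MSA/record mismatch: {err}") from err
        regions = _region_positions_for_conservation(rec, windows)
        row = {"protein_id": rec.protein_id}
        for key in region_keys:
            row[f"entropy_{key}"] = (
                region_mean_entropy(aln, regions[key], gap_policy)
                if regions[key].size
                else float("nan")
            )
        entropy_rows.append(row)
        if tree is not None:
            et: ETRankResult = et_rank(aln, tree)
            rrow = {"protein_id": rec.protein_id}
            for key in region_keys:
                rrow[f"rank_{key}"] = (
                    et.region_mean_rank(regions[key])
                    if regions[key].size
                    else float("nan")
                )
            rank_rows.append(rrow)

    entropy = pd.DataFrame(entropy_rows)
    _write(entropy, cfg.outdir / "conservation_per_protein.tsv")
    _write(
        _paired_region_tests(entropy, "entropy", region_keys),
        cfg.outdir / "conservation_tests.tsv",
    )
    if rank_rows:
        ranks = pd.DataFrame(rank_rows)
        _write(ranks, cfg.outdir / "et_per_protein.tsv")
        _write(
            _paired_region_tests(ranks, "rank", region_keys),
            cfg.outdir / "et_tests.tsv",
        )
    elif tree is None:
        log.info("no tree given: evolutionary-trace ranking skipped")


def _paired_region_tests(
    table: pd.DataFrame, prefix: str, region_keys
) -> pd.DataFrame:
    rows = []
    for i, ra in enumerate(region_keys):
        for rb in region_keys[i + 1 :]:
            ca, cb = f"{prefix}_{ra}", f"{prefix}_{rb}"
            if ca not in table or cb not in table or table.empty:
                continue
            res = wilcoxon_signed_rank(table[[ca, cb]].to_numpy())
            rows.append(
                {
                    "region_a": ra,
                    "region_b": rb,
                    "mean_a": float(table[ca].mean()),
                    "mean_b": float(table[cb].mean()),
                    "n_effective": res.n_effective,
                    "W": res.statistic,
                    "p": res.p_two_sided,
                    "method": res.method,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["region_a", "region_b", "mean_a", "mean_b", "n_effective", "W",
                 "p", "method"],
    )


def cmd_report(cfg: RunConfig) -> None:
    """Consolidated machine-readable summary of every available stage output."""
    rows = []
    tests_path = cfg.outdir / "metrics_tests.tsv"
    if tests_path.exists():
        for _, r in pd.read_csv(tests_path, sep="\t").iterrows():
            rows.append(
                {
                    "family": "region_metric",
                    "name": r["metric"],
                    "n": r["n_effective"],
                    "estimate": r["W"],
                    "p": r["p"],
                    "significant": r["p"] < 0.05 if pd.notna(r["p"]) else False,
                }
            )
    for label, _, _ in _COMPARISONS:
        for suffix, family in (("aa", "aa_enrichment"), ("properties", "property_enrichment")):
            path = cfg.outdir / f"enrichment_{label}_{suffix}.tsv"
            if not path.exists():
                continue
            df = pd.read_csv(path, sep="\t")
            rows.append(
                {
                    "family": family,
                    "name": label,
                    "n": len(df),
                    "estimate": float(df["significant"].sum()),
                    "p": float(df["p"].min()),
                    "significant": bool(df["significant"].any()),
                }
            )
    for name, path in (
        ("entropy", cfg.outdir / "conservation_tests.tsv"),
        ("et_rank", cfg.outdir / "et_tests.tsv"),
    ):
        if path.exists():
            for _, r in pd.read_csv(path, sep="\t").iterrows():
                rows.append(
                    {
                        "family": name,
                        "name": f"{r['region_a']}_vs_{r['region_b']}",
                        "n": r["n_effective"],
                        "estimate": r["mean_a"] - r["mean_b"],
                        "p": r["p"],
                        "significant": r["p"] < 0.05 if pd.notna(r["p"]) else False,
                    }
                )
    _write(pd.DataFrame(rows), cfg.outdir / "summary.tsv")
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": sorted(
            p.name for p in cfg.outdir.glob("*.tsv")
        ),
    }
    with open(cfg.outdir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(cfg: RunConfig) -> None:
    """Run every applicable stage in order."""
    if cfg.simulate:
        cmd_simulate(cfg)
    cmd_annotate(cfg)
    cmd_metrics(cfg)
    cmd_enrich(cfg)
    paths = _input_paths(cfg)
    if paths.get("msa_dir") and Path(paths["msa_dir"]).is_dir():
        cmd_conserve(cfg)
    cmd_report(cfg)
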