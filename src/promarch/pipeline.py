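"""End-to-end orchestration of the analysis stages.

Mirrors the three classic stages of this kind of study — data preparation,
promoter/peak overlap detection, and statistics — behind one config object
and a set of subcommands (``simulate``, ``profile``, ``breadth``,
``associate``, ``boundary``, ``stacking``, ``paralogs``, ``predict``).  Each
run writes its outputs plus a manifest (config hash, seed, package version)
into the output directory; deterministic stages reproduce byte-identical
outputs under the same manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture, association, expression as exm, paralogs as par
from .intervals import (
    GenomicInterval,
    filter_by_score,
    parse_bed,
    promoter_window,
    read_annotations,
    map_peaks_to_windows,
    write_bed,
)
from .synthetic import SyntheticConfig, gen_annotation, gen_expression, gen_paralog_families, gen_peaks, sample_classes

__all__ = ["RunConfig", "PipelineError", "load_config", "save_config", "run", "SUBCOMMANDS"]

log = logging.getLogger("promarch")

SUBCOMMANDS = (
    "simulate", "profile", "breadth", "associate", "boundary",
    "stacking", "paralogs", "predict",
)


class PipelineError(RuntimeError):
    """A pipeline-level failure (missing input, invalid config, degenerate data)."""


@dataclass
class RunConfig:
    input_dir: str = "."
    window_half_width: int = 500
    score_cutoff: int = 500
    tpm_cutoffs: tuple[float, ...] = (10.0, 100.0, 1000.0)
    active_tpm_cutoff: float = 10.0
    pol2_labels: tuple[str, ...] = tuple(sorted(architecture.POL2_LABELS))
    n_reps: int = 1000
    seed: int = 0
    boundary_grid: tuple[int, ...] = architecture.DEFAULT_GRID
    boundary_tolerance: float = 0.05
    breadth_broad_cutoff: float = 0.33
    tfbs_rich_cutoff: int = 10
    n_randomizations: int = 1
    simulate: dict = field(default_factory=dict)  # SyntheticConfig overrides

    def validate(self) -> None:
        if self.window_half_width <= 0:
            raise PipelineError("invalid config value: window_half_width must be positive")
        if not (0 <= self.score_cutoff <= 1000):
            raise PipelineError("invalid config value: score_cutoff outside [0, 1000]")
        if any(c < 0 for c in self.tpm_cutoffs):
            raise PipelineError("invalid config value: tpm_cutoffs must be non-negative")
        if self.n_reps < 1:
            raise PipelineError("invalid config value: n_reps must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config; defaults fill absent fields, unknown fields reject."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise PipelineError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise PipelineError(f"unknown config field(s): {sorted(unknown)}")
    for f in dataclasses.fields(RunConfig):
        if f.name in data and isinstance(f.default, tuple) and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, subcommand: str, config: RunConfig, inputs: list[str]) -> None:
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "inputs": sorted(inputs),
        "config": dataclasses.asdict(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    save_config(config, outdir / "config.yaml")


def _require(path: Path) -> Path:
    if not path.exists():
        raise PipelineError(f"missing input: {path}")
    return path


def _load_inputs(config: RunConfig):
    indir = Path(config.input_dir)
    with open(_require(indir / "annotations.bed")) as fh:
        anns = read_annotations(fh)
    with open(_require(indir / "peaks.bed")) as fh:
        peaks = parse_bed(fh)
    return anns, peaks


def _profile_frame(config: RunConfig, anns, peaks) -> pd.DataFrame:
    kept = filter_by_score(peaks, config.score_cutoff)
    windows = [promoter_window(tx, config.window_half_width) for tx in anns]
    mapped = map_peaks_to_windows(windows, kept)
    profiles = architecture.count_metrics(
        mapped,
        config.pol2_labels,
        window_half_width=config.window_half_width,
        score_cutoff=config.score_cutoff,
    )
    return architecture.profiles_to_frame(profiles)


def run(subcommand: str, config: RunConfig, outdir: str | Path) -> dict:
    """Execute one stage; returns a small dict of headline numbers.

    Inputs are read from ``config.input_dir`` (the output of ``simulate``
    unless real files are supplied); every stage writes tables plus a
    manifest under ``outdir`` and never mutates its inputs.
    """
    if subcommand not in SUBCOMMANDS:
        raise PipelineError(f"unknown subcommand: {subcommand}")
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: list[str] = []
    result: dict = {}

    if subcommand == "simulate":
        scfg = SyntheticConfig(seed=config.seed, **config.simulate)
        anns = gen_annotation(scfg)
        peaks, richness = gen_peaks(scfg, anns)
        expr = gen_expression(scfg, anns, richness)
        # 1-bp BED records whose 5' coordinate is the TSS under the usual
        # convention (start for '+', end for '-')
        with open(outdir / "annotations.bed", "w") as fh:
            write_bed(
                [
                    tx.span if tx.span is not None else GenomicInterval(
                        tx.chrom,
                        tx.tss if tx.strand == "+" else tx.tss - 1,
                        tx.tss + 1 if tx.strand == "+" else tx.tss,
                        tx.strand, 0, tx.tx_id,
                    )
                    for tx in anns
                ],
                fh,
            )
        with open(outdir / "peaks.bed", "w") as fh:
            write_bed(peaks, fh)
        table = exm.ExpressionTable(expr, sample_classes(scfg))
        with open(outdir / "expression.tsv", "w") as fh:
            exm.write_expression_table(table, fh)
        pdata = gen_paralog_families(scfg, expr)
        pdata.pairs.to_csv(outdir / "paralog_pairs.tsv", sep="\t", index=False)
        pdata.genes.to_csv(outdir / "paralog_genes.tsv", sep="\t")
        pdata.expression.to_csv(outdir / "paralog_expression.tsv", sep="\t", index_label="gene")
        with open(outdir / "repertoires.json", "w") as fh:
            json.dump({g: sorted(r) for g, r in pdata.repertoires.items()}, fh, indent=0, sort_keys=True)
        np.savetxt(outdir / "richness.txt", richness, fmt="%d")
        result = {"n_transcripts": len(anns), "n_peaks": len(peaks)}

    elif subcommand == "profile":
        anns, peaks = _load_inputs(config)
        inputs = ["annotations.bed", "peaks.bed"]
        prof = _profile_frame(config, anns, peaks)
        prof.to_csv(outdir / "profiles.tsv", sep="\t")
        summ = architecture.summarize_distribution(prof["tfbs_total"].to_numpy())
        result = {"median_tfbs": summ.tukey_five[2], "mean_tfbs": summ.mean}

    elif subcommand == "breadth":
        indir = Path(config.input_dir)
        inputs = ["expression.tsv"]
        table = exm.read_expression_table(_require(indir / "expression.tsv"))
        summ = exm.summarize_expression(table, config.tpm_cutoffs, config.active_tpm_cutoff)
        summ.to_csv(outdir / "expression_summary.tsv", sep="\t")
        fracs = summ["breadth_class"].value_counts(normalize=True).to_dict()
        result = {f"frac_{k}": float(v) for k, v in fracs.items()}

    elif subcommand == "associate":
        anns, peaks = _load_inputs(config)
        indir = Path(config.input_dir)
        inputs = ["annotations.bed", "peaks.bed", "expression.tsv"]
        prof = _profile_frame(config, anns, peaks)
        table = exm.read_expression_table(_require(indir / "expression.tsv"))
        summ = exm.summarize_expression(table, config.tpm_cutoffs, config.active_tpm_cutoff)
        boe_col = f"boe_{config.active_tpm_cutoff:g}"
        joined = prof.join(summ[[boe_col]], how="inner").dropna()
        for col in ("tfbs_total", boe_col):
            if joined[col].nunique() <= 1:
                raise PipelineError(f"constant column: {col}")
        corr = association.correlate(joined["tfbs_total"], joined[boe_col])
        null = association.shuffle_null(
            joined["tfbs_total"].to_numpy(), joined[boe_col].to_numpy(),
            n_reps=config.n_reps, seed=config.seed,
        )
        report = {
            "r": corr.r, "t": corr.t, "df": corr.df, "p": corr.p, "n": corr.n,
            "null_mean_t": float(null.replicates.mean()),
            "empirical_p": null.empirical_p,
        }
        (outdir / "association.json").write_text(json.dumps(report, indent=2) + "\n")
        result = report

    elif subcommand == "boundary":
        anns, peaks = _load_inputs(config)
        inputs = ["annotations.bed", "peaks.bed"]
        kept = filter_by_score(peaks, config.score_cutoff)
        est = architecture.estimate_boundary(
            anns, kept, grid=config.boundary_grid, tolerance=config.boundary_tolerance
        )
        pd.DataFrame({
            "half_width": est.grid,
            "mean_count": est.mean_counts,
            "smoothed": est.smoothed,
        }).to_csv(outdir / "boundary_sweep.tsv", sep="\t", index=False)
        (outdir / "boundary.json").write_text(json.dumps({"boundary": est.boundary}) + "\n")
        result = {"boundary": est.boundary}

    elif subcommand == "stacking":
        anns, peaks = _load_inputs(config)
        inputs = ["annotations.bed", "peaks.bed"]
        kept = filter_by_score(peaks, config.score_cutoff)
        windows = [promoter_window(tx, config.window_half_width) for tx in anns]
        mapped = map_peaks_to_windows(windows, kept)
        pairs = [(w, mapped[w.tx_id]) for w in windows if len(mapped[w.tx_id]) >= 2]
        if not pairs:
            raise PipelineError("no promoter has >= 2 peaks")
        res = architecture.stacking_test(pairs, config.n_randomizations, seed=config.seed)
        report = dataclasses.asdict(res)
        (outdir / "stacking.json").write_text(json.dumps(report, indent=2) + "\n")
        result = report

    elif subcommand == "paralogs":
        indir = Path(config.input_dir)
        inputs = ["paralog_pairs.tsv", "paralog_expression.tsv", "repertoires.json"]
        pairs = par.read_paralog_table(_require(indir / "paralog_pairs.tsv"))
        expr = pd.read_csv(_require(indir / "paralog_expression.tsv"), sep="\t", index_col=0)
        reps = {g: frozenset(v) for g, v in json.loads(_require(indir / "repertoires.json").read_text()).items()}
        records = par.build_divergence_records(pairs, reps, expr, config.active_tpm_cutoff)
        records.to_csv(outdir / "divergence_records.tsv", sep="\t", index=False)
        corr = par.divergence_analysis(records)
        summary, tests = par.age_group_summary(records)
        summary.to_csv(outdir / "age_group_summary.tsv", sep="\t")
        tests.to_csv(outdir / "age_group_tests.tsv", sep="\t", index=False)
        result = {"r_ji_coexpr": corr.r, "p": corr.p, "n_pairs": corr.n}
        (outdir / "paralogs.json").write_text(json.dumps(result, indent=2) + "\n")

    elif subcommand == "predict":
        anns, peaks = _load_inputs(config)
        indir = Path(config.input_dir)
        inputs = ["annotations.bed", "peaks.bed", "expression.tsv"]
        kept = filter_by_score(peaks, config.score_cutoff)
        windows = [promoter_window(tx, config.window_half_width) for tx in anns]
        mapped = map_peaks_to_windows(windows, kept)
        feats = architecture.label_count_matrix(mapped)
        table = exm.read_expression_table(_require(indir / "expression.tsv"))
        summ = exm.summarize_expression(table, config.tpm_cutoffs, config.active_tpm_cutoff)
        boe_col = f"boe_{config.active_tpm_cutoff:g}"
        common = feats.index.intersection(summ.index)
        rep = association.fit_predictor(
            feats.loc[common], summ.loc[common, boe_col].to_numpy(), split_seed=config.seed
        )
        report = {k: v for k, v in dataclasses.asdict(rep).items()}
        (outdir / "predictor.json").write_text(json.dumps(report, indent=2) + "\n")
        result = report

    _write_manifest(outdir, subcommand, config, inputs)
    log.info("%s finished: %s", subcommand, {k: v for k, v in result.items() if not isinstance(v, dict)})
    return result
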