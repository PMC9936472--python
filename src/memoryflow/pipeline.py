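"""End-to-end orchestration of the transcriptional memory pipeline.

A single :class:`RunConfig` drives simulation of every input (or loading of
user files), the screen statistic, memory classification, turnover
estimation and occupancy/CRAC features, with one global seed from which
each stage derives an independent substream.  Every stage writes plain-text
tables plus a JSON run report with conserved record counts
(in = kept + filtered for every filter).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .expression import ExpressionMemoryModel
from .occupancy import OccupancyAnalysis, crac_normalize
from .screen import ScreenMemoryModel
from .synthetic import (
    CoverageSignalSpec,
    ExpressionSimConfig,
    ScreenSimConfig,
    SlamSimConfig,
    simulate_coverage,
    simulate_crac,
    simulate_expression,
    simulate_screen,
    simulate_slam,
)
from .turnover import TurnoverModel

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

ALL_STAGES = ("screen", "classify", "turnover", "occupancy", "crac")


@dataclass
class RunConfig:
    """Parameters of a pipeline run; defaults are the published thresholds."""

    stages: tuple = ALL_STAGES
    out_dir: str = "memoryflow_out"
    seed: int = 0
    # screen
    z_threshold: float = 4.0
    n_strains: int = 40
    n_memory_strains: int = 6
    screen_delta: float = 1.5
    # classification
    ratio: float = 1.5
    delta: float = 0.58
    alpha: float = 0.001
    genes_per_category: int = 30
    # turnover
    min_reads: int = 20
    t_label: float = 10.0
    # occupancy / CRAC
    min_counts: int = 20
    n_coverage_genes: int = 20
    n_crac_genes: int = 200

    def to_flat(self) -> dict:
        d = asdict(self)
        d["stages"] = ",".join(self.stages)
        return d

    @classmethod
    def from_flat(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("stages"), str):
            d["stages"] = tuple(s for s in d["stages"].split(",") if s)
        return cls(**d)


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(ALL_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(ALL_STAGES, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages on synthetic data; returns the run report.

    Outputs are written under ``config.out_dir``; the report is also saved
    there as ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {"seed": config.seed, "parameters": config.to_flat(),
                    "stages": {}}
    from . import __version__

    report["version"] = __version__
    prov = [f"seed = {config.seed}"]

    if "screen" in config.stages:
        rng = np.random.default_rng(seeds["screen"])
        names = [f"strain_{i:04d}" for i in range(config.n_strains)]
        memory = rng.choice(config.n_strains, size=config.n_memory_strains,
                            replace=False)
        effects = {
            names[i]: float(config.screen_delta * (1 if k % 2 == 0 else -1))
            for k, i in enumerate(sorted(memory))
        }
        sim = ScreenSimConfig(n_strains=config.n_strains,
                              effect_table=effects, seed=seeds["screen"])
        counts, facs, truth = simulate_screen(sim)
        model = ScreenMemoryModel(counts, facs)
        res = model.fit(z_threshold=config.z_threshold)
        mio.write_tsv(counts, out / "screen_counts.tsv", prov)
        mio.write_tsv(facs, out / "screen_facs.tsv", prov)
        mio.write_tsv(truth, out / "screen_truth.tsv", prov)
        mio.write_tsv(res.calls.reset_index(), out / "screen_calls.tsv", prov)
        mio.write_tsv(res.gfp_scores.reset_index(),
                      out / "screen_gfp_scores.tsv", prov)
        n_in = counts["strain"].nunique() - truth["is_control"].sum()
        n_called = int(len(res.calls))
        report["stages"]["screen"] = {
            "records_in": int(n_in),
            "records_out": n_called,
            "filtered": int(n_in - n_called),
            "significant": int(res.calls["significant"].sum()),
        }

    if "classify" in config.stages:
        sim = ExpressionSimConfig(genes_per_category=config.genes_per_category,
                                  seed=seeds["classify"])
        counts, info, truth = simulate_expression(sim)
        model = ExpressionMemoryModel(
            counts, info, pd.Series(True, index=counts.index)
        )
        res = model.fit(alpha=config.alpha, ratio=config.ratio,
                        delta=config.delta)
        mio.write_tsv(counts.reset_index(), out / "expression_counts.tsv", prov)
        mio.write_tsv(info, out / "expression_design.tsv", prov)
        mio.write_tsv(truth, out / "expression_truth.tsv", prov)
        mio.write_tsv(res.annotation.reset_index(names="gene"),
                      out / "memory_annotation.tsv", prov)
        (out / "memory_categories.json").write_text(
            json.dumps({k: int(v) for k, v in res.category_counts().items()},
                       indent=2, sort_keys=True) + "\n"
        )
        report["stages"]["classify"] = {
            "records_in": int(len(counts)),
            "records_out": int(len(res.annotation)),
            "filtered": int(len(counts) - len(res.annotation)),
        }

    if "turnover" in config.stages:
        sim = SlamSimConfig(seed=seeds["turnover"])
        counts, truth = simulate_slam(sim)
        res = TurnoverModel(counts).fit(min_reads=config.min_reads,
                                        t_label_minutes=config.t_label)
        mio.write_tsv(counts, out / "slam_counts.tsv", prov)
        mio.write_tsv(truth, out / "slam_truth.tsv", prov)
        mio.write_tsv(res.table, out / "turnover.tsv", prov)
        if res.rates is not None:
            mio.write_tsv(res.rates, out / "decay_rates.tsv", prov)
        report["stages"]["turnover"] = {
            "records_in": int(len(counts)),
            "records_out": int(len(res.table)),
            "filtered": int(len(counts) - len(res.table)),
        }

    if "occupancy" in config.stages:
        plus, minus, ann, truth = simulate_coverage(
            config.n_coverage_genes, CoverageSignalSpec(),
            seed=seeds["occupancy"],
        )
        analysis = OccupancyAnalysis(plus, minus, ann)
        means = analysis.region_means()
        profile = analysis.metagene(flank=400)
        mio.write_bedgraph(plus, out / "coverage_plus.bedgraph", prov)
        mio.write_bedgraph(minus, out / "coverage_minus.bedgraph", prov)
        mio.write_bed6(ann, out / "genes.bed")
        mio.write_tsv(truth, out / "coverage_truth.tsv", prov)
        mio.write_tsv(means, out / "region_coverage.tsv", prov)
        mio.write_tsv(profile, out / "metagene_profile.tsv", prov)
        report["stages"]["occupancy"] = {
            "records_in": int(len(ann)),
            "records_out": int(means["gene"].nunique()),
            "filtered": int(len(ann) - means["gene"].nunique()),
        }

    if "crac" in config.stages:
        rng = np.random.default_rng(seeds["crac"])
        assoc = np.where(rng.random(config.n_crac_genes) < 0.5, 0.5, 2.0)
        table, truth = simulate_crac(config.n_crac_genes, assoc,
                                     seed=seeds["crac"])
        scores = crac_normalize(table, min_counts=config.min_counts)
        mio.write_tsv(table, out / "crac_counts.tsv", prov)
        mio.write_tsv(truth, out / "crac_truth.tsv", prov)
        mio.write_tsv(scores.reset_index(), out / "crac_scores.tsv", prov)
        report["stages"]["crac"] = {
            "records_in": int(len(table)),
            "records_out": int(len(scores)),
            "filtered": int(len(table) - len(scores)),
        }

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def validate_inputs(paths: dict) -> list[dict]:
    """Validate input files against their schemas.

    ``paths`` maps a kind in {"slam", "bed", "screen_counts", "facs"} to a
    file path.  Returns a list of violation records (empty when all files
    are valid); validation failures are the output, not exceptions.
    """
    violations: list[dict] = []

    def add(path, line, message):
        violations.append({"file": str(path), "line": int(line),
                           "message": message})

    for kind, path in paths.items():
        try:
            if kind == "slam":
                df = mio.read_tsv(path)
                for col in ("gene", "condition", "total_reads",
                            "converted_reads"):
                    if col not in df.columns:
                        add(path, 1, f"missing column {col!r}")
                if not violations or violations[-1]["file"] != str(path):
                    bad = df["converted_reads"] > df["total_reads"]
                    for i in df.index[bad]:
                        add(path, i + 2, "converted_reads > total_reads")
                    neg = (df[["total_reads", "converted_reads"]] < 0).any(axis=1)
                    for i in df.index[neg]:
                        add(path, i + 2, "negative read count")
            elif kind == "bed":
                df = pd.read_csv(path, sep="\t", comment="#", header=None)
                if df.shape[1] < 6:
                    add(path, 1, "BED6 requires 6 columns")
                else:
                    bad = ~df[5].isin(["+", "-"])
                    for i in df.index[bad]:
                        add(path, i + 1, f"invalid strand {df.loc[i, 5]!r}")
                    rev = df[2] <= df[1]
                    for i in df.index[rev]:
                        add(path, i + 1, "end must be > start")
            elif kind == "screen_counts":
                df = mio.read_tsv(path)
                for col in ("strain", "timepoint", "window", "replicate",
                            "count"):
                    if col not in df.columns:
                        add(path, 1, f"missing column {col!r}")
                if "count" in df.columns:
                    neg = df["count"] < 0
                    for i in df.index[neg]:
                        add(path, i + 2, "negative count")
            elif kind == "facs":
                df = mio.read_tsv(path)
                for col in ("timepoint", "window", "events"):
                    if col not in df.columns:
                        add(path, 1, f"missing column {col!r}")
            else:
                add(path, 0, f"unknown input kind {kind!r}")
        except Exception as exc:  # unreadable file is itself a violation
            add(path, 0, f"unreadable: {exc}")
    return violations
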