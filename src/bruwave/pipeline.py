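"""Pipeline orchestration: quantify -> classify -> wavefront, with config
validation, deterministic report outputs, and a provenance block."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from ._tsv import write_tsv
from .classify import classify_all, order_for_heatmap, summarize_counts, write_calls
from .quant import (
    StrandedCoverageSet,
    build_expression_matrix,
    expressed_filter,
    read_genes,
)
from .wavefront import FrontParams, run_wavefront, write_wavefront

log = logging.getLogger("bruwave")


@dataclass
class RunConfig:
    genes: str = ""
    samples: str = ""
    out: str = "bruwave_out"
    baseline: str = "starved"
    cap: int = 30_000
    min_interval: int = 300
    expressed_threshold: float = 0.5
    pseudocount: float = 0.1
    fold: float = 2.0
    min_starved_rpkm: float = 0.5
    bin_size: int = 1000
    beta: float = 0.25
    smooth_w: int = 5
    noise_floor: float = 0.0
    gap_tol: int = 2
    min_run: int = 5
    min_length: int = 200_000
    round_to: int | None = None
    test: str = "wilcoxon"
    include_first_interval: bool = False
    top_n: int | None = None
    count_reversal_in_directions: bool = True
    seed: int = 0
    labeling_min: float = 30.0
    _extras: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        kwargs = {k: v for k, v in raw.items() if k in known}
        cfg = cls(**kwargs)
        cfg._extras = {k: v for k, v in raw.items() if k not in known}
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_extras", None)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Aggregate all configuration errors (no fail-fast)."""
    errors: list[str] = []
    if not 0 < config.beta < 1:
        errors.append("beta out of range (0, 1)")
    if config.pseudocount <= 0:
        errors.append("pseudocount must be > 0")
    if config.cap <= 0:
        errors.append("cap must be > 0")
    if config.bin_size <= 0:
        errors.append("bin_size must be > 0")
    if config.fold <= 1:
        errors.append("fold must be > 1")
    if config.min_length < 0:
        errors.append("min_length must be >= 0")
    if config.smooth_w < 1:
        errors.append("smooth_w must be >= 1")
    if config.test not in ("wilcoxon", "ttest"):
        errors.append("test must be 'wilcoxon' or 'ttest'")
    if not config.genes:
        errors.append("genes path not set")
    elif not os.path.exists(config.genes):
        errors.append(f"genes file not found: {config.genes}")
    if not config.samples:
        errors.append("samples path not set")
    elif not os.path.exists(config.samples):
        errors.append(f"samples file not found: {config.samples}")
    for key in config._extras:
        errors.append(f"unknown config key: {key}")
    return errors


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("out", None)  # output location is not an analysis parameter
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run quantify -> classify -> wavefront and write the report bundle.

    Outputs are deterministic for a fixed config and inputs (no timestamps
    in any file); returns the report dictionary.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    os.makedirs(config.out, exist_ok=True)
    with open(os.path.join(config.out, "config_used.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # -- quantify -----------------------------------------------------------
    try:
        genes = read_genes(config.genes)
        coverage = StrandedCoverageSet.from_sample_sheet(config.samples, config.bin_size)
        matrix = build_expression_matrix(
            genes, coverage, cap=config.cap, baseline=config.baseline,
            min_interval=config.min_interval)
    except (ValueError, OSError, KeyError) as exc:
        raise StageError("quantify", str(exc)) from exc
    matrix.to_tsv(os.path.join(config.out, "expression_matrix.tsv"))
    log.info("quantify: %d genes, %d windows", len(matrix.values), len(matrix.windows))

    # -- classify -----------------------------------------------------------
    try:
        expressed = expressed_filter(matrix, config.expressed_threshold)
        fc, calls = classify_all(
            matrix, pseudocount=config.pseudocount, fold=config.fold,
            min_starved_rpkm=config.min_starved_rpkm, genes=sorted(expressed))
        counts = summarize_counts(calls, config.count_reversal_in_directions)
        order = order_for_heatmap(calls, fc)
    except (ValueError, KeyError) as exc:
        raise StageError("classify", str(exc)) from exc
    write_calls(calls, os.path.join(config.out, "calls.tsv"))
    write_tsv(counts, os.path.join(config.out, "counts.tsv"))
    ordered_fc = fc.loc[order].reset_index().rename(columns={"index": "gene_id"})
    write_tsv(ordered_fc, os.path.join(config.out, "fc_matrix_ordered.tsv"))
    log.info("classify: %d expressed, %d responders", len(expressed),
             sum(1 for c in calls if c.direction != "none"))

    # -- wavefront ----------------------------------------------------------
    try:
        params = FrontParams(
            smooth_w=config.smooth_w, beta=config.beta,
            noise_floor=config.noise_floor, gap_tol=config.gap_tol,
            min_run=config.min_run, round_to=config.round_to)
        wf = run_wavefront(
            genes, coverage, calls, params=params, min_length=config.min_length,
            labeling_min=config.labeling_min,
            include_first=config.include_first_interval, test=config.test,
            top_n=config.top_n)
    except (ValueError, KeyError) as exc:
        raise StageError("wavefront", str(exc)) from exc
    write_wavefront(wf, config.out)
    log.info("wavefront: %d front calls, %d estimates", len(wf.fronts), len(wf.estimates))

    if not genes:
        log.warning("gene list is empty: report contains zero genes")

    report = {
        "provenance": {
            "package": "bruwave",
            "version": __version__,
            "config_sha256": _config_hash(config),
            "seed": config.seed,
        },
        "n_genes": len(genes),
        "n_quantified": int(len(matrix.values)),
        "n_expressed": int(len(expressed)),
        "n_responders": int(sum(1 for c in calls if c.direction != "none")),
        "counts": counts.to_dict(orient="records"),
        "cohort_stats": {
            mode: wf.stats[mode].to_dict(orient="records")
            for mode in ("advancing", "retreating")
        },
        "cohort_comparisons": {
            mode: wf.comparisons[mode].to_dict(orient="records")
            for mode in ("advancing", "retreating")
        },
    }
    with open(os.path.join(config.out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
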