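"""Configuration-driven orchestration: simulate -> TE -> sites -> stratify -> model.

A single YAML config drives the full analysis; every stage writes a TSV
intermediate so any stage can be re-run or tested in isolation, and a
manifest records the seed, filters and library versions. Outputs are
deterministic for a fixed config (seed included).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import DEFAULT_MIN_COUNT, read_expression_table, repression_records
from .featmodel import compare_te_models
from .simdata import MiRNA, SimParams, simulate, write_fixture, read_sequences
from .stratstats import SiteFilter, stratified_comparison
from .targets import classify_targets, read_targetscan_summary

log = logging.getLogger("temir")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str = "temir_out"
    seed: int = 0
    mirna_name: str = "miR-sim"
    mirna_seq: str | None = None
    simulate: dict | None = None  # SimParams overrides; presence enables simulation
    counts: str | None = None
    sequences: str | None = None
    annotation: str | None = None
    min_count: int = DEFAULT_MIN_COUNT
    binnings: tuple[str, ...] = ("median", "quartiles")
    site_filter: dict = field(default_factory=dict)
    cv_folds: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "binnings" in raw:
            raw["binnings"] = tuple(raw["binnings"])
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("counts", "sequences"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineError(
                        f"config: either 'simulate' or an input path for {name!r} is required"
                    )
                if not Path(p).exists():
                    raise PipelineError(f"config: {name} path {p} does not exist")
        if self.simulate is None and self.mirna_seq is None and self.annotation is None:
            raise PipelineError("config: need mirna_seq or an annotation table")
        for b in self.binnings:
            if b not in ("median", "quartiles"):
                raise PipelineError(f"config: unknown binning {b!r}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict that is also written.

    Outputs in ``config.out_dir``: the simulated fixture (when
    simulating), ``records.tsv``, ``annotation.tsv``, per-comparison
    stratification tables, ``summary.json`` and ``manifest.json``.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mirna = None
    if config.mirna_seq:
        mirna = MiRNA(config.mirna_name, config.mirna_seq)

    truth = None
    if config.simulate is not None:
        params = SimParams(**{**config.simulate, "seed": config.seed})
        if mirna is None:
            raise PipelineError("stage 'simulate' failed: simulation needs mirna_seq")
        tx, tables, truth = _stage("simulate")(simulate)(params, mirna)
        write_fixture(out_dir / "fixture", tx, tables, truth)
    else:
        tx = _stage("load-sequences")(read_sequences)(config.sequences)
        tables = {
            (assay, cond): _stage("load-counts")(read_expression_table)(
                config.counts, assay, cond
            )
            for assay in ("RPF", "RNA")
            for cond in ("mock", "mir")
        }

    records = _stage("expression")(repression_records)(
        tables[("RPF", "mock")],
        tables[("RPF", "mir")],
        tables[("RNA", "mock")],
        tables[("RNA", "mir")],
        min_count=config.min_count,
    )
    if records.empty:
        raise PipelineError("stage 'expression' failed: no genes pass the count filters")
    records.to_csv(out_dir / "records.tsv", sep="\t")
    n_dropped = len(tx) - len(records)
    log.info("expression: %d genes retained, %d dropped by filters", len(records), n_dropped)

    if config.annotation is not None:
        annotation = _stage("annotation")(read_targetscan_summary)(config.annotation)
    else:
        annotation = _stage("sites")(classify_targets)(
            tx["utr3"].to_dict(), mirna
        )
    annotation.to_csv(out_dir / "annotation.tsv", sep="\t")

    sf = SiteFilter(**config.site_filter)
    summary: dict = {
        "n_genes": int(len(tx)),
        "n_records": int(len(records)),
        "n_dropped_by_filters": int(n_dropped),
        "stratified": {},
    }
    for assay in ("RPF", "RNA"):
        for binning in config.binnings:
            res = _stage(f"stratify-{assay}-{binning}")(stratified_comparison)(
                records, annotation, assay=assay, binning=binning, site_filter=sf
            )
            key = f"{assay.lower()}_{binning}"
            res.summary_frame().to_csv(out_dir / f"stratified_{key}.tsv", sep="\t", index=False)
            res.ks_frame().to_csv(out_dir / f"ks_{key}.tsv", sep="\t", index=False)
            summary["stratified"][key] = {
                "bins": [
                    {"label": b.label, "n": b.n, "median_fc": round(b.median_fc, 6)}
                    for b in res.bins
                ],
                "all_targets": {
                    "n": res.all_targets.n,
                    "median_fc": round(res.all_targets.median_fc, 6),
                },
                "ks": {
                    f"{a} vs {b}": {"D": round(d, 6), "p": float(f"{p:.6g}")}
                    for (a, b), (d, p) in res.pairwise_ks.items()
                },
            }

    comp = _stage("model")(compare_te_models)(
        records, cv_folds=config.cv_folds, seed=config.seed
    )
    summary["model"] = {
        "cv_r_with_te": round(comp["with_te"].cv_r, 6),
        "cv_r_without_te": round(comp["without_te"].cv_r, 6),
        "delta_cv_r": round(comp["delta_cv_r"], 6),
        "r_insample_with_te": round(comp["with_te"].r_insample, 6),
        "r_insample_without_te": round(comp["without_te"].r_insample, 6),
        "n": comp["with_te"].n,
    }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "temir_version": __version__,
        "seed": config.seed,
        "min_count": config.min_count,
        "site_filter": sf.describe(),
        "binnings": list(config.binnings),
        "simulated": config.simulate is not None,
        "versions": _library_versions(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def _library_versions() -> dict[str, str]:
    import numpy, scipy, statsmodels

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
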