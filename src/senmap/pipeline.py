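"""End-to-end pipeline driver: QC -> normalize -> gate -> score -> congruence
and/or the spatial test, from a single YAML config, with deterministic
per-stage seeding and plain-TSV outputs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    log_normalize,
    qc_filter_cells,
    read_expression,
    read_geneset,
    read_spot_expression,
    read_spot_table,
    attach_expression,
)
from .gating import gate_senescent, marker_positive, score_cell_cycle
from .scoring import composite_score
from .congruence import congruence, de_test
from .spatial import SampleExcludedError, run_spatial_test

log = logging.getLogger("senmap")

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and stage name, so
    reordering stages never changes a stage's random stream."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    """Paths and thresholds for a full run; defaults follow the pipeline's
    published conventions (positivity 0.5 log-normalized, spatial threshold
    1.0 normalized, ln fold-change cutoff 0.25, alpha 0.05, B = 10,000)."""

    out_dir: str = "senmap_run"
    matrix: str | None = None
    genes: str | None = None
    cells: str | None = None
    geneset: str | None = None
    geneset_format: str = "two_column"
    positions: str | None = None
    spot_expr: str | None = None
    marker: str = "CDKN1A"
    positivity_threshold: float = 0.5
    spatial_threshold: float = 1.0
    fc_cutoff: float = 0.25
    alpha: float = 0.05
    B: int = 10_000
    max_genes: int = 5000
    max_mito_frac: float = 0.05
    scale: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.positivity_threshold < 0 or self.spatial_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _check_paths(config: RunConfig) -> None:
    for name in ("matrix", "genes", "cells", "geneset", "positions", "spot_expr"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise FileNotFoundError(f"config {name}: {value} does not exist")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write one TSV per stage plus a
    ``run.json`` manifest.  Identical config and seed give byte-identical
    outputs.  On stage failure, partial outputs are kept next to a FAILED
    marker naming the stage."""
    _check_paths(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": [],
    }
    stage = "start"
    try:
        if config.matrix is not None:
            stage = "qc"
            t0 = time.time()
            m = read_expression(config.matrix, config.genes, config.cells)
            m = qc_filter_cells(
                m, max_genes=config.max_genes, max_mito_frac=config.max_mito_frac
            )
            log.info("qc: %d genes x %d cells after filtering (%.1fs)",
                     m.n_genes, m.n_cells, time.time() - t0)
            manifest["stages"].append({"stage": "qc", "n_genes": m.n_genes, "n_cells": m.n_cells})

            stage = "normalize"
            m = log_normalize(m, scale=config.scale)

            stage = "gate"
            cc = score_cell_cycle(m, seed=stage_seed(config.seed, "gate"))
            cells = m.meta.join(cc, how="left") if not m.meta.empty else cc
            cells[f"{config.marker}_pos"] = marker_positive(
                m, config.marker, config.positivity_threshold
            )
            cells = gate_senescent(cells, config.marker)
            cells.to_csv(out / "cells.tsv", sep="\t")
            manifest["stages"].append(
                {"stage": "gate", "n_senescent": int(cells["senescent"].sum())}
            )

            if config.geneset is not None:
                stage = "score"
                gs = read_geneset(config.geneset, format=config.geneset_format)[0]
                result = composite_score(m, gs)
                result.to_frame().to_csv(out / "scores.tsv", sep="\t")
                manifest["stages"].append(
                    {
                        "stage": "score",
                        "geneset": gs.name,
                        "genes_used_up": result.genes_used_up,
                        "genes_used_down": result.genes_used_down,
                        "dropped": result.dropped_genes,
                    }
                )

                stage = "congruence"
                sen = cells["senescent"].to_numpy(dtype=bool)
                de = de_test(
                    m, sen, ~sen, fc_cutoff=config.fc_cutoff, alpha=config.alpha
                )
                de.to_csv(out / "de.tsv", sep="\t")
                cong = congruence(de, gs)
                pd.DataFrame(
                    {
                        "geneset": [cong.geneset],
                        "n_total": [cong.n_total],
                        "n_congruent": [cong.n_congruent],
                        "proportion": [cong.proportion],
                    }
                ).to_csv(out / "congruence.tsv", sep="\t", index=False)
                manifest["stages"].append(
                    {
                        "stage": "congruence",
                        "n_congruent": cong.n_congruent,
                        "n_total": cong.n_total,
                    }
                )

        if config.positions is not None:
            stage = "spatial"
            grid = read_spot_table(config.positions)
            if config.spot_expr is not None:
                grid = attach_expression(grid, read_spot_expression(config.spot_expr))
            try:
                res = run_spatial_test(
                    grid,
                    config.marker,
                    threshold=config.spatial_threshold,
                    B=config.B,
                    seed=stage_seed(config.seed, "spatial"),
                    alpha=config.alpha,
                )
                pd.DataFrame(
                    {
                        "sample_id": [res.sample_id],
                        "gene": [res.gene],
                        "threshold": [res.threshold],
                        "n_spots": [res.n_spots],
                        "n_positive": [res.n_positive],
                        "observed_in_clusters": [res.observed_in_clusters],
                        "proportion_in_clusters": [res.proportion_in_clusters],
                        "percentile": [res.percentile],
                        "p_wilcoxon": [res.p_wilcoxon],
                        "p_empirical": [res.p_empirical],
                        "call": [res.call],
                    }
                ).to_csv(out / "spatial.tsv", sep="\t", index=False)
                np.savetxt(out / "spatial_null.tsv", res.null_draws, fmt="%d")
                manifest["stages"].append({"stage": "spatial", "call": res.call})
            except SampleExcludedError as exc:
                manifest["stages"].append({"stage": "spatial", "excluded": str(exc)})
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "run.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
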