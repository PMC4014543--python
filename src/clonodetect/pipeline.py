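"""End-to-end orchestration: simulate/load -> preprocess -> detect -> compare.

A :class:`PipelineConfig` (loadable from YAML) names at least two datasets,
each either a path to an annotated-read TSV (with an optional column-name
dialect) or an inline simulation spec. The run writes, under the output
directory: per-dataset clonotype tables and filter reports, multiway and
pairwise detection results, rank comparisons, the top-k overlap, and a
manifest with a checksum per output file. Reruns with the same config
reproduce every output bit-exactly.

Execution is single-process and in-memory: repertoires at desk scale (up
to a few million reads) fit comfortably, and simplicity wins over
parallelism.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .detection import detect_multiway
from .io import read_annotated_table, write_clonotype_table
from .preprocess import preprocess
from .simulate import (
    SyntheticRepertoireConfig,
    generate_ground_truth,
    simulate_library,
)
from .stats import pairwise_comparison_matrix, top_k_overlap
from .tables import ClonotypeTable

logger = logging.getLogger("clonodetect")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the dataset and stage."""


@dataclass
class DatasetSpec:
    """One input dataset: either a file on disk or a simulation recipe."""

    dataset_id: str
    path: str | None = None
    dialect: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if (self.path is None) == (self.simulate is None):
            raise ValueError(
                f"dataset {self.dataset_id!r}: exactly one of path/simulate required"
            )


@dataclass
class PipelineConfig:
    datasets: list[DatasetSpec]
    identifier_kind: str = "cdr3"
    min_cdr3_len: int = 4
    min_abundance: int = 2
    threshold: float = 0.95
    mode: str = "stop_at_first_drop"
    top_k: int = 30
    output_dir: str = "clonodetect_out"
    seed: int = 0
    drop_nonproductive: bool = False
    frequency_denominator: str = "retained"
    reference_dataset: str | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.datasets) < 2:
            raise ValueError("pipeline requires at least 2 datasets")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        datasets = [DatasetSpec(**d) for d in raw.pop("datasets")]
        return cls(datasets=datasets, **raw)


def _json_default(obj: Any) -> Any:
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_json(payload: Any, path: Path) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_dataset(spec: DatasetSpec, config: PipelineConfig):
    if spec.path is not None:
        return read_annotated_table(spec.path, spec.dialect)
    params = dict(spec.simulate or {})
    truth_seed = params.pop("truth_seed", config.seed)
    if "cdr3_length_range" in params:
        params["cdr3_length_range"] = tuple(params["cdr3_length_range"])
    sim_config = SyntheticRepertoireConfig(**params)
    truth = generate_ground_truth(
        SyntheticRepertoireConfig(
            n_clones=sim_config.n_clones,
            zipf_exponent=sim_config.zipf_exponent,
            cdr3_length_range=sim_config.cdr3_length_range,
            seed=truth_seed,
        )
    )
    return simulate_library(truth, sim_config, read_prefix=spec.dataset_id)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full comparison pipeline; returns the run report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    tables: list[ClonotypeTable] = []
    reports: dict[str, dict] = {}
    for spec in config.datasets:
        try:
            reads = _load_dataset(spec, config)
            logger.info("%s: loaded %d reads", spec.dataset_id, len(reads))
            table, report = preprocess(
                reads,
                identifier_kind=config.identifier_kind,
                dataset_id=spec.dataset_id,
                min_cdr3_len=config.min_cdr3_len,
                min_abundance=config.min_abundance,
                drop_nonproductive=config.drop_nonproductive,
                frequency_denominator=config.frequency_denominator,
            )
        except Exception as exc:
            raise PipelineError(
                f"dataset {spec.dataset_id!r}, stage preprocess: {exc}"
            ) from exc
        logger.info(
            "%s: %d reads in, %d clones out (%d singletons removed)",
            spec.dataset_id,
            report.n_input_reads,
            report.n_clones_final,
            report.n_singletons_removed,
        )
        tables.append(table)
        reports[spec.dataset_id] = report.as_dict()
        table_path = out_dir / f"{spec.dataset_id}.clonotypes.tsv"
        write_clonotype_table(table, table_path)
        outputs.append(table_path)

    try:
        results, summary = detect_multiway(tables, config.threshold, config.mode)
    except Exception as exc:
        raise PipelineError(f"stage detect_multiway: {exc}") from exc
    detection_payload = {
        "summary": summary,
        "results": [r.as_dict() for r in results],
    }

    try:
        matrix, comparisons = pairwise_comparison_matrix(
            tables, config.threshold, config.mode
        )
    except Exception as exc:
        raise PipelineError(f"stage pairwise_comparison: {exc}") from exc
    comparison_payload = {
        "r_matrix": {
            a: {b: (None if matrix.loc[a, b] != matrix.loc[a, b] else float(matrix.loc[a, b]))
                for b in matrix.columns}
            for a in matrix.index
        },
        "pairs": [
            dict(pair_a=a, pair_b=b, **(c.as_dict() if c else {"spearman_r": None}))
            for (a, b), c in comparisons.items()
        ],
    }

    reference = config.reference_dataset or config.datasets[0].dataset_id
    ref_table = next(t for t in tables if t.dataset_id == reference)
    topk_payload = None
    if len(ref_table) >= config.top_k:
        try:
            topk = top_k_overlap(tables, reference, config.top_k)
        except Exception as exc:
            raise PipelineError(f"stage top_k_overlap: {exc}") from exc
        topk_payload = topk.as_dict()

    report = {
        "config": {
            "identifier_kind": config.identifier_kind,
            "min_cdr3_len": config.min_cdr3_len,
            "min_abundance": config.min_abundance,
            "threshold": config.threshold,
            "mode": config.mode,
            "top_k": config.top_k,
            "seed": config.seed,
            "datasets": [d.dataset_id for d in config.datasets],
        },
        "filter_reports": reports,
        "detection": detection_payload,
        "comparison": comparison_payload,
        "top_k_overlap": topk_payload,
    }
    for name, payload in (
        ("filter_reports", reports),
        ("detection", detection_payload),
        ("comparison", comparison_payload),
        ("report", report),
    ):
        path = out_dir / f"{name}.json"
        _write_json(payload, path)
        outputs.append(path)

    manifest = {
        "clonodetect_version": __version__,
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    _write_json(manifest, out_dir / "manifest.json")
    return report
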