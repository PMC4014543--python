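"""Reusable study workflows: replicate comparison and RNA-input titration.

These functions compose the simulator with the preprocessing, detection and
comparison stages into the two analyses the package is built around:

- :func:`replicate_comparison`: several sequencing libraries of one
  repertoire (emulating library-preparation replicates), multiway reliable
  detection and pairwise rank correlation;
- :func:`titration_comparison`: libraries at decreasing template
  bottlenecks (emulating decreasing RNA input), pairwise rank correlation
  against the deepest library and top-k clone consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .detection import ReliableDetectionResult, detect_multiway
from .preprocess import filter_clonotypes
from .simulate import (
    GroundTruthRepertoire,
    SyntheticRepertoireConfig,
    generate_ground_truth,
    simulate_clonotypes,
    titration_seeds,
)
from .stats import pairwise_comparison_matrix, top_k_overlap
from .tables import ClonotypeTable


def simulate_filtered_tables(
    truth: GroundTruthRepertoire,
    configs: Sequence[SyntheticRepertoireConfig],
    dataset_ids: Sequence[str],
    min_abundance: int = 2,
) -> list[ClonotypeTable]:
    """Simulate one clonotype table per config and apply the abundance filter."""
    tables = []
    for config, dataset_id in zip(configs, dataset_ids):
        raw = simulate_clonotypes(truth, config, dataset_id)
        filtered, _ = filter_clonotypes(raw, min_abundance)
        tables.append(filtered)
    return tables


@dataclass
class ReplicateComparisonResult:
    tables: list[ClonotypeTable]
    detection_results: list[ReliableDetectionResult]
    detection_summary: dict
    r_matrix: "np.ndarray"
    mean_pairwise_r: float


def replicate_comparison(
    n_replicates: int = 3,
    base_config: SyntheticRepertoireConfig | None = None,
    truth: GroundTruthRepertoire | None = None,
    threshold: float = 0.95,
    mode: str = "stop_at_first_drop",
    min_abundance: int = 2,
    seed: int = 0,
) -> ReplicateComparisonResult:
    """Simulate replicates of one repertoire and compare them.

    Each replicate is an independent library (own sampling, amplification
    and error draws) of the same ground truth, the in-silico counterpart of
    preparing one sample several times.
    """
    if base_config is None:
        base_config = SyntheticRepertoireConfig(seed=seed)
    if truth is None:
        truth = generate_ground_truth(replace(base_config, seed=seed))
    seeds = titration_seeds(seed, n_replicates)
    configs = [replace(base_config, seed=s) for s in seeds]
    ids = [f"rep{i + 1}" for i in range(n_replicates)]
    tables = simulate_filtered_tables(truth, configs, ids, min_abundance)
    results, summary = detect_multiway(tables, threshold, mode)
    matrix, _ = pairwise_comparison_matrix(tables, threshold, mode)
    off_diag = matrix.to_numpy()[~np.eye(len(tables), dtype=bool)]
    return ReplicateComparisonResult(
        tables=tables,
        detection_results=results,
        detection_summary=summary,
        r_matrix=matrix,
        mean_pairwise_r=float(np.nanmean(off_diag)),
    )


@dataclass
class TitrationComparisonResult:
    bottlenecks: list[int]
    tables: list[ClonotypeTable]
    r_matrix: "np.ndarray"
    r_vs_deepest: list[float]
    cumulative_mean_r: list[float]
    detection_summary: dict
    top_k: dict | None


def titration_comparison(
    bottlenecks: Sequence[int] = (10**6, 10**5, 10**4, 10**3),
    base_config: SyntheticRepertoireConfig | None = None,
    truth: GroundTruthRepertoire | None = None,
    threshold: float = 0.95,
    mode: str = "stop_at_first_drop",
    min_abundance: int = 2,
    top_k: int | None = 30,
    seed: int = 0,
) -> TitrationComparisonResult:
    """Simulate a template-input titration and quantify the degradation.

    Reports the pairwise Spearman matrix over reliably detected clones, the
    correlation of each titrated library with the deepest one, the
    cumulative mean pairwise r as lower-input libraries are added, and the
    consistency of the lowest-input library's top-k clones across all
    libraries.
    """
    bottlenecks = list(bottlenecks)
    if base_config is None:
        base_config = SyntheticRepertoireConfig(depth=10**6, seed=seed)
    if truth is None:
        truth = generate_ground_truth(replace(base_config, seed=seed))
    seeds = titration_seeds(seed, len(bottlenecks))
    configs = [
        replace(base_config, bottleneck=b, seed=s)
        for b, s in zip(bottlenecks, seeds)
    ]
    ids = [f"bn{b}" for b in bottlenecks]
    tables = simulate_filtered_tables(truth, configs, ids, min_abundance)
    matrix, _ = pairwise_comparison_matrix(tables, threshold, mode)
    n = len(tables)
    r_vs_deepest = [float(matrix.iloc[0, j]) for j in range(1, n)]
    cumulative = [
        float(
            np.nanmean(
                [matrix.iloc[i, j] for i in range(k) for j in range(i + 1, k)]
            )
        )
        for k in range(2, n + 1)
    ]
    _, summary = detect_multiway(tables, threshold, mode)
    topk_payload = None
    if top_k is not None and len(tables[-1]) >= top_k:
        topk = top_k_overlap(tables, tables[-1].dataset_id, top_k)
        topk_payload = topk.as_dict()
    return TitrationComparisonResult(
        bottlenecks=bottlenecks,
        tables=tables,
        r_matrix=matrix,
        r_vs_deepest=r_vs_deepest,
        cumulative_mean_r=cumulative,
        detection_summary=summary,
        top_k=topk_payload,
    )
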