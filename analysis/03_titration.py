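"""Quantify how a shrinking template bottleneck degrades repertoire overlap.

Reads the titration libraries written by 01_simulate_libraries.py
(bottlenecks 1e6 -> 1e3 template molecules at constant sequencing depth),
preprocesses them, and reports the pairwise Spearman correlation of
reliably detected clones, the correlation of each library with the deepest
one, and the consistency of the lowest-input library's top-30 clones.
Writes results/titration.json.
"""

import json
from pathlib import Path

import numpy as np

from clonodetect.io import read_annotated_table
from clonodetect.preprocess import preprocess
from clonodetect.stats import pairwise_comparison_matrix, top_k_overlap

ROOT = Path(__file__).resolve().parent.parent
LIB = ROOT / "scratch" / "libraries"
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

bottlenecks = [10**6, 10**5, 10**4, 10**3]
tables = []
for bn in bottlenecks:
    reads = read_annotated_table(LIB / f"titration_bn{bn}.tsv")
    table, report = preprocess(reads, dataset_id=f"bn{bn}")
    print(f"bn{bn}: {report.n_clones_final} clones after filtering")
    tables.append(table)

matrix, _ = pairwise_comparison_matrix(tables, threshold=0.95)
print("pairwise Spearman r over reliably detected clones:")
print(matrix.round(3))

r_vs_deepest = [float(matrix.iloc[0, j]) for j in range(1, len(tables))]
print(
    "r vs deepest library (decreasing bottleneck):",
    " ".join(f"{r:.3f}" for r in r_vs_deepest),
)

topk = None
if len(tables[-1]) >= 30:
    topk = top_k_overlap(tables, tables[-1].dataset_id, k=30)
    print(
        f"top-30 clones of {topk.reference_dataset}: "
        f"{topk.n_present_in_all}/30 present in all libraries, "
        f"mean pairwise r over shared top clones = {topk.mean_pairwise_r:.3f}"
    )

payload = {
    "bottlenecks": bottlenecks,
    "r_matrix": {a: {b: float(matrix.loc[a, b]) for b in matrix.columns} for a in matrix.index},
    "r_vs_deepest": r_vs_deepest,
    "top_k_overlap": topk.as_dict() if topk else None,
}
(RESULTS / "titration.json").write_text(json.dumps(payload, indent=2) + "\n")
print(f"wrote {RESULTS / 'titration.json'}")
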