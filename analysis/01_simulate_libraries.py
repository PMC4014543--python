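"""Simulate the study's sequencing libraries.

Generates one 5,000-clone Zipf(1) ground-truth repertoire and writes, as
annotated-read TSVs under scratch/libraries/:

- three replicate libraries of 200,000 reads each (independent sampling,
  amplification and error draws of the same repertoire — the in-silico
  counterpart of preparing one sample with three library protocols);
- four titration libraries at template bottlenecks 1e6, 1e5, 1e4 and 1e3
  molecules (decreasing RNA input), 200,000 reads each.

Read tables are bulky intermediates, hence scratch/; the downstream
scripts write their summary tables under results/.
"""

from dataclasses import replace
from pathlib import Path

from clonodetect.io import write_annotated_table
from clonodetect.simulate import (
    SyntheticRepertoireConfig,
    generate_ground_truth,
    simulate_library,
    simulate_titration,
    titration_seeds,
)

SEED = 20240917
OUT = Path(__file__).resolve().parent.parent / "scratch" / "libraries"

base = SyntheticRepertoireConfig(n_clones=5000, depth=200_000, seed=SEED)
truth = generate_ground_truth(base)
OUT.mkdir(parents=True, exist_ok=True)

print(f"ground truth: {len(truth)} clones, top frequency {truth.true_frequency[0]:.4f}")

for j, s in enumerate(titration_seeds(SEED, 3)):
    lib = simulate_library(truth, replace(base, seed=s), read_prefix=f"rep{j+1}")
    path = OUT / f"replicate_{j+1}.tsv"
    write_annotated_table(lib, path)
    print(f"wrote {len(lib)} reads -> {path}")

bottlenecks = [10**6, 10**5, 10**4, 10**3]
for bn, lib in zip(bottlenecks, simulate_titration(truth, bottlenecks, base)):
    path = OUT / f"titration_bn{bn}.tsv"
    write_annotated_table(lib, path)
    print(f"wrote {len(lib)} reads (bottleneck {bn}) -> {path}")
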