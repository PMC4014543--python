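# clonodetect

Comparison of antibody-repertoire high-throughput sequencing (AIRR-seq)
datasets by **reliable detection**: given two or more sequencing libraries of
the same B-cell repertoire, which clones can be trusted to be real and
shared, down to what frequency, and how well is the clonal ranking
conserved?

The package is aimed at people who run repertoire-sequencing experiments
with technical replicates, alternative library-preparation protocols, or
varying RNA input, and want an objective, threshold-based statistic for how
deep their datasets agree — plus a simulator to study how sampling depth,
template bottlenecks and sequencing errors shape that agreement.

## The statistic

Reads are filtered (CDR3 and VDJ annotated; CDR3 length ≥ 4 aa) and
collapsed into clonotypes at exact (100%) amino-acid identity of the CDR3
(or full/trimmed VDJ); singleton clonotypes (abundance < 2) are removed as
presumed PCR/sequencing errors. For a target repertoire with clones ranked
by decreasing frequency, walk the list from rank 1, tracking the running
fraction of walked clones present in **all** reference dataset(s). The
**reliably detected** clones are the longest frequency-ranked prefix whose
presence fraction stays at or above a threshold *t* (default 0.95). Two
stopping rules are implemented — stop before the first clone whose
inclusion drops the fraction below *t* (default), or take the longest
prefix with fraction ≥ *t* — because a dipped fraction can in principle
recover.

From the reliable prefix follow the **ranges of reliable detection** (the
frequency and read-count span from the most to the least abundant reliable
clone), the **reads fraction** (share of the target's reads carried by
reliable clones), and rank-agreement statistics: Spearman's ρ over shared
clone abundances (highest abundance = highest numeric rank, midranks for
ties; exact permutation p for n ≤ 9, t-approximation otherwise, α = 0.05)
and top-k clone consistency across libraries.

The simulator draws clone sizes from a Zipf law over ranks, subsamples a
finite number of template molecules (the stand-in for RNA input), applies
gamma-distributed per-clone amplification factors, samples reads
multinomially, and substitutes single CDR3 residues at a configurable
per-read error rate.

## Worked example

```python
from dataclasses import replace
from clonodetect import (
    SyntheticRepertoireConfig, generate_ground_truth, simulate_library,
    preprocess, detect_reliable,
)

base = SyntheticRepertoireConfig(n_clones=5000, depth=200_000, seed=20240917)
truth = generate_ground_truth(base)
reps = []
for seed in (1, 2):
    lib = simulate_library(truth, replace(base, seed=seed))
    table, report = preprocess(lib, dataset_id=f"rep{seed}")
    reps.append(table)

res = detect_reliable(reps[0], [reps[1]], threshold=0.95)
print(res.n_reliable, res.freq_range, res.reads_fraction)
```

The same computation at command level, as run by the numbered drivers under
`analysis/` (01 simulates the libraries, 02 compares three replicates,
03 runs the template-input titration):

```
$ python analysis/01_simulate_libraries.py
$ python analysis/02_method_comparison.py
rep1: 200000 reads -> 4905 clones (284 singletons removed)
...
mean reliably detected clones: 4889
mean frequency range: 8.55% - 0.001%
mean abundance range: 17073 - 2 reads
mean reads fraction: 100.0%
pairwise Spearman r:
       rep1   rep2   rep3
rep1  1.000  0.698  0.703
```

Reading: of ~4,900 clonotypes surviving the filters, essentially all are
reliably detected across the three replicate libraries; they span about
four orders of magnitude in frequency (8.55% down to 0.001%) and carry
~100% of the reads, and the clonal ranking agrees between libraries at
ρ ≈ 0.70. The titration driver shows the degradation under shrinking
template input: ρ against the deepest library falls 0.66 → 0.55 → 0.43 as
the bottleneck drops from 10⁵ to 10³ molecules, while the lowest-input
library's top-30 clones remain present in all libraries.

A `clonodetect` console command exposes the same stages
(`simulate`, `preprocess`, `detect`, `compare`, `run`); see
`clonodetect --help`.

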