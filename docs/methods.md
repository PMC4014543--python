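# Methods

## Problem setting

Antibody-repertoire sequencing yields, per library, a list of reads
annotated with the heavy-chain CDR3 and full VDJ amino-acid sequences.
Clonotypes are defined at exact (100%) amino-acid identity of the chosen
identifier — CDR3 by default, full or primer-trimmed VDJ as finer
alternatives. Two libraries of the same biological sample never agree
perfectly: sampling depth, the number of input template molecules,
amplification bias and sequencing errors all perturb the observed clone
list and its abundance ranking. The reliable-detection statistic turns
this into a single, threshold-based depth of agreement.

## Filtering

Reads are retained when (i) both CDR3 and VDJ were annotated, and
(ii) the CDR3 has at least `min_cdr3_len` (default 4) amino acids.
After aggregation, clonotypes below `min_abundance` (default 2) reads are
removed; at these settings the removed clones are singletons, the typical
signature of PCR/sequencing errors. No productivity filter is applied by
default — identifiers containing `*` (stop) or `X` (ambiguous) are legal —
but `drop_nonproductive=True` removes stop-containing CDR3s.

Two deliberate choices where the procedure is underdetermined:

- **Frequency denominator after abundance filtering.** Default is the
  read total of *retained* clones (renormalization), so every emitted
  table is self-consistent (frequencies sum to 1). The alternative,
  frequencies relative to the pre-filter total, is available via
  `frequency_denominator="prefilter"`.
- **Rank ties.** Equal counts are ordered lexicographically by clone
  identifier. Any deterministic rule would do; without one, ranks — and
  hence the reliable prefix — would depend on input order.

## Reliable detection

Walk the target's clones in rank order (rank 1 = most abundant),
maintaining the running fraction of walked clones present in **all**
reference tables (presence = exact identifier membership after the
reference's own filtering; no abundance requirement in the reference).
With threshold *t*:

- `stop_at_first_drop` (default): stop immediately before the first clone
  whose inclusion makes the running fraction < *t*;
- `longest_prefix`: return the longest prefix whose fraction ≥ *t*.

The two rules differ only when the running fraction dips below *t* and
later recovers; the first rule's list is always a prefix of the second's.
Both are exposed because either reading is defensible, and the choice is
reported in every result. Derived quantities over the prefix: frequency
range and abundance range (first vs last reliable clone) and reads
fraction (prefix read mass / target total). An empty prefix reports
`None` ranges and reads fraction 0 rather than fabricated values.

Multiway mode runs each table once as target against all others jointly
as references and averages `n_reliable`, the range endpoints and the reads
fraction across targets.

Guaranteed properties (enforced by tests): agreement with an exhaustive
prefix-enumeration oracle; raising *t* or adding a reference never
lengthens the list, and the higher-threshold list is a prefix of the
lower-threshold one; self-comparison returns the entire repertoire.

## Rank comparison

Spearman's ρ is computed over a shared clone set, with ranks assigned by
abundance (highest abundance = highest numeric rank) and midranks for
ties. The p-value is an exact permutation enumeration for n ≤ 9 and the
usual t-approximation otherwise; significance is called at α = 0.05.
For pairwise comparisons the clone set defaults to the *union* of the two
directional reliable prefixes intersected with the clones present in both
tables — the union keeps the statistic symmetric in its arguments;
`target` and `intersection` rules are available. Top-k consistency takes
a reference's k most abundant clones, counts those present in every
library, and reports the mean pairwise ρ over the subset shared by all.

## Simulator

Per library, the sampling chain is: latent clone frequencies → multinomial
draw of `bottleneck` template molecules (skipped when unlimited) →
per-clone amplification factor from a unit-mean gamma distribution with
variance `amplification_dispersion` → multinomial draw of `depth` reads →
per-read, with probability `error_rate`, substitution of one uniformly
chosen CDR3 position by a uniformly chosen different residue. VDJ strings
are fixed framework sequences around each CDR3 (with a 10-residue
5'-trim for the `vdj_trimmed` identifier), so VDJ clonotyping refines CDR3
clonotyping. Errors never insert or delete.

Parameters, defaults, and why:

| parameter | default | rationale |
|---|---|---|
| `n_clones` | 10,000 | enough clones to span ~4 orders of frequency magnitude, as observed repertoires do |
| `zipf_exponent` | 1.0 | heavy-tailed clone sizes are the accepted repertoire model; exponent 1 gives top-clone frequency ≈ 1/H(n) ≈ 10% |
| `cdr3_length_range` | (8, 20) | typical heavy-chain CDR3 lengths; min ≥ 4 so simulated reads pass the length filter by construction |
| `depth` | 100,000 (10⁶ in the study-scale workflows) | deep libraries run at millions of reads; the reliable range then reaches counts near the singleton floor |
| `bottleneck` | unlimited | bottlenecks are the experimental variable; titration workflows set 10⁶–10³ |
| `error_rate` | 0.001 | order-of-magnitude stand-in for amplicon error per read; no quantitative error model is claimed |
| `amplification_dispersion` | 0.1 | mild per-clone PCR efficiency spread (CV ≈ 0.32); chosen so that unbottlenecked replicates remain strongly rank-correlated, as technical replicates are, while bottleneck effects still dominate at low input |

Determinism: all draws come from one `numpy` Generator seeded by the
config; derived per-dataset seeds come from `SeedSequence` spawning and
stay below 2³¹. `simulate_clonotypes` runs the identical chain at
count level (no per-read rows) and agrees bit-exactly with aggregating
`simulate_library` output under the same seed; the study-scale workflows
use it for 10⁶-read libraries.

What the simulator emulates: power-law clone sizes, replicate-to-replicate
sampling noise, input bottlenecks, dispersion of amplification, and
error-derived spurious clonotypes. What it does not: V-gene-specific
primer bias, chimeras, indel/annotation errors, length-dependent error
rates, Phred structure, and any biological clone-size correlation between
samples. Passing tests therefore demonstrate the statistical machinery
and its qualitative response to depth/bottleneck/error — not quantitative
agreement with any particular wet-lab dataset.

## Numerical choices and degenerate inputs

- Prefix fractions are compared to the threshold with plain `>=` on
  doubles; both implementation and test oracles use the same arithmetic,
  and thresholds like 0.75 at small denominators are exact.
- Empty tables, empty prefixes and shared clone sets of size < 2 return
  explicit empty/`None` results instead of raising, except where a
  precondition is violated (mismatched identifier kinds, fewer than two
  tables, absent clones in a requested comparison set).
- Clonotype TSV round-trips are exact for counts and ranks and to double
  precision for frequencies (written with 17 significant digits).

## Observed behavior worth knowing

- The fraction of error-derived clonotype identities that survive the
  abundance-2 filter *grows* with depth at fixed error rate (identical
  errors recur more often in deeper libraries — a birthday effect),
  though the filter still removes the large majority at desk scales.
  The regression test asserts both facts.
- Pairwise ρ depends strongly on the size of the compared clone set:
  tight bottlenecks shrink the reliable set toward well-measured top
  clones, which *raises* their ρ even as overall agreement collapses.
  The titration workflows therefore report, besides the pairwise matrix,
  ρ against the deepest library and the cumulative mean pairwise ρ as
  lower-input libraries are added; both decline monotonically with input
  in essentially all seeded runs at study scale.

## Known limitations

Desk-scale, single-process execution (a few million reads per library);
no nucleotide-level clonotyping, no clustering below 100% identity, no
capture–recapture richness estimation, and no multiple-testing correction
across comparison matrices (comparisons are reported individually).
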