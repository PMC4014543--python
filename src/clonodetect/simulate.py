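"""Synthetic antibody-repertoire and sequencing-library simulator.

The generator emulates the statistical structure the comparison analysis
assumes, so the whole pipeline is testable without external data:

- clone sizes follow a Zipf/power law over ranks (repertoire frequency
  spectra span several orders of magnitude and heavy tails are the accepted
  repertoire model);
- a *template bottleneck* subsamples a finite number of RNA/cDNA molecules
  from the latent repertoire before amplification — the minimal mechanism
  through which decreasing RNA input degrades cross-replicate overlap and
  rank correlation;
- per-template amplification factors are gamma-distributed with unit mean
  and configurable dispersion (PCR efficiency spread);
- per-read errors substitute exactly one CDR3 residue with probability
  ``error_rate``, creating the spurious low-abundance clonotypes that
  singleton filtering is meant to remove. Indels are excluded: the CDR3 is
  an annotation product and length-changing annotation errors are out of
  scope.

Sampling chain per library: truth frequencies -> multinomial template draw
(bottleneck) -> gamma amplification -> multinomial read draw (depth) ->
substitution errors. All draws are deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import AA_ALPHABET, AnnotatedReadTable, ClonotypeTable

#: deterministic VDJ framing around each CDR3 (framework-region stand-ins),
#: so identifier_kind="vdj" clonotyping refines cdr3 clonotyping
VDJ_PREFIX = "QVQLVESGGGVVQPGRSLRLSCAAS"
VDJ_SUFFIX = "WGQGTLVTVSS"
#: residues removed from the VDJ 5' end by the simulated primer trimming
TRIM_LEN = 10


class ConfigurationError(ValueError):
    """Simulator parameters are inconsistent or infeasible."""


@dataclass(frozen=True)
class SyntheticRepertoireConfig:
    """Free parameters of the repertoire/library simulator.

    Defaults describe a deep bulk antibody-repertoire library: 10,000
    clones with Zipf(1) sizes, CDR3 lengths 8-20 aa, 100,000 reads, no
    template bottleneck, a 0.1% per-read substitution rate and mild
    per-clone amplification dispersion (0.1), under which technical
    replicates remain strongly rank-correlated.
    """

    n_clones: int = 10_000
    zipf_exponent: float = 1.0
    cdr3_length_range: tuple[int, int] = (8, 20)
    depth: int = 100_000
    bottleneck: int | None = None
    error_rate: float = 0.001
    amplification_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cdr3_length_range
        if self.n_clones < 1:
            raise ConfigurationError("n_clones must be >= 1")
        if self.zipf_exponent < 0:
            raise ConfigurationError("zipf_exponent must be >= 0")
        if lo < 4 or hi < lo:
            raise ConfigurationError(
                "cdr3_length_range must satisfy 4 <= min <= max"
            )
        if self.depth < 0:
            raise ConfigurationError("depth must be >= 0")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ConfigurationError("bottleneck must be >= 1 or None")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError("error_rate must be in [0, 1)")
        if self.amplification_dispersion < 0:
            raise ConfigurationError("amplification_dispersion must be >= 0")
        # capacity check: enough distinct strings to host n_clones
        capacity = 0
        for length in range(lo, hi + 1):
            capacity += 20**length
            if capacity >= self.n_clones:
                break
        if capacity < self.n_clones:
            raise ConfigurationError(
                f"{self.n_clones} unique CDR3s cannot fit in lengths {lo}-{hi}"
            )


@dataclass
class GroundTruthRepertoire:
    """Latent clone-frequency distribution used as simulation ground truth."""

    clone_ids: list[str]
    vdj_aa: list[str]
    true_frequency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if abs(float(self.true_frequency.sum()) - 1.0) > 1e-12:
            raise ValueError("true frequencies must sum to 1 within 1e-12")
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("clone_ids must be unique")

    def __len__(self) -> int:
        return len(self.clone_ids)


def _frame_vdj(cdr3: str) -> str:
    return VDJ_PREFIX + cdr3 + VDJ_SUFFIX


def generate_ground_truth(config: SyntheticRepertoireConfig) -> GroundTruthRepertoire:
    """Draw a ground-truth repertoire under the configured power law.

    Clone i (1-based) receives unnormalized mass i**(-zipf_exponent); CDR3
    strings are drawn uniformly over the 20-letter alphabet at lengths from
    ``cdr3_length_range`` and regenerated on collision so all identifiers
    are unique.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_clones
    mass = np.arange(1, n + 1, dtype=float) ** (-config.zipf_exponent)
    freq = mass / mass.sum()
    lo, hi = config.cdr3_length_range
    alphabet = np.array(list(AA_ALPHABET))
    seen: set[str] = set()
    clone_ids: list[str] = []
    while len(clone_ids) < n:
        need = n - len(clone_ids)
        lengths = rng.integers(lo, hi + 1, size=need)
        for length in lengths:
            cdr3 = "".join(alphabet[rng.integers(0, 20, size=length)])
            while cdr3 in seen:
                cdr3 = "".join(alphabet[rng.integers(0, 20, size=length)])
            seen.add(cdr3)
            clone_ids.append(cdr3)
    return GroundTruthRepertoire(
        clone_ids=clone_ids,
        vdj_aa=[_frame_vdj(c) for c in clone_ids],
        true_frequency=freq,
    )


def _mutate(cdr3: str, rng: np.random.Generator) -> str:
    """Substitute one uniformly chosen position with a different residue."""
    pos = int(rng.integers(0, len(cdr3)))
    old = cdr3[pos]
    choices = [a for a in AA_ALPHABET if a != old]
    new = choices[int(rng.integers(0, len(choices)))]
    return cdr3[:pos] + new + cdr3[pos + 1 :]


def _sample_read_counts(
    truth: GroundTruthRepertoire,
    config: SyntheticRepertoireConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-clone read counts after bottleneck, amplification and sampling."""
    freqs = truth.true_frequency
    if config.bottleneck is not None:
        weights = rng.multinomial(config.bottleneck, freqs).astype(float)
    else:
        weights = freqs.astype(float)
    if config.amplification_dispersion > 0:
        d = config.amplification_dispersion
        factors = rng.gamma(shape=1.0 / d, scale=d, size=len(freqs))
        weights = weights * factors
    total = weights.sum()
    if total == 0 or config.depth == 0:
        return np.zeros(len(freqs), dtype=np.int64)
    return rng.multinomial(config.depth, weights / total)


def _apply_errors(
    truth: GroundTruthRepertoire,
    counts: np.ndarray,
    config: SyntheticRepertoireConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, int], np.ndarray]:
    """Split clean reads from errored ones; returns (errored cdr3 -> count, clean counts)."""
    clean = counts.copy()
    errored: dict[str, int] = {}
    if config.error_rate > 0:
        nonzero = np.flatnonzero(counts)
        n_err = rng.binomial(counts[nonzero], config.error_rate)
        for idx, k in zip(nonzero, n_err):
            clean[idx] -= k
            src = truth.clone_ids[idx]
            for _ in range(int(k)):
                mut = _mutate(src, rng)
                errored[mut] = errored.get(mut, 0) + 1
    return errored, clean


def simulate_library(
    truth: GroundTruthRepertoire,
    config: SyntheticRepertoireConfig,
    read_prefix: str = "read",
) -> AnnotatedReadTable:
    """Simulate one sequencing library as an annotated-read table.

    Emits exactly ``depth`` reads, each with cdr3_aa, vdj_aa and a
    primer-trimmed vdj_trimmed_aa populated. Deterministic under the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    counts = _sample_read_counts(truth, config, rng)
    errored, clean = _apply_errors(truth, counts, config, rng)
    cdr3s: list[str] = []
    nonzero = np.flatnonzero(clean)
    cdr3s.extend(np.repeat(np.array(truth.clone_ids, dtype=object)[nonzero], clean[nonzero]))
    for mut in sorted(errored):
        cdr3s.extend([mut] * errored[mut])
    vdjs = [_frame_vdj(c) for c in cdr3s]
    df = pd.DataFrame(
        {
            "read_id": [f"{read_prefix}_{i:07d}" for i in range(len(cdr3s))],
            "cdr3_aa": cdr3s,
            "vdj_aa": vdjs,
            "vdj_trimmed_aa": [v[TRIM_LEN:] for v in vdjs],
        }
    )
    return AnnotatedReadTable(df)


def simulate_clonotypes(
    truth: GroundTruthRepertoire,
    config: SyntheticRepertoireConfig,
    dataset_id: str = "sim",
) -> ClonotypeTable:
    """Simulate a library directly at clonotype-count level (cdr3 identity).

    Same sampling chain and RNG stream as :func:`simulate_library` without
    materializing per-read rows; use for deep libraries where only the
    clonotype table is needed. Aggregating :func:`simulate_library` output
    with the same seed yields the identical table.
    """
    rng = np.random.default_rng(config.seed)
    counts = _sample_read_counts(truth, config, rng)
    errored, clean = _apply_errors(truth, counts, config, rng)
    totals: dict[str, int] = {}
    for idx in np.flatnonzero(clean):
        totals[truth.clone_ids[idx]] = int(clean[idx])
    for mut, k in errored.items():
        totals[mut] = totals.get(mut, 0) + k
    return ClonotypeTable.from_counts(totals, dataset_id, "cdr3")


def simulate_titration(
    truth: GroundTruthRepertoire,
    bottlenecks: Sequence[int],
    config: SyntheticRepertoireConfig,
) -> list[AnnotatedReadTable]:
    """One library per bottleneck level, sharing one ground truth.

    Emulates an RNA input titration: the bottleneck list must be strictly
    decreasing (largest input first). Per-dataset seeds derive
    deterministically from the master seed and the bottleneck index.
    """
    bottlenecks = list(bottlenecks)
    if any(b2 >= b1 for b1, b2 in zip(bottlenecks, bottlenecks[1:])):
        raise ValueError("bottlenecks must be strictly decreasing")
    seeds = titration_seeds(config.seed, len(bottlenecks))
    return [
        simulate_library(
            truth,
            replace(config, bottleneck=b, seed=s),
            read_prefix=f"bn{b}",
        )
        for b, s in zip(bottlenecks, seeds)
    ]


def titration_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-dataset seeds below 2**31 derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
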