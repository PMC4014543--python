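"""The reliable-detection statistic.

A clone of a target repertoire is *reliably detected* if it belongs to the
highest-frequency prefix of the target's rank-ordered clone list within
which at least a threshold fraction (default 95%) of clones is
simultaneously present in all reference dataset(s). Two stopping rules are
provided, because a prefix fraction that dips below the threshold can in
principle recover later:

- ``stop_at_first_drop`` (default): walk clones in rank order and stop
  before the first clone whose inclusion pushes the running presence
  fraction below the threshold;
- ``longest_prefix``: return the longest prefix whose presence fraction
  meets the threshold, even if shorter prefixes dipped below it.

On instances where the running fraction is monotone past the first drop the
two rules coincide; the first rule's list is always a prefix of the second's.

Derived summaries over the reliable prefix: the frequency and abundance
ranges (most- to least-abundant reliable clone) and the fraction of the
target's total reads carried by reliable clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tables import ClonotypeTable

MODES = ("stop_at_first_drop", "longest_prefix")


@dataclass
class ReliableDetectionResult:
    """Reliably detected clones of one target versus reference dataset(s).

    ``freq_range`` and ``abundance_range`` are (max, min) pairs over the
    reliable prefix; they are ``None`` when the prefix is empty rather than
    fabricated.
    """

    target_id: str
    reference_ids: list[str]
    threshold: float
    mode: str
    reliable_clones: list[str]
    presence_flags: list[bool]
    n_reliable: int = field(init=False)
    presence_fraction: float | None = field(init=False)
    freq_range: tuple[float, float] | None = None
    abundance_range: tuple[int, int] | None = None
    reads_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.n_reliable = len(self.reliable_clones)
        if self.n_reliable:
            self.presence_fraction = float(
                sum(self.presence_flags) / self.n_reliable
            )
        else:
            self.presence_fraction = None

    def as_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "reference_ids": list(self.reference_ids),
            "threshold": self.threshold,
            "mode": self.mode,
            "n_reliable": self.n_reliable,
            "presence_fraction": self.presence_fraction,
            "freq_range": list(self.freq_range) if self.freq_range else None,
            "abundance_range": (
                [int(x) for x in self.abundance_range]
                if self.abundance_range
                else None
            ),
            "reads_fraction": self.reads_fraction,
            "reliable_clones": list(self.reliable_clones),
        }


def _prefix_length(present: np.ndarray, threshold: float, mode: str) -> int:
    """Length of the reliable prefix given per-clone presence flags."""
    n = len(present)
    if n == 0:
        return 0
    frac = np.cumsum(present) / np.arange(1, n + 1)
    ok = frac >= threshold
    if mode == "stop_at_first_drop":
        below = np.flatnonzero(~ok)
        return int(below[0]) if len(below) else n
    # longest_prefix
    above = np.flatnonzero(ok)
    return int(above[-1]) + 1 if len(above) else 0


def detect_reliable(
    target: ClonotypeTable,
    references: Sequence[ClonotypeTable],
    threshold: float = 0.95,
    mode: str = "stop_at_first_drop",
) -> ReliableDetectionResult:
    """Scan the target's rank-ordered clones for the reliable prefix.

    Presence means membership of the exact clone identifier in *all*
    reference tables (after their own filtering); no abundance requirement
    is placed on the reference occurrence.
    """
    if not references:
        raise ValueError("at least one reference table is required")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    for ref in references:
        if ref.identifier_kind != target.identifier_kind:
            raise ValueError(
                f"identifier_kind mismatch: target {target.identifier_kind!r} "
                f"vs reference {ref.dataset_id!r} ({ref.identifier_kind!r})"
            )
    clone_ids = target.data["clone_id"].to_numpy()
    present = np.ones(len(clone_ids), dtype=bool)
    for ref in references:
        members = ref.clone_set
        present &= np.fromiter(
            (c in members for c in clone_ids), dtype=bool, count=len(clone_ids)
        )
    k = _prefix_length(present, threshold, mode)
    result = ReliableDetectionResult(
        target_id=target.dataset_id,
        reference_ids=[r.dataset_id for r in references],
        threshold=threshold,
        mode=mode,
        reliable_clones=list(clone_ids[:k]),
        presence_flags=[bool(p) for p in present[:k]],
    )
    freq_range, abundance_range, reads_fraction = detection_ranges(result, target)
    result.freq_range = freq_range
    result.abundance_range = abundance_range
    result.reads_fraction = reads_fraction
    return result


def detection_ranges(
    result: ReliableDetectionResult, target: ClonotypeTable
) -> tuple[tuple[float, float] | None, tuple[int, int] | None, float]:
    """Frequency range, abundance range and reads fraction of a reliable prefix.

    Ranges run from the rank-1 reliable clone to the last reliable clone;
    an empty prefix yields ``(None, None, 0.0)``.
    """
    k = result.n_reliable
    if k == 0:
        return None, None, 0.0
    df = target.data.iloc[:k]
    if list(df["clone_id"]) != list(result.reliable_clones):
        raise ValueError("result does not match the target's rank prefix")
    freq_range = (float(df["frequency"].iloc[0]), float(df["frequency"].iloc[-1]))
    abundance_range = (int(df["count"].iloc[0]), int(df["count"].iloc[-1]))
    reads_fraction = float(df["count"].sum() / target.total_reads)
    return freq_range, abundance_range, reads_fraction


def detect_multiway(
    tables: Sequence[ClonotypeTable],
    threshold: float = 0.95,
    mode: str = "stop_at_first_drop",
) -> tuple[list[ReliableDetectionResult], dict]:
    """Run detection once per table against all others as joint references.

    The summary averages, across targets, the number of reliable clones,
    the frequency- and abundance-range endpoints, and the reads fraction —
    targets with an empty prefix contribute 0 reliable clones and reads
    fraction 0 and are excluded from the range means.
    """
    if len(tables) < 2:
        raise ValueError("multiway detection needs at least 2 tables")
    results = []
    for i, target in enumerate(tables):
        refs = [t for j, t in enumerate(tables) if j != i]
        results.append(detect_reliable(target, refs, threshold, mode))
    with_ranges = [r for r in results if r.n_reliable > 0]
    summary = {
        "threshold": threshold,
        "mode": mode,
        "n_targets": len(results),
        "mean_n_reliable": float(np.mean([r.n_reliable for r in results])),
        "mean_reads_fraction": float(np.mean([r.reads_fraction for r in results])),
        "mean_freq_range": (
            [
                float(np.mean([r.freq_range[0] for r in with_ranges])),
                float(np.mean([r.freq_range[1] for r in with_ranges])),
            ]
            if with_ranges
            else None
        ),
        "mean_abundance_range": (
            [
                float(np.mean([r.abundance_range[0] for r in with_ranges])),
                float(np.mean([r.abundance_range[1] for r in with_ranges])),
            ]
            if with_ranges
            else None
        ),
    }
    return results, summary
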