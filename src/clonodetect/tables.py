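"""Core tabular containers: annotated reads and exact-identity clonotype tables.

An :class:`AnnotatedReadTable` holds one row per sequencing read with its
amino-acid annotations (CDR3, full VDJ, optionally a primer-trimmed VDJ).
A :class:`ClonotypeTable` holds one row per clone — the set of reads sharing
an identical identifier string at 100% amino-acid identity — with read count,
frequency and abundance rank.

Absent annotations are represented by the empty string, never by a sentinel
token, so that every non-empty field is a legal amino-acid sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: the 20 standard residues plus stop ('*') and ambiguous ('X')
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY*X]*$")

IDENTIFIER_KINDS = ("cdr3", "vdj", "vdj_trimmed")

#: identifier_kind -> AnnotatedReadTable column carrying that identifier
IDENTIFIER_COLUMNS = {
    "cdr3": "cdr3_aa",
    "vdj": "vdj_aa",
    "vdj_trimmed": "vdj_trimmed_aa",
}

READ_COLUMNS = ("read_id", "cdr3_aa", "vdj_aa")
OPTIONAL_READ_COLUMNS = ("vdj_trimmed_aa",)


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """A parsed table violates a schema invariant."""


def _check_aa_column(values: pd.Series, column: str) -> None:
    bad = values[~values.map(lambda s: bool(_AA_RE.match(s)))]
    if len(bad):
        raise ValidationError(
            f"column {column!r} contains non-amino-acid characters, "
            f"first offender: {bad.iloc[0]!r}"
        )


@dataclass
class AnnotatedReadTable:
    """Per-read annotation records; the pipeline's raw input.

    ``data`` columns: ``read_id`` (unique), ``cdr3_aa``, ``vdj_aa`` and
    optionally ``vdj_trimmed_aa``. Empty string means the annotation is
    absent for that read.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in READ_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"annotated-read table lacks column(s): {missing}")
        df = df.copy()
        for col in df.columns:
            df[col] = df[col].fillna("").astype(str)
        dup = df["read_id"][df["read_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate read_id: {dup.iloc[0]!r}")
        for col in ("cdr3_aa", "vdj_aa") + tuple(
            c for c in OPTIONAL_READ_COLUMNS if c in df.columns
        ):
            _check_aa_column(df[col], col)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedReadTable):
            return NotImplemented
        return self.data.equals(other.data)


def rank_by_count(counts: np.ndarray, clone_ids: np.ndarray) -> np.ndarray:
    """Dense 1..n ranking by decreasing count; ties broken by ascending clone_id.

    The tie rule is deterministic so that downstream prefix scans are
    reproducible regardless of input order.
    """
    order = np.lexsort((clone_ids, -counts))
    ranks = np.empty(len(counts), dtype=np.int64)
    ranks[order] = np.arange(1, len(counts) + 1)
    return ranks


@dataclass
class ClonotypeTable:
    """Aggregated clones keyed by exact amino-acid identifier.

    ``data`` columns: ``clone_id``, ``count``, ``frequency``, ``rank``;
    rows are stored sorted by rank ascending (rank 1 = most abundant).
    """

    dataset_id: str
    identifier_kind: str
    data: pd.DataFrame
    total_reads: int
    _clone_set: frozenset = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.identifier_kind not in IDENTIFIER_KINDS:
            raise ValidationError(
                f"identifier_kind must be one of {IDENTIFIER_KINDS}, "
                f"got {self.identifier_kind!r}"
            )
        df = self.data
        needed = ["clone_id", "count", "frequency", "rank"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise FormatError(f"clonotype table lacks column(s): {missing}")
        df = df[needed].copy()
        df["clone_id"] = df["clone_id"].astype(str)
        df["count"] = df["count"].astype(np.int64)
        df["frequency"] = df["frequency"].astype(float)
        df["rank"] = df["rank"].astype(np.int64)
        self._validate(df)
        self.data = df.sort_values("rank").reset_index(drop=True)
        object.__setattr__(self, "_clone_set", frozenset(df["clone_id"]))

    def _validate(self, df: pd.DataFrame) -> None:
        n = len(df)
        if df["clone_id"].duplicated().any():
            dup = df["clone_id"][df["clone_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate clone_id: {dup!r}")
        if n == 0:
            if self.total_reads != 0:
                raise ValidationError("empty table must have total_reads 0")
            return
        if (df["count"] <= 0).any():
            raise ValidationError("clone counts must be positive integers")
        if int(df["count"].sum()) != self.total_reads:
            raise ValidationError(
                f"counts sum to {int(df['count'].sum())}, "
                f"expected total_reads={self.total_reads}"
            )
        if abs(df["frequency"].sum() - 1.0) > 1e-9:
            raise ValidationError("frequencies must sum to 1 within 1e-9")
        if sorted(df["rank"]) != list(range(1, n + 1)):
            raise ValidationError("ranks must be a permutation of 1..n")
        # ranks must follow decreasing count with the lexicographic tie-break
        expected = rank_by_count(
            df["count"].to_numpy(), df["clone_id"].to_numpy()
        )
        if not np.array_equal(expected, df["rank"].to_numpy()):
            raise ValidationError("ranks inconsistent with counts/tie-break rule")

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int] | pd.Series,
        dataset_id: str,
        identifier_kind: str = "cdr3",
        total_reads: int | None = None,
    ) -> "ClonotypeTable":
        """Build a table from clone_id -> read count, computing frequency and rank.

        ``total_reads`` defaults to the sum of counts; pass a larger value to
        express frequencies relative to a pre-filter read total.
        """
        if isinstance(counts, Mapping):
            counts = pd.Series(counts, dtype=np.int64)
        counts = counts.astype(np.int64)
        retained = int(counts.sum())
        denom = retained if total_reads is None else int(total_reads)
        clone_ids = counts.index.to_numpy(dtype=object).astype(str)
        cnt = counts.to_numpy()
        if len(cnt) == 0:
            df = pd.DataFrame(
                {"clone_id": [], "count": [], "frequency": [], "rank": []}
            )
            return cls(dataset_id, identifier_kind, df, 0)
        freq = cnt / denom if denom > 0 else np.zeros_like(cnt, dtype=float)
        df = pd.DataFrame(
            {
                "clone_id": clone_ids,
                "count": cnt,
                "frequency": freq,
                "rank": rank_by_count(cnt, clone_ids),
            }
        )
        if total_reads is None or denom == retained:
            return cls(dataset_id, identifier_kind, df, retained)
        # pre-filter denominator: frequencies intentionally sum to < 1, so
        # bypass the normalized-frequency invariant via a relaxed instance.
        obj = cls.__new__(cls)
        obj.dataset_id = dataset_id
        obj.identifier_kind = identifier_kind
        obj.data = df.sort_values("rank").reset_index(drop=True)
        obj.total_reads = retained
        object.__setattr__(obj, "_clone_set", frozenset(df["clone_id"]))
        return obj

    @property
    def clone_set(self) -> frozenset:
        return self._clone_set

    def __contains__(self, clone_id: str) -> bool:
        return clone_id in self._clone_set

    def __len__(self) -> int:
        return len(self.data)

    def counts_for(self, clone_ids: Iterable[str]) -> np.ndarray:
        """Read counts for the given clones, in the given order."""
        lookup = pd.Series(
            self.data["count"].to_numpy(), index=self.data["clone_id"]
        )
        ids = list(clone_ids)
        missing = [c for c in ids if c not in self._clone_set]
        if missing:
            raise KeyError(f"clone(s) absent from {self.dataset_id}: {missing[:3]}")
        return lookup.loc[ids].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClonotypeTable):
            return NotImplemented
        if (
            self.dataset_id != other.dataset_id
            or self.identifier_kind != other.identifier_kind
            or self.total_reads != other.total_reads
            or len(self) != len(other)
        ):
            return False
        a, b = self.data, other.data
        return (
            a["clone_id"].equals(b["clone_id"])
            and a["count"].equals(b["count"])
            and a["rank"].equals(b["rank"])
            and bool(np.allclose(a["frequency"], b["frequency"], atol=1e-12, rtol=0))
        )
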