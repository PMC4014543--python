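"""Read-level filtering and exact-identity clonotype aggregation.

The filtering rules mirror standard repertoire-sequencing pre-processing:
(i) both the CDR3 and the full VDJ region must have been annotated,
(ii) CDR3s must reach a minimal length (default 4 amino acids), and
(iii) clonotypes must reach a minimal abundance (default 2 reads), which
removes singletons presumed to arise from PCR/sequencing errors. Clonotype
identity is exact amino-acid identity (100%) of the chosen identifier.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .tables import (
    AnnotatedReadTable,
    ClonotypeTable,
    IDENTIFIER_COLUMNS,
    ValidationError,
)


@dataclass
class FilterReport:
    """Tally of reads and clones surviving each filtering stage."""

    n_input_reads: int = 0
    n_pass_detection: int = 0
    n_pass_length: int = 0
    n_clones_before_abundance_filter: int = 0
    n_singletons_removed: int = 0
    n_clones_final: int = 0
    total_reads_final: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def filter_reads(
    reads: AnnotatedReadTable,
    min_cdr3_len: int = 4,
    drop_nonproductive: bool = False,
    report: FilterReport | None = None,
) -> AnnotatedReadTable:
    """Retain reads with both CDR3 and VDJ annotated and CDR3 length ≥ minimum.

    ``drop_nonproductive`` additionally removes reads whose CDR3 contains a
    stop codon ('*'); off by default since the upstream analysis applies no
    productivity filter. Input row order is preserved.
    """
    if min_cdr3_len < 1:
        raise ValueError("min_cdr3_len must be >= 1")
    df = reads.data
    detected = (df["cdr3_aa"] != "") & (df["vdj_aa"] != "")
    long_enough = df["cdr3_aa"].str.len() >= min_cdr3_len
    keep = detected & long_enough
    if drop_nonproductive:
        keep &= ~df["cdr3_aa"].str.contains(r"\*", regex=True)
    if report is not None:
        report.n_input_reads = len(df)
        report.n_pass_detection = int(detected.sum())
        report.n_pass_length = int(keep.sum())
    return AnnotatedReadTable(df[keep])


def aggregate_clonotypes(
    reads: AnnotatedReadTable,
    identifier_kind: str = "cdr3",
    dataset_id: str = "dataset",
) -> ClonotypeTable:
    """Collapse reads into clones by exact identity of the identifier string.

    Every row must carry the chosen identifier (run :func:`filter_reads`
    first for cdr3/vdj; for vdj_trimmed the optional column must be
    populated).
    """
    column = IDENTIFIER_COLUMNS[identifier_kind]
    df = reads.data
    if column not in df.columns:
        raise ValidationError(f"reads carry no {column!r} column")
    empty = df[column] == ""
    if empty.any():
        row = df.index[empty][0]
        raise ValidationError(
            f"identifier {column!r} absent in row {row} "
            f"(read_id={df['read_id'].iloc[row]!r})"
        )
    counts = df[column].value_counts()
    return ClonotypeTable.from_counts(counts, dataset_id, identifier_kind)


def filter_clonotypes(
    table: ClonotypeTable,
    min_abundance: int = 2,
    frequency_denominator: str = "retained",
    report: FilterReport | None = None,
) -> tuple[ClonotypeTable, FilterReport]:
    """Remove clones below the abundance floor and recompute frequencies/ranks.

    ``frequency_denominator``:

    - ``"retained"`` (default): frequencies renormalize over reads in
      retained clones, keeping the output self-consistent;
    - ``"prefilter"``: frequencies stay relative to the pre-filter read
      total (they then sum to < 1).
    """
    if min_abundance < 1:
        raise ValueError("min_abundance must be >= 1")
    if frequency_denominator not in ("retained", "prefilter"):
        raise ValueError("frequency_denominator must be 'retained' or 'prefilter'")
    if report is None:
        report = FilterReport()
    df = table.data
    keep = df["count"] >= min_abundance
    kept = df[keep]
    report.n_clones_before_abundance_filter = len(df)
    report.n_singletons_removed = int((df["count"] < min_abundance).sum())
    report.n_clones_final = len(kept)
    report.total_reads_final = int(kept["count"].sum())
    counts = pd.Series(
        kept["count"].to_numpy(), index=kept["clone_id"].to_numpy()
    )
    total = table.total_reads if frequency_denominator == "prefilter" else None
    out = ClonotypeTable.from_counts(
        counts, table.dataset_id, table.identifier_kind, total_reads=total
    )
    return out, report


def preprocess(
    reads: AnnotatedReadTable,
    identifier_kind: str = "cdr3",
    dataset_id: str = "dataset",
    min_cdr3_len: int = 4,
    min_abundance: int = 2,
    drop_nonproductive: bool = False,
    frequency_denominator: str = "retained",
) -> tuple[ClonotypeTable, FilterReport]:
    """Full read-to-clonotype pipeline: filter reads, aggregate, filter clones."""
    report = FilterReport()
    filtered = filter_reads(
        reads, min_cdr3_len, drop_nonproductive=drop_nonproductive, report=report
    )
    clones = aggregate_clonotypes(filtered, identifier_kind, dataset_id)
    return filter_clonotypes(
        clones, min_abundance, frequency_denominator, report=report
    )
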