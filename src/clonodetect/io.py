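"""Readers and writers for the two tab-separated table formats.

Annotated-read files are the shape of per-read annotation summaries after
paired-end assembly (one row per read, amino-acid CDR3/VDJ columns). A
*dialect* mapping adapts external header names — e.g. an IMGT-style
``Sequence ID`` / ``CDR3-IMGT`` header — onto the internal schema, so the
reader is not tied to any one annotation vendor.

Clonotype files are this package's own format: ``clone_id  count
frequency  rank``, rows ordered by rank.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import (
    AnnotatedReadTable,
    ClonotypeTable,
    FormatError,
    OPTIONAL_READ_COLUMNS,
    READ_COLUMNS,
    ValidationError,
)

#: identity dialect: internal names used verbatim in the file header
DEFAULT_DIALECT = {c: c for c in READ_COLUMNS + OPTIONAL_READ_COLUMNS}

CLONOTYPE_COLUMNS = ["clone_id", "count", "frequency", "rank"]


def read_annotated_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> AnnotatedReadTable:
    """Read a tab-separated annotated-read file.

    Parameters
    ----------
    path
        Tab-separated text file with a header row.
    dialect
        Maps internal column names (``read_id``, ``cdr3_aa``, ``vdj_aa``,
        ``vdj_trimmed_aa``) onto the file's header names. Defaults to the
        identity mapping. ``vdj_trimmed_aa`` is optional; the three core
        columns must resolve.

    Rows with empty annotation fields are retained with absent values —
    filtering is a downstream, explicit step.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    rename = {}
    for internal in READ_COLUMNS:
        external = dialect[internal]
        if external not in df.columns:
            raise FormatError(
                f"{path}: required column {external!r} (mapped to {internal!r}) "
                "not found in header"
            )
        rename[external] = internal
    trimmed_ext = dialect.get("vdj_trimmed_aa")
    if trimmed_ext and trimmed_ext in df.columns:
        rename[trimmed_ext] = "vdj_trimmed_aa"
    df = df.rename(columns=rename)
    keep = [c for c in READ_COLUMNS + OPTIONAL_READ_COLUMNS if c in df.columns]
    return AnnotatedReadTable(df[keep])


def write_annotated_table(table: AnnotatedReadTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_clonotype_table(table: ClonotypeTable, path: str | Path) -> None:
    """Write a clonotype table as TSV, rows ordered by rank ascending.

    Frequencies are printed with 17 significant digits so a read-back
    reproduces them to double precision.
    """
    df = table.data.sort_values("rank")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_clonotype_table(
    path: str | Path,
    dataset_id: str | None = None,
    identifier_kind: str = "cdr3",
) -> ClonotypeTable:
    """Read a clonotype TSV written by :func:`write_clonotype_table`.

    ``total_reads`` is recomputed as the sum of counts and checked against
    the frequency column (tolerance 1e-6 per row).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CLONOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    try:
        counts = df["count"].astype(np.int64)
        ranks = df["rank"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer count or rank: {exc}") from exc
    if (df["count"].str.contains(r"[.eE]")).any():
        raise FormatError(f"{path}: non-integer count value")
    freqs = df["frequency"].astype(float)
    total = int(counts.sum())
    if total > 0:
        expected = counts / total
        bad = np.abs(freqs - expected) > 1e-6
        if bad.any():
            clone = df["clone_id"][bad].iloc[0]
            raise ValidationError(
                f"{path}: frequency of clone {clone!r} inconsistent with "
                f"count/total beyond 1e-6"
            )
    out = pd.DataFrame(
        {
            "clone_id": df["clone_id"],
            "count": counts,
            "frequency": freqs,
            "rank": ranks,
        }
    )
    if dataset_id is None:
        dataset_id = Path(path).stem
    return ClonotypeTable(dataset_id, identifier_kind, out, total)
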