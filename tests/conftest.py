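from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clonodetect.tables import AnnotatedReadTable, ClonotypeTable


def make_clonotype_table(
    counts: dict[str, int],
    dataset_id: str = "ds",
    identifier_kind: str = "cdr3",
) -> ClonotypeTable:
    return ClonotypeTable.from_counts(counts, dataset_id, identifier_kind)


def make_read_table(rows: list[dict]) -> AnnotatedReadTable:
    df = pd.DataFrame(rows)
    for col in ("read_id", "cdr3_aa", "vdj_aa"):
        if col not in df.columns:
            df[col] = ""
    return AnnotatedReadTable(df)


def random_clonotype_table(
    rng: np.random.Generator,
    n_clones: int,
    dataset_id: str = "ds",
    max_count: int = 50,
) -> ClonotypeTable:
    """Random table over a compact clone-id universe (collisions wanted)."""
    ids = [f"CL{j:04d}" for j in rng.choice(5 * n_clones, n_clones, replace=False)]
    counts = {c: int(rng.integers(1, max_count + 1)) for c in ids}
    return make_clonotype_table(counts, dataset_id)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table() -> ClonotypeTable:
    return make_clonotype_table({"CARWA": 10, "CARWB": 8, "CARWC": 6, "CARWD": 4, "CARWE": 2})
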