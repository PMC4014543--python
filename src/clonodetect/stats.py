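"""Rank-correlation and top-k consistency statistics over shared clones.

Ranks are assigned within the compared clone set by abundance, with the
highest abundance receiving the highest numeric rank (rank n for the top
clone) and tied counts receiving average (mid) ranks — the standard
Spearman convention. Since Spearman's coefficient is invariant under the
direction of the ranking, the convention only affects the reported rank
vectors, not r.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import detect_reliable
from .tables import ClonotypeTable

ALPHA = 0.05

#: above this clone-set size the p-value switches from exact enumeration to
#: the t-distribution approximation
EXACT_P_MAX_N = 9


@dataclass
class RankComparison:
    """Spearman comparison of two repertoires over a shared clone set."""

    dataset_a: str
    dataset_b: str
    clone_set: list[str]
    ranks_a: np.ndarray
    ranks_b: np.ndarray
    spearman_r: float
    p_value: float
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(self.p_value < ALPHA)

    def as_dict(self) -> dict:
        return {
            "dataset_a": self.dataset_a,
            "dataset_b": self.dataset_b,
            "n_clones": len(self.clone_set),
            "spearman_r": self.spearman_r,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def _ranks_highest_top(counts: np.ndarray) -> np.ndarray:
    # rankdata is ascending, so the largest count gets the largest rank
    return sps.rankdata(counts, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0.0:
        return math.nan
    return float(x @ y) / denom


def _exact_p(ranks_a: np.ndarray, ranks_b: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's r (small n).

    Enumerates all n! orderings of one rank vector; handles ties because
    the permuted vector keeps its midranks.
    """
    n = len(ranks_a)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = ranks_b[perms]
    a = ranks_a - ranks_a.mean()
    b = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt(float(a @ a) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore"):
        r_perm = (b @ a) / denom
    r_perm = np.nan_to_num(r_perm)
    return float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))


def _t_approx_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman_rank_correlation(
    a: ClonotypeTable, b: ClonotypeTable, clone_set: Sequence[str]
) -> RankComparison:
    """Spearman rank correlation of clone abundances over a shared clone set.

    Every clone in ``clone_set`` must exist in both tables and the set must
    contain at least 2 clones. The p-value is exact (permutation
    enumeration) for n ≤ 9 and the t-approximation otherwise; significance
    is called at alpha = 0.05.
    """
    clone_set = list(clone_set)
    if len(clone_set) < 2:
        raise ValueError("clone_set must contain at least 2 clones")
    counts_a = a.counts_for(clone_set)
    counts_b = b.counts_for(clone_set)
    ranks_a = _ranks_highest_top(counts_a)
    ranks_b = _ranks_highest_top(counts_b)
    r = _pearson(ranks_a, ranks_b)
    n = len(clone_set)
    if math.isnan(r):
        p = 1.0
    elif n <= EXACT_P_MAX_N:
        p = _exact_p(ranks_a, ranks_b, r)
    else:
        p = _t_approx_p(r, n)
    return RankComparison(
        dataset_a=a.dataset_id,
        dataset_b=b.dataset_id,
        clone_set=clone_set,
        ranks_a=ranks_a,
        ranks_b=ranks_b,
        spearman_r=r,
        p_value=p,
    )


@dataclass
class TopKOverlap:
    """Presence and ranking consistency of a reference's top-k clones."""

    k: int
    reference_dataset: str
    clones: list[str]
    n_present_in_all: int
    mean_pairwise_r: float | None

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "reference_dataset": self.reference_dataset,
            "n_present_in_all": self.n_present_in_all,
            "mean_pairwise_r": self.mean_pairwise_r,
            "clones": list(self.clones),
        }


def top_k_overlap(
    tables: Sequence[ClonotypeTable], reference: str, k: int = 30
) -> TopKOverlap:
    """How consistently a reference's k most abundant clones recur elsewhere.

    Counts the reference's top-k clones present in *every* table and
    reports the mean pairwise Spearman coefficient over the subset present
    in all tables (``None`` if that subset has fewer than 2 clones).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_id = {t.dataset_id: t for t in tables}
    if reference not in by_id:
        raise ValueError(f"reference dataset {reference!r} not among tables")
    ref = by_id[reference]
    if len(ref) < k:
        raise ValueError(
            f"reference {reference!r} has only {len(ref)} clones, need {k}"
        )
    top = list(ref.data["clone_id"].iloc[:k])
    shared = [c for c in top if all(c in t for t in tables)]
    mean_r: float | None = None
    if len(shared) >= 2:
        rs = [
            spearman_rank_correlation(ta, tb, shared).spearman_r
            for ta, tb in itertools.combinations(tables, 2)
        ]
        mean_r = float(np.mean(rs))
    return TopKOverlap(
        k=k,
        reference_dataset=reference,
        clones=top,
        n_present_in_all=len(shared),
        mean_pairwise_r=mean_r,
    )


def _pair_clone_set(
    a: ClonotypeTable,
    b: ClonotypeTable,
    threshold: float,
    mode: str,
    clone_set_rule: str,
) -> list[str]:
    res_ab = detect_reliable(a, [b], threshold, mode)
    res_ba = detect_reliable(b, [a], threshold, mode)
    set_ab = set(res_ab.reliable_clones)
    set_ba = set(res_ba.reliable_clones)
    if clone_set_rule == "union":
        chosen = set_ab | set_ba
    elif clone_set_rule == "intersection":
        chosen = set_ab & set_ba
    elif clone_set_rule == "target":
        chosen = set_ab
    else:
        raise ValueError("clone_set_rule must be union|intersection|target")
    shared = chosen & set(a.clone_set) & set(b.clone_set)
    # deterministic order: target table's rank order, then the other's
    ordered = [c for c in a.data["clone_id"] if c in shared]
    seen = set(ordered)
    ordered += [c for c in b.data["clone_id"] if c in shared and c not in seen]
    return ordered


def pairwise_comparison_matrix(
    tables: Sequence[ClonotypeTable],
    threshold: float = 0.95,
    mode: str = "stop_at_first_drop",
    clone_set_rule: str = "union",
) -> tuple[pd.DataFrame, dict[tuple[str, str], RankComparison | None]]:
    """All-pairs Spearman comparison over reliably detected clones.

    For each unordered pair, reliable detection runs pairwise in both
    directions; the compared clone set defaults to the union of the two
    reliable prefixes intersected with the clones present in both tables,
    which makes the statistic symmetric in its inputs. Returns a symmetric
    r matrix (diagonal 1) and the per-pair comparisons (``None`` where the
    shared set has fewer than 2 clones).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables")
    ids = [t.dataset_id for t in tables]
    matrix = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    comparisons: dict[tuple[str, str], RankComparison | None] = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(tables), 2):
        clone_set = _pair_clone_set(a, b, threshold, mode, clone_set_rule)
        if len(clone_set) < 2:
            comparisons[(ids[i], ids[j])] = None
            matrix.iloc[i, j] = matrix.iloc[j, i] = np.nan
            continue
        comp = spearman_rank_correlation(a, b, clone_set)
        comparisons[(ids[i], ids[j])] = comp
        matrix.iloc[i, j] = matrix.iloc[j, i] = comp.spearman_r
    return matrix, comparisons
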