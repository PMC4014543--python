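"""Reliable-detection prefix scan: worked examples, oracle equivalence,
monotonicity properties."""

from __future__ import annotations

import numpy as np
import pytest

from clonodetect.detection import (
    detect_multiway,
    detect_reliable,
    detection_ranges,
)

from conftest import make_clonotype_table


def _first_drop(present: list[bool], threshold: float) -> int:
    """Exhaustive scan over every prefix; the independent first-drop oracle."""
    for k in range(1, len(present) + 1):
        if sum(present[:k]) / k < threshold:
            return k - 1
    return len(present)


def _random_instance(rng, max_clones=50):
    n = int(rng.integers(1, max_clones + 1))
    counts = {f"T{i:03d}": int(c) for i, c in enumerate(rng.integers(1, 40, n))}
    target = make_clonotype_table(counts, "target")
    member_p = rng.uniform(0.1, 1.0)
    members = [c for c in counts if rng.random() < member_p]
    if not members:
        members = ["ZZZZ"]
    ref = make_clonotype_table({c: 1 for c in members}, "ref")
    return target, ref


class TestWorkedExamples:
    def test_self_comparison_returns_everything(self, small_table):
        for threshold in (0.5, 0.95, 1.0):
            res = detect_reliable(small_table, [small_table], threshold)
            assert res.n_reliable == len(small_table)
            assert res.presence_fraction == 1.0
            assert res.reads_fraction == 1.0

    def test_disjoint_repertoires_detect_nothing(self, small_table):
        ref = make_clonotype_table({"XXXX": 1}, "ref")
        res = detect_reliable(small_table, [ref], 0.95)
        assert res.n_reliable == 0
        assert res.freq_range is None and res.abundance_range is None
        assert res.reads_fraction == 0.0

    def test_partial_overlap_both_modes(self):
        """Counts a..e = 10,8,6,4,2 with {a,b,d} in the reference at 0.75:
        the first-drop rule stops at [a,b]; the longest-prefix rule reaches
        [a,b,c,d] where the fraction recovers to exactly 3/4."""
        target = make_clonotype_table(
            {"a": 10, "b": 8, "c": 6, "d": 4, "e": 2}, "t"
        )
        ref = make_clonotype_table({"a": 1, "b": 1, "d": 1}, "r")
        stop = detect_reliable(target, [ref], 0.75, "stop_at_first_drop")
        assert stop.reliable_clones == ["a", "b"]
        longest = detect_reliable(target, [ref], 0.75, "longest_prefix")
        assert longest.reliable_clones == ["a", "b", "c", "d"]
        # cross-checked against the exhaustive oracle
        present = [True, True, False, True, False]
        assert _first_drop(present, 0.75) == 2
        fracs = [sum(present[:k]) / k for k in range(1, 6)]
        assert max(k for k in range(1, 6) if fracs[k - 1] >= 0.75) == 4

    def test_empty_target(self):
        target = make_clonotype_table({}, "t")
        ref = make_clonotype_table({"AAAA": 1}, "r")
        res = detect_reliable(target, [ref])
        assert res.n_reliable == 0

    def test_identifier_kind_mismatch_rejected(self, small_table):
        ref = make_clonotype_table({"AAAA": 1}, "r", identifier_kind="vdj")
        with pytest.raises(ValueError, match="identifier_kind"):
            detect_reliable(small_table, [ref])


class TestOracleEquivalence:
    def test_matches_exhaustive_prefix_oracle(self, rng):
        """1,000 random instances, 5 thresholds, both modes."""
        thresholds = [0.5, 0.75, 0.85, 0.95, 1.0]
        for _ in range(1000):
            target, ref = _random_instance(rng)
            members = ref.clone_set
            present = [c in members for c in target.data["clone_id"]]
            for threshold in thresholds:
                expected_stop = _first_drop(present, threshold)
                fracs = [
                    sum(present[: k + 1]) / (k + 1) for k in range(len(present))
                ]
                ok = [k + 1 for k in range(len(present)) if fracs[k] >= threshold]
                expected_longest = max(ok) if ok else 0
                res_stop = detect_reliable(target, [ref], threshold, "stop_at_first_drop")
                res_long = detect_reliable(target, [ref], threshold, "longest_prefix")
                assert res_stop.n_reliable == expected_stop
                assert res_long.n_reliable == expected_longest


class TestMonotonicity:
    def test_threshold_and_reference_monotonicity(self, rng):
        """500 random instances: raising the threshold or adding a reference
        never lengthens the reliable list; first-drop ⊆ longest-prefix."""
        for _ in range(500):
            target, ref1 = _random_instance(rng, max_clones=30)
            _, ref2 = _random_instance(rng, max_clones=30)
            prev = {m: None for m in ("stop_at_first_drop", "longest_prefix")}
            for threshold in (0.5, 0.75, 0.85, 0.95, 1.0):
                for mode in prev:
                    res = detect_reliable(target, [ref1], threshold, mode)
                    if prev[mode] is not None:
                        assert res.n_reliable <= prev[mode].n_reliable
                        # higher-threshold list is a prefix of the lower's
                        assert (
                            prev[mode].reliable_clones[: res.n_reliable]
                            == res.reliable_clones
                        )
                    prev[mode] = res
                stop = prev["stop_at_first_drop"]
                longest = prev["longest_prefix"]
                assert set(stop.reliable_clones) <= set(longest.reliable_clones)
                two_ref = detect_reliable(
                    target, [ref1, ref2], threshold, "stop_at_first_drop"
                )
                assert two_ref.n_reliable <= stop.n_reliable


class TestRanges:
    def test_whole_table_ranges(self):
        target = make_clonotype_table({"AAAA": 3, "CCCC": 1}, "t")
        res = detect_reliable(target, [target], 0.95)
        freq_range, abundance_range, reads_fraction = detection_ranges(res, target)
        assert freq_range == (0.75, 0.25)
        assert abundance_range == (3, 1)
        assert reads_fraction == 1.0

    def test_prefix_reads_fraction_matches_direct_sum(self, rng):
        counts = {f"CL{i:05d}": int(c) for i, c in enumerate(rng.integers(1, 1000, 10_000))}
        target = make_clonotype_table(counts, "t")
        prefix_ids = list(target.data["clone_id"].iloc[:1000])
        ref = make_clonotype_table({c: 1 for c in prefix_ids}, "r")
        res = detect_reliable(target, [ref], 1.0)
        assert res.n_reliable == 1000
        direct = sum(counts[c] for c in prefix_ids) / sum(counts.values())
        assert res.reads_fraction == pytest.approx(direct, abs=1e-12)

    def test_ranges_are_non_increasing_pairs(self, rng):
        for _ in range(50):
            target, ref = _random_instance(rng)
            res = detect_reliable(target, [ref], 0.75)
            if res.n_reliable:
                assert res.freq_range[0] >= res.freq_range[1]
                assert res.abundance_range[0] >= res.abundance_range[1]
                assert 0.0 <= res.reads_fraction <= 1.0


class TestMultiway:
    def test_identical_tables_all_reliable(self, small_table):
        results, summary = detect_multiway([small_table] * 3, 0.95)
        assert all(r.n_reliable == len(small_table) for r in results)
        assert summary["mean_reads_fraction"] == 1.0

    def test_each_table_is_target_once(self, small_table):
        other = make_clonotype_table({"CARWA": 5, "CARWB": 3}, "other")
        results, _ = detect_multiway([small_table, other])
        assert [r.target_id for r in results] == ["ds", "other"]
        assert results[0].reference_ids == ["other"]

    def test_fewer_than_two_tables_rejected(self, small_table):
        with pytest.raises(ValueError):
            detect_multiway([small_table])

    def test_mean_n_reliable_within_monte_carlo_band(self, rng):
        """Three deep, error-free replicates of one truth: the pipeline's
        mean reliable count sits within ±3 SD of a 200-run Monte-Carlo
        re-simulation of the same statistic."""
        from dataclasses import replace

        from clonodetect.simulate import (
            SyntheticRepertoireConfig,
            generate_ground_truth,
            simulate_clonotypes,
        )

        base = SyntheticRepertoireConfig(
            n_clones=200,
            depth=20_000,
            error_rate=0.0,
            amplification_dispersion=0.0,
            seed=5,
        )
        truth = generate_ground_truth(base)

        def mean_reliable(seed0: int) -> float:
            tables = [
                simulate_clonotypes(truth, replace(base, seed=seed0 + j), f"d{j}")
                for j in range(3)
            ]
            _, summary = detect_multiway(tables, 0.95)
            return summary["mean_n_reliable"]

        observed = mean_reliable(1_000_000)
        mc = np.array([mean_reliable(3 * i) for i in range(200)])
        assert abs(observed - mc.mean()) <= 3 * max(mc.std(), 1e-9) + 1e-9
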