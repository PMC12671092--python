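"""Inference engine: dense reference, alignment, streaming, scheduling."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from microfunc import (
    AbundanceTable,
    FunctionMicrobeMatrix,
    MemoryPlan,
    align_microbes,
    infer_dense,
    infer_streamed,
    normalize_by_marker_copy_number,
    run_concurrent,
    schedule,
)
from microfunc import simulate as sim
from microfunc.errors import ValidationError


def _gcn(values, functions=None, microbes=None):
    values = np.asarray(values, dtype=float)
    functions = functions or [f"K{i}" for i in range(values.shape[0])]
    microbes = microbes or [f"m{k}" for k in range(values.shape[1])]
    return FunctionMicrobeMatrix(functions, microbes, values)


def _table(values, microbes=None, samples=None):
    values = np.asarray(values, dtype=float)
    microbes = microbes or [f"m{k}" for k in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceTable(microbes, samples, values)


class TestDense:
    def test_identity_gcn_returns_the_table(self):
        B = _table([[3, 0], [1, 5]])
        C = infer_dense(_gcn(np.eye(2)), B)
        np.testing.assert_array_equal(C.values, B.values)
        assert C.sample_ids == B.sample_ids

    def test_hand_multiplication(self):
        C = infer_dense(_gcn([[1, 2], [3, 4]]), _table([[5], [6]]))
        np.testing.assert_array_equal(C.values, [[17], [39]])

    def test_zero_sample_column_propagates(self):
        C = infer_dense(_gcn([[1, 2], [3, 4]]), _table([[5, 0], [6, 0]]))
        np.testing.assert_array_equal(C.values[:, 1], [0, 0])

    def test_unreconciled_axes_rejected(self):
        A = _gcn([[1, 2]], microbes=["mX", "mY"])
        B = _table([[1], [1]], microbes=["mY", "mX"])
        with pytest.raises(ValidationError, match="reconciled"):
            infer_dense(A, B)


class TestAlignment:
    def test_subset_passes_with_empty_report(self):
        A = _gcn([[1, 2, 3]], microbes=["m0", "m1", "m2"])
        B = _table([[4], [5]], microbes=["m2", "m0"])
        A2, B2, report = align_microbes(A, B, policy="strict")
        assert report.empty
        assert A2.microbe_ids == B2.microbe_ids == ["m2", "m0"]
        np.testing.assert_array_equal(B2.values, B.values)

    def test_intersect_reports_dropped_abundance_fraction(self):
        A = _gcn([[1, 1]], microbes=["m0", "m1"])
        # unknown microbe carries 10 of 100 total counts
        B = _table([[50], [40], [10]], microbes=["m0", "m1", "unknown"])
        A2, B2, report = align_microbes(A, B, policy="intersect")
        assert report.dropped_microbe_ids == ("unknown",)
        assert report.dropped_abundance_fraction == pytest.approx(0.10)
        assert B2.microbe_ids == ["m0", "m1"]

    def test_strict_errors_listing_offending_ids(self):
        A = _gcn([[1]], microbes=["m0"])
        B = _table([[1], [2]], microbes=["m0", "mystery"])
        with pytest.raises(ValidationError, match="mystery"):
            align_microbes(A, B, policy="strict")

    def test_intersect_leaving_nothing_errors(self):
        A = _gcn([[1]], microbes=["m0"])
        B = _table([[1]], microbes=["other"])
        with pytest.raises(ValidationError, match="zero microbes"):
            align_microbes(A, B, policy="intersect")


class TestCopyNumberNormalization:
    def test_unit_copy_numbers_are_identity(self):
        B = _table([[6, 2], [3, 9]])
        B2 = normalize_by_marker_copy_number(B, {"m0": 1, "m1": 1})
        np.testing.assert_array_equal(B2.values, B.values)

    def test_divides_by_copy_number(self):
        B = _table([[6]])
        B2 = normalize_by_marker_copy_number(B, {"m0": 3})
        assert B2.values[0, 0] == 2

    def test_missing_or_zero_copy_number_rejected(self):
        B = _table([[6]])
        with pytest.raises(ValidationError, match="missing"):
            normalize_by_marker_copy_number(B, {})
        with pytest.raises(ValidationError, match="non-positive"):
            normalize_by_marker_copy_number(B, {"m0": 0})

    def test_normalize_then_infer_equals_infer_of_predivided_table(self):
        A = sim.make_gcn(10, 8, seed=5)
        B = sim.make_abundance_table(8, 4, mean_depth=200, seed=5)
        cn = {m: 1.0 + i % 4 for i, m in enumerate(B.microbe_ids)}
        left = infer_dense(A, normalize_by_marker_copy_number(B, cn))
        divided = _table(
            B.values / np.array([cn[m] for m in B.microbe_ids])[:, None],
            microbes=B.microbe_ids, samples=B.sample_ids,
        )
        right = infer_dense(A, divided)
        np.testing.assert_array_equal(left.values, right.values)


class TestSchedule:
    def test_round_robin_balances_workers(self):
        plan = MemoryPlan.manual(n_microbes=10, n_partitions=2, b_batch_size=3,
                                 iteration_size=12, n_workers=2)
        units = schedule(plan, n_partitions=2, n_samples=12)  # 4 batches per stage
        assert len(units) == 8
        loads = [sum(1 for u in units if u.worker_id == w) for w in range(2)]
        assert loads == [4, 4]

    def test_single_worker_serial_order(self):
        plan = MemoryPlan.manual(10, 2, 5, 10, n_workers=1)
        units = schedule(plan, 2, n_samples=10)
        assert [u.worker_id for u in units] == [0] * 4
        keys = [(u.a_partition_index, u.sample_batch_range) for u in units]
        assert keys == sorted(keys)

    def test_more_workers_than_batches_still_covers_exactly(self):
        plan = MemoryPlan.manual(10, 1, 10, 10, n_workers=8)
        units = schedule(plan, 1, n_samples=10)
        assert len(units) == 1  # idle workers allowed
        assert units[0].sample_batch_range == (0, 10)

    def test_remainder_batches_go_to_lower_worker_ids(self):
        plan = MemoryPlan.manual(10, 1, 2, 10, n_workers=2)
        units = schedule(plan, 1, n_samples=10)  # 5 batches over 2 workers
        loads = [sum(1 for u in units if u.worker_id == w) for w in range(2)]
        assert loads == [3, 2]


class TestConcurrent:
    def test_width_one_and_four_are_bit_identical(self, small_gcn, small_table):
        plan = MemoryPlan.manual(small_gcn.n_microbes, 3, 4, 25, n_workers=4)
        c1 = run_concurrent(small_gcn, small_table, plan, executor_width=1)
        c4 = run_concurrent(small_gcn, small_table, plan, executor_width=4)
        np.testing.assert_array_equal(c1.values, c4.values)

    def test_zero_samples_give_empty_result(self, small_gcn):
        empty = AbundanceTable(small_gcn.microbe_ids, [], np.zeros((small_gcn.n_microbes, 0)))
        plan = MemoryPlan.manual(small_gcn.n_microbes, 2, 3, 5, n_workers=2)
        C = run_concurrent(small_gcn, empty, plan)
        assert C.values.shape == (small_gcn.n_functions, 0)

    def test_three_workers_match_dense_oracle(self, small_gcn, small_table):
        plan = MemoryPlan.manual(small_gcn.n_microbes, 2, 5, 25, n_workers=3)
        got = run_concurrent(small_gcn, small_table, plan)
        want = infer_dense(small_gcn, small_table)
        np.testing.assert_allclose(got.values, want.values, rtol=1e-12)

    def test_worker_failure_carries_unit_context(self, small_gcn, small_table):
        def exploding_backend(a, b):
            raise FloatingPointError("boom")

        plan = MemoryPlan.manual(small_gcn.n_microbes, 2, 10, 25, n_workers=2)
        with pytest.raises(RuntimeError, match="partition"):
            run_concurrent(small_gcn, small_table, plan, backend=exploding_backend)


class TestStreamed:
    @pytest.mark.parametrize("n_partitions", [1, 2, 5])
    @pytest.mark.parametrize("b_batch", [1, 7, 25])
    def test_matches_dense_under_partitioning(self, small_gcn, small_table, n_partitions, b_batch):
        plan = MemoryPlan.manual(small_gcn.n_microbes, n_partitions, b_batch, 25, n_workers=2)
        got = infer_streamed(small_gcn, small_table, plan)
        want = infer_dense(small_gcn, small_table)
        rel = np.abs(got.values - want.values) / np.maximum(1.0, np.abs(want.values))
        assert rel.max() <= 1e-5

    def test_degenerate_plan_is_bit_identical_to_dense(self, small_gcn, small_table):
        plan = MemoryPlan.manual(small_gcn.n_microbes, 1, small_table.n_samples,
                                 small_table.n_samples, n_workers=1)
        got = infer_streamed(small_gcn, small_table, plan)
        want = infer_dense(small_gcn, small_table)
        np.testing.assert_array_equal(got.values, want.values)

    def test_iteration_size_one_runs_per_sample(self, small_gcn, small_table):
        ten = small_table.select_samples(0, 10)
        plan = MemoryPlan.manual(small_gcn.n_microbes, 2, 4, iteration_size=1, n_workers=1)
        got = infer_streamed(small_gcn, ten, plan)
        want = infer_dense(small_gcn, ten)
        np.testing.assert_allclose(got.values, want.values, rtol=1e-12)

    def test_accepts_an_iterable_of_chunks(self, small_gcn):
        spec = dict(n_microbes=60, n_samples=13, mean_depth=900, seed=11)
        plan = MemoryPlan.manual(60, 3, 2, iteration_size=4, n_workers=2)
        got = infer_streamed(small_gcn, sim.stream_batches(spec, 4), plan)
        want = infer_dense(small_gcn, sim.make_abundance_table(**spec))
        np.testing.assert_allclose(got.values, want.values, rtol=1e-12)

    def test_plan_inconsistent_with_matrix_dims_rejected(self, small_gcn, small_table):
        plan = MemoryPlan.manual(n_microbes=59, n_partitions=2, b_batch_size=5, iteration_size=25)
        with pytest.raises(Exception, match="microbes"):
            infer_streamed(small_gcn, small_table, plan)

    @given(seed=st.integers(0, 50))
    def test_sample_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        A = sim.make_gcn(6, 9, seed=seed)
        B = sim.make_abundance_table(9, 7, mean_depth=100, seed=seed)
        perm = rng.permutation(7)
        Bp = AbundanceTable(B.microbe_ids, [B.sample_ids[j] for j in perm], B.values[:, perm])
        plan = MemoryPlan.manual(9, 3, 2, 4, n_workers=2)
        C = infer_streamed(A, B, plan)
        Cp = infer_streamed(A, Bp, plan)
        np.testing.assert_array_equal(Cp.values, C.values[:, perm])
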