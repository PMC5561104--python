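"""Binned counting and median-of-ratios normalization."""

import numpy as np
import pandas as pd
import pytest

from cistromekit import (BinCountMatrix, BinScheme, GenomeLayout, Interval,
                         IntervalSet, average_profiles, count_in_bins,
                         count_in_window, normchip, normchip_apply,
                         normchip_size_factors, two_step_normalize)


def naive_size_factors(values: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios oracle: direct product form, explicit loops."""
    values = np.asarray(values, float)
    n_rows, n_exp = values.shape
    ratios: list[list[float]] = [[] for _ in range(n_exp)]
    for j in range(n_rows):
        row = values[j]
        if all(v > 0 for v in row):
            g = float(np.prod(row)) ** (1.0 / n_exp)
            for i in range(n_exp):
                ratios[i].append(row[i] / g)
    return np.array([float(np.median(r)) for r in ratios])


def _matrix(values, labels=None, contexts=None, factors=None) -> BinCountMatrix:
    values = np.asarray(values, float)
    n_rows, n_exp = values.shape
    labels = labels or [f"e{i}" for i in range(n_exp)]
    row_meta = pd.DataFrame({"site_id": ["s1"] * n_rows,
                             "bin_index": np.arange(n_rows)})
    col_meta = pd.DataFrame({"label": labels,
                             "factor": factors or labels,
                             "context": contexts or [""] * n_exp})
    return BinCountMatrix(values, row_meta, col_meta)


class TestBinScheme:
    def test_defaults_give_200_bins(self):
        assert BinScheme().n_bins == 200

    def test_bin_size_must_divide_window(self):
        with pytest.raises(ValueError, match="divide"):
            BinScheme(half_window=5000, bin_size=33)


class TestCounting:
    def test_read_at_5025_lands_in_bin_100(self):
        sites = IntervalSet([Interval("chr1", 4_990, 5_010)])   # center 5000
        reads = IntervalSet([Interval("chr1", 5_020, 5_030)])   # midpoint 5025
        m = count_in_bins({"x": reads}, sites)
        col = m.column("x")
        assert col[100] == 1 and col.sum() == 1

    def test_zero_reads_all_zero_matrix(self):
        sites = IntervalSet([Interval("chr1", 10_000, 10_100)])
        m = count_in_bins({"x": IntervalSet([], "empty")}, sites)
        assert m.values.shape == (200, 1) and not m.values.any()

    def test_out_of_bounds_window_dropped_with_warning(self):
        layout = GenomeLayout.from_dict({"chr1": 12_000})
        sites = IntervalSet([Interval("chr1", 100, 200),        # window < 0
                             Interval("chr1", 5_990, 6_010)])   # fits exactly
        reads = IntervalSet([Interval("chr1", 6_000, 6_002)])
        with pytest.warns(UserWarning, match="dropped 1"):
            m = count_in_bins({"x": reads}, sites, layout=layout)
        assert m.site_ids == ["site_2"]

    def test_empty_site_list_errors(self):
        with pytest.raises(ValueError, match="empty site"):
            count_in_bins({"x": IntervalSet([])}, IntervalSet([]))

    def test_window_counts_boundary_convention(self):
        sites = IntervalSet([Interval("chr1", 990, 1_010)])     # center 1000
        inside = IntervalSet([Interval("chr1", 1_149, 1_151)])  # midpoint 1150
        counts, _ = count_in_window(inside, sites, half_width=200)
        assert counts.tolist() == [1.0]
        edge = IntervalSet([Interval("chr1", 1_199, 1_201)])    # midpoint 1200
        counts, _ = count_in_window(edge, sites, half_width=200)
        assert counts.tolist() == [0.0]                          # half-open right edge

    def test_window_mean_is_sum_over_sites(self):
        sites = IntervalSet([Interval("chr1", 9_990, 10_010),
                             Interval("chr1", 19_990, 20_010),
                             Interval("chr1", 29_990, 30_010)])
        reads = IntervalSet([Interval("chr1", 10_000, 10_002)] * 3 +
                            [Interval("chr1", 20_000, 20_002)])
        counts, mean = count_in_window(reads, sites)
        assert counts.tolist() == [3.0, 1.0, 0.0]
        assert mean == pytest.approx(4.0 / 3.0)

    def test_matrix_tsv_round_trip(self, tmp_path):
        sites = IntervalSet([Interval("chr1", 9_990, 10_010)])
        reads = IntervalSet([Interval("chr1", 10_000, 10_002)])
        m = count_in_bins({"a": reads, "b": reads}, sites)
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = BinCountMatrix.from_tsv(path)
        assert back.labels == ["a", "b"]
        assert np.array_equal(back.values, m.values)


class TestSizeFactors:
    def test_worked_example(self):
        s = normchip_size_factors(np.array([[2, 8], [4, 16], [6, 24]], float))
        assert s == pytest.approx([0.5, 2.0], abs=1e-12)

    def test_identical_columns_give_unit_factors(self):
        s = normchip_size_factors(np.array([[3, 3], [7, 7], [1, 1]], float))
        assert s == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_zero_row_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            s = normchip_size_factors(np.array([[0, 0], [4, 16], [6, 24]], float))
        assert s == pytest.approx([0.5, 2.0], abs=1e-12)

    def test_error_paths(self):
        with pytest.raises(ValueError, match="pseudocount"):
            normchip_size_factors(np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match="at least 2"):
            normchip_size_factors(np.array([[1.0], [2.0]]))
        s = normchip_size_factors(np.array([[0, 1], [1, 0]], float), pseudocount=0.5)
        assert (s > 0).all()

    def test_log_space_matches_direct_product(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            m = rng.integers(1, 500, size=(rng.integers(2, 40), rng.integers(2, 6)))
            assert normchip_size_factors(m.astype(float)) == pytest.approx(
                naive_size_factors(m), abs=1e-12)

    def test_matches_naive_oracle_with_zeros(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            m = rng.poisson(3.0, size=(50, 3)).astype(float)  # some zero rows
            if not (m > 0).all(axis=1).any():
                continue
            with np.errstate(all="ignore"), pytest.warns(UserWarning):
                got = normchip_size_factors(m)
            assert got == pytest.approx(naive_size_factors(m), abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        m = rng.integers(1, 100, size=(60, 4)).astype(float)
        s = normchip_size_factors(m)
        perm = rng.permutation(4)
        assert normchip_size_factors(m[:, perm]) == pytest.approx(s[perm], abs=1e-12)
        rows = rng.permutation(60)
        assert normchip_size_factors(m[rows]) == pytest.approx(s, abs=1e-12)


class TestNormalize:
    def test_apply_worked_example(self):
        m = _matrix([[2, 8], [4, 16], [6, 24]])
        norm = normchip_apply(m, np.array([0.5, 2.0]))
        assert norm.values == pytest.approx(np.array([[4, 4], [8, 8], [12, 12]], float))
        assert norm.normalized and norm.size_factors.tolist() == [0.5, 2.0]

    def test_unit_factors_identity(self):
        m = _matrix([[1, 2], [3, 4]])
        assert np.array_equal(normchip_apply(m, np.ones(2)).values, m.values)

    def test_invalid_factors_rejected(self):
        m = _matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            normchip_apply(m, np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            normchip_apply(m, np.ones(3))

    def test_fixed_point_property(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            m = _matrix(rng.integers(1, 300, size=(80, 4)).astype(float))
            norm = normchip(m)
            s2 = normchip_size_factors(norm)
            # renormalizing yields equal factors: the original geometric mean residue
            assert np.ptp(s2) == pytest.approx(0.0, abs=1e-10)

    def test_scale_recovery_on_planted_poisson(self):
        from cistromekit import SimulationSpec, simulate_signal, simulate_truth
        spec = SimulationSpec(seed=123, n_sites=50)
        truth = simulate_truth(spec)
        m = simulate_signal(truth, spec)
        s = normchip_size_factors(m)
        s_star = np.array(spec.size_factors)
        rec = s / np.exp(np.mean(np.log(s)))
        expect = s_star / np.exp(np.mean(np.log(s_star)))
        assert rec == pytest.approx(expect, rel=0.02)


class TestAveragingAndTwoStep:
    def test_average_examples(self):
        m = _matrix([[0, 2], [2, 0]], labels=["a", "b"])
        avg = average_profiles(m, {"g": ["a", "b"]})
        assert avg.values[:, 0].tolist() == [1.0, 1.0]
        same = _matrix([[5, 5], [7, 7]], labels=["a", "b"])
        avg2 = average_profiles(same, {"g": ["a", "b"]})
        assert avg2.values[:, 0].tolist() == [5.0, 7.0]

    def test_average_matches_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.random((30, 5))
        m = _matrix(vals, labels=[f"c{i}" for i in range(5)])
        avg = average_profiles(m, {"all": m.labels})
        assert avg.values[:, 0] == pytest.approx(vals.sum(axis=1) / 5)

    def test_average_by_metadata_key(self):
        m = _matrix([[1, 3], [5, 7]], labels=["a", "b"], contexts=["c1", "c1"])
        avg = average_profiles(m, "context")
        assert avg.labels == ["c1"] and avg.values[:, 0].tolist() == [2.0, 6.0]

    def test_two_step_equalizes_planted_replicate_scale(self):
        rng = np.random.default_rng(7)
        base = rng.integers(1, 100, size=30).astype(float)
        m = _matrix(np.column_stack([base, 2 * base]),
                    labels=["r1", "r2"], factors=["f", "f"], contexts=["c", "c"])
        with pytest.warns(UserWarning, match="single factor"):
            out = two_step_normalize(m)
        assert out.labels == ["f@c"]
        gm = np.sqrt(base * 2 * base)
        assert out.values[:, 0] == pytest.approx(gm)  # both columns equalized to gm

    def test_two_step_near_identity_on_common_scale(self):
        rng = np.random.default_rng(9)
        shared = rng.integers(5, 200, size=(100,)).astype(float)
        noise = rng.poisson(shared).astype(float) + 1
        m = _matrix(np.column_stack([shared, noise]),
                    labels=["fa", "fb"], factors=["fa", "fb"], contexts=["c", "c"])
        with pytest.warns(UserWarning, match="single dataset"):
            out = two_step_normalize(m)
        s = normchip_size_factors(out)
        assert np.abs(s - 1.0).max() < 0.01

    def test_two_step_order_invariance(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(1, 50, size=(40, 4)).astype(float)
        meta = dict(labels=["a1", "a2", "b1", "b2"],
                    factors=["fa", "fa", "fb", "fb"],
                    contexts=["c1", "c2", "c1", "c2"])
        m = _matrix(vals, **meta)
        perm = [2, 0, 3, 1]
        m_perm = _matrix(vals[:, perm],
                         labels=[meta["labels"][i] for i in perm],
                         factors=[meta["factors"][i] for i in perm],
                         contexts=[meta["contexts"][i] for i in perm])
        a, b = two_step_normalize(m), two_step_normalize(m_perm)
        for key in zip(a.col_meta["factor"], a.col_meta["context"]):
            ia = list(zip(a.col_meta["factor"], a.col_meta["context"])).index(key)
            ib = list(zip(b.col_meta["factor"], b.col_meta["context"])).index(key)
            assert a.values[:, ia] == pytest.approx(b.values[:, ib], abs=1e-12)

    def test_mismatched_rows_error(self):
        a = _matrix([[1, 2]])
        b = BinCountMatrix(np.ones((1, 1)),
                           pd.DataFrame({"site_id": ["zz"], "bin_index": [0]}),
                           pd.DataFrame({"label": ["x"], "factor": ["x"],
                                         "context": [""]}))
        assert not a.same_rows(b)
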