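import numpy as np
import pytest

from mtvlmm.data_io import LongitudinalDataset
from mtvlmm.design import (
    BinnedDataset,
    CommunityCoding,
    build_kinship,
    build_lagged_design,
    quantile_bin,
)


def single_series(values, m_extra=2, seed=0):
    from conftest import make_series_dataset

    return make_series_dataset({"A": np.asarray(values)}, m_extra=m_extra,
                               seed=seed)


class TestQuantileBin:
    def test_constant_taxon_maps_to_middle(self):
        ds = single_series([0.3] * 8, m_extra=0)
        binned = quantile_bin(ds)
        assert set(np.unique(binned.matrices["A"])) == {1}

    def test_zero_inflated_interpolated_quantiles(self):
        # 10 pooled values; type-7 quantiles: q25 = 0 (zeros bin to the
        # middle since "below" is strict), q75 = 0.175 by interpolation
        vals = [0, 0, 0, 0, 0, 0, 0.1, 0.2, 0.3, 0.4]
        ds = single_series(vals, m_extra=0)
        binned = quantile_bin(ds)
        np.testing.assert_allclose(binned.bin_thresholds[0], [0.0, 0.175])
        np.testing.assert_array_equal(
            binned.matrices["A"][0], [1, 1, 1, 1, 1, 1, 1, 2, 2, 2]
        )

    def test_alternative_quantile_pair_changes_coding(self):
        rng = np.random.default_rng(3)
        ds = single_series(rng.uniform(size=30), m_extra=0)
        default = quantile_bin(ds, 0.25, 0.75)
        narrow = quantile_bin(ds, 0.05, 0.55)
        assert not np.array_equal(default.matrices["A"], narrow.matrices["A"])

    def test_entries_validated(self):
        with pytest.raises(ValueError, match="0, 1, 2"):
            BinnedDataset(
                matrices={"A": np.array([[3.0]])}, taxa_ids=["t"],
                bin_thresholds=np.zeros((1, 2)),
            )


class TestBuildLaggedDesign:
    def test_p1_q1_single_individual(self):
        y = np.array([0.4, 0.3, 0.2, 0.1])
        ds = single_series(y, m_extra=2)
        binned = quantile_bin(ds)
        d = build_lagged_design(ds, binned, "focal", p=1, q=1)
        np.testing.assert_allclose(d.y, [0.3, 0.2, 0.1])
        np.testing.assert_allclose(
            d.X, [[1, 0.4], [1, 0.3], [1, 0.2]]
        )

    def test_p0_gives_intercept_only(self):
        ds = single_series([0.4, 0.3, 0.2, 0.1])
        d = build_lagged_design(ds, quantile_bin(ds), "focal", p=0, q=1)
        np.testing.assert_array_equal(d.X, np.ones((3, 1)))

    def test_taxon_major_lag_order_q2(self):
        # 3 kinship taxa, q = 2: columns must run (taxon1 lag1, taxon1
        # lag2, taxon2 lag1, ...); verified against a hand-built coding
        T = 5
        codes = {
            "A": np.array(
                [[0, 1, 2, 1, 0],
                 [2, 2, 0, 0, 1],
                 [1, 0, 1, 2, 2]], dtype=float
            )
        }
        ds = single_series(np.linspace(0.1, 0.5, T), m_extra=3)
        coding = CommunityCoding(matrices=codes, taxa_ids=["x0", "x1", "x2"])
        d = build_lagged_design(
            ds, coding, "focal", p=0, q=2, kinship_taxa=["x0", "x1", "x2"]
        )
        # first design row targets t=3 (0-based 2): lags at columns 1, 0
        np.testing.assert_array_equal(
            d.W_tilde[0], [1, 0, 2, 2, 0, 1]
        )
        # last row targets t=5: lags at columns 3, 2
        np.testing.assert_array_equal(
            d.W_tilde[-1], [1, 2, 0, 0, 2, 1]
        )

    def test_identity_coding_reproduces_raw_lag_matrix(self):
        # with q=1 and the raw matrix as "coding", W~ is the community
        # matrix shifted by one time step
        rng = np.random.default_rng(5)
        ds = single_series(rng.uniform(size=6), m_extra=2, seed=5)
        raw = CommunityCoding(
            matrices={"A": ds.matrices["A"][1:]}, taxa_ids=["x0", "x1"]
        )
        d = build_lagged_design(ds, raw, "focal", p=0, q=1,
                                kinship_taxa=["x0", "x1"])
        np.testing.assert_allclose(d.W_tilde, ds.matrices["A"][1:, :-1].T)

    def test_causality(self):
        # perturbing the sample at time t never changes rows targeting <= t
        rng = np.random.default_rng(7)
        y = rng.uniform(size=10)
        ds = single_series(y, m_extra=2, seed=7)
        binned = quantile_bin(ds)
        base = build_lagged_design(ds, binned, "focal", p=1, q=1, rng_seed=0)
        t_perturb = 6  # 0-based position
        ds2 = ds.copy()
        ds2.matrices["A"][0, t_perturb] += 0.5
        mod = build_lagged_design(ds2, quantile_bin(ds2), "focal", p=1, q=1,
                                  rng_seed=0)
        for r, (_, t) in enumerate(base.row_index):
            # labels are 1-based; the lag columns of the row targeting the
            # perturbed time use strictly earlier samples
            if t <= t_perturb + 1:
                np.testing.assert_array_equal(base.X[r], mod.X[r])
            if t < t_perturb + 1:
                assert base.y[r] == mod.y[r]

    def test_h_is_within_block_permutation(self):
        from conftest import make_series_dataset

        rng = np.random.default_rng(11)
        ds = make_series_dataset(
            {"A": rng.uniform(size=8), "B": rng.uniform(size=6)},
            m_extra=3, seed=11,
        )
        binned = quantile_bin(ds)
        d = build_lagged_design(ds, binned, "focal", p=0, q=1, rng_seed=4)
        blocks = d.individual_blocks()
        for ind, rows in blocks.items():
            w_rows = {tuple(r) for r in d.W_tilde[rows]}
            h_rows = {tuple(r) for r in d.H[rows]}
            assert w_rows == h_rows

    def test_short_individual_dropped_all_dropped_errors(self):
        from conftest import make_series_dataset

        ds = make_series_dataset({"A": np.array([0.1, 0.2])}, m_extra=2)
        binned = quantile_bin(ds)
        with pytest.raises(ValueError, match="max\\(p, q\\)"):
            build_lagged_design(ds, binned, "focal", p=2, q=2)


class TestBuildKinship:
    def test_hand_computed_gram(self):
        ds = single_series([0.1, 0.2, 0.3], m_extra=2)
        d = build_lagged_design(ds, quantile_bin(ds), "focal", p=0, q=1)
        d.W_tilde = np.array([[1.0, 0.0], [0.0, 2.0]])
        d.H = d.W_tilde.copy()
        k = build_kinship(d)
        np.testing.assert_allclose(k.K1, [[0.5, 0.0], [0.0, 2.0]])

    def test_identical_rows_give_rank_one(self):
        ds = single_series([0.1, 0.2, 0.3, 0.4], m_extra=2)
        d = build_lagged_design(ds, quantile_bin(ds), "focal", p=0, q=1)
        d.W_tilde = np.tile([1.0, 2.0, 0.0], (3, 1))
        k = build_kinship(d)
        assert np.allclose(k.K1, k.K1[0, 0])
        assert np.linalg.matrix_rank(k.K1) == 1

    def test_psd_and_matches_gram_oracle(self):
        rng = np.random.default_rng(13)
        W = rng.choice([0.0, 1.0, 2.0], size=(6, 9))
        ds = single_series(rng.uniform(size=7), m_extra=2, seed=13)
        d = build_lagged_design(ds, quantile_bin(ds), "focal", p=0, q=1)
        d.W_tilde = W
        d.H = W[rng.permutation(6)]
        k = build_kinship(d)
        oracle = np.array(
            [[np.dot(W[i], W[j]) / 9 for j in range(6)] for i in range(6)]
        )
        np.testing.assert_allclose(k.K1, oracle)
        assert np.linalg.eigvalsh(k.K1).min() >= -1e-9 * np.trace(k.K1)

    def test_h_blocks_preserve_trace(self):
        from conftest import make_series_dataset

        rng = np.random.default_rng(17)
        ds = make_series_dataset(
            {"A": rng.uniform(size=9), "B": rng.uniform(size=7)},
            m_extra=4, seed=17,
        )
        d = build_lagged_design(ds, quantile_bin(ds), "focal", p=0, q=1,
                                rng_seed=3)
        k = build_kinship(d)
        for ind, rows in d.individual_blocks().items():
            b1 = k.K1[np.ix_(rows, rows)]
            b2 = k.K2[np.ix_(rows, rows)]
            assert np.trace(b1) == pytest.approx(np.trace(b2))
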