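import numpy as np
import pytest

from trajpresence import (ConfigError, DataMatrix, NullDistribution,
                          RunConfig, TrajectoryPresenceTest, build_mst,
                          kmeans_centers, null_distribution, p_value,
                          permute_matrix, stat_triple,
                          test_trajectory_presence as run_presence_test)
from trajpresence.model import TAILS


class TestPermuteMatrix:
    def test_columns_are_multiset_equal(self, gaussian_matrix):
        Y = permute_matrix(gaussian_matrix, seed=0)
        for j in range(gaussian_matrix.p):
            np.testing.assert_array_equal(
                np.sort(Y.values[:, j]),
                np.sort(gaussian_matrix.values[:, j]))

    def test_constant_matrix_unchanged(self):
        X = DataMatrix.from_array(np.full((6, 3), 2.5))
        np.testing.assert_array_equal(permute_matrix(X, 1).values, X.values)

    def test_single_column_leaves_geometry_unchanged(self):
        # 1-D geometry is order-free: permuting one column cannot change
        # any MST statistic
        rng = np.random.default_rng(4)
        X = DataMatrix.from_array(rng.normal(size=(40, 1)))
        base = stat_triple(build_mst(kmeans_centers(X, 5, seed=0)))
        Y = permute_matrix(X, seed=9)
        assert stat_triple(build_mst(kmeans_centers(Y, 5, seed=0))) == base

    def test_actually_shuffles(self, gaussian_matrix):
        Y = permute_matrix(gaussian_matrix, seed=0)
        assert not np.array_equal(Y.values, gaussian_matrix.values)


class TestPValue:
    def _null(self, samples, stat="D2", k=10):
        return NullDistribution(statistic=stat, k=k,
                                samples=np.asarray(samples))

    def test_observed_below_all_samples_lower_tail(self):
        null = self._null([5] * 99, stat="D1")
        assert p_value(3, null, "lower") == pytest.approx(0.01)

    def test_all_ties_give_one_either_tail(self):
        null = self._null([4] * 50)
        assert p_value(4, null, "lower") == 1.0
        assert p_value(4, null, "upper") == 1.0

    def test_hand_counted_upper_tail(self):
        null = self._null([2, 3, 4, 5, 6])
        assert p_value(4, null, "upper") == pytest.approx(2 / 3)

    def test_bad_tail_rejected(self):
        with pytest.raises(ValueError):
            p_value(4, self._null([2, 3, 4]), "both")

    def test_monotone_in_observed_value(self):
        rng = np.random.default_rng(0)
        null = self._null(rng.integers(0, 9, size=99), k=11)
        ups = [p_value(o, null, "upper") for o in range(0, 10)]
        assert all(b <= a for a, b in zip(ups, ups[1:]))
        lows = [p_value(o, null, "lower") for o in range(0, 10)]
        assert all(b >= a for a, b in zip(lows, lows[1:]))


class TestNullDistribution:
    def test_reproducible_given_seed(self, gaussian_matrix):
        a = null_distribution(gaussian_matrix, k=6, statistic="Lmax", B=50,
                              seed=7, n_restarts=3)
        b = null_distribution(gaussian_matrix, k=6, statistic="Lmax", B=50,
                              seed=7, n_restarts=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_samples_respect_stat_bounds(self, gaussian_matrix):
        null = null_distribution(gaussian_matrix, k=10, statistic="D1",
                                 B=30, seed=1, n_restarts=3)
        assert null.samples.min() >= 2 and null.samples.max() <= 9
        assert null.B == 30

    def test_out_of_range_sample_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            NullDistribution(statistic="D1", k=10, samples=np.array([1]))


def _small_cfg(**kw):
    base = dict(k_min=5, k_max=8, n_permutations=19, seed=0,
                pca_dims=None, n_restarts=3)
    base.update(kw)
    return RunConfig(**base)


class TestTrajectoryPresenceTest:
    def test_report_shape_and_ranges(self, gaussian_matrix):
        res = run_presence_test(gaussian_matrix, _small_cfg())
        assert len(res.table) == 4 * 3
        assert set(res.table["k"]) == {5, 6, 7, 8}
        assert ((res.table["p_value"] > 0) &
                (res.table["p_value"] <= 1)).all()
        assert res.pvalues.shape == (3, 4)

    def test_statistics_subset_contract(self, gaussian_matrix):
        res = run_presence_test(
            gaussian_matrix, _small_cfg(statistics=("Lmax",)))
        assert set(res.table["statistic"]) == {"Lmax"}
        assert list(res.median_pvalues.index) == ["Lmax"]

    def test_median_is_midpoint_for_even_sweeps(self, gaussian_matrix):
        res = run_presence_test(gaussian_matrix, _small_cfg())
        for stat in ("D1", "D2", "Lmax"):
            sub = np.sort(res.table.loc[res.table["statistic"] == stat,
                                        "p_value"].to_numpy())
            assert res.median_pvalues[stat] == pytest.approx(
                (sub[1] + sub[2]) / 2)

    def test_bit_level_reproducibility(self, gaussian_matrix, tmp_path):
        r1 = TrajectoryPresenceTest(gaussian_matrix, _small_cfg()).fit()
        r2 = TrajectoryPresenceTest(gaussian_matrix, _small_cfg()).fit()
        assert r1.table.equals(r2.table)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        r1.to_tsv(str(p1))
        r2.to_tsv(str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_kmax_too_large_fails_before_compute(self, gaussian_matrix):
        with pytest.raises(ConfigError, match="k_max"):
            TrajectoryPresenceTest(gaussian_matrix,
                                   _small_cfg(k_max=60))

    def test_accepts_dataframe_and_kwargs(self, gaussian_matrix):
        df = gaussian_matrix.to_dataframe()
        model = TrajectoryPresenceTest.from_dataframe(
            df, k_min=5, k_max=6, n_permutations=19, n_restarts=2,
            pca_dims=None)
        res = model.fit(seed=3)
        assert res.seed == 3 and len(res.table) == 2 * 3

    def test_observed_seed_stream_matches_direct_call(self, gaussian_matrix):
        # the observed statistic per k reuses the (seed, k) k-means stream
        res = TrajectoryPresenceTest(gaussian_matrix, _small_cfg()).fit()
        seed_k = np.random.SeedSequence(0, spawn_key=(5,))
        cs = kmeans_centers(gaussian_matrix, 5, seed_k, n_restarts=3)
        expect = stat_triple(build_mst(cs)).as_dict()
        sub = res.table[res.table["k"] == 5].set_index("statistic")
        for stat in ("D1", "D2", "Lmax"):
            assert sub.loc[stat, "observed"] == expect[stat]

    def test_noiseless_line_is_maximally_linear(self):
        # points on a slanted line: every k gives a path MST, the leaf
        # count sits at its minimum, and the evidence is at least as strong
        # as on structureless uniform data under the same seed
        rng = np.random.default_rng(55)
        t = rng.uniform(size=(500, 1))
        line = DataMatrix.from_array(np.hstack([t, 0.7 * t]))
        unif = DataMatrix.from_array(rng.uniform(size=(500, 2)))
        cfg = RunConfig(k_min=5, k_max=9, n_permutations=99, seed=0,
                        pca_dims=None, n_restarts=3)
        res_line = run_presence_test(line, cfg)
        res_unif = run_presence_test(unif, cfg)
        d1 = res_line.table[res_line.table["statistic"] == "D1"]
        assert (d1["observed"] == 2).all()
        assert (res_line.median_pvalues <= res_unif.median_pvalues).all()

    def test_keep_nulls(self, gaussian_matrix):
        res = TrajectoryPresenceTest(gaussian_matrix, _small_cfg()).fit(
            keep_nulls=True)
        assert set(res.nulls) == {(s, k) for s in ("D1", "D2", "Lmax")
                                  for k in range(5, 9)}
        null = res.nulls[("D1", 5)]
        obs = res.table.set_index(["statistic", "k"]).loc[("D1", 5),
                                                          "observed"]
        p = res.table.set_index(["statistic", "k"]).loc[("D1", 5), "p_value"]
        assert p_value(int(obs), null, TAILS["D1"]) == p

    def test_tsv_report_format(self, gaussian_matrix, tmp_path):
        res = TrajectoryPresenceTest(gaussian_matrix, _small_cfg()).fit()
        path = tmp_path / "report.tsv"
        res.to_tsv(str(path))
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "statistic\tk\tobserved\tp_value"
        body = [l for l in lines if not l.startswith("#")]
        footer = [l for l in lines if l.startswith("#")]
        assert len(body) == 1 + 12
        assert len(footer) == 3
        assert all(f.startswith("# median ") for f in footer)

    def test_permute_before_pca_flag_runs(self):
        rng = np.random.default_rng(3)
        X = DataMatrix.from_array(rng.normal(size=(40, 12)))
        cfg = _small_cfg(k_max=6, pca_dims=2, permute_before_pca=True)
        res = run_presence_test(X, cfg)
        assert len(res.table) == 2 * 3

    def test_summary_mentions_medians(self, gaussian_matrix):
        res = TrajectoryPresenceTest(gaussian_matrix, _small_cfg()).fit()
        text = res.summary()
        assert "median p" in text
        for stat in ("D1", "D2", "Lmax"):
            assert stat in text


class TestPlot:
    def test_plot_writes_nonempty_file(self, gaussian_matrix, tmp_path):
        res = TrajectoryPresenceTest(gaussian_matrix, _small_cfg()).fit()
        out = tmp_path / "fig.png"
        res.plot(path=str(out))
        assert out.exists() and out.stat().st_size > 0

    def test_empty_report_errors_without_file(self, gaussian_matrix,
                                              tmp_path):
        res = TrajectoryPresenceTest(gaussian_matrix, _small_cfg()).fit()
        res.table = res.table.iloc[0:0]
        out = tmp_path / "fig.png"
        with pytest.raises(ValueError, match="empty"):
            res.plot(path=str(out))
        assert not out.exists()
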