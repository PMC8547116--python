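"""Mantel, MMRR and the IBD/IBE suite."""

import numpy as np
import pytest

import landgen as lg
from landgen.differentiation import FstMatrix
from landgen.matrix_tests import climate_dissimilarity

LABELS = [f"p{i}" for i in range(15)]


def random_distance_matrix(rng, labels=LABELS):
    pts = rng.normal(size=(len(labels), 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return lg.PairwiseMatrix(list(labels), d)


class TestClimateDissimilarity:
    def test_equal_values_zero_matrix(self):
        mat = climate_dissimilarity({"a": 2.0, "b": 2.0, "c": 2.0})
        assert (mat.values == 0).all()

    def test_hand_values(self):
        mat = climate_dissimilarity({"a": 1.0, "b": 3.0, "c": 6.0})
        assert mat.values[0, 1] == 2.0
        assert mat.values[0, 2] == 5.0
        assert mat.values[1, 2] == 3.0

    def test_shift_invariance(self):
        vals = {"a": 1.0, "b": 3.0, "c": 6.0}
        shifted = {k: v + 100.0 for k, v in vals.items()}
        np.testing.assert_allclose(
            climate_dissimilarity(vals).values,
            climate_dissimilarity(shifted).values,
        )


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        X = random_distance_matrix(rng)
        res = lg.mantel_test(X, X, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_p_never_zero(self):
        rng = np.random.default_rng(1)
        X = random_distance_matrix(rng)
        res = lg.mantel_test(X, X, n_perm=500, seed=0)
        assert res.p_value > 0

    def test_needs_four_populations(self):
        small = lg.PairwiseMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(lg.ValidationError):
            lg.mantel_test(small, small, n_perm=10, seed=0)

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(2)
        X = random_distance_matrix(rng)
        flat = lg.PairwiseMatrix(LABELS, np.ones((15, 15)) - np.eye(15))
        with pytest.raises(lg.ValidationError, match="zero-variance"):
            lg.mantel_test(flat, X, n_perm=10, seed=0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        X, Y = random_distance_matrix(rng), random_distance_matrix(rng)
        res1 = lg.mantel_test(X, Y, n_perm=199, seed=9)
        perm = list(rng.permutation(LABELS))
        res2 = lg.mantel_test(X.reorder(perm), Y.reorder(perm), n_perm=199, seed=9)
        assert res2.r == pytest.approx(res1.r)

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(10)
        rej = 0
        n_reps = 200
        for _ in range(n_reps):
            X, Y = random_distance_matrix(rng), random_distance_matrix(rng)
            res = lg.mantel_test(X, Y, n_perm=199, seed=int(rng.integers(2**31)))
            rej += res.p_value < 0.05
        assert rej / n_reps == pytest.approx(0.05, abs=0.04)


class TestMMRR:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        X = random_distance_matrix(rng)
        Y = lg.PairwiseMatrix(LABELS, 2.0 * X.values)
        res = lg.mmrr(Y, [X], n_perm=99, seed=0)
        assert res.coefficients[1] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_single_predictor_reproduces_mantel_r2(self):
        rng = np.random.default_rng(1)
        X, Y = random_distance_matrix(rng), random_distance_matrix(rng)
        r = lg.mantel_test(X, Y, n_perm=49, seed=0).r
        r2 = lg.mmrr(Y, [X], n_perm=49, seed=0).r_squared
        assert r2 == pytest.approx(r**2, abs=1e-10)

    def test_signal_and_noise_predictors(self):
        rng = np.random.default_rng(2)
        recovered = significant = insignificant = 0
        n_reps = 60
        for _ in range(n_reps):
            X1, X2 = random_distance_matrix(rng), random_distance_matrix(rng)
            noise = rng.normal(0, 0.05, size=(15, 15))
            noise = np.abs(noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            Y = lg.PairwiseMatrix(LABELS, 2.0 * X1.values + noise)
            res = lg.mmrr(Y, [X1, X2], n_perm=199, seed=int(rng.integers(2**31)))
            recovered += abs(res.coefficients[1] - 2.0) < 0.2
            significant += res.p_values[0] < 0.05
            insignificant += res.p_values[1] > 0.05
        assert recovered >= 0.9 * n_reps
        assert significant == n_reps
        assert insignificant >= 0.9 * n_reps

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(3)
        X = random_distance_matrix(rng)
        X2 = lg.PairwiseMatrix(LABELS, 3.0 * X.values)
        Y = random_distance_matrix(rng)
        with pytest.raises(lg.ValidationError, match="collinear"):
            lg.mmrr(Y, [X, X2], n_perm=10, seed=0, names=["a", "b"])

    def test_too_few_pairs_rejected(self):
        labels = ["a", "b", "c"]
        rng = np.random.default_rng(4)
        mats = []
        for _ in range(3):
            v = np.abs(rng.normal(size=(3, 3)))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            mats.append(lg.PairwiseMatrix(labels, v))
        with pytest.raises(lg.ValidationError, match="fewer pairs"):
            lg.mmrr(mats[0], mats[1:] * 2, n_perm=10, seed=0)

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(11)
        rej = 0
        n_reps = 200
        for _ in range(n_reps):
            X, Y = random_distance_matrix(rng), random_distance_matrix(rng)
            res = lg.mmrr(Y, [X], n_perm=199, seed=int(rng.integers(2**31)))
            rej += res.p_values[0] < 0.05
        assert rej / n_reps == pytest.approx(0.05, abs=0.04)

    def test_predict_on_training_matrices(self):
        rng = np.random.default_rng(5)
        X = random_distance_matrix(rng)
        Y = lg.PairwiseMatrix(LABELS, 1.5 * X.values)
        est = lg.MMRR(n_permutations=19, seed=0).fit([X], Y)
        np.testing.assert_allclose(est.predict([X]), Y.tri(), atol=1e-9)


class TestSuite:
    def test_pure_ibd_flags_only_distance(self):
        sc = lg.make_scenario("stepping_stone", seed=13)
        g, m = lg.simulate_dataset(sc)
        fst = lg.pairwise_fst(g, m)
        geo = lg.euclidean_distance_matrix(
            lg.project_coordinates(m), labels=m.population_ids
        )
        # an environment orthogonal to the coast axis
        rng = np.random.default_rng(0)
        clim = climate_dissimilarity(
            {p: float(v) for p, v in zip(m.population_ids,
                                         rng.permutation(sc.n_pops))}
        ).reorder(m.population_ids)
        report = lg.ibd_ibe_suite(
            fst, geo, clim={"shuffled_climate": clim}, n_perm=499, seed=3,
        )
        ibd = report[report.test == "ibd_mantel"].iloc[0]
        ibe = report[report.test == "ibe_shuffled_climate"].iloc[0]
        assert ibd.p_value < 0.05
        assert ibe.p_value > 0.05

    def test_one_row_per_test_with_metadata(self):
        sc = lg.make_scenario("stepping_stone", seed=14, n_pops=6, sizes=[15] * 6)
        g, m = lg.simulate_dataset(sc)
        fst = lg.pairwise_fst(g, m)
        geo = lg.euclidean_distance_matrix(
            lg.project_coordinates(m), labels=m.population_ids
        )
        report = lg.ibd_ibe_suite(fst, geo, n_perm=99, seed=5)
        assert set(report.columns) >= {"test", "p_value", "n_perm", "seed"}
        assert (report.n_perm == 99).all()
        assert (report.seed == 5).all()
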