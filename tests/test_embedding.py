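import numpy as np
import pytest

from genostab import (
    DistanceMatrix,
    ParameterError,
    hudson_fst,
    mds_embed,
    mean_impute,
    pairwise_distance,
    pca_embed,
    read_matrix,
)
from genostab.embedding import _raw_stress, classical_scaling
from tests.conftest import make_dataset


def _oracle_scores(dataset, n_components):
    """Dense eigendecomposition of the Patterson-scaled covariance."""
    x = mean_impute(dataset)
    mu = x.mean(axis=0)
    p = mu / 2.0
    denom = np.sqrt(p * (1 - p))
    xs = x - mu
    ok = denom > 1e-12
    xs[:, ok] /= denom[ok]
    xs[:, ~ok] = 0.0
    w, v = np.linalg.eigh(xs @ xs.T)
    order = np.argsort(w)[::-1][:n_components]
    return v[:, order] * np.sqrt(np.clip(w[order], 0, None)), xs


class TestPCA:
    def test_two_separated_groups_split_on_pc1(self):
        dosages = np.vstack([np.zeros((4, 10)), np.full((4, 10), 2)]).astype(int)
        ds = read_matrix(dosages)
        emb = pca_embed(ds, n_components=1)
        pc1 = np.round(emb.coords[:, 0], 9)
        assert len(set(pc1)) == 2
        assert len(set(pc1[:4])) == 1 and len(set(pc1[4:])) == 1

    def test_matches_dense_eigendecomposition_oracle(self):
        ds = make_dataset(seed=11, m=20, k=100, missing_frac=0.05)
        emb = pca_embed(ds, n_components=6)
        oracle, _ = _oracle_scores(ds, 6)
        for j in range(6):  # per-axis sign is arbitrary
            a, b = emb.coords[:, j], oracle[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_score_columns_orthogonal_with_eigenvalue_variances(self):
        ds = make_dataset(seed=5, m=15, k=60)
        emb = pca_embed(ds, n_components=5)
        gram = emb.coords.T @ emb.coords
        assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        col_var = emb.coords.var(axis=0, ddof=1)
        assert np.allclose(col_var, emb.explained_variance, rtol=1e-10)
        assert (np.diff(emb.explained_variance) <= 1e-12).all()

    def test_equivariant_to_individual_reordering(self):
        ds = make_dataset(seed=7, m=12, k=40)
        perm = np.random.default_rng(0).permutation(12)
        ds_perm = read_matrix(
            ds.dosages[perm],
            individual_ids=[ds.individual_ids[i] for i in perm],
            populations=[ds.populations[i] for i in perm],
        )
        emb = pca_embed(ds, n_components=4)
        emb_perm = pca_embed(ds_perm, n_components=4)
        assert np.allclose(emb.coords[perm], emb_perm.coords, atol=1e-8)

    def test_projection_of_duplicated_individual_recovers_its_scores(self):
        ds = make_dataset(seed=9, m=10, k=50)
        dup = np.vstack([ds.dosages, ds.dosages[3]])
        ds_dup = read_matrix(dup)
        emb = pca_embed(ds_dup, n_components=5, project_ids=["ind_10"])
        assert np.allclose(emb.coords[10], emb.coords[3], atol=1e-8)

    def test_projected_individual_excluded_from_fit(self):
        ds = make_dataset(seed=13, m=10, k=50)
        base = pca_embed(
            read_matrix(ds.dosages[:9]), n_components=4
        )
        with_proj = pca_embed(ds, n_components=4, project_ids=["ind_9"])
        assert np.allclose(base.coords, with_proj.coords[:9], atol=1e-8)

    def test_parameter_errors(self):
        ds = make_dataset(seed=1, m=5, k=10)
        with pytest.raises(ParameterError, match="n_components"):
            pca_embed(ds, n_components=5)  # > M_fit - 1
        with pytest.raises(ParameterError, match="fewer than 2"):
            pca_embed(ds, n_components=2, project_ids=[f"ind_{i}" for i in range(4)])
        with pytest.raises(ParameterError, match="unknown project_ids"):
            pca_embed(ds, n_components=2, project_ids=["nope"])


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        ds = read_matrix(np.tile([0, 1, 2, 1], (3, 1)))
        for metric in ("euclidean", "manhattan", "hamming"):
            d = pairwise_distance(ds, metric)
            assert np.allclose(d.values, 0)

    def test_hand_computed_metrics(self):
        ds = read_matrix([[0, 2], [2, 0]])
        assert pairwise_distance(ds, "euclidean").values[0, 1] == pytest.approx(np.sqrt(8))
        assert pairwise_distance(ds, "manhattan").values[0, 1] == pytest.approx(4)
        assert pairwise_distance(ds, "hamming").values[0, 1] == pytest.approx(2)

    def test_permutation_equivariance(self):
        ds = make_dataset(seed=3, m=8, k=20)
        perm = [3, 1, 0, 2, 7, 6, 5, 4]
        ds_perm = read_matrix(
            ds.dosages[perm], individual_ids=[ds.individual_ids[i] for i in perm]
        )
        d = pairwise_distance(ds, "euclidean").values
        d_perm = pairwise_distance(ds_perm, "euclidean").values
        assert np.allclose(d[np.ix_(perm, perm)], d_perm)

    def test_fst_requires_population_level(self):
        ds = make_dataset(seed=1, m=6, k=10)
        with pytest.raises(ParameterError, match="population level"):
            pairwise_distance(ds, "fst", "individual")

    def test_fst_matrix_symmetric_zero_diagonal(self):
        ds = make_dataset(seed=4, m=12, k=200, n_pops=3)
        d = pairwise_distance(ds, "fst", "population")
        assert d.values.shape == (3, 3)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        assert (d.values >= 0).all() and (d.values <= 1).all()


class TestHudsonFst:
    def test_no_differentiation_clamps_to_zero(self):
        p = np.full(100, 0.5)
        n = np.full(100, 1000.0)
        assert hudson_fst(p, n, p, n) == 0.0

    def test_fixed_difference_gives_one(self):
        assert hudson_fst([0.0], [50], [1.0], [50]) == pytest.approx(1.0)

    def test_matches_per_snp_hand_computation(self):
        p1, p2 = np.array([0.2, 0.5]), np.array([0.8, 0.5])
        n = np.array([20.0, 20.0])
        num = sum(
            (a - b) ** 2 - a * (1 - a) / 19 - b * (1 - b) / 19
            for a, b in zip(p1, p2)
        )
        den = sum(a * (1 - b) + b * (1 - a) for a, b in zip(p1, p2))
        assert hudson_fst(p1, n, p2, n) == pytest.approx(num / den)

    def test_symmetric_in_population_order(self):
        rng = np.random.default_rng(8)
        p1, p2 = rng.random(50), rng.random(50)
        n = np.full(50, 30.0)
        assert hudson_fst(p1, n, p2, n) == pytest.approx(hudson_fst(p2, n, p1, n))

    def test_monomorphic_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no polymorphism"):
            assert hudson_fst([0.0], [10], [0.0], [10]) == 0.0

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            hudson_fst([1.5], [10], [0.5], [10])
        with pytest.raises(ParameterError):
            hudson_fst([0.5], [1], [0.5], [10])


class TestMDS:
    def test_collinear_configuration_reproduced(self):
        d = DistanceMatrix(
            values=[[0, 1, 2], [1, 0, 1], [2, 1, 0]], row_labels=["a", "b", "c"]
        )
        emb = mds_embed(d, n_components=2)
        got = np.linalg.norm(emb.coords[:, None] - emb.coords[None], axis=-1)
        assert np.allclose(got, d.values, atol=1e-6)

    def test_zero_distances_give_coincident_points(self):
        d = DistanceMatrix(values=np.zeros((4, 4)), row_labels=list("abcd"))
        emb = mds_embed(d, n_components=2)
        assert np.allclose(emb.coords, emb.coords[0])

    def test_stress_never_exceeds_classical_init(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(10, 4))
        dv = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dv += rng.random(dv.shape) * 0.05
        dv = np.triu(dv, 1)
        dv = dv + dv.T
        d = DistanceMatrix(values=dv, row_labels=[str(i) for i in range(10)])
        emb = mds_embed(d, n_components=2)
        init = classical_scaling(d.values, 2)
        assert _raw_stress(d.values, emb.coords) <= _raw_stress(d.values, init) + 1e-9

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ParameterError, match="symmetric"):
            DistanceMatrix(values=[[0, 1], [2, 0]], row_labels=["a", "b"])
        with pytest.raises(ParameterError, match="nonnegative"):
            DistanceMatrix(values=[[0, -1], [-1, 0]], row_labels=["a", "b"])
        with pytest.raises(ParameterError, match="diagonal"):
            DistanceMatrix(values=[[1, 0], [0, 1]], row_labels=["a", "b"])
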