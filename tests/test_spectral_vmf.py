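import numpy as np
import pandas as pd
import pytest
from scipy.special import iv
from sklearn.metrics import adjusted_rand_score

from ghufinder.spectral_vmf import (
    SpectralEmbedding,
    build_laplacian,
    build_similarity,
    embed,
    fit_movmf,
    hard_assign,
    log_vmf_normalizer,
)
from .conftest import make_matrix


def reference_mixture_loglik(coords, means, weights, kappa):
    """Independent evaluation of the vMF mixture log-likelihood.

    Uses the unscaled modified Bessel function directly, unlike the
    implementation under test.
    """
    d = coords.shape[1]
    nu = d / 2 - 1
    const = kappa**nu / ((2 * np.pi) ** (d / 2) * iv(nu, kappa))
    dens = const * np.exp(kappa * coords @ means.T)  # (n, k)
    return float(np.log(dens @ weights).sum())


class TestSimilarity:
    def test_identical_rows_have_cosine_one(self):
        gm = make_matrix([[1.0, 0.0], [2.0, 0.0], [0.0, 1.0]])
        w = build_similarity(gm)
        assert w.loc["G1", "G2"] == pytest.approx(1.0)
        assert w.loc["G1", "G3"] == pytest.approx(0.0)
        assert np.allclose(np.diag(w), 1.0)

    def test_hand_computed_three_gene_table(self):
        gm = make_matrix([[1.0, 0.0], [1.0, 1.0], [-1.0, 1.0]])
        w = build_similarity(gm).to_numpy()
        s = 1 / np.sqrt(2)
        expected = np.array([[1, s, 0], [s, 1, 0], [0, 0, 1]])
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_zero_row_dropped(self, caplog):
        gm = make_matrix([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        w = build_similarity(gm)
        assert list(w.index) == ["G1", "G3"]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        gm = make_matrix(rng.normal(size=(6, 4)))
        perm = [3, 0, 5, 1, 4, 2]
        permuted = make_matrix(gm.values[perm], genes=[gm.gene_ids[i] for i in perm])
        w = build_similarity(gm)
        wp = build_similarity(permuted)
        np.testing.assert_allclose(
            wp.to_numpy(), w.to_numpy()[np.ix_(perm, perm)], atol=1e-12
        )
        lp = build_laplacian(wp)
        l0 = build_laplacian(w)
        np.testing.assert_allclose(
            lp.to_numpy(), l0.to_numpy()[np.ix_(perm, perm)], atol=1e-12
        )
        # the embedding is equivariant up to eigenvector sign: compare Grams
        g0 = embed(l0, 3).coords @ embed(l0, 3).coords.T
        gp = embed(lp, 3).coords @ embed(lp, 3).coords.T
        np.testing.assert_allclose(gp, g0[np.ix_(perm, perm)], atol=1e-8)


class TestLaplacian:
    def test_identity_similarity_gives_zero(self):
        w = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        lap = build_laplacian(w)
        np.testing.assert_allclose(lap.to_numpy(), 0.0, atol=1e-12)

    def test_two_node_complete_graph_eigenvalues(self):
        w = pd.DataFrame(np.ones((2, 2)), index=list("ab"), columns=list("ab"))
        vals = np.linalg.eigvalsh(build_laplacian(w).to_numpy())
        np.testing.assert_allclose(sorted(vals), [0.0, 1.0], atol=1e-12)

    def test_spectrum_bounds_and_trivial_eigenvector(self):
        rng = np.random.default_rng(0)
        gm = make_matrix(rng.uniform(size=(8, 5)))
        w = build_similarity(gm)
        lap = build_laplacian(w)
        vals, vecs = np.linalg.eigh(lap.to_numpy())
        assert vals.min() >= -1e-8 and vals.max() <= 2 + 1e-8
        assert vals[0] == pytest.approx(0.0, abs=1e-10)
        expected = np.sqrt(np.asarray(w).sum(axis=1))
        expected /= np.linalg.norm(expected)
        got = vecs[:, 0] / np.linalg.norm(vecs[:, 0])
        assert abs(np.dot(got, expected)) == pytest.approx(1.0, abs=1e-8)

    def test_zero_degree_gene_is_named(self):
        w = pd.DataFrame(np.diag([1.0, 0.0]), index=["ga", "gb"], columns=["ga", "gb"])
        with pytest.raises(ValueError, match="gb"):
            build_laplacian(w)


class TestEmbed:
    def test_disconnected_blocks_separate(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        wdf = pd.DataFrame(w, index=[f"g{i}" for i in range(6)], columns=[f"g{i}" for i in range(6)])
        emb = embed(build_laplacian(wdf), 2)
        within_a = emb.coords[:3] @ emb.coords[:3].T
        across = emb.coords[:3] @ emb.coords[3:].T
        assert np.allclose(within_a, 1.0, atol=1e-8)
        assert np.all(across < 0.99)

    def test_rows_unit_norm_full_basis(self):
        rng = np.random.default_rng(1)
        gm = make_matrix(rng.uniform(size=(5, 4)))
        emb = embed(build_laplacian(build_similarity(gm)), 5)
        np.testing.assert_allclose(np.linalg.norm(emb.coords, axis=1), 1.0, atol=1e-10)

    def test_k_bounds(self):
        w = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        lap = build_laplacian(w)
        with pytest.raises(ValueError):
            embed(lap, 1)
        with pytest.raises(ValueError):
            embed(lap, 4)


def _cap_embedding(rng, n_per_cap=50):
    """Two tight antipodal caps on the unit sphere in 4 dimensions."""
    center = np.array([1.0, 0.0, 0.0, 0.0])
    pts = []
    labels = []
    for sign in (1, -1):
        raw = sign * center + rng.normal(0, 0.05, size=(n_per_cap, 4))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        pts.append(raw)
        labels += [sign] * n_per_cap
    coords = np.vstack(pts)
    ids = [f"g{i}" for i in range(coords.shape[0])]
    return SpectralEmbedding(ids, coords), np.array(labels)


class TestMovMF:
    def test_single_direction_single_component(self):
        v = np.array([0.0, 1.0, 0.0])
        coords = np.tile(v, (10, 1))
        emb = SpectralEmbedding([f"g{i}" for i in range(10)], coords)
        model = fit_movmf(emb, k=1, kappa=10.0, n_restarts=3, seed=0)
        np.testing.assert_allclose(model.means[0], v, atol=1e-8)
        np.testing.assert_allclose(model.weights, [1.0])
        np.testing.assert_allclose(model.posteriors, 1.0)

    def test_antipodal_caps_recovered_and_loglik_matches_oracle(self):
        rng = np.random.default_rng(5)
        emb, truth = _cap_embedding(rng)
        model = fit_movmf(emb, k=2, kappa=10.0, n_restarts=10, seed=1)
        labels = hard_assign(model).to_numpy()
        assert adjusted_rand_score(truth, labels) == 1.0
        oracle = reference_mixture_loglik(emb.coords, model.means, model.weights, model.kappa)
        assert model.log_likelihood == pytest.approx(oracle, rel=1e-9)

    def test_em_monotone_and_normalized(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(60, 3))
        coords /= np.linalg.norm(coords, axis=1, keepdims=True)
        emb = SpectralEmbedding([f"g{i}" for i in range(60)], coords)
        model = fit_movmf(emb, k=3, kappa=5.0, n_restarts=20, seed=3)
        assert model.min_loglik_increase >= -1e-9
        assert model.max_invariant_error <= 1e-8
        np.testing.assert_allclose(model.posteriors.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(model.weights.sum(), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(model.means, axis=1), 1.0, atol=1e-10)

    def test_restart_determinism(self):
        rng = np.random.default_rng(4)
        emb, _ = _cap_embedding(rng, n_per_cap=20)
        a = fit_movmf(emb, k=2, kappa=10.0, n_restarts=5, seed=11)
        b = fit_movmf(emb, k=2, kappa=10.0, n_restarts=5, seed=11)
        np.testing.assert_array_equal(a.posteriors, b.posteriors)
        assert a.log_likelihood == b.log_likelihood

    def test_parameter_validation(self):
        rng = np.random.default_rng(0)
        emb, _ = _cap_embedding(rng, n_per_cap=5)
        with pytest.raises(ValueError):
            fit_movmf(emb, k=0, kappa=10.0)
        with pytest.raises(ValueError):
            fit_movmf(emb, k=2, kappa=-1.0)
        with pytest.raises(ValueError):
            fit_movmf(emb, k=2, kappa=10.0, n_restarts=0)


class TestHardAssign:
    @pytest.mark.parametrize(
        "row,expected",
        [((0.8, 0.2), 1), ((0.5, 0.5), 1), ((0.0, 1.0), 2)],
    )
    def test_argmax_with_low_index_ties(self, row, expected):
        model_post = np.array([row])
        from ghufinder.spectral_vmf import SoftClusterModel

        model = SoftClusterModel(
            k=2,
            kappa=10.0,
            means=np.eye(2),
            weights=np.array([0.5, 0.5]),
            posteriors=model_post,
            log_likelihood=0.0,
            gene_ids=["g"],
        )
        assert hard_assign(model).iloc[0] == expected


def test_log_normalizer_matches_direct_bessel():
    for d, kappa in [(2, 10.0), (4, 10.0), (5, 3.0)]:
        nu = d / 2 - 1
        direct = nu * np.log(kappa) - (d / 2) * np.log(2 * np.pi) - np.log(iv(nu, kappa))
        assert log_vmf_normalizer(d, kappa) == pytest.approx(direct, rel=1e-12)
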