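import numpy as np
import pytest
from scipy import stats

from mdtr.io import Pathway
from mdtr.pathway import (
    DegenerateSpaceError,
    build_toxicity_space,
    compute_pathway_distances,
    embed_samples,
    fit_f_null,
    fit_reference,
    latent_dim,
    load_spaces,
    mahalanobis_sq,
    min_max_normalize,
    pathway_weight,
    save_spaces,
)
from mdtr.svdd import rbf_kernel_matrix


def kpca_oracle(X_train, X_test, gamma, d):
    """Explicit double-centered kernel PCA projection (independent route)."""
    n = len(X_train)
    K = rbf_kernel_matrix(X_train, X_train, gamma)
    one = np.full((n, n), 1.0 / n)
    Kc = K - one @ K - K @ one + one @ K @ one
    eigval, eigvec = np.linalg.eigh(Kc)
    order = np.argsort(eigval)[::-1][:d]
    lam, V = eigval[order], eigvec[:, order]
    K_test = rbf_kernel_matrix(X_test, X_train, gamma)
    ones_t = np.full((len(X_test), n), 1.0 / n)
    K_test_c = K_test - ones_t @ K - K_test @ one + ones_t @ K @ one
    return K_test_c @ V / np.sqrt(lam)


def assert_allclose_up_to_sign(A, B, atol):
    for j in range(A.shape[1]):
        direct = np.abs(A[:, j] - B[:, j]).max()
        flipped = np.abs(A[:, j] + B[:, j]).max()
        assert min(direct, flipped) < atol


def _pathway(l):
    return Pathway("pw", "pw", frozenset(f"g{i}" for i in range(l)))


class TestBuildToxicitySpace:
    @pytest.mark.parametrize("l_p, expected", [(100, 3), (20, 2), (30, 3), (15, 1), (5, 1)])
    def test_latent_dim_formula(self, l_p, expected):
        assert latent_dim(l_p) == expected

    def test_gamma_is_inverse_gene_count(self):
        rng = np.random.default_rng(0)
        space = build_toxicity_space(rng.normal(size=(8, 20)), _pathway(20))
        assert space.gamma == pytest.approx(1 / 20)

    def test_training_scores_match_explicit_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 15))
        space = build_toxicity_space(X, _pathway(15))
        Z = embed_samples(space, X)
        Z_ref = kpca_oracle(X, X, space.gamma, space.dim)
        assert_allclose_up_to_sign(Z, Z_ref, atol=1e-8)

    def test_out_of_sample_matches_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 15))
        T = rng.normal(size=(10, 15))
        space = build_toxicity_space(X, _pathway(15))
        assert_allclose_up_to_sign(
            embed_samples(space, T), kpca_oracle(X, T, space.gamma, space.dim), atol=1e-8
        )

    def test_identical_profiles_degenerate(self):
        X = np.ones((5, 12))
        with pytest.raises(DegenerateSpaceError):
            build_toxicity_space(X, _pathway(12))

    def test_batch_vs_single_embedding_identical(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 20))
        T = rng.normal(size=(6, 20))
        space = build_toxicity_space(X, _pathway(20))
        batch = embed_samples(space, T)
        singles = np.vstack([embed_samples(space, t[None, :]) for t in T])
        np.testing.assert_allclose(batch, singles, atol=1e-10)

    def test_duplicate_of_training_sample_same_point(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 20))
        space = build_toxicity_space(X, _pathway(20))
        z_train = embed_samples(space, X)[3]
        z_dup = embed_samples(space, X[3][None, :])[0]
        np.testing.assert_allclose(z_dup, z_train, atol=1e-10)


class TestMahalanobis:
    def test_zero_at_mean(self):
        mu = np.array([1.0, 2.0])
        assert mahalanobis_sq(mu, mu, np.eye(2)) == 0.0

    def test_identity_covariance_is_squared_euclidean(self):
        z, mu = np.array([3.0, 4.0]), np.zeros(2)
        assert mahalanobis_sq(z, mu, np.eye(2)) == pytest.approx(25.0)

    def test_matches_explicit_inverse(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        mu = rng.normal(size=3)
        z = rng.normal(size=3)
        expected = float((z - mu) @ np.linalg.inv(cov) @ (z - mu))
        assert mahalanobis_sq(z, mu, cov) == pytest.approx(expected, abs=1e-10)

    def test_invariance_under_linear_reparameterization(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(40, 3))
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)  # invertible map
        mu, cov = Z.mean(0), np.cov(Z, rowvar=False, ddof=1)
        ZA = Z @ A.T
        muA, covA = ZA.mean(0), np.cov(ZA, rowvar=False, ddof=1)
        d = mahalanobis_sq(Z, mu, cov)
        dA = mahalanobis_sq(ZA, muA, covA)
        np.testing.assert_allclose(d, dA, atol=1e-8)


class TestFitReference:
    def test_two_symmetric_points_sample_convention(self):
        rng = np.random.default_rng(7)
        space = build_toxicity_space(rng.normal(size=(5, 20)), _pathway(20))
        v = 1.5
        Z = np.array([[v], [-v], [0.0]])
        mu, cov = fit_reference(space, Z)
        assert mu[0] == pytest.approx(0.0)
        # sample covariance of (v, -v, 0) with ddof=1 is v^2, plus tiny ridge
        assert cov[0, 0] == pytest.approx(v**2, rel=1e-5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(8)
        space = build_toxicity_space(rng.normal(size=(5, 20)), _pathway(20))
        Z = rng.normal(size=(30, 2))
        mu1, cov1 = fit_reference(space, Z)
        perm = rng.permutation(30)
        mu2, cov2 = fit_reference(space, Z[perm])
        np.testing.assert_allclose(mu1, mu2, atol=1e-12)
        np.testing.assert_allclose(cov1, cov2, atol=1e-12)

    def test_ridge_barely_changes_well_conditioned_distances(self):
        rng = np.random.default_rng(9)
        space = build_toxicity_space(rng.normal(size=(5, 20)), _pathway(20))
        Z = rng.normal(size=(50, 2))
        mu, cov = fit_reference(space, Z)
        cov_plain = np.cov(Z, rowvar=False, ddof=1)
        d_ridge = mahalanobis_sq(Z, mu, cov)
        d_plain = mahalanobis_sq(Z, Z.mean(0), cov_plain)
        assert np.max(np.abs(d_ridge - d_plain) / np.maximum(d_plain, 1e-12)) < 1e-3

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(10)
        space = build_toxicity_space(rng.normal(size=(5, 20)), _pathway(20))
        with pytest.raises(ValueError, match="embedded samples"):
            fit_reference(space, np.zeros((3, 2)))


class TestMinMaxNormalize:
    def test_basic(self):
        np.testing.assert_allclose(
            min_max_normalize(np.array([0.2, 0.6, 1.0])), [0.0, 0.5, 1.0]
        )

    def test_constant_input_maps_to_zero(self):
        np.testing.assert_array_equal(min_max_normalize(np.full(4, 2.5)), np.zeros(4))

    def test_attains_both_bounds_and_idempotent(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=50)
        out = min_max_normalize(v)
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_allclose(min_max_normalize(out), out, atol=1e-15)


class TestFNull:
    def test_parameter_recovery(self):
        x = stats.f.rvs(5, 10, size=5000, random_state=np.random.default_rng(12))
        d1, d2, scale = fit_f_null(x)
        assert abs(d1 - 5) / 5 < 0.15
        assert abs(d2 - 10) / 10 < 0.15

    def test_fit_is_local_likelihood_optimum(self):
        x = stats.f.rvs(4, 8, size=2000, random_state=np.random.default_rng(13))
        d1, d2, scale = fit_f_null(x, fit_scale=False)
        ll = stats.f.logpdf(x, d1, d2).sum()
        for delta in [(0.1, 0), (-0.1, 0), (0, 0.1), (0, -0.1)]:
            assert ll >= stats.f.logpdf(x, d1 + delta[0], d2 + delta[1]).sum()

    def test_zeros_lifted_to_floor(self):
        x = np.concatenate([np.zeros(5), stats.f.rvs(3, 6, size=100,
                            random_state=np.random.default_rng(14))])
        d1, d2, scale = fit_f_null(x)
        assert np.isfinite(d1) and np.isfinite(d2) and d1 > 0 and d2 > 0

    def test_all_zero_degenerate(self):
        with pytest.raises(ArithmeticError, match="degenerate"):
            fit_f_null(np.zeros(20))


class TestPathwayWeight:
    def test_closed_form_f22_at_one(self):
        # F(2,2) CDF at 1 is 1/(1+1) = 0.5 in both tail conventions
        assert pathway_weight(1.0, 2, 2, tail="cdf") == pytest.approx(np.log(2), abs=1e-9)
        assert pathway_weight(1.0, 2, 2, tail="survival") == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_cdf_mode_vanishes_at_large_distance(self):
        assert pathway_weight(1e6, 3, 7, tail="cdf") == pytest.approx(0.0, abs=1e-6)

    def test_weights_nonnegative_and_clamped(self):
        grid = np.linspace(0, 50, 200)
        for tail in ("cdf", "survival"):
            w = pathway_weight(grid, 2.5, 6.0, tail=tail)
            assert np.all(w >= 0) and np.all(w <= 700.0)

    def test_monotonicity_by_tail_mode(self):
        grid = np.linspace(0.01, 10, 300)
        w_cdf = pathway_weight(grid, 3.0, 5.0, tail="cdf")
        w_surv = pathway_weight(grid, 3.0, 5.0, tail="survival")
        assert np.all(np.diff(w_cdf) <= 1e-12)
        assert np.all(np.diff(w_surv) >= -1e-12)

    def test_scale_rescales_argument(self):
        assert pathway_weight(0.5, 3, 5, scale=0.5, tail="survival") == pytest.approx(
            pathway_weight(1.0, 3, 5, scale=1.0, tail="survival"), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pathway_weight(np.nan, 2, 2)
        with pytest.raises(ValueError):
            pathway_weight(1.0, -1, 2)


class TestComputePathwayDistances:
    def test_normalized_bounds_and_weights(self, default_cohort, fitted_pipeline):
        expr, meta, *_ = default_cohort
        boundary, spaces, _ = fitted_pipeline
        pid = next(iter(spaces))
        res = compute_pathway_distances(
            spaces[pid], expr, meta, set(boundary.pt_sample_ids)
        )
        assert res.normalized.min() == 0.0
        assert res.normalized.max() == 1.0
        assert np.all(res.weights >= 0)
        assert np.all(np.isfinite(res.weights))

    def test_perturbed_pathway_separates_toxic_from_dmso(
        self, default_cohort, fitted_pipeline
    ):
        expr, meta, pathways, mech_map, truth = default_cohort
        boundary, spaces, _ = fitted_pipeline
        pid = truth.perturbed_pathway_ids[0]
        res = compute_pathway_distances(
            spaces[pid], expr, meta, set(boundary.pt_sample_ids)
        )
        idx = {s: i for i, s in enumerate(res.sample_ids)}
        tox = [idx[s] for s in meta.ids_in_group("TOXIC")
               if meta.row(s)["dose_um"] >= 3.0]
        dmso = [idx[s] for s in meta.ids_in_group("DMSO")]
        assert res.normalized[tox].mean() > res.normalized[dmso].mean()

    def test_gene_order_permutation_invariance(self, small_cohort):
        (expr, meta, pathways, mech_map, truth), cfg = small_cohort
        from mdtr.io import intersect_pathway
        from mdtr.svdd import fit_dual_boundaries

        boundary = fit_dual_boundaries(expr, meta)
        pw = pathways[0]
        subset = intersect_pathway(pw, expr.gene_ids)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(subset))
        pt = boundary.pt_sample_ids

        m1 = expr.subset_genes(subset).sample_matrix(pt)
        m2 = expr.subset_genes(perm).sample_matrix(pt)
        s1 = build_toxicity_space(m1, pw, subset)
        s2 = build_toxicity_space(m2, pw, perm)
        r1 = compute_pathway_distances(s1, expr, meta, set(pt))
        r2 = compute_pathway_distances(s2, expr, meta, set(pt))
        np.testing.assert_allclose(r1.raw, r2.raw, atol=1e-10)
        np.testing.assert_allclose(r1.normalized, r2.normalized, atol=1e-10)

    def test_space_round_trip_serialization(self, tmp_path, default_cohort, fitted_pipeline):
        expr, meta, *_ = default_cohort
        boundary, spaces, _ = fitted_pipeline
        path = tmp_path / "spaces.json"
        save_spaces(spaces, path)
        back = load_spaces(path)
        assert set(back) == set(spaces)
        pid = next(iter(spaces))
        X = expr.subset_genes(spaces[pid].gene_subset).sample_matrix()[:5]
        np.testing.assert_allclose(
            np.abs(embed_samples(back[pid], X)),
            np.abs(embed_samples(spaces[pid], X)),
            atol=1e-8,
        )
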