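"""Sparsification, cosine affinity, diffusion map, orientation, matching."""

import itertools

import numpy as np
import pytest
import scipy.linalg

from conngrad.connectome import ConnectivityMatrix
from conngrad.embed import (
    AffinityMatrix,
    GradientSet,
    cosine_affinity,
    diffusion_map,
    load_gradients,
    match_gradients,
    orient_gradients,
    save_gradients,
    sparsify_rows,
    variance_explained,
)
from conngrad.exceptions import (
    DegenerateRowError,
    GraphConnectivityError,
    InvalidParameterError,
    InvalidStateError,
)


def _conn(values):
    values = np.asarray(values, dtype=float)
    return ConnectivityMatrix(
        values, np.arange(values.shape[0]), np.arange(values.shape[1]), "fisher-z"
    )


def _random_affinity(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.random((n, n + 5))
    unit = x / np.linalg.norm(x, axis=1, keepdims=True)
    aff = unit @ unit.T
    aff = (aff + aff.T) / 2
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(aff, np.arange(n))


def oracle_diffusion_map(aff, n_components, alpha=0.5, diffusion_time=0.0):
    """Independent dense route: generalized symmetric eigenproblem
    W' u = lambda D' u solved directly by scipy.linalg.eigh(W', D')."""
    w = aff.values.copy()
    d = w.sum(axis=1)
    if alpha > 0:
        da = d**-alpha
        w = w * da[:, None] * da[None, :]
        d = w.sum(axis=1)
    lam, u = scipy.linalg.eigh(w, np.diag(d))
    lam, u = lam[::-1], u[:, ::-1]
    psi = u / u[:, [0]]
    lam_k = np.clip(lam[1 : n_components + 1], -1 + 1e-15, 1 - 1e-15)
    scale = lam_k**diffusion_time if diffusion_time > 0 else lam_k / (1 - lam_k)
    return psi[:, 1 : n_components + 1] * scale[None, :], lam[1 : n_components + 1]


def assert_equal_up_to_sign(a, b, atol):
    for j in range(a.shape[1]):
        d = min(np.max(np.abs(a[:, j] - b[:, j])), np.max(np.abs(a[:, j] + b[:, j])))
        assert d < atol, f"component {j}: {d}"


class TestSparsifyRows:
    def test_keep_all_is_identity(self):
        conn = _conn(np.random.default_rng(0).standard_normal((5, 20)))
        np.testing.assert_array_equal(sparsify_rows(conn, 100).values, conn.values)

    def test_top_one_of_ten(self):
        row = np.array([[5, 4, 3, 2, 1, 0, -1, -2, -3, -4]], dtype=float)
        out = sparsify_rows(_conn(row), 10).values[0]
        np.testing.assert_array_equal(out, [5, 0, 0, 0, 0, 0, 0, 0, 0, 0])

    def test_survivor_counts_match_sort_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((20, 50))
        values[3, :10] = values[3, 10]  # inject ties
        out = sparsify_rows(_conn(values), 10).values
        for i in range(20):
            # independent percentile: sort + linear interpolation, closed threshold
            srt = np.sort(values[i])
            pos = 0.90 * (50 - 1)
            lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            cut = srt[lo] + frac * (srt[min(lo + 1, 49)] - srt[lo])
            assert (out[i] != 0).sum() == (values[i] >= cut).sum()

    def test_out_of_range_pct_rejected(self):
        conn = _conn(np.ones((2, 4)))
        with pytest.raises(InvalidParameterError):
            sparsify_rows(conn, 0)
        with pytest.raises(InvalidParameterError):
            sparsify_rows(conn, 101)


class TestCosineAffinity:
    def test_identical_rows_have_unit_similarity(self):
        aff = cosine_affinity(_conn([[1, 2, 3], [1, 2, 3]]))
        assert aff.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rows_have_zero_similarity(self):
        aff = cosine_affinity(_conn([[1, 0, 0], [0, 1, 0]]))
        assert aff.values[0, 1] == 0.0

    def test_direct_formula_example(self):
        aff = cosine_affinity(_conn([[1, 1, 0], [1, 0, 1]]))
        assert aff.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_row_rejected(self):
        with pytest.raises(DegenerateRowError) as err:
            cosine_affinity(_conn([[1, 1, 0], [0, 0, 0]]))
        assert err.value.rows == [1]


class TestDiffusionMap:
    def test_two_block_affinity_splits_on_gradient_one(self):
        n = 30
        w = np.full((n, n), 0.01)
        w[:15, :15] = 1.0
        w[15:, 15:] = 1.0
        np.fill_diagonal(w, 1.0)
        g = diffusion_map(AffinityMatrix(w, np.arange(n)), n_components=2)
        g1 = g.gradient(1)
        assert np.sign(g1[:15]).min() != np.sign(g1[15:]).min()  # opposite blocks
        assert np.ptp(g1[:15]) < 1e-6 and np.ptp(g1[15:]) < 1e-6

    def test_constant_affinity_is_structureless(self):
        aff = AffinityMatrix(np.ones((20, 20)), np.arange(20))
        g = diffusion_map(aff, n_components=3)
        assert np.max(np.abs(g.eigenvalues)) < 1e-8
        assert variance_explained(g)[0] < 1e-6 or np.max(np.abs(g.components)) < 1e-6

    @pytest.mark.parametrize("alpha,diffusion_time", [(0.5, 0.0), (0.0, 0.0), (1.0, 2.0)])
    def test_matches_dense_generalized_eigendecomposition(self, alpha, diffusion_time):
        aff = _random_affinity(30, seed=7)
        g = diffusion_map(aff, n_components=5, alpha=alpha, diffusion_time=diffusion_time)
        comps, evals = oracle_diffusion_map(aff, 5, alpha, diffusion_time)
        np.testing.assert_allclose(g.eigenvalues, evals, atol=1e-8)
        assert_equal_up_to_sign(g.components, comps, atol=1e-8)

    def test_disconnected_graph_raises(self):
        w = np.zeros((10, 10))
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        with pytest.raises(GraphConnectivityError):
            diffusion_map(AffinityMatrix(w, np.arange(10)), n_components=2)

    def test_permutation_equivariance(self):
        aff = _random_affinity(25, seed=8)
        rng = np.random.default_rng(9)
        perm = rng.permutation(25)
        g = diffusion_map(aff, n_components=4)
        aff_p = AffinityMatrix(aff.values[np.ix_(perm, perm)], np.arange(25))
        g_p = diffusion_map(aff_p, n_components=4)
        assert_equal_up_to_sign(g_p.components, g.components[perm], atol=1e-8)

    def test_components_uncorrelated_under_stationary_weighting(self):
        aff = _random_affinity(35, seed=10)
        g = diffusion_map(aff, n_components=4)
        w = aff.values.copy()
        d = w.sum(axis=1)
        da = d**-0.5
        w2 = w * da[:, None] * da[None, :]
        pi = w2.sum(axis=1)
        pi = pi / pi.sum()
        x = g.components
        gram = (x * pi[:, None]).T @ x
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6


class TestVarianceExplained:
    def test_single_component_is_everything(self):
        g = GradientSet(np.zeros((5, 1)), np.array([0.7]), np.arange(5))
        assert variance_explained(g)[0] == 1.0

    def test_hand_formula(self):
        g = GradientSet(np.zeros((5, 2)), np.array([0.8, 0.4]), np.arange(5))
        np.testing.assert_allclose(
            variance_explained(g), [0.64 / 0.80, 0.16 / 0.80], atol=1e-15
        )

    def test_sums_to_one(self):
        lam = np.array([0.9, 0.5, 0.3, 0.1])
        g = GradientSet(np.zeros((6, 4)), lam, np.arange(6))
        assert variance_explained(g).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_spectrum_rejected(self):
        g = GradientSet(np.zeros((5, 0)), np.zeros(0), np.arange(5))
        with pytest.raises(InvalidStateError):
            variance_explained(g)


class TestOrientGradients:
    def _g(self, col):
        return GradientSet(np.asarray(col, dtype=float)[:, None], np.array([0.5]), np.arange(4))

    def test_negative_anchor_mean_unchanged(self):
        g = self._g([-3, -1, 1, 1])
        anchor = np.array([True, True, False, False])
        out = orient_gradients(g, anchor)
        np.testing.assert_array_equal(out.components, g.components)
        assert out.orientation == ["kept"]

    def test_positive_anchor_mean_flipped(self):
        g = self._g([3, 1, -1, -1])
        out = orient_gradients(g, np.array([True, True, False, False]))
        np.testing.assert_array_equal(out.components[:, 0], [-3, -1, 1, 1])
        assert out.orientation == ["flipped"]

    def test_idempotent(self):
        g = self._g([3, 1, -1, -1])
        anchor = np.array([True, True, False, False])
        once = orient_gradients(g, anchor)
        twice = orient_gradients(once, anchor)
        np.testing.assert_array_equal(once.components, twice.components)

    def test_reference_vector_form(self):
        g = self._g([1, 2, 3, 4])
        out = orient_gradients(g, np.array([4.0, 3.0, 2.0, 1.0]))
        np.testing.assert_array_equal(out.components[:, 0], [-1, -2, -3, -4])


class TestMatchGradients:
    def _pair(self, n=50, k=3, seed=11):
        rng = np.random.default_rng(seed)
        ref = GradientSet(rng.standard_normal((n, k)), np.linspace(0.9, 0.5, k), np.arange(n))
        return ref

    def test_swapped_components_restored(self):
        ref = self._pair()
        tgt = ref.copy()
        tgt.components = tgt.components[:, [1, 0, 2]]
        out = match_gradients(tgt, ref, 3)
        np.testing.assert_allclose(out.components, ref.components, atol=1e-12)
        assert out.params["matching"]["abs_correlations"] == pytest.approx([1, 1, 1])

    def test_negated_component_sign_restored(self):
        ref = self._pair()
        tgt = ref.copy()
        tgt.components = tgt.components.copy()
        tgt.components[:, 0] *= -1
        out = match_gradients(tgt, ref, 3)
        np.testing.assert_allclose(out.components, ref.components, atol=1e-12)

    def test_equals_exhaustive_signed_permutation_search(self):
        rng = np.random.default_rng(12)
        n, k = 40, 3
        ref = GradientSet(rng.standard_normal((n, k)), np.linspace(0.9, 0.5, k), np.arange(n))
        mix = rng.standard_normal((k, k))
        tgt = GradientSet(ref.components @ mix, np.linspace(0.9, 0.5, k), np.arange(n))
        out = match_gradients(tgt, ref, k)

        def total_abs_corr(components):
            return sum(
                abs(np.corrcoef(components[:, j], ref.components[:, j])[0, 1])
                for j in range(k)
            )

        best = -np.inf
        for perm in itertools.permutations(range(k)):
            for signs in itertools.product([1, -1], repeat=k):
                cand = tgt.components[:, list(perm)] * np.array(signs)
                best = max(best, total_abs_corr(cand))
        assert total_abs_corr(out.components) == pytest.approx(best, abs=1e-10)

    def test_k_too_large_rejected(self):
        ref = self._pair(k=2)
        with pytest.raises(InvalidParameterError):
            match_gradients(ref, ref, 5)


class TestGradientIO:
    def test_roundtrip(self, tmp_path):
        aff = _random_affinity(20, seed=13)
        g = diffusion_map(aff, n_components=4)
        save_gradients(g, tmp_path / "grad")
        back = load_gradients(tmp_path / "grad")
        np.testing.assert_allclose(back.components, g.components, atol=1e-12)
        np.testing.assert_allclose(back.eigenvalues, g.eigenvalues, atol=1e-12)
        np.testing.assert_array_equal(back.voxel_ids, g.voxel_ids)
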