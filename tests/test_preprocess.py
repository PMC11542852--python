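import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from mcadet.preprocess import (
    CountMatrix,
    build_correspondence,
    drop_degenerate_genes,
    fuzzy_code,
    pearson_residuals,
)


def _cm(values):
    values = np.asarray(values)
    n, p = values.shape
    return CountMatrix(values, [f"g{j}" for j in range(p)], [f"c{i}" for i in range(n)])


class TestCountMatrix:
    @pytest.mark.parametrize(
        "values, message",
        [
            ([[0, 1], [1, -1]], "non-negative"),
            ([[0.5, 1], [1, 2]], "integer"),
            ([[1, 2]], "at least 2"),
        ],
    )
    def test_rejects_invalid_values(self, values, message):
        with pytest.raises(ValueError, match=message):
            _cm(values)

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="unique"):
            CountMatrix(np.ones((2, 2), dtype=int), ["g", "g"], ["a", "b"])

    def test_accepts_sparse(self):
        cm = _cm([[0, 1], [2, 3]])
        sp_cm = CountMatrix(sp.csr_matrix(cm.values), cm.gene_ids, cm.cell_ids)
        assert np.array_equal(sp_cm.dense(), cm.dense())


class TestDropDegenerateGenes:
    def test_all_zero_column_dropped(self):
        cm = _cm([[0, 1, 2], [0, 3, 1], [0, 2, 5]])
        out = drop_degenerate_genes(cm)
        assert out.n_genes == 2 and out.gene_ids == ["g1", "g2"]

    def test_constant_nonzero_column_dropped(self):
        cm = _cm([[5, 1, 0], [5, 3, 2], [5, 2, 4]])
        out = drop_degenerate_genes(cm)
        assert out.gene_ids == ["g1", "g2"]

    def test_identity_when_no_constant_gene(self):
        cm = _cm([[0, 1], [2, 3], [1, 0]])
        out = drop_degenerate_genes(cm)
        assert out is cm

    def test_all_constant_is_an_error(self):
        with pytest.raises(ValueError, match="no usable genes"):
            drop_degenerate_genes(_cm([[1, 2], [1, 2]]))


class TestFuzzyCode:
    def test_linear_map_endpoints(self):
        Z, m1, m2 = fuzzy_code(_cm([[0, 3], [2, 3], [4, 9]]))
        assert np.allclose(Z[:, 0], [0, 0.5, 1])  # gene 0 "+"
        assert np.allclose(Z[:, 1], [1, 0.5, 0])  # gene 0 "-"
        assert np.allclose(Z[:, 2], [0, 0, 1])    # gene 1 "+": min->0, max->1
        assert np.array_equal(m1, [0, 3]) and np.array_equal(m2, [4, 9])

    def test_pairs_sum_to_one(self, rng):
        Y = rng.poisson(3.0, size=(12, 7)) + np.arange(7)  # no constant columns w.h.p.
        Z, _, _ = fuzzy_code(drop_degenerate_genes(_cm(Y)))
        assert np.allclose(Z[:, 0::2] + Z[:, 1::2], 1.0)
        assert Z.min() >= 0 and Z.max() <= 1

    def test_constant_column_names_gene(self):
        with pytest.raises(ValueError, match="g1"):
            fuzzy_code(_cm([[0, 7], [1, 7]]))


class TestCorrespondence:
    def test_margins(self, small_model):
        n, p = small_model.n_cells, small_model.n_genes
        assert np.allclose(small_model.row_mass, 1.0 / n)
        assert np.isclose(small_model.col_mass.sum(), 1.0)
        assert np.isclose(small_model.P.sum(), 1.0)
        assert np.isclose(small_model.Z.sum(), n * p)

    def test_uniform_fuzzy_matrix_gives_uniform_column_mass(self):
        Z = np.full((4, 6), 0.5)
        model = build_correspondence(Z)
        assert np.allclose(model.col_mass, 1.0 / 6)

    def test_row_mass_is_half_for_two_cells(self, rng):
        Z, _, _ = fuzzy_code(_cm([[0, 1, 5], [3, 2, 1]]))
        model = build_correspondence(Z)
        assert np.allclose(model.row_mass, 0.5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=9),
    p=st.integers(min_value=2, max_value=7),
    seed=st.integers(min_value=0, max_value=10**6),
)
def test_model_invariants_on_random_count_matrices(n, p, seed):
    """Fuzzy matrix, correspondence matrix and masses satisfy their defining
    identities on arbitrary valid count matrices."""
    rng = np.random.default_rng(seed)
    Y = rng.poisson(2.0, size=(n, p))
    Y[0] = 0
    Y[1] = Y[1] + 1  # every column contains 0 and >= 1: never constant
    Z, m1, m2 = fuzzy_code(_cm(Y))
    assert Z.min() >= 0 and Z.max() <= 1
    assert np.allclose(Z[:, 0::2] + Z[:, 1::2], 1.0)
    model = build_correspondence(Z, m1, m2)
    assert np.allclose(model.row_mass, 1.0 / n)
    assert model.col_mass.min() >= 0
    assert np.isclose(model.col_mass.sum(), 1.0)
    assert np.isclose(model.P.sum(), 1.0)
    R = pearson_residuals(model).R
    back = np.sqrt(np.outer(model.row_mass, model.col_mass)) * R + np.outer(
        model.row_mass, model.col_mass
    )
    assert np.allclose(back, model.P, atol=1e-10)


class TestPearsonResiduals:
    def test_independence_table_gives_zero(self):
        # every row identical -> P factorizes as r c^T exactly
        Z = np.tile([0.2, 0.8, 0.7, 0.3], (5, 1))
        R = pearson_residuals(build_correspondence(Z)).R
        assert np.allclose(R, 0.0, atol=1e-12)

    def test_elementwise_formula(self, small_model):
        R = pearson_residuals(small_model).R
        r, c, P = small_model.row_mass, small_model.col_mass, small_model.P
        for i in (0, 7):
            for j in (0, 5, 29):
                expected = (P[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
                assert R[i, j] == pytest.approx(expected, abs=1e-15)

    def test_row_permutation_equivariance(self, small_counts, rng):
        perm = rng.permutation(small_counts.n_cells)
        Z1, m1, m2 = fuzzy_code(small_counts)
        R1 = pearson_residuals(build_correspondence(Z1)).R
        permuted = CountMatrix(
            np.asarray(small_counts.values)[perm],
            small_counts.gene_ids,
            [small_counts.cell_ids[i] for i in perm],
        )
        Z2, _, _ = fuzzy_code(permuted)
        R2 = pearson_residuals(build_correspondence(Z2)).R
        assert np.allclose(R2, R1[perm], atol=1e-12)
        # Frobenius norm (total inertia) is permutation invariant
        assert np.isclose(np.linalg.norm(R1), np.linalg.norm(R2))

    def test_residuals_invert_back_to_p(self, small_model):
        R = pearson_residuals(small_model).R
        r, c = small_model.row_mass, small_model.col_mass
        P_back = np.sqrt(np.outer(r, c)) * R + np.outer(r, c)
        assert np.allclose(P_back, small_model.P, atol=1e-10)
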