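"""Relationship-matrix machinery against brute-force tabular oracles."""

import numpy as np
import pandas as pd
import pytest

from ipsim import kinship
from ipsim.kinship import (GenotypeMatrix, apy_inverse, build_A22, build_A_inverse,
                           build_G_raw, build_H_inverse_delta, inbreeding,
                           pedigree_arrays, tabular_A, tune_and_blend)

from conftest import make_random_pedigree


def trio_pedigree():
    return pd.DataFrame({"id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
                         "sex": ["M", "F", "M"], "generation": [0, 0, 1]})


class TestAInverse:
    def test_trio_matches_hand_inverse(self):
        ainv, F = build_A_inverse(trio_pedigree())
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(ainv.toarray(), expected, atol=1e-12)
        np.testing.assert_allclose(F, 0.0)

    def test_single_founder(self):
        ped = pd.DataFrame({"id": [1], "sire": [0], "dam": [0]})
        ainv, _ = build_A_inverse(ped)
        np.testing.assert_allclose(ainv.toarray(), [[1.0]])

    def test_random_pedigree_inverts_tabular_A(self, random_pedigree_200):
        """Henderson-rule A⁻¹ equals the numerical inverse of tabular A."""
        ainv, F = build_A_inverse(random_pedigree_200)
        sire, dam = pedigree_arrays(random_pedigree_200)
        A = tabular_A(sire, dam)
        assert F.max() > 0  # the loops really produce inbreeding
        np.testing.assert_allclose(F, np.diag(A) - 1.0, atol=1e-10)
        np.testing.assert_allclose(ainv.toarray(), np.linalg.inv(A), atol=1e-8)

    def test_unsorted_pedigree_rejected(self):
        ped = pd.DataFrame({"id": [1, 2], "sire": [2, 0], "dam": [0, 0]})
        with pytest.raises(ValueError, match="precede"):
            build_A_inverse(ped)

    def test_incremental_inbreeding_matches_full(self, random_pedigree_200):
        sire, dam = pedigree_arrays(random_pedigree_200)
        full = inbreeding(sire, dam)
        part = inbreeding(sire[:120], dam[:120])
        grown = inbreeding(sire, dam, F_init=part, start=120)
        np.testing.assert_allclose(grown, full, atol=1e-13)


class TestA22:
    def test_all_genotyped_equals_A(self, random_pedigree_200):
        sire, dam = pedigree_arrays(random_pedigree_200)
        A = tabular_A(sire, dam)
        a22 = build_A22(random_pedigree_200, np.arange(1, 201), method="solve")
        np.testing.assert_allclose(a22, A, atol=1e-10)

    def test_trio_offspring_only(self):
        a22 = build_A22(trio_pedigree(), np.array([3]))
        np.testing.assert_allclose(a22, [[1.0]], atol=1e-12)

    def test_random_subset_matches_tabular_submatrix(self, random_pedigree_200, rng):
        sire, dam = pedigree_arrays(random_pedigree_200)
        A = tabular_A(sire, dam)
        ids = np.sort(rng.choice(200, size=50, replace=False)) + 1
        a22 = build_A22(random_pedigree_200, ids, method="solve")
        np.testing.assert_allclose(a22, A[np.ix_(ids - 1, ids - 1)], atol=1e-10)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            build_A22(trio_pedigree(), np.array([9]))


class TestGenomicG:
    def test_hand_example(self):
        gm = GenotypeMatrix(np.array([[0, 2], [2, 0]]), [1, 2],
                            allele_freqs=[0.5, 0.5])
        assert gm.k == pytest.approx(1.0)
        np.testing.assert_allclose(gm.Z, [[-1.0, 1.0], [1.0, -1.0]])
        np.testing.assert_allclose(build_G_raw(gm), [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_rows_give_identical_relationships(self, rng):
        codes = rng.integers(0, 3, size=(5, 30))
        codes[3] = codes[1]
        G = build_G_raw(GenotypeMatrix(codes, np.arange(1, 6)))
        np.testing.assert_allclose(G[1], G[3], atol=1e-12)
        assert G[1, 1] == pytest.approx(G[3, 3])

    def test_mean_diagonal_near_one_for_hwe_genotypes(self, rng):
        """VanRaden expectation: mean(diag G) ≈ 1 + mean F (here F = 0)."""
        p = rng.uniform(0.1, 0.9, size=2000)
        codes = rng.binomial(2, p, size=(200, 2000))
        G = build_G_raw(GenotypeMatrix(codes, np.arange(1, 201)))
        assert abs(np.diag(G).mean() - 1.0) < 0.05

    def test_observed_freq_centering_zeroes_column_sums(self, rng):
        codes = rng.integers(0, 3, size=(40, 60))
        gm = GenotypeMatrix(codes, np.arange(1, 41))
        np.testing.assert_allclose(gm.Z.sum(axis=0), 0.0, atol=1e-9)
        G = build_G_raw(gm)
        np.testing.assert_allclose(G @ np.ones(40), 0.0, atol=1e-8)

    def test_monomorphic_only_rejected(self):
        gm = GenotypeMatrix(np.full((3, 4), 2), [1, 2, 3])
        with pytest.raises(ValueError, match="monomorphic"):
            build_G_raw(gm)


class TestTuneAndBlend:
    def test_equal_means_give_zero_shift(self, rng):
        A22 = np.eye(4)
        G = np.eye(4).copy()
        gs, bt = tune_and_blend(G, A22, alpha=0.05)
        assert bt.c == 0.0 and bt.d == 1.0
        np.testing.assert_allclose(gs, 0.95 * G + 0.05 * A22)

    def test_alpha_zero_no_shift_returns_G(self):
        G = np.array([[1.0, 0.2], [0.2, 1.0]])
        A22 = np.full((2, 2), G.mean())  # same mean, so c = 0
        gs, bt = tune_and_blend(G, A22, alpha=0.0)
        np.testing.assert_allclose(gs, G, atol=1e-12)
        assert bt.c == 0.0 and bt.d == 1.0

    def test_mean_identity_on_simulated_data(self, rng):
        codes = rng.integers(0, 3, size=(30, 80))
        G = build_G_raw(GenotypeMatrix(codes, np.arange(1, 31)))
        ped = make_random_pedigree(60, rng)
        A22 = build_A22(ped, np.arange(21, 51), method="tabular")
        gs, bt = tune_and_blend(G, A22, alpha=0.05, clamp_negative_shift=False)
        lhs = gs.mean()
        rhs = 0.95 * (bt.c + bt.d * G.mean()) + 0.05 * A22.mean()
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_alpha_one_recovers_A22(self):
        A22 = np.array([[1.1, 0.3], [0.3, 1.0]])
        gs, _ = tune_and_blend(A22.copy(), A22, alpha=1.0)
        np.testing.assert_allclose(gs, A22, atol=1e-12)

    def test_negative_shift_clamped_by_default(self):
        G = np.eye(3) + 1.0          # mean well above A22's
        A22 = np.eye(3)
        _, bt = tune_and_blend(G, A22, alpha=0.05)
        assert bt.c == 0.0 and bt.d == 1.0
        _, bt2 = tune_and_blend(G, A22, alpha=0.05, clamp_negative_shift=False)
        assert bt2.c < 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            tune_and_blend(np.eye(3), np.eye(4))


def random_spd_gstar(n, rng, n_loci=None):
    codes = rng.integers(0, 3, size=(n, n_loci or 4 * n))
    G = build_G_raw(GenotypeMatrix(codes, np.arange(1, n + 1)))
    return G + 0.05 * np.eye(n) + 0.05


class TestApy:
    def test_full_core_equals_dense_inverse(self, rng):
        gs = random_spd_gstar(40, rng)
        apy = apy_inverse(gs, np.arange(40))
        np.testing.assert_allclose(apy, np.linalg.inv(gs), atol=1e-8)

    def test_single_core_identity(self):
        np.testing.assert_allclose(apy_inverse(np.eye(5), np.array([0])), np.eye(5),
                                   atol=1e-12)

    def test_random_core_recovers_solutions(self, rng):
        """APY G⁻¹ applied to G*v reproduces v and the implied GEBV
        correlate > 0.99 with the dense-inverse GEBV."""
        gs = random_spd_gstar(100, rng, n_loci=600)
        core = np.sort(rng.choice(100, size=80, replace=False))
        apy = apy_inverse(gs, core)
        u = rng.standard_normal(100)
        sol_apy = apy @ u
        sol_dense = np.linalg.inv(gs) @ u
        r = np.corrcoef(sol_apy, sol_dense)[0, 1]
        assert r > 0.99
        v = rng.standard_normal(100)
        back = apy @ (gs @ v)
        assert np.corrcoef(back, v)[0, 1] > 0.99

    def test_empty_core_rejected(self):
        with pytest.raises(ValueError):
            apy_inverse(np.eye(3), np.array([], dtype=int))


class TestHInverseDelta:
    def test_gstar_equal_a22_gives_zero(self, rng):
        A22 = random_spd_gstar(10, rng)
        inv = np.linalg.inv(A22)
        delta = build_H_inverse_delta(inv, inv)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_symmetry(self, rng):
        a = random_spd_gstar(8, rng)
        b = random_spd_gstar(8, rng)
        d = build_H_inverse_delta(np.linalg.inv(a), np.linalg.inv(b))
        np.testing.assert_allclose(d, d.T, atol=1e-12)

    def test_assembled_H_inverse_matches_textbook_H(self, rng):
        """A⁻¹ plus the genotyped-block delta inverts the explicit H."""
        ped = make_random_pedigree(50, rng)
        sire, dam = pedigree_arrays(ped)
        A = tabular_A(sire, dam)
        gen = np.sort(rng.choice(50, size=20, replace=False))
        non = np.setdiff1d(np.arange(50), gen)
        gs = random_spd_gstar(20, rng)
        A22 = A[np.ix_(gen, gen)]
        A22i = np.linalg.inv(A22)
        D = gs - A22
        H = A.copy()
        H[np.ix_(non, non)] += A[np.ix_(non, gen)] @ A22i @ D @ A22i @ A[np.ix_(gen, non)]
        H[np.ix_(non, gen)] += A[np.ix_(non, gen)] @ A22i @ D
        H[np.ix_(gen, non)] += D @ A22i @ A[np.ix_(gen, non)]
        H[np.ix_(gen, gen)] += D
        Hinv = np.linalg.inv(A)
        Hinv[np.ix_(gen, gen)] += build_H_inverse_delta(np.linalg.inv(gs), A22i)
        np.testing.assert_allclose(Hinv @ H, np.eye(50), atol=1e-6)


def test_lower_triangle_dump_roundtrip(tmp_path, rng):
    M = random_spd_gstar(5, rng)
    ids = np.array([3, 7, 9, 12, 15])
    path = tmp_path / "mat.txt"
    kinship.write_lower_triangle(path, M, ids)
    rows = np.loadtxt(path)
    assert rows.shape == (15, 3)
    assert rows[0, :2].tolist() == [3, 3]
    np.testing.assert_allclose(rows[-1, 2], M[4, 4], rtol=1e-9)
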