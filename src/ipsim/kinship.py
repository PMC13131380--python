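"""Pedigree and genomic relationship machinery.

Implements the relationship matrices used by single-step GBLUP:

* ``A``\\ :sup:`-1` from Henderson's rules with inbreeding coefficients from
  the Meuwissen-Luo algorithm;
* ``A22``, the pedigree relationships among genotyped animals;
* ``G``, the VanRaden (first method) genomic relationship matrix
  ``ZZ' / 2 Σ p(1-p)``;
* tuning and blending ``G* = (1-α)(11'c + dG) + αA22`` with
  ``c = mean(A22) - mean(G)`` and ``d = 1 - c/2``;
* the APY sparse inverse of ``G*``;
* the genotyped-block correction ``G*⁻¹ - A22⁻¹`` that, added onto
  ``A⁻¹``, yields ``H⁻¹``.

Pedigrees are pandas DataFrames with columns ``id, sire, dam`` (ids are
positive integers in birth order, 0 = unknown parent); internally 0-based
arrays with -1 for unknown are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from ._compat import njit

__all__ = [
    "GenotypeMatrix",
    "BlendTune",
    "pedigree_arrays",
    "inbreeding",
    "mendelian_variances",
    "build_A_inverse",
    "tabular_A",
    "build_A22",
    "build_G_raw",
    "tune_and_blend",
    "apy_inverse",
    "build_H_inverse_delta",
    "write_lower_triangle",
]


# ---------------------------------------------------------------------------
# pedigree utilities
# ---------------------------------------------------------------------------

def pedigree_arrays(pedigree: pd.DataFrame):
    """Validate a pedigree frame and return 0-based (sire, dam) arrays.

    Requires ids 1..n in order, parents listed before offspring, and no
    animal that is its own ancestor (implied by the ordering check).
    """
    ids = np.asarray(pedigree["id"], dtype=np.int64)
    n = ids.size
    if n == 0:
        raise ValueError("empty pedigree")
    if not np.array_equal(ids, np.arange(1, n + 1)):
        raise ValueError("pedigree ids must be dense 1..n in birth order")
    sire = np.asarray(pedigree["sire"], dtype=np.int64) - 1
    dam = np.asarray(pedigree["dam"], dtype=np.int64) - 1
    for p in (sire, dam):
        bad = p >= np.arange(n)
        if np.any(bad):
            raise ValueError(
                "parents must precede offspring (cyclic or self-ancestral pedigree)"
            )
        if np.any(p < -1):
            raise ValueError("parent codes must be 0 (unknown) or a prior id")
    return sire, dam


@njit(cache=True)
def _inbreeding_kernel(sire, dam, F, start):  # pragma: no cover - jitted
    n = sire.size
    L = np.zeros(n)
    for i in range(start, n):
        si = sire[i]
        di = dam[i]
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        # Trace the L-row of animal i (Meuwissen & Luo): a_ii = Σ L² d = 1 + F_i.
        L[i] = 1.0
        acc = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            sj = sire[j]
            dj = dam[j]
            if sj >= 0 and dj >= 0:
                dv = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0:
                dv = 0.75 - 0.25 * F[sj]
            elif dj >= 0:
                dv = 0.75 - 0.25 * F[dj]
            else:
                dv = 1.0
            acc += lj * lj * dv
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
            L[j] = 0.0
        F[i] = acc - 1.0
    return F


def inbreeding(sire: np.ndarray, dam: np.ndarray, F_init: np.ndarray | None = None,
               start: int = 0) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo tracing algorithm.

    ``F_init``/``start`` allow incremental extension of a growing pedigree:
    coefficients below ``start`` are taken as already computed.
    """
    sire = np.ascontiguousarray(sire, dtype=np.int64)
    dam = np.ascontiguousarray(dam, dtype=np.int64)
    F = np.zeros(sire.size)
    if F_init is not None:
        F[: len(F_init)] = F_init
    return _inbreeding_kernel(sire, dam, F, start)


def mendelian_variances(sire, dam, F) -> np.ndarray:
    """Within-family (Mendelian sampling) variance fractions d_i of A = TDT'."""
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    Fs = np.where(sire >= 0, F[np.maximum(sire, 0)], -1.0)
    Fd = np.where(dam >= 0, F[np.maximum(dam, 0)], -1.0)
    return 0.5 - 0.25 * (Fs + Fd)


def build_A_inverse(pedigree: pd.DataFrame, F: np.ndarray | None = None):
    """Sparse ``A``\\ :sup:`-1` by Henderson's rules with inbreeding.

    Returns ``(A_inverse_csr, F)``.
    """
    sire, dam = pedigree_arrays(pedigree)
    n = sire.size
    if F is None:
        F = inbreeding(sire, dam)
    b = 1.0 / mendelian_variances(sire, dam, F)
    i_idx = np.arange(n)
    rows = [i_idx]
    cols = [i_idx]
    vals = [b]
    for p in (sire, dam):
        known = p >= 0
        ii, pp, bb = i_idx[known], p[known], b[known]
        rows += [ii, pp, pp]
        cols += [pp, ii, pp]
        vals += [-0.5 * bb, -0.5 * bb, 0.25 * bb]
    both = (sire >= 0) & (dam >= 0)
    ii, ss, dd, bb = i_idx[both], sire[both], dam[both], b[both]
    rows += [ss, dd]
    cols += [dd, ss]
    vals += [0.25 * bb, 0.25 * bb]
    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return Ainv, F


def tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (O(n²) memory)."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def build_A22(pedigree: pd.DataFrame, genotyped_ids: np.ndarray,
              method: str = "auto", a_inverse=None, F=None,
              chunk: int = 1024) -> np.ndarray:
    """Pedigree relationships among the genotyped animals.

    ``method='tabular'`` builds the full dense A (small pedigrees);
    ``method='solve'`` extracts columns of ``A`` by solving with a sparse
    factorization of ``A``\\ :sup:`-1`, which scales to large pedigrees.
    """
    sire, dam = pedigree_arrays(pedigree)
    n = sire.size
    idx = np.asarray(genotyped_ids, dtype=np.int64) - 1
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("genotyped id not present in pedigree")
    if method == "auto":
        method = "tabular" if n <= 2000 else "solve"
    if method == "tabular":
        return tabular_A(sire, dam)[np.ix_(idx, idx)]
    if a_inverse is None:
        a_inverse, F = build_A_inverse(pedigree, F)
    lu = sp.linalg.splu(a_inverse.tocsc())
    out = np.empty((idx.size, idx.size))
    for lo in range(0, idx.size, chunk):
        sel = idx[lo:lo + chunk]
        rhs = np.zeros((n, sel.size))
        rhs[sel, np.arange(sel.size)] = 1.0
        out[:, lo:lo + sel.size] = lu.solve(rhs)[idx]
    return 0.5 * (out + out.T)


# ---------------------------------------------------------------------------
# genomic relationships
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Allele counts (0/1/2) for a set of animals with centering frequencies.

    ``allele_freqs`` default to the observed frequencies of this matrix;
    passing frequencies from another set (e.g. the training animals when
    centering validation candidates) keeps the centering consistent across
    sets. Monomorphic loci (p in {0, 1}) get zero columns in ``Z`` and
    contribute nothing to the scaling constant ``k``.
    """

    codes: np.ndarray
    animal_ids: np.ndarray
    allele_freqs: np.ndarray | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (animals x loci)")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 2):
            raise ValueError("genotype codes must be in {0, 1, 2}")
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        if self.animal_ids.size != self.codes.shape[0]:
            raise ValueError("animal_ids length must match rows of codes")
        if self.allele_freqs is None:
            self.allele_freqs = self.codes.mean(axis=0) / 2.0
        else:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if self.allele_freqs.size != self.codes.shape[1]:
                raise ValueError("allele_freqs length must match loci")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def polymorphic(self) -> np.ndarray:
        p = self.allele_freqs
        return (p > 0.0) & (p < 1.0)

    @property
    def k(self) -> float:
        """VanRaden scaling constant 2 Σ p(1-p) over polymorphic loci."""
        p = self.allele_freqs[self.polymorphic]
        return float(2.0 * np.sum(p * (1.0 - p)))

    @property
    def Z(self) -> np.ndarray:
        """Centered gene contents; monomorphic columns are zeroed."""
        Z = self.codes - 2.0 * self.allele_freqs
        Z[:, ~self.polymorphic] = 0.0
        return Z

    def subset(self, ids) -> "GenotypeMatrix":
        """Row subset by animal id, keeping the centering frequencies."""
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            rows = np.array([pos[a] for a in np.asarray(ids)], dtype=np.int64)
        except KeyError as e:
            raise ValueError(f"animal id {e} not in genotype matrix") from None
        return GenotypeMatrix(self.codes[rows], np.asarray(ids), self.allele_freqs)


@dataclass(frozen=True)
class BlendTune:
    """Blending weight and tuning constants used to form G*."""

    alpha: float = 0.05
    c: float = 0.0
    d: float = 1.0


def build_G_raw(genotypes: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix ``ZZ' / k``."""
    k = genotypes.k
    if k <= 0:
        raise ValueError("all loci monomorphic: k = 0")
    Z = genotypes.Z
    G = (Z @ Z.T) / k
    return 0.5 * (G + G.T)


def tune_and_blend(G_raw: np.ndarray, A22: np.ndarray, alpha: float = 0.05,
                   method: str = "mean", clamp_negative_shift: bool = True):
    """Tune G to the A22 base and blend: ``G* = (1-α)(11'c + dG) + αA22``.

    ``method='mean'`` (default) matches the overall means: ``c = mean(A22)
    - mean(G)``, ``d = 1 - c/2``. ``method='moments'`` solves the
    two-equation diagonal/off-diagonal system for (c, d) instead.

    The additive shift exists to lift a genomic matrix whose average
    relationship sits below the pedigree base. When gene contents are
    centered at base-population frequencies in a strongly drifted
    population, ``mean(G)`` can exceed ``mean(A22)``; a negative shift
    ``c·11'`` would then destroy positive definiteness, so by default the
    shift is only applied upward (``c = max(0, ·)``, giving ``c=0, d=1``
    in that regime). Returns ``(G_star, BlendTune)``.
    """
    G_raw = np.asarray(G_raw, float)
    A22 = np.asarray(A22, float)
    if G_raw.shape != A22.shape or G_raw.shape[0] != G_raw.shape[1]:
        raise ValueError("G and A22 must be square with matching dimensions")
    n = G_raw.shape[0]
    if method == "mean":
        c = float(A22.mean() - G_raw.mean())
        if clamp_negative_shift:
            c = max(0.0, c)
        d = 1.0 - c / 2.0
    elif method == "moments":
        # mean(diag) and mean(offdiag) of c + dG matched to A22.
        dg, da = np.diag(G_raw), np.diag(A22)
        og = (G_raw.sum() - dg.sum()) / max(n * n - n, 1)
        oa = (A22.sum() - da.sum()) / max(n * n - n, 1)
        mg, ma = dg.mean(), da.mean()
        denom = mg - og
        d = (ma - oa) / denom if denom != 0 else 1.0
        c = ma - d * mg
    else:
        raise ValueError(f"unknown tuning method {method!r}")
    G_star = (1.0 - alpha) * (c + d * G_raw) + alpha * A22
    return 0.5 * (G_star + G_star.T), BlendTune(alpha=alpha, c=c, d=d)


def _spd_inverse(M: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    c, low = sla.cho_factor(M, lower=True, check_finite=False)
    inv = sla.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


def apy_inverse(G_star: np.ndarray, core_idx: np.ndarray) -> np.ndarray:
    """Sparse-structured inverse of G* by the algorithm for proven and young.

    Only the core block is inverted directly; each noncore animal's
    breeding value is regressed on the core, with independent residuals.
    With all animals in the core the result equals the dense inverse.
    Returned in the original animal ordering (dense storage).
    """
    G_star = np.asarray(G_star, float)
    n = G_star.shape[0]
    core_idx = np.asarray(core_idx, dtype=np.int64)
    if core_idx.size == 0:
        raise ValueError("core must be nonempty")
    noncore = np.setdiff1d(np.arange(n), core_idx)
    Gcc = G_star[np.ix_(core_idx, core_idx)]
    try:
        Gcc_inv = _spd_inverse(Gcc)
    except sla.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular core block: {e}") from None
    out = np.zeros((n, n))
    if noncore.size == 0:
        out[np.ix_(core_idx, core_idx)] = Gcc_inv
        return out
    Gcn = G_star[np.ix_(core_idx, noncore)]
    X = Gcc_inv @ Gcn                               # core regressions P_cn
    m = np.diag(G_star)[noncore] - np.sum(Gcn * X, axis=0)
    if np.any(m <= 0):
        raise np.linalg.LinAlgError("nonpositive APY residual variance")
    minv = 1.0 / m
    out[np.ix_(core_idx, core_idx)] = Gcc_inv + (X * minv) @ X.T
    out[np.ix_(core_idx, noncore)] = -X * minv
    out[np.ix_(noncore, core_idx)] = (-X * minv).T
    out[np.ix_(noncore, noncore)] = np.diag(minv)
    return 0.5 * (out + out.T)


def build_H_inverse_delta(g_star_inverse: np.ndarray, a22_inverse: np.ndarray) -> np.ndarray:
    """Genotyped-block correction ``G*⁻¹ - A22⁻¹`` to add onto ``A⁻¹``."""
    g_star_inverse = np.asarray(g_star_inverse, float)
    a22_inverse = np.asarray(a22_inverse, float)
    if g_star_inverse.shape != a22_inverse.shape:
        raise ValueError("G*⁻¹ and A22⁻¹ dimensions differ")
    delta = g_star_inverse - a22_inverse
    return 0.5 * (delta + delta.T)


def write_lower_triangle(path, M: np.ndarray, ids: np.ndarray) -> None:
    """Dump a symmetric matrix as 'row_id col_id value' text, lower triangle."""
    ids = np.asarray(ids)
    with open(path, "w") as fh:
        for i in range(M.shape[0]):
            for j in range(i + 1):
                fh.write(f"{ids[i]} {ids[j]} {M[i, j]:.10g}\n")
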