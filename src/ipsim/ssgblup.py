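"""Single-step GBLUP: single-trait animal model with an overall mean.

The model is ``y = 1μ + u + e`` with ``u ~ N(0, H σ²a)`` and
``e ~ N(0, I σ²e)``, where ``H⁻¹ = A⁻¹ + [0, 0; 0, G*⁻¹ - A22⁻¹]`` combines
pedigree and genomic relationships. Henderson's mixed-model equations are

    [ n      1'W    ] [ μ ]   [ 1'y ]
    [ W1  W + λH⁻¹  ] [ u ] = [ Wy  ]

with ``λ = σ²e/σ²a`` and ``W`` the (diagonal) phenotype incidence. Animals
without records enter with zero incidence and are predicted through their
relationships. Variance components are taken as known.

Usage mirrors statsmodels: build a :class:`SingleStepGBLUP` from data, call
``fit()``, read estimates off the returned :class:`SSGBLUPResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import kinship
from .kinship import BlendTune, GenotypeMatrix, _spd_inverse

__all__ = ["SingleStepGBLUP", "SSGBLUPResults", "MmeSystem", "assemble_mme",
           "solve_mme", "run_benchmark", "run_reduced"]


@dataclass
class MmeSystem:
    """Assembled mixed-model equations.

    The coefficient matrix is kept as a sparse part (mean, incidence,
    ``λA⁻¹``) plus an optional dense genotyped-block correction, so the
    system supports both direct factorization and matrix-free iteration.
    Unknown order: ``[μ, u_1..u_n]`` following pedigree order.
    """

    sparse_part: sp.csr_matrix
    rhs: np.ndarray
    geno_idx: np.ndarray | None = None   # 0-based animal positions, offset by 1 in unknowns
    dense_block: np.ndarray | None = None  # λ * (G*⁻¹ - A22⁻¹)

    @property
    def n(self) -> int:
        return self.rhs.size

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.sparse_part @ x
        if self.dense_block is not None:
            sel = self.geno_idx + 1
            y[sel] += self.dense_block @ x[sel]
        return y

    def diagonal(self) -> np.ndarray:
        dg = np.asarray(self.sparse_part.diagonal()).copy()
        if self.dense_block is not None:
            dg[self.geno_idx + 1] += np.diag(self.dense_block)
        return dg

    def to_dense(self) -> np.ndarray:
        C = self.sparse_part.toarray()
        if self.dense_block is not None:
            sel = self.geno_idx + 1
            C[np.ix_(sel, sel)] += self.dense_block
        return C

    def residual_norm(self, x: np.ndarray) -> float:
        b = np.linalg.norm(self.rhs)
        return float(np.linalg.norm(self.matvec(x) - self.rhs) / (b if b > 0 else 1.0))


def assemble_mme(y: np.ndarray, has_record: np.ndarray, a_inverse: sp.spmatrix,
                 lam: float, geno_idx: np.ndarray | None = None,
                 h_delta: np.ndarray | None = None) -> MmeSystem:
    """Build the MME for ``y = 1μ + u + e``.

    ``y`` and ``has_record`` are aligned to pedigree order (length n,
    ``y`` ignored where ``has_record`` is False). ``h_delta`` is the
    genotyped-block correction ``G*⁻¹ - A22⁻¹`` over ``geno_idx``.
    """
    if lam <= 0:
        raise ValueError("variance ratio lambda must be positive")
    n = a_inverse.shape[0]
    w = np.asarray(has_record, dtype=float)
    n_rec = int(w.sum())
    if n_rec == 0:
        raise ValueError("no phenotypes")
    yy = np.where(has_record, np.asarray(y, float), 0.0)
    top = sp.hstack([sp.csr_matrix([[float(n_rec)]]), sp.csr_matrix(w[None, :])])
    left = sp.csr_matrix(w[:, None])
    uu = sp.diags(w) + lam * a_inverse
    S = sp.vstack([top, sp.hstack([left, uu])]).tocsr()
    rhs = np.concatenate([[yy.sum()], yy])
    dense = None if h_delta is None else lam * np.asarray(h_delta, float)
    return MmeSystem(S, rhs, None if geno_idx is None else np.asarray(geno_idx), dense)


def solve_mme(system: MmeSystem, method: str = "auto", tol: float = 1e-10,
              maxiter: int = 20000, dense_threshold: int = 4000):
    """Solve the MME; returns ``(x, converged, relative_residual)``.

    ``auto`` uses a sparse direct factorization when there is no dense
    genomic block, a dense factorization for small systems, and Jacobi
    preconditioned conjugate gradients otherwise.
    """
    n = system.n
    if method == "auto":
        if system.dense_block is None:
            method = "splu"
        elif n <= dense_threshold:
            method = "dense"
        else:
            method = "pcg"
    if method == "splu":
        if system.dense_block is not None:
            method = "dense" if n <= dense_threshold else "pcg"
    if method == "dense":
        x = sla.solve(system.to_dense(), system.rhs, assume_a="sym")
    elif method == "splu":
        x = spla.splu(system.sparse_part.tocsc()).solve(system.rhs)
    elif method == "pcg":
        dg = system.diagonal()
        dg = np.where(dg > 1e-12, dg, 1.0)
        M = spla.LinearOperator((n, n), matvec=lambda v: v / dg)
        A = spla.LinearOperator((n, n), matvec=system.matvec)
        x, info = spla.cg(A, system.rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
        if info != 0:
            res = system.residual_norm(x)
            return x, False, res
    else:
        raise ValueError(f"unknown solver method {method!r}")
    return x, True, system.residual_norm(x)


class SingleStepGBLUP:
    """Single-trait ssGBLUP animal model.

    Parameters
    ----------
    phenotypes : pandas.Series
        Records indexed by animal id; animals absent from the index carry
        no record but are still evaluated.
    pedigree : pandas.DataFrame
        Columns ``id, sire, dam`` (ids dense 1..n in birth order, 0 =
        unknown parent).
    genotypes : GenotypeMatrix, optional
        Gene contents of the genotyped animals. Omit for pedigree BLUP.
    sigma2_a, sigma2_e : float
        Known additive and residual variances; ``λ = σ²e/σ²a``.
    alpha : float
        Blending weight toward ``A22`` when forming ``G*``.
    tuning : str
        ``'mean'`` or ``'moments'``, see :func:`ipsim.kinship.tune_and_blend`.

    A ``precomputed`` dict may carry ``a_inverse`` (+ ``inbreeding``),
    ``a22`` and/or ``g_raw`` to avoid rebuilding shared pieces across runs.
    """

    def __init__(self, phenotypes: pd.Series, pedigree: pd.DataFrame,
                 genotypes: GenotypeMatrix | None = None,
                 sigma2_a: float = 0.25, sigma2_e: float = 0.75,
                 alpha: float = 0.05, tuning: str = "mean",
                 precomputed: dict | None = None):
        precomputed = precomputed or {}
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.sigma2_a = float(sigma2_a)
        self.sigma2_e = float(sigma2_e)
        self.alpha = float(alpha)
        n = len(pedigree)
        self.n_animals = n
        ids = np.asarray(pedigree["id"])
        ph_ids = np.asarray(phenotypes.index, dtype=np.int64)
        if ph_ids.size and (ph_ids.min() < 1 or ph_ids.max() > n):
            raise ValueError("phenotyped animal missing from pedigree")
        self.y = np.zeros(n)
        self.has_record = np.zeros(n, dtype=bool)
        self.y[ph_ids - 1] = np.asarray(phenotypes, float)
        self.has_record[ph_ids - 1] = True

        if "a_inverse" in precomputed:
            self.a_inverse = precomputed["a_inverse"]
            self.F = precomputed.get("inbreeding")
        else:
            self.a_inverse, self.F = kinship.build_A_inverse(pedigree)

        self.blend: BlendTune | None = None
        self.g_star_inverse: np.ndarray | None = None
        self.a22: np.ndarray | None = None
        self.h_delta: np.ndarray | None = None
        self.geno_idx: np.ndarray | None = None
        if genotypes is not None:
            gid = genotypes.animal_ids
            if gid.min() < 1 or gid.max() > n:
                raise ValueError("genotyped animal missing from pedigree")
            self.geno_idx = gid.astype(np.int64) - 1
            self.a22 = precomputed.get("a22")
            if self.a22 is None:
                self.a22 = kinship.build_A22(pedigree, gid, a_inverse=self.a_inverse,
                                             F=self.F)
            g_raw = precomputed.get("g_raw")
            if g_raw is None:
                g_raw = kinship.build_G_raw(genotypes)
            g_star, self.blend = kinship.tune_and_blend(g_raw, self.a22, alpha,
                                                        method=tuning)
            self.g_star = g_star
            self.g_star_inverse = _spd_inverse(g_star)
            a22_inv = _spd_inverse(self.a22)
            self.h_delta = kinship.build_H_inverse_delta(self.g_star_inverse, a22_inv)
        del ids

    @classmethod
    def from_population(cls, pop, genotypes=None, exclude_phenotype_generations=(),
                        **kwargs):
        """Build from a simulated :class:`~ipsim.popsim.Population`."""
        ped = pop.pedigree_frame()
        mask = ~np.isin(pop.generation, list(exclude_phenotype_generations))
        phen = pd.Series(pop.phenotype[mask], index=pop.id[mask])
        return cls(phen, ped, genotypes=genotypes, **kwargs)

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_a

    def fit(self, method: str = "auto", tol: float = 1e-10,
            maxiter: int = 20000) -> "SSGBLUPResults":
        system = assemble_mme(self.y, self.has_record, self.a_inverse, self.lam,
                              self.geno_idx, self.h_delta)
        x, converged, res = solve_mme(system, method=method, tol=tol, maxiter=maxiter)
        return SSGBLUPResults(self, x[0], x[1:], bool(converged), res)


@dataclass
class SSGBLUPResults:
    """Fitted ssGBLUP solutions.

    ``gebv`` is a pandas Series over all pedigree ids; use
    :meth:`gebv_for` to pull subsets (e.g. validation candidates) and
    :meth:`backsolve_snp_effects` to convert genotyped-animal GEBV into
    marker effects.
    """

    model: SingleStepGBLUP
    mu: float
    _u: np.ndarray
    converged: bool
    mme_residual_norm: float

    @property
    def gebv(self) -> pd.Series:
        return pd.Series(self._u, index=np.asarray(self.model.pedigree["id"]),
                         name="gebv")

    def gebv_for(self, ids) -> np.ndarray:
        return self._u[np.asarray(ids, dtype=np.int64) - 1]

    def backsolve_snp_effects(self):
        """Marker effects from the genotyped animals' GEBV (see
        :func:`ipsim.indirect.backsolve_snp_effects`)."""
        from .indirect import backsolve_snp_effects

        m = self.model
        if m.genotypes is None:
            raise ValueError("model has no genotypes to back-solve from")
        u_t = self.gebv_for(m.genotypes.animal_ids)
        return backsolve_snp_effects(u_t, m.genotypes.Z, m.g_star_inverse, m.blend,
                                     m.genotypes.k, freqs=m.genotypes.allele_freqs)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Single-step GBLUP (animal model, overall mean)",
            f"  animals: {m.n_animals}   records: {int(m.has_record.sum())}"
            f"   genotyped: {0 if m.geno_idx is None else m.geno_idx.size}",
            f"  sigma2_a: {m.sigma2_a:.4g}   sigma2_e: {m.sigma2_e:.4g}"
            f"   lambda: {m.lam:.4g}",
        ]
        if m.blend is not None:
            lines.append(
                f"  blending alpha: {m.blend.alpha:.3g}   tuning c: {m.blend.c:.4g}"
                f"   d: {m.blend.d:.4g}"
            )
        lines += [
            f"  mu_hat: {self.mu:.6g}",
            f"  converged: {self.converged}   relative residual: "
            f"{self.mme_residual_norm:.3e}",
            f"  gebv: mean {self._u.mean():.4g}  sd {self._u.std(ddof=1):.4g}",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"id": np.asarray(self.model.pedigree["id"]),
                           "effect": "animal", "solution": self._u})
        df = pd.concat([pd.DataFrame({"id": [0], "effect": ["mean"],
                                      "solution": [self.mu]}), df])
        df.to_csv(path, index=False)


def run_benchmark(pop, genotypes_all: GenotypeMatrix, validation_ids,
                  phenotypes: pd.Series | None = None, **kwargs) -> SSGBLUPResults:
    """Full evaluation including young candidates' genotypes (benchmark GEBV).

    Validation animals are unphenotyped by design: when ``phenotypes`` is
    omitted they are built from the population excluding the validation
    cohort; a supplied series carrying a validation record is a config
    violation and is rejected.
    """
    validation_ids = np.asarray(validation_ids, dtype=np.int64)
    ped = pop.pedigree_frame()
    if phenotypes is None:
        mask = ~np.isin(pop.id, validation_ids)
        phenotypes = pd.Series(pop.phenotype[mask], index=pop.id[mask])
    elif np.intersect1d(np.asarray(phenotypes.index), validation_ids).size:
        raise ValueError("validation animals must not carry phenotypes")
    model = SingleStepGBLUP(phenotypes, ped, genotypes=genotypes_all, **kwargs)
    return model.fit()


def run_reduced(pop, genotypes_training: GenotypeMatrix, validation_ids,
                **kwargs) -> SSGBLUPResults:
    """Reduced evaluation: candidate genotypes (and phenotypes) removed."""
    validation_ids = np.asarray(validation_ids, dtype=np.int64)
    if genotypes_training.n_animals == 0:
        raise ValueError("empty training set")
    if np.intersect1d(genotypes_training.animal_ids, validation_ids).size:
        raise ValueError("training genotypes must exclude validation animals")
    ped = pop.pedigree_frame()
    mask = ~np.isin(pop.id, validation_ids)
    phen = pd.Series(pop.phenotype[mask], index=pop.id[mask])
    model = SingleStepGBLUP(phen, ped, genotypes=genotypes_training, **kwargs)
    return model.fit()
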