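"""Indirect predictions: SNP effect back-solving and genotyping errors.

SNP effects are recovered from the GEBV of the genotyped training animals
by the linear back-solve

    â = (1 - α) · d · (1 / 2Σp(1-p)) · Z't · (G*tt)⁻¹ · ût,

where α, c, d are the blending/tuning constants used when forming G*.
Indirect predictions for young candidates are then ``IP = Zv â`` with the
candidate gene contents centered by the *training* allele frequencies.

Genotyping errors are simulated by substitution: a chosen fraction of each
animal's loci is replaced by one of the two alternative codes (0→1/2,
1→0/2, 2→0/1), each with probability one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinship import BlendTune, GenotypeMatrix

__all__ = ["SnpEffects", "ErrorSpec", "IpResult", "backsolve_snp_effects",
           "compute_ip", "inject_errors", "run_scenarios", "scenario_label"]


@dataclass
class SnpEffects:
    """Back-solved additive marker effects with their centering context."""

    a_hat: np.ndarray
    alpha: float
    d: float
    k: float
    freqs: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.a_hat)):
            raise ValueError("non-finite SNP effects")

    @property
    def n_loci(self) -> int:
        return self.a_hat.size

    def to_frame(self, chromosomes=None, positions=None):
        import pandas as pd

        n = self.n_loci
        return pd.DataFrame({
            "locus_index": np.arange(n),
            "chromosome": chromosomes if chromosomes is not None else np.zeros(n, int),
            "position": positions if positions is not None else np.zeros(n),
            "effect": self.a_hat,
        })


@dataclass(frozen=True)
class ErrorSpec:
    """Substitution-error scenario for one genotype set."""

    rate: float
    seed: int = 0
    target: str = "validation"  # 'validation' | 'training'
    shared_loci: bool = False

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")
        if self.target not in ("validation", "training"):
            raise ValueError("target must be 'validation' or 'training'")


@dataclass
class IpResult:
    """Per-candidate indirect predictions for one scenario."""

    ip: np.ndarray
    scenario: str
    animal_ids: np.ndarray | None = None


def scenario_label(rate: float) -> str:
    return "correct" if rate == 0 else f"E{round(rate * 100):02d}"


def backsolve_snp_effects(u_hat_t: np.ndarray, Z_t: np.ndarray,
                          g_star_inverse: np.ndarray, blend: BlendTune,
                          k: float, freqs: np.ndarray | None = None) -> SnpEffects:
    """â = (1-α)·d·(1/k)·Z't·G*⁻¹·ût."""
    u_hat_t = np.asarray(u_hat_t, float)
    Z_t = np.asarray(Z_t, float)
    if k <= 0:
        raise ValueError("scaling constant k must be positive")
    if Z_t.shape[0] != u_hat_t.size or g_star_inverse.shape[0] != u_hat_t.size:
        raise ValueError("dimension mismatch between u_hat, Z and G*")
    w = g_star_inverse @ u_hat_t
    a = (1.0 - blend.alpha) * blend.d / k * (Z_t.T @ w)
    if freqs is None:
        freqs = np.full(Z_t.shape[1], np.nan)
    return SnpEffects(a_hat=a, alpha=blend.alpha, d=blend.d, k=k,
                      freqs=np.asarray(freqs, float))


def compute_ip(codes_or_Z, effects: SnpEffects, centered: bool = False,
               animal_ids=None, scenario: str = "correct") -> IpResult:
    """IP = Zv·â, centering raw candidate codes by the training frequencies."""
    X = np.asarray(codes_or_Z, float)
    if X.shape[1] != effects.n_loci:
        raise ValueError("locus count mismatch between genotypes and effects")
    if not centered:
        X = X - 2.0 * effects.freqs
    return IpResult(ip=X @ effects.a_hat, scenario=scenario,
                    animal_ids=None if animal_ids is None else np.asarray(animal_ids))


def inject_errors(codes: np.ndarray, spec: ErrorSpec,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Substitute ``round(rate · n_loci)`` genotypes per animal.

    By default each animal gets its own uniformly random locus subset
    (random genotyping error); with ``shared_loci`` one subset is drawn
    once and applied to every animal (platform/imputation artifact).
    Every substituted code differs from its original: the replacement is
    one of the two alternative codes with probability 1/2 each.
    """
    codes = np.asarray(codes)
    if codes.size and (codes.min() < 0 or codes.max() > 2):
        raise ValueError("genotype codes must be in {0, 1, 2}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_animals, n_loci = codes.shape
    n_err = int(round(spec.rate * n_loci))
    out = codes.copy()
    if n_err == 0 or n_animals == 0:
        return out
    if spec.shared_loci:
        loci = rng.choice(n_loci, size=n_err, replace=False)
        rows = np.repeat(np.arange(n_animals), n_err)
        cols = np.tile(loci, n_animals)
    else:
        # independent subset per animal: first n_err of a random permutation
        perm = rng.random((n_animals, n_loci)).argpartition(n_err - 1, axis=1)
        cols = perm[:, :n_err].reshape(-1)
        rows = np.repeat(np.arange(n_animals), n_err)
    shift = rng.integers(1, 3, size=rows.size)  # +1 or +2 mod 3: never the original
    out[rows, cols] = (out[rows, cols] + shift) % 3
    return out


def run_scenarios(codes_validation: np.ndarray, effects: SnpEffects,
                  rates, rng: np.random.Generator,
                  animal_ids=None, shared_loci: bool = False) -> dict:
    """IP for the error-free genotypes and each error rate.

    Raw candidate codes are perturbed first and centered afterwards with
    the training frequencies held in ``effects`` — errors never leak into
    the centering constants. Returns ``{label: IpResult}`` ordered
    correct-first then ascending rate.
    """
    out = {"correct": compute_ip(codes_validation, effects, animal_ids=animal_ids,
                                 scenario="correct")}
    for rate in sorted(r for r in rates if r > 0):
        label = scenario_label(rate)
        spec = ErrorSpec(rate=rate, shared_loci=shared_loci)
        perturbed = inject_errors(codes_validation, spec, rng)
        out[label] = compute_ip(perturbed, effects, animal_ids=animal_ids,
                                scenario=label)
    return out
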