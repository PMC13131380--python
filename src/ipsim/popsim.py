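"""Forward-in-time breeding-program simulator.

Emulates a livestock genomic-selection design: a long bottlenecked
historical population (random union of gametes, no selection) establishes
mutation-drift structure and linkage disequilibrium; a short expansion
phase grows the population; a current population then undergoes
truncation selection on estimated breeding values (EBV) with assortative
mating, overlapping parents and fixed sire/dam replacement rates. The
trait is additive: a finite set of QTL plus a residual polygenic term,
with phenotypes recorded on both sexes.

Generations are birth cohorts. Later cohorts form the training
(phenotyped + genotyped) and validation (genotyped only) sets of the
single-step evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kinship
from .genome import GenomeMap, meiose, mutate_gametes

__all__ = [
    "TraitModel",
    "SimConfig",
    "HaplotypePool",
    "Population",
    "simulate_historical",
    "expand_and_found",
    "assign_qtl_effects",
    "simulate_selection",
    "simulate_population",
]

MALE, FEMALE = 0, 1


@dataclass(frozen=True)
class TraitModel:
    """Additive trait: h² split into QTL-explained and residual polygenic parts.

    ``sigma2_p`` is the phenotypic variance (default 1, so that with
    h² = 0.25 the additive SD is 0.5). ``qtl_effects`` are allele
    substitution effects, ``None`` until assigned and scaled against the
    founder allele frequencies.
    """

    h2: float = 0.25
    rpg_fraction: float = 0.05
    sigma2_p: float = 1.0
    qtl_effects: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if not 0.0 <= self.rpg_fraction <= self.h2:
            raise ValueError("rpg_fraction must satisfy 0 <= rpg <= h2")
        if self.sigma2_p <= 0:
            raise ValueError("sigma2_p must be positive")

    @property
    def sigma2_a(self) -> float:
        """Total additive variance h²·σ²p."""
        return self.h2 * self.sigma2_p

    @property
    def sigma2_qtl(self) -> float:
        """Marker-explained additive variance (h² − rpg)·σ²p."""
        return (self.h2 - self.rpg_fraction) * self.sigma2_p

    @property
    def sigma2_pg(self) -> float:
        """Residual polygenic variance rpg·σ²p."""
        return self.rpg_fraction * self.sigma2_p

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.h2) * self.sigma2_p


@dataclass(frozen=True)
class SimConfig:
    """Structural parameters of the simulated breeding program.

    The full-scale defaults follow a dairy-cattle-like design: two
    historical bottlenecks (1,000→200 over 1,020 generations, then
    200→100 over 1,000) giving Ne ≈ 100, eight expansion generations,
    then 15 generations of EBV selection with 25 sires and 2,500 dams,
    60%/20% sire/dam replacement and 30% growth of the breeding females
    (capped at ``max_dams``; uncapped compounding is inconsistent with
    near-stationary cohort sizes).
    """

    # historical phase: (start_size, end_size, n_generations) per bottleneck
    historical_schedule: tuple = ((1000, 200, 1020), (200, 100, 1000))
    expansion_generations: int = 8
    n_sires: int = 25
    n_dams: int = 2500
    max_dams: int | None = 2500
    n_generations: int = 15
    growth_rate: float = 0.30
    sire_replacement: float = 0.60
    dam_replacement: float = 0.20
    litter_size: int = 5
    training_generations: tuple = (11, 12, 13, 14)
    validation_generation: int = 15
    n_replicates: int = 5
    seed: int = 0
    selection_on: str = "blup"  # 'blup' | 'phenotype' | 'random'
    # genome
    n_chromosomes: int = 29
    n_snps: int = 70000
    n_qtl: int = 1000
    total_cM: float = 2333.0
    mutation_rate: float = 1e-4
    pool_multiplier: float = 8.0
    maf_min: float = 0.05
    founder_freq: float = 0.5

    def scaled(self, scale_factor: float) -> "SimConfig":
        """Proportionally shrink animal counts, marker counts and the
        historical phase while preserving the design's ratios."""
        if scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        f = scale_factor

        def c(x, lo=1):
            return max(lo, int(round(x * f)))

        hist = tuple((c(a, 4), c(b, 4), c(g, 2)) for a, b, g in self.historical_schedule)
        return replace(
            self,
            historical_schedule=hist,
            n_sires=c(self.n_sires, 2),
            n_dams=c(self.n_dams, 2),
            max_dams=None if self.max_dams is None else c(self.max_dams, 2),
            n_snps=c(self.n_snps, 10),
            n_qtl=c(self.n_qtl, 2),
        )

    def dam_schedule(self) -> list:
        """Planned number of breeding dams for generations 1..n_generations."""
        out, d = [], self.n_dams
        for _ in range(self.n_generations):
            out.append(d)
            d = int(math.floor(d * (1.0 + self.growth_rate)))
            if self.max_dams is not None:
                d = min(d, self.max_dams)
        return out

    def cohort_sizes(self) -> list:
        """Planned offspring per generation 1..n_generations."""
        return [d * self.litter_size for d in self.dam_schedule()]


@dataclass
class HaplotypePool:
    """Final-generation haplotypes of the historical phase."""

    genome: GenomeMap
    haplotypes: np.ndarray  # (2N, n_loci) uint8

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


class Population:
    """Pedigreed population with haplotypes, true and estimated breeding values.

    Arrays are aligned: element ``i`` describes animal with id ``i + 1``.
    Haplotypes of animal ``i`` are rows ``2i`` (paternal) and ``2i + 1``
    (maternal). Sex is 0 = male, 1 = female; parent id 0 = unknown.
    """

    def __init__(self, genome: GenomeMap, trait: TraitModel):
        self.genome = genome
        self.trait = trait
        n0 = 0
        self.id = np.zeros(n0, dtype=np.int64)
        self.sire = np.zeros(n0, dtype=np.int64)
        self.dam = np.zeros(n0, dtype=np.int64)
        self.sex = np.zeros(n0, dtype=np.int8)
        self.generation = np.zeros(n0, dtype=np.int64)
        self.tbv = np.zeros(n0)
        self.poly = np.zeros(n0)
        self.phenotype = np.zeros(n0)
        self.ebv = np.zeros(n0)
        self.inbreeding = np.zeros(n0)
        self.haplotypes = np.zeros((0, genome.n_loci), dtype=np.uint8)
        self.breeding_log: list = []

    # -- bookkeeping ----------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.id.size

    def append(self, sire: np.ndarray, dam: np.ndarray, sex: np.ndarray,
               generation: int, haplotypes: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """Add a cohort; computes inbreeding, TBV, polygenic term and phenotype.

        ``sire``/``dam`` are animal ids (0 = unknown); ``haplotypes`` has
        two rows per new animal. Returns the new ids.
        """
        m = sire.size
        start = self.n_animals
        new_ids = np.arange(start + 1, start + m + 1, dtype=np.int64)
        self.id = np.concatenate([self.id, new_ids])
        self.sire = np.concatenate([self.sire, sire.astype(np.int64)])
        self.dam = np.concatenate([self.dam, dam.astype(np.int64)])
        self.sex = np.concatenate([self.sex, sex.astype(np.int8)])
        self.generation = np.concatenate(
            [self.generation, np.full(m, generation, dtype=np.int64)]
        )
        self.haplotypes = np.concatenate([self.haplotypes, haplotypes.astype(np.uint8)])
        self.inbreeding = kinship.inbreeding(self.sire - 1, self.dam - 1,
                                             F_init=self.inbreeding, start=start)
        t = self.trait
        codes_qtl = (haplotypes[0::2] + haplotypes[1::2]).astype(float)[:, self.genome.qtl_mask]
        effects = t.qtl_effects if t.qtl_effects is not None else np.zeros(self.genome.n_qtl)
        tbv_qtl = codes_qtl @ effects
        known = (sire > 0) & (dam > 0)
        poly = np.empty(m)
        poly[~known] = rng.normal(0.0, math.sqrt(t.sigma2_pg), size=int((~known).sum()))
        if known.any():
            ps = self.poly[sire[known] - 1]
            pd_ = self.poly[dam[known] - 1]
            fbar = 0.5 * (self.inbreeding[sire[known] - 1] + self.inbreeding[dam[known] - 1])
            ms_var = 0.5 * t.sigma2_pg * (1.0 - fbar)
            poly[known] = 0.5 * (ps + pd_) + rng.normal(size=int(known.sum())) * np.sqrt(ms_var)
        tbv = tbv_qtl + poly
        phen = tbv + rng.normal(0.0, math.sqrt(t.sigma2_e), size=m)
        self.poly = np.concatenate([self.poly, poly])
        self.tbv = np.concatenate([self.tbv, tbv])
        self.phenotype = np.concatenate([self.phenotype, phen])
        self.ebv = np.concatenate([self.ebv, np.full(m, np.nan)])
        return new_ids

    def genotypes(self, ids=None) -> np.ndarray:
        """Allele counts (0/1/2): sum of the two inherited gametes."""
        if ids is None:
            rows = np.arange(self.n_animals)
        else:
            rows = np.asarray(ids, dtype=np.int64) - 1
        return (self.haplotypes[2 * rows] + self.haplotypes[2 * rows + 1]).astype(np.int8)

    def ids_of_generation(self, gens) -> np.ndarray:
        gens = np.atleast_1d(gens)
        return self.id[np.isin(self.generation, gens)]

    def genotype_matrix(self, ids, allele_freqs=None) -> kinship.GenotypeMatrix:
        return kinship.GenotypeMatrix(self.genotypes(ids), np.asarray(ids),
                                      allele_freqs)

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.id, "sire": self.sire, "dam": self.dam,
            "sex": np.where(self.sex == MALE, "M", "F"),
            "generation": self.generation,
        })


# ---------------------------------------------------------------------------
# historical phase
# ---------------------------------------------------------------------------

def _random_union_generation(haps, sexes, n_next, genome, rng):
    """One generation of random union of gametes with an equal sex ratio."""
    males = np.flatnonzero(sexes == MALE)
    females = np.flatnonzero(sexes == FEMALE)
    if males.size == 0 or females.size == 0:
        raise ValueError("historical generation lost one sex entirely")
    sires = males[rng.integers(0, males.size, size=n_next)]
    dams = females[rng.integers(0, females.size, size=n_next)]
    pat = mutate_gametes(meiose(haps, sires, genome, rng), genome.mutation_rate, rng)
    mat = mutate_gametes(meiose(haps, dams, genome, rng), genome.mutation_rate, rng)
    out = np.empty((2 * n_next, genome.n_loci), dtype=np.uint8)
    out[0::2] = pat
    out[1::2] = mat
    new_sex = np.full(n_next, FEMALE, dtype=np.int8)
    new_sex[: n_next // 2] = MALE
    return out, new_sex


def _phase_sizes(start: int, end: int, n_gens: int) -> np.ndarray:
    """Linearly interpolated population sizes across a bottleneck phase."""
    return np.round(np.linspace(start, end, n_gens + 1)).astype(int)[1:]


def simulate_historical(config: SimConfig, rng: np.random.Generator,
                        genome: GenomeMap | None = None,
                        initial_haplotypes: np.ndarray | None = None) -> HaplotypePool:
    """Bottlenecked random-mating history; returns the final haplotype pool.

    When ``genome`` is not supplied, a locus pool of
    ``pool_multiplier * (n_snps + n_qtl)`` candidate positions is
    simulated and, at the end, the configured numbers of SNPs and QTL are
    drawn from loci still segregating with minor allele frequency at
    least ``maf_min`` (relaxed to any segregating locus if needed), so
    fixed positions are discarded exactly as a genotyping panel would.
    """
    for ns, ne, ng in config.historical_schedule:
        if min(ns, ne) < 2 or ng < 1:
            raise ValueError("degenerate historical schedule")
    select = genome is None
    if select:
        n_pool = int(math.ceil((config.n_snps + config.n_qtl) * config.pool_multiplier))
        genome = GenomeMap.random(n_pool, 0, rng, config.n_chromosomes,
                                  config.total_cM, config.mutation_rate)
    n0 = config.historical_schedule[0][0]
    if initial_haplotypes is not None:
        haps = np.asarray(initial_haplotypes, dtype=np.uint8)
        n0 = haps.shape[0] // 2
    else:
        haps = (rng.random((2 * n0, genome.n_loci)) < config.founder_freq).astype(np.uint8)
    sexes = np.full(n0, FEMALE, dtype=np.int8)
    sexes[: n0 // 2] = MALE
    for ns, ne, ng in config.historical_schedule:
        for n_next in _phase_sizes(ns, ne, ng):
            haps, sexes = _random_union_generation(haps, sexes, n_next, genome, rng)
    if select:
        genome, haps = _select_panel(genome, haps, config, rng)
    return HaplotypePool(genome=genome, haplotypes=haps)


def _select_panel(pool_genome, haps, config, rng):
    """Draw the SNP panel and QTL positions from segregating pool loci."""
    p = haps.mean(axis=0)
    maf = np.minimum(p, 1.0 - p)
    lengths = pool_genome.chrom_length_cM
    from .genome import _apportion

    n_chrom = pool_genome.n_chromosomes
    off = pool_genome.offsets
    eligible = []
    for c in range(n_chrom):
        local_maf = maf[off[c]:off[c + 1]]
        el = np.flatnonzero(local_maf >= config.maf_min)
        if el.size == 0:
            el = np.flatnonzero(local_maf > 0.0)
        eligible.append(el)
    capacity = np.array([e.size for e in eligible])
    n_total = config.n_snps + config.n_qtl
    if capacity.sum() < n_total:
        raise ValueError(
            "insufficient segregating loci after the historical phase; "
            "increase pool_multiplier or soften the bottlenecks"
        )
    # length-proportional apportionment, reallocating where drift fixed a
    # chromosome below its quota (per-chromosome counts vary, as on real panels)
    alloc = np.minimum(_apportion(n_total, lengths), capacity)
    while alloc.sum() < n_total:
        room = capacity - alloc
        extra = _apportion(n_total - alloc.sum(), np.where(room > 0, lengths, 0.0))
        alloc = np.minimum(alloc + extra, capacity)
    qtl_alloc = np.minimum(_apportion(config.n_qtl, lengths), alloc)
    while qtl_alloc.sum() < config.n_qtl:
        room = alloc - qtl_alloc
        extra = _apportion(config.n_qtl - qtl_alloc.sum(),
                           np.where(room > 0, lengths, 0.0))
        qtl_alloc = np.minimum(qtl_alloc + extra, alloc)
    keep = np.zeros(pool_genome.n_loci, dtype=bool)
    qtl_flags = []
    for c in range(n_chrom):
        chosen = np.sort(rng.choice(eligible[c], size=alloc[c], replace=False))
        keep[off[c] + chosen] = True
        q = np.zeros(alloc[c], dtype=bool)
        if qtl_alloc[c]:
            q[rng.choice(alloc[c], size=qtl_alloc[c], replace=False)] = True
        qtl_flags.append(q)
    qtl_flags = np.concatenate(qtl_flags)
    return pool_genome.subset(keep, qtl_flags), np.ascontiguousarray(haps[:, keep])


# ---------------------------------------------------------------------------
# expansion and founding
# ---------------------------------------------------------------------------

def expand_and_found(config: SimConfig, pool: HaplotypePool, trait: TraitModel,
                     rng: np.random.Generator) -> Population:
    """Random-mating expansion, then random draw of the current founders.

    The number of females grows exponentially across the expansion
    generations at the rate needed to supply the requested breeding dams
    (with a 15% margin); males track the female count. Founders
    (``n_sires`` males, ``n_dams`` females) are drawn without
    replacement. If the trait has no QTL effects yet they are assigned
    and scaled against the founder allele frequencies.
    """
    haps = pool.haplotypes
    genome = pool.genome
    n = pool.n_individuals
    if n < 2:
        raise ValueError("historical pool is empty or has a single individual")
    sexes = np.full(n, FEMALE, dtype=np.int8)
    sexes[rng.permutation(n)[: n // 2]] = MALE
    f0 = int((sexes == FEMALE).sum())
    target_f = max(int(math.ceil(1.15 * config.n_dams)), f0)
    G = config.expansion_generations
    rate = (target_f / f0) ** (1.0 / G) if G > 0 else 1.0
    for g in range(1, G + 1):
        n_f = max(2, int(round(f0 * rate**g)))
        n_next = 2 * n_f
        haps, sexes = _random_union_generation(haps, sexes, n_next, genome, rng)
    males = np.flatnonzero(sexes == MALE)
    females = np.flatnonzero(sexes == FEMALE)
    if males.size < config.n_sires or females.size < config.n_dams:
        raise ValueError("expanded pool too small to supply the requested founders")
    chosen_m = rng.choice(males, size=config.n_sires, replace=False)
    chosen_f = rng.choice(females, size=config.n_dams, replace=False)
    chosen = np.concatenate([chosen_m, chosen_f])
    rows = np.empty(2 * chosen.size, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    founder_haps = haps[rows]
    founder_sex = np.concatenate([
        np.full(config.n_sires, MALE, dtype=np.int8),
        np.full(config.n_dams, FEMALE, dtype=np.int8),
    ])
    if trait.qtl_effects is None:
        codes = (founder_haps[0::2] + founder_haps[1::2]).astype(float)
        trait = assign_qtl_effects(trait, codes[:, genome.qtl_mask], rng)
    popn = Population(genome, trait)
    zero = np.zeros(chosen.size, dtype=np.int64)
    popn.append(zero, zero, founder_sex, 0, founder_haps, rng)
    return popn


def assign_qtl_effects(trait: TraitModel, founder_qtl_codes: np.ndarray,
                       rng: np.random.Generator) -> TraitModel:
    """Draw (or re-use) symmetric raw effects and scale the QTL variance.

    Effects are rescaled so the realized founder QTL variance — the
    population variance of ``codes @ a`` among the founders, which
    includes linkage-disequilibrium covariances — equals
    ``(h² - rpg)·σ²p``. (Scaling by the Hardy-Weinberg/linkage-equilibrium
    sum ``Σ 2p(1-p)a²`` instead leaves the realized variance systematically
    short in bottlenecked founders.) Monomorphic QTL get zero effect and
    rescaling already-scaled effects is a fixed point. For a single QTL in
    Hardy-Weinberg proportions the result is the closed form
    ``|a| = sqrt(target / 2p(1-p))``.
    """
    codes = np.asarray(founder_qtl_codes, float)
    if codes.ndim != 2:
        raise ValueError("founder_qtl_codes must be animals x QTL")
    p = codes.mean(axis=0) / 2.0
    seg = (p > 0.0) & (p < 1.0)
    if not seg.any():
        raise ValueError("all QTL are monomorphic in the founders")
    raw = (np.array(trait.qtl_effects, float) if trait.qtl_effects is not None
           else rng.standard_normal(p.size))
    raw = raw.copy()
    raw[~seg] = 0.0
    target = trait.sigma2_qtl
    if target == 0.0:
        return replace(trait, qtl_effects=np.zeros(p.size))
    denom = float(np.var(codes @ raw))  # population (ddof=0) variance
    if denom <= 0.0:
        raise ValueError("raw effects carry no variance at segregating QTL")
    return replace(trait, qtl_effects=raw * math.sqrt(target / denom))


# ---------------------------------------------------------------------------
# selection phase
# ---------------------------------------------------------------------------

def _refit_ebv(popn: Population, config: SimConfig, rng: np.random.Generator) -> None:
    """Within-simulation EBV on all phenotypes to date.

    'blup' refits a pedigree animal model (true variance ratio) each
    generation; 'phenotype' uses the raw record; 'random' draws noise
    (zero selection intensity control).
    """
    if config.selection_on == "phenotype":
        popn.ebv = popn.phenotype.copy()
        return
    if config.selection_on == "random":
        popn.ebv = rng.standard_normal(popn.n_animals)
        return
    from .ssgblup import SingleStepGBLUP

    t = popn.trait
    a_inv, _ = kinship.build_A_inverse(popn.pedigree_frame(), F=popn.inbreeding)
    phen = pd.Series(popn.phenotype, index=popn.id)
    model = SingleStepGBLUP(phen, popn.pedigree_frame(), None,
                            sigma2_a=t.sigma2_a, sigma2_e=t.sigma2_e,
                            precomputed={"a_inverse": a_inv,
                                         "inbreeding": popn.inbreeding})
    popn.ebv = model.fit(method="splu")._u


def _select_top(candidates: np.ndarray, ebv: np.ndarray, k: int) -> np.ndarray:
    """ids of the k highest-EBV candidates (stable by id on ties)."""
    if k == 0:
        return candidates[:0]
    if candidates.size < k:
        raise ValueError("insufficient candidates to meet the replacement quota")
    order = np.lexsort((candidates, -ebv[candidates - 1]))
    return candidates[order[:k]]


def simulate_selection(config: SimConfig, popn: Population,
                       rng: np.random.Generator) -> Population:
    """Run the selection generations (1..n_generations) in place.

    Each generation: dams are ranked on EBV and split into contiguous
    rank blocks assigned to EBV-ranked sires (assortative mating); each
    dam leaves ``litter_size`` offspring; offspring are phenotyped and
    EBV refit; the lowest-EBV parents are culled at the replacement rates
    and the highest-EBV new candidates recruited, with the dam herd
    growing by ``growth_rate`` per generation up to ``max_dams``.
    """
    _refit_ebv(popn, config, rng)
    founders = popn.ids_of_generation(0)
    sires = founders[popn.sex[founders - 1] == MALE]
    dams = founders[popn.sex[founders - 1] == FEMALE]
    if sires.size != config.n_sires or dams.size != config.n_dams:
        raise ValueError("founder population does not match the configured sizes")
    popn.breeding_log = [{"generation": 0, "sires": sires.copy(), "dams": dams.copy()}]
    n_dams_now = dams.size
    for gen in range(1, config.n_generations + 1):
        # assortative mating: rank blocks of dams to ranked sires
        s_sorted = _select_top(sires, popn.ebv, sires.size)
        d_sorted = _select_top(dams, popn.ebv, dams.size)
        blocks = np.array_split(d_sorted, s_sorted.size)
        mate_sire = np.concatenate([
            np.full(b.size, s, dtype=np.int64) for s, b in zip(s_sorted, blocks)
        ])
        off_sire = np.repeat(mate_sire, config.litter_size)
        off_dam = np.repeat(d_sorted, config.litter_size)
        m = off_sire.size
        pat = mutate_gametes(meiose(popn.haplotypes, off_sire - 1, popn.genome, rng),
                             popn.genome.mutation_rate, rng)
        mat = mutate_gametes(meiose(popn.haplotypes, off_dam - 1, popn.genome, rng),
                             popn.genome.mutation_rate, rng)
        haps = np.empty((2 * m, popn.genome.n_loci), dtype=np.uint8)
        haps[0::2] = pat
        haps[1::2] = mat
        sex = rng.integers(0, 2, size=m).astype(np.int8)
        new_ids = popn.append(off_sire, off_dam, sex, gen, haps, rng)
        _refit_ebv(popn, config, rng)
        # replacement: cull lowest-EBV parents, recruit highest-EBV candidates
        cand_m = new_ids[popn.sex[new_ids - 1] == MALE]
        cand_f = new_ids[popn.sex[new_ids - 1] == FEMALE]
        n_repl_s = int(round(config.sire_replacement * config.n_sires))
        keep_s = _select_top(sires, popn.ebv, config.n_sires - n_repl_s)
        new_s = _select_top(cand_m, popn.ebv, n_repl_s)
        sires = np.concatenate([keep_s, new_s])
        n_dams_next = int(math.floor(n_dams_now * (1.0 + config.growth_rate)))
        if config.max_dams is not None:
            n_dams_next = min(n_dams_next, config.max_dams)
        n_cull_d = int(round(config.dam_replacement * n_dams_now))
        n_keep_d = min(n_dams_now - n_cull_d, n_dams_next)
        keep_d = _select_top(dams, popn.ebv, n_keep_d)
        new_d = _select_top(cand_f, popn.ebv, n_dams_next - n_keep_d)
        dams = np.concatenate([keep_d, new_d])
        n_dams_now = dams.size
        popn.breeding_log.append(
            {"generation": gen, "sires": sires.copy(), "dams": dams.copy()}
        )
    return popn


def simulate_population(config: SimConfig, trait: TraitModel, seed: int) -> Population:
    """Full replicate: history → expansion/founding → selection.

    One master seed; the historical, expansion/trait and selection stages
    draw from independently spawned substreams (in that fixed order), so
    each stage is reproducible on its own.
    """
    ss = np.random.SeedSequence(seed)
    rng_hist, rng_found, rng_sel = (np.random.default_rng(s) for s in ss.spawn(3))
    pool = simulate_historical(config, rng_hist)
    popn = expand_and_found(config, pool, trait, rng_found)
    return simulate_selection(config, popn, rng_sel)
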