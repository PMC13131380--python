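"""Genome map and gametogenesis.

The genome is a set of linkage groups (chromosomes) carrying ordered
biallelic loci, each either a neutral marker (SNP) or a QTL. Crossovers are
placed by a homogeneous Poisson process along the genetic map (Haldane
mapping function, no interference), and recurrent mutation flips allele
state at a fixed per-locus, per-gamete rate.

Haplotypes are stored as ``uint8`` arrays of shape ``(2 * n_individuals,
n_loci)`` with the two gametes of individual ``i`` in rows ``2i`` and
``2i + 1``; loci are ordered chromosome-major by map position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeMap", "meiose", "mutate_gametes"]


@dataclass(frozen=True)
class GenomeMap:
    """Ordered marker and QTL positions on a multi-chromosome genetic map.

    Parameters
    ----------
    chrom_length_cM : ndarray, shape (C,)
        Map length of each chromosome in centimorgans.
    positions : list of ndarray
        Per-chromosome locus positions in cM, strictly increasing and
        within ``[0, chrom_length_cM[c]]``.
    is_qtl : list of ndarray of bool
        Per-chromosome flags marking QTL; the remainder are SNPs.
    mutation_rate : float
        Per-locus, per-gamete probability of an allele flip.
    """

    chrom_length_cM: np.ndarray
    positions: list
    is_qtl: list
    mutation_rate: float = 1e-4

    def __post_init__(self):
        object.__setattr__(
            self, "chrom_length_cM", np.asarray(self.chrom_length_cM, dtype=float)
        )
        if len(self.positions) != self.n_chromosomes or len(self.is_qtl) != self.n_chromosomes:
            raise ValueError("positions/is_qtl must have one entry per chromosome")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        pos, qtl = [], []
        for c in range(self.n_chromosomes):
            p = np.asarray(self.positions[c], dtype=float)
            q = np.asarray(self.is_qtl[c], dtype=bool)
            if p.shape != q.shape:
                raise ValueError("positions and is_qtl shapes differ")
            if p.size and (np.any(np.diff(p) <= 0) or p[0] < 0 or p[-1] > self.chrom_length_cM[c]):
                raise ValueError(f"positions on chromosome {c} not strictly increasing in range")
            pos.append(p)
            qtl.append(q)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "is_qtl", qtl)

    # -- basic geometry -------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_length_cM)

    @property
    def n_loci(self) -> int:
        return int(sum(p.size for p in self.positions))

    @property
    def n_qtl(self) -> int:
        return int(sum(q.sum() for q in self.is_qtl))

    @property
    def n_snps(self) -> int:
        return self.n_loci - self.n_qtl

    @property
    def total_length_cM(self) -> float:
        return float(self.chrom_length_cM.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Flat column offsets: locus columns of chromosome c are offsets[c]:offsets[c+1]."""
        return np.concatenate([[0], np.cumsum([p.size for p in self.positions])]).astype(int)

    @property
    def qtl_mask(self) -> np.ndarray:
        """Flat boolean mask over all locus columns; True at QTL."""
        if self.n_loci == 0:
            return np.zeros(0, dtype=bool)
        return np.concatenate(self.is_qtl)

    @property
    def snp_mask(self) -> np.ndarray:
        return ~self.qtl_mask

    @property
    def snp_positions(self) -> list:
        return [p[~q] for p, q in zip(self.positions, self.is_qtl)]

    @property
    def qtl_positions(self) -> list:
        return [p[q] for p, q in zip(self.positions, self.is_qtl)]

    def snp_table(self):
        """Flat (chromosome, position_cM) arrays for the SNPs, in column order."""
        chroms = np.concatenate(
            [np.full((~q).sum(), c + 1) for c, q in enumerate(self.is_qtl)]
        )
        pos = np.concatenate(self.snp_positions)
        return chroms.astype(int), pos

    # -- constructors ---------------------------------------------------
    @staticmethod
    def default_lengths(n_chromosomes: int = 29, total_cM: float = 2333.0,
                        min_cM: float = 40.0, max_cM: float = 146.0) -> np.ndarray:
        """Descending chromosome lengths emulating the bovine autosomes.

        Lengths decrease from ``max_cM`` to ``min_cM`` following a power
        curve whose exponent is solved so the total map length matches
        ``total_cM``.
        """
        if n_chromosomes == 1:
            return np.array([total_cM])
        w = np.linspace(1.0, 0.0, n_chromosomes)
        span, base = max_cM - min_cM, min_cM

        def total(a):
            return float(np.sum(base + span * w**a))

        lo, hi = 1e-3, 60.0
        if not (total(hi) <= total_cM <= total(lo)):
            # Infeasible with the given bounds: fall back to proportional scaling.
            lens = base + span * w
            return lens * (total_cM / lens.sum())
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if total(mid) > total_cM:
                lo = mid
            else:
                hi = mid
        return base + span * w ** (0.5 * (lo + hi))

    @classmethod
    def random(cls, n_snps: int, n_qtl: int, rng: np.random.Generator,
               n_chromosomes: int = 29, total_cM: float = 2333.0,
               mutation_rate: float = 1e-4, chrom_length_cM=None) -> "GenomeMap":
        """Place ``n_snps + n_qtl`` loci uniformly at random on the map.

        Loci are apportioned to chromosomes proportionally to map length
        (largest-remainder rounding); QTL labels are assigned to a random
        subset within each chromosome, so SNP and QTL sets are disjoint by
        construction.
        """
        lengths = (np.asarray(chrom_length_cM, float) if chrom_length_cM is not None
                   else cls.default_lengths(n_chromosomes, total_cM))
        n_chromosomes = len(lengths)
        n_loci = n_snps + n_qtl
        counts = _apportion(n_loci, lengths)
        qtl_counts = _apportion(n_qtl, lengths)
        # Guard: a chromosome cannot hold more QTL than loci.
        qtl_counts = np.minimum(qtl_counts, counts)
        short = n_qtl - qtl_counts.sum()
        while short > 0:
            room = np.argmax(counts - qtl_counts)
            qtl_counts[room] += 1
            short -= 1
        positions, is_qtl = [], []
        for c in range(n_chromosomes):
            p = np.sort(rng.uniform(0.0, lengths[c], size=counts[c]))
            # Resolve (measure-zero) ties by resampling.
            while np.any(np.diff(p) <= 0):
                p = np.sort(rng.uniform(0.0, lengths[c], size=counts[c]))
            q = np.zeros(counts[c], dtype=bool)
            q[rng.choice(counts[c], size=qtl_counts[c], replace=False)] = True
            positions.append(p)
            is_qtl.append(q)
        return cls(lengths, positions, is_qtl, mutation_rate)

    def subset(self, keep: np.ndarray, qtl_flags: np.ndarray | None = None) -> "GenomeMap":
        """New map retaining the flat locus columns in boolean mask ``keep``.

        ``qtl_flags`` optionally reassigns the QTL labels of the retained
        loci (flat, over retained columns).
        """
        keep = np.asarray(keep, bool)
        off = self.offsets
        positions, is_qtl = [], []
        new_flags = qtl_flags if qtl_flags is not None else self.qtl_mask[keep]
        start = 0
        for c in range(self.n_chromosomes):
            m = keep[off[c]:off[c + 1]]
            positions.append(self.positions[c][m])
            k = int(m.sum())
            is_qtl.append(np.asarray(new_flags[start:start + k], bool))
            start += k
        return GenomeMap(self.chrom_length_cM, positions, is_qtl, self.mutation_rate)


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(quota - counts)[::-1]
        counts[order[:rem]] += 1
    return counts


def meiose(haplotypes: np.ndarray, parents: np.ndarray, genome: GenomeMap,
           rng: np.random.Generator, return_counts: bool = False):
    """Form one gamete per entry of ``parents`` by recombining parent rows.

    Crossovers per chromosome follow a Poisson process with intensity equal
    to the map length in Morgans (Haldane / no-interference model); the
    starting homologue is chosen uniformly. Returns the gametes
    ``(m, n_loci)`` and, when ``return_counts``, the per-gamete,
    per-chromosome crossover counts.
    """
    parents = np.asarray(parents)
    m = parents.size
    off = genome.offsets
    origins = np.empty((m, genome.n_loci), dtype=np.uint8)
    counts = np.zeros((m, genome.n_chromosomes), dtype=np.int64) if return_counts else None
    for c in range(genome.n_chromosomes):
        pos = genome.positions[c]
        L = genome.chrom_length_cM[c] / 100.0  # Morgans
        nl = pos.size
        k_total = rng.poisson(m * L)
        who = rng.integers(0, m, size=k_total)
        where = rng.uniform(0.0, L, size=k_total)
        start = rng.integers(0, 2, size=m, dtype=np.uint8)
        if return_counts:
            counts[:, c] = np.bincount(who, minlength=m)
        if nl == 0:
            continue
        iv = np.searchsorted(pos / 100.0, where)  # crossover affects loci >= iv
        inside = iv < nl
        cnt = np.zeros((m, nl), dtype=np.int64)
        np.add.at(cnt, (who[inside], iv[inside]), 1)
        parity = np.cumsum(cnt, axis=1, dtype=np.int64) & 1
        origins[:, off[c]:off[c + 1]] = (start[:, None] + parity) & 1
    h0 = haplotypes[2 * parents]
    h1 = haplotypes[2 * parents + 1]
    gametes = np.where(origins, h1, h0)
    if return_counts:
        return gametes, counts
    return gametes


def mutate_gametes(gametes: np.ndarray, mutation_rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Flip allele state in place at recurrently mutating positions.

    The number of mutation events is Poisson with mean ``rate * size``;
    event positions are uniform over all (gamete, locus) cells. Two hits
    on the same cell cancel, which is exactly recurrent (back) mutation.
    """
    if mutation_rate <= 0 or gametes.size == 0:
        return gametes
    n_events = rng.poisson(mutation_rate * gametes.size)
    if n_events:
        flat = gametes.reshape(-1)
        idx = rng.integers(0, flat.size, size=n_events)
        np.bitwise_xor.at(flat, idx, 1)
    return gametes
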