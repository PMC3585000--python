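"""Synthetic genotype data with known truth.

The generator realises exactly the statistical structure the analysis
pipeline assumes:

* ancestral populations diverged by pure drift — per-SNP allele frequencies
  drawn from the Balding–Nichols Beta distribution around a shared ancestral
  frequency, with drift coefficient F per population;
* reference panels — binomial sampling of diploid genotypes from one
  population's frequencies;
* admixed cohorts — instantaneous two-way admixture ``n_gens`` generations
  ago with mixture proportion ``alpha``: each haplotype is a mosaic of
  ancestry segments whose breakpoints follow a Poisson process of rate
  ``n_gens`` per Morgan along the genetic map, each segment's ancestry an
  independent Bernoulli(alpha) draw.  This gives admixture LD that decays as
  exp(-n_gens * d) in genetic distance d — the signal the dating module fits.

Every generator is deterministic given its seed, and each admixed cohort
carries a :class:`SimTruth` record of the parameters that produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genodata import GenotypeDataset, SampleRecord, SnpRecord

#: Ancestral allele-frequency support; truncated away from fixation so that
#: reference-panel frequency differences stay informative.
ANCESTRAL_FREQ_RANGE = (0.05, 0.95)


@dataclass
class SimTruth:
    """Ground-truth parameters attached to a simulated dataset."""

    alpha: float
    n_gens: int
    F: tuple[float, ...]
    seed: int
    t_gens: float | None = None
    ne: float | None = None
    map_summary: dict = field(default_factory=dict)


def simulate_map(n_chrom: int, morgans_per_chrom: float, snps_per_chrom: int,
                 seed: int, cm_per_mb: float = 1.0) -> list[SnpRecord]:
    """Uniform SNP positions on ``n_chrom`` chromosomes of equal genetic
    length, with a constant cM/Mb recombination rate tying physical to
    genetic coordinates."""
    if n_chrom < 1 or snps_per_chrom < 1 or morgans_per_chrom <= 0:
        raise ValueError("all counts must be >= 1 and map length positive")
    rng = np.random.default_rng(seed)
    chrom_bp = int(round(morgans_per_chrom * 100 / cm_per_mb * 1e6))
    snps: list[SnpRecord] = []
    for c in range(1, n_chrom + 1):
        pos = np.sort(rng.uniform(0, chrom_bp, size=snps_per_chrom))
        phys = pos.astype(np.int64) + 1
        # enforce strict increase after integer truncation
        for i in range(1, snps_per_chrom):
            if phys[i] <= phys[i - 1]:
                phys[i] = phys[i - 1] + 1
        for i, bp in enumerate(phys):
            snps.append(SnpRecord(
                chrom=str(c),
                snp_id=f"snp{c}_{i}",
                genetic_pos=float(bp) / 1e6 * cm_per_mb,
                phys_pos=int(bp),
            ))
    return snps


def simulate_ancestral_freqs(M: int, F_by_pop: list[float] | tuple[float, ...],
                             seed: int,
                             freq_range: tuple[float, float] = ANCESTRAL_FREQ_RANGE
                             ) -> np.ndarray:
    """Balding–Nichols population frequencies.

    The ancestral frequency p is Uniform over ``freq_range`` per SNP; each
    population j draws its frequency from Beta(p(1-F_j)/F_j,
    (1-p)(1-F_j)/F_j), so E = p and Var = F_j p(1-p).  F_j = 0 copies p
    exactly.  Returns a (n_pops, M) matrix.
    """
    F_by_pop = tuple(float(f) for f in F_by_pop)
    if any(f < 0 or f >= 1 for f in F_by_pop):
        raise ValueError("each F must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=M)
    rows = []
    for f in F_by_pop:
        if f == 0:
            rows.append(p.copy())
        else:
            scale = (1.0 - f) / f
            draw = rng.beta(p * scale, (1.0 - p) * scale)
            # Beta support is open (0,1) but draws can round to the
            # boundary at strong drift; keep frequencies strictly interior
            rows.append(np.clip(draw, 1e-9, 1.0 - 1e-9))
    return np.vstack(rows)


def _default_snps(m: int) -> list[SnpRecord]:
    return [SnpRecord("1", f"snp1_{i}", genetic_pos=(i + 1) * 1e-3,
                      phys_pos=i + 1) for i in range(m)]


def simulate_panel(freqs: np.ndarray, N: int, seed: int,
                   snps: list[SnpRecord] | None = None,
                   population: str = "pop") -> GenotypeDataset:
    """Reference panel: N diploid genotypes drawn Binomial(2, p_m)
    independently across samples and SNPs."""
    if N < 1:
        raise ValueError("N must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, freqs, size=(N, freqs.size)).astype(np.int8)
    if snps is None:
        snps = _default_snps(freqs.size)
    samples = [SampleRecord(f"{population}_{i}", population=population)
               for i in range(N)]
    return GenotypeDataset(samples, list(snps), geno)


def _chrom_slices(snps: list[SnpRecord]) -> list[tuple[str, slice]]:
    out = []
    start = 0
    for i in range(1, len(snps) + 1):
        if i == len(snps) or snps[i].chrom != snps[start].chrom:
            out.append((snps[start].chrom, slice(start, i)))
            start = i
    return out


def _ancestry_haplotypes(rng: np.random.Generator, pos_morgans: np.ndarray,
                         n_hap: int, alpha: float, n_gens: float
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Ancestry indicators (1 = population 1) for ``n_hap`` haplotypes along
    one chromosome; returns (n_hap x M ancestry matrix, breakpoints per
    haplotype)."""
    lo, hi = float(pos_morgans[0]), float(pos_morgans[-1])
    length = hi - lo
    anc = np.empty((n_hap, pos_morgans.size), dtype=np.int8)
    n_breaks = rng.poisson(n_gens * length, size=n_hap)
    for h in range(n_hap):
        k = int(n_breaks[h])
        bps = np.sort(rng.uniform(lo, hi, size=k))
        seg_anc = (rng.random(k + 1) < alpha).astype(np.int8)
        seg_idx = np.searchsorted(bps, pos_morgans, side="right")
        anc[h] = seg_anc[seg_idx]
    return anc, n_breaks


def simulate_admixed(freqs_pop1: np.ndarray, freqs_pop2: np.ndarray,
                     snp_map: list[SnpRecord], N: int, alpha: float,
                     n_gens: int, seed: int,
                     population: str = "admixed"
                     ) -> tuple[GenotypeDataset, SimTruth]:
    """Instantaneously admixed cohort with known truth.

    Per haploid genome and chromosome, ancestry breakpoints are a Poisson
    process of rate ``n_gens`` per Morgan; each segment's ancestry is
    Bernoulli(``alpha``) (1 = population 1).  Alleles are drawn
    Bernoulli(frequency of the segment's ancestral population), and the
    genotype is the sum of two independent haplotypes.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    if n_gens < 1:
        raise ValueError("n_gens must be >= 1")
    f1 = np.asarray(freqs_pop1, dtype=float)
    f2 = np.asarray(freqs_pop2, dtype=float)
    if f1.size != len(snp_map) or f2.size != len(snp_map):
        raise ValueError("frequency vectors must match the SNP map")
    pos_cm = np.array([s.genetic_pos for s in snp_map], dtype=float)
    rng = np.random.default_rng(seed)
    n_hap = 2 * N
    haplo = np.empty((n_hap, len(snp_map)), dtype=np.int8)
    total_span = 0.0
    for chrom, sl in _chrom_slices(snp_map):
        pos_m = pos_cm[sl] / 100.0
        if pos_m[-1] - pos_m[0] <= 0:
            raise ValueError(f"chromosome {chrom} has zero genetic length")
        total_span += pos_m[-1] - pos_m[0]
        anc, _ = _ancestry_haplotypes(rng, pos_m, n_hap, alpha, n_gens)
        freq = np.where(anc == 1, f1[sl], f2[sl])
        haplo[:, sl] = (rng.random(anc.shape) < freq).astype(np.int8)
    geno = haplo[0::2] + haplo[1::2]
    samples = [SampleRecord(f"{population}_{i}", population=population)
               for i in range(N)]
    ds = GenotypeDataset(samples, list(snp_map), geno)
    truth = SimTruth(
        alpha=alpha, n_gens=n_gens, F=(), seed=seed,
        map_summary={
            "n_chrom": len(_chrom_slices(snp_map)),
            "n_snps": len(snp_map),
            "total_morgans": total_span,
        },
    )
    return ds, truth


def fst_from_divergence(t_gens: float, ne: float) -> float:
    """Pure-drift divergence: FST accumulated after ``t_gens`` generations of
    separation at diploid effective size ``ne`` is 1 - exp(-t/(2*Ne)) — the
    exact inverse of the dating module's logarithmic FST-to-time formula."""
    if t_gens < 0:
        raise ValueError("t_gens must be >= 0")
    if ne <= 0:
        raise ValueError("ne must be > 0")
    return 1.0 - math.exp(-t_gens / (2.0 * ne))
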