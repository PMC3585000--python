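"""Genotype data model, PLINK-format I/O, QC, LD pruning, IBS distances and
stratified subsampling.

The central container is :class:`GenotypeDataset`: an ``N x M`` matrix of
diploid allele-1 dosages (0, 1, 2, or :data:`MISSING`) together with a SNP map
(chromosome, genetic position in centiMorgans, physical position) and sample
labels (population / subgroup / region).  Everything downstream — MDS/PCA,
ancestry decomposition, admixture-LD dating — consumes this object.

Supported on-disk dialects are PLINK binary (BED/BIM/FAM, BED v1 SNP-major)
and PLINK text (PED/MAP).  The FAM/PED family columns are repurposed to carry
the sample annotation: FID = population, IID = sample id, father = subgroup,
mother = region ("0" marks an absent label), which keeps the files
PLINK-conformant while making the sample table round-trippable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Chromosome labels treated as autosomal.
AUTOSOMES = tuple(str(c) for c in range(1, 23))

_BED_MAGIC = bytes([0x6C, 0x1B])


def _ext(prefix: "Path", ext: str) -> "Path":
    return prefix.parent / (prefix.name + ext)

_BED_MODE_SNP_MAJOR = 0x01
# 2-bit BED code -> allele-1 dosage: 00=hom A1, 01=missing, 10=het, 11=hom A2
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


class GenotypeFormatError(ValueError):
    """Malformed on-disk genotype file (bad magic, unparsable columns...)."""


class GenotypeValidationError(ValueError):
    """Dataset violates an invariant (duplicate ids, bad dosage values...)."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    """One SNP: map position plus the two alleles.

    ``genetic_pos`` is in centiMorgans, ``phys_pos`` in 1-based base pairs.
    Dosages in the genotype matrix count copies of ``allele1``.
    """

    chrom: str
    snp_id: str
    genetic_pos: float
    phys_pos: int
    allele1: str = "A"
    allele2: str = "B"


@dataclass(frozen=True)
class SampleRecord:
    """One sample with its grouping labels (population / subgroup / region)."""

    sample_id: str
    population: str = "pop"
    subgroup: str = "0"
    region: str | None = None


@dataclass
class GenotypeDataset:
    """N samples x M SNPs of diploid allele-1 dosages.

    ``genotypes[i, m]`` is the number of copies of ``snps[m].allele1`` carried
    by ``samples[i]`` (0/1/2), or :data:`MISSING`.
    """

    samples: list[SampleRecord]
    snps: list[SnpRecord]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise GenotypeValidationError("genotype matrix must be 2-D")
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.snps):
            raise GenotypeValidationError(
                f"matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeValidationError("genotype entries must be 0/1/2/MISSING")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise GenotypeValidationError("duplicate sample_id")

    # -- convenience accessors ---------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def chrom_array(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    def genetic_pos_cm(self) -> np.ndarray:
        return np.array([s.genetic_pos for s in self.snps], dtype=float)

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def snp_missing_fraction(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return self.missing_mask().mean(axis=0)

    def allele_freqs(self) -> np.ndarray:
        """Allele-1 frequency per SNP over non-missing calls (NaN if none)."""
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(g, axis=0) / 2.0

    def take_samples(self, index: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(index, dtype=int)
        return GenotypeDataset(
            [self.samples[i] for i in idx], list(self.snps), self.genotypes[idx]
        )

    def take_snps(self, index: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(index, dtype=int)
        return GenotypeDataset(
            list(self.samples), [self.snps[i] for i in idx], self.genotypes[:, idx]
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise distance matrix with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise GenotypeValidationError("distance matrix shape mismatch")


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM)
# ---------------------------------------------------------------------------


def _norm_chrom(raw: str) -> str:
    """PLINK numeric sex/mt codes -> letter labels; everything as str."""
    return {"23": "X", "24": "Y", "26": "MT", "25": "XY"}.get(raw, raw)


def _fam_records(path: Path) -> list[SampleRecord]:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 4:
        raise GenotypeFormatError(f"{path}: expected >=4 FAM columns")
    recs = []
    for row in fam.itertuples(index=False):
        region = None if row[3] == "0" else str(row[3])
        recs.append(
            SampleRecord(
                sample_id=str(row[1]),
                population=str(row[0]),
                subgroup=str(row[2]),
                region=region,
            )
        )
    ids = [r.sample_id for r in recs]
    if len(set(ids)) != len(ids):
        raise GenotypeValidationError(f"{path}: duplicate sample_id")
    return recs


def _bim_records(path: Path) -> list[SnpRecord]:
    bim = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 6:
        raise GenotypeFormatError(f"{path}: expected 6 BIM columns")
    try:
        return [
            SnpRecord(
                chrom=_norm_chrom(str(r[0])),
                snp_id=str(r[1]),
                genetic_pos=float(r[2]),
                phys_pos=int(r[3]),
                allele1=str(r[4]),
                allele2=str(r[5]),
            )
            for r in bim.itertuples(index=False)
        ]
    except ValueError as exc:  # unparsable cM / bp column
        raise GenotypeFormatError(f"{path}: unparsable BIM column ({exc})") from exc


def _read_bed(prefix: Path) -> GenotypeDataset:
    samples = _fam_records(_ext(prefix, ".fam"))
    snps = _bim_records(_ext(prefix, ".bim"))
    n, m = len(samples), len(snps)
    raw = _ext(prefix, ".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise GenotypeFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _BED_MODE_SNP_MAJOR:
        raise GenotypeFormatError(f"{prefix}.bed: not SNP-major (mode byte != 0x01)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise IOError(
            f"{prefix}.bed: truncated genotype block "
            f"({body.size} bytes, expected {m * bytes_per_snp})"
        )
    blocks = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):  # sample order is little-endian within a byte
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    geno = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeDataset(samples, snps, geno)


def _write_bed(ds: GenotypeDataset, prefix: Path) -> None:
    n, m = ds.n_samples, ds.n_snps
    fam_rows = [
        (s.population, s.sample_id, s.subgroup, s.region or "0", "0", "-9")
        for s in ds.samples
    ]
    pd.DataFrame(fam_rows).to_csv(_ext(prefix, ".fam"), sep="\t",
                                  header=False, index=False)
    bim_rows = [
        (s.chrom, s.snp_id, np.format_float_positional(s.genetic_pos, trim="0"),
         s.phys_pos, s.allele1, s.allele2)
        for s in ds.snps
    ]
    pd.DataFrame(bim_rows).to_csv(_ext(prefix, ".bim"), sep="\t",
                                  header=False, index=False)
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_BED_CODE.items():
        lut[dosage % 4] = code  # MISSING=-1 -> index 3
    codes = lut[ds.genotypes.T % 4]  # (M, N)
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    quads = codes.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_MODE_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------


def _read_ped(prefix: Path) -> GenotypeDataset:
    map_df = pd.read_csv(_ext(prefix, ".map"), sep=r"\s+", header=None,
                         dtype=str)
    if map_df.shape[1] < 4:
        raise GenotypeFormatError(f"{prefix}.map: expected 4 MAP columns")
    try:
        map_rows = [
            (_norm_chrom(str(r[0])), str(r[1]), float(r[2]), int(r[3]))
            for r in map_df.itertuples(index=False)
        ]
    except ValueError as exc:
        raise GenotypeFormatError(f"{prefix}.map: unparsable column ({exc})") from exc
    m = len(map_rows)

    samples: list[SampleRecord] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(_ext(prefix, ".ped")) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise GenotypeFormatError(
                    f"{prefix}.ped: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            samples.append(
                SampleRecord(
                    sample_id=fields[1],
                    population=fields[0],
                    subgroup=fields[2],
                    region=None if fields[3] == "0" else fields[3],
                )
            )
            allele_pairs.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(m)]
            )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise GenotypeValidationError(f"{prefix}.ped: duplicate sample_id")

    # PED carries no allele declaration; allele1 is the lexicographically
    # smaller observed allele ("0" = missing call).
    geno = np.full((len(samples), m), MISSING, dtype=np.int8)
    snps = []
    for j, (chrom, snp_id, cm, bp) in enumerate(map_rows):
        observed = sorted(
            {a for pairs in allele_pairs for a in pairs[j] if a != "0"}
        )
        if len(observed) > 2:
            raise GenotypeFormatError(
                f"{prefix}.ped: SNP {snp_id} has >2 alleles: {observed}"
            )
        a1 = observed[0] if observed else "0"
        a2 = observed[1] if len(observed) > 1 else "0"
        snps.append(SnpRecord(chrom, snp_id, cm, bp, a1, a2))
        for i, pairs in enumerate(allele_pairs):
            x, y = pairs[j]
            if x == "0" or y == "0":
                continue
            geno[i, j] = (x == a1) + (y == a1)
    return GenotypeDataset(samples, snps, geno)


def _write_ped(ds: GenotypeDataset, prefix: Path) -> None:
    map_rows = [
        (s.chrom, s.snp_id, np.format_float_positional(s.genetic_pos, trim="0"),
         s.phys_pos)
        for s in ds.snps
    ]
    pd.DataFrame(map_rows).to_csv(_ext(prefix, ".map"), sep="\t",
                                  header=False, index=False)
    with open(_ext(prefix, ".ped"), "w") as fh:
        for i, s in enumerate(ds.samples):
            fields = [s.population, s.sample_id, s.subgroup, s.region or "0",
                      "0", "-9"]
            for j, snp in enumerate(ds.snps):
                g = int(ds.genotypes[i, j])
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [snp.allele1, snp.allele1]
                elif g == 1:
                    fields += [snp.allele1, snp.allele2]
                else:
                    fields += [snp.allele2, snp.allele2]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, dialect: str = "bed") -> GenotypeDataset:
    """Read a PLINK fileset (``path`` is the prefix without extension).

    ``dialect='bed'`` reads BED/BIM/FAM (BED v1 SNP-major); ``dialect='ped'``
    reads PED/MAP.  Dosages count copies of allele 1 as declared in the
    BIM (for PED, the lexicographically smaller observed allele).
    """
    prefix = Path(path)
    if dialect == "bed":
        ds = _read_bed(prefix)
    elif dialect == "ped":
        ds = _read_ped(prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    logger.info("read %d samples x %d SNPs from %s (%s)",
                ds.n_samples, ds.n_snps, prefix, dialect)
    return ds


def write_genotypes(ds: GenotypeDataset, path: str | Path,
                    dialect: str = "bed") -> None:
    """Write ``ds`` as a PLINK fileset at prefix ``path``."""
    if ds.n_samples == 0 or ds.n_snps == 0:
        raise GenotypeValidationError("refusing to write an empty dataset")
    prefix = Path(path)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "bed":
        _write_bed(ds, prefix)
    elif dialect == "ped":
        _write_ped(ds, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    logger.info("wrote %d samples x %d SNPs to %s (%s)",
                ds.n_samples, ds.n_snps, prefix, dialect)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(ds: GenotypeDataset, max_snp_missing: float = 0.01,
              drop_nonautosomal: bool = True) -> GenotypeDataset:
    """Drop SNPs failing the per-SNP call-rate threshold and, by default,
    everything not on an autosome.

    A SNP is retained when its missing fraction is <= ``max_snp_missing``
    (a 99% genotyping success rate corresponds to the 0.01 default).  The
    sample set is never altered and retained genotype values are untouched.
    """
    if not 0.0 <= max_snp_missing <= 1.0:
        raise ValueError("max_snp_missing must be in [0, 1]")
    miss_frac = ds.snp_missing_fraction()
    keep = miss_frac <= max_snp_missing
    n_missing_fail = int((~keep).sum())
    n_nonauto = 0
    if drop_nonautosomal:
        autosomal = np.isin(ds.chrom_array(), AUTOSOMES)
        n_nonauto = int((keep & ~autosomal).sum())
        keep &= autosomal
    out = ds.take_snps(np.flatnonzero(keep))
    logger.info(
        "qc_filter: %d -> %d SNPs (%d failed missingness > %g, %d non-autosomal)",
        ds.n_snps, out.n_snps, n_missing_fail, max_snp_missing, n_nonauto,
    )
    if out.n_snps == 0:
        warnings.warn("qc_filter removed every SNP", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def pairwise_r2(genotypes: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, using
    pairwise-complete observations; undefined (zero-variance or <2 shared
    observations) pairs are reported as 0."""
    g = np.asarray(genotypes, dtype=float)
    present = (g != MISSING).astype(float)
    x = np.where(g == MISSING, 0.0, g)
    n = present.T @ present
    sx = x.T @ present  # sum of col-i dosages over samples complete in (i, j)
    sxy = x.T @ x
    sxx = (x * x).T @ present
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = sx / n
        cov = sxy / n - mx * mx.T
        var_x = sxx / n - mx**2
        r2 = cov**2 / (var_x * var_x.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(ds: GenotypeDataset, r2_max: float = 0.4, window_snps: int = 50,
             step_snps: int = 5) -> GenotypeDataset:
    """Greedy windowed LD pruning: within each sliding window (per
    chromosome), repeatedly drop one SNP of the worst-correlated retained pair
    until no retained pair has r^2 > ``r2_max``.

    Tie-break on which SNP of a pair to drop: higher missingness first, then
    the later SNP in map order.  Monomorphic SNPs have undefined r^2, treated
    as 0 (never pruned for LD).
    """
    if window_snps <= step_snps:
        raise ValueError("window_snps must exceed step_snps")
    keep = np.ones(ds.n_snps, dtype=bool)
    miss_frac = ds.snp_missing_fraction()
    chroms = ds.chrom_array()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step_snps):
            win = idx[start:start + window_snps]
            if len(win) < 2:
                continue
            r2 = pairwise_r2(ds.genotypes[:, win])
            np.fill_diagonal(r2, 0.0)
            alive = keep[win].copy()
            while True:
                masked = np.where(np.outer(alive, alive), r2, 0.0)
                i, j = np.unravel_index(np.argmax(masked), masked.shape)
                if masked[i, j] <= r2_max:
                    break
                a, b = win[i], win[j]
                if miss_frac[a] != miss_frac[b]:
                    drop = a if miss_frac[a] > miss_frac[b] else b
                else:
                    drop = max(a, b)  # later in map order
                alive[win == drop] = False
                keep[drop] = False
            if start + window_snps >= len(idx):
                break
    out = ds.take_snps(np.flatnonzero(keep))
    logger.info("ld_prune: %d -> %d SNPs (r2 > %g removed)",
                ds.n_snps, out.n_snps, r2_max)
    return out


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------


def ibs_distance_matrix(ds: GenotypeDataset) -> DistanceMatrix:
    """Genome-wide identity-by-state distances.

    Per pair, similarity = (#SNPs sharing both alleles + 0.5 * #SNPs sharing
    one allele) / #SNPs compared over pairwise-complete SNPs; distance is
    1 - similarity.  For dosages a, b the number of shared alleles is
    2 - |a - b|, so the pairwise sum of |a - b| is assembled from one-hot
    indicator products.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = ds.genotypes
    ind = [(g == d).astype(float) for d in (0, 1, 2)]
    present = (g != MISSING).astype(float)
    n_comp = present @ present.T
    # sum over compared SNPs of |a - b|
    diff = np.zeros_like(n_comp)
    for a in range(3):
        for b in range(3):
            if a != b:
                diff += abs(a - b) * (ind[a] @ ind[b].T)
    zero_overlap = n_comp == 0
    np.fill_diagonal(zero_overlap, False)
    if zero_overlap.any():
        i, j = np.argwhere(zero_overlap)[0]
        raise ValueError(
            "no overlapping non-missing SNPs for pair "
            f"({ds.samples[i].sample_id}, {ds.samples[j].sample_id})"
        )
    with np.errstate(invalid="ignore"):
        dist = diff / (2.0 * n_comp)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(ds.sample_ids, dist)


# ---------------------------------------------------------------------------
# Stratified subsampling
# ---------------------------------------------------------------------------


def stratified_subsample(ds: GenotypeDataset, group_field: str, per_group: int,
                         seed: int, allow_smaller: bool = False
                         ) -> GenotypeDataset:
    """Draw exactly ``per_group`` samples per group (without replacement),
    reproducibly by ``seed``; used to equalise group sizes before structure
    analysis.  ``group_field`` is one of 'population', 'subgroup', 'region'."""
    if group_field not in ("population", "subgroup", "region"):
        raise ValueError(f"unknown group_field {group_field!r}")
    labels = np.array(
        [getattr(s, group_field) or "" for s in ds.samples], dtype=object
    )
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for grp in pd.unique(labels):
        members = np.flatnonzero(labels == grp)
        if len(members) < per_group:
            if not allow_smaller:
                raise ValueError(
                    f"group {grp!r} has {len(members)} < {per_group} samples"
                )
            chosen.extend(members)
        else:
            chosen.extend(rng.choice(members, size=per_group, replace=False))
    chosen = sorted(chosen)
    logger.info("stratified_subsample: kept %d of %d samples (%d per %s)",
                len(chosen), ds.n_samples, per_group, group_field)
    return ds.take_samples(chosen)
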