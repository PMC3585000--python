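"""Admixture dating from the decay of admixture LD, and FST-to-divergence-time
conversion under pure drift.

Admixture between two differentiated populations creates linkage
disequilibrium between loci that decays by recombination as exp(-n*d) for
genetic distance d (Morgans) after n generations.  The weighted LD statistic
correlates, over SNP pairs binned by d, the product of reference
allele-frequency differences (delta_x * delta_y) with the observed dosage
correlation in the admixed cohort; fitting A(d) = amplitude * exp(-rate * d)
then reads off n = rate, and a leave-one-chromosome-out weighted jackknife
supplies the standard error.  Dates in years use a generation time
(default 25 years).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .genodata import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

DEFAULT_GEN_TIME_YEARS = 25.0


@dataclass
class LdDecayCurve:
    """Binned weighted-LD statistic A(d) with per-chromosome sufficient sums
    (kept for the jackknife)."""

    bin_centers: np.ndarray  # Morgans, strictly increasing
    A: np.ndarray            # statistic per bin; NaN where undefined
    pair_counts: np.ndarray
    bin_width: float
    chromosomes: list[str]
    # per chromosome: rows (sum dxdy*z, sum (dxdy)^2, sum z^2, n_pairs) x bins
    chrom_sums: dict[str, np.ndarray] = field(default_factory=dict)
    snps_per_chrom: dict[str, int] = field(default_factory=dict)


@dataclass
class DecayFit:
    """Exponential decay fit of an LD curve; rate is generations since
    admixture."""

    amplitude: float
    rate_per_morgan: float
    offset: float
    rss: float
    se_rate: float = float("nan")
    gen_time: float = DEFAULT_GEN_TIME_YEARS
    n_bins: int = 0

    @property
    def date_years(self) -> float:
        return self.rate_per_morgan * self.gen_time

    @property
    def date_se_years(self) -> float:
        return self.se_rate * self.gen_time


@dataclass
class DivergenceEstimate:
    """FST plus an effective-size range converted to a divergence-time
    range in years."""

    fst: float
    ne_low: float
    ne_high: float
    gen_years: float
    formula: str
    t_years_low: float
    t_years_high: float


# ---------------------------------------------------------------------------
# Weighted LD statistic
# ---------------------------------------------------------------------------


def _ref_freq(ds: GenotypeDataset) -> np.ndarray:
    f = ds.allele_freqs()
    return np.nan_to_num(f, nan=0.5)


def _check_shared_map(*datasets: GenotypeDataset) -> None:
    ref = [(s.chrom, s.snp_id, s.phys_pos) for s in datasets[0].snps]
    for other in datasets[1:]:
        if [(s.chrom, s.snp_id, s.phys_pos) for s in other.snps] != ref:
            raise ValueError("datasets do not share the same SNP map")


def _pairwise_corr(g: np.ndarray, min_obs: int) -> np.ndarray:
    """Pearson correlation between dosage columns over pairwise-complete
    samples; entries with < min_obs shared observations or zero variance are
    NaN."""
    present = g != MISSING
    if present.all():
        x = g.astype(float)
        x -= x.mean(axis=0)
        norm = np.sqrt((x * x).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (x.T @ x) / np.outer(norm, norm)
        if g.shape[0] < min_obs:
            corr[:] = np.nan
        return corr
    w = present.astype(float)
    x = np.where(present, g, 0).astype(float)
    n = w.T @ w
    sx = x.T @ w
    sxy = x.T @ x
    sxx = (x * x).T @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = sx / n
        cov = sxy / n - mx * mx.T
        var = sxx / n - mx**2
        corr = cov / np.sqrt(var * var.T)
    corr[n < max(min_obs, 2)] = np.nan
    return corr


def weighted_ld_statistic(admixed: GenotypeDataset, ref1: GenotypeDataset,
                          ref2: GenotypeDataset, bin_width: float = 0.001,
                          d_max: float = 0.30, min_pair_obs: int = 10
                          ) -> LdDecayCurve:
    """Binned weighted admixture-LD statistic.

    Per SNP the weight is delta_m = freq(ref1) - freq(ref2).  For every
    same-chromosome SNP pair (x, y) at genetic distance 0 < d <= ``d_max``,
    z(x, y) is the Pearson correlation of mean-centred dosages in the admixed
    cohort (pairwise-complete; pairs with fewer than ``min_pair_obs`` shared
    calls are skipped).  Pairs are binned by d and the per-bin statistic is

        A(d) = sum dx*dy*z / sqrt(sum (dx*dy)^2 * sum z^2),

    an (uncentred) correlation between weight products and LD over the bin's
    pairs; swapping the references flips every delta and leaves A unchanged.
    Empty bins are retained with A = NaN.
    """
    _check_shared_map(admixed, ref1, ref2)
    delta = _ref_freq(ref1) - _ref_freq(ref2)
    if np.allclose(delta, 0.0):
        raise ValueError("uninformative references: allele frequencies "
                         "identical at every SNP")
    n_bins = int(math.ceil(d_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers = (edges[:-1] + edges[1:]) / 2.0

    chroms = admixed.chrom_array()
    pos_m = admixed.genetic_pos_cm() / 100.0
    chrom_sums: dict[str, np.ndarray] = {}
    snps_per_chrom: dict[str, int] = {}
    for chrom in dict.fromkeys(chroms):  # preserve map order
        idx = np.flatnonzero(chroms == chrom)
        snps_per_chrom[chrom] = len(idx)
        sums = np.zeros((4, n_bins))
        if len(idx) >= 2:
            z = _pairwise_corr(admixed.genotypes[:, idx], min_pair_obs)
            d = np.abs(pos_m[idx][:, None] - pos_m[idx][None, :])
            dd = np.outer(delta[idx], delta[idx])
            iu, ju = np.triu_indices(len(idx), k=1)
            zv, dv, ddv = z[iu, ju], d[iu, ju], dd[iu, ju]
            ok = np.isfinite(zv) & (dv > 0) & (dv <= d_max)
            if ok.any():
                b = np.minimum((dv[ok] / bin_width).astype(int), n_bins - 1)
                sums[0] = np.bincount(b, weights=ddv[ok] * zv[ok],
                                      minlength=n_bins)
                sums[1] = np.bincount(b, weights=ddv[ok] ** 2,
                                      minlength=n_bins)
                sums[2] = np.bincount(b, weights=zv[ok] ** 2,
                                      minlength=n_bins)
                sums[3] = np.bincount(b, minlength=n_bins)
        chrom_sums[chrom] = sums

    total = sum(chrom_sums.values())
    a, counts = _curve_from_sums(total)
    logger.info("weighted_ld_statistic: %d bins, %d pairs",
                n_bins, int(counts.sum()))
    return LdDecayCurve(
        bin_centers=centers, A=a, pair_counts=counts, bin_width=bin_width,
        chromosomes=list(chrom_sums), chrom_sums=chrom_sums,
        snps_per_chrom=snps_per_chrom,
    )


def _curve_from_sums(sums: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s1, s2, s3, n = sums
    with np.errstate(invalid="ignore", divide="ignore"):
        a = s1 / np.sqrt(s2 * s3)
    a[n == 0] = np.nan
    return a, n


# ---------------------------------------------------------------------------
# Exponential decay fit
# ---------------------------------------------------------------------------


def _exp_model(d: np.ndarray, amplitude: float, rate: float) -> np.ndarray:
    return amplitude * np.exp(-rate * d)


def _exp_model_affine(d: np.ndarray, amplitude: float, rate: float,
                      offset: float) -> np.ndarray:
    return amplitude * np.exp(-rate * d) + offset


def fit_exponential_decay(curve: LdDecayCurve, d_min: float = 0.005,
                          d_max: float = 0.30, affine: bool = False,
                          gen_time: float = DEFAULT_GEN_TIME_YEARS
                          ) -> DecayFit:
    """Weighted nonlinear least squares of A(d) = amplitude * exp(-rate*d)
    (+ offset when ``affine``) over bins with centre in [d_min, d_max], each
    bin weighted by its pair count; rate is constrained >= 0 and converts to
    a date as rate * gen_time years."""
    sel = ((curve.bin_centers >= d_min) & (curve.bin_centers <= d_max)
           & np.isfinite(curve.A) & (curve.pair_counts > 0))
    if sel.sum() < 5:
        raise ValueError(f"only {int(sel.sum())} usable bins in "
                         f"[{d_min}, {d_max}]; need >= 5")
    d = curve.bin_centers[sel]
    a = curve.A[sel]
    sigma = 1.0 / np.sqrt(curve.pair_counts[sel])

    # log-linear initial guess for the rate from the positive bins
    pos = a > 0
    if pos.sum() >= 2:
        slope = np.polyfit(d[pos], np.log(a[pos]), 1)[0]
        rate0 = max(-slope, 0.0)
    else:
        rate0 = 0.0
    amp_span = a[0] - a[-1]
    starts = [(amp_span if affine else a[0], rate0)]
    starts += [(max(a[0], 1e-3), r) for r in (1.0, 10.0, 30.0, 100.0, 300.0)]

    best = None
    model = _exp_model_affine if affine else _exp_model
    for amp0, r0 in starts:
        p0 = [amp0, r0] + ([a[-1]] if affine else [])
        lo = [-np.inf, 0.0] + ([-np.inf] if affine else [])
        hi = [np.inf] * len(p0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, d, a, p0=p0, sigma=sigma,
                                    bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float((((model(d, *popt) - a) / sigma) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, popt)
    if best is None:
        raise RuntimeError(
            "exponential fit failed to converge from all starting points; "
            f"bins={int(sel.sum())}, A range=({a.min():.3g}, {a.max():.3g})"
        )
    rss, popt = best
    offset = float(popt[2]) if affine else 0.0
    fit = DecayFit(amplitude=float(popt[0]), rate_per_morgan=float(popt[1]),
                   offset=offset, rss=rss, gen_time=gen_time,
                   n_bins=int(sel.sum()))
    logger.info("fit_exponential_decay: rate=%.2f/Morgan -> %.0f years",
                fit.rate_per_morgan, fit.date_years)
    return fit


# ---------------------------------------------------------------------------
# Jackknife over chromosomes
# ---------------------------------------------------------------------------


def _refit_without(curve: LdDecayCurve, chrom: str, **fit_kw) -> float:
    total = sum(v for c, v in curve.chrom_sums.items() if c != chrom)
    a, n = _curve_from_sums(total)
    sub = LdDecayCurve(
        bin_centers=curve.bin_centers, A=a, pair_counts=n,
        bin_width=curve.bin_width,
        chromosomes=[c for c in curve.chromosomes if c != chrom],
    )
    return fit_exponential_decay(sub, **fit_kw).rate_per_morgan


def jackknife_date(admixed: GenotypeDataset, ref1: GenotypeDataset,
                   ref2: GenotypeDataset, bin_width: float = 0.001,
                   d_min: float = 0.005, d_max: float = 0.30,
                   affine: bool = False,
                   gen_time: float = DEFAULT_GEN_TIME_YEARS
                   ) -> DecayFit:
    """Full decay fit plus a leave-one-chromosome-out weighted jackknife
    standard error on the rate (blocks weighted by their SNP counts)."""
    curve = weighted_ld_statistic(admixed, ref1, ref2, bin_width=bin_width,
                                  d_max=d_max)
    if len(curve.chromosomes) < 3:
        raise ValueError("jackknife needs >= 3 chromosomes")
    fit_kw = dict(d_min=d_min, d_max=d_max, affine=affine, gen_time=gen_time)
    full = fit_exponential_decay(curve, **fit_kw)
    theta = full.rate_per_morgan
    chroms = curve.chromosomes
    theta_c = np.array([_refit_without(curve, c, **fit_kw) for c in chroms])
    m = np.array([curve.snps_per_chrom[c] for c in chroms], dtype=float)
    n_tot = m.sum()
    g = len(chroms)
    h = n_tot / m
    # weighted delete-one jackknife (Busing et al. convention)
    theta_j = g * theta - float(((1.0 - m / n_tot) * theta_c).sum())
    tau = h * theta - (h - 1.0) * theta_c
    var = float((((tau - theta_j) ** 2) / (h - 1.0)).sum()) / g
    se = math.sqrt(max(var, 0.0))
    logger.info("jackknife_date: rate=%.2f +- %.2f (%d blocks)",
                theta, se, g)
    return DecayFit(amplitude=full.amplitude,
                    rate_per_morgan=theta, offset=full.offset,
                    rss=full.rss, se_rate=se, gen_time=gen_time,
                    n_bins=full.n_bins)


# ---------------------------------------------------------------------------
# FST -> divergence time
# ---------------------------------------------------------------------------


def fst_to_divergence_time(fst: float, ne_low: float, ne_high: float,
                           gen_years: float = DEFAULT_GEN_TIME_YEARS,
                           formula: str = "linear") -> DivergenceEstimate:
    """Convert an FST between two groups into a divergence-time range over an
    effective-population-size range.

    ``linear``: t = 2*Ne*FST generations (first-order drift approximation);
    ``log``:    t = -2*Ne*ln(1-FST) (exact under pure drift divergence).
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must lie in [0, 1)")
    if ne_low <= 0 or ne_high <= 0 or ne_low > ne_high:
        raise ValueError("need 0 < ne_low <= ne_high")
    if formula == "linear":
        t = lambda ne: 2.0 * ne * fst
    elif formula == "log":
        t = lambda ne: -2.0 * ne * math.log1p(-fst)
    else:
        raise ValueError(f"unknown formula {formula!r}")
    return DivergenceEstimate(
        fst=fst, ne_low=ne_low, ne_high=ne_high, gen_years=gen_years,
        formula=formula,
        t_years_low=t(ne_low) * gen_years,
        t_years_high=t(ne_high) * gen_years,
    )
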