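"""Admixture-LD decay statistic, exponential dating fit, chromosome
jackknife, and FST-to-divergence-time conversion."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import levantstrat as lv
from levantstrat.dating import LdDecayCurve

from conftest import make_dataset


# ---------------------------------------------------------------------------
# weighted LD statistic
# ---------------------------------------------------------------------------


def _brute_force_curve(admixed, ref1, ref2, bin_width, d_max):
    """Independent per-pair loop evaluating the same definition."""
    delta = ref1.allele_freqs() - ref2.allele_freqs()
    pos = admixed.genetic_pos_cm() / 100.0
    chroms = admixed.chrom_array()
    n_bins = math.ceil(d_max / bin_width)
    sums = np.zeros((3, n_bins))
    counts = np.zeros(n_bins)
    g = admixed.genotypes.astype(float)
    m = admixed.n_snps
    for x in range(m):
        for y in range(x + 1, m):
            if chroms[x] != chroms[y]:
                continue
            d = abs(pos[x] - pos[y])
            if not 0 < d <= d_max:
                continue
            z = np.corrcoef(g[:, x], g[:, y])[0, 1]
            if not np.isfinite(z):
                continue
            b = min(int(d / bin_width), n_bins - 1)
            w = delta[x] * delta[y]
            sums[0, b] += w * z
            sums[1, b] += w * w
            sums[2, b] += z * z
            counts[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[0] / np.sqrt(sums[1] * sums[2])
    a[counts == 0] = np.nan
    return a, counts


def test_statistic_matches_exhaustive_pair_oracle():
    rng = np.random.default_rng(61)
    g = rng.integers(0, 3, size=(6, 4))
    pos_cm = [1.0, 3.0, 26.0, 31.0]
    admixed = make_dataset(g, genetic_pos=pos_cm)
    ref1 = make_dataset(rng.integers(0, 3, size=(8, 4)), genetic_pos=pos_cm)
    ref2 = make_dataset(rng.integers(0, 3, size=(8, 4)), genetic_pos=pos_cm)
    curve = lv.weighted_ld_statistic(admixed, ref1, ref2, bin_width=0.05,
                                     d_max=0.30, min_pair_obs=2)
    a, counts = _brute_force_curve(admixed, ref1, ref2, 0.05, 0.30)
    assert np.array_equal(curve.pair_counts, counts)
    both = np.isfinite(curve.A) & np.isfinite(a)
    assert np.allclose(curve.A[both], a[both], atol=1e-12)
    assert np.array_equal(np.isfinite(curve.A), np.isfinite(a))


def test_statistic_reference_swap_invariance(admixture_sim):
    c1 = lv.weighted_ld_statistic(admixture_sim["admixed"],
                                  admixture_sim["ref1"],
                                  admixture_sim["ref2"])
    c2 = lv.weighted_ld_statistic(admixture_sim["admixed"],
                                  admixture_sim["ref2"],
                                  admixture_sim["ref1"])
    ok = np.isfinite(c1.A)
    assert np.array_equal(ok, np.isfinite(c2.A))
    assert np.allclose(c1.A[ok], c2.A[ok], atol=1e-12)


def test_statistic_is_bounded_correlation_and_decreases(admixture_sim):
    curve = lv.weighted_ld_statistic(admixture_sim["admixed"],
                                     admixture_sim["ref1"],
                                     admixture_sim["ref2"])
    assert (np.diff(curve.bin_centers) > 0).all()
    assert (curve.pair_counts >= 0).all()
    ok = np.isfinite(curve.A)
    assert np.abs(curve.A[ok]).max() <= 1.0
    # trend check on noise-averaged coarse bins: per-pair sampling noise
    # dominates individual fine bins once the signal has decayed
    coarse = lv.weighted_ld_statistic(admixture_sim["admixed"],
                                      admixture_sim["ref1"],
                                      admixture_sim["ref2"],
                                      bin_width=0.01)
    sel = np.isfinite(coarse.A) & (coarse.bin_centers >= 0.005)
    rho = spearmanr(coarse.bin_centers[sel], coarse.A[sel]).statistic
    assert rho < -0.8


def test_statistic_null_when_admixed_has_single_ancestry():
    """A cohort drawn purely from population 1 (the alpha -> 1 limit) shows
    no admixture LD: every bin stays inside sampling noise."""
    snp_map = lv.simulate_map(10, 1.0, 1000, seed=62)
    fr = lv.simulate_ancestral_freqs(len(snp_map), (0.05, 0.05), seed=63)
    null = lv.simulate_panel(fr[0], 200, seed=64, snps=snp_map,
                             population="null")
    r1 = lv.simulate_panel(fr[0], 200, seed=65, snps=snp_map,
                           population="r1")
    r2 = lv.simulate_panel(fr[1], 200, seed=66, snps=snp_map,
                           population="r2")
    curve = lv.weighted_ld_statistic(null, r1, r2)
    assert np.nanmax(np.abs(curve.A)) < 0.1
    fit = lv.fit_exponential_decay(curve, affine=True)
    assert abs(fit.amplitude) < 0.05


def test_statistic_identical_references_error(admixture_sim):
    with pytest.raises(ValueError, match="uninformative"):
        lv.weighted_ld_statistic(admixture_sim["admixed"],
                                 admixture_sim["ref1"],
                                 admixture_sim["ref1"])


def test_statistic_requires_shared_map(admixture_sim):
    trimmed = admixture_sim["ref1"].take_snps(range(100))
    with pytest.raises(ValueError, match="SNP map"):
        lv.weighted_ld_statistic(admixture_sim["admixed"], trimmed,
                                 admixture_sim["ref2"])


# ---------------------------------------------------------------------------
# exponential fit
# ---------------------------------------------------------------------------


def _synthetic_curve(values, centers=None, pairs=1000):
    centers = centers if centers is not None \
        else np.arange(0.0005, 0.30, 0.001)
    return LdDecayCurve(
        bin_centers=np.asarray(centers), A=np.asarray(values),
        pair_counts=np.full(len(centers), float(pairs)), bin_width=0.001,
        chromosomes=["1"],
    )


def test_noiseless_decay_recovered_to_machine_precision():
    d = np.arange(0.0005, 0.30, 0.001)
    curve = _synthetic_curve(0.08 * np.exp(-30.0 * d), centers=d)
    fit = lv.fit_exponential_decay(curve)
    assert fit.rate_per_morgan == pytest.approx(30.0, abs=1e-6)
    assert fit.amplitude == pytest.approx(0.08, abs=1e-8)
    assert fit.date_years == pytest.approx(750.0, abs=1e-4)


def test_constant_curve_affine_degenerate_decay():
    curve = _synthetic_curve(np.full(295, 0.05),
                             centers=np.arange(0.0055, 0.30, 0.001))
    fit = lv.fit_exponential_decay(curve, affine=True)
    assert fit.rate_per_morgan == pytest.approx(0.0, abs=1e-6)
    assert fit.offset == pytest.approx(0.05, abs=1e-6)


def test_fit_requires_enough_bins():
    curve = _synthetic_curve([0.1, 0.05, 0.02], centers=[0.01, 0.02, 0.03])
    with pytest.raises(ValueError, match="usable bins"):
        lv.fit_exponential_decay(curve)


def test_simulated_rate_recovery_single_seed(admixture_sim):
    curve = lv.weighted_ld_statistic(admixture_sim["admixed"],
                                     admixture_sim["ref1"],
                                     admixture_sim["ref2"])
    fit = lv.fit_exponential_decay(curve)
    assert fit.rate_per_morgan == pytest.approx(30.0, rel=0.20)


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------


def _tile_chromosomes(base, n_copies):
    """Dataset whose chromosomes are identical copies of one block."""
    snps = []
    for c in range(n_copies):
        for s in base.snps:
            snps.append(lv.SnpRecord(str(c + 1), f"c{c}_{s.snp_id}",
                                     s.genetic_pos, s.phys_pos,
                                     s.allele1, s.allele2))
    geno = np.tile(base.genotypes, (1, n_copies))
    return lv.GenotypeDataset(base.samples, snps, geno)


def test_jackknife_zero_variance_on_identical_chromosomes():
    snp_map = lv.simulate_map(1, 1.0, 400, seed=71)
    fr = lv.simulate_ancestral_freqs(400, (0.05, 0.05), seed=72)
    adm, _ = lv.simulate_admixed(fr[0], fr[1], snp_map, N=150, alpha=0.3,
                                 n_gens=20, seed=73)
    r1 = lv.simulate_panel(fr[0], 100, seed=74, snps=snp_map)
    r2 = lv.simulate_panel(fr[1], 100, seed=75, snps=snp_map,
                           population="p2")
    adm3 = _tile_chromosomes(adm, 3)
    fit = lv.jackknife_date(adm3, _tile_chromosomes(r1, 3),
                            _tile_chromosomes(r2, 3))
    assert fit.se_rate == pytest.approx(0.0, abs=1e-9)


def test_jackknife_consistency_and_date_scaling(admixture_sim):
    fit = lv.jackknife_date(admixture_sim["admixed"],
                            admixture_sim["ref1"], admixture_sim["ref2"])
    assert fit.se_rate >= 0
    assert fit.date_years == pytest.approx(fit.rate_per_morgan * 25.0)
    assert fit.date_se_years == pytest.approx(fit.se_rate * 25.0)
    # delete-one estimates scatter around the full estimate
    from levantstrat.dating import _refit_without, weighted_ld_statistic
    curve = weighted_ld_statistic(admixture_sim["admixed"],
                                  admixture_sim["ref1"],
                                  admixture_sim["ref2"])
    loo = [_refit_without(curve, c) for c in curve.chromosomes]
    assert np.mean(loo) == pytest.approx(fit.rate_per_morgan, rel=0.10)


def test_jackknife_requires_three_chromosomes():
    snp_map = lv.simulate_map(2, 1.0, 200, seed=81)
    fr = lv.simulate_ancestral_freqs(len(snp_map), (0.05, 0.05), seed=82)
    adm, _ = lv.simulate_admixed(fr[0], fr[1], snp_map, N=30, alpha=0.3,
                                 n_gens=10, seed=83)
    r1 = lv.simulate_panel(fr[0], 30, seed=84, snps=snp_map)
    r2 = lv.simulate_panel(fr[1], 30, seed=85, snps=snp_map,
                           population="p2")
    with pytest.raises(ValueError, match=">= 3 chromosomes"):
        lv.jackknife_date(adm, r1, r2)


def test_jackknife_coverage_of_true_rate():
    """The +-2 SE interval covers the true admixture age in most seeded
    replicates (small-scale coverage check)."""
    hits = 0
    reps = 6
    for s in range(reps):
        snp_map = lv.simulate_map(10, 1.0, 800, seed=900 + s)
        fr = lv.simulate_ancestral_freqs(len(snp_map), (0.05, 0.05),
                                         seed=920 + s)
        adm, _ = lv.simulate_admixed(fr[0], fr[1], snp_map, N=200,
                                     alpha=0.2, n_gens=30, seed=940 + s)
        r1 = lv.simulate_panel(fr[0], 150, seed=960 + s, snps=snp_map)
        r2 = lv.simulate_panel(fr[1], 150, seed=980 + s, snps=snp_map,
                               population="p2")
        fit = lv.jackknife_date(adm, r1, r2)
        if abs(fit.rate_per_morgan - 30.0) <= 2 * fit.se_rate:
            hits += 1
    assert hits >= 0.8 * reps - 1  # >= 4 of 6


# ---------------------------------------------------------------------------
# FST -> divergence time
# ---------------------------------------------------------------------------


def test_divergence_time_hand_computed_values():
    est = lv.fst_to_divergence_time(0.046, 7006, 9505, 25, "linear")
    assert est.t_years_low == pytest.approx(16113.8, abs=0.1)
    assert est.t_years_high == pytest.approx(21861.5, abs=0.1)
    log_est = lv.fst_to_divergence_time(0.035, 8677, 8677, 25, "log")
    expected = 2 * 8677 * (-math.log(0.965)) * 25
    assert log_est.t_years_low == pytest.approx(expected, abs=1e-6)
    assert log_est.t_years_low == pytest.approx(15456.7, abs=0.5)


def test_divergence_time_zero_fst_and_errors():
    est = lv.fst_to_divergence_time(0.0, 5000, 8000)
    assert (est.t_years_low, est.t_years_high) == (0.0, 0.0)
    with pytest.raises(ValueError):
        lv.fst_to_divergence_time(1.0, 5000, 8000)
    with pytest.raises(ValueError):
        lv.fst_to_divergence_time(-0.1, 5000, 8000)
    with pytest.raises(ValueError):
        lv.fst_to_divergence_time(0.1, 8000, 5000)


def test_divergence_time_monotone_and_log_dominates_linear():
    prev = 0.0
    for fst in (0.01, 0.02, 0.05, 0.1):
        lin = lv.fst_to_divergence_time(fst, 5000, 9000, formula="linear")
        log = lv.fst_to_divergence_time(fst, 5000, 9000, formula="log")
        assert lin.t_years_low <= lin.t_years_high
        assert log.t_years_low > lin.t_years_low  # -ln(1-x) > x for x > 0
        assert lin.t_years_low > prev
        prev = lin.t_years_low
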