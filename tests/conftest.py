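"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import levantstrat as lv


def make_dataset(genotypes, chroms=None, genetic_pos=None, populations=None,
                 alleles=("A", "C")):
    """Build a GenotypeDataset from a raw dosage matrix with sensible
    defaults: all SNPs on chromosome 1 at 0.1-cM spacing."""
    g = np.asarray(genotypes)
    n, m = g.shape
    chroms = chroms or ["1"] * m
    genetic_pos = genetic_pos if genetic_pos is not None \
        else [(i + 1) * 0.1 for i in range(m)]
    populations = populations or ["pop"] * n
    snps = [lv.SnpRecord(str(chroms[j]), f"snp{j}", float(genetic_pos[j]),
                         j + 1, alleles[0], alleles[1]) for j in range(m)]
    samples = [lv.SampleRecord(f"ind{i}", population=populations[i])
               for i in range(n)]
    return lv.GenotypeDataset(samples, snps, g)


def stack_panels(*panels):
    """Concatenate panels sharing a SNP map into one cohort."""
    samples = [s for p in panels for s in p.samples]
    geno = np.vstack([p.genotypes for p in panels])
    return lv.GenotypeDataset(samples, list(panels[0].snps), geno)


def two_population_cohort(F=0.1, n_per_pop=50, m=2000, seed=1):
    freqs = lv.simulate_ancestral_freqs(m, (F, F), seed=seed)
    pa = lv.simulate_panel(freqs[0], n_per_pop, seed=seed + 1, population="a")
    pb = lv.simulate_panel(freqs[1], n_per_pop, seed=seed + 2, population="b")
    return stack_panels(pa, pb), freqs


@pytest.fixture(scope="session")
def two_pop_small():
    """100 samples x 2000 SNPs from two drift-diverged populations."""
    return two_population_cohort(F=0.1, n_per_pop=50, m=2000, seed=1)


@pytest.fixture(scope="session")
def admixture_sim():
    """Two-way admixed cohort (n_gens=30, alpha=0.2) with reference panels,
    at a reduced scale shared by the dating unit tests."""
    snp_map = lv.simulate_map(10, 1.0, 1000, seed=50)
    freqs = lv.simulate_ancestral_freqs(len(snp_map), (0.05, 0.05), seed=51)
    admixed, truth = lv.simulate_admixed(freqs[0], freqs[1], snp_map, N=200,
                                         alpha=0.2, n_gens=30, seed=52)
    ref1 = lv.simulate_panel(freqs[0], 150, seed=53, snps=snp_map,
                             population="ref1")
    ref2 = lv.simulate_panel(freqs[1], 150, seed=54, snps=snp_map,
                             population="ref2")
    return {"admixed": admixed, "ref1": ref1, "ref2": ref2, "truth": truth,
            "freqs": freqs, "map": snp_map}
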