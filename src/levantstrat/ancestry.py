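"""Unsupervised ancestry decomposition under the binomial admixture model,
cross-validation over the number of components K, and FST between inferred
components.

Model: individual i's genotype at SNP m is Binomial(2, pi_im) with
pi_im = sum_k Q_ik P_km, where Q holds per-individual ancestry proportions
(rows sum to 1) and P holds per-component allele frequencies.  Fitting is by
EM-style alternating conditional maximisation of the binomial log-likelihood,
which shares its stationary points with the block-relaxation solvers used by
the standard tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genodata import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

_P_EPS = 1e-6  # keep component frequencies away from {0,1}


@dataclass
class AdmixtureFit:
    """Fitted (Q, P) with the log-likelihood trace of the run."""

    K: int
    Q: np.ndarray  # (N, K) ancestry proportions, rows sum to 1
    P: np.ndarray  # (K, M) component allele frequencies
    loglik_trace: list[float]
    seed: int
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


@dataclass
class CvResult:
    """Held-out prediction error per K from masked-entry cross-validation."""

    K_values: list[int]
    cv_error: dict[int, float]
    folds: int
    seed: int

    @property
    def best_K(self) -> int:
        return min(self.K_values, key=lambda k: self.cv_error[k])


def _split_counts(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """(g, 2-g) with missing entries zeroed in both, so they drop out of
    every sum."""
    g = ds.genotypes.astype(float)
    miss = g == MISSING
    gp = np.where(miss, 0.0, g)
    hp = np.where(miss, 0.0, 2.0 - g)
    return gp, hp


def admixture_loglik(ds: GenotypeDataset, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial admixture log-likelihood (binomial coefficient omitted).

    sum over non-missing (i, m) of g*log(pi) + (2-g)*log(1-pi) with
    pi = Q @ P.  An exactly-fixed pi incompatible with an observed genotype
    makes the likelihood -infinity, reported as an error.
    """
    Q = np.asarray(Q, dtype=float)
    P = np.asarray(P, dtype=float)
    if Q.shape != (ds.n_samples, P.shape[0]) or P.shape[1] != ds.n_snps:
        raise ValueError("Q/P shapes inconsistent with dataset")
    gp, hp = _split_counts(ds)
    pi = Q @ P
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = gp * np.log(pi) + hp * np.log1p(-pi)
    terms[(gp == 0) & (hp == 0)] = 0.0  # missing entries contribute nothing
    total = float(terms.sum())
    if not np.isfinite(total):
        raise ValueError("log-likelihood is -infinity: pi fixed at 0 or 1 "
                         "at a non-missing genotype")
    return total


def fit_admixture(ds: GenotypeDataset, K: int, seed: int,
                  max_iter: int = 500, tol: float = 1e-4) -> AdmixtureFit:
    """Fit the K-component admixture model by EM.

    Q rows start from a flat Dirichlet draw; P starts at the observed allele
    frequencies perturbed by seeded noise (clipped into (0, 1)).  Each
    iteration applies the joint EM update of Q and P, which cannot decrease
    the likelihood; iteration stops once the gain drops below ``tol`` or
    after ``max_iter`` rounds.  Components are re-ordered by descending total
    ancestry mass so output is deterministic per seed.
    """
    n, m = ds.n_samples, ds.n_snps
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    gp, hp = _split_counts(ds)
    n_obs = gp + hp  # 2 * (non-missing indicator)
    m_i = n_obs.sum(axis=1)  # 2 * non-missing SNPs per sample
    if not (m_i > 0).all():
        raise ValueError("sample with no non-missing genotypes")
    freqs = np.nan_to_num(ds.allele_freqs(), nan=0.5)
    if np.all((freqs <= 0) | (freqs >= 1)):
        raise ValueError("no polymorphic SNPs")

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(freqs[None, :] + 0.05 * rng.standard_normal((K, m)),
                _P_EPS, 1.0 - _P_EPS)

    def _loglik_from_pi(pi: np.ndarray) -> float:
        terms = gp * np.log(pi) + hp * np.log1p(-pi)
        ll = float(terms.sum())
        if not np.isfinite(ll):
            bad = int(np.argmax(~np.isfinite(terms.sum(axis=0))))
            raise ValueError(f"non-finite likelihood at SNP "
                             f"{ds.snps[bad].snp_id}")
        return ll

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        pi = Q @ P
        ll = _loglik_from_pi(pi)  # likelihood of the current (Q, P)
        if trace:
            gain = ll - trace[-1]
            # EM is monotone up to float rounding (and the P clip); mask
            # rounding-scale decreases so the trace stays non-decreasing
            slack = 1e-9 * max(1.0, abs(trace[-1]))
            trace.append(max(ll, trace[-1]) if -slack < gain < 0 else ll)
            if gain < tol:
                converged = True
                break
        else:
            trace.append(ll)
        a = gp / pi           # g / pi
        b = hp / (1.0 - pi)   # (2 - g) / (1 - pi)
        # E-step expectations folded into the M-step updates
        q_new = Q * (a @ P.T + b @ (1.0 - P).T) / m_i[:, None]
        q_new /= q_new.sum(axis=1, keepdims=True)
        num = P * (Q.T @ a)
        den = num + (1.0 - P) * (Q.T @ b)
        with np.errstate(invalid="ignore"):
            p_new = np.where(den > 0, num / den, P)
        P = np.clip(p_new, _P_EPS, 1.0 - _P_EPS)
        Q = q_new
    else:
        ll = _loglik_from_pi(Q @ P)
        slack = 1e-9 * max(1.0, abs(trace[-1]))
        trace.append(max(ll, trace[-1]) if trace[-1] - slack < ll else ll)

    order = np.argsort(-Q.sum(axis=0), kind="stable")
    Q, P = Q[:, order], P[order]
    logger.info("fit_admixture K=%d: loglik %.2f after %d iterations "
                "(converged=%s)", K, trace[-1], len(trace) - 1, converged)
    return AdmixtureFit(K=K, Q=Q, P=P, loglik_trace=trace, seed=seed,
                        converged=converged)


def admixture_cv(ds: GenotypeDataset, K_list: list[int], folds: int = 5,
                 seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-4) -> CvResult:
    """Masked-entry cross-validation over K.

    Non-missing genotype entries are partitioned at random into ``folds``
    disjoint masks.  For each fold the masked entries are hidden, the model
    refit, and the hidden dosages predicted as 2 * (Q @ P); cv_error(K) is
    the mean squared prediction error pooled over all held-out entries.
    """
    if not K_list:
        raise ValueError("K_list is empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    obs = np.argwhere(ds.genotypes != MISSING)
    perm = rng.permutation(len(obs))
    fold_of = np.empty(len(obs), dtype=int)
    fold_of[perm] = np.arange(len(obs)) % folds

    cv_error: dict[int, float] = {}
    for K in K_list:
        sq_sum = 0.0
        count = 0
        for f in range(folds):
            held = obs[fold_of == f]
            geno = ds.genotypes.copy()
            geno[held[:, 0], held[:, 1]] = MISSING
            masked = GenotypeDataset(ds.samples, ds.snps, geno)
            fit = fit_admixture(masked, K, seed=int(rng.integers(2**31)),
                                max_iter=max_iter, tol=tol)
            pred = 2.0 * (fit.Q @ fit.P)
            truth = ds.genotypes[held[:, 0], held[:, 1]].astype(float)
            sq_sum += float(((pred[held[:, 0], held[:, 1]] - truth) ** 2).sum())
            count += len(held)
        cv_error[K] = sq_sum / count
        logger.info("admixture_cv K=%d: cv_error=%.5f", K, cv_error[K])
    return CvResult(K_values=list(K_list), cv_error=cv_error, folds=folds,
                    seed=seed)


def component_fst(P: np.ndarray, k: int, l: int,
                  estimator: str = "hudson") -> float:
    """FST between two rows of a component allele-frequency matrix.

    Ratio-of-averages across SNPs (never an average of per-SNP ratios):

    * ``hudson``: sum (p_k - p_l)^2 / sum [p_k(1-p_l) + p_l(1-p_k)]
    * ``nei``:    sum (p_k - p_l)^2 / 2 / sum p_bar(1-p_bar)

    The result is clipped to [0, 1).
    """
    P = np.asarray(P, dtype=float)
    pk, pl = P[k], P[l]
    if ((pk < 0) | (pk > 1) | (pl < 0) | (pl > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    num = float(((pk - pl) ** 2).sum())
    if estimator == "hudson":
        den = float((pk * (1 - pl) + pl * (1 - pk)).sum())
    elif estimator == "nei":
        num /= 2.0
        pbar = (pk + pl) / 2.0
        den = float((pbar * (1 - pbar)).sum())
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if den == 0:
        raise ValueError("both components fixed at every SNP; FST undefined")
    return float(np.clip(num / den, 0.0, np.nextafter(1.0, 0.0)))


def panel_fst(ds1: "GenotypeDataset", ds2: "GenotypeDataset",
              estimator: str = "hudson") -> float:
    """Hudson FST between two genotype panels with the finite-sample
    correction on the numerator (subtracting each panel's sampling variance
    p(1-p)/(n-1), n = allele count), so the estimate is unbiased for the
    population FST; ratio-of-averages across SNPs."""
    if estimator != "hudson":
        raise ValueError("panel_fst implements the hudson estimator only")
    out = []
    for ds in (ds1, ds2):
        g = ds.genotypes
        n_alleles = 2.0 * (g != MISSING).sum(axis=0)
        if (n_alleles < 4).any():
            raise ValueError("need >= 2 genotyped samples per SNP per panel")
        p = np.nan_to_num(ds.allele_freqs(), nan=0.0)
        out.append((p, n_alleles))
    (p1, n1), (p2, n2) = out
    num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1)).sum()
    den = (p1 * (1 - p2) + p2 * (1 - p1)).sum()
    if den == 0:
        raise ValueError("both panels fixed at every SNP; FST undefined")
    return float(np.clip(num / den, 0.0, np.nextafter(1.0, 0.0)))
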