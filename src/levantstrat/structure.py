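"""Population-structure embeddings: classical MDS on IBS distances,
variance-normalised PCA of the genotype matrix, and iterative PCA-based
outlier trimming that keeps the core cluster of a cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genodata import MISSING, DistanceMatrix, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    """Low-dimensional sample embedding with its eigenvalue spectrum."""

    labels: list[str]
    coords: np.ndarray  # (N, k)
    eigenvalues: np.ndarray  # (k,), non-increasing
    method: str  # 'mds' or 'pca'


@dataclass
class OutlierReport:
    """Record of iterative PCA outlier trimming."""

    removed_ids: list[list[str]] = field(default_factory=list)
    sigma: float = 6.0
    n_pcs: int = 10
    iterations: int = 0

    @property
    def all_removed(self) -> list[str]:
        return [sid for batch in self.removed_ids for sid in batch]


def _orient_columns(coords: np.ndarray, basis: np.ndarray | None = None
                    ) -> np.ndarray:
    """Deterministic sign convention: flip each column so the
    largest-magnitude coordinate of the orienting vector is positive."""
    ref = coords if basis is None else basis
    out = coords.copy()
    for j in range(coords.shape[1]):
        col = ref[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -out[:, j]
    return out


def classical_mds(D: DistanceMatrix, dims: int) -> EmbeddingResult:
    """Torgerson/classical multidimensional scaling.

    Double-centres the squared distance matrix, eigendecomposes it, and
    returns the top ``dims`` coordinates scaled by the square root of the
    (non-negative) eigenvalues.  Negative eigenvalues — a non-Euclidean
    distance matrix — are truncated; if fewer than ``dims`` positive
    eigenvalues exist, fewer columns are returned with a warning.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    d = np.asarray(D.values, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-12 * abs(vals[0]) if n else 0)
    n_pos = int(pos.sum())
    k = min(dims, n_pos)
    if k < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k} dimensions",
            stacklevel=2,
        )
    coords = vecs[:, :k] * np.sqrt(vals[:k]) if k else np.zeros((n, 0))
    coords = _orient_columns(coords)
    return EmbeddingResult(list(D.labels), coords, vals[:k], method="mds")


def _normalized_matrix(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, frequency-normalised genotype matrix.

    Each SNP column is centred by its mean dosage and divided by
    sqrt(p(1-p)) with p = mean/2 — the drift-scale normalisation that makes
    PCA eigenvalues comparable across allele frequencies.  Monomorphic
    columns are dropped; returns (X, kept_column_index).
    """
    g = ds.genotypes.astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g), np.broadcast_to(mu, g.shape), g)
    p = mu / 2.0
    with np.errstate(invalid="ignore"):
        scale = np.sqrt(p * (1.0 - p))
    keep = np.isfinite(scale) & (scale > 0) & (np.nanstd(inds, axis=0) > 0)
    if not keep.any():
        raise ValueError("all SNPs are monomorphic; PCA undefined")
    x = (inds[:, keep] - mu[keep]) / scale[keep]
    return x, np.flatnonzero(keep)


def pca_normalized(ds: GenotypeDataset, n_pcs: int) -> EmbeddingResult:
    """PCA of the frequency-normalised genotype matrix.

    Missing genotypes are imputed to the column mean before scaling.  Returns
    the top ``n_pcs`` sample projections and the corresponding eigenvalues of
    the sample covariance.  Column signs follow the loading-vector
    orientation convention for determinism.
    """
    n = ds.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_pcs > n - 1:
        raise ValueError("n_pcs must be <= N - 1")
    x, _ = _normalized_matrix(ds)
    xc = x - x.mean(axis=0)  # centre samples so PCs are covariance eigvecs
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_pcs, s.size)
    coords = u[:, :k] * s[:k]
    coords = _orient_columns(coords, basis=vt[:k].T)
    eigenvalues = (s[:k] ** 2) / (n - 1)
    return EmbeddingResult(ds.sample_ids, coords, eigenvalues, method="pca")


def pca_outlier_removal(ds: GenotypeDataset, sigma: float = 6.0,
                        n_pcs: int = 10, max_iter: int = 5
                        ) -> tuple[GenotypeDataset, OutlierReport]:
    """Iteratively drop samples lying more than ``sigma`` standard deviations
    from the mean along any of the top ``n_pcs`` principal components,
    recomputing the PCA after each pass, until no sample is flagged or
    ``max_iter`` passes have run.  Stops early (with a warning) rather than
    shrink the cohort below 3 samples.
    """
    if ds.n_samples <= n_pcs:
        raise ValueError("need more samples than n_pcs")
    report = OutlierReport(sigma=sigma, n_pcs=n_pcs)
    current = ds
    for _ in range(max_iter):
        k = min(n_pcs, current.n_samples - 1)
        emb = pca_normalized(current, k)
        scores = emb.coords
        mean = scores.mean(axis=0)
        std = scores.std(axis=0, ddof=1)
        std[std == 0] = np.inf
        flagged = (np.abs(scores - mean) > sigma * std).any(axis=1)
        if not flagged.any():
            break
        if current.n_samples - int(flagged.sum()) < 3:
            warnings.warn("outlier removal would leave < 3 samples; stopping",
                          stacklevel=2)
            break
        removed = [current.samples[i].sample_id
                   for i in np.flatnonzero(flagged)]
        report.removed_ids.append(removed)
        report.iterations += 1
        current = current.take_samples(np.flatnonzero(~flagged))
        logger.info("outlier pass %d removed %d samples",
                    report.iterations, len(removed))
    return current, report
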