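"""Standardized-genotype kinship matrix and its principal components.

Dosages are mean-imputed (missing cells), centered per locus, and scaled
either by the locus empirical SD (default, the "standard score") or by
sqrt(2p(1-p)), the binomial SD under Hardy-Weinberg. The kinship matrix is
K = M M^T / (2L) with L the number of loci; its eigenvectors are the
principal components describing population structure. Because columns of M
are centered, every row of K sums to zero, and with unit-variance scaling
the mean diagonal is ~0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DosageMatrix

__all__ = ["StandardizedMatrix", "KinshipMatrix", "PCAResult",
           "standardize", "kinship", "pca", "group_separation"]


@dataclass
class StandardizedMatrix:
    M: np.ndarray                # (n_samples, n_loci)
    center: np.ndarray           # per-locus mean dosage
    scale: np.ndarray            # per-locus divisor
    imputed: int                 # number of mean-imputed cells
    sample_ids: list[str]
    habitat: list[str]


@dataclass
class KinshipMatrix:
    K: np.ndarray                # (n, n) symmetric
    n_loci: int
    sample_ids: list[str]
    habitat: list[str]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray      # descending
    eigenvectors: np.ndarray     # columns are PCs, orthonormal
    proportion_variance: np.ndarray


def standardize(d: DosageMatrix, scaling: str = "empirical_sd") -> StandardizedMatrix:
    """Mean-impute, center and scale the dosage matrix per locus.

    ``scaling='empirical_sd'`` divides by the observed dosage SD;
    ``'binomial'`` divides by sqrt(2p(1-p)) with p the minor-allele
    frequency. A monomorphic locus (zero scale) is an error.
    """
    if scaling not in ("empirical_sd", "binomial"):
        raise ValueError(f"unknown scaling {scaling!r}")
    vals = d.values.astype(float)
    miss = vals < 0
    vals[miss] = np.nan
    center = np.nanmean(vals, axis=0)
    if np.isnan(center).any():
        bad = d.locus_ids[int(np.flatnonzero(np.isnan(center))[0])]
        raise ValueError(f"locus {bad}: all calls missing")
    imputed = int(miss.sum())
    vals = np.where(miss, center, vals)
    if scaling == "empirical_sd":
        scale = vals.std(axis=0)
    else:
        p = center / 2.0
        scale = np.sqrt(2.0 * p * (1.0 - p))
    if (scale == 0).any():
        bad = d.locus_ids[int(np.flatnonzero(scale == 0)[0])]
        raise ValueError(f"locus {bad}: monomorphic (zero scale)")
    M = (vals - center) / scale
    return StandardizedMatrix(
        M=M, center=center, scale=scale, imputed=imputed,
        sample_ids=list(d.sample_ids), habitat=list(d.habitat),
    )


def kinship(sm: StandardizedMatrix) -> KinshipMatrix:
    """K = M M^T / (2L); symmetric, rows sum to ~0 by construction."""
    L = sm.M.shape[1]
    K = sm.M @ sm.M.T / (2.0 * L)
    K = (K + K.T) / 2.0
    return KinshipMatrix(K=K, n_loci=L, sample_ids=sm.sample_ids,
                         habitat=sm.habitat)


def pca(km: KinshipMatrix) -> PCAResult:
    """Full eigendecomposition of K, eigenvalues descending.

    Each eigenvector's sign is fixed so its largest-magnitude loading is
    positive (eigenvectors are otherwise sign-ambiguous).
    """
    if not np.isfinite(km.K).all():
        raise ValueError("kinship matrix has non-finite entries")
    w, v = np.linalg.eigh(km.K)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    for j in range(v.shape[1]):
        k = int(np.argmax(np.abs(v[:, j])))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    total = w.sum()
    prop = w / total if total != 0 else np.zeros_like(w)
    return PCAResult(eigenvalues=w, eigenvectors=v, proportion_variance=prop)


def group_separation(
    scores: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation check of group separation along one PC.

    The statistic is the one-way variance ratio (between-group sum of
    squares over within-group sum of squares) of the PC scores across the
    labels; the null distribution comes from label permutations. Returns the
    observed ratio, the null 95th percentile, and an empirical P (add-one).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)

    def ratio(lab: np.ndarray) -> float:
        grand = scores.mean()
        between = within = 0.0
        for g in uniq:
            x = scores[lab == g]
            between += len(x) * (x.mean() - grand) ** 2
            within += ((x - x.mean()) ** 2).sum()
        return between / within if within > 0 else np.inf

    rng = np.random.default_rng(seed)
    observed = ratio(labels)
    null = np.array([ratio(rng.permutation(labels)) for _ in range(n_perm)])
    return {
        "observed_ratio": float(observed),
        "null_95th": float(np.quantile(null, 0.95)),
        "empirical_p": float(((null >= observed).sum() + 1) / (n_perm + 1)),
        "separated": bool(observed > np.quantile(null, 0.95)),
    }
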