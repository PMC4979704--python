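"""Pairwise relatedness (coancestry) estimation and the within-group
permutation test.

All estimators return relatedness r — twice the kinship coefficient — from
unphased biallelic genotypes and reference allele frequencies taken from the
full sample. Implemented estimators:

- ``quellergt``  Queller & Goodnight moment estimator, multilocus ratio of
  summed numerators/denominators, symmetrized over the two orderings.
- ``lynchli``    Li et al. similarity index: r = sum(S - S0) / sum(1 - S0)
  with S the genotype-similarity score and S0 its expectation for
  unrelated individuals.
- ``ritland``    Ritland kinship moment estimator (times two), averaged
  over loci.
- ``lynchrd``    Lynch & Ritland regression estimator with their
  inverse-variance locus weighting, averaged over the two reference
  orderings.
- ``wang_moment``  Wang-style moment estimator: the expectations of the
  genotype-similarity categories (identical; homozygote-heterozygote
  sharing) are linear in the IBD-state probabilities (k1, k2), and the
  weighted least-squares solution of that linear system across loci gives
  r = k2 + k1/2.
- ``dyadml``     Dyadic maximum likelihood (three non-inbred IBD states):
  the dyad likelihood is a per-locus mixture over IBD states with weights
  (k0, k1, k2); the mixture weights are maximized by EM and
  r = k2 + k1/2 in [0, 1].

The group-structure test permutes individuals across groups (group sizes
fixed) and compares each group's observed mean within-group r to the
permutation null; empirical P uses the add-one convention
(count + 1) / (n_perm + 1). With three groups and all seven estimators the
study design yields 21 tests, hence a Bonferroni threshold of
0.05 / 21 ~ 0.002.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DosageMatrix

__all__ = [
    "ESTIMATORS",
    "CoancestryTable",
    "PermutationTestResult",
    "estimate_pair",
    "pairwise_relatedness",
    "relatedness_matrix",
    "coancestry_table",
    "permutation_test",
    "bonferroni_threshold",
    "dyad_loglik",
]

ESTIMATORS = ("quellergt", "lynchli", "lynchrd", "ritland", "wang_moment",
              "dyadml")

_HABITAT_CODE = {"benthic": "B", "littoral": "L", "pelagic": "P"}


@dataclass
class PermutationTestResult:
    group: str
    estimator: str
    observed_mean: float
    null_means: np.ndarray
    empirical_p: float
    threshold: float
    n_perm: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.empirical_p < self.threshold


@dataclass
class CoancestryTable:
    """Long-format table of pairwise relatedness values per estimator."""

    table: pd.DataFrame  # columns: sample_i, sample_j, classification, <est...>
    estimators: list[str]


def bonferroni_threshold(family_alpha: float, n_tests: int) -> float:
    """Per-test significance threshold family_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


# ---------------------------------------------------------------------------
# Vectorized estimator core
#
# Genotypes enter as minor-allele dosages g in {0,1,2} (-1 missing); q is the
# per-locus minor frequency, p = 1 - q the major frequency. Per-locus pair
# statistics are functions of the ordered category 3*g_i + g_j, tabulated as
# (9, L) arrays and gathered per pair.
# ---------------------------------------------------------------------------


def _check_freqs(q: np.ndarray) -> None:
    if ((q <= 0) | (q >= 1)).any():
        raise ValueError(
            "reference minor-allele frequencies must lie strictly in (0,1); "
            "drop monomorphic loci first"
        )


def _gather(T9: np.ndarray, idx: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Sum per-locus table values over valid loci for each pair.

    T9: (9, L); idx: (P, L) category codes; valid: (P, L) mask.
    """
    cols = np.arange(T9.shape[1])[None, :]
    vals = T9[np.where(valid, idx, 0), cols]
    return np.where(valid, vals, 0.0).sum(axis=1)


def _categories(values: np.ndarray, pairs: np.ndarray):
    gi = values[pairs[:, 0], :].astype(np.int64)
    gj = values[pairs[:, 1], :].astype(np.int64)
    valid = (gi >= 0) & (gj >= 0)
    return gi, gj, valid


def _qg_tables(q: np.ndarray):
    p = 1.0 - q
    L = q.shape[0]
    num = np.empty((9, L))
    den_x = np.empty((9, L))
    for gx in range(3):
        xa, xb = 2 - gx, gx
        ref = xa * p + xb * q
        dx = 1.0 + (1 if gx != 1 else 0) - ref
        for gy in range(3):
            ya, yb = 2 - gy, gy
            num[3 * gx + gy] = 0.5 * (xa * ya + xb * yb) - ref
            den_x[3 * gx + gy] = dx
    return num, den_x


def _quellergt(values, pairs, q):
    gi, gj, valid = _categories(values, pairs)
    num, den = _qg_tables(q)
    idx_xy = 3 * gi + gj
    idx_yx = 3 * gj + gi
    n = _gather(num, idx_xy, valid) + _gather(num, idx_yx, valid)
    d = _gather(den, idx_xy, valid) + _gather(den, idx_yx, valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(d != 0, n / d, np.nan)


_S_SCORE = np.array([1.0, 0.75, 0.0,
                     0.75, 1.0, 0.75,
                     0.0, 0.75, 1.0])  # index 3*gx + gy


def _lynchli(values, pairs, q):
    p = 1.0 - q
    a2 = p**2 + q**2
    a3 = p**3 + q**3
    s0 = 2.0 * a2 - a3
    gi, gj, valid = _categories(values, pairs)
    S = _S_SCORE[:, None] - s0[None, :]          # S - S0 per category/locus
    n = _gather(S, 3 * gi + gj, valid)
    d = np.where(valid, (1.0 - s0)[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(d != 0, n / d, np.nan)


def _ritland(values, pairs, q):
    p = 1.0 - q
    L = q.shape[0]
    tab = np.empty((9, L))
    for gx in range(3):
        pa_x, pb_x = (2 - gx) / 2.0, gx / 2.0
        for gy in range(3):
            pa_y, pb_y = (2 - gy) / 2.0, gy / 2.0
            tab[3 * gx + gy] = 2.0 * (pa_x * pa_y / p + pb_x * pb_y / q - 1.0)
    gi, gj, valid = _categories(values, pairs)
    n = _gather(tab, 3 * gi + gj, valid)
    cnt = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, n / cnt, np.nan)


def _lr_tables(q: np.ndarray):
    """Lynch-Ritland directional tables, already divided by the 2*pa*pb
    weight so that ratio-of-sums implements their locus weighting."""
    p = 1.0 - q
    L = q.shape[0]
    num = np.empty((9, L))
    den_x = np.empty((9, L))
    for gx in range(3):
        for gy in range(3):
            ya, yb = 2 - gy, gy
            if gx == 0:      # reference homozygous major
                num[3 * gx + gy] = ya / p - 2.0
                den_x[3 * gx + gy] = 2.0 * q / p
            elif gx == 2:    # homozygous minor
                num[3 * gx + gy] = yb / q - 2.0
                den_x[3 * gx + gy] = 2.0 * p / q
            else:            # heterozygous reference
                num[3 * gx + gy] = yb / (2 * q) + ya / (2 * p) - 2.0
                den_x[3 * gx + gy] = (1.0 - 4.0 * p * q) / (2.0 * p * q)
    return num, den_x


def _lynchrd(values, pairs, q):
    gi, gj, valid = _categories(values, pairs)
    num, den = _lr_tables(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        n1 = _gather(num, 3 * gi + gj, valid)
        d1 = _gather(den, 3 * gi + gj, valid)
        n2 = _gather(num, 3 * gj + gi, valid)
        d2 = _gather(den, 3 * gj + gi, valid)
        r1 = np.where(d1 != 0, n1 / d1, np.nan)
        r2 = np.where(d2 != 0, n2 / d2, np.nan)
    return 0.5 * (r1 + r2)


def _wang_moment(values, pairs, q):
    """Weighted least-squares solution of the similarity-category moment
    equations for (k1, k2); r = k2 + k1/2.

    For a biallelic locus with power sums a2..a4 and pq = p(1-p):
      E[P1 - b]  = k2 (1 - b)  + k1 (a2 - b),    b  = 2 a2^2 - a4
      E[P2 - dd] = k2 (-dd)    + k1 (2pq - dd),  dd = 4 pq a2
    where P1 indicates identical genotypes and P2 a homozygote-heterozygote
    pair sharing an allele. Loci are weighted by 1 / (2 a2 - a3).
    """
    p = 1.0 - q
    pq = p * q
    a2 = p**2 + q**2
    a3 = p**3 + q**3
    a4 = p**4 + q**4
    b = 2.0 * a2**2 - a4
    dd = 4.0 * pq * a2
    w = 1.0 / (2.0 * a2 - a3)

    # design coefficients per locus: rows (eq1, eq2) x cols (k2, k1)
    c11, c12 = 1.0 - b, a2 - b
    c21, c22 = -dd, 2.0 * pq - dd

    ident = (_S_SCORE == 1.0).astype(float)[:, None] * np.ones_like(q)[None, :]
    homhet = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0], float)[:, None] * np.ones_like(q)

    gi, gj, valid = _categories(values, pairs)
    idx = 3 * gi + gj
    # observation side: A^T W y, with y = (P1 - b, P2 - dd) per locus
    y1 = _gather(w * (c11 * (ident - b)), idx, valid) + _gather(
        w * (c21 * (homhet - dd)), idx, valid
    )
    y2 = _gather(w * (c12 * (ident - b)), idx, valid) + _gather(
        w * (c22 * (homhet - dd)), idx, valid
    )
    # normal matrix: A^T W A summed over the pair's non-missing loci
    m11 = (w * (c11**2 + c21**2))[None, :]
    m12 = (w * (c11 * c12 + c21 * c22))[None, :]
    m22 = (w * (c12**2 + c22**2))[None, :]
    M11 = np.where(valid, m11, 0.0).sum(axis=1)
    M12 = np.where(valid, m12, 0.0).sum(axis=1)
    M22 = np.where(valid, m22, 0.0).sum(axis=1)
    det = M11 * M22 - M12**2
    with np.errstate(invalid="ignore", divide="ignore"):
        k2 = (M22 * y1 - M12 * y2) / det
        k1 = (M11 * y2 - M12 * y1) / det
        r = k2 + 0.5 * k1
    return np.where((det != 0) & (valid.sum(axis=1) > 0), r, np.nan)


def _state_likelihoods(values, pairs, q):
    """Per-pair, per-locus likelihoods under IBD states 0, 1, 2."""
    p = 1.0 - q
    geno_p = np.stack([p**2, 2 * p * q, q**2])           # (3, L)
    l1 = np.empty((9, q.shape[0]))
    l1[0] = p**3
    l1[1] = l1[3] = p**2 * q
    l1[2] = l1[6] = 0.0
    l1[4] = p * q
    l1[5] = l1[7] = p * q**2
    l1[8] = q**3
    gi, gj, valid = _categories(values, pairs)
    cols = np.arange(q.shape[0])[None, :]
    safe_i = np.where(valid, gi, 0)
    safe_j = np.where(valid, gj, 0)
    L0 = geno_p[safe_i, cols] * geno_p[safe_j, cols]
    L1 = l1[3 * safe_i + safe_j, cols]
    L2 = np.where(gi == gj, geno_p[safe_i, cols], 0.0)
    out = np.stack([L0, L1, L2], axis=-1)                # (P, L, 3)
    return out, valid


def dyad_loglik(k: np.ndarray, state_lik: np.ndarray,
                valid: np.ndarray) -> np.ndarray:
    """Log-likelihood of dyads at IBD-state weights ``k`` ((P,3) or (3,))."""
    k = np.asarray(k, float)
    if k.ndim == 1:
        k = np.broadcast_to(k, (state_lik.shape[0], 3))
    mix = (state_lik * k[:, None, :]).sum(axis=-1)
    with np.errstate(divide="ignore"):
        ll = np.where(valid, np.log(np.maximum(mix, 1e-300)), 0.0)
    return ll.sum(axis=1)


def _dyadml(values, pairs, q, tol: float = 1e-6, max_iter: int = 2000):
    """EM over the IBD-state mixture weights; returns r = k2 + k1/2."""
    lik, valid = _state_likelihoods(values, pairs, q)
    P = lik.shape[0]
    k = np.full((P, 3), 1.0 / 3.0)
    counts = valid.sum(axis=1)
    ok = counts > 0
    active = np.arange(P)  # dyads whose EM has not yet converged
    for _ in range(max_iter):
        la = lik[active]
        ka = k[active]
        mix = (la * ka[:, None, :]).sum(axis=-1)
        resp = la * ka[:, None, :] / np.maximum(mix, 1e-300)[:, :, None]
        resp = np.where(valid[active][:, :, None], resp, 0.0)
        k_new = resp.sum(axis=1) / np.maximum(counts[active], 1)[:, None]
        delta = np.abs(k_new - ka).max(axis=1)
        k[active] = k_new
        active = active[delta >= tol]
        if active.size == 0:
            break
    r = k[:, 2] + 0.5 * k[:, 1]
    return np.where(ok, r, np.nan), k


_DISPATCH = {
    "quellergt": _quellergt,
    "lynchli": _lynchli,
    "lynchrd": _lynchrd,
    "ritland": _ritland,
    "wang_moment": _wang_moment,
}


def pairwise_relatedness(
    d: DosageMatrix,
    pairs: np.ndarray,
    estimator: str,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Relatedness for an array of sample-index pairs under one estimator.

    ``freqs`` is the per-locus reference minor-allele frequency; by default
    it is computed from the full sample (focal dyad included).
    """
    if estimator not in ESTIMATORS:
        raise KeyError(f"unknown estimator {estimator!r}")
    pairs = np.asarray(pairs, int)
    q = d.minor_freq() if freqs is None else np.asarray(freqs, float)
    _check_freqs(q)
    if estimator == "dyadml":
        r, _ = _dyadml(d.values, pairs, q)
        return r
    return _DISPATCH[estimator](d.values, pairs, q)


def estimate_pair(
    d: DosageMatrix,
    i,
    j,
    estimator: str,
    freqs: np.ndarray | None = None,
) -> float:
    """Relatedness of one dyad (indices or sample ids)."""
    if isinstance(i, str):
        i = d.sample_ids.index(i)
    if isinstance(j, str):
        j = d.sample_ids.index(j)
    if i == j:
        raise ValueError("a dyad needs two distinct samples")
    r = pairwise_relatedness(d, np.array([[i, j]]), estimator, freqs=freqs)
    val = float(r[0])
    if np.isnan(val):
        raise ValueError("dyad shares no typed loci")
    return val


def _all_pairs(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def relatedness_matrix(
    d: DosageMatrix, estimator: str, freqs: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric n x n relatedness matrix (nan diagonal)."""
    n = d.n_samples
    pairs = _all_pairs(n)
    r = pairwise_relatedness(d, pairs, estimator, freqs=freqs)
    out = np.full((n, n), np.nan)
    out[pairs[:, 0], pairs[:, 1]] = r
    out[pairs[:, 1], pairs[:, 0]] = r
    return out


def _classify(h1: str, h2: str) -> str:
    a, b = sorted((_HABITAT_CODE.get(h1, h1[0].upper()),
                   _HABITAT_CODE.get(h2, h2[0].upper())))
    return a + b


def coancestry_table(
    d: DosageMatrix,
    estimators=ESTIMATORS,
    freqs: np.ndarray | None = None,
) -> CoancestryTable:
    """All unordered pairs x requested estimators, with BB/LL/PP/BL/BP/LP
    classification from the habitat labels."""
    if d.n_samples < 2:
        raise ValueError("need at least two samples")
    pairs = _all_pairs(d.n_samples)
    data = {
        "sample_i": [d.sample_ids[i] for i in pairs[:, 0]],
        "sample_j": [d.sample_ids[j] for j in pairs[:, 1]],
        "classification": [
            _classify(d.habitat[i], d.habitat[j]) for i, j in pairs
        ],
    }
    est_list = list(estimators)
    for est in est_list:
        data[est] = pairwise_relatedness(d, pairs, est, freqs=freqs)
        n_nan = int(np.isnan(data[est]).sum())
        if n_nan:
            warnings.warn(
                f"{est}: {n_nan} dyads share no typed loci and were dropped",
                stacklevel=2,
            )
    return CoancestryTable(table=pd.DataFrame(data), estimators=est_list)


def permutation_test(
    d: DosageMatrix,
    groups,
    estimator: str,
    n_perm: int = 2500,
    family_alpha: float = 0.05,
    n_tests: int = 21,
    seed: int = 0,
    freqs: np.ndarray | None = None,
) -> list[PermutationTestResult]:
    """Test whether within-group mean relatedness exceeds the permutation null.

    Individuals are shuffled across groups with group sizes fixed; each
    permutation recomputes every group's mean within-group r from the
    precomputed pair matrix. One result per group.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = list(groups)
    labels = sorted(set(groups))
    sizes = {g: groups.count(g) for g in labels}
    if min(sizes.values()) < 2:
        raise ValueError("every group needs at least 2 members")
    R = relatedness_matrix(d, estimator, freqs=freqs)
    codes = np.array([labels.index(g) for g in groups])
    threshold = bonferroni_threshold(family_alpha, n_tests)

    def group_means(assign: np.ndarray) -> np.ndarray:
        out = np.empty(len(labels))
        for gidx in range(len(labels)):
            rows = np.flatnonzero(assign == gidx)
            sub = R[np.ix_(rows, rows)]
            iu = np.triu_indices(len(rows), k=1)
            out[gidx] = np.nanmean(sub[iu])
        return out

    observed = group_means(codes)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(labels)))
    for b in range(n_perm):
        null[b] = group_means(rng.permutation(codes))

    results = []
    for gidx, g in enumerate(labels):
        count = int((null[:, gidx] >= observed[gidx]).sum())
        results.append(
            PermutationTestResult(
                group=str(g),
                estimator=estimator,
                observed_mean=float(observed[gidx]),
                null_means=null[:, gidx].copy(),
                empirical_p=(count + 1) / (n_perm + 1),
                threshold=threshold,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results
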