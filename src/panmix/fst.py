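"""Weir & Cockerham (1984) variance-components Fst (theta).

Per locus, genotype data grouped into populations yield three variance
components: ``a`` (among populations), ``b`` (among individuals within
populations) and ``c`` (within individuals). The multi-locus estimate is the
ratio of sums theta = sum(a) / sum(a + b + c) — not the mean of per-locus
ratios. Individuals missing at a locus are dropped from that locus only, so
per-locus sample sizes vary; negative per-locus estimates are retained.

The estimator uses the unequal-sample-size formulation with
n_bar (mean group size), n_c (size variance correction), p_bar (weighted
mean allele frequency), s2 (weighted among-group variance of frequencies)
and h_bar (weighted mean observed heterozygote proportion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DosageMatrix

__all__ = ["WCComponents", "FstEstimate", "wc_components", "wc_overall",
           "wc_theta_matrix"]


@dataclass
class WCComponents:
    locus_id: str
    a: float
    b: float
    c: float
    n_pops: int
    pop_sizes: list[int]

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else float("nan")


@dataclass
class FstEstimate:
    theta_overall: float
    per_locus_theta: np.ndarray
    loci_used: list[str]


def _group_stats(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-group, per-locus call counts, dosage sums, het counts.

    values: (n, L) int dosages with -1 missing; codes: (n,) group indices.
    Returns (counts, sums, hets), each (n_groups, L).
    """
    n, L = values.shape
    ok = values >= 0
    counts = np.zeros((n_groups, L))
    sums = np.zeros((n_groups, L))
    hets = np.zeros((n_groups, L))
    for g in range(n_groups):
        rows = codes == g
        v = values[rows]
        m = ok[rows]
        counts[g] = m.sum(axis=0)
        sums[g] = np.where(m, v, 0).sum(axis=0)
        hets[g] = (v == 1).sum(axis=0)
    return counts, sums, hets


def wc_theta_matrix(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """Vectorized W&C components for every locus at once.

    Returns (a, b, c, r) arrays of shape (L,); loci where fewer than two
    groups have data, or with no variation, get a = b = c = 0 (they
    contribute nothing to either sum).
    """
    counts, sums, hets = _group_stats(values, codes, n_groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        present = counts > 0
        r = present.sum(axis=0).astype(float)  # groups with data per locus
        ntot = counts.sum(axis=0)
        nbar = ntot / np.maximum(r, 1)
        freq = np.where(present, sums / np.maximum(2 * counts, 1), 0.0)
        pbar = sums.sum(axis=0) / np.maximum(2 * ntot, 1)
        s2 = (counts * (freq - pbar) ** 2).sum(axis=0) / (
            np.maximum(r - 1, 1) * np.maximum(nbar, 1)
        )
        hbar = hets.sum(axis=0) / np.maximum(ntot, 1)
        nc = (ntot - (counts**2).sum(axis=0) / np.maximum(ntot, 1)) / np.maximum(
            r - 1, 1
        )
        pq = pbar * (1 - pbar)
        inner = pq - (r - 1) / r * s2
        a = (nbar / np.maximum(nc, 1e-300)) * (
            s2 - (inner - hbar / 4) / np.maximum(nbar - 1, 1e-300)
        )
        b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
            inner - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    # degenerate loci: <2 groups with data, n_bar <= 1, or monomorphic overall
    bad = (r < 2) | (nbar <= 1) | ((pq == 0) & (s2 == 0) & (hbar == 0))
    a = np.where(bad, 0.0, a)
    b = np.where(bad, 0.0, b)
    c = np.where(bad, 0.0, c)
    return a, b, c, r


def _codes(groups) -> tuple[np.ndarray, list]:
    labels = sorted(set(groups))
    lookup = {g: i for i, g in enumerate(labels)}
    return np.array([lookup[g] for g in groups]), labels


def wc_components(d: DosageMatrix, groups, locus_id: str) -> WCComponents:
    """Variance components for one locus (groups given per sample)."""
    if locus_id not in d.locus_ids:
        raise KeyError(f"unknown locus {locus_id!r}")
    j = d.locus_ids.index(locus_id)
    codes, labels = _codes(list(groups))
    col = d.values[:, [j]]
    counts, _, _ = _group_stats(col, codes, len(labels))
    with_data = counts[:, 0] > 0
    if with_data.sum() < 2:
        raise ValueError(
            f"locus {locus_id}: fewer than 2 groups with non-missing calls"
        )
    a, b, c, r = wc_theta_matrix(col, codes, len(labels))
    return WCComponents(
        locus_id=locus_id,
        a=float(a[0]),
        b=float(b[0]),
        c=float(c[0]),
        n_pops=int(r[0]),
        pop_sizes=[int(x) for x in counts[:, 0] if x > 0],
    )


def wc_overall(d: DosageMatrix, groups) -> FstEstimate:
    """Overall theta across loci as the ratio of summed components."""
    codes, labels = _codes(list(groups))
    a, b, c, _ = wc_theta_matrix(d.values, codes, len(labels))
    denom = a + b + c
    use = denom != 0
    if not use.any():
        raise ValueError("zero total denominator: no usable loci")
    theta = float(a[use].sum() / denom[use].sum())
    per_locus = np.full(d.n_loci, np.nan)
    per_locus[use] = a[use] / denom[use]
    return FstEstimate(
        theta_overall=theta,
        per_locus_theta=per_locus,
        loci_used=[l for l, u in zip(d.locus_ids, use) if u],
    )
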