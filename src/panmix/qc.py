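"""Per-locus QC: allele-frequency summaries, exact HWE tests, LD screening,
and the monomorphic/HWE filtering chain.

Summaries mirror the usual SNP-panel report: call count, major/minor allele
with frequencies, expected heterozygosity He = 2p(1-p), and an exact
Hardy-Weinberg P-value. The exact test is the conditional test on the
heterozygote count given the allele counts, with the two-sided
probability-ordering P (sum of probabilities of all configurations no more
probable than the observed one). Linkage is screened with the composite r^2:
the squared Pearson correlation of 0/1/2 dosage vectors over
pairwise-complete samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import DosageMatrix

__all__ = [
    "LocusSummary",
    "QCReport",
    "summarize_locus",
    "summarize_all",
    "mean_he",
    "hwe_exact_test",
    "pairwise_r2",
    "qc_filter",
]


@dataclass
class LocusSummary:
    locus_id: str
    linkage_group: int
    n_genotypes: int
    major_allele: str
    major_freq: float
    minor_allele: str
    minor_freq: float
    he: float
    hwe_p: float


@dataclass
class QCReport:
    """Record of the filtering chain: what went in, what was removed and why."""

    loci_in: list[str]
    monomorphic_removed: list[str]
    hwe_removed: list[tuple[str, float]]  # (locus_id, exact P)
    max_pairwise_r2: float
    loci_out: list[str]

    def to_dict(self) -> dict:
        return {
            "n_loci_in": len(self.loci_in),
            "monomorphic_removed": self.monomorphic_removed,
            "hwe_removed": [
                {"locus_id": l, "hwe_p": p} for l, p in self.hwe_removed
            ],
            "max_pairwise_r2": self.max_pairwise_r2,
            "loci_out": self.loci_out,
        }


def expected_heterozygosity(p: float) -> float:
    """He = 2p(1-p) for a biallelic locus; invariant to major/minor swap."""
    return 2.0 * p * (1.0 - p)


def summarize_locus(d: DosageMatrix, locus_id: str) -> LocusSummary:
    """Table-style summary of one locus from its non-missing calls."""
    if locus_id not in d.locus_ids:
        raise KeyError(f"unknown locus {locus_id!r}")
    j = d.locus_ids.index(locus_id)
    col = d.values[:, j]
    ok = col >= 0
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"locus {locus_id}: no non-missing calls")
    q = float(col[ok].sum()) / (2.0 * n)  # minor-allele frequency
    n_het = int((col[ok] == 1).sum())
    n_hom_minor = int((col[ok] == 2).sum())
    return LocusSummary(
        locus_id=locus_id,
        linkage_group=d.linkage_group[j],
        n_genotypes=n,
        major_allele=d.major_allele[j],
        major_freq=1.0 - q,
        minor_allele=d.minor_allele[j],
        minor_freq=q,
        he=expected_heterozygosity(q),
        hwe_p=hwe_exact_test(n - n_het - n_hom_minor, n_het, n_hom_minor),
    )


def summarize_all(d: DosageMatrix) -> list[LocusSummary]:
    return [summarize_locus(d, l) for l in d.locus_ids]


def mean_he(summaries: list[LocusSummary]) -> float:
    """Arithmetic mean expected heterozygosity over loci."""
    if not summaries:
        raise ValueError("empty summary list")
    return float(np.mean([s.he for s in summaries]))


def _log_hwe_prob(n_het: int, n: int, n_minor: int) -> float:
    """Log probability of n_het heterozygotes given n diploids and n_minor
    minor-allele copies, under the conditional HWE distribution."""
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = n - n_het - n_hom_minor
    n_major = 2 * n - n_minor
    return (
        gammaln(n + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(n_hom_major + 1)
        + n_het * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional HWE test for a biallelic locus.

    Given the genotype counts, conditions on the observed allele counts and
    sums, over all possible heterozygote counts of the right parity, the
    probabilities of configurations whose probability does not exceed the
    observed one (two-sided, probability ordering).
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("all genotype counts zero")
    n_minor = n_het + 2 * n_hom_minor
    n_minor = min(n_minor, 2 * n - n_minor)  # symmetry: use the rarer allele
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) // 2 + hets <= n]
    logp = np.array([_log_hwe_prob(int(h), n, n_minor) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    # tolerate float ties when summing "no more probable" configurations
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def pairwise_r2(d: DosageMatrix) -> np.ndarray:
    """Composite-LD matrix: squared Pearson correlation of dosage vectors.

    Uses pairwise-complete samples per locus pair; diagonal is 1. A pair with
    fewer than two jointly typed samples, or with a constant dosage vector on
    the joint support, raises ValueError.
    """
    L = d.n_loci
    if L < 2:
        raise ValueError("need at least two loci")
    out = np.ones((L, L))
    vals = d.values
    for a in range(L):
        for b in range(a + 1, L):
            ok = (vals[:, a] >= 0) & (vals[:, b] >= 0)
            if ok.sum() < 2:
                raise ValueError(
                    f"loci {d.locus_ids[a]}/{d.locus_ids[b]}: "
                    "<2 jointly typed samples"
                )
            x = vals[ok, a].astype(float)
            y = vals[ok, b].astype(float)
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                # a rare allele can vanish on the joint support; no
                # correlation is estimable, which is no linkage evidence
                out[a, b] = out[b, a] = 0.0
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            out[a, b] = out[b, a] = r * r
    return out


def qc_filter(
    d: DosageMatrix, hwe_alpha: float = 0.001
) -> tuple[DosageMatrix, QCReport]:
    """Apply the filtering chain: drop monomorphic loci, then loci whose
    exact HWE P falls below ``hwe_alpha``; report every removal and the
    maximum pairwise r^2 among survivors."""
    mono, hwe_removed, keep = [], [], []
    for j, lid in enumerate(d.locus_ids):
        col = d.values[:, j]
        ok = col >= 0
        if ok.sum() == 0 or col[ok].sum() == 0:
            mono.append(lid)
            continue
        s = summarize_locus(d, lid)
        if s.hwe_p < hwe_alpha:
            hwe_removed.append((lid, s.hwe_p))
        else:
            keep.append(j)
    if not keep:
        raise ValueError("all loci removed by QC")
    filtered = d.subset(loci=keep)
    max_r2 = 0.0
    if filtered.n_loci >= 2:
        r2 = pairwise_r2(filtered)
        iu = np.triu_indices(filtered.n_loci, k=1)
        max_r2 = float(r2[iu].max())
    report = QCReport(
        loci_in=list(d.locus_ids),
        monomorphic_removed=mono,
        hwe_removed=hwe_removed,
        max_pairwise_r2=max_r2,
        loci_out=list(filtered.locus_ids),
    )
    return filtered, report
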