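"""Locus QC: summaries, exact HWE testing against an enumeration oracle,
composite LD, and the filtering chain."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import panmix
from panmix.qc import (
    expected_heterozygosity,
    hwe_exact_test,
    mean_he,
    pairwise_r2,
    qc_filter,
    summarize_all,
    summarize_locus,
)
from panmix.synthetic import GeneratorSpec, generate


def hwe_enumeration_oracle(n_hom_major, n_het, n_hom_minor):
    """Exact-arithmetic enumeration of the conditional HWE distribution.

    Probability of h heterozygotes given n diploids and the allele counts is
    proportional to 2**h * n! / (hom_major! h! hom_minor!); the two-sided P
    sums configurations no more probable than the observed one.
    """
    n = n_hom_major + n_het + n_hom_minor
    n_minor = n_het + 2 * n_hom_minor
    n_minor = min(n_minor, 2 * n - n_minor)
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hm = (n_minor - h) // 2
        hM = n - h - hm
        if hM < 0:
            continue
        weights[h] = Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(hm) * math.factorial(hM),
        )
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHweExactTest:
    def test_modal_configuration_has_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_single_genotype_only_configuration(self):
        assert hwe_exact_test(1, 0, 0) == 1.0

    def test_all_heterozygotes_matches_oracle(self):
        for n in (5, 8, 12):
            p = hwe_exact_test(0, n, 0)
            assert p == pytest.approx(hwe_enumeration_oracle(0, n, 0),
                                      rel=1e-9)
            assert p < 0.2  # heterozygote excess is unlikely under HWE

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 0)

    def test_exhaustive_agreement_with_enumeration(self):
        # every genotype configuration with n <= 30 individuals
        for n in range(1, 31, 3):
            for n_het in range(n + 1):
                for n_hom_minor in range(n - n_het + 1):
                    n_hom_major = n - n_het - n_hom_minor
                    got = hwe_exact_test(n_hom_major, n_het, n_hom_minor)
                    want = hwe_enumeration_oracle(
                        n_hom_major, n_het, n_hom_minor)
                    assert got == pytest.approx(want, rel=1e-8), (
                        n_hom_major, n_het, n_hom_minor)

    def test_conservative_under_null(self):
        # exact tests reject at most ~alpha under HWE data
        rng = np.random.default_rng(42)
        rejections = 0
        n_loci = 2000
        for _ in range(n_loci):
            q = rng.uniform(0.05, 0.5)
            g = rng.binomial(2, q, size=159)
            p = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()),
                               int((g == 2).sum()))
            rejections += p < 0.05
        assert rejections / n_loci <= 0.06


class TestSummaries:
    def test_he_values(self):
        assert expected_heterozygosity(0.05) == pytest.approx(0.095)
        assert expected_heterozygosity(0.5) == pytest.approx(0.5)
        assert expected_heterozygosity(0.0) == 0.0

    def test_he_invariant_to_label_swap(self):
        for p in (0.1, 0.35, 0.72):
            assert expected_heterozygosity(p) == pytest.approx(
                expected_heterozygosity(1 - p))

    def test_summary_counts_missing(self, panel):
        table, _ = generate(GeneratorSpec(mode="panmictic", seed=3,
                                          match_missingness=True))
        d = panmix.to_dosage(table)
        s = summarize_locus(d, "13903")
        assert s.n_genotypes == panel["13903"].n_genotypes  # 150 of 159
        assert s.major_freq + s.minor_freq == pytest.approx(1.0)
        with pytest.raises(KeyError):
            summarize_locus(d, "nope")

    def test_mean_he(self, panmictic_dosage):
        summaries = summarize_all(panmictic_dosage)
        assert mean_he(summaries) == pytest.approx(
            np.mean([s.he for s in summaries]))
        assert mean_he(summaries[:1]) == summaries[0].he
        with pytest.raises(ValueError):
            mean_he([])


class TestPairwiseR2:
    def test_duplicated_locus_r2_one(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, size=60).astype(np.int8)
        table, _ = generate(GeneratorSpec(mode="panmictic", seed=1))
        d = panmix.to_dosage(table).subset(loci=[0, 1])
        d.values[:60, 0] = g[:60]
        d.values[:, 1] = d.values[:, 0]
        r2 = pairwise_r2(d)
        assert r2[0, 1] == pytest.approx(1.0)

    def test_complement_locus_r2_one(self, panmictic_dosage):
        d = panmictic_dosage.subset(loci=[3, 4])
        d.values[:, 1] = 2 - d.values[:, 0]
        assert pairwise_r2(d)[0, 1] == pytest.approx(1.0)

    def test_independent_loci_match_permutation_null(self, panmictic_dosage):
        d = panmictic_dosage
        observed = pairwise_r2(d)
        iu = np.triu_indices(d.n_loci, k=1)
        obs_vals = observed[iu]
        # permutation oracle: shuffle one locus against another repeatedly
        rng = np.random.default_rng(5)
        null = []
        x = d.values[:, 5].astype(float)
        y = d.values[:, 9].astype(float)
        for _ in range(600):
            null.append(np.corrcoef(x, rng.permutation(y))[0, 1] ** 2)
        ks = stats.ks_2samp(obs_vals, null)
        assert ks.pvalue > 0.01
        # unlinked loci: even the largest of ~500 pairwise r2 stays small
        assert obs_vals.max() < 0.25


class TestQcFilter:
    def test_study_filtering_chain(self):
        # 55 loci -> remove 22 monomorphic -> remove 1 HWE violation -> 32
        table, truth = generate(GeneratorSpec(mode="qc_fixture", seed=2))
        d = panmix.to_dosage(table)
        filtered, report = qc_filter(d)
        assert len(report.loci_in) == 55
        assert len(report.monomorphic_removed) == 22
        assert len(report.hwe_removed) == 1
        assert report.hwe_removed[0][0] == f"Q{truth['hwe_violation_locus']:04d}"
        assert report.hwe_removed[0][1] < 1e-10
        assert len(report.loci_out) == 32
        assert filtered.n_loci == 32
        # survivors are polymorphic and in HWE
        assert (filtered.minor_freq() > 0).all()
        for locus in filtered.locus_ids:
            assert summarize_locus(filtered, locus).hwe_p >= 0.001

    def test_clean_panel_untouched(self, panmictic_dosage):
        filtered, report = qc_filter(panmictic_dosage)
        # the generator may fix ultra-rare alleles by chance; everything
        # retained must be exactly the non-monomorphic input loci
        assert report.hwe_removed == []
        assert report.loci_out == [
            l for l, q in zip(panmictic_dosage.locus_ids,
                              panmictic_dosage.minor_freq()) if q > 0
        ]

    def test_zero_alpha_removes_only_monomorphic(self):
        table, _ = generate(GeneratorSpec(mode="qc_fixture", seed=4))
        d = panmix.to_dosage(table)
        filtered, report = qc_filter(d, hwe_alpha=0.0)
        assert len(report.monomorphic_removed) == 22
        assert report.hwe_removed == []
        assert filtered.n_loci == 33
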