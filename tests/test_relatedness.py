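"""Pairwise coancestry estimators: recovery of pedigree truth, symmetry and
invariance properties, the dyadic-ML likelihood guarantee, and the
permutation group test."""

import numpy as np
import pytest
from scipy import stats

import panmix
from panmix.relatedness import (
    ESTIMATORS,
    bonferroni_threshold,
    coancestry_table,
    dyad_loglik,
    estimate_pair,
    pairwise_relatedness,
    permutation_test,
    relatedness_matrix,
    _dyadml,
    _state_likelihoods,
)
from panmix.synthetic import GeneratorSpec, generate

MOMENT_ESTIMATORS = ("quellergt", "lynchli", "lynchrd", "ritland",
                     "wang_moment")


def _dyads(relationship, n_dyads=500, seed=5):
    table, truth = generate(GeneratorSpec(
        mode="pedigree_dyads", relationship=relationship,
        n_dyads=n_dyads, seed=seed))
    d = panmix.to_dosage(table)
    return d, np.asarray(truth["pairs"]), truth


class TestRecovery:
    @pytest.mark.parametrize("estimator", MOMENT_ESTIMATORS + ("dyadml",))
    def test_parent_offspring_mean_half(self, estimator):
        d, pairs, _ = _dyads("parent_offspring")
        r = pairwise_relatedness(d, pairs, estimator)
        assert float(np.nanmean(r)) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("estimator", MOMENT_ESTIMATORS)
    def test_unrelated_mean_zero(self, estimator):
        d, pairs, _ = _dyads("unrelated")
        r = pairwise_relatedness(d, pairs, estimator)
        assert float(np.nanmean(r)) == pytest.approx(0.0, abs=0.02)

    def test_dyadml_unrelated_nonnegative_bias(self):
        # estimators constrained to [0,1] cannot average to zero on
        # unrelated dyads; the bias is upward by construction
        d, pairs, _ = _dyads("unrelated")
        r = pairwise_relatedness(d, pairs, "dyadml")
        assert np.nanmean(r) >= 0.0
        assert np.nanmin(r) >= 0.0 and np.nanmax(r) <= 1.0

    def test_full_sib_mean_half(self):
        d, pairs, _ = _dyads("full_sib", n_dyads=300, seed=6)
        r = pairwise_relatedness(d, pairs, "quellergt")
        assert float(np.nanmean(r)) == pytest.approx(0.5, abs=0.04)

    def test_duplicate_individual_r_one(self, panmictic_dosage):
        d = panmictic_dosage.subset(samples=[0, 0])
        d.sample_ids = ["orig", "copy"]
        assert estimate_pair(d, 0, 1, "quellergt",
                             freqs=panmictic_dosage.minor_freq()) == (
            pytest.approx(1.0))


class TestProperties:
    @pytest.mark.parametrize("estimator", ESTIMATORS)
    def test_symmetric_in_dyad_order(self, panmictic_dosage, estimator):
        pairs = np.array([[0, 5], [3, 17], [40, 99]])
        fwd = pairwise_relatedness(panmictic_dosage, pairs, estimator)
        rev = pairwise_relatedness(panmictic_dosage, pairs[:, ::-1], estimator)
        assert np.allclose(fwd, rev, atol=1e-9)

    @pytest.mark.parametrize("estimator", ESTIMATORS)
    def test_invariant_to_locus_order_and_allele_labels(
            self, panmictic_dosage, estimator):
        d = panmictic_dosage
        pairs = np.array([[1, 2], [10, 20]])
        q = d.minor_freq()
        base = pairwise_relatedness(d, pairs, estimator, freqs=q)
        perm = np.random.default_rng(0).permutation(d.n_loci)
        shuffled = d.subset(loci=perm)
        assert np.allclose(
            pairwise_relatedness(shuffled, pairs, estimator, freqs=q[perm]),
            base, atol=1e-8)
        flipped = d.subset()
        qf = q.copy()
        for j in range(0, d.n_loci, 2):
            col = flipped.values[:, j]
            flipped.values[:, j] = np.where(col >= 0, 2 - col, -1)
            qf[j] = 1 - qf[j]
        assert np.allclose(
            pairwise_relatedness(flipped, pairs, estimator, freqs=qf),
            base, atol=1e-8)

    def test_dyadml_beats_vertex_likelihoods(self, panmictic_dosage):
        d = panmictic_dosage
        pairs = np.array([[i, i + 1] for i in range(0, 40, 2)])
        q = d.minor_freq()
        _, k = _dyadml(d.values, pairs, q)
        lik, valid = _state_likelihoods(d.values, pairs, q)
        at_mle = dyad_loglik(k, lik, valid)
        for vertex in ([1, 0, 0], [0, 1, 0], [0, 0, 1]):
            at_vertex = dyad_loglik(np.array(vertex, float), lik, valid)
            # slack covers the EM stopping rule when the optimum sits on a
            # simplex vertex and the last geometric steps are truncated
            assert np.all(at_mle >= at_vertex - 1e-3)

    def test_unknown_estimator_and_bad_freqs(self, panmictic_dosage):
        with pytest.raises(KeyError):
            pairwise_relatedness(panmictic_dosage, [[0, 1]], "wang2007")
        bad_q = panmictic_dosage.minor_freq().copy()
        bad_q[0] = 0.0
        with pytest.raises(ValueError):
            pairwise_relatedness(panmictic_dosage, [[0, 1]], "quellergt",
                                 freqs=bad_q)

    def test_no_shared_loci_error(self):
        table, _ = generate(GeneratorSpec(mode="panmictic", seed=9))
        d = panmix.to_dosage(table)
        d.values[0, :] = -1
        d.values[0, 0] = 1
        d.values[1, :] = -1
        d.values[1, 1] = 1
        with pytest.raises(ValueError):
            estimate_pair(d, 0, 1, "quellergt")


class TestCoancestryTable:
    def test_pair_combinatorics_and_classes(self, panmictic_dosage):
        ct = coancestry_table(panmictic_dosage, estimators=("quellergt",))
        assert len(ct.table) == 159 * 158 // 2 == 12561
        counts = ct.table["classification"].value_counts()
        assert counts["BB"] == 55 * 54 // 2
        assert counts["LL"] == 55 * 54 // 2
        assert counts["PP"] == 49 * 48 // 2
        assert counts["BL"] == 55 * 55
        assert counts["BP"] == counts["LP"] == 55 * 49

    def test_within_between_indistinguishable_under_panmixia(
            self, panmictic_dosage):
        ct = coancestry_table(panmictic_dosage,
                              estimators=("quellergt", "ritland"))
        cls = ct.table["classification"]
        within = cls.isin(["BB", "LL", "PP"])
        for est in ("quellergt", "ritland"):
            ks = stats.ks_2samp(ct.table[est][within],
                                ct.table[est][~within])
            assert ks.pvalue > 0.01

    def test_planted_sib_trio_visible_in_group(self, panmictic_dosage):
        from panmix.synthetic import sibship
        d = panmictic_dosage.subset()
        fam, _ = sibship(3, seed=12)
        d.values[:3] = panmix.to_dosage(fam).values
        ct = coancestry_table(d, estimators=("quellergt",))
        bb = ct.table[ct.table["classification"] == "BB"]["quellergt"]
        assert bb.max() > 0.35  # the family pairs stand out in their group


class TestPermutationTest:
    def test_panmictic_groups_not_significant(self, panmictic_dosage):
        for res in permutation_test(panmictic_dosage,
                                    panmictic_dosage.habitat,
                                    "quellergt", n_perm=500, seed=1):
            assert res.empirical_p > res.threshold
            assert len(res.null_means) == 500

    def test_planted_sibship_detected(self):
        # replace the benthic group with one full-sib family
        from panmix.synthetic import sibship
        table, _ = generate(GeneratorSpec(mode="panmictic", seed=30))
        d = panmix.to_dosage(table)
        fam, _ = sibship(55, seed=31)
        d.values[:55] = panmix.to_dosage(fam).values
        d = d.subset(loci=np.flatnonzero(d.minor_freq() > 0))
        results = {res.group: res for res in permutation_test(
            d, d.habitat, "quellergt", n_perm=2500, seed=32)}
        assert results["benthic"].empirical_p < bonferroni_threshold(0.05, 21)
        assert results["pelagic"].empirical_p > 0.002

    def test_single_permutation_degenerate(self, panmictic_dosage):
        for res in permutation_test(panmictic_dosage,
                                    panmictic_dosage.habitat,
                                    "quellergt", n_perm=1, seed=2):
            assert res.empirical_p in (0.5, 1.0)

    def test_null_concentrates_around_grand_mean(self, panmictic_dosage):
        R = relatedness_matrix(panmictic_dosage, "quellergt")
        grand = np.nanmean(R)
        res = permutation_test(panmictic_dosage, panmictic_dosage.habitat,
                               "quellergt", n_perm=300, seed=3)[0]
        assert res.null_means.mean() == pytest.approx(grand, abs=0.01)

    def test_group_too_small(self, panmictic_dosage):
        labels = ["littoral"] * 158 + ["pelagic"]
        with pytest.raises(ValueError):
            permutation_test(panmictic_dosage, labels, "quellergt",
                             n_perm=10)


def test_bonferroni_threshold_values():
    assert bonferroni_threshold(0.05, 21) == pytest.approx(0.00238, abs=5e-5)
    assert round(bonferroni_threshold(0.05, 21), 3) == 0.002
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.01, 10) == pytest.approx(0.001)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
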