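"""Weir-Cockerham theta: component correctness against a scalar oracle,
boundary cases, ratio-of-sums combination, and invariances."""

import numpy as np
import pytest

import panmix
from panmix.fst import wc_components, wc_overall, wc_theta_matrix
from panmix.io import DosageMatrix
from panmix.synthetic import GeneratorSpec, generate


def wc_oracle_single_locus(dosages_by_group):
    """Independent scalar transliteration of the variance-component formulas
    (explicit loops, no vectorization) for one biallelic locus.

    dosages_by_group: list of 1-D arrays of 0/1/2 dosages (missing removed).
    Returns (a, b, c).
    """
    groups = [np.asarray(g, float) for g in dosages_by_group if len(g) > 0]
    r = len(groups)
    sizes = [len(g) for g in groups]
    nbar = sum(sizes) / r
    nc = (sum(sizes) - sum(s * s for s in sizes) / sum(sizes)) / (r - 1)
    freqs = [g.sum() / (2 * len(g)) for g in groups]
    pbar = sum(s * p for s, p in zip(sizes, freqs)) / sum(sizes)
    s2 = sum(s * (p - pbar) ** 2 for s, p in zip(sizes, freqs)) / (
        (r - 1) * nbar
    )
    hets = [(g == 1).mean() for g in groups]
    hbar = sum(s * h for s, h in zip(sizes, hets)) / sum(sizes)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def _dosage(values, habitat=None):
    values = np.asarray(values, dtype=np.int8)
    n, L = values.shape
    return DosageMatrix(
        values=values,
        minor_allele=["G"] * L,
        major_allele=["A"] * L,
        sample_ids=[f"s{i}" for i in range(n)],
        habitat=habitat or ["littoral"] * n,
        batch=[1] * n,
        locus_ids=[f"L{j}" for j in range(L)],
        linkage_group=[0] * L,
    )


class TestComponents:
    def test_fixed_opposite_groups_theta_one(self):
        values = np.vstack([np.zeros((50, 1)), np.full((50, 1), 2)])
        d = _dosage(values)
        groups = ["a"] * 50 + ["b"] * 50
        comp = wc_components(d, groups, "L0")
        assert comp.theta == pytest.approx(1.0)
        assert comp.n_pops == 2 and comp.pop_sizes == [50, 50]

    def test_duplicated_group_no_differentiation(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=(40, 6))
        d = _dosage(np.vstack([g, g]))
        groups = ["a"] * 40 + ["b"] * 40
        est = wc_overall(d, groups)
        assert est.theta_overall <= 0.0 + 1e-12
        assert abs(est.theta_overall) < 0.05

    def test_six_individual_hand_case_matches_oracle(self):
        # genotypes: group1 = {0,1,2}, group2 = {1,1,0}
        d = _dosage(np.array([[0], [1], [2], [1], [1], [0]]))
        groups = ["x", "x", "x", "y", "y", "y"]
        comp = wc_components(d, groups, "L0")
        a, b, c = wc_oracle_single_locus([[0, 1, 2], [1, 1, 0]])
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.b == pytest.approx(b, abs=1e-12)
        assert comp.c == pytest.approx(c, abs=1e-12)

    def test_random_datasets_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sizes = rng.integers(3, 15, size=rng.integers(2, 5))
            q = rng.uniform(0.1, 0.9)
            parts = [rng.binomial(2, q + rng.uniform(-0.05, 0.05), size=s)
                     for s in sizes]
            values = np.concatenate(parts)[:, None]
            codes = np.concatenate(
                [np.full(s, i) for i, s in enumerate(sizes)])
            a, b, c, _ = wc_theta_matrix(values, codes, len(sizes))
            ao, bo, co = wc_oracle_single_locus(parts)
            assert a[0] == pytest.approx(ao, abs=1e-10)
            assert b[0] == pytest.approx(bo, abs=1e-10)
            assert c[0] == pytest.approx(co, abs=1e-10)

    def test_missing_dropped_per_locus(self):
        values = np.array([[0, 0], [1, -1], [2, 2], [1, 1]], dtype=np.int8)
        d = _dosage(values)
        groups = ["a", "a", "b", "b"]
        comp = wc_components(d, groups, "L1")
        a, b, c = wc_oracle_single_locus([[0], [2, 1]])
        assert comp.a == pytest.approx(a, abs=1e-12)

    def test_fewer_than_two_groups_with_data(self):
        values = np.array([[0], [1], [-1], [-1]], dtype=np.int8)
        d = _dosage(values)
        with pytest.raises(ValueError):
            wc_components(d, ["a", "a", "b", "b"], "L0")


class TestOverall:
    def test_ratio_of_sums_not_mean_of_ratios(self):
        # locus 1 strongly differentiated, locus 2 nearly panmictic with a
        # big denominator: the two combination rules disagree
        rng = np.random.default_rng(3)
        l1 = np.concatenate([np.zeros(30), np.full(30, 2)])
        l2 = rng.binomial(2, 0.5, size=60)
        d = _dosage(np.column_stack([l1, l2]))
        groups = ["a"] * 30 + ["b"] * 30
        est = wc_overall(d, groups)
        a, b, c, _ = wc_theta_matrix(d.values, np.array([0] * 30 + [1] * 30), 2)
        ratio_of_sums = a.sum() / (a + b + c).sum()
        mean_of_ratios = np.mean(a / (a + b + c))
        assert abs(ratio_of_sums - mean_of_ratios) > 0.01
        assert est.theta_overall == pytest.approx(ratio_of_sums)

    def test_panmictic_theta_near_zero(self, panmictic_dosage):
        est = wc_overall(panmictic_dosage, panmictic_dosage.habitat)
        assert abs(est.theta_overall) < 0.01

    def test_parameter_recovery_island_structure(self):
        table, _ = generate(GeneratorSpec(
            mode="balding_nichols", fst=0.1, group_sizes=(500, 500, 500),
            n_loci=300, seed=3))
        d = panmix.to_dosage(table)
        est = wc_overall(d, d.habitat)
        assert est.theta_overall == pytest.approx(0.1, abs=0.01)

    def test_label_permutation_destroys_structure(self):
        table, _ = generate(GeneratorSpec(
            mode="balding_nichols", fst=0.1, seed=5))
        d = panmix.to_dosage(table)
        rng = np.random.default_rng(9)
        perm_thetas = [
            wc_overall(d, rng.permutation(d.habitat)).theta_overall
            for _ in range(30)
        ]
        assert abs(np.mean(perm_thetas)) < 0.01
        assert wc_overall(d, d.habitat).theta_overall > 0.05

    def test_invariances(self, panmictic_dosage):
        d = panmictic_dosage
        base = wc_overall(d, d.habitat).theta_overall
        # allele relabeling: flip dosages at half the loci
        flipped = d.subset()
        for j in range(0, d.n_loci, 2):
            col = flipped.values[:, j]
            flipped.values[:, j] = np.where(col >= 0, 2 - col, -1)
        assert wc_overall(flipped, d.habitat).theta_overall == pytest.approx(
            base, abs=1e-12)
        # locus order
        perm = np.random.default_rng(2).permutation(d.n_loci)
        assert wc_overall(d.subset(loci=perm),
                          d.habitat).theta_overall == pytest.approx(base)

    def test_zero_denominator_error(self):
        d = _dosage(np.zeros((6, 2)))
        with pytest.raises(ValueError):
            wc_overall(d, ["a", "a", "a", "b", "b", "b"])
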