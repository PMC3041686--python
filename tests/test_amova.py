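"""AMOVA decomposition against hand computation and a brute-force oracle,
plus permutation-test behaviour."""

import itertools
import math

import numpy as np
import pytest

from sporesort import (
    AlignedSequenceSet,
    DistanceMatrix,
    NoVarianceError,
    amova_components,
    amova_permutation_test,
    gen_structured_sequences,
    pairwise_difference_matrix,
)
from sporesort.synthetic import SeqGenConfig


def brute_force_amova(d2, labels):
    """Independent plain-loop implementation of the two-level decomposition."""
    n = len(labels)
    pops = sorted(set(labels))
    p = len(pops)
    ssd_total = sum(d2[i][j] for i in range(n) for j in range(n)) / (2 * n)
    ssd_within = 0.0
    sizes = []
    for pop in pops:
        idx = [i for i in range(n) if labels[i] == pop]
        sizes.append(len(idx))
        ssd_within += sum(d2[i][j] for i in idx for j in idx) / (2 * len(idx))
    ssd_among = ssd_total - ssd_within
    ms_among = ssd_among / (p - 1)
    ms_within = ssd_within / (n - p)
    n0 = (n - sum(s * s for s in sizes) / n) / (p - 1)
    s2_within = ms_within
    s2_among = (ms_among - ms_within) / n0
    return ssd_total, ssd_within, ssd_among, s2_among, s2_within


def fixed_difference_matrix(k=4.0):
    """Two populations of two identical haplotypes, every cross pair k apart."""
    values = np.zeros((4, 4))
    for i in (0, 1):
        for j in (2, 3):
            values[i, j] = values[j, i] = k
    dm = DistanceMatrix(ids=["s1", "s2", "s3", "s4"], values=values)
    pops = {"s1": "p1", "s2": "p1", "s3": "p2", "s4": "p2"}
    return dm, pops


class TestComponents:
    def test_zero_variance_error(self):
        dm = DistanceMatrix(ids=list("abcd"), values=np.zeros((4, 4)))
        pops = {"a": "p1", "b": "p1", "c": "p2", "d": "p2"}
        with pytest.raises(NoVarianceError):
            amova_components(dm, pops)

    def test_fixed_difference_hand_derivation(self):
        """SSD_total = k, SSD_within = 0, sigma2_among = k/2, 100% among."""
        k = 4.0
        dm, pops = fixed_difference_matrix(k)
        res = amova_components(dm, pops)
        # 8 ordered cross pairs of delta2=k over 2N=8 -> SSD_total = k
        assert res.ssd_total == pytest.approx(k)
        assert res.ssd_within == pytest.approx(0.0)
        assert res.sigma2_within == pytest.approx(0.0)
        assert res.sigma2_among == pytest.approx(k / 2)
        assert res.pct_among == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(10):
            raw = rng.integers(0, 6, size=(8, 8)).astype(float)
            d2 = np.triu(raw, 1)
            d2 = d2 + d2.T
            if not d2.any():
                continue
            labels = ["p1"] * 3 + ["p2"] * 5
            dm = DistanceMatrix(ids=[f"s{i}" for i in range(8)], values=d2)
            res = amova_components(dm, dict(zip(dm.ids, labels)))
            exp = brute_force_amova(d2.tolist(), labels)
            assert res.ssd_total == pytest.approx(exp[0], abs=1e-9)
            assert res.ssd_within == pytest.approx(exp[1], abs=1e-9)
            assert res.ssd_among == pytest.approx(exp[2], abs=1e-9)
            if exp[3] >= 0:
                assert res.sigma2_among == pytest.approx(exp[3], abs=1e-9)
            else:
                assert res.sigma2_among == 0.0 and res.clamped
            assert res.sigma2_within == pytest.approx(exp[4], abs=1e-9)
            assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)

    def test_invariance_to_relabeling_and_reordering(self, rng):
        raw = rng.random((6, 6))
        d2 = np.triu(raw, 1)
        d2 = d2 + d2.T
        ids = [f"s{i}" for i in range(6)]
        pops = {"s0": "x", "s1": "x", "s2": "x", "s3": "y", "s4": "y", "s5": "y"}
        res1 = amova_components(DistanceMatrix(ids=ids, values=d2), pops)
        order = [5, 2, 0, 4, 1, 3]
        dm2 = DistanceMatrix(
            ids=[ids[k] for k in order], values=d2[np.ix_(order, order)]
        )
        renamed = {i: {"x": "north", "y": "south"}[pops[i]] for i in ids}
        res2 = amova_components(dm2, renamed)
        assert res2.phi_st == pytest.approx(res1.phi_st, abs=1e-12)
        assert res2.ssd_within == pytest.approx(res1.ssd_within, abs=1e-12)

    def test_pct_among_monotone_in_between_population_shift(self):
        values = np.zeros((4, 4))
        rng = np.random.default_rng(7)
        raw = rng.random((4, 4))
        base = np.triu(raw, 1)
        base = base + base.T
        pops = {"s1": "p1", "s2": "p1", "s3": "p2", "s4": "p2"}
        pcts = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            d2 = base.copy()
            for i in (0, 1):
                for j in (2, 3):
                    d2[i, j] += shift
                    d2[j, i] += shift
            dm = DistanceMatrix(ids=["s1", "s2", "s3", "s4"], values=d2)
            pcts.append(amova_components(dm, pops).pct_among)
        assert pcts == sorted(pcts) and pcts[0] < pcts[-1]

    def test_clonal_duplicate_across_populations_clamps_to_zero(self):
        """Same haplotype pool in both populations: Phi_ST = 0 after clamping."""
        seqs = AlignedSequenceSet(
            ids=["a1", "a2", "b1", "b2"],
            sequences=["AAAA", "TTTT", "AAAA", "TTTT"],
        )
        dm = pairwise_difference_matrix(seqs)
        res = amova_components(dm, {"a1": "p1", "a2": "p1", "b1": "p2", "b2": "p2"})
        assert res.phi_st == 0.0
        assert res.clamped


class TestPermutationTest:
    def test_determinism(self):
        dm, pops = fixed_difference_matrix()
        p1 = amova_permutation_test(dm, pops, n_permutations=99, seed=5).p_value
        p2 = amova_permutation_test(dm, pops, n_permutations=99, seed=5).p_value
        assert p1 == p2

    def test_invalid_permutation_count(self):
        dm, pops = fixed_difference_matrix()
        with pytest.raises(ValueError):
            amova_permutation_test(dm, pops, n_permutations=0)

    def test_small_fixed_difference_p_matches_enumeration(self):
        """With N=4 (2+2), exactly 2 of the 6 distinct labelings reach the
        observed Phi, so the permutation p must converge to ~1/3 — the
        minimum attainable for this design."""
        dm, pops = fixed_difference_matrix()
        res = amova_permutation_test(dm, pops, n_permutations=1023, seed=11)
        assert res.p_value == pytest.approx(1 / 3, abs=0.05)

    def test_extreme_phi_significant_with_enough_individuals(self):
        """Fixed differences between two populations of 10: only 2 of
        C(20,10) labelings are as extreme, so p <= 0.05."""
        n_per = 10
        values = np.zeros((2 * n_per, 2 * n_per))
        values[:n_per, n_per:] = 5.0
        values[n_per:, :n_per] = 5.0
        ids = [f"s{i}" for i in range(2 * n_per)]
        pops = {i: ("p1" if k < n_per else "p2") for k, i in enumerate(ids)}
        res = amova_permutation_test(
            DistanceMatrix(ids=ids, values=values), pops,
            n_permutations=1023, seed=3,
        )
        assert res.p_value <= 0.05

    def test_p_matches_exhaustive_enumeration_tiny_instance(self, rng):
        """N=5 split 2/3: compare the Monte-Carlo p with exhaustive
        enumeration over all C(5,2)=10 label assignments."""
        raw = rng.integers(0, 5, size=(5, 5)).astype(float)
        d2 = np.triu(raw, 1)
        d2 = d2 + d2.T
        labels = ["p1", "p1", "p2", "p2", "p2"]
        ids = [f"s{i}" for i in range(5)]
        dm = DistanceMatrix(ids=ids, values=d2)

        def phi_for(assignment):
            exp = brute_force_amova(d2.tolist(), list(assignment))
            total = exp[3] + exp[4]
            return exp[3] / total if total > 0 else 0.0

        phi_obs = phi_for(labels)
        phis = []
        for ones in itertools.combinations(range(5), 2):
            assign = ["p2"] * 5
            for k in ones:
                assign[k] = "p1"
            phis.append(phi_for(assign))
        exact = sum(1 for v in phis if v >= phi_obs - 1e-12) / len(phis)
        res = amova_permutation_test(dm, dict(zip(ids, labels)),
                                     n_permutations=4999, seed=21)
        mc_se = math.sqrt(exact * (1 - exact) / 4999) if 0 < exact < 1 else 0.0
        assert abs(res.p_value - exact) <= 4 * mc_se + 2 / 5000

    def test_null_p_values_approximately_uniform(self):
        """Zero between-population signal: mean permutation p over replicate
        datasets should sit near 0.5, and rejections at alpha = 0.05 should
        stay near the nominal rate.

        Mutation density is high enough that individuals share polymorphic
        sites: with rare mutations every individual's variants are private,
        pairwise differences become additive (d_ij = m_i + m_j), SSD_among
        is identically zero for every labelling, and the permutation
        distribution of Phi degenerates to a point."""
        n_reps = 200
        p_values = []
        for rep in range(n_reps):
            seqs = gen_structured_sequences(
                SeqGenConfig(n_pops=2, n_per_pop=6, n_sites=60,
                             p_between=0.0, p_within=0.3, seed=10_000 + rep)
            )
            dm = pairwise_difference_matrix(seqs)
            try:
                res = amova_permutation_test(
                    dm, seqs.populations(), n_permutations=199, seed=20_000 + rep
                )
            except NoVarianceError:
                continue
            p_values.append(res.p_value)
        p = np.array(p_values)
        assert len(p) > 150
        assert 0.4 <= p.mean() <= 0.6
        assert np.mean(p <= 0.05) <= 0.10
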