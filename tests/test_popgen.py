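"""Diversity, distance, structure and LD statistics against hand oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ssrmine as sm
from ssrmine.datamodel import NULL
from ssrmine.popgen import (
    ADMIXED,
    NEI_SENTINEL,
    _dprime_from_calls,
    informativeness_class,
)

from conftest import make_genotypes


def genotypes_from_freqs(freqs: dict, n: int):
    """Deterministic single-locus panel with exact allele counts."""
    calls = []
    for allele, f in freqs.items():
        calls.extend([allele] * round(f * n))
    return make_genotypes({f"A{i:03d}": [c] for i, c in enumerate(calls)})


class TestLocusSummary:
    def test_monomorphic(self):
        g = genotypes_from_freqs({100: 1.0}, 20)
        row = sm.locus_summary(g).iloc[0]
        assert row["gene_diversity"] == 0
        assert row["pic"] == 0
        assert row["class"] == "slight"

    def test_symmetric_biallelic(self):
        g = genotypes_from_freqs({100: 0.5, 102: 0.5}, 20)
        row = sm.locus_summary(g).iloc[0]
        assert row["gene_diversity"] == pytest.approx(0.5)
        assert row["pic"] == pytest.approx(0.375)
        assert row["class"] == "moderate"

    def test_botstein_three_alleles(self):
        # freqs 0.5/0.3/0.2: He = 1-0.38 = 0.62;
        # PIC = 0.62 - 2(0.25*0.09 + 0.25*0.04 + 0.09*0.04) = 0.5417...
        g = genotypes_from_freqs({100: 0.5, 102: 0.3, 104: 0.2}, 10)
        row = sm.locus_summary(g).iloc[0]
        expected_pic = 0.62 - 2 * (0.25 * 0.09 + 0.25 * 0.04 + 0.09 * 0.04)
        assert row["pic"] == pytest.approx(expected_pic, abs=1e-12)
        assert row["class"] == "high"

    def test_null_excluded_by_default(self):
        g = make_genotypes({"A": [100], "B": [100], "C": [NULL], "D": [102]})
        default = sm.locus_summary(g).iloc[0]
        with_null = sm.locus_summary(g, include_null=True).iloc[0]
        assert default["n_alleles"] == 2
        assert with_null["n_alleles"] == 3

    @given(
        st.lists(st.floats(0.05, 1.0), min_size=2, max_size=8).map(
            lambda w: np.array(w) / np.sum(w)
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_pic_he_bounds(self, p):
        """PIC <= He <= 1 - 1/k for any k-allele frequency vector."""
        he = 1 - np.sum(p**2)
        pic = he - sum(
            2 * p[i] ** 2 * p[j] ** 2
            for i in range(len(p))
            for j in range(i + 1, len(p))
        )
        assert pic <= he + 1e-12
        assert he <= 1 - 1 / len(p) + 1e-12


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        g = make_genotypes(
            {"A1": [100, 200], "A2": [102, 202], "B1": [100, 200], "B2": [102, 202]}
        )
        d, flags = sm.nei_distance(g, {"X": ["A1", "A2"], "Y": ["B1", "B2"]})
        assert d.at["X", "Y"] == pytest.approx(0.0, abs=1e-12)
        assert not flags.at["X", "Y"]

    def test_fixed_different_sentinel(self):
        g = make_genotypes({"A1": [100], "A2": [100], "B1": [102], "B2": [102]})
        d, flags = sm.nei_distance(g, {"X": ["A1", "A2"], "Y": ["B1", "B2"]})
        assert d.at["X", "Y"] == NEI_SENTINEL
        assert flags.at["X", "Y"]

    def test_hand_two_locus_example(self):
        # both loci: freqs 0.8/0.2 in X vs 0.2/0.8 in Y
        # J_xy = 0.32, J_x = J_y = 0.68 -> D = -ln(0.32/0.68) = 0.7538
        rows = {}
        for i in range(10):
            rows[f"X{i}"] = [100 if i < 8 else 102, 200 if i < 8 else 202]
        for i in range(10):
            rows[f"Y{i}"] = [100 if i < 2 else 102, 200 if i < 2 else 202]
        g = make_genotypes(rows)
        d, _ = sm.nei_distance(
            g, {"X": [f"X{i}" for i in range(10)], "Y": [f"Y{i}" for i in range(10)]}
        )
        assert d.at["X", "Y"] == pytest.approx(-np.log(0.32 / 0.68), abs=1e-12)


class TestNJTree:
    def test_three_leaf_exact(self):
        # three-point formulas: a = (dAB + dAC - dBC)/2, etc.
        d = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]], index=list("ABC"), columns=list("ABC"),
            dtype=float,
        )
        tree = sm.nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_additive_four_taxon_recovery(self):
        # additive tree: (A,B) vs (C,D); path lengths reconstructed exactly
        d = pd.DataFrame(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = sm.nj_tree(d)
        for x, y in itertools.combinations("ABCD", 2):
            tx = tree.find(x)
            assert tx.distance(tree.find(y)) == pytest.approx(d.at[x, y], abs=1e-9)

    def test_leaf_order_invariance(self):
        d = pd.DataFrame(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        perm = ["C", "A", "D", "B"]
        t1, t2 = sm.nj_tree(d), sm.nj_tree(d.loc[perm, perm])
        for x, y in itertools.combinations("ABCD", 2):
            assert t1.find(x).distance(t1.find(y)) == pytest.approx(
                t2.find(x).distance(t2.find(y)), abs=1e-9
            )

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float,
                         index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError):
            sm.nj_tree(d)


class TestEvanno:
    @staticmethod
    def _table(mean_by_k, sd, n_rep=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k, m in mean_by_k.items():
            # exact sd via standardized residuals
            x = rng.normal(size=n_rep)
            x = (x - x.mean()) / x.std(ddof=1)
            for r, xi in enumerate(x):
                rows.append({"K": k, "replicate": r, "loglik": m + sd * xi})
        return pd.DataFrame(rows)

    def test_direct_formula(self):
        # |L''(3)| = |40 - 2*30 + 10| = 10, sd = 2 -> deltaK = 5
        t = self._table({2: 10, 3: 30, 4: 40}, sd=2.0)
        out = sm.evanno_delta_k(t)
        assert out.at[3, "deltaK"] == pytest.approx(5.0)

    def test_linear_zero_curvature(self):
        t = self._table({k: 100 * k for k in range(1, 7)}, sd=3.0)
        out = sm.evanno_delta_k(t)
        assert np.allclose(out["deltaK"].dropna(), 0.0, atol=1e-9)

    def test_scale_invariance(self):
        t1 = self._table({2: 10, 3: 30, 4: 40, 5: 45}, sd=2.0, seed=4)
        t2 = t1.copy()
        t2["loglik"] += 12345.0
        pd.testing.assert_series_equal(
            sm.evanno_delta_k(t1)["deltaK"], sm.evanno_delta_k(t2)["deltaK"]
        )

    def test_zero_sd_flagged(self):
        t = self._table({2: 10, 3: 30, 4: 40}, sd=2.0)
        t.loc[t["K"] == 3, "loglik"] = 30.0
        out = sm.evanno_delta_k(t)
        assert out.at[3, "undefined"]
        assert np.isnan(out.at[3, "deltaK"])


class TestAssignSubpopulations:
    @pytest.mark.parametrize(
        "row,expected",
        [((0.95, 0.05), "Q1"), ((0.6, 0.4), ADMIXED), ((0.9, 0.1), ADMIXED)],
    )
    def test_threshold_rule(self, row, expected):
        q = sm.QMatrix(pd.DataFrame([row], index=["A"], columns=["Q1", "Q2"]))
        assert sm.assign_subpopulations(q)["A"] == expected


class TestAmova:
    def test_fixation_limit(self):
        g = make_genotypes(
            {"A1": [100, 200], "A2": [100, 200], "B1": [102, 202], "B2": [102, 202]}
        )
        res = sm.amova(g, {"X": ["A1", "A2"], "Y": ["B1", "B2"]}, n_permutations=20)
        assert res.pct_among == pytest.approx(100.0)

    def test_panmictic_null(self):
        rng = np.random.default_rng(3)
        rows = {
            f"A{i:03d}": [int(rng.choice([100, 102, 104])) for _ in range(20)]
            for i in range(60)
        }
        g = make_genotypes(rows, markers=[f"M{j}" for j in range(20)])
        accs = list(rows)
        res = sm.amova(
            g, {"X": accs[:30], "Y": accs[30:]}, n_permutations=99, seed=1
        )
        assert res.pct_among < 5.0
        assert res.p_value > 0.05

    def test_hand_decomposition(self):
        # 6 accessions, 2 loci; squared distance = allele mismatch count
        g = make_genotypes(
            {
                "A1": [100, 200], "A2": [100, 200], "A3": [100, 202],
                "B1": [102, 202], "B2": [102, 202], "B3": [102, 200],
            }
        )
        groups = {"X": ["A1", "A2", "A3"], "Y": ["B1", "B2", "B3"]}
        res = sm.amova(g, groups, n_permutations=0)
        # hand computation: within X pairs d = (0+1+1)=2 -> SSD_X = 2/3
        # within Y same -> SSD_within = 4/3
        # cross distances: A1B1=2 A1B2=2 A1B3=1, A2 same as A1 (2,2,1),
        # A3B1=1 A3B2=1 A3B3=2 -> cross sum = 14
        # SSD_total = (2+2+14)/6 = 3; SSD_among = 3 - 4/3 = 5/3
        assert res.ssd_within == pytest.approx(4 / 3)
        assert res.ssd_among == pytest.approx(5 / 3)
        # variance components: MS_w = (4/3)/4 = 1/3; n0 = 3
        # sigma_a = (5/3 - 1/3)/3 = 4/9
        assert res.sigma2_within == pytest.approx(1 / 3)
        assert res.sigma2_among == pytest.approx(4 / 9)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_percentages_sum(self, sim_panel):
        g, q = sim_panel["genotypes"], sim_panel["q"]
        assigned = sm.assign_subpopulations(q)
        groups = {
            s: list(assigned[assigned == s].index)
            for s in assigned.unique()
            if s != ADMIXED and (assigned == s).sum() >= 2
        }
        res = sm.amova(g, groups, n_permutations=30, seed=2)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-6)
        assert res.pct_among > 10  # structured panel


def _theta_biallelic_oracle(n1, n2, p1, p2):
    """Independent haploid ANOVA theta for one biallelic locus."""
    total = 0.0
    num = den = 0.0
    n = n1 + n2
    nc = n - (n1**2 + n2**2) / n
    for q1, q2 in ((p1, p2), (1 - p1, 1 - p2)):
        qbar = (n1 * q1 + n2 * q2) / n
        msa = n1 * (q1 - qbar) ** 2 + n2 * (q2 - qbar) ** 2
        msw = (n1 * q1 * (1 - q1) + n2 * q2 * (1 - q2)) / (n - 2)
        sa = (msa - msw) / nc
        num += sa
        den += sa + msw
    return num / den


class TestFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(9)
        rows = {}
        for i in range(200):
            rows[f"A{i:03d}"] = [int(rng.choice([100, 102], p=[0.6, 0.4])) for _ in range(25)]
        g = make_genotypes(rows, markers=[f"M{j}" for j in range(25)])
        accs = list(rows)
        theta, _ = sm.pairwise_fst(g, {"X": accs[:100], "Y": accs[100:]})
        assert abs(theta.at["X", "Y"]) < 0.02

    def test_fixed_different_is_one(self):
        g = make_genotypes(
            {"A1": [100], "A2": [100], "A3": [100], "B1": [102], "B2": [102], "B3": [102]}
        )
        theta, _ = sm.pairwise_fst(g, {"X": ["A1", "A2", "A3"], "Y": ["B1", "B2", "B3"]})
        assert theta.at["X", "Y"] == pytest.approx(1.0)

    def test_matches_independent_oracle(self):
        # biallelic, p1 = 0.9, p2 = 0.1, 50 per group
        rows = {}
        for i in range(50):
            rows[f"X{i:02d}"] = [100 if i < 45 else 102]
        for i in range(50):
            rows[f"Y{i:02d}"] = [100 if i < 5 else 102]
        g = make_genotypes(rows)
        theta, _ = sm.pairwise_fst(
            g,
            {"X": [f"X{i:02d}" for i in range(50)], "Y": [f"Y{i:02d}" for i in range(50)]},
        )
        assert theta.at["X", "Y"] == pytest.approx(
            _theta_biallelic_oracle(50, 50, 0.9, 0.1), abs=1e-9
        )

    def test_monomorphic_pair_flagged(self):
        g = make_genotypes({"A1": [100], "A2": [100], "B1": [100], "B2": [100]})
        theta, _ = sm.pairwise_fst(g, {"X": ["A1", "A2"], "Y": ["B1", "B2"]})
        assert np.isnan(theta.at["X", "Y"])


class TestLD:
    def test_perfect_association(self):
        rows = {f"A{i}": [100, 200] for i in range(10)}
        rows.update({f"B{i}": [102, 202] for i in range(10)})
        g = make_genotypes(rows)
        res = sm.ld_dprime(g, n_permutations=50, seed=1)
        assert res.iloc[0]["dprime"] == pytest.approx(1.0)
        assert res.iloc[0]["p_value"] < 0.05

    def test_exact_independence(self):
        rows = {}
        i = 0
        for a in (100, 102):
            for b in (200, 202):
                for _ in range(25):
                    rows[f"A{i:03d}"] = [a, b]
                    i += 1
        g = make_genotypes(rows)
        res = sm.ld_dprime(g, n_permutations=0, seed=1)
        assert res.iloc[0]["dprime"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_2x2_example(self):
        # counts 40/10/10/40: p = q = 0.5, D = 0.15, Dmax = 0.25, D' = 0.6
        rows = {}
        i = 0
        for a, b, n in ((100, 200, 40), (100, 202, 10), (102, 200, 10), (102, 202, 40)):
            for _ in range(n):
                rows[f"A{i:03d}"] = [a, b]
                i += 1
        g = make_genotypes(rows)
        res = sm.ld_dprime(g, n_permutations=0)
        assert res.iloc[0]["dprime"] == pytest.approx(0.6, abs=1e-12)

    def test_monomorphic_flagged(self):
        g = make_genotypes({"A": [100, 200], "B": [100, 202]})
        res = sm.ld_dprime(g, n_permutations=0)
        assert res.iloc[0]["undefined"]

    def test_relabeling_and_swap_invariance(self):
        rng = np.random.default_rng(4)
        a = list(rng.choice([100, 102, 104], 60))
        b = list(rng.choice([200, 202], 60))
        d1 = _dprime_from_calls(a, b)
        d2 = _dprime_from_calls(b, a)  # locus swap
        relabel = {100: 7, 102: 1, 104: 9}
        d3 = _dprime_from_calls([relabel[x] for x in a], b)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert d1 == pytest.approx(d3, abs=1e-12)
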