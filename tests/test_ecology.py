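"""Community statistics: richness estimators, dissimilarities, ordination."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edna.ecology import (
    IncidenceSummary,
    accumulation_curve,
    build_motu_table,
    chao2,
    common_motu_filter,
    ice,
    incidence_summary,
    jaccard_dissimilarity,
    morisita_horn_dissimilarity,
    nmds,
    pairwise_dissimilarity,
    renkonen_similarity,
    spearman_rho,
)
from tests.conftest import make_motu_table


def summary(s_obs, m, **qk):
    q = np.zeros(m)
    for k, v in qk.items():
        q[int(k[1:]) - 1] = v
    return IncidenceSummary(s_obs=s_obs, m=m, q=q)


def paper_like_meta():
    rows = []
    for hab in ("Bedok", "Pandan"):
        for site in range(1, 8):
            for depth in ("surface", "benthic"):
                rows.append((f"{hab}-S{site}-{depth}", hab, f"S{site}", depth))
    return rows


class TestBuildMotuTable:
    def test_counts_sum_across_replicates(self, two_habitat_design):
        from edna.cluster import objective_cluster

        table = pd.DataFrame(
            {("S", 1): [3], ("S", 2): [4]},
            index=["A" * 40],
        )
        table.columns = pd.MultiIndex.from_tuples(table.columns,
                                                  names=["sample", "replicate"])
        part = objective_cluster(["A" * 40], 0.03)
        meta = pd.DataFrame({"habitat": ["H"], "site": ["S1"],
                             "depth": ["surface"]}, index=["S"])
        mt = build_motu_table(part, table, meta)
        assert mt.counts.iloc[0, 0] == 7
        assert mt.incidence.iloc[0, 0]

    def test_missing_metadata_fails(self):
        from edna.cluster import objective_cluster

        table = pd.DataFrame({("S", 1): [1]}, index=["A" * 40])
        table.columns = pd.MultiIndex.from_tuples(table.columns,
                                                  names=["sample", "replicate"])
        part = objective_cluster(["A" * 40], 0.03)
        with pytest.raises(ValueError, match="metadata"):
            build_motu_table(part, table, pd.DataFrame({"habitat": []}))

    def test_noiseless_incidence_equals_truth(self, noiseless_run):
        pool, _, truth, results = noiseless_run
        det = truth.detected_incidence()
        mt = results["motu_table"]
        rep_to_sp = {sp.barcode: sp.species_id for sp in pool.species}
        for motu, rep in results["partition"].representatives.items():
            expected = det.loc[rep_to_sp[rep], mt.incidence.columns].to_numpy()
            assert (mt.incidence.loc[motu].to_numpy() == expected).all()


class TestCommonMotuFilter:
    def _table(self, presence: dict):
        counts = {m: {s: 1 for s in samples} for m, samples in presence.items()}
        return make_motu_table(counts, paper_like_meta())

    def test_five_of_seven_surface_retained(self):
        t = self._table({"M1": [f"Bedok-S{i}-surface" for i in range(1, 6)]})
        assert "M1" in common_motu_filter(t).counts.index

    def test_three_everywhere_removed(self):
        samples = (
            [f"Bedok-S{i}-surface" for i in (1, 2, 3)]
            + [f"Bedok-S{i}-benthic" for i in (1, 2, 3)]
            + [f"Pandan-S{i}-surface" for i in (1, 2, 3)]
            + [f"Pandan-S{i}-benthic" for i in (1, 2, 3)]
        )
        t = self._table({"M1": samples})
        assert "M1" not in common_motu_filter(t).counts.index

    def test_four_of_seven_single_stratum_retained(self):
        t = self._table({"M1": [f"Pandan-S{i}-benthic" for i in range(1, 5)]})
        assert "M1" in common_motu_filter(t).counts.index


class TestAccumulationCurve:
    def test_single_sample(self):
        inc = pd.DataFrame({"s1": [1, 0, 1]}).astype(bool)
        curve = accumulation_curve(inc, n_permutations=5, seed=0)
        assert list(curve["mean"]) == [2.0]

    def test_identical_samples_flat_sd_zero(self):
        inc = pd.DataFrame({"s1": [1, 1, 0], "s2": [1, 1, 0],
                            "s3": [1, 1, 0]}).astype(bool)
        curve = accumulation_curve(inc, n_permutations=20, seed=0)
        assert list(curve["mean"]) == [2.0, 2.0, 2.0]
        assert (curve["sd"] == 0).all()

    def test_exhaustive_matches_independent_enumeration(self):
        rng = np.random.default_rng(5)
        inc = pd.DataFrame(rng.random((10, 4)) < 0.4)
        mat = inc.to_numpy()
        m = mat.shape[1]
        # independent brute-force mean over all m! orderings
        sums = np.zeros(m)
        n_orders = 0
        for order in itertools.permutations(range(m)):
            seen = np.zeros(mat.shape[0], dtype=bool)
            for k, col in enumerate(order):
                seen |= mat[:, col]
                sums[k] += seen.sum()
            n_orders += 1
        expected = sums / n_orders
        got = accumulation_curve(inc, exhaustive=True)["mean"].to_numpy()
        assert np.allclose(got, expected)
        assert got[-1] == mat.any(axis=1).sum()

    def test_mean_nondecreasing(self):
        rng = np.random.default_rng(8)
        inc = pd.DataFrame(rng.random((30, 6)) < 0.3)
        curve = accumulation_curve(inc, n_permutations=50, seed=1)
        assert (np.diff(curve["mean"]) >= -1e-12).all()


class TestChao2:
    def test_no_uniques_equals_observed(self):
        assert chao2(summary(10, 5, q2=4, q3=6)) == 10.0

    def test_frozen_example(self):
        # 10 + (13/14) * 16/4 evaluated independently as a fraction
        expected = float(Fraction(10) + Fraction(13, 14) * Fraction(16, 4))
        assert chao2(summary(10, 14, q1=4, q2=2, q3=4)) == pytest.approx(expected)
        assert expected == pytest.approx(13.714285714285714)

    def test_bias_corrected_branch(self):
        assert chao2(summary(5, 10, q1=3, q5=2)) == pytest.approx(7.7)

    def test_requires_two_units(self):
        with pytest.raises(ValueError):
            chao2(summary(1, 1, q1=1))

    def test_never_below_observed(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(2, 20))
            inc = pd.DataFrame(rng.random((40, m)) < rng.uniform(0.05, 0.9))
            s = incidence_summary(inc)
            assert chao2(s) >= s.s_obs - 1e-12


class TestIce:
    def test_all_frequent_equals_observed(self):
        s = summary(6, 14, q12=2, q13=1, q14=3)
        assert ice(s) == 6.0

    def test_all_uniques_falls_back_to_chao2(self):
        s = summary(8, 12, q1=4, q12=4)
        assert ice(s) == pytest.approx(chao2(s))

    def test_frozen_hand_example(self):
        # m=12, Q1=5, Q2=3, Q3=2, plus 4 frequent MOTUs at k=12.
        # Independent evaluation: S_infr=10, N_infr=17, C=12/17,
        # gamma^2 = max(10*17/12 * 12/11 * 18/289 - 1, 0) = 0,
        # ICE = 4 + 10/(12/17) = 4 + 170/12
        expected = float(Fraction(4) + Fraction(170, 12))
        s = summary(14, 12, q1=5, q2=3, q3=2, q12=4)
        assert ice(s) == pytest.approx(expected)
        assert expected == pytest.approx(18.166666666666668)

    def test_never_below_observed(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            m = int(rng.integers(2, 20))
            inc = pd.DataFrame(rng.random((40, m)) < rng.uniform(0.05, 0.9))
            s = incidence_summary(inc)
            assert ice(s) >= s.s_obs - 1e-9

    def test_requires_two_units(self):
        with pytest.raises(ValueError):
            ice(summary(1, 1, q1=1))


binary_vec = st.lists(st.booleans(), min_size=1, max_size=30)


class TestDissimilarities:
    def test_jaccard_examples(self):
        assert jaccard_dissimilarity([1, 1, 0], [1, 1, 0]) == 0.0
        assert jaccard_dissimilarity([1, 0], [0, 1]) == 1.0
        assert jaccard_dissimilarity([], []) == 0.0

    def test_jaccard_from_venn_counts(self):
        # 95 shared MOTUs of a 516-MOTU union
        a = np.zeros(516, dtype=bool)
        b = np.zeros(516, dtype=bool)
        a[:376] = True
        b[376 - 95 :] = True
        assert (a & b).sum() == 95 and (a | b).sum() == 516
        assert jaccard_dissimilarity(a, b) == pytest.approx(1 - 95 / 516)

    @given(a=binary_vec, b=binary_vec, c=binary_vec)
    @settings(max_examples=200, deadline=None)
    def test_jaccard_triangle_inequality(self, a, b, c):
        n = max(len(a), len(b), len(c))
        a, b, c = (v + [False] * (n - len(v)) for v in (a, b, c))
        dab = jaccard_dissimilarity(a, b)
        dbc = jaccard_dissimilarity(b, c)
        dac = jaccard_dissimilarity(a, c)
        assert dac <= dab + dbc + 1e-12

    def test_morisita_horn_examples(self):
        assert morisita_horn_dissimilarity([3, 1], [3, 1]) == pytest.approx(0.0)
        assert morisita_horn_dissimilarity([2, 0], [0, 5]) == pytest.approx(1.0)
        assert morisita_horn_dissimilarity([1, 1], [1, 3]) == pytest.approx(1 / 9)

    @given(
        x=st.lists(st.integers(0, 50), min_size=2, max_size=15),
        c=st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_morisita_horn_scale_invariance(self, x, c):
        if sum(x) == 0:
            x[0] = 1
        y = [v + 1 for v in x[::-1]]
        base = morisita_horn_dissimilarity(x, y)
        scaled = morisita_horn_dissimilarity([c * v for v in x], y)
        assert abs(base - scaled) < 1e-12

    def test_morisita_horn_zero_sum_fails(self):
        with pytest.raises(ValueError):
            morisita_horn_dissimilarity([0, 0], [1, 2])

    def test_renkonen_examples(self):
        assert renkonen_similarity([2, 2], [1, 1]) == pytest.approx(1.0)
        assert renkonen_similarity([1, 0], [0, 2]) == pytest.approx(0.0)
        assert renkonen_similarity([3, 1], [1, 3]) == pytest.approx(0.5)

    def test_renkonen_zero_sum_fails(self):
        with pytest.raises(ValueError):
            renkonen_similarity([0], [0])

    def test_dissimilarities_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            x = rng.integers(0, 20, size=8)
            y = rng.integers(0, 20, size=8)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert 0 <= morisita_horn_dissimilarity(x, y) <= 1 + 1e-12
            assert 0 <= jaccard_dissimilarity(x > 0, y > 0) <= 1
            assert 0 <= renkonen_similarity(x, y) <= 1


class TestNmds:
    def test_equilateral_embeds_with_near_zero_stress(self):
        d = pd.DataFrame(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        coords, stress = nmds(d, seed=0, n_restarts=4)
        assert stress < 0.01
        dists = [
            math.dist(coords.loc[i], coords.loc[j])
            for i, j in itertools.combinations("abc", 2)
        ]
        assert max(dists) - min(dists) < 0.05 * max(dists)

    def test_duplicate_samples_coincide(self):
        d = np.array([
            [0, 0, 0.8, 0.8],
            [0, 0, 0.8, 0.8],
            [0.8, 0.8, 0, 0.3],
            [0.8, 0.8, 0.3, 0],
        ])
        coords, _ = nmds(pd.DataFrame(d), seed=1, n_restarts=4)
        gap = math.dist(coords.iloc[0], coords.iloc[1])
        spread = math.dist(coords.iloc[0], coords.iloc[2])
        assert gap < 0.05 * spread

    def test_habitat_separation_on_simulated_table(self):
        from edna.synth import generate_species_pool, simulate_incidence

        pool = generate_species_pool(30, 20, 10, 0, seed=17)
        inc = simulate_incidence(pool, dropout_prob=0.3, seed=17)
        meta = pool.design.metadata()
        d = pairwise_dissimilarity(inc.astype(int), "jaccard")
        coords, _ = nmds(d, seed=2, n_restarts=8)
        groups = {
            hab: coords.loc[[s for s in coords.index
                             if meta.loc[s, "habitat"] == hab]]
            for hab in ("Bedok", "Pandan")
        }
        centroids = {h: g.mean(axis=0) for h, g in groups.items()}
        sep = math.dist(centroids["Bedok"], centroids["Pandan"])
        within = max(
            np.linalg.norm(g - centroids[h], axis=1).mean()
            for h, g in groups.items()
        )
        assert sep > within

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((2, 2)))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        a, sa = nmds(pd.DataFrame(d), seed=5)
        b, sb = nmds(pd.DataFrame(d), seed=5)
        assert np.allclose(a.to_numpy(), b.to_numpy()) and sa == sb


class TestSpearman:
    def test_examples(self):
        assert spearman_rho([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_input_undefined(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])
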