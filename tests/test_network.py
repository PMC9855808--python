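import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iegnet import (CohortSpec, RegionTable, ThresholdSpec, ValidationError, bh_fdr,
                    binarize, correlate_table, make_ground_truth, p_two_tailed,
                    pearson_r, simulate_cohort)

from oracles import bh_oracle, pearson_oracle


class TestPearsonR:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),   # cov-sum 4 over dev-sums 5 each
    ])
    def test_known_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r = pearson_r(x, y)
        assert pearson_r(y, x) == pytest.approx(r)
        assert pearson_r(3.5 * x + 2.0, y) == pytest.approx(r)
        assert pearson_r(x, -2.0 * y + 7.0) == pytest.approx(-r)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=12))
    @settings(deadline=None, max_examples=40)
    def test_matches_textbook_formula(self, x):
        rng = np.random.default_rng(7)
        y = list(rng.normal(size=len(x)))
        if np.std(x) < 1e-6:  # near-degenerate variance underflows the oracle
            return
        assert pearson_r(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-10)


class TestPTwoTailed:
    def test_reproduces_published_amygdala_pair(self):
        """BLA–BMA at n=12: r = 0.6193 must give p = 0.0318."""
        assert p_two_tailed(0.6193, 12) == pytest.approx(0.0318, abs=0.0005)

    def test_reproduces_published_pallidum_pair(self):
        """BLA–PALv at n=12: r = 0.2539 must give p = 0.4258."""
        assert p_two_tailed(0.2539, 12) == pytest.approx(0.4258, abs=0.0005)

    @pytest.mark.parametrize("r,expected", [(0.0, 1.0), (1.0, 0.0), (-1.0, 0.0)])
    def test_boundary_values(self, r, expected):
        assert p_two_tailed(r, 12) == pytest.approx(expected)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            p_two_tailed(0.5, 2)

    @given(r=st.floats(-0.999, 0.999), n=st.integers(3, 50))
    @settings(deadline=None, max_examples=60)
    def test_even_in_r_and_decreasing_in_magnitude(self, r, n):
        p = p_two_tailed(r, n)
        assert 0 <= p <= 1
        assert p == pytest.approx(p_two_tailed(-r, n))
        assert p <= p_two_tailed(r * 0.5, n) + 1e-12


class TestBhFdr:
    @pytest.mark.parametrize("p,q,expected", [
        ([0.9, 0.95], 0.05, [False, False]),
        ([0.01, 0.02, 0.04, 0.8], 0.05, [True, True, False, False]),
        ([0.001, 0.002, 0.003], 0.05, [True, True, True]),
        ([], 0.05, []),
    ])
    def test_step_up_examples(self, p, q, expected):
        assert bh_fdr(p, q).tolist() == expected

    def test_agrees_with_brute_force_definition(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
            q = float(rng.uniform(0.01, 0.2))
            assert bh_fdr(p, q).tolist() == bh_oracle(p, q)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=30)
            ours = bh_fdr(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert ours.tolist() == ref.tolist()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.floats(0.01, 0.3))
    @settings(deadline=None, max_examples=60)
    def test_retained_set_monotone_in_q(self, p, q):
        lo = bh_fdr(p, q)
        hi = bh_fdr(p, min(1.0, q * 2))
        assert np.all(hi[lo])  # everything retained at q stays retained at 2q


class TestCorrelateTable:
    def test_affine_copies_give_unit_correlation(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        vals = np.vstack([base, 2 * base + 1, 0.5 * base + 3])
        table = RegionTable(["A", "B", "C"], [f"m{i}" for i in range(5)], vals)
        corr = correlate_table(table)
        _, r, _ = corr.upper_triangle()
        np.testing.assert_allclose(r, 1.0)

    def test_sixty_regions_gives_1770_pairs(self, paper_scale_cohort):
        corr = correlate_table(paper_scale_cohort)
        _, r, p = corr.upper_triangle()
        assert r.size == p.size == 1770
        assert corr.n == 12

    def test_matrices_symmetric_with_nan_diagonal(self, small_table):
        corr = correlate_table(small_table)
        np.testing.assert_allclose(corr.r, corr.r.T)
        assert np.all(np.isnan(np.diag(corr.p)))
        np.testing.assert_allclose(np.diag(corr.r), 1.0)

    def test_constant_region_gets_r0_p1(self, small_table):
        vals = small_table.values.copy()
        vals[2, :] = 1.5
        table = RegionTable(small_table.regions, small_table.animals, vals)
        corr = correlate_table(table)
        assert corr.n_constant_regions == 1
        assert np.all(corr.r[2, [0, 1, 3, 4]] == 0)
        assert np.all(corr.p[2, [0, 1, 3, 4]] == 1)

    def test_null_effect_mean_absolute_r_small(self):
        truth = make_ground_truth(30, 0.0, seed=0, effect_r=0.0)
        table = simulate_cohort(truth, CohortSpec(n_animals=400, transform="none"), seed=2)
        _, r, _ = correlate_table(table).upper_triangle()
        assert np.mean(np.abs(r)) < 0.06  # E|r| ~ sqrt(2/(pi n)) ~ 0.04 at n=400

    def test_animal_permutation_leaves_matrices_unchanged(self, paper_scale_cohort):
        rng = np.random.default_rng(3)
        perm = rng.permutation(paper_scale_cohort.n_animals)
        shuffled = paper_scale_cohort.select_animals(perm)
        a = correlate_table(paper_scale_cohort)
        b = correlate_table(shuffled)
        np.testing.assert_allclose(a.r, b.r, atol=1e-12)

    def test_region_permutation_permutes_consistently(self, paper_scale_cohort):
        rng = np.random.default_rng(4)
        perm = rng.permutation(paper_scale_cohort.n_regions)
        from iegnet import restrict_regions

        permuted = restrict_regions(paper_scale_cohort,
                                    [paper_scale_cohort.regions[i] for i in perm])
        a = correlate_table(paper_scale_cohort)
        b = correlate_table(permuted)
        np.testing.assert_allclose(b.r, a.r[np.ix_(perm, perm)], atol=1e-12)


class TestBinarize:
    def test_nothing_passes(self, toy_corr):
        corr = toy_corr
        corr.p[~np.eye(4, dtype=bool)] = 0.5
        net = binarize(corr, ThresholdSpec(alpha=0.05, fdr_q=None))
        assert net.n_edges == 0

    def test_everything_passes_when_p_zero(self, small_table):
        vals = np.vstack([small_table.values[0] * k for k in (1.0, 2.0, 3.0)])
        table = RegionTable(["A", "B", "C"], small_table.animals, vals)
        net = binarize(correlate_table(table), ThresholdSpec())
        assert net.n_edges == 3  # complete graph on 3 nodes

    def test_sign_policy_on_fixture(self, toy_corr):
        """(C,D) is significantly anticorrelated: dropped under positive_only,
        present under absolute and signed."""
        pos = binarize(toy_corr, ThresholdSpec(alpha=0.05, fdr_q=None,
                                               sign_policy="positive_only"))
        assert pos.edge_set() == {("A", "B")}
        absol = binarize(toy_corr, ThresholdSpec(alpha=0.05, fdr_q=None,
                                                 sign_policy="absolute"))
        assert absol.edge_set() == {("A", "B"), ("C", "D")}
        signed = binarize(toy_corr, ThresholdSpec(alpha=0.05, fdr_q=None,
                                                  sign_policy="signed"))
        assert signed.signs is not None
        assert signed.signs[0, 1] == 1 and signed.signs[2, 3] == -1

    def test_r_min_floor(self, toy_corr):
        net = binarize(toy_corr, ThresholdSpec(alpha=0.05, fdr_q=None, r_min=0.95))
        assert net.n_edges == 0

    def test_fdr_filter_is_applied_within_the_pair_family(self, toy_corr):
        # 6 pairs; only p=0.001 and p=0.002 survive BH at q=0.01:
        # thresholds k*0.01/6 -> 0.00167, 0.00333, ...
        net = binarize(toy_corr, ThresholdSpec(alpha=0.05, fdr_q=0.01,
                                               sign_policy="absolute"))
        assert net.edge_set() == {("A", "B"), ("C", "D")}

    def test_nestedness_across_alpha_levels(self, paper_scale_cohort):
        corr = correlate_table(paper_scale_cohort)
        nets = {a: binarize(corr, ThresholdSpec(alpha=a, fdr_q=None))
                for a in (0.05, 0.005, 0.0005)}
        assert nets[0.0005].edge_set() <= nets[0.005].edge_set() <= nets[0.05].edge_set()

    def test_stricter_r_min_is_nested(self, paper_scale_cohort):
        corr = correlate_table(paper_scale_cohort)
        loose = binarize(corr, ThresholdSpec(alpha=0.05, fdr_q=None, r_min=0.3))
        strict = binarize(corr, ThresholdSpec(alpha=0.05, fdr_q=None, r_min=0.6))
        assert strict.edge_set() <= loose.edge_set()

    def test_edge_list_carries_r_p_sign(self, toy_corr):
        net = binarize(toy_corr, ThresholdSpec(alpha=0.05, fdr_q=None,
                                               sign_policy="absolute"))
        df = net.edge_list.set_index(["region_a", "region_b"])
        assert df.loc[("A", "B"), "r"] == pytest.approx(0.92)
        assert df.loc[("C", "D"), "sign"] == -1

    def test_invalid_threshold_specs(self):
        for kwargs in (dict(alpha=0.0), dict(alpha=0.05, r_min=1.0),
                       dict(alpha=0.05, fdr_q=0.0), dict(sign_policy="bogus")):
            with pytest.raises(ValidationError):
                ThresholdSpec(**kwargs)
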