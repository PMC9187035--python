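import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coevnet import (
    CovarianceMatrix,
    FunctionalAnnotation,
    benchmark_summary,
    build_graph,
    covariance_matrix,
    distance_distribution,
    generate_annotation,
    generate_msa,
    lo_clique,
    lo_score,
    p_lo,
    propensity_table,
    protein_lo_report,
)
from coevnet.enrichment import _log_odds


def matrix_with_neighborhood(i, neighbors, L, score=0.9):
    """Matrix whose only couplings >= 0.5 are (i, j) for j in neighbors."""
    values = np.zeros((L, L))
    for j in neighbors:
        values[i - 1, j - 1] = values[j - 1, i - 1] = score
    return CovarianceMatrix(values=values, metric="chi2", alphabet="2-letter")


class TestLoScore:
    def test_hand_worked_example(self):
        # N=101, R_f=10, n=5, r=4 -> ln((4/9)/(5/100))
        sites = {1, 2, 3, 4, 5, 6, 7, 8, 9, 10}
        neighbors = [2, 3, 4, 5, 50]  # 4 functional + 1 background
        m = matrix_with_neighborhood(1, neighbors, L=101)
        res = lo_score(1, m, sites, cutoff=0.5)
        assert (res.count_same_function, res.count_covarying) == (4, 5)
        assert res.lo == pytest.approx(math.log((4 / 9) / (5 / 100)))
        assert res.lo == pytest.approx(2.185, abs=1e-3)

    def test_all_and_only_functional_residues_covary(self):
        # N=520, R_f=10, n=r=9 -> ln((9/9)/(9/519)) = ln(519/9)
        sites = set(range(1, 11))
        m = matrix_with_neighborhood(1, range(2, 11), L=520)
        res = lo_score(1, m, sites, cutoff=0.5)
        assert res.lo == pytest.approx(math.log(519 / 9))
        assert res.lo == pytest.approx(4.054, abs=1e-3)

    def test_na_when_no_functional_partner_covaries(self):
        sites = {1, 50, 60}
        m = matrix_with_neighborhood(1, [7, 9], L=101)
        res = lo_score(1, m, sites, cutoff=0.5)
        assert res.is_na and res.count_same_function == 0

    def test_na_when_nothing_covaries(self):
        m = matrix_with_neighborhood(1, [], L=101)
        assert lo_score(1, m, {1, 2}, cutoff=0.5).is_na

    def test_na_when_residue_is_the_only_functional_site(self):
        m = matrix_with_neighborhood(1, [2, 3], L=101)
        assert lo_score(1, m, {1}, cutoff=0.5).is_na

    def test_masked_couplings_count_as_below_cutoff(self):
        values = np.full((4, 4), np.nan)
        np.fill_diagonal(values, 1.0)
        values[0, 1] = values[1, 0] = 0.9
        m = CovarianceMatrix(values=values, metric="chi2")
        res = lo_score(1, m, {1, 2}, cutoff=0.5)
        assert res.count_covarying == 1

    def test_unannotated_residue_rejected(self):
        m = matrix_with_neighborhood(1, [2], L=10)
        with pytest.raises(ValueError):
            lo_score(3, m, {1, 2}, cutoff=0.5)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        N=st.integers(20, 500),
        R=st.integers(2, 15),
        n=st.integers(1, 19),
        r=st.integers(0, 14),
    )
    def test_sign_logic(self, N, R, n, r):
        # LO > 0 iff r/(R-1) > n/(N-1)
        r = min(r, n, R - 1)
        res = _log_odds(r, n, R, N)
        if r == 0:
            assert res.is_na
        else:
            assert (res.lo > 0) == (r / (R - 1) > n / (N - 1))


class TestLoClique:
    def test_clique_of_functional_residues(self):
        # clique = {i} + 9 functional partners, N=101, R_f=10
        res = lo_clique(1, set(range(1, 11)), set(range(1, 11)), protein_length=101)
        assert res.lo == pytest.approx(math.log((9 / 9) / (9 / 100)))
        assert res.lo == pytest.approx(2.408, abs=1e-3)

    def test_na_without_functional_partners(self):
        res = lo_clique(1, {1, 20, 30}, {1, 50}, protein_length=101)
        assert res.is_na

    def test_membership_not_direct_coupling_drives_counts(self):
        # clique members count toward n even with cov(i, j) below the cutoff
        res = lo_clique(1, {1, 2, 3, 4}, {1, 2}, protein_length=101)
        assert res.count_covarying == 3
        assert res.count_same_function == 1

    def test_residue_must_belong_to_clique(self):
        with pytest.raises(ValueError):
            lo_clique(9, {1, 2}, {9, 1}, protein_length=50)

    def test_equals_neighborhood_lo_when_clique_is_the_neighborhood(self):
        sites = {1, 2, 3, 7}
        m = matrix_with_neighborhood(1, [2, 3, 5], L=30)
        res_n = lo_score(1, m, sites, cutoff=0.5)
        clique = {1, 2, 3, 5}  # i plus its cutoff neighborhood
        res_q = lo_clique(1, clique, sites, protein_length=30)
        assert res_q.lo == pytest.approx(res_n.lo)


class TestPLo:
    def test_survival_extremes(self):
        assert p_lo([0.1, 0.2], 1.0) == 0.0
        assert p_lo([1.5, 2.0], 1.0) == 1.0

    def test_survival_fraction(self):
        assert p_lo([1, 2, 3, 4], 2.5) == 0.5

    def test_na_values_excluded(self):
        assert p_lo([None, 2.0, None, 0.0], 1.0) == 0.5

    def test_empty_finite_set_is_na(self):
        assert p_lo([None, None], 0.0) is None

    def test_non_increasing_in_cutoff(self, rng):
        values = rng.normal(size=50).tolist()
        cuts = np.linspace(-3, 3, 13)
        fracs = [p_lo(values, c) for c in cuts]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestPropensities:
    @staticmethod
    def toy():
        ann = FunctionalAnnotation()
        # 10 metal sites, 4 of which are C
        seq = "C" * 4 + "H" * 6 + "A" * 70 + "C"  # background F_C = 5/81
        for pos in range(1, 11):
            ann.add("P1", "metal", pos, seq[pos - 1])
        return ann, {"P1": seq}

    def test_enrichment_log_ratio(self):
        ann, seqs = self.toy()
        table = propensity_table(ann, seqs)
        f_c = 4 / 10
        F_c = 5 / 81
        assert table.value("C", "metal") == pytest.approx(math.log(f_c / F_c))

    def test_zero_observation_cell_is_na(self):
        ann, seqs = self.toy()
        table = propensity_table(ann, seqs)
        assert np.isnan(table.value("W", "metal"))

    def test_no_enrichment_gives_zero(self):
        ann = FunctionalAnnotation()
        seq = "AC" * 10  # F_A = F_C = 0.5
        ann.add("P1", "sugar", 1, "A")
        ann.add("P1", "sugar", 2, "C")
        table = propensity_table(ann, {"P1": seq})
        assert table.value("A", "sugar") == pytest.approx(0.0)

    def test_exp_propensity_reconstructs_site_fraction(self):
        msa, truth = generate_msa(L=40, N=5, seed=17,
                                  planted=[(2, 9, 1.0), (14, 30, 1.0)])
        ann = generate_annotation(truth, category="metal", decoys=3)
        table = propensity_table(ann, {"synthetic": truth.query})
        for aa in table.propensity.index:
            p = table.propensity.loc[aa, "metal"]
            if np.isnan(p):
                continue
            assert math.exp(p) * table.background[aa] == pytest.approx(
                table.site_fraction.loc[aa, "metal"], abs=1e-12
            )

    def test_fractions_sum_to_one(self):
        ann, seqs = self.toy()
        table = propensity_table(ann, seqs)
        assert table.site_fraction["metal"].sum() == pytest.approx(1.0)
        assert table.background.sum() == pytest.approx(1.0)


class TestDistanceDistribution:
    def test_single_pair_in_first_bin(self):
        ann = FunctionalAnnotation()
        ann.add("P1", "metal", 10)
        ann.add("P1", "metal", 12)
        dist = distance_distribution(ann)
        assert dist.loc["1-4", "metal"] == pytest.approx(100.0)

    def test_consecutive_differences(self):
        ann = FunctionalAnnotation()
        for pos in (1, 3, 40):
            ann.add("P1", "heme", pos)
        dist = distance_distribution(ann)
        assert dist["heme"].tolist() == pytest.approx([50.0, 0.0, 50.0])

    def test_lone_site_contributes_nothing(self):
        ann = FunctionalAnnotation()
        ann.add("P1", "sugar", 5)
        dist = distance_distribution(ann)
        assert dist["sugar"].isna().all()

    def test_percentages_sum_to_100(self):
        ann = FunctionalAnnotation()
        rng = np.random.default_rng(3)
        for p, positions in enumerate(rng.integers(1, 900, size=(4, 8))):
            for pos in positions:
                ann.add(f"P{p}", "metal", int(pos))
        dist = distance_distribution(ann)
        assert dist["metal"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_huge_distances_clamped_into_last_bin(self):
        ann = FunctionalAnnotation()
        ann.add("P1", "DNA/RNA", 1)
        ann.add("P1", "DNA/RNA", 2000)
        dist = distance_distribution(ann)
        assert dist.loc["30-1000", "DNA/RNA"] == pytest.approx(100.0)

    def test_all_pairs_variant(self):
        ann = FunctionalAnnotation()
        for pos in (1, 3, 40):
            ann.add("P1", "heme", pos)
        dist = distance_distribution(ann, all_pairs=True)
        # pairs: 2, 37, 39 -> 1/3 in bin 1, 0, 2/3 in bin 3
        assert dist["heme"].tolist() == pytest.approx([100 / 3, 0.0, 200 / 3])


class TestBenchmarkSummary:
    def test_counts_distinct_residues_per_category(self):
        ann = FunctionalAnnotation()
        for pos in (10, 20, 30):
            ann.add("P1", "metal", pos)
        ann.add("P2", "sugar", 5)
        ann.add("P2", "sugar", 5)  # duplicate position
        counts = benchmark_summary(ann)
        assert counts["metal"] == 3
        assert counts["sugar"] == 1

    def test_empty_annotation(self):
        assert benchmark_summary(FunctionalAnnotation()).empty


class TestProteinLoReport:
    def test_planted_sites_score_high_at_high_cutoff(self):
        msa, truth = generate_msa(L=40, N=200,
                                  planted=[(4, 20, 1.0), (9, 33, 1.0)], seed=6)
        ann = generate_annotation(truth, category="metal")
        m = covariance_matrix(msa, "chi2")
        report = protein_lo_report(m, ann, "synthetic", cutoffs=[0.1, 0.6])
        assert set(report.index) == set(truth.planted_positions())
        # each planted residue's only strong partner is its planted mate
        assert (report[0.6].dropna() > 1.0).all()

    def test_cutoff_above_matrix_maximum_gives_all_na(self):
        msa, truth = generate_msa(L=20, N=50, planted=[(3, 11, 1.0)], seed=6)
        ann = generate_annotation(truth, category="metal")
        m = covariance_matrix(msa, "chi2")
        report = protein_lo_report(m, ann, "synthetic", cutoffs=[0.99])
        assert report[0.99].isna().all()

    def test_unannotated_protein_gives_empty_report(self):
        msa, truth = generate_msa(L=20, N=50, seed=6)
        m = covariance_matrix(msa, "chi2")
        report = protein_lo_report(m, FunctionalAnnotation(), "synthetic", [0.5])
        assert report.empty

    def test_clique_mode_reports_best_clique_lo(self):
        msa, truth = generate_msa(L=30, N=200, planted=[(4, 20, 1.0)], seed=8)
        ann = generate_annotation(truth, category="metal")
        m = covariance_matrix(msa, "chi2")
        report = protein_lo_report(m, ann, "synthetic", cutoffs=[0.6],
                                   mode="clique")
        g = build_graph(m, 0.6)
        assert set(map(tuple, map(sorted, g.edges()))) == {(4, 20)}
        # the 2-clique {4, 20} is all-functional: LO = ln((1/1)/(1/29))
        assert report.loc[4, 0.6] == pytest.approx(math.log(29))
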