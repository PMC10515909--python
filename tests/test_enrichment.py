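import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from entorip.domainsets import build_domain_count_matrix
from entorip.enrichment import (
    NO_PFAM, DegenerateTableError, EnrichmentParams, chi_squared_2x2,
    fisher_exact_batch, fisher_exact_two_sided, fold_vs_median,
    gene_set_domain_enrichment, pairwise_domain_enrichment)
from entorip.io_core import ValidationError
from entorip.synthetic_data import (PlantedEnrichment, SimAnnotationParams,
                                    simulate_domain_count_matrix)

from conftest import annot


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration over all tables with the same margins."""
    r1, r2, m = a + b, c + d, a + c
    denom = math.comb(r1 + r2, m)
    obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, m - r2), min(r1, m) + 1):
        prob = Fraction(math.comb(r1, k) * math.comb(r2, m - k), denom)
        if prob <= obs * (Fraction(10**7 + 1, 10**7)):
            total += prob
    return float(min(total, 1))


table_strategy = st.tuples(
    st.integers(0, 40), st.integers(0, 40),
    st.integers(0, 40), st.integers(0, 40)).filter(
        lambda t: t[0] + t[1] > 0 and t[2] + t[3] > 0
        and t[0] + t[2] > 0 and t[1] + t[3] > 0)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((3, 1, 1, 3), 34 / 70),
        ((0, 5, 5, 0), 2 / 252),
        ((2, 2, 2, 2), 1.0),
    ])
    def test_enumerated_examples(self, table, expected):
        assert fisher_exact_two_sided(*table) == pytest.approx(expected)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            fisher_exact_two_sided(0, 0, 3, 4)

    @given(table_strategy)
    @settings(max_examples=300, deadline=None)
    def test_matches_rational_oracle_and_scipy(self, table):
        p = fisher_exact_two_sided(*table)
        assert p == pytest.approx(fisher_oracle(*table), abs=1e-12)
        a, b, c, d = table
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1],
                                  abs=1e-9)
        assert 0 < p <= 1

    @given(table_strategy)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_in_genome_order(self, table):
        a, b, c, d = table
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            fisher_exact_two_sided(c, d, a, b))

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 60, size=300)
        c = rng.integers(0, 60, size=300)
        b, d = 2000 - a, 2000 - c
        p_batch = fisher_exact_batch(a, b, c, d)
        for i in range(0, 300, 17):
            assert p_batch[i] == pytest.approx(
                fisher_exact_two_sided(a[i], b[i], c[i], d[i]), rel=1e-9)

    def test_batch_zero_column_margin_is_one(self):
        p = fisher_exact_batch([0], [10], [0], [10])
        assert p[0] == 1.0


class TestChiSquared:
    def test_printed_secretion_table(self):
        stat, p = chi_squared_2x2(17, 3, 45, 60)
        assert p == pytest.approx(0.00055, abs=5e-5)

    def test_flat_table(self):
        stat, p = chi_squared_2x2(10, 10, 10, 10)
        assert stat == 0
        assert p == pytest.approx(1.0)

    def test_diagonal_statistic(self):
        stat, _ = chi_squared_2x2(20, 0, 0, 20)
        assert stat == pytest.approx(40.0)

    def test_continuity_correction_shrinks_statistic(self):
        plain, _ = chi_squared_2x2(17, 3, 45, 60)
        corrected, _ = chi_squared_2x2(17, 3, 45, 60,
                                       continuity_correction=True)
        assert corrected < plain

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_squared_2x2(0, 0, 5, 5)


class TestFoldVsMedian:
    def test_bdfae_counts(self):
        counts = {"EMU": 1, "EMA": 2, "ZRA": 3, "CCO": 23, "NTH": 25,
                  "PFO": 20, "SCA": 23}
        fold, direction, median = fold_vs_median(counts, "EMU")
        assert median == 20
        assert fold == pytest.approx(20.0)
        assert direction == "down"

    def test_lipase_fold_up(self):
        counts = {"EMU": 348, "EMA": 132, "ZRA": 190, "a": 66, "b": 66,
                  "c": 40, "d": 30}
        fold, direction, median = fold_vs_median(counts, "EMU")
        assert median == 66
        assert fold == pytest.approx(348 / 66)
        assert fold >= 5
        assert direction == "up"

    def test_all_equal_at_median(self):
        fold, direction, _ = fold_vs_median({"a": 5, "b": 5, "c": 5}, "a")
        assert fold == 1.0
        assert direction == "at_median"

    def test_zero_vs_positive_median_is_infinite(self):
        fold, direction, _ = fold_vs_median({"a": 0, "b": 4, "c": 6}, "a")
        assert math.isinf(fold)
        assert direction == "down"

    def test_unknown_focal(self):
        with pytest.raises(KeyError):
            fold_vs_median({"a": 1, "b": 2}, "zz")


class TestPairwiseEnrichment:
    def _matrix(self, columns, totals_value=10_000):
        """columns: dict accession -> per-genome counts (list)."""
        genomes = [f"G{i + 1}" for i in range(
            len(next(iter(columns.values()))))]
        records = []
        for acc, counts in columns.items():
            for g, n in zip(genomes, counts):
                for k in range(n):
                    records.append(annot(g, f"{g}_{acc}_{k}", acc))
        totals = {g: totals_value for g in genomes}
        return build_domain_count_matrix(records, totals)

    def test_identical_margins_nothing_significant(self):
        m = self._matrix({"PF1": [30, 30, 30, 30]})
        for r in pairwise_domain_enrichment(m):
            assert r.n_significant_pairs == 0

    def test_strong_focal_enrichment_all_pairs(self):
        m = self._matrix({"PF1": [300, 30, 30, 30, 30, 30, 30]})
        results = {r.genome: r for r in pairwise_domain_enrichment(m)}
        focal = results["G1"]
        assert focal.n_significant_pairs == 6
        assert focal.direction == "up"
        assert focal.representation == "over"

    def test_single_genome_domain_skipped(self):
        m = self._matrix({"PF1": [5, 0, 0], "PF2": [5, 5, 5]})
        by_domain = {}
        for r in pairwise_domain_enrichment(m):
            by_domain.setdefault(r.domain[0], []).append(r)
        assert all(r.skipped for r in by_domain["PF1"])
        assert not any(r.skipped for r in by_domain["PF2"])

    def test_bonferroni_factor_is_pair_count(self):
        m = self._matrix({"PF1": [40, 10, 10]}, totals_value=500)
        results = {r.genome: r for r in pairwise_domain_enrichment(m)}
        raw = fisher_exact_two_sided(40, 460, 10, 490)
        adj = results["G1"].pairwise_adjusted_p["G2"]
        assert adj == pytest.approx(min(1.0, raw * 3), rel=1e-6)


class TestGeneSetEnrichment:
    def _universe(self, n_genes, domain_genes):
        """records giving PF0001 to the first ``domain_genes`` genes."""
        return ([annot("g", f"gene{i}", "PF0001")
                 for i in range(domain_genes)],
                [f"gene{i}" for i in range(n_genes)])

    def test_planted_odds_ratio(self):
        records, universe = self._universe(1000, 100)
        gene_set = [f"gene{i}" for i in range(50)] + [
            f"gene{i}" for i in range(900, 950)]
        results = {r.pfam: r for r in gene_set_domain_enrichment(
            gene_set, records, universe_genes=universe)}
        r = results["PF0001"]
        assert (r.in_set_with, r.in_set_without) == (50, 50)
        assert (r.out_set_with, r.out_set_without) == (50, 850)
        assert r.odds_ratio == pytest.approx(17.0)
        assert r.significant

    def test_no_pfam_pseudo_domain(self):
        records, universe = self._universe(100, 40)
        results = {r.pfam: r for r in gene_set_domain_enrichment(
            [f"gene{i}" for i in range(95, 100)], records,
            universe_genes=universe)}
        r = results[NO_PFAM]
        assert r.in_set_with == 5  # genes 95-99 carry no Pfam
        assert r.out_set_with == 55

    def test_set_equals_universe_degenerate(self):
        records, universe = self._universe(50, 10)
        results = gene_set_domain_enrichment(universe, records,
                                             universe_genes=universe)
        assert all(r.degenerate for r in results)
        assert all(r.odds_ratio == 1.0 for r in results)
        assert not any(r.significant for r in results)

    def test_set_gene_outside_universe_rejected(self):
        records, universe = self._universe(10, 5)
        with pytest.raises(ValidationError):
            gene_set_domain_enrichment(["stranger"], records,
                                       universe_genes=universe)


class TestCalibration:
    def test_null_fwer_and_planted_power_small(self):
        """Few replicates of the null/planted design (full study in the
        acceptance suite): family-wise FP rate stays near the Bonferroni
        level and an 8-fold planted effect is found."""
        n_fp_domains = n_domains = n_rec = n_planted = 0
        for rep in range(8):
            planted = (PlantedEnrichment("SYN00000", "G1", 8.0),)
            matrix, _ = simulate_domain_count_matrix(SimAnnotationParams(
                n_genomes=7, n_domains=120, baseline_lambda=20.0,
                totals=5000, planted_enrichments=planted, seed=900 + rep))
            fp_domains = set()
            for r in pairwise_domain_enrichment(matrix, EnrichmentParams()):
                if r.skipped:
                    continue
                if r.domain[0] == "SYN00000":
                    if r.genome == "G1":
                        n_planted += 1
                        if r.representation == "over":
                            n_rec += 1
                elif r.n_significant_pairs >= 1:
                    fp_domains.add(r.domain[0])
            n_fp_domains += len(fp_domains)
            n_domains += 119
        assert n_rec == n_planted == 8
        assert n_fp_domains / n_domains <= 0.05
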