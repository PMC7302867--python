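import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage

from polytract import (
    EnrichmentResult,
    Territory,
    binom_p,
    bonferroni_flag,
    compute_overlap,
    embed_binomial_p,
    enrich,
    find_hinges,
    hypergeom_embed_test,
    ks_species_matrix,
    length_density_correlation,
    relative_risk,
    rr_heatmap_impute,
    scan_sequence,
    territory_from_hinges,
    territory_from_tracts,
)

from .oracles import (
    oracle_binom_over,
    oracle_binom_under,
    oracle_hypergeom_over,
    oracle_ks,
    oracle_overlap,
    oracle_pearson,
)


class TestTerritory:
    def test_size_must_match_intervals(self):
        with pytest.raises(ValueError):
            Territory(N=100, n=5, intervals={"c": [(0, 10)]}, seq_lengths={"c": 100})

    def test_from_tracts_extension_default(self, small_genome):
        genome, _ = small_genome
        sizes = {"chr1": len(genome)}
        tracts = scan_sequence(genome, chrom="chr1")
        exact = territory_from_tracts(tracts, sizes, extend=False)
        ext = territory_from_tracts(tracts, sizes)  # extension is the default
        assert ext.extended and not exact.extended
        assert ext.n > exact.n
        # each tract contributes at most 2 extra nucleotides
        assert ext.n <= exact.n + 2 * len(tracts)

    def test_union_territory_not_larger_than_clade_sum(self, small_genome):
        genome, _ = small_genome
        sizes = {"chr1": len(genome)}
        tracts = scan_sequence(genome, chrom="chr1")
        union = territory_from_tracts(tracts, sizes, extend=False)
        total = sum(
            territory_from_tracts(tracts, sizes, clades=[c], extend=False).n
            for c in ("MNR", "DNR", "TNR")
            if any(t.clade == c for t in tracts)
        )
        assert union.n <= total

    def test_hinge_territory(self, small_genome):
        genome, _ = small_genome
        sizes = {"chr1": len(genome)}
        hinges = find_hinges(scan_sequence(genome, chrom="chr1"))
        assert hinges
        terr = territory_from_hinges(hinges, sizes)
        assert terr.n == len(hinges)
        assert all(terr.contains("chr1", h.pos) for h in hinges)


class TestComputeOverlap:
    def test_point_inside_singleton(self, toy_territory):
        ov = compute_overlap([("chr1", 50, 51)], toy_territory, "singleton")
        assert (ov.k, ov.M) == (1, 1)

    def test_interval_multiplex(self):
        terr = Territory(
            N=100, n=10, intervals={"c": [(10, 20)]}, seq_lengths={"c": 100}
        )
        ov = compute_overlap([("c", 5, 15)], terr, "multiplex")
        assert (ov.k, ov.M) == (5, 10)

    def test_instance_spanning_two_intervals_counts_once(self):
        terr = Territory(
            N=100, n=10, intervals={"c": [(10, 15), (20, 25)]}, seq_lengths={"c": 100}
        )
        ov = compute_overlap([("c", 12, 23)], terr, "singleton")
        assert (ov.k, ov.M) == (1, 1)

    def test_out_of_bounds_clipped_with_warning(self):
        terr = Territory(N=50, n=10, intervals={"c": [(40, 50)]}, seq_lengths={"c": 50})
        with pytest.warns(UserWarning, match="clipped"):
            ov = compute_overlap([("c", 45, 60)], terr, "multiplex")
        assert (ov.k, ov.M) == (5, 5)

    @pytest.mark.parametrize("mode", ["singleton", "multiplex"])
    def test_random_intervals_match_per_nucleotide_count(self, mode, toy_territory):
        rng = np.random.default_rng(23)
        starts = rng.integers(0, 99_000, size=200)
        lengths = rng.integers(1, 60, size=200)
        feats = [("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)]
        ov = compute_overlap(feats, toy_territory, mode)
        k, M = oracle_overlap(feats, toy_territory.intervals, mode)
        assert (ov.k, ov.M) == (k, M)


GRID = [
    (k, M, n, N)
    for M in (1, 2, 5, 10, 25, 50)
    for k in (0, 1, M // 2, M)
    for (n, N) in ((1, 10), (50, 100), (100, 1000), (999, 1000))
    if k <= M
]


class TestBinomP:
    def test_two_of_two(self):
        assert binom_p(2, 2, 50, 100, "over") == pytest.approx(0.25)

    def test_k_zero_over_is_one(self):
        for M in (1, 7, 100):
            assert binom_p(0, M, 30, 100, "over") == 1.0

    @pytest.mark.parametrize("k,M,n,N", GRID)
    def test_exact_tails_against_rational_oracle(self, k, M, n, N):
        for direction, oracle in (("over", oracle_binom_over), ("under", oracle_binom_under)):
            got = binom_p(k, M, n, N, direction)
            want = float(oracle(k, M, n, N))
            assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize("k,M,n,N", [g for g in GRID if g[0] >= 1])
    def test_tail_complementarity(self, k, M, n, N):
        assert binom_p(k, M, n, N, "over") + binom_p(k - 1, M, n, N, "under") == pytest.approx(1.0, rel=1e-12)

    def test_monotone_in_k(self):
        M, n, N = 40, 100, 1000
        over = [binom_p(k, M, n, N, "over") for k in range(M + 1)]
        under = [binom_p(k, M, n, N, "under") for k in range(M + 1)]
        assert all(a >= b for a, b in zip(over, over[1:]))
        assert all(a <= b for a, b in zip(under, under[1:]))

    def test_role_swapped_parameterization(self):
        # the published alternative uses Binomial(n, M/N); numerically different
        got = binom_p(3, 10, 100, 1000, "over", swap_roles=True)
        want = float(oracle_binom_over(3, 100, 10, 1000))
        assert got == pytest.approx(want, rel=1e-12)
        assert got != pytest.approx(binom_p(3, 10, 100, 1000, "over"), rel=1e-3)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            binom_p(3, 2, 50, 100)
        with pytest.raises(ValueError):
            binom_p(1, 2, 200, 100)
        with pytest.raises(ValueError):
            binom_p(1, 2, 50, 100, direction="sideways")


class TestRelativeRisk:
    def test_null_rate(self):
        rr, lo, hi = relative_risk(5, 10, 50, 100)
        assert rr == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_double_rate(self):
        assert relative_risk(10, 10, 50, 100)[0] == pytest.approx(2.0)

    def test_k_zero_flagged(self):
        rr, lo, hi = relative_risk(0, 10, 50, 100)
        assert rr == 0.0
        assert math.isnan(lo) and math.isnan(hi)

    def test_ci_matches_parametric_bootstrap(self):
        # k ~ Binomial(100, 0.4) under RR = 2 with n/N = 0.2
        k, M, n, N = 40, 100, 200, 1000
        rr, lo, hi = relative_risk(k, M, n, N)
        assert lo < 2.0 < hi
        rng = np.random.default_rng(31)
        boot = rng.binomial(M, 0.4, size=200_000) / M / (n / N)
        b_lo, b_hi = np.quantile(boot, [0.025, 0.975])
        # Katz interval and the bootstrap percentile interval agree coarsely
        assert lo == pytest.approx(b_lo, rel=0.08)
        assert hi == pytest.approx(b_hi, rel=0.08)


class TestHypergeomEmbed:
    def test_saturated_population(self):
        assert hypergeom_embed_test(5, 5, 100, 100) == pytest.approx(1.0)

    def test_k_zero(self):
        assert hypergeom_embed_test(5, 0, 100, 20) == 1.0

    def test_against_enumeration(self):
        got = hypergeom_embed_test(5, 4, 100, 20)
        want = float(oracle_hypergeom_over(5, 4, 100, 20))
        assert got == pytest.approx(want, rel=1e-12)

    def test_rejects_oversized_draw(self):
        with pytest.raises(ValueError):
            hypergeom_embed_test(101, 5, 100, 20)

    def test_binomial_alternative_tracks_enumeration(self):
        # one trial per region with q = 1 - (1 - n/N)^L; at L = 1 the trial
        # probability reduces to n/N and the exact oracle applies
        got = embed_binomial_p(10, 3, 1000, 100, L=1)
        want = float(oracle_binom_over(3, 10, 100, 1000))
        assert got == pytest.approx(want, rel=1e-12)
        # longer regions embed more easily, so the same k_e grows less surprising
        ps = [embed_binomial_p(10, 3, 1000, 100, L=L) for L in (1, 5, 50)]
        assert ps[0] < ps[1] < ps[2]


class TestBonferroni:
    def test_landscape_threshold(self):
        flags = bonferroni_flag([5e-5, 2e-4, 5e-3], alpha=0.01, m_tests=94)
        assert flags.tolist() == [True, False, False]

    def test_single_test(self):
        assert bonferroni_flag([5e-3], alpha=0.01, m_tests=1).tolist() == [True]

    def test_explicit_threshold_policy(self):
        flags = bonferroni_flag([5e-5, 1.05e-4], threshold=1e-4)
        assert flags.tolist() == [True, False]


class TestRRImpute:
    @pytest.mark.parametrize(
        "rr,p,expected",
        [(0.5, 1e-9, 1.0), (3.2, 0.2, 1.0), (3.2, 1e-5, 3.2)],
    )
    def test_over_view(self, rr, p, expected):
        df = pd.DataFrame(
            [{"feature": "f", "subset": "s", "RR": rr, "p": p}]
        )
        out = rr_heatmap_impute(df, direction="over")
        assert out.loc["f", "s"] == pytest.approx(expected)

    def test_under_view_symmetric(self):
        df = pd.DataFrame(
            [
                {"feature": "f", "subset": "a", "RR": 0.2, "p": 1e-6},
                {"feature": "f", "subset": "b", "RR": 3.0, "p": 1e-6},
            ]
        )
        out = rr_heatmap_impute(df, direction="under")
        assert out.loc["f", "a"] == pytest.approx(0.2)
        assert out.loc["f", "b"] == pytest.approx(1.0)


class TestKSMatrix:
    def test_identical_samples(self):
        m = ks_species_matrix({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert m.D[0, 1] == 0.0

    def test_disjoint_supports(self):
        m = ks_species_matrix({"a": [1, 1, 1], "b": [2, 2, 2]})
        assert m.D[0, 1] == 1.0

    def test_small_sample_against_ecdf_enumeration(self):
        a, b = [6, 7, 9], [6, 10, 12]
        m = ks_species_matrix({"a": a, "b": b})
        assert m.D[0, 1] == pytest.approx(oracle_ks(a, b))

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        samples = {f"s{i}": rng.poisson(9 + i, size=50) + 6 for i in range(5)}
        m = ks_species_matrix(samples)
        assert np.allclose(m.D, m.D.T)
        assert np.all(np.diag(m.D) == 0)
        assert np.all((m.D >= 0) & (m.D <= 1))

    def test_short_sample_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            m = ks_species_matrix({"a": [1, 2, 3], "b": [5], "c": [2, 3, 9]})
        assert m.labels == ["a", "c"]

    def test_dendrogram_reproducible(self):
        rng = np.random.default_rng(7)
        samples = {f"s{i}": rng.poisson(9 + i, size=40) + 6 for i in range(6)}
        z1 = ks_species_matrix(samples).linkage
        z2 = ks_species_matrix(samples).linkage
        assert np.array_equal(z1, z2)


class TestLengthDensityCorrelation:
    def test_perfectly_linear(self):
        r, p = length_density_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_anti_linear(self):
        r, _ = length_density_correlation([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_random_pairs_match_textbook_formula(self):
        rng = np.random.default_rng(13)
        x = rng.random(10).tolist()
        y = rng.random(10).tolist()
        r, _ = length_density_correlation(x, y)
        assert r == pytest.approx(oracle_pearson(x, y), rel=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = length_density_correlation([1, 1, 1], [2, 3, 4])
        assert math.isnan(r) and math.isnan(p)


class TestEnrichPipeline:
    def test_end_to_end_fields(self, toy_territory):
        feats = [("chr1", i * 333 + 10, i * 333 + 11) for i in range(50)]
        res = enrich(feats, toy_territory, feature_id="planted")
        assert isinstance(res, EnrichmentResult)
        assert (res.k, res.M) == (50, 50)
        assert res.RR == pytest.approx((50 / 50) / (toy_territory.n / toy_territory.N))
        assert res.significant and res.p < 1e-10
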