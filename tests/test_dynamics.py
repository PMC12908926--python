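"""Diversity-parabola fitting, pre/post classification, switch-point
distances and breakpoint homology."""

import numpy as np
import pytest

from admixsv.core_io import (
    AncestryTract,
    GenomicInterval,
    PopulationPanel,
    ValidationError,
    switch_points,
)
from admixsv.dynamics import (
    DiversityPoint,
    breakpoint_homology,
    classify_pre_post,
    diversity_points,
    fit_diversity_models,
    homology_enrichment_fisher,
    permutation_parabola_test,
    segregating_sites,
    sequential_subpopulations,
    switch_distance,
    switch_enrichment_test,
)
from conftest import make_sv


def panel_with_ancestry(anc):
    n = len(anc)
    return PopulationPanel([f"s{i}" for i in range(n)], ["ADMIXED"] * n,
                           ancestry_west=np.asarray(anc))


class TestSubpopulations:
    def test_exact_k_gives_one_window(self):
        panel = panel_with_ancestry(np.linspace(0.2, 0.8, 5))
        assert len(sequential_subpopulations(panel, k=5)) == 1

    def test_window_means_non_decreasing_and_match_sort(self):
        rng = np.random.default_rng(0)
        anc = rng.random(30)
        panel = panel_with_ancestry(anc)
        wins = sequential_subpopulations(panel, k=10)
        east = 1 - anc
        order = np.argsort(east)
        means = [east[w].mean() for w in wins]
        assert (np.diff(means) >= -1e-12).all()
        # brute-force sort-and-slice oracle
        for i, w in enumerate(wins):
            assert sorted(w) == sorted(order[i:i + 10])

    def test_small_cohort_errors(self):
        with pytest.raises(ValidationError):
            sequential_subpopulations(panel_with_ancestry([0.5, 0.5]), k=5)


class TestSegregatingSites:
    def test_monomorphic_zero_and_singleton_counted(self):
        fixed = make_sv("f", genotypes=[2, 2, 2])
        absent = make_sv("a", genotypes=[0, 0, 0])
        single = make_sv("s", genotypes=[1, 0, 0])
        idx = np.array([0, 1, 2])
        assert segregating_sites([fixed, absent], idx) == 0
        assert segregating_sites([single], idx) == 1

    def test_duplications_excluded_by_default(self):
        dup = make_sv("d", svtype="DUP", genotypes=[1, 0, 0])
        assert segregating_sites([dup], np.array([0, 1, 2])) == 0
        assert segregating_sites([dup], np.array([0, 1, 2]),
                                 exclude_types=frozenset()) == 1

    def test_matches_per_column_oracle(self):
        rng = np.random.default_rng(1)
        recs = [make_sv(f"v{i}", genotypes=rng.integers(0, 3, 12),
                        svtype=str(rng.choice(["DEL", "INS", "INV"])))
                for i in range(100)]
        idx = np.array([0, 3, 5, 7, 8])
        expected = 0
        for r in recs:
            ac = r.genotypes[idx].sum()
            expected += 0 < ac < 2 * len(idx)
        assert segregating_sites(recs, idx) == expected


class TestFits:
    def test_exact_parabola_interpolated(self):
        x = np.linspace(0.2, 0.8, 9)
        y = -100 * (x - 0.5) ** 2 + 50
        pts = [DiversityPoint(xi, yi, None) for xi, yi in zip(x, y)]
        fit = fit_diversity_models(pts)
        assert fit.r2_quad == pytest.approx(1.0)
        assert fit.vertex == pytest.approx(0.5, abs=1e-9)

    def test_exact_line_nested_models_equal(self):
        x = np.linspace(0, 1, 8)
        pts = [DiversityPoint(xi, 3 * xi + 1, None) for xi in x]
        fit = fit_diversity_models(pts)
        assert fit.r2_quad == pytest.approx(fit.r2_lin)
        assert fit.delta_r2 == pytest.approx(0.0, abs=1e-9)

    def test_three_point_normal_equations_oracle(self):
        pts = [DiversityPoint(0.0, 1.0, None), DiversityPoint(0.5, 2.0, None),
               DiversityPoint(1.0, 1.5, None), DiversityPoint(0.25, 1.6, None),
               DiversityPoint(0.75, 1.9, None)]
        x = np.array([p.east_mean for p in pts])
        y = np.array([p.segregating for p in pts], float)
        X = np.column_stack([x**2, x, np.ones_like(x)])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_diversity_models(pts)
        np.testing.assert_allclose(fit.quad_coef, coef, atol=1e-9)

    def test_degenerate_x_errors(self):
        pts = [DiversityPoint(0.5, float(i), None) for i in range(6)]
        with pytest.raises(ValidationError):
            fit_diversity_models(pts)


class TestParabolaPermutation:
    def test_p_bounds_and_null_calibration(self):
        rng = np.random.default_rng(2)
        n = 40
        panel = panel_with_ancestry(rng.random(n))
        recs = [make_sv(f"v{i}", genotypes=rng.integers(0, 3, n))
                for i in range(150)]
        ps = []
        for seed in range(8):
            fit = permutation_parabola_test(panel, recs, k=20,
                                            permutations=99, seed=seed)
            ps.append(fit.p_permutation)
            assert 1 / 100 <= fit.p_permutation <= 1
        # genotypes independent of ancestry: P should not pile up small
        assert np.median(ps) > 0.1


class TestPrePost:
    def test_rule_order(self):
        sv = make_sv("q", start=100, end=600, genotypes=[1, 0])
        in_west = [make_sv("w", start=100, end=600, genotypes=[1, 1])]
        absent_west = [make_sv("w", start=100, end=600, genotypes=[0, 0])]
        east_empty = []
        catalog = [[(GenomicInterval("chr1", 100, 600), "DEL")]]
        # polymorphic panel match -> pre
        assert classify_pre_post([sv], in_west, east_empty).label[0] == "pre"
        # monomorphic panel, catalog hit -> ambiguous
        assert classify_pre_post([sv], absent_west, east_empty,
                                 catalog).label[0] == "ambiguous"
        # nothing anywhere -> post
        assert classify_pre_post([sv], absent_west, east_empty).label[0] == "post"

    def test_generator_truth_recovery(self, small_sim):
        from admixsv.core_io import MISSING
        sim = small_sim
        svs = [r for r in sim.sv_records
               if (r.genotypes[r.genotypes != MISSING]
                   != (2 if r.svtype == "mCNV" else 0)).any()]
        lab = classify_pre_post(svs, sim.panels.sv_records("SRC_WEST"),
                                sim.panels.sv_records("SRC_EAST"))
        lab_of = dict(zip(lab.id, lab.label))
        post_true = {r.id for r in svs if r.id.startswith("postsv")}
        # every injected post-admixture SV must be labeled post
        assert all(lab_of[i] == "post" for i in post_true)


class TestSwitchDistance:
    def _tracts(self):
        return [
            AncestryTract("s0", 0, GenomicInterval("chr1", 0, 1000), "WEST"),
            AncestryTract("s0", 0, GenomicInterval("chr1", 1000, 5000), "EAST"),
            AncestryTract("s0", 1, GenomicInterval("chr1", 0, 5000), "WEST"),
            AncestryTract("s1", 0, GenomicInterval("chr1", 0, 3000), "EAST"),
            AncestryTract("s1", 0, GenomicInterval("chr1", 3000, 5000), "WEST"),
            AncestryTract("s1", 1, GenomicInterval("chr1", 0, 5000), "EAST"),
        ]

    def test_boundary_zero_and_min_over_carriers(self):
        b = switch_points(self._tracts())
        samples = ["s0", "s1"]
        at_boundary = make_sv("x", start=1000, end=1100, genotypes=[1, 0])
        assert switch_distance(at_boundary, b, samples) == 0
        # carried by both: min over all carrier haplotypes
        both = make_sv("y", start=2000, end=2100, genotypes=[1, 1])
        assert switch_distance(both, b, samples) == 1000  # chr boundary at 1000 and 3000

    def test_no_switch_haplotypes_inf(self):
        tracts = [AncestryTract("s0", h, GenomicInterval("chr1", 0, 5000), "WEST")
                  for h in (0, 1)]
        sv = make_sv("z", start=2000, end=2100, genotypes=[1])
        assert switch_distance(sv, switch_points(tracts), ["s0"]) == np.inf

    def test_no_carrier_errors(self):
        sv = make_sv("z", genotypes=[0, 0])
        with pytest.raises(ValidationError):
            switch_distance(sv, switch_points(self._tracts()), ["s0", "s1"])

    def test_matches_brute_force_over_boundaries(self):
        rng = np.random.default_rng(3)
        tracts, samples = [], []
        for i in range(6):
            s = f"s{i}"
            samples.append(s)
            for h in (0, 1):
                cuts = np.sort(rng.choice(np.arange(1000, 49_000), 4,
                                          replace=False))
                edges = [0, *cuts.tolist(), 50_000]
                for j, (a, bnd) in enumerate(zip(edges, edges[1:])):
                    tracts.append(AncestryTract(
                        s, h, GenomicInterval("chr1", a, bnd),
                        "WEST" if j % 2 == 0 else "EAST"))
        b = switch_points(tracts)
        for _ in range(20):
            pos = int(rng.integers(0, 50_000))
            geno = rng.integers(0, 3, 6)
            if geno.sum() == 0:
                geno[0] = 1
            sv = make_sv("q", start=pos, end=pos + 60, genotypes=geno)
            brute = min(
                abs(pos - p)
                for i in np.flatnonzero(geno) for h in (0, 1)
                for p in b[(samples[i], h, "chr1")]
            )
            assert switch_distance(sv, b, samples) == brute


class TestSwitchEnrichment:
    def test_no_switches_refuses(self):
        tracts = [AncestryTract("s0", h, GenomicInterval("chr1", 0, 5000), "WEST")
                  for h in (0, 1)]
        sv = make_sv("p", start=100, end=200, genotypes=[1])
        with pytest.raises(ValidationError, match="switch"):
            switch_enrichment_test([sv], [], tracts, ["s0"], {"chr1": 5000})

    def test_constructed_enrichment_detected_and_null_mean_sane(self):
        rng = np.random.default_rng(4)
        L = 10_000_000
        tracts, samples = [], []
        for i in range(8):
            s = f"s{i}"
            samples.append(s)
            for h in (0, 1):
                cuts = np.sort(rng.choice(np.arange(100_000, L - 100_000), 6,
                                          replace=False))
                edges = [0, *cuts.tolist(), L]
                for j, (a, bnd) in enumerate(zip(edges, edges[1:])):
                    tracts.append(AncestryTract(
                        s, h, GenomicInterval("chr1", a, bnd),
                        "WEST" if j % 2 == 0 else "EAST"))
        b = switch_points(tracts)
        # post SVs planted right at switch points of their carrier
        post = []
        for k in range(25):
            i = k % 8
            pts = b[(samples[i], 0, "chr1")]
            pos = int(pts[k % len(pts)]) + int(rng.integers(-2000, 2000))
            geno = np.zeros(8, int)
            geno[i] = 1
            post.append(make_sv(f"post{k}", start=pos, end=pos + 100,
                                genotypes=geno))
        pre = []
        for k in range(60):
            start = int(rng.integers(0, L - 200))
            geno = rng.integers(0, 3, 8)
            if geno.sum() == 0:
                geno[0] = 1
            pre.append(make_sv(f"pre{k}", start=start, end=start + 150,
                               genotypes=geno))
        out = switch_enrichment_test(post, pre, tracts, samples, {"chr1": L},
                                     window=50_000, permutations=199, seed=5)
        assert out.statistic == 1.0
        assert out.p_value < 0.05
        # geometric null: ~ 2 * W * (#switches) / L coverage per haplotype,
        # increased by the union over carrier haplotypes
        assert 0 < out.null.mean() < 0.5
        # planted-uniform pre SVs pass the uniformity check
        assert out.pre_uniformity_p is None or out.pre_uniformity_p > 0.01


def _fix_end(sv, end):
    return sv


class TestBreakpointHomology:
    def test_planted_repeat_flagged_and_random_not(self):
        rng = np.random.default_rng(6)
        alphabet = np.array(list("ACGT"))
        repeat = "".join(rng.choice(alphabet, 200))
        left_fill = "".join(rng.choice(alphabet, 300))
        middle = "".join(rng.choice(alphabet, 3000))
        right_fill = "".join(rng.choice(alphabet, 300))
        seq = left_fill + repeat + middle + repeat + right_fill
        # SV between the repeats: left-outer flank ends with repeat 1,
        # right-outer flank begins with repeat 2
        sv_start = len(left_fill) + 200
        sv_end = sv_start + 3000
        sv = make_sv("nahr", start=sv_start, end=sv_end, genotypes=[1])
        out = breakpoint_homology(sv, {"chr1": seq}, flank=250)
        assert out["homologous"]
        assert out["identity"] >= 0.8

        misses = 0
        for _ in range(30):
            seq2 = "".join(rng.choice(alphabet, 8000))
            sv2 = make_sv("r", start=2000, end=6000, genotypes=[1])
            misses += not breakpoint_homology(sv2, {"chr1": seq2})["homologous"]
        assert misses >= 29

    def test_score_matches_dp_oracle_on_toys(self):
        def dp(a, b, match=1, mismatch=-1, gap=-2):
            n, m = len(a), len(b)
            H = np.zeros((n + 1, m + 1))
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = match if a[i - 1] == b[j - 1] else mismatch
                    H[i, j] = max(0, H[i - 1, j - 1] + s,
                                  H[i - 1, j] + gap, H[i, j - 1] + gap)
                    best = max(best, H[i, j])
            return best

        rng = np.random.default_rng(7)
        alphabet = np.array(list("ACGT"))
        for _ in range(10):
            left = "".join(rng.choice(alphabet, 30))
            right = "".join(rng.choice(alphabet, 30))
            seq = left + "A" * 100 + right
            sv = make_sv("t", start=30, end=130, genotypes=[1])
            out = breakpoint_homology(sv, {"chr1": seq}, flank=30,
                                      min_len=5, min_ident=0.9)
            assert out["score"] == pytest.approx(dp(left, right))

    def test_truncated_flank_noted(self):
        sv = make_sv("e", start=10, end=60, genotypes=[1], length=50)
        out = breakpoint_homology(sv, {"chr1": "ACGT" * 40}, flank=500)
        assert out["truncated"]


class TestFisher:
    def test_balanced_table(self):
        out = homology_enrichment_fisher([True] * 10 + [False] * 10,
                                         [True] * 10 + [False] * 10)
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p_two_sided"] == pytest.approx(1.0)

    def test_or4_matches_hypergeometric_enumeration(self):
        from scipy.stats import hypergeom
        at = [True] * 20 + [False] * 10
        el = [True] * 10 + [False] * 20
        out = homology_enrichment_fisher(at, el)
        assert out["odds_ratio"] == pytest.approx(4.0)
        # exhaustive two-sided exact P from the hypergeometric pmf
        M, n, N = 60, 30, 30
        probs = np.array([hypergeom.pmf(k, M, n, N) for k in range(0, 31)])
        p_exact = probs[probs <= probs[20] * (1 + 1e-9)].sum()
        assert out["p_two_sided"] == pytest.approx(p_exact, rel=1e-6)

    def test_zero_cell_haldane_anscombe(self):
        out = homology_enrichment_fisher([True] * 5 + [False] * 5,
                                         [False] * 10)
        assert out["haldane_anscombe"]
        assert out["odds_ratio"] > 1

    def test_empty_margin_errors(self):
        with pytest.raises(ValidationError):
            homology_enrichment_fisher([], [True, False])

    def test_planted_enrichment_power(self):
        rng = np.random.default_rng(8)
        wins = 0
        for _ in range(20):
            at = rng.random(100) < 0.6
            el = rng.random(100) < 0.3
            out = homology_enrichment_fisher(at, el)
            wins += out["odds_ratio"] > 1 and out["p_one_sided"] < 0.05
        assert wins >= 16
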