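"""cis-eQTL, eSV ratios, heritability partition, USVC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admixsv.core_io import (
    ExpressionMatrix,
    PopulationPanel,
    ValidationError,
)
from admixsv.regulome import (
    ancestry_specific_alleles,
    cis_eqtl,
    enumerate_usvc,
    esv_ratio,
    esv_set,
    esv_vs_divergence,
    hwe_expected_hom,
    joint_usvc_model,
    partition_heritability,
)
from conftest import make_snv, make_sv


def _expr(genes, tss, samples, values):
    return ExpressionMatrix(genes, ["chr1"] * len(genes),
                            np.asarray(tss), samples, np.asarray(values))


class TestCisEqtl:
    def test_planted_effect_recovered_within_2se(self):
        rng = np.random.default_rng(0)
        hits = sig = 0
        reps = 12
        for rep in range(reps):
            n = 80
            g = rng.binomial(2, 0.35, n)
            y_raw = 0.8 * g + rng.normal(0, 0.5, n)
            sd = y_raw.std()
            beta_std = 0.8 / sd        # z-scoring rescales the effect
            expr = _expr(["g1"], [1_000_000], [f"s{i}" for i in range(n)],
                         y_raw[None, :])
            sv = make_sv("sv1", start=1_100_000, end=1_100_300, genotypes=g)
            out = cis_eqtl(expr, [sv])
            row = out.iloc[0]
            sig += bool(row.significant)
            hits += abs(row.beta - beta_std) < 2 * row.se
        assert sig >= 0.9 * reps
        assert hits >= 0.9 * reps

    def test_window_rule_excludes_distant_variants(self):
        n = 30
        rng = np.random.default_rng(1)
        expr = _expr(["g1"], [2_000_000], [f"s{i}" for i in range(n)],
                     rng.normal(size=(1, n)))
        near = make_sv("near", start=2_900_000, end=2_900_200,
                       genotypes=rng.binomial(2, 0.5, n))
        far = make_sv("far", start=3_100_001, end=3_100_200,
                      genotypes=rng.binomial(2, 0.5, n))
        out = cis_eqtl(expr, [near, far])
        assert set(out.variant) == {"near"}

    def test_permuted_expression_bh_controls_false_positives(self):
        rng = np.random.default_rng(2)
        n, n_genes, n_vars = 60, 30, 40
        genes = [f"g{i}" for i in range(n_genes)]
        tss = rng.integers(500_000, 1_500_000, n_genes)
        expr = _expr(genes, tss, [f"s{i}" for i in range(n)],
                     rng.normal(size=(n_genes, n)))
        svs = [make_sv(f"v{i}", start=int(p), end=int(p) + 200,
                       genotypes=rng.binomial(2, 0.4, n))
               for i, p in enumerate(
                   rng.integers(400_000, 1_600_000, n_vars))]
        out = cis_eqtl(expr, svs, fdr=0.05)
        assert len(out) > 100
        assert out.significant.mean() <= 0.05

    def test_too_many_covariates_error(self):
        expr = _expr(["g1"], [100], ["a", "b", "c"], np.zeros((1, 3)))
        with pytest.raises(ValidationError):
            cis_eqtl(expr, [], covariates=np.zeros((3, 2)))


class TestEsvRatio:
    def test_self_comparison_near_one_and_reproducible(self):
        rng = np.random.default_rng(3)
        n = 40
        g = [rng.binomial(2, 0.4, n) for _ in range(6)]
        svs = [make_sv(f"v{i}", start=900_000 + 1000 * i,
                       end=900_200 + 1000 * i, genotypes=gi)
               for i, gi in enumerate(g)]
        y = np.vstack([1.0 * g[0] + rng.normal(0, 0.4, n),
                       -0.8 * g[3] + rng.normal(0, 0.4, n)])
        expr = _expr(["g1", "g2"], [1_000_000, 1_000_500],
                     [f"s{i}" for i in range(n)], y)
        out = esv_ratio(expr, svs, expr, svs, n_match=n, samplings=4, seed=0)
        assert out["esv_ratio_mean"] == pytest.approx(1.0)
        assert out["sv_ratio_mean"] == pytest.approx(1.0)
        out2 = esv_ratio(expr, svs, expr, svs, n_match=n, samplings=4, seed=0)
        assert out2["esv_ratio_mean"] == out["esv_ratio_mean"]

    def test_overlarge_match_errors(self):
        expr = _expr(["g1"], [100], ["a", "b"], np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            esv_ratio(expr, [], expr, [], n_match=5)


class TestEsvDivergence:
    def test_boundary_binning_and_null(self):
        # |df| = 0.025 belongs to the second bin under half-open binning
        esv = {"a": True, "b": False}
        fw = {"a": 0.5, "b": 0.525}
        fe = {"a": 0.475, "b": 0.5}
        out = esv_vs_divergence(esv, fw, fe)
        tab = out["table"]
        assert len(tab) == 1
        assert tab.bin_lo.iloc[0] == pytest.approx(0.025)

    def test_planted_monotone_relation_detected(self):
        rng = np.random.default_rng(4)
        ids = [f"v{i}" for i in range(3000)]
        div = rng.uniform(0, 0.6, 3000)
        fw = {i: 0.2 + d for i, d in zip(ids, div)}
        fe = {i: 0.2 for i in ids}
        esv = {i: bool(rng.random() < 0.1 + 0.8 * min(d, 0.5))
               for i, d in zip(ids, div)}
        out = esv_vs_divergence(esv, fw, fe)
        assert out["rho"] > 0.5
        assert out["p"] < 0.05

    def test_independent_flags_null_rho(self):
        rng = np.random.default_rng(5)
        rhos = []
        for rep in range(10):
            ids = [f"v{i}" for i in range(800)]
            fw = {i: float(rng.uniform(0, 1)) for i in ids}
            fe = {i: float(rng.uniform(0, 1)) for i in ids}
            esv = {i: bool(rng.random() < 0.3) for i in ids}
            rhos.append(esv_vs_divergence(esv, fw, fe)["rho"])
        assert abs(np.mean(rhos)) < 0.25


class TestHeritability:
    def test_pure_sv_signal_lead_sv(self):
        rng = np.random.default_rng(6)
        n = 100
        g = rng.binomial(2, 0.4, n).astype(float)
        Z = rng.binomial(2, 0.5, (n, 10)).astype(float)
        out = partition_heritability(g.copy(), g, Z)
        assert out["sv_share"] > 0.9
        assert out["lead_sv"] and out["is_genetic"]

    def test_polygenic_snv_signal_not_lead_sv(self):
        rng = np.random.default_rng(7)
        n = 150
        g = rng.binomial(2, 0.4, n).astype(float)
        Z = rng.binomial(2, 0.5, (n, 30)).astype(float)
        betas = rng.normal(0, 0.4, 30)
        y = Z @ betas + rng.normal(0, 0.5, n)
        out = partition_heritability(y, g, Z)
        assert not out["lead_sv"]
        assert out["snv_share"] > 0.3

    def test_pure_noise_rarely_genetic(self):
        rng = np.random.default_rng(8)
        flags = 0
        for _ in range(10):
            n = 100
            g = rng.binomial(2, 0.4, n).astype(float)
            Z = rng.binomial(2, 0.5, (n, 15)).astype(float)
            y = rng.normal(0, 1, n)
            flags += partition_heritability(y, g, Z)["is_genetic"]
        assert flags <= 4

    def test_needs_two_snvs(self):
        with pytest.raises(ValidationError):
            partition_heritability(np.zeros(10), np.zeros(10),
                                   np.zeros((10, 1)))


class TestHWE:
    @pytest.mark.parametrize("q,expected", [(0.0, 0.0), (0.1, 0.01),
                                            (1.0, 1.0)])
    def test_square(self, q, expected):
        assert hwe_expected_hom(q) == pytest.approx(expected)

    def test_low_frequency_homozygote_rarity(self):
        # a ~0.055 allele yields ~0.003 expected homozygotes
        assert hwe_expected_hom(0.0548) == pytest.approx(0.003, abs=2e-4)


class TestSpecificity:
    def test_strict_and_frequency_modes(self):
        variants = [make_sv("w"), make_sv("e"), make_sv("both"),
                    make_sv("rare_leak")]
        west = {"w": np.array([1, 1, 0]), "e": np.zeros(3, int),
                "both": np.array([2, 2, 2]), "rare_leak": np.array([1, 2, 0])}
        east = {"w": np.zeros(3, int), "e": np.array([0, 1, 0]),
                "both": np.array([2, 2, 2]), "rare_leak": np.array([1, 0, 0])}
        strict = ancestry_specific_alleles(variants, west, east)
        assert strict == {"w": "WEST", "e": "EAST"}
        relaxed = ancestry_specific_alleles(variants, west, east,
                                            max_other=0.2,
                                            frequency_mode=True)
        # the 0.5 vs 0.17 contrast now qualifies as WEST-specific
        assert relaxed["rare_leak"] == "WEST"


class TestUSVC:
    def _fixture(self):
        # 4 variants, 4 samples; spec labels set by construction
        sv_del = make_sv("del1", start=1000, end=2000, svtype="DEL",
                         genotypes=[1, 0, 1, 0])
        sv_dup = make_sv("dup1", start=500_000, end=501_000, svtype="DUP",
                         genotypes=[0, 1, 1, 0])
        snv_in = make_snv("snv_in", pos=1500, genotypes=[1, 1, 0, 0])
        snv_cis = make_snv("snv_cis", pos=600_000, genotypes=[0, 1, 0, 1])
        spec = {"del1": "EAST", "dup1": "WEST", "snv_in": "WEST",
                "snv_cis": "EAST"}
        samples = ["s0", "s1", "s2", "s3"]
        return [sv_del, sv_dup], [snv_in, snv_cis], spec, samples

    def test_matches_exhaustive_enumeration(self):
        svs, snvs, spec, samples = self._fixture()
        out = enumerate_usvc(svs, snvs, spec, samples)
        got = {(r.usvc_class, r.variant_a, r.variant_b) for r in out}
        # oracle: double loop over all pairs applying the three rules
        expected = set()
        for sv in svs:
            for snv in snvs:
                if spec[sv.id] == spec[snv.id]:
                    continue
                joint = (sv.genotypes > 0) & (snv.genotypes > 0)
                if not joint.any():
                    continue
                if (sv.svtype in ("DEL", "DUP")
                        and sv.interval.start <= snv.pos < sv.interval.end):
                    expected.add(("overlap-DEL-SNV", sv.id, snv.id))
                elif abs(snv.pos - sv.interval.start) <= 1_000_000:
                    expected.add(("cis-SV-SNV", sv.id, snv.id))
        for a, b in itertools.combinations(svs, 2):
            if spec[a.id] != spec[b.id] and (
                    (a.genotypes > 0) & (b.genotypes > 0)).any():
                if abs(b.interval.start - a.interval.start) <= 1_000_000:
                    expected.add(("cis-SV-SV", a.id, b.id))
        assert got == expected

    def test_same_ancestry_and_no_joint_carrier_excluded(self):
        svs, snvs, spec, samples = self._fixture()
        spec_same = dict(spec, snv_in="EAST")   # same side as del1
        out = enumerate_usvc(svs, snvs, spec_same, samples)
        assert not any(r.variant_b == "snv_in" and r.variant_a == "del1"
                       for r in out)
        # remove joint carriage
        svs[0] = make_sv("del1", start=1000, end=2000, svtype="DEL",
                         genotypes=[0, 0, 1, 0])
        snvs[0] = make_snv("snv_in", pos=1500, genotypes=[1, 1, 0, 0])
        out2 = enumerate_usvc(svs, snvs, spec, samples)
        assert not any(r.variant_a == "del1" and r.variant_b == "snv_in"
                       for r in out2)

    def test_joint_model_recovers_directions(self):
        rng = np.random.default_rng(9)
        n = 120
        samples = [f"s{i}" for i in range(n)]
        g_sv = rng.binomial(2, 0.3, n)
        g_snv = rng.binomial(2, 0.3, n)
        y_uni = -0.5 * g_sv - 0.5 * g_snv + rng.normal(0, 0.3, n)
        y_opp = -0.6 * g_sv + 0.6 * g_snv + rng.normal(0, 0.3, n)
        expr = _expr(["g_uni", "g_opp"], [1000, 2000], samples,
                     np.vstack([y_uni, y_opp]))
        sv = make_sv("sv1", start=1200, end=1400, genotypes=g_sv)
        snv = make_snv("snv1", pos=1300, genotypes=g_snv)
        from admixsv.regulome import USVCRecord
        rec = USVCRecord("overlap-DEL-SNV", "sv1", "WEST", "snv1", "EAST", [])
        out = joint_usvc_model(
            [rec], expr, {"sv1": g_sv, "snv1": g_snv},
            variant_positions={"sv1": ("chr1", 1200)})
        out = out.set_index("gene")
        assert bool(out.loc["g_uni", "significant"])
        assert out.loc["g_uni", "direction"] == "uni"
        assert out.loc["g_opp", "direction"] == "opposite"

    def test_collinear_pair_untestable(self):
        n = 40
        g = np.random.default_rng(10).binomial(2, 0.5, n)
        expr = _expr(["g1"], [1000], [f"s{i}" for i in range(n)],
                     np.random.default_rng(11).normal(size=(1, n)))
        from admixsv.regulome import USVCRecord
        rec = USVCRecord("cis-SV-SNV", "a", "WEST", "b", "EAST", [])
        out = joint_usvc_model([rec], expr, {"a": g, "b": g},
                               variant_positions={"a": ("chr1", 1000)})
        assert out.untestable.all()

    def test_null_expression_joint_fdr_bound(self, small_sim):
        # permuted expression: the dual-significance rule rejects ~0
        rng = np.random.default_rng(12)
        n = 100
        samples = [f"s{i}" for i in range(n)]
        genes = [f"g{i}" for i in range(20)]
        expr = _expr(genes, rng.integers(0, 2_000_000, 20), samples,
                     rng.normal(size=(20, n)))
        from admixsv.regulome import USVCRecord
        recs, genos, pos = [], {}, {}
        for i in range(15):
            a, b = f"sv{i}", f"snv{i}"
            genos[a] = rng.binomial(2, 0.4, n)
            genos[b] = rng.binomial(2, 0.4, n)
            pos[a] = ("chr1", int(rng.integers(0, 2_000_000)))
            recs.append(USVCRecord("cis-SV-SNV", a, "WEST", b, "EAST", []))
        out = joint_usvc_model(recs, expr, genos, variant_positions=pos,
                               fdr=0.1)
        tested = out[~out.untestable]
        assert len(tested) > 30
        assert tested.significant.mean() <= 0.1
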