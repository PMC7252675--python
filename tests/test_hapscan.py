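"""Genotype QC, GRM PCs, window enumeration and association-test oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from recessivescan.hapscan import test_haplotype as assoc_test
from recessivescan.hapscan import (
    Window,
    conditional_scan,
    enumerate_windows,
    genomic_lambda,
    grm_pcs,
    hwe_exact_p,
    qc_genotypes,
    scan,
    window_haplotypes,
)
from recessivescan.panel import HaplotypePanel


def _markers(n, chrom="1", start=1000, spacing=100):
    return pd.DataFrame({
        "snp_id": [f"s{chrom}_{i}" for i in range(n)],
        "chrom": chrom,
        "pos": start + spacing * np.arange(n),
        "ref": "A",
        "alt": "C",
    })


def _panel_from_H(H, chrom="1"):
    n2, m = H.shape
    return HaplotypePanel(
        samples=[f"S{i}" for i in range(n2 // 2)],
        markers=_markers(m, chrom),
        H=np.asarray(H, np.uint8),
    )


class TestHWE:
    @staticmethod
    def _oracle(het, hom1, hom2):
        """Full enumeration with exact log-factorial probabilities."""
        n = het + hom1 + hom2
        n_a = 2 * hom1 + het
        n_b = 2 * hom2 + het

        def logp(h):
            ha = (n_a - h) // 2
            hb = (n_b - h) // 2
            return (
                gammaln(n + 1) - gammaln(ha + 1) - gammaln(hb + 1) - gammaln(h + 1)
                + h * np.log(2) + gammaln(n_a + 1) + gammaln(n_b + 1)
                - gammaln(2 * n + 1)
            )
        hs = [h for h in range(min(n_a, n_b) + 1) if (n_a - h) % 2 == 0 and h % 2 == n_a % 2]
        ps = {h: np.exp(logp(h)) for h in hs}
        p_obs = ps[het]
        return sum(v for v in ps.values() if v <= p_obs * (1 + 1e-12))

    @pytest.mark.parametrize("counts", [(57, 14, 50), (21, 968, 11), (10, 90, 0),
                                        (0, 100, 0), (1, 0, 0), (0, 5, 5)])
    def test_matches_enumeration_oracle(self, counts):
        het, h1, h2 = counts
        assert hwe_exact_p(het, h1, h2) == pytest.approx(
            min(1.0, self._oracle(het, h1, h2)), rel=1e-9
        )

    def test_random_counts_match_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 200))
            g = rng.integers(0, 3, n)
            het, h1, h2 = int((g == 1).sum()), int((g == 0).sum()), int((g == 2).sum())
            assert hwe_exact_p(het, h1, h2) == pytest.approx(
                min(1.0, self._oracle(het, h1, h2)), rel=1e-9
            )


class TestQC:
    def test_maf_and_monomorphic_filters(self, rng):
        n = 1000
        G = rng.binomial(2, 0.4, (n, 4))  # Hardy-Weinberg proportions
        G[:, 1] = 0  # monomorphic
        G[:, 2] = 0
        G[:4, 2] = 1  # MAF = 0.002 < 0.005
        Gq, mk, keep_s, report = qc_genotypes(G, _markers(4))
        assert list(mk["snp_id"]) == ["s1_0", "s1_3"]
        assert report["n_snps_low_maf"] == 2

    def test_missingness_drops_samples_then_snps(self, rng):
        G = rng.integers(0, 3, (50, 10))
        G[0, :] = -1  # fully missing sample
        G[1:, 3] = -1  # SNP missing in everyone else
        Gq, mk, keep_s, report = qc_genotypes(G, _markers(10))
        assert 0 not in keep_s
        assert "s1_3" not in set(mk["snp_id"])

    def test_hwe_violators_removed(self, rng):
        n = 500
        G = rng.binomial(1, 0.5, (n, 3)) + rng.binomial(1, 0.5, (n, 3))
        G[:, 0] = np.where(np.arange(n) % 2 == 0, 0, 2)  # no hets at freq 0.5
        _, mk, _, report = qc_genotypes(G, _markers(3))
        assert "s1_0" not in set(mk["snp_id"])
        assert report["n_snps_hwe"] >= 1

    def test_everything_removed_raises(self):
        G = np.zeros((10, 2), dtype=int)  # monomorphic everywhere
        with pytest.raises(ValueError, match="every SNP"):
            qc_genotypes(G, _markers(2))


class TestGrmPcs:
    def test_duplicated_samples_share_pc_rows(self, rng):
        G = rng.integers(0, 3, (20, 100))
        G[1] = G[0]
        pcs, _ = grm_pcs(G, k=5)
        assert np.allclose(pcs[0], pcs[1], atol=1e-8)

    def test_matches_full_eigendecomposition_oracle(self, rng):
        G = rng.integers(0, 3, (30, 100)).astype(float)
        pcs, evals = grm_pcs(G, k=6)
        p = G.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        W = (G[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
        K = W @ W.T / W.shape[1]
        w, v = np.linalg.eigh(K)
        order = np.argsort(w)[::-1][:6]
        oracle = v[:, order] * np.sqrt(w[order])
        for j in range(6):  # eigenvectors defined up to sign
            assert np.allclose(np.abs(pcs[:, j]), np.abs(oracle[:, j]), atol=1e-8)

    def test_grm_of_centered_matrix_has_zero_row_means(self, rng):
        G = rng.integers(0, 3, (40, 200)).astype(float)
        p = G.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        W = (G[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
        K = W @ W.T / W.shape[1]
        assert np.abs(K.mean(axis=0)).max() < 1e-10


class TestWindows:
    def test_80_snps_three_windows(self):
        ws = enumerate_windows(_markers(80), window_size=50, step=15)
        assert [(w.start, w.end) for w in ws] == [(0, 49), (15, 64), (30, 79)]

    @pytest.mark.parametrize("n, expected", [(50, 1), (49, 0), (65, 2)])
    def test_exact_window_counts(self, n, expected):
        assert len(enumerate_windows(_markers(n))) == expected

    def test_windows_never_span_chromosomes(self):
        mk = pd.concat([_markers(60, "1"), _markers(60, "2")], ignore_index=True)
        for w in enumerate_windows(mk):
            chroms = mk["chrom"].iloc[w.start : w.end + 1].unique()
            assert len(chroms) == 1 and chroms[0] == w.chrom


class TestWindowHaplotypes:
    def test_uniform_panel_single_haplotype(self):
        H = np.ones((20, 50), np.uint8)
        panel = _panel_from_H(H)
        w = enumerate_windows(panel.markers)[0]
        haps = window_haplotypes(panel, w, min_freq=0.0)
        assert len(haps) == 1 and haps[0][2] == 1.0

    def test_constructed_frequency(self, rng):
        H = rng.integers(0, 2, (100, 50)).astype(np.uint8)
        target = rng.integers(0, 2, 50).astype(np.uint8)
        H[:24] = target
        panel = _panel_from_H(H)
        w = enumerate_windows(panel.markers)[0]
        haps = window_haplotypes(panel, w, min_freq=0.0)
        top = haps[0]
        assert top[0] == "".join(map(str, target))
        assert top[2] == pytest.approx(0.24)

    def test_copy_counts_conserved(self, rng):
        H = rng.integers(0, 2, (60, 50)).astype(np.uint8)
        H[:30] = H[0]  # create some sharing
        panel = _panel_from_H(H)
        w = enumerate_windows(panel.markers)[0]
        haps = window_haplotypes(panel, w, min_freq=0.0)
        total = sum(copies.sum() for _, copies, _ in haps)
        assert total == H.shape[0]
        freqs = [f for _, _, f in haps]
        assert sum(freqs) == pytest.approx(1.0)


class TestAssociation:
    def test_matches_statsmodels_ols_oracle(self, rng):
        import statsmodels.api as sm

        n = 40
        pcs = rng.normal(0, 1, (n, 3))
        copies = rng.integers(0, 3, n)
        y = 0.3 * copies + pcs @ [0.5, -0.2, 0.1] + rng.normal(0, 1, n)
        for model, coder in [("additive", copies.astype(float)),
                             ("dominant", (copies >= 1).astype(float)),
                             ("recessive", (copies == 2).astype(float))]:
            res = assoc_test(y, pcs, copies, model)
            X = sm.add_constant(np.column_stack([pcs, coder]))
            fit = sm.OLS(y, X).fit()
            assert res["beta"] == pytest.approx(fit.params[-1], abs=1e-10)
            assert res["se"] == pytest.approx(fit.bse[-1], abs=1e-10)
            assert res["p"] == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_recessive_needs_one_percent_homozygotes(self):
        copies = np.zeros(300, dtype=int)
        copies[:2] = 2  # 2 < ceil(0.01 * 300) = 3
        y = np.random.default_rng(0).normal(0, 1, 300)
        assert assoc_test(y, None, copies, "recessive") is None
        copies[:3] = 2
        assert assoc_test(y, None, copies, "recessive") is not None

    def test_constant_predictor_skipped(self):
        y = np.random.default_rng(0).normal(0, 1, 50)
        assert assoc_test(y, None, np.ones(50, int), "dominant") is None

    def test_p_invariant_under_affine_phenotype(self, rng):
        n = 80
        copies = rng.integers(0, 3, n)
        pcs = rng.normal(0, 1, (n, 2))
        y = rng.normal(0, 1, n)
        p1 = assoc_test(y, pcs, copies, "additive")["p"]
        p2 = assoc_test(7.0 - 3.0 * y, pcs, copies, "additive")["p"]
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_null_p_values_uniform(self, rng):
        n = 500
        copies = rng.integers(0, 3, n)
        pcs = rng.normal(0, 1, (n, 3))
        pvals = []
        for _ in range(1000):
            y = rng.normal(0, 1, n)
            pvals.append(assoc_test(y, pcs, copies, "additive")["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestLambda:
    def test_formula_matches_direct_oracle(self, rng):
        p = rng.uniform(0, 1, 1000)
        direct = np.median(stats.chi2.ppf(1 - p, 1)) / 0.45493642311957283
        assert genomic_lambda(p) == pytest.approx(direct, rel=1e-12)

    def test_null_uniform_p_gives_lambda_one(self, rng):
        p = rng.uniform(0, 1, 200_000)
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.02)


class TestScan:
    @pytest.fixture(scope="class")
    def qtl_scan(self):
        from recessivescan.synthgen import SimConfig, simulate_panel

        cfg = SimConfig(seed=17, n_bulls=400, n_snps_per_chrom=(300,),
                        qtl_window_index=4)
        panel, status, truth = simulate_panel(cfg)
        rng = np.random.default_rng(99)
        y = np.where(status.to_numpy() == 2, -1.55, 0.0) + rng.normal(0, 1, 400)
        pcs, _ = grm_pcs(panel.genotypes(), k=10)
        return panel, status, truth, y, pcs

    def test_scan_is_deterministic(self, qtl_scan):
        panel, status, truth, y, pcs = qtl_scan
        r1 = scan(panel, y, pcs=pcs, model="recessive")
        r2 = scan(panel, y, pcs=pcs, model="recessive")
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_recessive_beats_additive_at_causal_window(self, qtl_scan):
        panel, status, truth, y, pcs = qtl_scan

        def top_p(model):
            res = scan(panel, y, pcs=pcs, model=model)
            rec = res.records
            at = rec[(rec["start"] <= truth.window_end) & (rec["end"] >= truth.window_start)]
            return at["p"].min()

        assert top_p("recessive") < top_p("additive")

    def test_bonferroni_uses_performed_tests(self, qtl_scan):
        panel, status, truth, y, pcs = qtl_scan
        res = scan(panel, y, pcs=pcs, model="recessive")
        assert res.bonferroni_alpha == pytest.approx(0.05 / res.n_tests)
        assert ((res.records["freq"] > 0.01) & (res.records["freq"] < 1)).all()
        assert (res.records["p"] > 0).all() and (res.records["p"] <= 1).all()

    def test_missing_phenotypes_dropped(self, qtl_scan):
        panel, status, truth, y, pcs = qtl_scan
        y2 = pd.Series(y.copy(), index=panel.samples)
        y2.iloc[:5] = np.nan
        res = scan(panel, y2, pcs=pcs, model="additive")
        assert res.dropped_samples == panel.samples[:5]

    def test_conditioning_on_causal_removes_signal(self, qtl_scan):
        panel, status, truth, y, pcs = qtl_scan
        base = scan(panel, y, pcs=pcs, model="recessive")
        assert len(base.significant()) > 0
        cond = conditional_scan(panel, y, pcs, "recessive", status)
        assert len(cond.significant()) == 0

    def test_constant_conditioning_equals_unconditioned(self, qtl_scan):
        panel, status, truth, y, pcs = qtl_scan
        base = scan(panel, y, pcs=pcs, model="recessive")
        with pytest.warns(UserWarning, match="constant"):
            cond = conditional_scan(panel, y, pcs, "recessive",
                                    np.zeros(len(panel.samples)))
        pd.testing.assert_frame_equal(base.records, cond.records)

    def test_conditioning_on_random_haplotype_keeps_signal(self, qtl_scan):
        panel, status, truth, y, pcs = qtl_scan
        rng = np.random.default_rng(3)
        random_status = pd.Series(rng.integers(0, 3, len(panel.samples)),
                                  index=panel.samples)
        cond = conditional_scan(panel, y, pcs, "recessive", random_status)
        rec = cond.records
        at = rec[(rec["start"] <= truth.window_end) & (rec["end"] >= truth.window_start)]
        assert (at["p"] < cond.bonferroni_alpha).any()
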