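import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grainqtl import gwas, simulate
from grainqtl.genio import MISSING, GeneModel
from grainqtl.gwas import (KinshipMatrix, LodConfirm, allele_effect_ai,
                           assign_candidate_genes, fit_null_mlm,
                           genomic_inflation, kinship, lod_confirm,
                           pve_of_snp, scan_mlm, structure_covariates,
                           suggestive_mtas)
from grainqtl.simulate import QTLSpec, SimConfig

from conftest import make_genotypes


def gls_oracle_pvalues(G, y, Q, null):
    """Independent check: whiten by the null covariance, ordinary regression."""
    K = null.eigvecs @ np.diag(null.eigvals) @ null.eigvecs.T
    V = null.sigma_g2 * K + null.sigma_e2 * np.eye(len(y))
    d, U = np.linalg.eigh(V)
    W = U @ np.diag(1.0 / np.sqrt(d)) @ U.T  # V^{-1/2}
    yt, Xt = W @ y, W @ Q
    X_all = G.imputed()
    out = []
    for j in range(G.n_markers):
        g = X_all[:, j]
        if g.std() == 0:
            continue
        D = np.column_stack([Xt, W @ g])
        beta, _, _, _ = np.linalg.lstsq(D, yt, rcond=None)
        resid = yt - D @ beta
        dof = len(y) - D.shape[1]
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(D.T @ D)
        t = beta[-1] / np.sqrt(cov[-1, -1])
        out.append(2 * stats.t.sf(abs(t), dof))
    return np.array(out)


class TestKinship:
    def test_duplicate_rows(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 2], size=(5, 30)).astype(np.int8)
        calls[1] = calls[0]  # duplicate accession
        K = kinship(make_genotypes(calls)).values
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_brute_force_matrix_oracle(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 1, 2], size=(5, 8)).astype(np.int8)
        K = kinship(make_genotypes(calls)).values
        # hand-computed centered cross-product
        X = calls.astype(float)
        p = X.mean(axis=0) / 2
        W = X - 2 * p
        expected = W @ W.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_symmetric_psd(self, small_panel):
        G, _, _ = small_panel
        K = kinship(G).values
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_monomorphic_only_rejected(self):
        calls = np.zeros((4, 3), dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            kinship(make_genotypes(calls))


class TestStructureCovariates:
    def test_two_subpops_separated(self):
        cfg = SimConfig(n_accessions=80, n_subpops=2, n_snps=400,
                        divergence=0.4, rng_seed=2)
        G, labels = simulate.simulate_genotypes(cfg)
        Q = structure_covariates(G, 2)
        pc1 = Q[:, 1]
        lab = (np.array(labels) == labels[0]).astype(float)
        r = np.corrcoef(pc1, lab)[0, 1]
        assert abs(r) > 0.9

    def test_no_structure_pc_is_null(self):
        cfg = SimConfig(n_accessions=80, n_subpops=2, n_snps=400,
                        divergence=0.0, rng_seed=3)
        G, _ = simulate.simulate_genotypes(cfg)
        X = G.imputed()
        Xc = X - X.mean(axis=0)
        s1 = np.linalg.svd(Xc, compute_uv=False)[0]
        frac = s1 ** 2 / (Xc ** 2).sum()
        # permutation null for the leading variance fraction
        rng = np.random.default_rng(0)
        null_fracs = []
        for _ in range(20):
            Xp = np.column_stack([rng.permutation(Xc[:, j])
                                  for j in range(Xc.shape[1])])
            sp = np.linalg.svd(Xp, compute_uv=False)[0]
            null_fracs.append(sp ** 2 / (Xp ** 2).sum())
        assert frac < np.max(null_fracs) * 1.25

    def test_sign_flip_leaves_pvalues_unchanged(self, small_panel):
        G, _, _ = small_panel
        rng = np.random.default_rng(4)
        y = rng.normal(size=G.n_samples)
        K = kinship(G)
        Q = structure_covariates(G, 2)
        Q2 = Q.copy()
        Q2[:, 1] = -Q2[:, 1]
        p1 = scan_mlm(G, y, Q, K)["p"]
        p2 = scan_mlm(G, y, Q2, K)["p"]
        np.testing.assert_allclose(p1, p2, rtol=1e-9)

    def test_bad_component_count(self, small_panel):
        G, _, _ = small_panel
        with pytest.raises(ValueError):
            structure_covariates(G, 0)
        with pytest.raises(ValueError):
            structure_covariates(G, G.n_samples)


class TestFitNullMlm:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        n = 60
        Q = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = Q @ np.array([1.0, 2.0]) + rng.normal(size=n)
        K = KinshipMatrix(np.eye(n), [f"a{i}" for i in range(n)])
        fit = fit_null_mlm(y, Q, K)
        beta_ols, res, _, _ = np.linalg.lstsq(Q, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-6)
        s2_ols = res[0] / (n - 2)
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(s2_ols, rel=1e-4)

    def test_h2_recovery(self):
        # median estimated h2 within 0.1 of the simulated 0.5
        cfg = SimConfig(n_accessions=150, n_subpops=4, n_snps=400,
                        divergence=0.15, rng_seed=6)
        G, _ = simulate.simulate_genotypes(cfg)
        K = kinship(G)
        d, U = np.linalg.eigh(K.values)
        L = U @ np.diag(np.sqrt(np.maximum(d, 0)))
        Q = np.ones((150, 1))
        rng = np.random.default_rng(7)
        h2s = []
        for _ in range(100):
            u = L @ rng.standard_normal(150) * np.sqrt(0.5)
            e = rng.standard_normal(150) * np.sqrt(0.5)
            fit = fit_null_mlm(u + e, Q, K)
            h2s.append(fit.h2)
        assert abs(np.median(h2s) - 0.5) < 0.1

    def test_global_optimum_over_random_deltas(self, small_panel):
        G, _, _ = small_panel
        K = kinship(G)
        Q = structure_covariates(G, 2)
        rng = np.random.default_rng(8)
        y = rng.normal(size=G.n_samples)
        fit = fit_null_mlm(y, Q, K)
        from grainqtl.gwas import _reml_loglik
        d, U = np.linalg.eigh(K.values)
        d = np.maximum(d, 0)
        ys, Xs = U.T @ y, U.T @ Q
        _, logdet_xtx = np.linalg.slogdet(Q.T @ Q)
        for delta in 10 ** rng.uniform(-5, 5, size=50):
            assert fit.loglik >= _reml_loglik(delta, d, ys, Xs,
                                              logdet_xtx) - 1e-6

    def test_constant_y_rejected(self, small_panel):
        G, _, _ = small_panel
        K = kinship(G)
        with pytest.raises(ValueError, match="constant"):
            fit_null_mlm(np.ones(G.n_samples), np.ones((G.n_samples, 1)), K)


class TestScanMlm:
    def test_matches_gls_whitening_oracle(self):
        cfg = SimConfig(n_accessions=20, n_subpops=2, n_snps=50,
                        divergence=0.2, rng_seed=9)
        G, _ = simulate.simulate_genotypes(cfg)
        K = kinship(G)
        Q = structure_covariates(G, 2)
        rng = np.random.default_rng(10)
        y = rng.normal(size=20)
        null = fit_null_mlm(y, Q, K)
        scan = scan_mlm(G, y, Q, K, null=null)
        oracle = gls_oracle_pvalues(G, y, Q, null)
        np.testing.assert_allclose(scan["p"].to_numpy(), oracle, atol=1e-8)

    def test_identity_kinship_matches_simple_regression(self):
        rng = np.random.default_rng(11)
        calls = rng.choice([0, 2], size=(40, 30)).astype(np.int8)
        G = make_genotypes(calls)
        y = rng.normal(size=40)
        K = KinshipMatrix(np.eye(40), G.samples)
        Q = np.ones((40, 1))
        scan = scan_mlm(G, y, Q, K)
        for _, row in scan.iterrows():
            j = int(np.where(G.markers["id"] == row["snp"])[0][0])
            res = stats.linregress(calls[:, j].astype(float), y)
            assert row["p"] == pytest.approx(res.pvalue, abs=1e-8)

    def test_covariate_collinear_marker_p1(self):
        rng = np.random.default_rng(12)
        calls = rng.choice([0, 2], size=(30, 5)).astype(np.int8)
        G = make_genotypes(calls)
        y = rng.normal(size=30)
        K = KinshipMatrix(np.eye(30), G.samples)
        Q = np.column_stack([np.ones(30), calls[:, 0].astype(float)])
        scan = scan_mlm(G, y, Q, K)
        row = scan[scan["snp"] == G.markers["id"][0]].iloc[0]
        assert row["p"] == 1.0 and row["beta"] == 0.0

    def test_affine_rescaling_invariance(self, small_panel):
        G, _, _ = small_panel
        K = kinship(G)
        Q = structure_covariates(G, 2)
        rng = np.random.default_rng(13)
        y = rng.normal(size=G.n_samples)
        p1 = scan_mlm(G, y, Q, K)["p"].to_numpy()
        p2 = scan_mlm(G, 3.0 * y + 7.0, Q, K)["p"].to_numpy()
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_accession_reordering_invariance(self, small_panel):
        G, _, _ = small_panel
        rng = np.random.default_rng(14)
        y = rng.normal(size=G.n_samples)
        K = kinship(G)
        Q = structure_covariates(G, 2)
        p1 = scan_mlm(G, y, Q, K)["p"].to_numpy()
        perm = rng.permutation(G.n_samples)
        from grainqtl.genio import GenotypeMatrix
        G2 = GenotypeMatrix(samples=[G.samples[i] for i in perm],
                            markers=G.markers.copy(),
                            calls=G.calls[perm])
        K2 = kinship(G2)
        Q2 = structure_covariates(G2, 2)
        p2 = scan_mlm(G2, y[perm], Q2, K2)["p"].to_numpy()
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_mean_imputation_of_missing(self):
        cfg = SimConfig(n_accessions=50, n_subpops=2, n_snps=60,
                        missing_rate=0.1, rng_seed=15)
        G, _ = simulate.simulate_genotypes(cfg)
        K = kinship(G)
        Q = structure_covariates(G, 2)
        rng = np.random.default_rng(16)
        scan = scan_mlm(G, rng.normal(size=50), Q, K)
        assert np.isfinite(scan["p"]).all()


class TestPve:
    def test_zero_beta(self):
        g = np.array([0., 2., 0., 2.])
        y = np.array([1., 2., 3., 4.])
        assert pve_of_snp(0.0, g, y) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(17)
        g = rng.choice([0., 2.], size=100)
        y = g * 0.5 + rng.normal(size=100)
        beta = np.polyfit(g, y, 1)[0]
        p1 = pve_of_snp(beta, g, y)
        p2 = pve_of_snp(beta * 10, g, y * 10)
        assert p1 == pytest.approx(p2)

    def test_generator_truth_average(self):
        # marker built to explain 20% of variance
        pves = []
        rng = np.random.default_rng(18)
        for _ in range(200):
            g = rng.choice([0., 2.], size=400)
            beta = np.sqrt(0.2 / g.var())
            y = beta * g + rng.normal(0, np.sqrt(0.8), size=400)
            b_hat = np.polyfit(g, y, 1)[0]
            pves.append(pve_of_snp(b_hat, g, y))
        assert abs(np.mean(pves) - 20.0) < 3.0

    def test_zero_variance_y(self):
        with pytest.raises(ValueError):
            pve_of_snp(1.0, np.array([0., 2.]), np.array([1., 1.]))


class TestSuggestiveMtas:
    def make_records(self, pvals):
        return pd.DataFrame({
            "snp": [f"S1_{i}" for i in range(len(pvals))],
            "chrom": "1", "pos": np.arange(len(pvals)) * 10,
            "p": pvals, "neglog10p": -np.log10(pvals),
        })

    def test_threshold_boundaries(self):
        rec = self.make_records([1e-6, 1e-4, 1e-5])
        out = suggestive_mtas(rec)
        assert list(out["p"]) == [1e-6]  # 1e-5 dropped: strict inequality

    def test_peak_grouping_keeps_top(self):
        rec = pd.DataFrame({
            "snp": ["a", "b", "c"], "chrom": "1",
            "pos": [1_000_000, 1_500_000, 5_000_000],
            "p": [1e-8, 1e-7, 1e-9],
        })
        rec["neglog10p"] = -np.log10(rec["p"])
        out = suggestive_mtas(rec, peak_window_bp=1_000_000)
        assert set(out["snp"]) == {"a", "c"}  # b within 1 Mb of better a


class TestLodConfirm:
    def test_default_threshold(self):
        assert LodConfirm().lod_threshold == 3.0

    def test_single_marker_lrt_identity(self):
        cfg = SimConfig(n_accessions=80, n_subpops=2, n_snps=50,
                        divergence=0.1, rng_seed=19,
                        qtls=[QTLSpec(7, "RS", 25)])
        G, _ = simulate.simulate_genotypes(cfg)
        pheno, _ = simulate.simulate_phenotypes(G, cfg)
        y = pheno["RS"].to_numpy()
        K = kinship(G)
        Q = structure_covariates(G, 2)
        null = fit_null_mlm(y, Q, K)
        out = lod_confirm(y, Q, K, G, [7], null=null)
        # direct likelihood computation on whitened data
        d, U = null.eigvals, null.eigvecs
        sw = np.sqrt(1 / (d + null.delta))
        yt = sw * (U.T @ y)
        Xt = sw[:, None] * (U.T @ Q)
        g = sw * (U.T @ G.imputed()[:, 7])
        n = len(y)

        def ll(design):
            r = yt - design @ np.linalg.lstsq(design, yt, rcond=None)[0]
            rss = r @ r
            return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)

        lrt = 2 * (ll(np.column_stack([Xt, g])) - ll(Xt))
        assert out["lod"].iloc[0] == pytest.approx(lrt / (2 * np.log(10)),
                                                   rel=1e-6)

    def test_null_markers_rarely_confirmed(self):
        rng = np.random.default_rng(20)
        n_conf = n_tot = 0
        for seed in range(20):
            cfg = SimConfig(n_accessions=100, n_subpops=2, n_snps=60,
                            divergence=0.1, rng_seed=seed + 100)
            G, _ = simulate.simulate_genotypes(cfg)
            K = kinship(G)
            Q = structure_covariates(G, 2)
            y = rng.normal(size=100)
            out = lod_confirm(y, Q, K, G, list(range(0, 60, 12)))
            n_conf += int(out["confirmed"].sum())
            n_tot += len(out)
        assert n_conf / n_tot < 0.05

    def test_ranked_truncation(self):
        rng = np.random.default_rng(21)
        calls = rng.choice([0, 2], size=(12, 40)).astype(np.int8)
        G = make_genotypes(calls)
        K = kinship(G)
        Q = np.ones((12, 1))
        y = rng.normal(size=12)
        out = lod_confirm(y, Q, K, G, list(range(40)))
        assert out["in_model"].sum() <= 12 - 1 - 2


class TestAlleleEffects:
    def test_balanced_algebra(self):
        calls = np.array([0, 0, 0, 2, 2, 2], dtype=np.int8)
        y = np.array([10., 10., 10., 20., 20., 20.])
        eff = allele_effect_ai(calls, y, "RS")
        assert eff.a_ref == pytest.approx(-5.0)
        assert eff.a_alt == pytest.approx(5.0)
        assert eff.favorable_allele == "alt"  # RS: increase favorable

    def test_toy_table_brute_force(self):
        calls = np.array([0, 0, 2, 2, 2, 2], dtype=np.int8)
        y = np.array([3., 5., 2., 4., 6., 8.])
        eff = allele_effect_ai(calls, y, "AC")
        overall = y.mean()
        assert eff.a_ref == pytest.approx(y[:2].mean() - overall)
        assert eff.a_alt == pytest.approx(y[2:].mean() - overall)

    def test_pgi_decrease_is_favorable(self):
        # sign convention anchor: allele lowering PGI by 2.91 is favorable
        calls = np.array([0] * 5 + [2] * 5, dtype=np.int8)
        y = np.concatenate([np.full(5, 70.0 - 2 * 2.91), np.full(5, 70.0)])
        eff = allele_effect_ai(calls, y, "PGI", ref="A", alt="G")
        assert eff.a_ref == pytest.approx(-2.91)
        assert eff.favorable_allele == "ref"
        assert eff.favorable_base == "A"

    def test_heterozygotes_carry_both(self):
        calls = np.array([0, 1, 2], dtype=np.int8)
        y = np.array([1., 2., 3.])
        eff = allele_effect_ai(calls, y, "RS")
        assert eff.a_ref == pytest.approx(np.mean([1., 2.]) - 2.0)
        assert eff.a_alt == pytest.approx(np.mean([2., 3.]) - 2.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            allele_effect_ai(np.array([0, 0], dtype=np.int8),
                             np.array([1., 2.]), "RS")


class TestCandidateGenes:
    GENES = [GeneModel("g1", "1", 100, 500),
             GeneModel("g2", "1", 1000, 1500),
             GeneModel("g3", "1", 3000, 3500),
             GeneModel("g4", "2", 100, 200)]

    def test_containment(self):
        assert assign_candidate_genes("1", 300, self.GENES) == [("g1", 0)]

    def test_flanked_by_two(self):
        out = assign_candidate_genes("1", 2000, self.GENES)
        assert out == [("g2", 500), ("g3", 1000)]

    def test_edge_single_flank(self):
        assert assign_candidate_genes("1", 50, self.GENES) == [("g1", 50)]

    def test_no_genes_on_chrom(self):
        with pytest.raises(ValueError):
            assign_candidate_genes("9", 100, self.GENES)

    def test_interval_oracle_random_placements(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            pos = int(rng.integers(1, 4000))
            got = assign_candidate_genes("1", pos, self.GENES)
            chrom_genes = [g for g in self.GENES if g.chrom == "1"]
            inside = [g for g in chrom_genes if g.start <= pos <= g.end]
            if inside:
                assert got == [(inside[0].gene_id, 0)]
            else:
                expect = []
                left = [g for g in chrom_genes if g.end < pos]
                right = [g for g in chrom_genes if g.start > pos]
                if left:
                    g = max(left, key=lambda g: g.end)
                    expect.append((g.gene_id, pos - g.end))
                if right:
                    g = min(right, key=lambda g: g.start)
                    expect.append((g.gene_id, g.start - pos))
                assert got == expect


def test_genomic_inflation_null_uniform():
    rng = np.random.default_rng(23)
    lam = genomic_inflation(rng.uniform(size=20000))
    assert lam == pytest.approx(1.0, abs=0.05)
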