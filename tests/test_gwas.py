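"""Association stage: QC, BLUPs, kinship, MLM REML/scan, FDR, clumping, phase."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from idcpheno import (
    GenotypeMatrix,
    KinshipMatrix,
    MLMAssociation,
    MLMResults,
    TraitArchitecture,
    bh_fdr,
    classify_phase,
    clump_loci,
    compute_blups,
    filter_snps,
    fit_null_mlm,
    ld_r2,
    scan_markers,
    simulate_genotypes,
    simulate_phenotypes,
    vanraden_kinship,
)


def _toy_genotypes(dosages, chrom=None, pos=None):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return GenotypeMatrix(
        dosages=d,
        chrom=np.asarray(chrom if chrom is not None else ["Gm01"] * m),
        pos=np.asarray(pos if pos is not None else 100 * (1 + np.arange(m))),
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        line_ids=np.array([f"L{i}" for i in range(n)]),
    )


class TestFilterSnps:
    def test_missing_then_maf_enumeration(self):
        # 10 lines x 5 SNPs: s1 is 20% missing; s3 has MAF 0.05 < min
        nan = np.nan
        d = np.zeros((10, 5))
        d[:, 0] = [0, 2] * 5
        d[:, 1] = [nan, nan, 0, 0, 0, 2, 2, 2, 0, 2]
        d[:, 2] = [0, 0, 2, 2, 0, 2, 0, 2, 0, 2]
        d[:, 3] = [2] * 9 + [0]  # freq 0.9 -> MAF 0.1... keep at 0.15 min? no
        d[:, 4] = [0, 2, 0, 2, 0, 2, 0, 2, 0, nan]
        g = _toy_genotypes(d)
        out = filter_snps(g, max_missing=0.10, min_maf=0.15)
        assert list(out.snp_ids) == ["s0", "s2", "s4"]
        assert not np.isnan(out.dosages).any()

    def test_modal_imputation(self):
        d = np.array([[0.0], [0.0], [2.0], [np.nan]] )
        g = _toy_genotypes(d)
        out = filter_snps(g, max_missing=0.5, min_maf=0.0)
        assert out.dosages[3, 0] == 0.0  # mode

    def test_all_removed_raises(self):
        g = _toy_genotypes(np.zeros((4, 2)))  # monomorphic, MAF 0
        with pytest.raises(ValueError, match="all SNPs removed"):
            filter_snps(g, min_maf=0.05)


class TestBlups:
    def test_identical_observations(self):
        p = pd.DataFrame(
            {"line": list("aabb"), "rep": ["r1", "r2", "r1", "r2"],
             "value": [5.0] * 4}
        )
        with pytest.warns(UserWarning, match="zero between-line"):
            b = compute_blups(p)
        assert np.allclose(b.values, 5.0)

    def test_balanced_shrinkage_matches_closed_form(self):
        # engineered data: line means (10,12,14), r=4, ANOVA gives the
        # closed-form shrinkage r*sg2/(r*sg2 + se2)
        rng = np.random.default_rng(0)
        rows = []
        for i, m in enumerate([10.0, 12.0, 14.0]):
            e = rng.normal(0, 1.5, 4)
            e -= e.mean()  # keep line means exact
            for r in range(4):
                rows.append({"line": f"L{i}", "rep": f"r{r}",
                             "value": m + e[r]})
        p = pd.DataFrame(rows)
        b = compute_blups(p)
        shrink = 4 * b.sigma_g2 / (4 * b.sigma_g2 + b.sigma_e2)
        expected = 12.0 + shrink * (np.array([10.0, 12.0, 14.0]) - 12.0)
        np.testing.assert_allclose(
            b.values.loc[["L0", "L1", "L2"]].to_numpy(), expected, atol=1e-10
        )
        assert 0.0 < shrink < 1.0  # shrinkage toward the grand mean

    def test_rep_label_permutation_invariance(self):
        g = simulate_genotypes(n_lines=25, m_snps=40, seed=3)
        p = simulate_phenotypes(g, TraitArchitecture(h2=0.5), seed=4)
        b1 = compute_blups(p)
        p2 = p.copy()
        p2["rep"] = p2["rep"].map({"rep1": "rep3", "rep2": "rep1",
                                   "rep3": "rep4", "rep4": "rep2"})
        b2 = compute_blups(p2)
        np.testing.assert_allclose(b1.values.to_numpy(),
                                   b2.values.to_numpy(), atol=1e-10)

    def test_single_line_rejected(self):
        p = pd.DataFrame({"line": ["a", "a"], "rep": ["r1", "r2"],
                          "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compute_blups(p)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_lme4_reference(self, tmp_path):
        g = simulate_genotypes(n_lines=30, m_snps=40, seed=13)
        p = simulate_phenotypes(g, TraitArchitecture(h2=0.5, n_reps=3), seed=14)
        b = compute_blups(p)
        csv = tmp_path / "p.csv"
        p.to_csv(csv, index=False)
        script = tmp_path / "blup.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"p <- read.csv('{csv}')\n"
            "m <- lmer(value ~ (1|line) + (1|rep), data=p, REML=TRUE)\n"
            "b <- fixef(m)[1] + ranef(m)$line[,1]\n"
            "out <- data.frame(line=rownames(ranef(m)$line), blup=b)\n"
            f"write.csv(out, '{tmp_path / 'b.csv'}', row.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "b.csv").set_index("line")["blup"]
        ours = b.values.loc[ref.index]
        np.testing.assert_allclose(ours.to_numpy(), ref.to_numpy(), atol=1e-5)


class TestKinship:
    def test_hand_computed_toy(self):
        d = np.array([[0.0, 2.0], [2.0, 2.0], [0.0, 0.0]])
        g = _toy_genotypes(d)
        K = vanraden_kinship(g)
        p = np.array([1 / 3, 2 / 3])
        W = d - 2 * p
        expected = W @ W.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_identical_lines_share_rows(self):
        d = np.array([[0.0, 2.0, 0.0], [0.0, 2.0, 0.0], [2.0, 0.0, 2.0]])
        K = vanraden_kinship(_toy_genotypes(d))
        np.testing.assert_allclose(K.values[0], K.values[1])
        assert K.values[0, 1] == pytest.approx(K.values[0, 0])

    def test_symmetric_psd_and_monomorphic_warning(self):
        g = simulate_genotypes(n_lines=40, m_snps=100, seed=5)
        d = g.dosages.copy()
        d[:, 0] = 0.0  # monomorphic
        g2 = _toy_genotypes(d)
        with pytest.warns(UserWarning, match="monomorphic"):
            K = vanraden_kinship(g2)
        np.testing.assert_allclose(K.values, K.values.T)
        assert np.linalg.eigvalsh(K.values).min() >= -1e-8


def _dense_reml_loglik(delta, y, X, G):
    """Independent dense restricted likelihood for the ratio Ve/Vg."""
    n, q = X.shape
    H = G + delta * np.eye(n)
    Hi = np.linalg.inv(H)
    A = X.T @ Hi @ X
    beta = np.linalg.solve(A, X.T @ Hi @ y)
    r = y - X @ beta
    rss = float(r @ Hi @ r)
    _, ldH = np.linalg.slogdet(H)
    _, ldA = np.linalg.slogdet(A)
    return -0.5 * ((n - q) * np.log(rss) + ldH + ldA)


class TestNullMLM:
    @pytest.mark.parametrize("seed", [0, 1, 3, 12])
    def test_reml_matches_dense_grid_oracle_n10(self, seed):
        rng = np.random.default_rng(seed)
        # a small structured kinship with a clear genetic signal so the
        # REML optimum is interior to the oracle's grid
        W = rng.choice([0.0, 2.0], size=(10, 30)) - 1.0
        G2 = 2 * (W @ W.T) / 30
        y = rng.multivariate_normal(np.zeros(10),
                                    3.0 * G2 + 0.5 * np.eye(10))
        K = KinshipMatrix(values=G2 / 2, denom=1.0)
        fit = fit_null_mlm(y, K)
        X = np.ones((10, 1))
        grid = 10 ** np.arange(-3, 3.0001, 0.01)
        lls = [_dense_reml_loglik(d, y, X, G2) for d in grid]
        k = int(np.argmax(lls))
        assert 0 < k < grid.size - 1, "oracle optimum must be interior"
        ours = fit.Ve / fit.Vg
        # within one grid step (2.3% in ratio) of the brute-force optimum
        assert abs(np.log10(ours) - np.log10(grid[k])) <= 0.011

    def test_null_data_gives_negligible_vg(self):
        vgs = []
        for rep in range(12):
            rng = np.random.default_rng(900 + rep)
            y = rng.normal(size=60)
            K = KinshipMatrix(values=np.eye(60) / 2, denom=1.0)
            fit = fit_null_mlm(y, K)
            vgs.append(fit.Vg / y.var())
        assert np.median(vgs) < 0.05

    def test_strong_signal_gives_high_vg_share(self):
        g = simulate_genotypes(n_lines=150, m_snps=300, seed=15)
        p = simulate_phenotypes(g, TraitArchitecture(h2=0.9), seed=16)
        b = compute_blups(p)
        fit = MLMAssociation(b, g).fit()
        assert fit.Vg / (fit.Vg + fit.Ve) > 0.5

    def test_non_psd_kinship_rejected(self):
        y = np.zeros(4)
        bad = np.diag([1.0, 1.0, 1.0, -2.0])
        with pytest.raises(ValueError):
            fit_null_mlm(y, KinshipMatrix(values=bad, denom=1.0))


class TestScan:
    def test_reduces_to_ols_when_vg_zero(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        n, m = 60, 25
        g = _toy_genotypes(rng.choice([0.0, 2.0], size=(n, m)))
        y = rng.normal(size=n)
        s, U = np.linalg.eigh(np.eye(n))  # 2K with K = I/2
        fit = MLMResults(Vg=0.0, Ve=1.0, beta=np.array([y.mean()]),
                         X=np.ones((n, 1)), eig=(s, U), y=y)
        assoc = scan_markers(fit, g, y)
        for j in range(m):
            ols = sm.OLS(y, sm.add_constant(g.dosages[:, j])).fit()
            assert assoc["p"][j] == pytest.approx(ols.pvalues[1], abs=1e-10)
            assert assoc["effect"][j] == pytest.approx(ols.params[1], abs=1e-10)

    def test_monomorphic_snp_flagged_p_one(self):
        d = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        g = _toy_genotypes(d)
        y = np.array([0.1, 1.9, -0.2, 2.2])
        s, U = np.linalg.eigh(np.eye(4))
        fit = MLMResults(Vg=0.0, Ve=1.0, beta=np.array([y.mean()]),
                         X=np.ones((4, 1)), eig=(s, U), y=y)
        assoc = scan_markers(fit, g, y)
        assert assoc["monomorphic"].tolist() == [False, True]
        assert assoc["p"][1] == 1.0

    def test_permuted_phenotype_pvalues_uniform(self):
        g = simulate_genotypes(n_lines=150, m_snps=400, seed=19)
        p = simulate_phenotypes(g, TraitArchitecture(h2=0.6), seed=20)
        b = compute_blups(p)
        y = b.to_array(line_order=g.line_ids)
        rng = np.random.default_rng(21)
        yp = rng.permutation(y)
        fit = MLMAssociation(yp, g).fit()
        assoc = fit.scan()
        from scipy.stats import kstest

        assert kstest(assoc["p"], "uniform").pvalue > 0.01


class TestFDR:
    @pytest.mark.parametrize(
        "pvals,q,expected",
        [
            ([0.01, 0.02, 0.03, 0.2], 0.05, [True, True, True, False]),
            ([1.0, 1.0, 1.0], 0.05, [False, False, False]),
            ([1e-6] * 100, 0.05, [True] * 100),
        ],
    )
    def test_step_up_hand_lists(self, pvals, q, expected):
        reject, qvals = bh_fdr(pvals, q=q)
        assert reject.tolist() == expected
        # q-values reproduce the step-up definition independently
        p = np.asarray(pvals, dtype=float)
        m = p.size
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expect_q = np.empty(m)
        expect_q[order] = np.minimum(ranked, 1.0)
        np.testing.assert_allclose(qvals, expect_q, atol=1e-12)

    def test_empty_input(self):
        reject, qvals = bh_fdr([])
        assert reject.size == 0 and qvals.size == 0

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestLD:
    def test_identical_vectors_r2_one(self):
        d = np.array([[0.0, 0.0], [2.0, 2.0], [0.0, 0.0], [2.0, 2.0]])
        assert ld_r2(_toy_genotypes(d), 0, 1) == pytest.approx(1.0)

    def test_orthogonal_vectors_r2_zero(self):
        d = np.column_stack([[0, 2, 0, 2], [0, 0, 2, 2]]).astype(float)
        assert ld_r2(_toy_genotypes(d), 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_r2_one(self):
        d = np.column_stack([[0, 2, 0, 2], [2, 0, 2, 0]]).astype(float)
        assert ld_r2(_toy_genotypes(d), 0, 1) == pytest.approx(1.0)

    def test_monomorphic_raises(self):
        d = np.column_stack([[0, 0, 0, 0], [0, 2, 0, 2]]).astype(float)
        with pytest.raises(ValueError):
            ld_r2(_toy_genotypes(d), 0, 1)


class TestClump:
    def _assoc(self, g, pvals, sig=None):
        m = g.m_snps
        return pd.DataFrame(
            {
                "snp": g.snp_ids,
                "chrom": g.chrom,
                "pos": g.pos,
                "p": pvals,
                "significant": sig if sig is not None else [True] * m,
            }
        )

    def test_greedy_hand_oracle(self):
        rng = np.random.default_rng(23)
        base = rng.choice([0.0, 2.0], size=60)
        # s1 ~ base; s2 correlated with s1; s3 independent
        s2 = base.copy()
        flip = rng.random(60) < 0.15
        s2[flip] = 2.0 - s2[flip]
        s3 = rng.choice([0.0, 2.0], size=60)
        g = _toy_genotypes(np.column_stack([base, s2, s3]))
        assert ld_r2(g, 0, 1) > 0.2 and ld_r2(g, 0, 2) < 0.2
        assoc = self._assoc(g, [1e-8, 1e-6, 1e-5])
        clusters = clump_loci(assoc, g, r2_threshold=0.20)
        assert len(clusters) == 2
        peaks = {c.peak: c for c in clusters}
        assert set(peaks) == {"s0", "s2"}
        assert peaks["s0"].members == ("s1",)
        assert peaks["s2"].members == ()

    def test_single_snp_forms_own_cluster(self):
        g = _toy_genotypes(np.array([[0.0], [2.0], [0.0], [2.0]]))
        clusters = clump_loci(self._assoc(g, [1e-9]), g)
        assert len(clusters) == 1 and clusters[0].peak == "s0"

    def test_low_ld_same_chromosome_stays_split(self):
        # r^2 ~ 0.11 between two leading SNPs -> two distinct loci
        rng = np.random.default_rng(29)
        a = rng.choice([0.0, 2.0], size=200)
        b = a.copy()
        redraw = rng.random(200) < 0.67  # keeps r ~ 0.33, r^2 ~ 0.11
        b[redraw] = rng.choice([0.0, 2.0], size=redraw.sum())
        g = _toy_genotypes(np.column_stack([a, b]))
        r2 = ld_r2(g, 0, 1)
        assert 0.0 < r2 < 0.2
        clusters = clump_loci(self._assoc(g, [1e-9, 1e-7]), g)
        assert len(clusters) == 2

    def test_cross_chromosome_never_merges(self):
        d = np.column_stack([[0, 2, 0, 2], [0, 2, 0, 2]]).astype(float)
        g = _toy_genotypes(d, chrom=["Gm01", "Gm02"], pos=[100, 100])
        clusters = clump_loci(self._assoc(g, [1e-9, 1e-8]), g)
        assert len(clusters) == 2  # identical dosages but different chromosome

    def test_peaks_mutually_unlinked(self):
        g = simulate_genotypes(n_lines=200, m_snps=300, n_chrom=3,
                               ld_rho=0.8, seed=31)
        rng = np.random.default_rng(32)
        pv = rng.uniform(1e-10, 1e-6, g.m_snps)
        clusters = clump_loci(self._assoc(g, pv), g, r2_threshold=0.20)
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                if a.chrom == b.chrom:
                    assert ld_r2(g, a.peak, b.peak) <= 0.20


class TestPhase:
    def test_four_line_counting(self):
        # allele pairs (F,F),(U,U),(F,U),(F,F); favorable dosage = 2 at both
        d = np.array([[2.0, 2.0], [0.0, 0.0], [2.0, 0.0], [2.0, 2.0]])
        ph = classify_phase(_toy_genotypes(d), 0, 1, 2.0, 2.0)
        assert ph.n_informative == 4
        assert ph.n_coupling == 3 and ph.n_repulsion == 1
        assert ph.n_favorable_favorable == 2
        assert ph.coupling_fraction == 0.75
        assert ph.coupling_fraction + ph.repulsion_fraction == 1.0

    def test_all_favorable(self):
        d = np.full((5, 2), 2.0)
        ph = classify_phase(_toy_genotypes(d), 0, 1, 2.0, 2.0)
        assert ph.coupling_fraction == 1.0 and ph.favorable_fraction == 1.0

    def test_heterozygous_excluded_with_warning(self):
        d = np.array([[2.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="heterozygous"):
            ph = classify_phase(_toy_genotypes(d), 0, 1, 2.0, 2.0)
        assert ph.n_informative == 2

    def test_all_missing_raises(self):
        d = np.array([[np.nan, 2.0], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="no informative"):
            classify_phase(_toy_genotypes(d), 0, 1, 2.0, 2.0)
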