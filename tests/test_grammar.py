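"""Mixed-model association: relationship matrix, REML, residual scan,
genomic control, thresholds and conditional analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from earmap.formats import Pedigree, PhenotypeTable
from earmap.grammar import (
    AssocResult, bonferroni_threshold, conditional_scan, fit_polygenic,
    genomic_control, gwas_scan, relationship_matrix, residual_scan,
)
from earmap.simdata import SimConfig, simulate_cross


def _ped(rows):
    return Pedigree(pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "generation"]))


class TestRelationshipMatrix:
    def test_unrelated_founders_identity(self):
        ped = _ped([("a", "", "", "M", "F0"), ("b", "", "", "F", "F0")])
        A, ids = relationship_matrix(ped)
        np.testing.assert_array_equal(A, np.eye(2))

    def test_hand_tabular_values(self):
        """Parent-offspring 0.5; full sibs 0.5; half sibs 0.25."""
        ped = _ped([
            ("s", "", "", "M", "F0"), ("d1", "", "", "F", "F0"),
            ("d2", "", "", "F", "F0"),
            ("k1", "s", "d1", "M", "F1"), ("k2", "s", "d1", "F", "F1"),
            ("k3", "s", "d2", "F", "F1"),
        ])
        A, ids = relationship_matrix(ped)
        ix = {iid: i for i, iid in enumerate(ids)}
        assert A[ix["s"], ix["k1"]] == pytest.approx(0.5)
        assert A[ix["k1"], ix["k2"]] == pytest.approx(0.5)   # full sibs
        assert A[ix["k1"], ix["k3"]] == pytest.approx(0.25)  # half sibs
        assert A[ix["k1"], ix["k1"]] == pytest.approx(1.0)

    def test_inbred_offspring_diagonal(self):
        """Offspring of full sibs: A_ii = 1 + F = 1.25."""
        ped = _ped([
            ("s", "", "", "M", "F0"), ("d", "", "", "F", "F0"),
            ("b1", "s", "d", "M", "F1"), ("b2", "s", "d", "F", "F1"),
            ("x", "b1", "b2", "M", "F2"),
        ])
        A, ids = relationship_matrix(ped)
        ix = {iid: i for i, iid in enumerate(ids)}
        assert A[ix["x"], ix["x"]] == pytest.approx(1.25)

    def test_f2_to_sire_half(self, default_sim):
        _, ped, pheno, _ = default_sim
        A, ids = relationship_matrix(ped)
        ix = {iid: i for i, iid in enumerate(ids)}
        kid = pheno.ids[0]
        sire = ped.parents(kid)[0]
        assert A[ix[kid], ix[sire]] == pytest.approx(0.5)


class TestFitPolygenic:
    def test_degenerate_limit_matches_ols(self):
        """sigma2_a = sigma2_c = 0: components hit the floor, y* = OLS
        residuals of the fixed-effect regression."""
        cfg = SimConfig(seed=42, qtl_variance_fraction=0.0,
                        qtl_marker_index=None, sigma2_a=0.0, sigma2_c=0.0)
        g, ped, pheno, _ = simulate_cross(cfg)
        fit = fit_polygenic(pheno, ped)
        vy = pheno.table["ear_area"].var()
        assert fit.sigma2_a < 0.05 * vy
        assert fit.sigma2_c < 0.05 * vy
        from earmap.grammar import MixedModelSpec, build_design
        y, X, T, ids, _ = build_design(pheno, MixedModelSpec())
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ols_resid = y - X @ beta
        assert np.corrcoef(fit.y_star, ols_resid)[0, 1] > 0.99

    def test_residuals_orthogonal_to_design(self, default_sim):
        g, ped, pheno, _ = default_sim
        fit = fit_polygenic(pheno, ped)
        from earmap.grammar import MixedModelSpec, build_design
        y, X, T, ids, _ = build_design(pheno, MixedModelSpec())
        # y* = sigma2_e * P y with P annihilating X exactly
        proj = X.T @ fit.y_star
        assert np.abs(proj).max() < 1e-6 * np.abs(y).sum()

    def test_loglik_nondecreasing_to_convergence(self, default_sim):
        g, ped, pheno, _ = default_sim
        fit = fit_polygenic(pheno, ped)
        assert fit.converged
        diffs = np.diff(fit.trace)
        assert (diffs > -1e-8).all()

    def test_parameter_recovery_across_replicates(self):
        """REML means approach the generating components (identifiable
        design: no QTL so family variance is purely polygenic+litter)."""
        est = []
        cfg0 = SimConfig(qtl_variance_fraction=0.0, qtl_marker_index=None,
                         additive_variance_fraction=0.30,
                         litter_variance_fraction=0.15)
        truth_comp = cfg0.variance_components()[2:]
        for seed in range(40):
            cfg = SimConfig(seed=900 + seed, qtl_variance_fraction=0.0,
                            qtl_marker_index=None,
                            additive_variance_fraction=0.30,
                            litter_variance_fraction=0.15)
            g, ped, pheno, _ = simulate_cross(cfg)
            fit = fit_polygenic(pheno, ped)
            est.append([fit.sigma2_a, fit.sigma2_c, fit.sigma2_e])
        est = np.asarray(est)
        mean = est.mean(axis=0)
        sem = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for m, s, t in zip(mean, sem, truth_comp):
            assert abs(m - t) < max(4 * s, 0.10 * sum(truth_comp))


class TestResidualScan:
    def test_zero_residuals_zero_statistics(self, default_sim):
        g, ped, pheno, _ = default_sim
        fit = fit_polygenic(pheno, ped)
        fit.y_star = np.zeros_like(fit.y_star)
        res = residual_scan(fit, g)
        tested = [r for r in res if r.tested]
        assert all(r.k_hat == 0 and r.T2 == 0 for r in tested)

    def test_closed_form_regression_oracle(self, geno_factory):
        """8-point hand data: slope and its variance match the textbook
        least-squares formulas to 12 digits."""
        x = np.array([0, 0, 1, 1, 1, 2, 2, 2], float)
        y = np.array([1.0, 1.5, 2.0, 2.2, 1.8, 3.1, 2.9, 3.3])
        g = geno_factory(x[:, None])
        from earmap.grammar import GrammarResiduals
        fit = GrammarResiduals(
            ids=[f"i{i}" for i in range(8)], y_star=y,
            sigma2_a=0, sigma2_c=0, sigma2_e=1, loglik=0, converged=True,
            n_iter=0, beta=np.zeros(1), beta_names=["intercept"],
        )
        r = residual_scan(fit, g)[0]
        xc = x - x.mean()
        k = (xc @ y) / (xc @ xc)
        rss = ((y - y.mean() - k * xc) ** 2).sum()
        var_k = rss / (len(x) - 2) / (xc @ xc)
        assert r.k_hat == pytest.approx(k, rel=1e-12)
        assert r.var_k == pytest.approx(var_k, rel=1e-12)
        assert r.T2 == pytest.approx(k * k / var_k, rel=1e-12)
        # R^2 oracle for variance explained
        r2 = (xc @ (y - y.mean())) ** 2 / ((xc @ xc) * ((y - y.mean()) ** 2).sum())
        assert r.var_pct == pytest.approx(100 * r2, rel=1e-10)

    def test_monomorphic_marker_skipped_not_error(self, geno_factory):
        d = np.column_stack([np.ones(8), np.arange(8) % 3]).astype(float)
        g = geno_factory(d)
        from earmap.grammar import GrammarResiduals
        fit = GrammarResiduals(
            ids=[f"i{i}" for i in range(8)], y_star=np.random.default_rng(0).normal(size=8),
            sigma2_a=0, sigma2_c=0, sigma2_e=1, loglik=0, converged=True,
            n_iter=0, beta=np.zeros(1), beta_names=["intercept"],
        )
        res = residual_scan(fit, g)
        assert res[0].tested is False
        assert res[1].tested is True

    def test_missing_dosages_pairwise_deleted(self, geno_factory):
        rng = np.random.default_rng(8)
        x_full = rng.integers(0, 3, 50).astype(float)
        y = rng.normal(size=50)
        x = x_full.copy()
        x[:10] = np.nan
        from earmap.grammar import GrammarResiduals
        fit = GrammarResiduals(
            ids=[f"i{i}" for i in range(50)], y_star=y,
            sigma2_a=0, sigma2_c=0, sigma2_e=1, loglik=0, converged=True,
            n_iter=0, beta=np.zeros(1), beta_names=["intercept"],
        )
        r = residual_scan(fit, geno_factory(x[:, None]))[0]
        xs, ys = x_full[10:], y[10:]
        xc = xs - xs.mean()
        assert r.n_used == 40
        assert r.k_hat == pytest.approx((xc @ ys) / (xc @ xc), rel=1e-10)


def _mk(t2s):
    return [
        AssocResult(f"m{i}", "5", 1000 + i, 100, 1.0, 1.0, float(t), 0.0)
        for i, t in enumerate(t2s)
    ]


class TestGenomicControl:
    def test_all_equal_median_constant_gives_lambda_one(self):
        res = genomic_control(_mk([0.456] * 5))
        assert res[0].lambda_gc == pytest.approx(1.0)
        assert res[2].T2_adj == pytest.approx(0.456)

    def test_scale_equivariance(self):
        base = [0.1, 0.3, 0.456, 1.2, 5.0]
        r1 = genomic_control(_mk(base))
        r2 = genomic_control(_mk([7.0 * t for t in base]))
        assert r2[0].lambda_gc == pytest.approx(7.0 * r1[0].lambda_gc)
        for a, b in zip(r1, r2):
            assert a.T2_adj == pytest.approx(b.T2_adj)

    def test_null_chi2_draws_lambda_near_one(self):
        rng = np.random.default_rng(0)
        draws = stats.chi2.rvs(1, size=10_000, random_state=rng)
        res = genomic_control(_mk(draws))
        assert 0.93 <= res[0].lambda_gc <= 1.07

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        t2s = rng.chisquare(1, 50)
        res = genomic_control(_mk(t2s))
        order_in = np.argsort(t2s)
        order_out = np.argsort([r.T2_adj for r in res])
        np.testing.assert_array_equal(order_in, order_out)

    def test_degenerate_scan_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            genomic_control(_mk([0.0, 0.0, 0.0]))


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.01, 48355, 2.07e-7),
        (0.05, 48355, 1.03e-6),
        (0.05, 1, 0.05),
    ])
    def test_threshold_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestConditionalScan:
    def test_conditioning_on_qtl_clears_chromosome(self, default_sim):
        g, ped, pheno, truth = default_sim
        qm = str(truth.markers.marker_id[truth.qtl_marker_index])
        _, cond = conditional_scan(pheno, ped, None, g, qm)
        thr = bonferroni_threshold(0.01, 48355)
        assert all(
            not (r.tested and r.P is not None and r.P < thr)
            for r in cond if r.chromosome == "5"
        )
        assert all(r.marker_id != qm for r in cond)

    def test_second_unlinked_qtl_survives_conditioning(self):
        cfg = SimConfig(seed=77, n_chromosomes=2, n_markers=200,
                        qtl_marker_index=50, qtl_variance_fraction=0.30,
                        qtl2_marker_index=150, qtl2_variance_fraction=0.25)
        g, ped, pheno, truth = simulate_cross(cfg)
        qm1 = str(truth.markers.marker_id[50])
        _, cond = conditional_scan(pheno, ped, None, g, qm1)
        top = min((r for r in cond if r.tested), key=lambda r: r.P)
        # the second chromosome's QTL is now the strongest signal
        assert top.chromosome == str(truth.markers.chromosome[150])
        assert abs(top.position_bp - truth.markers.position_bp[150]) <= 3_000_000

    def test_conditioning_on_null_marker_keeps_peak(self, default_sim):
        g, ped, pheno, truth = default_sim
        _, primary = gwas_scan(pheno, ped, g)
        top0 = min((r for r in primary if r.tested), key=lambda r: r.P)
        null_marker = str(truth.markers.marker_id[5])  # far from the QTL
        _, cond = conditional_scan(pheno, ped, None, g, null_marker)
        top1 = min((r for r in cond if r.tested), key=lambda r: r.P)
        assert top1.marker_id == top0.marker_id

    def test_monomorphic_conditioning_marker_raises(self, geno_factory):
        g, ped, pheno, truth = simulate_cross(SimConfig(seed=9))
        g.dosage[:, 3] = 1.0
        with pytest.raises(ValueError, match="monomorphic"):
            conditional_scan(pheno, ped, None, g,
                             str(g.markers.marker_id[3]))
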