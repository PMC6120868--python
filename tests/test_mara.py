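"""Motif-activity fitting: identifiability, recovery, shrinkage, categorization."""

import numpy as np
import pandas as pd
import pytest

from cagedyn.io import MotifSiteMatrix, ValidationError
from cagedyn.mara import (
    categorize_motif_dynamics,
    choose_ridge_lambda,
    fit_motif_activities,
    motif_dynamism_z,
    select_proximal_sites,
)
from cagedyn.normalize import ExpressionMatrix
from cagedyn.simulate import SynthConfig, simulate_motif_system


def _expr(arr, regions=None, samples=None, scale="log"):
    arr = np.asarray(arr, float)
    return ExpressionMatrix(
        pd.DataFrame(arr,
                     index=regions or [f"r{i}" for i in range(arr.shape[0])],
                     columns=samples or [f"s{j}" for j in range(arr.shape[1])]),
        scale=scale,
    )


def _sites(arr, regions=None, motifs=None):
    arr = np.asarray(arr, float)
    return MotifSiteMatrix(
        pd.DataFrame(arr,
                     index=regions or [f"r{i}" for i in range(arr.shape[0])],
                     columns=motifs or [f"m{j}" for j in range(arr.shape[1])])
    )


def _double_center(E):
    E = E - E.mean(axis=1, keepdims=True)
    return E - E.mean(axis=0, keepdims=True)


class TestSelectProximal:
    def test_subset(self):
        sites = _sites(np.ones((5, 2)))
        out = select_proximal_sites(sites, ["r0", "r2", "r4"])
        assert out.region_ids == ["r0", "r2", "r4"]

    def test_missing_promoter_errors(self):
        sites = _sites(np.ones((2, 2)))
        with pytest.raises(ValidationError):
            select_proximal_sites(sites, ["r0", "nope"])

    def test_empty_intersection_errors(self):
        with pytest.raises(ValidationError):
            select_proximal_sites(_sites(np.ones((2, 2))), ["x", "y"])

    def test_passthrough_identity(self):
        sites = _sites(np.arange(6.0).reshape(3, 2) + 1)
        out = select_proximal_sites(sites, ["r0", "r1", "r2"])
        pd.testing.assert_frame_equal(out.data, sites.data)


class TestFit:
    def test_identity_sites_recover_double_centered_expression(self):
        rng = np.random.default_rng(0)
        M = 8
        E = rng.normal(size=(M, 5))
        fit = fit_motif_activities(_expr(E), _sites(np.eye(M)), ridge_lambda=0.0)
        expected = _double_center(E)
        expected = expected - expected.mean(axis=1, keepdims=True)
        assert np.allclose(fit.activities.to_numpy(), expected, atol=1e-9)

    def test_all_zero_expression(self):
        fit = fit_motif_activities(_expr(np.zeros((6, 4))),
                                   _sites(np.eye(6)), ridge_lambda=0.0)
        assert np.allclose(fit.activities.to_numpy(), 0.0)
        assert fit.noise_sd == 0.0

    def test_activity_row_centering_invariant(self):
        cfg = SynthConfig(n_promoters=300, n_motifs=10, noise_sd=0.2, seed=2)
        expr, sites, _ = simulate_motif_system(cfg)
        fit = fit_motif_activities(expr, sites, ridge_lambda=0.5)
        assert np.allclose(fit.activities.mean(axis=1), 0.0, atol=1e-9)

    def test_residual_sample_means_are_zero(self):
        cfg = SynthConfig(n_promoters=300, n_motifs=10, noise_sd=0.2, seed=3)
        expr, sites, _ = simulate_motif_system(cfg)
        fit = fit_motif_activities(expr, sites, ridge_lambda=0.5)
        E = expr.data.to_numpy()
        N = sites.data.to_numpy()
        Nc = N - N.mean(axis=0, keepdims=True)
        pred = (fit.promoter_const.to_numpy()[:, None]
                + fit.sample_const.to_numpy()[None, :]
                + Nc @ fit.activities.to_numpy())
        resid = E - pred
        assert np.allclose(resid.mean(axis=0), 0.0, atol=1e-9)

    def test_constant_expression_shift_leaves_activities_unchanged(self):
        cfg = SynthConfig(n_promoters=200, n_motifs=8, noise_sd=0.1, seed=4)
        expr, sites, _ = simulate_motif_system(cfg)
        fit1 = fit_motif_activities(expr, sites, ridge_lambda=1.0)
        shifted = ExpressionMatrix(expr.data + 7.5, scale="log")
        fit2 = fit_motif_activities(shifted, sites, ridge_lambda=1.0)
        assert np.allclose(fit1.activities, fit2.activities, atol=1e-9)

    def test_recovery_on_planted_system(self):
        cfg = SynthConfig(n_promoters=2000, n_motifs=50, noise_sd=0.1, seed=11)
        expr, sites, truth = simulate_motif_system(cfg)
        fit = fit_motif_activities(expr, sites, ridge_lambda=1.0)
        rs = [
            np.corrcoef(fit.activities.loc[m], truth.activities.loc[m])[0, 1]
            for m in fit.activities.index
            if truth.archetype[m] != "static"
        ]
        assert np.median(rs) >= 0.9

    def test_shrinkage_monotone_in_lambda(self):
        cfg = SynthConfig(n_promoters=300, n_motifs=10, noise_sd=0.3, seed=5)
        expr, sites, _ = simulate_motif_system(cfg)
        norms = [
            np.linalg.norm(fit_motif_activities(expr, sites, lam).activities)
            for lam in [0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert all(norms[i + 1] <= norms[i] + 1e-9 for i in range(len(norms) - 1))

    def test_underdetermined_lambda_zero_errors(self):
        with pytest.raises(ValidationError, match="ridge"):
            fit_motif_activities(_expr(np.zeros((3, 4))), _sites(np.ones((3, 5))),
                                 ridge_lambda=0.0)

    def test_negative_lambda_errors(self):
        with pytest.raises(ValidationError):
            fit_motif_activities(_expr(np.zeros((3, 2))), _sites(np.eye(3)),
                                 ridge_lambda=-1.0)

    def test_sample_permutation_equivariance(self):
        cfg = SynthConfig(n_promoters=200, n_motifs=8, noise_sd=0.1, seed=6)
        expr, sites, _ = simulate_motif_system(cfg)
        fit1 = fit_motif_activities(expr, sites, ridge_lambda=1.0)
        perm = list(expr.data.columns[::-1])
        fit2 = fit_motif_activities(ExpressionMatrix(expr.data[perm], scale="log"),
                                    sites, ridge_lambda=1.0)
        assert np.allclose(fit1.activities[perm], fit2.activities, atol=1e-9)

    def test_constant_site_column_yields_zero_activity(self):
        # the GC-rich caveat: no variance in site counts -> nothing attributable
        cfg = SynthConfig(n_promoters=400, n_motifs=10, noise_sd=0.05, seed=7,
                          activity_amplitude=5.0)
        expr, sites, _ = simulate_motif_system(cfg, constant_site_motifs=1)
        fit = fit_motif_activities(expr, sites, ridge_lambda=1.0)
        assert np.abs(fit.activities.loc["CONSTMOTIF000"]).max() < 1e-6
        assert fit.site_count_variance["CONSTMOTIF000"] == pytest.approx(0.0)


class TestLambdaChoice:
    def test_single_element_grid(self):
        cfg = SynthConfig(n_promoters=100, n_motifs=5, seed=8)
        expr, sites, _ = simulate_motif_system(cfg)
        assert choose_ridge_lambda(expr, sites, grid=[3.5]) == 3.5

    def test_noiseless_system_picks_smallest(self):
        cfg = SynthConfig(n_promoters=500, n_motifs=10, noise_sd=0.0, seed=9)
        expr, sites, _ = simulate_motif_system(cfg)
        assert choose_ridge_lambda(expr, sites, grid=[0.01, 1.0, 100.0], seed=1) == 0.01

    def test_pure_noise_picks_largest(self):
        rng = np.random.default_rng(10)
        expr = _expr(rng.normal(size=(300, 6)))
        sites = _sites(rng.poisson(0.5, size=(300, 10)).astype(float))
        assert choose_ridge_lambda(expr, sites, grid=[0.01, 1.0, 1e4], seed=1) == 1e4

    def test_empty_grid_errors(self):
        cfg = SynthConfig(n_promoters=50, n_motifs=5, seed=8)
        expr, sites, _ = simulate_motif_system(cfg)
        with pytest.raises(ValidationError):
            choose_ridge_lambda(expr, sites, grid=[])


class TestDynamismAndCategories:
    def _fit_with(self, A, se_value=1.0):
        motifs = [f"m{j}" for j in range(A.shape[0])]
        samples = [f"s{j}" for j in range(A.shape[1])]
        from cagedyn.mara import MaraFit

        return MaraFit(
            activities=pd.DataFrame(A, index=motifs, columns=samples),
            promoter_const=pd.Series(dtype=float),
            sample_const=pd.Series(0.0, index=samples),
            noise_sd=1.0,
            activity_se=pd.DataFrame(se_value, index=motifs, columns=samples),
            ridge_lambda=1.0,
            regions_used=(),
            site_count_variance=pd.Series(1.0, index=motifs),
        )

    def test_zero_activity_zero_z(self):
        fit = self._fit_with(np.zeros((2, 4)))
        assert (motif_dynamism_z(fit) == 0).all()

    def test_unit_ratio_gives_z_one(self):
        fit = self._fit_with(np.ones((1, 4)))
        assert motif_dynamism_z(fit).iloc[0] == pytest.approx(1.0)

    def test_zero_se_errors(self):
        fit = self._fit_with(np.ones((1, 4)), se_value=0.0)
        with pytest.raises(ValidationError):
            motif_dynamism_z(fit)

    def test_planted_dynamic_outranks_static(self):
        cfg = SynthConfig(n_promoters=800, n_motifs=12, noise_sd=0.1, seed=12)
        expr, sites, truth = simulate_motif_system(cfg)
        z = motif_dynamism_z(fit_motif_activities(expr, sites, ridge_lambda=1.0))
        dyn = z[truth.archetype != "static"].min()
        stat = z[truth.archetype == "static"].max()
        assert dyn > stat

    def test_category_rules(self):
        times = [0.0, 60.0, 180.0]
        # m0: enhancer-only; m1: promoter-only; m2: enhancer peak precedes
        # promoter peak; m3: static
        A_prom = np.array([[0.1, 0.1, -0.2], [0, 5, 0], [0, 0, 5], [0.1, 0, -0.1]])
        A_enh = np.array([[0, 5, 0], [0.1, 0.1, -0.2], [0, 5, 0], [0, 0.1, -0.1]])
        fit_p = self._fit_with(A_prom)
        fit_e = self._fit_with(A_enh)
        cats = {c.motif_id: c.category
                for c in categorize_motif_dynamics(fit_p, fit_e, 2.0, times=times)}
        assert cats == {
            "m0": "enhancer_only",
            "m1": "promoter_only",
            "m2": "enhancer_before_promoter",
            "m3": "static",
        }

    def test_simultaneous_peaks_are_both_other(self):
        times = [0.0, 60.0, 180.0]
        A = np.array([[0, 5, 0]])
        cats = categorize_motif_dynamics(self._fit_with(A), self._fit_with(A),
                                         2.0, times=times)
        assert cats[0].category == "both_other"

    def test_disjoint_motif_sets_error(self):
        fit_a = self._fit_with(np.zeros((2, 3)))
        fit_b = self._fit_with(np.zeros((2, 3)))
        fit_b = fit_b.__class__(**{**vars(fit_b),
                                   "activities": fit_b.activities.rename(index={"m0": "x0", "m1": "x1"}),
                                   "activity_se": fit_b.activity_se.rename(index={"m0": "x0", "m1": "x1"})})
        with pytest.raises(ValidationError):
            categorize_motif_dynamics(fit_a, fit_b, 2.0)
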