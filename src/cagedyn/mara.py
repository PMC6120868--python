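"""Motif Activity Response Analysis (MARA).

The log expression of promoter p in sample s is modelled as a linear function
of the predicted transcription-factor binding-site counts near the promoter:

    e[p, s] = noise + c_p + c_s + sum_m N[p, m] * A[m, s]

with c_p a promoter-dependent constant (basal strength), c_s a
sample-dependent constant (global offset of the library), N[p, m] the site
count for motif m in the proximal promoter region, and A[m, s] the motif
"activity" -- the sample-dependent capacity of the motif to drive expression
of the promoters that carry it.  Noise is Gaussian with one standard
deviation shared by all promoters.

Fitting double-centers E (removing c_p then c_s), centers each site-count
column over regions (so motif terms are not confounded with c_s), and solves
an independent ridge regression per sample with a shared factorization:

    A_s = (N'N + lambda I)^-1 N' E_s

Activities are re-centered to zero mean across samples per motif.  Standard
errors come from the residual noise scale and diag((N'N + lambda I)^-1);
the per-motif dynamism score is the root-mean-square of A/se across samples.
The ridge penalty is chosen by region-wise cross-validation when not fixed.

A structural caveat worth knowing: a motif whose site counts barely vary
across promoters (typical of GC-rich motifs in CpG-island promoters) has a
near-zero centered column and therefore near-zero fitted activity no matter
how strongly its targets respond.  `site_count_variance` on the fit makes
this inspectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.model_selection import KFold

from .io import MotifSiteMatrix, ValidationError
from .normalize import ExpressionMatrix, log_expression

logger = logging.getLogger(__name__)

__all__ = [
    "MaraFit",
    "MotifDynamics",
    "select_proximal_sites",
    "fit_motif_activities",
    "choose_ridge_lambda",
    "motif_dynamism_z",
    "categorize_motif_dynamics",
]


@dataclass(frozen=True)
class MaraFit:
    """Fitted motif activities with uncertainties and the model's constants."""

    activities: pd.DataFrame  # motifs x samples
    promoter_const: pd.Series  # c_p
    sample_const: pd.Series  # c_s
    noise_sd: float
    activity_se: pd.DataFrame  # motifs x samples (constant across samples per motif)
    ridge_lambda: float
    regions_used: tuple
    site_count_variance: pd.Series  # per-motif variance of N columns over regions


@dataclass(frozen=True)
class MotifDynamics:
    motif_id: str
    z_promoter: float
    z_enhancer: float
    peak_time_promoter: float | None
    peak_time_enhancer: float | None
    category: str  # enhancer_only | promoter_only | enhancer_before_promoter | both_other | static


def select_proximal_sites(
    sites: MotifSiteMatrix,
    promoter_ids: list[str],
    window: tuple[int, int] = (-300, 100),
) -> MotifSiteMatrix:
    """Restrict the site matrix to the promoters under analysis.

    Site counting against the proximal window (default -300..+100 bp around
    the representative CAGE peak) happens upstream; when the matrix already
    holds one row per promoter this subsets and validates.  Requested
    promoters missing from the matrix are an error; extra rows are dropped.
    """
    present = [p for p in promoter_ids if p in sites.data.index]
    if not present:
        raise ValidationError("no requested promoters present in the site matrix")
    missing = [p for p in promoter_ids if p not in sites.data.index]
    if missing:
        raise ValidationError(f"promoters absent from the site matrix: {missing[:5]}")
    logger.debug("select_proximal_sites: window %s assumed applied upstream", window)
    return MotifSiteMatrix(sites.data.loc[promoter_ids])


def _prepare(expr: ExpressionMatrix, sites: MotifSiteMatrix):
    expr = log_expression(expr)
    if list(expr.data.index) != list(sites.data.index):
        missing = set(expr.data.index) - set(sites.data.index)
        if missing:
            raise ValidationError(f"regions missing from the site matrix: {sorted(missing)[:5]}")
        sites = MotifSiteMatrix(sites.data.loc[expr.data.index])
    N = sites.data
    zero_cols = N.columns[(N.to_numpy() == 0).all(axis=0)]
    if len(zero_cols):
        logger.warning("dropping %d all-zero site columns: %s",
                       len(zero_cols), list(zero_cols[:5]))
        N = N.drop(columns=zero_cols)
    return expr, N


def fit_motif_activities(
    expr: ExpressionMatrix,
    sites: MotifSiteMatrix,
    ridge_lambda: float = 1.0,
) -> MaraFit:
    """Fit the linear motif-activity model by per-sample ridge regression.

    `expr` is log2(TPM+1) expression (TPM input is converted) restricted to
    the regions under analysis -- typically those with >= 10 TPM in at least
    one sample.  With ridge_lambda = 0 the minimum-norm least-squares solution
    is used, which requires at least as many regions as motifs.
    """
    if ridge_lambda < 0:
        raise ValidationError("ridge_lambda must be >= 0")
    expr, N_df = _prepare(expr, sites)
    E = expr.data.to_numpy(dtype=float)
    P, S = E.shape
    M = N_df.shape[1]
    if ridge_lambda == 0 and P < M:
        raise ValidationError(
            f"{P} regions < {M} motifs: the unpenalized fit is underdetermined; use ridge_lambda > 0"
        )

    c_p = E.mean(axis=1)
    R = E - c_p[:, None]
    c_s = R.mean(axis=0)
    Et = R - c_s[None, :]

    N = N_df.to_numpy(dtype=float)
    n_mean = N.mean(axis=0)
    Nc = N - n_mean[None, :]

    G = Nc.T @ Nc
    if ridge_lambda > 0:
        factor = cho_factor(G + ridge_lambda * np.eye(M))
        A = cho_solve(factor, Nc.T @ Et)  # motifs x samples
        inv_diag = np.diag(cho_solve(factor, np.eye(M)))
    else:
        A, *_ = np.linalg.lstsq(Nc, Et, rcond=None)
        inv_diag = np.diag(np.linalg.pinv(G))

    # per-motif zero mean across samples; the removed mean is a region-wise
    # constant through N and belongs to c_p
    a_bar = A.mean(axis=1)
    A = A - a_bar[:, None]
    c_p = c_p + Nc @ a_bar

    resid = Et - Nc @ A - (Nc @ a_bar)[:, None]
    rss = float((resid**2).sum())

    sv = np.linalg.svd(Nc, compute_uv=False)
    if ridge_lambda > 0:
        edf_per_sample = float((sv**2 / (sv**2 + ridge_lambda)).sum())
    else:
        edf_per_sample = float((sv > sv.max() * 1e-12).sum()) if sv.size else 0.0
    dof = max(P * S - (P + S - 1) - S * edf_per_sample, 1.0)
    noise_var = rss / dof
    noise_sd = float(np.sqrt(max(noise_var, 0.0)))

    se_m = np.sqrt(np.clip(noise_var * inv_diag, 0.0, None))
    se = np.tile(se_m[:, None], (1, S))

    motifs = list(N_df.columns)
    samples = list(expr.data.columns)
    return MaraFit(
        activities=pd.DataFrame(A, index=motifs, columns=samples),
        promoter_const=pd.Series(c_p, index=expr.data.index, name="c_p"),
        sample_const=pd.Series(c_s, index=samples, name="c_s"),
        noise_sd=noise_sd,
        activity_se=pd.DataFrame(se, index=motifs, columns=samples),
        ridge_lambda=float(ridge_lambda),
        regions_used=tuple(expr.data.index),
        site_count_variance=pd.Series(N.var(axis=0), index=motifs, name="site_variance"),
    )


def choose_ridge_lambda(
    expr: ExpressionMatrix,
    sites: MotifSiteMatrix,
    grid: list[float],
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the ridge penalty by region-wise K-fold cross-validation.

    For each fold, activities and the sample constants are fitted on the
    training regions; held-out regions are predicted after removing their own
    row means (their c_p is a free nuisance).  Returns the grid value with the
    smallest mean held-out squared error; ties go to the smaller lambda.
    """
    if not grid:
        raise ValidationError("lambda grid is empty")
    if any(g < 0 for g in grid):
        raise ValidationError("lambda grid values must be >= 0")
    grid = sorted(set(float(g) for g in grid))
    if len(grid) == 1:
        return grid[0]
    expr, N_df = _prepare(expr, sites)
    E = expr.data.to_numpy(dtype=float)
    N = N_df.to_numpy(dtype=float)
    P, _ = E.shape
    M = N.shape[1]
    kf = KFold(n_splits=min(folds, P), shuffle=True, random_state=seed)
    mse = np.zeros(len(grid))
    for train, test in kf.split(np.arange(P)):
        E_tr, E_te = E[train], E[test]
        R_tr = E_tr - E_tr.mean(axis=1, keepdims=True)
        c_s = R_tr.mean(axis=0)
        Et_tr = R_tr - c_s[None, :]
        Et_te = E_te - E_te.mean(axis=1, keepdims=True) - c_s[None, :]
        n_mean = N[train].mean(axis=0)
        Nc_tr = N[train] - n_mean[None, :]
        Nc_te = N[test] - n_mean[None, :]
        G = Nc_tr.T @ Nc_tr
        NtE = Nc_tr.T @ Et_tr
        for i, lam in enumerate(grid):
            if lam == 0:
                if len(train) < M:
                    mse[i] += np.inf
                    continue
                A, *_ = np.linalg.lstsq(Nc_tr, Et_tr, rcond=None)
            else:
                A = cho_solve(cho_factor(G + lam * np.eye(M)), NtE)
            mse[i] += float(((Et_te - Nc_te @ A) ** 2).sum())
    return grid[int(np.argmin(mse))]


def motif_dynamism_z(fit: MaraFit) -> pd.Series:
    """Root-mean-square standardized activity per motif: sqrt(mean_s (A/se)^2)."""
    se = fit.activity_se.to_numpy()
    if (se <= 0).any():
        raise ValidationError("zero standard errors; the dynamism score is undefined")
    z = np.sqrt(np.mean((fit.activities.to_numpy() / se) ** 2, axis=1))
    return pd.Series(z, index=fit.activities.index, name="z")


def _peak_times(fit: MaraFit, times: np.ndarray, mode: str) -> pd.Series:
    A = fit.activities.to_numpy()
    if mode == "max":
        idx = A.argmax(axis=1)
    elif mode == "absmax":
        idx = np.abs(A).argmax(axis=1)
    else:
        raise ValidationError(f"unknown peak mode {mode!r}")
    return pd.Series(times[idx], index=fit.activities.index)


def categorize_motif_dynamics(
    fit_promoter: MaraFit,
    fit_enhancer: MaraFit,
    z_threshold: float = 2.0,
    times: list[float] | None = None,
    peak_mode: str = "max",
) -> list[MotifDynamics]:
    """Classify each shared motif by where its activity is dynamic.

    A motif is dynamic in a compartment when its z score reaches z_threshold.
    Dynamic in one compartment only -> enhancer_only / promoter_only; dynamic
    in both with the enhancer peak strictly earlier -> enhancer_before_promoter,
    otherwise both_other; dynamic in neither -> static.  Samples must be
    ordered by time; `times` supplies the time axis (defaults to column order).
    """
    shared = [m for m in fit_promoter.activities.index if m in set(fit_enhancer.activities.index)]
    if not shared:
        raise ValidationError("promoter and enhancer fits share no motifs")
    s_p = fit_promoter.activities.columns
    s_e = fit_enhancer.activities.columns
    t_p = np.asarray(times if times is not None else range(len(s_p)), dtype=float)
    t_e = np.asarray(times if times is not None else range(len(s_e)), dtype=float)
    z_p = motif_dynamism_z(fit_promoter)
    z_e = motif_dynamism_z(fit_enhancer)
    peak_p = _peak_times(fit_promoter, t_p, peak_mode)
    peak_e = _peak_times(fit_enhancer, t_e, peak_mode)
    out = []
    for m in shared:
        dyn_p = z_p[m] >= z_threshold
        dyn_e = z_e[m] >= z_threshold
        if dyn_e and not dyn_p:
            cat = "enhancer_only"
        elif dyn_p and not dyn_e:
            cat = "promoter_only"
        elif dyn_p and dyn_e:
            cat = "enhancer_before_promoter" if peak_e[m] < peak_p[m] else "both_other"
        else:
            cat = "static"
        out.append(
            MotifDynamics(
                motif_id=m,
                z_promoter=float(z_p[m]),
                z_enhancer=float(z_e[m]),
                peak_time_promoter=float(peak_p[m]) if dyn_p else None,
                peak_time_enhancer=float(peak_e[m]) if dyn_e else None,
                category=cat,
            )
        )
    return out
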