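"""Bayesian kernel models for single- and multi-environment genomic prediction.

Five model flavours are provided, all fit by Gibbs sampling:

* ``GBLUP`` / ``RKHS`` — single-environment y = mu + u + eps with
  u ~ N(0, sigma_u^2 K), K the linear or Gaussian kernel;
* ``GBLUP-GxE`` / ``RKHS-1`` — the marker-by-environment decomposition
  y = mu_e + u0 + u_Ee + eps, with u0 ~ N(0, sigma_u0^2 K0) shared across
  environments and independent environment-specific deviations
  u_Ee ~ N(0, sigma_uEe^2 K_e);
* ``RKHS-2`` — the environmental-covariance model y = mu_e + u + f + eps,
  u ~ N(0, Sigma_u (x) K) with an m x m genetic covariance between
  environments (Kronecker structure with the kernel), and
  f ~ N(0, Sigma_f (x) I) catching genetic effects not captured by u.

Sampling is performed in the eigenbasis of each kernel (one spectral
decomposition per fit), which makes every full-conditional diagonal — or,
for RKHS-2, block-diagonal in m x m blocks — so a sweep costs O(n m) vector
work.  Missing phenotype cells are handled by data augmentation: they are
sampled from their conditional each sweep, which leaves the marginal
posterior over parameters identical to observed-data-likelihood inference
and keeps the conditionals diagonal.

Variance priors are scaled-inverse-chi-square with df = 5 and scale set so
the prior mode equals an equal split of the sample phenotypic variance over
the random terms; the RKHS-2 covariances get inverse-Wishart(m+2, I) priors.
Chain defaults (35,000 sweeps, 5,000 burn-in, thinning 10 -> 3,000 retained
samples) follow common practice for these models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import invwishart

logger = logging.getLogger("gxepred.gxemodels")

_EIG_REL_FLOOR = 1e-8
_PSD_TOL = 1e-8

MODEL_NAMES = ("GBLUP", "RKHS", "GBLUP-GxE", "RKHS-1", "RKHS-2")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Chain settings and priors for one Gibbs fit."""

    model: str = "GBLUP"
    n_iter: int = 35_000
    burn_in: int = 5_000
    thin: int = 10
    df_prior: float = 5.0
    prior_mode: float | None = None  # None: equal split of var(y) over terms
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ModelError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        if not (0 <= self.burn_in < self.n_iter):
            raise ModelError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")
        if self.n_chains < 1:
            raise ModelError("n_chains must be >= 1")

    @property
    def retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class FitResult:
    """Posterior summaries of one fitted model.

    ``predictions`` is intercept_e + posterior-mean genetic components per
    (genotype, environment); ``samples`` holds per-chain scalar traces
    (intercepts and variances) for convergence diagnostics.
    """

    model: str
    genotype_ids: list[str]
    environments: list[str]
    intercepts: pd.Series
    genetic_values: pd.DataFrame
    genetic_sd: pd.DataFrame
    predictions: pd.DataFrame
    variances: pd.DataFrame
    u_main: pd.Series | None = None
    env_corr: np.ndarray | None = None
    samples: dict = field(default_factory=dict)
    retained: int = 0
    n_chains: int = 1
    spec: ModelSpec | None = None

    def to_csv(self, path) -> None:
        long = self.predictions.reset_index(names="genotype_id").melt(
            id_vars="genotype_id", var_name="environment", value_name="prediction")
        sd = self.genetic_sd.reset_index(names="genotype_id").melt(
            id_vars="genotype_id", var_name="environment", value_name="sd")
        long.merge(sd, on=["genotype_id", "environment"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _eigenbasis(k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with PSD check; returns (Phi, lam) with Phi = U sqrt(lam)."""
    n = k.shape[0]
    w, u = np.linalg.eigh((k + k.T) / 2.0)
    if w.min() < -_PSD_TOL * max(np.trace(k), 1.0) / n:
        raise ModelError(f"kernel is not positive semi-definite (min eig {w.min():.3g})")
    keep = w > max(w.max(), 0.0) * _EIG_REL_FLOOR
    if not keep.any():
        raise ModelError("kernel has no positive eigenvalues")
    w, u = w[keep], u[:, keep]
    return u * np.sqrt(w), w


def _as_matrix(y, genotype_ids=None) -> pd.DataFrame:
    """Coerce phenotypes to a genotype x environment DataFrame (NaN = missing)."""
    if isinstance(y, pd.DataFrame):
        return y
    if isinstance(y, pd.Series):
        return y.to_frame(name=y.name or "env")
    arr = np.asarray(y, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    ids = genotype_ids or [f"G{i+1:04d}" for i in range(arr.shape[0])]
    cols = [f"E{j+1}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=ids, columns=cols)


def _scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    return scale_sum / rng.chisquare(df)


def _prior_scale(mode: float, df: float) -> float:
    # mode of scaled-inv-chi2(df, s2) is df*s2/(df+2)
    return mode * (df + 2.0) / df


# ---------------------------------------------------------------------------
# main-effect + environment-deviation sampler (GBLUP, RKHS, GBLUP-GxE, RKHS-1)
# ---------------------------------------------------------------------------

def _run_main_env_chain(y_obs: np.ndarray, observed: np.ndarray,
                        phi0, lam0, phi_e, lam_e, spec: ModelSpec,
                        fixed: Mapping, chain: int):
    """One chain of the shared + per-environment kernel sampler.

    ``phi0`` may be None (no shared term: plain single/independent fits).
    ``phi_e``/``lam_e`` are lists per environment (entries may be None).
    Residual variances are environment-specific.  Posterior means of the
    genetic values are accumulated from the full-conditional means
    (Rao-Blackwellized); posterior spreads from the draws.
    """
    n, m = y_obs.shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, chain]))
    df0 = spec.df_prior
    var_y = float(np.nanvar(y_obs))
    if var_y <= 0:
        raise ModelError("phenotypes have zero variance")
    fixed_u0 = fixed.get("u0", fixed.get("u"))
    fixed_ue = fixed.get("uE")
    fixed_e = fixed.get("e")

    def env_fixed(spec_val, j):
        if spec_val is None:
            return None
        if isinstance(spec_val, Mapping):
            return spec_val.get(j)
        return spec_val

    k_active = int(phi0 is not None and fixed_u0 != 0.0)
    k_active += sum(p is not None and env_fixed(fixed_ue, j) != 0.0
                    for j, p in enumerate(phi_e))
    mode = (spec.prior_mode if spec.prior_mode is not None
            else var_y / (max(k_active, 1) + 1.0))
    s0 = _prior_scale(mode, df0)

    y = np.where(observed, y_obs, 0.0)
    col_mean = np.nanmean(np.where(observed, y_obs, np.nan), axis=0)
    mu = np.where(np.isfinite(col_mean), col_mean, np.nanmean(y_obs))
    sig_e = np.array([var_y / 2.0 if env_fixed(fixed_e, j) is None
                      else float(env_fixed(fixed_e, j)) for j in range(m)])
    n_obs_col = observed.sum(axis=0)

    if phi0 is not None:
        q0 = phi0.shape[1]
        delta0 = np.zeros(q0)
        sig_u0 = mode if fixed_u0 is None else float(fixed_u0)
    u0 = np.zeros(n)
    u0_mean = np.zeros(n)
    ue = np.zeros((n, m))
    ue_mean = np.zeros((n, m))

    sig_ue = np.array([mode if env_fixed(fixed_ue, j) is None
                       else float(env_fixed(fixed_ue, j)) for j in range(m)])

    retained = spec.retained
    trace = {}
    for j in range(m):
        trace[f"mu[{j}]"] = np.empty(retained)
        trace[f"sigma2_e[{j}]"] = np.empty(retained)
        if phi_e[j] is not None:
            trace[f"sigma2_uE[{j}]"] = np.empty(retained)
    if phi0 is not None:
        trace["sigma2_u0"] = np.empty(retained)
    sum_g = np.zeros((n, m)); sum_draw = np.zeros((n, m)); sum_draw2 = np.zeros((n, m))
    sum_u0 = np.zeros(n); sum_mu = np.zeros(m)
    kept = 0

    for it in range(1, spec.n_iter + 1):
        fitted = u0[:, None] + ue
        # data augmentation for missing cells
        if not observed.all():
            draw = (mu[None, :] + fitted
                    + rng.standard_normal((n, m)) * np.sqrt(sig_e)[None, :])
            y = np.where(observed, y, draw)
        # intercepts
        r = y - fitted
        mu = r.mean(axis=0) + rng.standard_normal(m) * np.sqrt(sig_e / n)
        # shared genetic term
        if phi0 is not None and sig_u0 > 0:
            r0 = (y - mu[None, :] - ue) / sig_e[None, :]
            s = phi0.T @ r0.sum(axis=1)
            prec = lam0 * np.sum(1.0 / sig_e) + 1.0 / sig_u0
            u0_cmean_coef = s / prec
            delta0 = u0_cmean_coef + rng.standard_normal(q0) / np.sqrt(prec)
            u0 = phi0 @ delta0
            u0_mean = phi0 @ u0_cmean_coef
            if fixed_u0 is None:
                sig_u0 = _scaled_inv_chi2(rng, df0 + q0, df0 * s0 + delta0 @ delta0)
        # environment-specific terms
        for j in range(m):
            pj = phi_e[j]
            if pj is None or sig_ue[j] <= 0:
                continue
            rj = y[:, j] - mu[j] - u0
            s = pj.T @ rj
            prec = lam_e[j] / sig_e[j] + 1.0 / sig_ue[j]
            cmean = s / (sig_e[j] * prec)
            dj = cmean + rng.standard_normal(len(s)) / np.sqrt(prec)
            ue[:, j] = pj @ dj
            ue_mean[:, j] = pj @ cmean
            if env_fixed(fixed_ue, j) is None:
                sig_ue[j] = _scaled_inv_chi2(rng, df0 + len(dj), df0 * s0 + dj @ dj)
        # residual variances, one per environment
        resid = y - mu[None, :] - u0[:, None] - ue
        for j in range(m):
            if env_fixed(fixed_e, j) is None:
                sig_e[j] = _scaled_inv_chi2(rng, df0 + n,
                                            df0 * s0 + np.sum(resid[:, j] ** 2))
        # record
        if it > spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            g_draw = u0[:, None] + ue
            g_cond = u0_mean[:, None] + ue_mean
            sum_g += g_cond; sum_draw += g_draw; sum_draw2 += g_draw**2
            sum_u0 += u0_mean; sum_mu += mu
            for j in range(m):
                trace[f"mu[{j}]"][kept] = mu[j]
                trace[f"sigma2_e[{j}]"][kept] = sig_e[j]
                if phi_e[j] is not None:
                    trace[f"sigma2_uE[{j}]"][kept] = sig_ue[j]
            if phi0 is not None:
                trace["sigma2_u0"][kept] = sig_u0
            kept += 1

    return {"sum_g": sum_g, "sum_draw": sum_draw, "sum_draw2": sum_draw2,
            "sum_u0": sum_u0, "sum_mu": sum_mu, "kept": kept, "trace": trace}


def _fit_main_env(kernel_main, kernels_env, y, spec: ModelSpec, model_name: str,
                  fixed_variances: Mapping | None = None,
                  genotype_ids=None) -> FitResult:
    ymat = _as_matrix(y, genotype_ids)
    envs = list(ymat.columns)
    ids = [str(g) for g in ymat.index]
    n, m = ymat.shape
    y_obs = ymat.to_numpy(float)
    observed = np.isfinite(y_obs)
    for j, e in enumerate(envs):
        if not observed[:, j].any():
            raise ModelError(f"environment {e!r} has no observations")
    if not observed.any(axis=1).all():
        pass  # genotypes with no data anywhere are fine: they are predicted

    fixed = dict(fixed_variances or {})
    phi0 = lam0 = None
    if kernel_main is not None:
        phi0, lam0 = _eigenbasis(np.asarray(kernel_main, float))
    phi_e, lam_e = [], []
    for j, e in enumerate(envs):
        ke = kernels_env[j] if kernels_env is not None else None
        if ke is None:
            phi_e.append(None); lam_e.append(None)
        else:
            p, l = _eigenbasis(np.asarray(ke, float))
            phi_e.append(p); lam_e.append(l)

    chains = []
    for c in range(spec.n_chains):
        chains.append(_run_main_env_chain(y_obs, observed, phi0, lam0,
                                          phi_e, lam_e, spec, fixed, c))
    kept_total = sum(ch["kept"] for ch in chains)
    g_mean = sum(ch["sum_g"] for ch in chains) / kept_total
    draw_mean = sum(ch["sum_draw"] for ch in chains) / kept_total
    g_var = np.maximum(sum(ch["sum_draw2"] for ch in chains) / kept_total
                       - draw_mean**2, 0.0)
    mu_mean = sum(ch["sum_mu"] for ch in chains) / kept_total
    u0_mean = sum(ch["sum_u0"] for ch in chains) / kept_total

    samples = {name: np.stack([ch["trace"][name] for ch in chains])
               for name in chains[0]["trace"]}
    var_rows = []
    for name, arr in samples.items():
        if name.startswith("sigma2"):
            var_rows.append({"parameter": name, "mean": float(arr.mean()),
                             "sd": float(arr.std(ddof=1))})
    genetic = pd.DataFrame(g_mean, index=ids, columns=envs)
    preds = genetic + mu_mean[None, :]
    return FitResult(
        model=model_name, genotype_ids=ids, environments=envs,
        intercepts=pd.Series(mu_mean, index=envs),
        genetic_values=genetic,
        genetic_sd=pd.DataFrame(np.sqrt(g_var), index=ids, columns=envs),
        predictions=preds,
        variances=pd.DataFrame(var_rows),
        u_main=pd.Series(u0_mean, index=ids) if phi0 is not None else None,
        samples=samples, retained=spec.retained, n_chains=spec.n_chains,
        spec=spec,
    )


def fit_single_env(kernel: np.ndarray, phenotypes, spec: ModelSpec | None = None,
                   fixed_variances: Mapping | None = None,
                   genotype_ids=None) -> FitResult:
    """Single-environment kernel model y = mu + u + eps, u ~ N(0, s2 K).

    ``phenotypes`` may be a Series (index = genotype ids aligned with the
    kernel) with NaN for genotypes to predict.  Pass
    ``fixed_variances={'u': v, 'e': w}`` to fix variances (0 removes the term).
    """
    spec = spec or ModelSpec(model="GBLUP")
    ymat = _as_matrix(phenotypes, genotype_ids)
    if ymat.shape[1] != 1:
        raise ModelError("fit_single_env expects a single phenotype column")
    return _fit_main_env(kernel, None, ymat, spec, spec.model,
                         fixed_variances=fixed_variances)


def fit_gblup_gxe(kernel: np.ndarray, phenotypes, spec: ModelSpec | None = None,
                  fixed_variances: Mapping | None = None,
                  genotype_ids=None) -> FitResult:
    """Extended GBLUP: shared u0 plus independent per-environment deviations."""
    spec = spec or ModelSpec(model="GBLUP-GxE")
    ymat = _as_matrix(phenotypes, genotype_ids)
    kernels_env = [kernel] * ymat.shape[1]
    return _fit_main_env(kernel, kernels_env, ymat, spec, "GBLUP-GxE",
                         fixed_variances=fixed_variances)


def fit_rkhs1(kernels, phenotypes, spec: ModelSpec | None = None,
              fixed_variances: Mapping | None = None,
              genotype_ids=None) -> FitResult:
    """Gaussian-kernel marker-by-environment model (same structure as
    GBLUP-GxE, Gaussian kernels).  ``kernels`` is either a single matrix
    used for the shared and all per-environment terms, or a mapping with key
    ``'main'`` plus one entry per environment label."""
    spec = spec or ModelSpec(model="RKHS-1")
    ymat = _as_matrix(phenotypes, genotype_ids)
    if isinstance(kernels, Mapping):
        k0 = kernels["main"]
        kernels_env = [kernels[e] for e in ymat.columns]
    else:
        k0 = kernels
        kernels_env = [kernels] * ymat.shape[1]
    return _fit_main_env(k0, kernels_env, ymat, spec, "RKHS-1",
                         fixed_variances=fixed_variances)


# ---------------------------------------------------------------------------
# RKHS-2: environmental covariance model
# ---------------------------------------------------------------------------

def _run_rkhs2_chain(y_obs, observed, phi_u, lam, u_basis, spec: ModelSpec,
                     diagonal: bool, chain: int):
    n, m = y_obs.shape
    q = len(lam)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, chain]))
    df0 = spec.df_prior
    var_y = float(np.nanvar(y_obs))
    if var_y <= 0:
        raise ModelError("phenotypes have zero variance")
    mode = spec.prior_mode if spec.prior_mode is not None else var_y / 3.0
    s0 = _prior_scale(mode, df0)
    df_w = m + 2.0
    sw = np.eye(m)

    y = np.where(observed, y_obs, 0.0)
    col_mean = np.nanmean(np.where(observed, y_obs, np.nan), axis=0)
    mu = np.where(np.isfinite(col_mean), col_mean, np.nanmean(y_obs))
    sig_e = np.full(m, var_y / 2.0)  # environment-specific residual variances
    sigma_u = np.eye(m) * mode
    sigma_f = np.eye(m) * mode
    v = np.zeros((q, m))
    u = np.zeros((n, m))
    f = np.zeros((n, m))
    u_rb = np.zeros((n, m))
    f_rb = np.zeros((n, m))

    retained = spec.retained
    trace = {}
    for j in range(m):
        trace[f"mu[{j}]"] = np.empty(retained)
        trace[f"sigma2_e[{j}]"] = np.empty(retained)
        trace[f"Sigma_u[{j},{j}]"] = np.empty(retained)
        trace[f"Sigma_f[{j},{j}]"] = np.empty(retained)
    if m > 1 and not diagonal:
        trace["rho_u"] = np.empty(retained)
    sum_g = np.zeros((n, m)); sum_draw = np.zeros((n, m)); sum_draw2 = np.zeros((n, m))
    sum_mu = np.zeros(m); sum_corr = np.zeros((m, m))
    kept = 0
    eye_m = np.eye(m)

    for it in range(1, spec.n_iter + 1):
        if not observed.all():
            draw = (mu[None, :] + u + f
                    + rng.standard_normal((n, m)) * np.sqrt(sig_e)[None, :])
            y = np.where(observed, y, draw)
        r = y - u - f
        mu = r.mean(axis=0) + rng.standard_normal(m) * np.sqrt(sig_e / n)
        # genetic values in the kernel eigenbasis: m x m block per eigenindex
        su_inv = np.linalg.inv(sigma_u)
        t = u_basis.T @ (y - mu[None, :] - f)          # q x m
        prec = np.diag(1.0 / sig_e)[None, :, :] + su_inv[None, :, :] / lam[:, None, None]
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, (t / sig_e[None, :])[:, :, None])
        z = rng.standard_normal((q, m, 1))
        dev = np.linalg.solve(np.transpose(chol, (0, 2, 1)), z)
        v = (mean + dev)[:, :, 0]
        u = u_basis @ v
        u_rb = u_basis @ mean[:, :, 0]
        # extra genetic effects f, exchangeable across genotypes
        sf_inv = np.linalg.inv(sigma_f)
        prec_f = np.diag(1.0 / sig_e) + sf_inv
        cov_f = np.linalg.inv(prec_f)
        r2 = y - mu[None, :] - u
        f_rb = (r2 / sig_e[None, :]) @ cov_f.T
        f = f_rb + rng.standard_normal((n, m)) @ np.linalg.cholesky(cov_f).T
        # covariances
        scatter_u = (v.T / lam) @ v
        scatter_f = f.T @ f
        if diagonal:
            for j in range(m):
                sigma_u[j, j] = _scaled_inv_chi2(rng, df0 + q, df0 * s0 + scatter_u[j, j])
                sigma_f[j, j] = _scaled_inv_chi2(rng, df0 + n, df0 * s0 + scatter_f[j, j])
            sigma_u[~np.eye(m, dtype=bool)] = 0.0
            sigma_f[~np.eye(m, dtype=bool)] = 0.0
        else:
            sigma_u = invwishart.rvs(df=df_w + q, scale=sw + scatter_u, random_state=rng)
            sigma_f = invwishart.rvs(df=df_w + n, scale=sw + scatter_f, random_state=rng)
            sigma_u = np.atleast_2d(sigma_u)
            sigma_f = np.atleast_2d(sigma_f)
        resid = y - mu[None, :] - u - f
        for j in range(m):
            sig_e[j] = _scaled_inv_chi2(rng, df0 + n,
                                        df0 * s0 + np.sum(resid[:, j] ** 2))

        if it > spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            g_draw = u + f
            sum_g += u_rb + f_rb; sum_draw += g_draw; sum_draw2 += g_draw**2
            sum_mu += mu
            d = np.sqrt(np.diag(sigma_u))
            corr = sigma_u / np.outer(d, d)
            sum_corr += corr
            for j in range(m):
                trace[f"mu[{j}]"][kept] = mu[j]
                trace[f"sigma2_e[{j}]"][kept] = sig_e[j]
                trace[f"Sigma_u[{j},{j}]"][kept] = sigma_u[j, j]
                trace[f"Sigma_f[{j},{j}]"][kept] = sigma_f[j, j]
            if m > 1 and not diagonal:
                trace["rho_u"][kept] = corr[0, 1]
            kept += 1

    return {"sum_g": sum_g, "sum_draw": sum_draw, "sum_draw2": sum_draw2,
            "sum_mu": sum_mu, "sum_corr": sum_corr, "kept": kept, "trace": trace}


def fit_rkhs2(kernel: np.ndarray, phenotypes, spec: ModelSpec | None = None,
              diagonal_covariance: bool = False,
              genotype_ids=None) -> FitResult:
    """Environmental-covariance kernel model y = mu_e + u + f + eps.

    The m x m genetic covariance Sigma_u couples environments through the
    Kronecker structure Sigma_u (x) K; ``diagonal_covariance=True``
    constrains Sigma_u and Sigma_f diagonal (independent environments).
    With a single environment the model delegates to ``fit_single_env``.
    """
    spec = spec or ModelSpec(model="RKHS-2")
    ymat = _as_matrix(phenotypes, genotype_ids)
    if ymat.shape[1] == 1:
        return fit_single_env(kernel, ymat, replace(spec, model="RKHS"))
    envs = list(ymat.columns)
    ids = [str(g) for g in ymat.index]
    y_obs = ymat.to_numpy(float)
    observed = np.isfinite(y_obs)
    for j, e in enumerate(envs):
        if not observed[:, j].any():
            raise ModelError(f"environment {e!r} has no observations")
    phi, lam = _eigenbasis(np.asarray(kernel, float))
    u_basis = phi / np.sqrt(lam)  # orthonormal eigenvectors

    chains = [_run_rkhs2_chain(y_obs, observed, phi, lam, u_basis, spec,
                               diagonal_covariance, c)
              for c in range(spec.n_chains)]
    kept_total = sum(ch["kept"] for ch in chains)
    g_mean = sum(ch["sum_g"] for ch in chains) / kept_total
    draw_mean = sum(ch["sum_draw"] for ch in chains) / kept_total
    g_var = np.maximum(sum(ch["sum_draw2"] for ch in chains) / kept_total
                       - draw_mean**2, 0.0)
    mu_mean = sum(ch["sum_mu"] for ch in chains) / kept_total
    corr_mean = sum(ch["sum_corr"] for ch in chains) / kept_total

    samples = {name: np.stack([ch["trace"][name] for ch in chains])
               for name in chains[0]["trace"]}
    var_rows = [{"parameter": name, "mean": float(arr.mean()),
                 "sd": float(arr.std(ddof=1))}
                for name, arr in samples.items() if not name.startswith("mu[")]
    genetic = pd.DataFrame(g_mean, index=ids, columns=envs)
    return FitResult(
        model="RKHS-2", genotype_ids=ids, environments=envs,
        intercepts=pd.Series(mu_mean, index=envs),
        genetic_values=genetic,
        genetic_sd=pd.DataFrame(np.sqrt(g_var), index=ids, columns=envs),
        predictions=genetic + mu_mean[None, :],
        variances=pd.DataFrame(var_rows),
        env_corr=corr_mean,
        samples=samples, retained=spec.retained, n_chains=spec.n_chains,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def potential_scale_reduction(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin PSRF from an (n_chains, n_samples) array."""
    m, n = chains.shape
    if m < 2 or n < 2:
        return float("nan")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def check_convergence(fit: FitResult, threshold: float = 1.1) -> pd.DataFrame:
    """Gelman-Rubin report per monitored scalar parameter.

    With a single chain the report states diagnostics are unavailable
    (``available=False`` rows) instead of passing silently.
    """
    rows = []
    for name, arr in fit.samples.items():
        if fit.n_chains < 2:
            rows.append({"parameter": name, "psrf": float("nan"),
                         "flagged": False, "available": False})
        else:
            psrf = potential_scale_reduction(arr)
            rows.append({"parameter": name, "psrf": psrf,
                         "flagged": bool(psrf > threshold), "available": True})
    report = pd.DataFrame(rows)
    if not report.empty and not report["available"].any():
        logger.warning("convergence diagnostics unavailable: single chain")
    return report
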