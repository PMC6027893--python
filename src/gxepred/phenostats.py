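"""Per-system and combined mixed models for multi-environment trial data.

The per-system model (one water-management system at a time) is

    y_ijk = mu + year_i (+ rep-within-year) + g_j + gy_ij + eps_ijk,

with genotype and genotype-by-year random, estimated by REML.  Adjusted
means are mu_hat + BLUP(g_j) and feed every downstream stage.  The combined
model stacks both systems and adds water-management fixed effects and
genotype-by-management random terms; the significance of the
genotype-by-management component is assessed by a restricted likelihood
ratio test against the 50:50 chi-square mixture (variance on the boundary).

REML is implemented by direct maximization of the restricted log-likelihood
over variance ratios gamma_k = sigma_k^2 / sigma_e^2 (residual variance
profiled out), with the Woodbury identity keeping every evaluation at the
cost of one Cholesky factorization of a Q x Q matrix, Q the total number of
random-effect levels.  Components are constrained non-negative; boundary
estimates are reported as exactly zero.

Entry-mean broad-sense heritability uses harmonic-mean replication:

    H2 = sigma_g^2 / (sigma_g^2 + sigma_gy^2 / n_y + sigma_e^2 / n_r)

and the conditional coefficient of determination is
(fixed_var + sigma_g^2 + sigma_gy^2) / total, with fixed_var the population
variance of the fitted fixed-effect predictor across plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .simdata import TrialObservations

logger = logging.getLogger("gxepred.phenostats")

_BOUNDARY_TOL = 1e-8  # variance ratios below this (relative) are reported as 0
_LOG_GAMMA_BOUNDS = (-30.0, 30.0)


class PhenostatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def _one_hot(labels: pd.Series) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(labels, sort=True)
    z = np.zeros((len(codes), len(levels)))
    z[np.arange(len(codes)), codes] = 1.0
    return z, list(levels)


def _dummies(labels: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies (first level dropped)."""
    codes, levels = pd.factorize(labels, sort=True)
    cols, names = [], []
    for k, lev in enumerate(levels[1:], start=1):
        cols.append((codes == k).astype(float))
        names.append(f"{prefix}[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(codes), 0)), []


class RemlFit(NamedTuple):
    sigma2: dict            # per random term
    sigma2_e: float
    beta: np.ndarray
    fixed_names: list
    blups: dict             # per random term: pd.Series indexed by level
    fitted_fixed: np.ndarray
    neg2_reml: float
    n_obs: int
    converged: bool
    message: str


class _RemlProblem:
    """Mixed model y = X beta + sum_k Z_k u_k + eps with u_k ~ N(0, s2_k I)."""

    def __init__(self, y: np.ndarray, x: np.ndarray, fixed_names: list[str],
                 terms: dict[str, pd.Series]):
        self.y = np.asarray(y, float)
        self.x = np.asarray(x, float)
        self.fixed_names = fixed_names
        self.term_names = list(terms)
        self.z_blocks, self.levels = [], {}
        for name, labels in terms.items():
            z, lev = _one_hot(labels)
            self.z_blocks.append(z)
            self.levels[name] = lev
        self.z = np.hstack(self.z_blocks) if self.z_blocks else np.empty((len(self.y), 0))
        self.block_slices = {}
        start = 0
        for name, z in zip(self.term_names, self.z_blocks):
            self.block_slices[name] = slice(start, start + z.shape[1])
            start += z.shape[1]
        self.q = self.z.shape[1]
        self.n, self.p = self.x.shape
        if self.n <= self.p:
            raise PhenostatsError("more fixed-effect columns than observations")
        # precomputed cross-products
        self.ztz = self.z.T @ self.z
        self.ztx = self.z.T @ self.x
        self.zty = self.z.T @ self.y
        self.xtx = self.x.T @ self.x
        self.xty = self.x.T @ self.y
        self.yty = float(self.y @ self.y)

    def _expand(self, gammas: np.ndarray) -> np.ndarray:
        d = np.empty(self.q)
        for g, name in zip(gammas, self.term_names):
            d[self.block_slices[name]] = g
        return d

    def _core(self, gammas: np.ndarray):
        """Shared pieces: returns (logdetM, xhx, xhy, yhy, chol, dhalf)."""
        dhalf = np.sqrt(self._expand(gammas))
        m = dhalf[:, None] * self.ztz * dhalf[None, :]
        m[np.diag_indices_from(m)] += 1.0
        c = cho_factor(m, lower=True, check_finite=False)
        logdet_m = 2.0 * np.log(np.diag(c[0])).sum()
        wx = dhalf[:, None] * self.ztx
        wy = dhalf * self.zty
        minv_wx = cho_solve(c, wx, check_finite=False)
        minv_wy = cho_solve(c, wy, check_finite=False)
        xhx = self.xtx - wx.T @ minv_wx
        xhy = self.xty - wx.T @ minv_wy
        yhy = self.yty - wy @ minv_wy
        return logdet_m, xhx, xhy, yhy, c, dhalf

    def neg2_profiled(self, gammas: np.ndarray) -> float:
        """-2 restricted log-likelihood with sigma_e^2 profiled out (up to const)."""
        try:
            logdet_m, xhx, xhy, yhy, _, _ = self._core(np.maximum(gammas, 0.0))
            cx = cho_factor(xhx, lower=True, check_finite=False)
            logdet_x = 2.0 * np.log(np.diag(cx[0])).sum()
            beta = cho_solve(cx, xhy, check_finite=False)
            ypy = yhy - xhy @ beta
            if not np.isfinite(ypy) or ypy <= 0:
                return 1e12
            val = (self.n - self.p) * np.log(ypy) + logdet_m + logdet_x
            return val if np.isfinite(val) else 1e12
        except np.linalg.LinAlgError:
            return 1e12

    def neg2_full(self, sigma2s: np.ndarray, sigma2_e: float) -> float:
        """-2 restricted log-likelihood at explicit variance components."""
        if sigma2_e <= 0 or np.any(np.asarray(sigma2s) < 0):
            return np.inf
        gammas = np.asarray(sigma2s, float) / sigma2_e
        try:
            logdet_m, xhx, xhy, yhy, _, _ = self._core(gammas)
            cx = cho_factor(xhx, lower=True, check_finite=False)
            logdet_x = 2.0 * np.log(np.diag(cx[0])).sum()
            beta = cho_solve(cx, xhy, check_finite=False)
            ypy = yhy - xhy @ beta
            return ((self.n - self.p) * np.log(sigma2_e) + logdet_m + logdet_x
                    + ypy / sigma2_e)
        except np.linalg.LinAlgError:
            return np.inf

    def fit(self, starts: Sequence[np.ndarray] | None = None) -> RemlFit:
        k = len(self.term_names)
        if k == 0:
            return self._finalize(np.empty(0))
        if starts is None:
            starts = [np.full(k, g0) for g0 in (0.1, 1.0)]
        lo, hi = _LOG_GAMMA_BOUNDS
        best = None
        trace = []
        for s in starts:
            theta0 = np.clip(np.log(np.maximum(np.asarray(s, float), 1e-8)), lo, hi)
            res = optimize.minimize(
                lambda t: self.neg2_profiled(np.exp(t)), theta0,
                method="L-BFGS-B", bounds=[(lo, hi)] * k,
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
            trace.append(f"start={np.round(s, 4)} -> f={res.fun:.6f} nit={res.nit}")
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("REML did not converge; trace:\n" + "\n".join(trace))
        # derivative-free polish: the L-BFGS finite-difference gradient limits
        # accuracy near flat directions
        polish = optimize.minimize(
            lambda t: self.neg2_profiled(np.exp(np.clip(t, lo, hi))), best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 80 * k,
                     "maxfev": 80 * k})
        if polish.fun <= best.fun:
            best = polish
        gammas = np.exp(np.clip(best.x, lo, hi))
        gammas[gammas < _BOUNDARY_TOL] = 0.0
        return self._finalize(gammas, converged=bool(best.success),
                              message="; ".join(trace))

    def _finalize(self, gammas: np.ndarray, converged: bool = True,
                  message: str = "") -> RemlFit:
        if self.q:
            logdet_m, xhx, xhy, yhy, c, dhalf = self._core(gammas)
        else:
            xhx, xhy, yhy = self.xtx, self.xty, self.yty
        cx = cho_factor(xhx, lower=True, check_finite=False)
        beta = cho_solve(cx, xhy, check_finite=False)
        ypy = yhy - xhy @ beta
        sigma2_e = max(float(ypy) / (self.n - self.p), 0.0)
        sigma2 = {name: float(g * sigma2_e) for name, g in zip(self.term_names, gammas)}
        # BLUPs: u = D Z' H^{-1} (y - X beta)
        resid = self.y - self.x @ beta
        blups = {}
        if self.q:
            ztr = self.z.T @ resid
            wr = dhalf * ztr
            hinv_part = ztr - self.ztz @ (dhalf * cho_solve(c, wr, check_finite=False))
            u = self._expand(gammas) * hinv_part
            for name in self.term_names:
                blups[name] = pd.Series(u[self.block_slices[name]],
                                        index=self.levels[name])
        neg2 = self.neg2_profiled(gammas) if self.q else (self.n - self.p) * np.log(max(ypy, 1e-300))
        return RemlFit(sigma2=sigma2, sigma2_e=sigma2_e, beta=beta,
                       fixed_names=self.fixed_names, blups=blups,
                       fitted_fixed=self.x @ beta, neg2_reml=float(neg2),
                       n_obs=self.n, converged=converged, message=message)

    def component_cov(self, sigma2s: np.ndarray, sigma2_e: float) -> np.ndarray:
        """Asymptotic covariance of (sigma2s..., sigma2_e) from the numerical
        Hessian of the restricted log-likelihood (central differences)."""
        theta = np.append(np.asarray(sigma2s, float), sigma2_e)
        k = len(theta)

        def f(t):
            return self.neg2_full(t[:-1], t[-1])

        h = np.maximum(np.abs(theta), sigma2_e) * 1e-4 + 1e-10
        hess = np.zeros((k, k))
        f0 = f(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        # -2lR Hessian -> information = H/2
        info = hess / 2.0
        try:
            return np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return np.full((k, k), np.nan)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML variance partition for one trait in one system."""

    sigma2_g: float
    sigma2_gy: float
    sigma2_e: float
    fixed_var: float
    n_y: float
    n_r: float
    component_cov: np.ndarray | None = None  # cov of (g, gy, e), approximate
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_gy", "sigma2_e", "fixed_var"):
            if getattr(self, name) < -1e-12:
                raise PhenostatsError(f"{name} must be non-negative")
        if self.n_y < 1 or self.n_r < 1:
            raise PhenostatsError("harmonic means n_y, n_r must be >= 1")

    @property
    def total(self) -> float:
        return self.fixed_var + self.sigma2_g + self.sigma2_gy + self.sigma2_e


@dataclass
class AdjustedMeans:
    """Adjusted means mu_hat(system) + BLUP(genotype), wide over systems."""

    trait: str
    values: pd.DataFrame  # index genotype_id, one column per system

    @property
    def systems(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    def blups(self) -> pd.DataFrame:
        return self.values - self.values.mean(axis=0)

    @classmethod
    def merge(cls, parts: Sequence["AdjustedMeans"]) -> "AdjustedMeans":
        traits = {p.trait for p in parts}
        if len(traits) != 1:
            raise PhenostatsError("cannot merge adjusted means across traits")
        values = pd.concat([p.values for p in parts], axis=1)
        return cls(trait=parts[0].trait, values=values)

    def to_csv(self, path) -> None:
        long = self.values.reset_index(names="genotype_id").melt(
            id_vars="genotype_id", var_name="system", value_name="value")
        long.insert(1, "trait", self.trait)
        long.to_csv(path, index=False)


@dataclass
class CombinedModelFit:
    """Joint two-system fit with the genotype-by-management LRT."""

    varcomps: dict
    sigma2_e: float
    fixed_effects: pd.Series
    neg2_reml_full: float
    neg2_reml_reduced: float
    lrt_statistic: float
    p_value: float
    dropped: list = field(default_factory=list)


class OutlierScreen(NamedTuple):
    flags: pd.DataFrame
    cleaned: TrialObservations


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _harmonic_mean(counts: np.ndarray) -> float:
    counts = np.asarray(counts, float)
    return len(counts) / np.sum(1.0 / counts)


def _build_fixed_single(df: pd.DataFrame, design: str):
    n = len(df)
    x_cols = [np.ones(n)]
    names = ["intercept"]
    dropped = []
    if df["year"].nunique() > 1:
        z, nm = _dummies(df["year"], "year")
        x_cols.append(z); names += nm
        if design == "rcbd":
            yr = df["year"].astype(str) + ":" + df["replicate"].astype(str)
            # replicate nested in year: drop the first replicate of each year
            first_rep = df.groupby("year")["replicate"].transform("min")
            mask_cols, mask_names = [], []
            for lev in sorted(yr.unique()):
                y_lab, r_lab = lev.split(":")
                sub = (yr == lev)
                if (df.loc[sub, "replicate"] == first_rep[sub]).all():
                    continue
                mask_cols.append(sub.to_numpy(float))
                mask_names.append(f"rep[{lev}]")
            if mask_cols:
                x_cols.append(np.column_stack(mask_cols)); names += mask_names
    else:
        dropped.append("year")
    return np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in x_cols]), names, dropped


def fit_single_system(obs: TrialObservations, trait: str, system: str,
                      design: str = "crd", compute_se: bool = False,
                      ) -> tuple[AdjustedMeans, VarianceComponents]:
    """REML fit of the per-system model; returns adjusted means and components.

    ``design='crd'`` fits year as the only fixed factor (complete randomized
    design); ``design='rcbd'`` adds replicate nested within year.  With a
    single year the genotype-by-year term is dropped and flagged.
    """
    df = obs.subset(trait=trait, environment=system)
    if df.empty:
        raise PhenostatsError(f"no records for trait {trait!r} in system {system!r}")
    if df["genotype_id"].nunique() < 2:
        raise PhenostatsError("need at least 2 genotypes with records")
    y = df["value"].to_numpy(float)
    x, fixed_names, dropped = _build_fixed_single(df, design)
    terms = {"g": df["genotype_id"]}
    if df["year"].nunique() > 1:
        terms["gy"] = df["genotype_id"].astype(str) + ":" + df["year"].astype(str)
    else:
        dropped.append("gy")
    prob = _RemlProblem(y, x, fixed_names, terms)
    fit = prob.fit()
    if dropped:
        logger.warning("system %s: dropped inestimable terms %s", system, dropped)

    mu_hat = float(fit.fitted_fixed.mean())
    blup_g = fit.blups["g"]
    means = AdjustedMeans(trait=trait,
                          values=(mu_hat + blup_g).to_frame(name=system))

    per_geno = df.groupby("genotype_id")
    n_y = _harmonic_mean(per_geno["year"].nunique().to_numpy())
    n_r = _harmonic_mean(per_geno.size().to_numpy())
    cov = None
    if compute_se:
        full = prob.component_cov(
            np.array([fit.sigma2.get("g", 0.0), fit.sigma2.get("gy", 0.0)]),
            fit.sigma2_e)
        cov = full  # order (g, gy, e)
    vc = VarianceComponents(
        sigma2_g=fit.sigma2.get("g", 0.0),
        sigma2_gy=fit.sigma2.get("gy", 0.0),
        sigma2_e=fit.sigma2_e,
        fixed_var=float(np.var(fit.fitted_fixed)),
        n_y=n_y, n_r=n_r, component_cov=cov, dropped=dropped,
    )
    return means, vc


def heritability(vc: VarianceComponents, se: bool = False):
    """Entry-mean broad-sense heritability, optionally with a delta-method SE.

    The SE uses the (approximate) REML covariance of the variance components
    and is only available when the fit stored it (``compute_se=True``).
    """
    denom = vc.sigma2_g + vc.sigma2_gy / vc.n_y + vc.sigma2_e / vc.n_r
    if denom <= 0:
        raise PhenostatsError("heritability undefined: all variance components are zero")
    h2 = vc.sigma2_g / denom
    if not se:
        return h2
    if vc.component_cov is None or not np.all(np.isfinite(vc.component_cov)):
        return h2, float("nan")
    # gradient of H2 wrt (sigma2_g, sigma2_gy, sigma2_e)
    g, d = vc.sigma2_g, denom
    grad = np.array([(d - g) / d**2, -g / (vc.n_y * d**2), -g / (vc.n_r * d**2)])
    var = float(grad @ vc.component_cov @ grad)
    return h2, float(np.sqrt(max(var, 0.0)))


def conditional_r2(vc: VarianceComponents) -> float:
    """Conditional coefficient of determination of the per-system model."""
    if vc.total <= 0:
        raise PhenostatsError("conditional R2 undefined: total variance is zero")
    return (vc.fixed_var + vc.sigma2_g + vc.sigma2_gy) / vc.total


def _build_fixed_combined(df: pd.DataFrame, design: str):
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    env_z, env_names = _dummies(df["environment"], "m")
    cols.append(env_z); names += env_names
    multi_year = df["year"].nunique() > 1
    if multi_year:
        yr_z, yr_names = _dummies(df["year"], "y")
        cols.append(yr_z); names += yr_names
        for i in range(env_z.shape[1]):
            for j in range(yr_z.shape[1]):
                cols.append((env_z[:, i] * yr_z[:, j])[:, None])
                names.append(f"{env_names[i]}*{yr_names[j]}")
        if design == "rcbd":
            cell = (df["environment"].astype(str) + ":" + df["year"].astype(str))
            first_rep = df.groupby(["environment", "year"])["replicate"].transform("min")
            extra = df["replicate"] != first_rep
            for lev in sorted((cell + ":" + df["replicate"].astype(str))[extra].unique()):
                e_lab, y_lab, r_lab = lev.split(":")
                sub = ((df["environment"].astype(str) == e_lab)
                       & (df["year"].astype(str) == y_lab)
                       & (df["replicate"].astype(str) == r_lab))
                cols.append(sub.to_numpy(float)[:, None])
                names.append(f"rep[{lev}]")
    x = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return x, names, multi_year


def fit_combined(obs: TrialObservations, trait: str, design: str = "crd") -> CombinedModelFit:
    """Joint REML fit over both systems with the g-by-management LRT.

    Random terms: genotype (g), genotype-by-management (gm), genotype-by-year
    (gy) and the three-way gmy; fixed: management, year and their
    interaction (plus replicate nesting under ``design='rcbd'``).  The gm
    significance test compares restricted likelihoods with and without gm,
    referred to the 50:50 mixture of chi-square(0) and chi-square(1).
    """
    df = obs.subset(trait=trait)
    envs = sorted(df["environment"].unique())
    if len(envs) < 2:
        raise PhenostatsError("combined model needs both systems present")
    y = df["value"].to_numpy(float)
    x, fixed_names, multi_year = _build_fixed_combined(df, design)
    dropped = []
    g = df["genotype_id"].astype(str)
    terms = {"g": g, "gm": g + ":" + df["environment"].astype(str)}
    if multi_year:
        terms["gy"] = g + ":" + df["year"].astype(str)
        terms["gmy"] = g + ":" + df["environment"].astype(str) + ":" + df["year"].astype(str)
    else:
        dropped += ["gy", "gmy"]

    reduced_terms = {k: v for k, v in terms.items() if k != "gm"}
    prob_red = _RemlProblem(y, x, fixed_names, reduced_terms)
    fit_red = prob_red.fit()
    prob_full = _RemlProblem(y, x, fixed_names, terms)
    # multi-start including the reduced optimum (gm ratio ~ 0) so the full
    # model's restricted likelihood can never fall below the reduced one
    red_gammas = np.array([fit_red.sigma2[k] / max(fit_red.sigma2_e, 1e-12)
                           for k in reduced_terms])
    k_full = len(terms)
    start_from_red = []
    for name in terms:
        if name == "gm":
            start_from_red.append(1e-8)
        else:
            start_from_red.append(max(fit_red.sigma2[name] / max(fit_red.sigma2_e, 1e-12), 1e-8))
    starts = [np.asarray(start_from_red), np.full(k_full, 0.1), np.full(k_full, 1.0)]
    fit_full = prob_full.fit(starts=starts)

    stat = max(0.0, fit_red.neg2_reml - fit_full.neg2_reml)
    p = 0.5 * chi2.sf(stat, 1) + (0.5 if stat <= 1e-10 else 0.0)
    return CombinedModelFit(
        varcomps={k: fit_full.sigma2.get(k, 0.0) for k in ("g", "gm", "gy", "gmy")},
        sigma2_e=fit_full.sigma2_e,
        fixed_effects=pd.Series(fit_full.beta, index=fit_full.fixed_names),
        neg2_reml_full=fit_full.neg2_reml,
        neg2_reml_reduced=fit_red.neg2_reml,
        lrt_statistic=stat, p_value=float(min(p, 1.0)), dropped=dropped,
    )


def screen_outliers(obs: TrialObservations, trait: str, threshold: float = 4.0,
                    remove: bool = False, design: str = "crd") -> OutlierScreen:
    """Flag plots whose standardized conditional residual exceeds ``threshold``.

    A per-system model is fitted and residuals y - X beta - Z u are scaled
    by the residual standard deviation.  Removal is opt-in; removed records
    are logged.  ``threshold=inf`` flags nothing (identity).
    """
    flags = []
    for system in obs.environments:
        df = obs.subset(trait=trait, environment=system).copy()
        if df.empty:
            continue
        y = df["value"].to_numpy(float)
        x, fixed_names, _ = _build_fixed_single(df, design)
        terms = {"g": df["genotype_id"]}
        if df["year"].nunique() > 1:
            terms["gy"] = df["genotype_id"].astype(str) + ":" + df["year"].astype(str)
        fit = _RemlProblem(y, x, fixed_names, terms).fit()
        pred = fit.fitted_fixed.copy()
        pred += fit.blups["g"].reindex(df["genotype_id"]).to_numpy()
        if "gy" in fit.blups:
            key = df["genotype_id"].astype(str) + ":" + df["year"].astype(str)
            pred += fit.blups["gy"].reindex(key).to_numpy()
        sd = np.sqrt(max(fit.sigma2_e, 1e-300))
        std_resid = (y - pred) / sd
        df = df.assign(std_residual=std_resid)
        flags.append(df[np.abs(df["std_residual"]) > threshold])
    flags = (pd.concat(flags, ignore_index=True) if flags
             else obs.data.iloc[0:0].assign(std_residual=[]))
    if remove and not flags.empty:
        keys = ["genotype_id", "environment", "year", "replicate", "trait"]
        merged = obs.data.merge(flags[keys].assign(_drop=True), on=keys, how="left")
        cleaned_df = obs.data[merged["_drop"].isna().to_numpy()]
        logger.info("screen_outliers removed %d records at threshold %.3g",
                    len(flags), threshold)
        cleaned = TrialObservations(data=cleaned_df.copy(), truth=obs.truth,
                                    masking_log=list(obs.masking_log))
    else:
        cleaned = obs
    return OutlierScreen(flags=flags, cleaned=cleaned)
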