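"""Validation designs: cross-validation, Z-statistic ANOVA, CDmean, progeny tests.

Cross-validation partitions a population 80/20 into training and validation
sets.  Three schemes differ in what the model sees for validation genotypes:

* ``single`` — per-environment model, validation genotypes unobserved;
* ``M1``     — multi-environment model, validation genotypes unobserved in
  every environment (predicting brand-new lines);
* ``M2``     — multi-environment model, each validation genotype observed in
  exactly one environment (predicting the other one); the observed
  environment is assigned at random, balanced across environments.

Predictive ability is the Pearson correlation between predictions and the
held-out adjusted means, computed within each environment.  The same
partitions are reused for every model so abilities are paired across models.
For factorial analysis, abilities are transformed to Z = atanh(r) and fed to
a fixed-effects ANOVA; means are back-transformed for reporting.

Progeny validation trains on a subset of the reference panel — the parental
lines (S1), an optimized subset (S2, CDmean criterion), or the whole panel
(S3) — and predicts all progeny lines.  CDmean selection greedily exchanges
members to maximize the mean coefficient of determination of predicting the
non-selected individuals under the kernel mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import f as f_dist

from .gxemodels import (ModelSpec, fit_gblup_gxe, fit_rkhs1,
                        fit_rkhs2, fit_single_env)
from .kernels import KernelSet
from .simdata import GenotypeMatrix

logger = logging.getLogger("gxepred.evalframe")

SCHEMES = ("single", "M1", "M2")
SCENARIOS = ("S1", "S2", "S3")


class EvalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionPlan:
    """One training/validation split, with the M2 observed-environment map."""

    replicate: int
    scheme: str
    training: tuple[str, ...]
    validation: tuple[str, ...]
    observed_env: Mapping[str, str] | None = None  # M2 only
    seed: int = 0

    def __post_init__(self):
        overlap = set(self.training) & set(self.validation)
        if overlap:
            raise EvalError(f"training and validation overlap: {sorted(overlap)[:3]}")


def make_partitions(population: Sequence[str], fraction: float = 0.8,
                    n_reps: int = 100, scheme: str = "M1", seed: int = 0,
                    environments: Sequence[str] = ("AWD", "CF"),
                    ) -> list[PartitionPlan]:
    """Uniformly random 80/20 partitions; N=284 gives 227 training / 57 validation.

    For M2, each validation genotype is assigned one observed environment at
    random, balanced across environments within the replicate.
    """
    population = [str(g) for g in population]
    if len(population) < 5:
        raise EvalError("population too small to partition")
    if not (0.0 < fraction < 1.0):
        raise EvalError(f"fraction must be in (0,1), got {fraction}")
    if scheme not in SCHEMES:
        raise EvalError(f"scheme must be one of {SCHEMES}")
    n_train = int(round(fraction * len(population)))
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(n_reps):
        perm = rng.permutation(population)
        training = tuple(sorted(perm[:n_train]))
        validation = tuple(sorted(perm[n_train:]))
        observed = None
        if scheme == "M2":
            envs = list(environments)
            # balanced assignment of the single observed environment, drawn
            # from a child stream so the splits stay identical across schemes
            env_rng = np.random.default_rng([seed & 0x7FFFFFFF, rep, 1])
            assign = [envs[i % len(envs)] for i in range(len(validation))]
            env_rng.shuffle(assign)
            observed = dict(zip(validation, assign))
        plans.append(PartitionPlan(replicate=rep, scheme=scheme,
                                   training=training, validation=validation,
                                   observed_env=observed, seed=seed))
    return plans


def apply_partition(y: pd.DataFrame, plan: PartitionPlan) -> pd.DataFrame:
    """Mask a genotype x environment table according to the partition scheme."""
    masked = y.copy()
    val = list(plan.validation)
    if plan.scheme in ("single", "M1"):
        masked.loc[val, :] = np.nan
    else:  # M2
        for g in val:
            keep = plan.observed_env[g]
            for col in masked.columns:
                if col != keep:
                    masked.loc[g, col] = np.nan
    return masked


# ---------------------------------------------------------------------------
# predictive ability
# ---------------------------------------------------------------------------

def predictive_ability(predictions, observed, by_environment: bool = True):
    """Pearson r between predictions and observations, per environment stratum.

    Inputs are genotype x environment frames restricted to the validation
    set (or aligned Series for a single response).  Strata with fewer than 3
    pairs or zero variance are returned as NaN and logged.
    """
    if isinstance(predictions, pd.Series):
        predictions = predictions.to_frame("r")
        observed = observed.to_frame("r")
    out = {}
    for col in observed.columns:
        pair = pd.concat([predictions[col], observed[col]], axis=1, keys=["p", "o"]).dropna()
        if len(pair) < 3:
            logger.warning("stratum %s: <3 paired values; ability undefined", col)
            out[col] = float("nan")
            continue
        if pair["p"].std() == 0 or pair["o"].std() == 0:
            logger.warning("stratum %s: zero variance; ability undefined", col)
            out[col] = float("nan")
            continue
        out[col] = float(np.corrcoef(pair["p"], pair["o"])[0, 1])
    if not by_environment:
        return float(np.nanmean(list(out.values())))
    return out


def z_transform(r: float) -> float:
    return float(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))


# ---------------------------------------------------------------------------
# model dispatch
# ---------------------------------------------------------------------------

def _fit_predict(model: str, ks: KernelSet, y_masked: pd.DataFrame,
                 spec: ModelSpec) -> pd.DataFrame:
    from dataclasses import replace as _replace
    if model in ("GBLUP", "RKHS"):
        spec = _replace(spec, model=model)
    if model in ("GBLUP", "RKHS"):
        kernel = ks.k_linear if model == "GBLUP" else ks.k_gauss
        cols = {}
        for col in y_masked.columns:
            fit = fit_single_env(kernel, y_masked[col].rename(col), spec)
            cols[col] = fit.predictions.iloc[:, 0]
        return pd.DataFrame(cols, index=y_masked.index)
    if model == "GBLUP-GxE":
        return fit_gblup_gxe(ks.k_linear, y_masked, spec).predictions
    if model == "RKHS-1":
        return fit_rkhs1(ks.k_gauss, y_masked, spec).predictions
    if model == "RKHS-2":
        return fit_rkhs2(ks.k_gauss, y_masked, spec).predictions
    raise EvalError(f"unknown model {model!r}")


def _single_env_name(model: str) -> str:
    return "GBLUP" if model.startswith("GBLUP") else "RKHS"


# ---------------------------------------------------------------------------
# cross-validation experiment
# ---------------------------------------------------------------------------

def run_cv_experiment(ks: KernelSet, y: pd.DataFrame,
                      models: Sequence[str] = ("GBLUP-GxE",),
                      schemes: Sequence[str] = ("single", "M1", "M2"),
                      spec: ModelSpec | None = None,
                      n_reps: int = 100, fraction: float = 0.8,
                      seed: int = 0, trait: str = "",
                      response: str | None = None) -> pd.DataFrame:
    """Cross-validate models over random partitions; returns tidy ability records.

    ``y`` is the genotype x environment table of adjusted means (one column
    for a computed response variable, in which case only the ``single``
    scheme applies).  Identical partitions are reused across models and
    schemes so records are paired by replicate id.  Failed fits are logged
    and recorded with NaN ability rather than silently dropped.
    """
    spec = spec or ModelSpec()
    y = y.loc[[str(g) for g in ks.genotype_ids]]
    envs = list(y.columns)
    if y.shape[1] == 1:
        schemes = tuple(s for s in schemes if s == "single") or ("single",)
    records = []
    base_plans = make_partitions(list(y.index), fraction=fraction,
                                 n_reps=n_reps, scheme="M1", seed=seed,
                                 environments=envs)
    for scheme in schemes:
        if scheme == "M2":
            plans = make_partitions(list(y.index), fraction=fraction,
                                    n_reps=n_reps, scheme="M2", seed=seed,
                                    environments=envs)
        else:
            plans = [PartitionPlan(replicate=p.replicate, scheme=scheme,
                                   training=p.training, validation=p.validation,
                                   seed=p.seed) for p in base_plans]
        for plan in plans:
            masked = apply_partition(y, plan)
            for model in models:
                name = _single_env_name(model) if scheme == "single" else model
                try:
                    preds = _fit_predict(name, ks, masked, spec)
                    val = list(plan.validation)
                    abil = predictive_ability(preds.loc[val], y.loc[val])
                except Exception as exc:  # noqa: BLE001 - record, don't hide
                    logger.error("fit failed (rep=%d scheme=%s model=%s): %s",
                                 plan.replicate, scheme, model, exc)
                    abil = {e: float("nan") for e in envs}
                for env, r in abil.items():
                    records.append({
                        "replicate": plan.replicate, "trait": trait,
                        "response": response or env, "model": model,
                        "scheme": scheme, "environment": env,
                        "r": r, "Z": z_transform(r) if np.isfinite(r) else np.nan,
                    })
    return pd.DataFrame(records)


def summarize_ability(records: pd.DataFrame,
                      by: Sequence[str] = ("scheme", "model", "environment"),
                      ) -> pd.DataFrame:
    """Mean predictive ability and its standard error over replicates."""
    def _agg(g):
        r = g["r"].dropna()
        return pd.Series({"mean_r": r.mean(),
                          "se": r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else np.nan,
                          "n": len(r), "n_failed": int(g["r"].isna().sum())})
    return records.groupby(list(by)).apply(_agg, include_groups=False).reset_index()


# ---------------------------------------------------------------------------
# Z-statistic factorial ANOVA
# ---------------------------------------------------------------------------

def zstat_anova(records: pd.DataFrame, factors: Sequence[str],
                interactions: bool = False) -> pd.DataFrame:
    """Fixed-effects ANOVA of Z-transformed abilities.

    Returns a table with Source, DF, SS, MS, FValue, ProbF rows (model,
    error, total, then one row per factor/interaction) and scalar summaries
    (R2, CV, RMSE, overall mean Z, back-transformed level means) in
    ``DataFrame.attrs``.
    """
    df = records.dropna(subset=["Z"]).copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise EvalError(f"factor {f!r} has fewer than 2 levels")
    terms = [f"C({f})" for f in factors]
    if interactions:
        terms += [f"C({a}):C({b})" for i, a in enumerate(factors)
                  for b in factors[i + 1:]]
    formula = "Z ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise EvalError(f"aliased factors in design: {factors} (rank-deficient)")
    fit = model.fit()
    an = sm.stats.anova_lm(fit, typ=1)

    ss_total = float(((df["Z"] - df["Z"].mean()) ** 2).sum())
    ss_err = float(an.loc["Residual", "sum_sq"])
    df_err = float(an.loc["Residual", "df"])
    ss_model = ss_total - ss_err
    df_model = float(an["df"].sum() - df_err)
    mse = ss_err / df_err
    rows = [
        {"Source": "Model", "DF": df_model, "SS": ss_model,
         "MS": ss_model / df_model, "FValue": (ss_model / df_model) / mse,
         "ProbF": float(f_dist.sf((ss_model / df_model) / mse, df_model, df_err))},
        {"Source": "Error", "DF": df_err, "SS": ss_err, "MS": mse,
         "FValue": np.nan, "ProbF": np.nan},
        {"Source": "Corrected Total", "DF": df_model + df_err, "SS": ss_total,
         "MS": np.nan, "FValue": np.nan, "ProbF": np.nan},
    ]
    for src in an.index:
        if src == "Residual":
            continue
        label = src.replace("C(", "").replace(")", "")
        rows.append({"Source": label, "DF": float(an.loc[src, "df"]),
                     "SS": float(an.loc[src, "sum_sq"]),
                     "MS": float(an.loc[src, "sum_sq"] / an.loc[src, "df"]),
                     "FValue": float(an.loc[src, "F"]),
                     "ProbF": float(an.loc[src, "PR(>F)"])})
    table = pd.DataFrame(rows)
    mean_z = float(df["Z"].mean())
    table.attrs["R2"] = ss_model / ss_total if ss_total > 0 else np.nan
    table.attrs["RMSE"] = float(np.sqrt(mse))
    table.attrs["CV"] = 100.0 * np.sqrt(mse) / mean_z if mean_z != 0 else np.nan
    table.attrs["mean"] = mean_z
    table.attrs["level_means"] = {
        f: {lev: float(np.tanh(sub["Z"].mean()))
            for lev, sub in df.groupby(f)} for f in factors}
    return table


# ---------------------------------------------------------------------------
# CDmean training-set optimization
# ---------------------------------------------------------------------------

def _cdmean(k: np.ndarray, selected: np.ndarray, others: np.ndarray,
            lam: float) -> float:
    """Mean CD_i = 1 - PEV_i / (sigma_g^2 K_ii) over non-selected individuals."""
    kss = k[np.ix_(selected, selected)]
    v = kss + lam * np.eye(len(selected))
    try:
        vinv = np.linalg.inv(v)
    except np.linalg.LinAlgError:
        v = v + 1e-8 * np.eye(len(selected))
        vinv = np.linalg.inv(v)
        logger.info("cdmean: singular system, ridge jitter 1e-8 applied")
    ones = np.ones(len(selected))
    w = vinv @ ones
    p = vinv - np.outer(w, w) / float(ones @ w)
    kos = k[np.ix_(others, selected)]
    num = np.einsum("ij,jk,ik->i", kos, p, kos)
    kii = np.diag(k)[others]
    return float(np.mean(num / kii))


def cdmean_select(kernel: np.ndarray, candidates: Sequence[str],
                  target_size: int = 100, lam: float = 1.0,
                  n_iter: int = 2000, seed: int = 0,
                  ) -> tuple[list[str], float, list[float]]:
    """Greedy-exchange maximization of the mean coefficient of determination.

    ``lam`` is the variance ratio sigma_e^2 / sigma_g^2 (default 1,
    corresponding to h2 = 0.5 when no REML estimate is supplied).  Returns
    (selected ids, final CDmean, objective trace); the trace is
    non-decreasing because only improving swaps are accepted.
    """
    candidates = [str(c) for c in candidates]
    n = len(candidates)
    if target_size >= n:
        logger.warning("cdmean_select: target_size >= candidates; returning full set")
        return list(candidates), float("nan"), []
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    selected = list(idx[:target_size])
    pool = list(idx[target_size:])
    current = _cdmean(kernel, np.array(selected), np.array(pool), lam)
    trace = [current]
    for _ in range(n_iter):
        i = rng.integers(len(selected))
        j = rng.integers(len(pool))
        selected[i], pool[j] = pool[j], selected[i]
        cand = _cdmean(kernel, np.array(selected), np.array(pool), lam)
        if cand > current:
            current = cand
        else:
            selected[i], pool[j] = pool[j], selected[i]
        trace.append(current)
    return sorted(candidates[i] for i in selected), current, trace


# ---------------------------------------------------------------------------
# progeny validation
# ---------------------------------------------------------------------------

def common_markers(ref: GenotypeMatrix, prog: GenotypeMatrix,
                   min_overlap: float = 0.5) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two genotype matrices to their shared marker set.

    Warns when intersecting (with overlap >= ``min_overlap`` of the smaller
    set), fails below it.
    """
    shared = [m for m in ref.marker_ids if m in set(prog.marker_ids)]
    smaller = min(ref.n_markers, prog.n_markers)
    if len(shared) < min_overlap * smaller:
        raise EvalError(f"marker overlap {len(shared)}/{smaller} below "
                        f"{min_overlap:.0%}; cannot combine populations")
    if len(shared) < smaller:
        logger.warning("marker sets intersected: %d shared of %d", len(shared), smaller)

    def _sub(g: GenotypeMatrix) -> GenotypeMatrix:
        keep = [g.marker_ids.index(m) for m in shared]
        return GenotypeMatrix(codes=g.codes[:, keep], genotype_ids=list(g.genotype_ids),
                              marker_ids=list(shared))
    return _sub(ref), _sub(prog)


def run_progeny_validation(ks: KernelSet, ref_y: pd.DataFrame,
                           prog_y: pd.DataFrame, scenario: str = "S3",
                           models: Sequence[str] = ("GBLUP-GxE",),
                           spec: ModelSpec | None = None,
                           parents: Sequence[str] | None = None,
                           cd_size: int = 100, cd_lambda: float = 1.0,
                           seed: int = 0, trait: str = "") -> pd.DataFrame:
    """Train on a reference subset and predict all progeny lines.

    The kernel set must cover reference and progeny genotypes together.
    Training sets: S1 = the parental lines, S2 = ``cd_size`` reference
    accessions chosen by CDmean, S3 = the whole reference panel.
    """
    spec = spec or ModelSpec()
    if scenario not in SCENARIOS:
        raise EvalError(f"scenario must be one of {SCENARIOS}")
    all_ids = [str(g) for g in ks.genotype_ids]
    ref_ids = [g for g in all_ids if g in set(map(str, ref_y.index))]
    prog_ids = [g for g in all_ids if g in set(map(str, prog_y.index))]
    if scenario == "S1":
        if not parents:
            raise EvalError("scenario S1 needs the parental line ids")
        train = [str(p) for p in parents]
        missing = [p for p in train if p not in set(ref_ids)]
        if missing:
            raise EvalError(f"parents absent from reference data: {missing[:5]}")
    elif scenario == "S2":
        sub = [all_ids.index(g) for g in ref_ids]
        ksub = ks.k_linear[np.ix_(sub, sub)]
        train, _, _ = cdmean_select(ksub, ref_ids, target_size=cd_size,
                                    lam=cd_lambda, seed=seed)
    else:
        train = ref_ids

    y = pd.DataFrame(np.nan, index=all_ids, columns=ref_y.columns)
    y.loc[train] = ref_y.loc[train].to_numpy()
    records = []
    for model in models:
        try:
            preds = _fit_predict(model, ks, y, spec)
            abil = predictive_ability(preds.loc[prog_ids], prog_y.loc[prog_ids])
        except Exception as exc:  # noqa: BLE001
            logger.error("progeny fit failed (scenario=%s model=%s): %s",
                         scenario, model, exc)
            abil = {e: float("nan") for e in ref_y.columns}
        for env, r in abil.items():
            records.append({"scenario": scenario, "trait": trait, "model": model,
                            "environment": env, "n_train": len(train),
                            "r": r, "Z": z_transform(r) if np.isfinite(r) else np.nan})
    return pd.DataFrame(records)
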