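"""Genotypic response variables for the stress vs. control comparison.

Given adjusted means per genotype under the stress (AWD) and control (CF)
systems, this module computes the two response variables used as phenotypes
for genomic prediction:

* the index of relative performance I_j = (Y_j,AWD - Y_j,CF) / Y_j,CF
  (negative values = loss under stress), and its population-level analogue,
  the stress intensity;
* the joint-regression slope beta_j of a genotype's adjusted means on the
  environmental indexes theta_m (the mean of all genotypes in system m);
  beta_j = 1 means average responsiveness, and the mean slope over genotypes
  is exactly 1 by construction.

It also provides the genetic correlation between systems with its
Fisher-transform confidence interval, and the ratio of correlated response
under CF to direct response under AWD, rG * sqrt(H2_CF / H2_AWD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

from .phenostats import AdjustedMeans

logger = logging.getLogger("gxepred.response")

_EPS_DENOM = 1e-9


class ResponseError(ValueError):
    pass


@dataclass
class ResponseProfile:
    """Per-genotype response variables plus population-level summaries."""

    trait: str
    table: pd.DataFrame        # index genotype: columns index, slope, intercept
    population_index: float
    rg: float
    rg_ci: tuple[float, float]
    cr_dr: float | None = None

    def to_csv(self, path) -> None:
        out = self.table.reset_index(names="genotype_id")
        out.insert(1, "trait", self.trait)
        out.to_csv(path, index=False)


def _wide(means: AdjustedMeans | pd.DataFrame) -> pd.DataFrame:
    if isinstance(means, AdjustedMeans):
        return means.values
    return means


def response_index(means: AdjustedMeans | pd.DataFrame,
                   stress: str = "AWD", reference: str = "CF") -> pd.Series:
    """Index of relative performance per genotype, (stress - ref) / ref.

    Genotypes with a (near-)zero reference mean are excluded with a warning.
    """
    wide = _wide(means)
    for col in (stress, reference):
        if col not in wide.columns:
            raise ResponseError(f"system {col!r} absent from adjusted means")
    ref = wide[reference]
    ok = ref.abs() > _EPS_DENOM
    if not ok.all():
        logger.warning("response_index: %d genotypes with ~zero %s mean excluded",
                       int((~ok).sum()), reference)
    idx = (wide.loc[ok, stress] - ref[ok]) / ref[ok]
    idx.name = "index"
    return idx


def population_stress_intensity(means: AdjustedMeans | pd.DataFrame,
                                stress: str = "AWD", reference: str = "CF") -> float:
    """Population-level relative performance: the intensity of the stress."""
    wide = _wide(means)
    ref = wide[reference].mean()
    if abs(ref) <= _EPS_DENOM:
        raise ResponseError("population reference mean is zero")
    return float((wide[stress].mean() - ref) / ref)


def joint_regression(means: AdjustedMeans | pd.DataFrame) -> pd.DataFrame:
    """Per-genotype regression of adjusted means on the environmental indexes.

    theta_m is the mean of all genotypes in system m (left uncentered; the
    intercept absorbs location).  With exactly two systems the least-squares
    fit is exact and the slope reduces to the two-point formula
    (Y_j,2 - Y_j,1) / (theta_2 - theta_1).
    """
    wide = _wide(means)
    if wide.shape[1] < 2:
        raise ResponseError("joint regression needs >= 2 environments")
    theta = wide.mean(axis=0).to_numpy()
    if np.ptp(theta) <= _EPS_DENOM:
        raise ResponseError("environmental indexes identical; slope undefined")
    y = wide.to_numpy()
    tbar = theta.mean()
    sxx = np.sum((theta - tbar) ** 2)
    slope = (y - y.mean(axis=1, keepdims=True)) @ (theta - tbar) / sxx
    intercept = y.mean(axis=1) - slope * tbar
    return pd.DataFrame({"intercept": intercept, "slope": slope}, index=wide.index)


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-transform confidence interval for a correlation coefficient."""
    if n <= 3:
        raise ResponseError("Fisher CI needs n > 3")
    if abs(r) >= 1:
        raise ResponseError("correlation of +-1 gives a degenerate interval")
    z = math.atanh(r)
    half = norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def genetic_correlation_ci(means: AdjustedMeans | pd.DataFrame,
                           n: int | None = None, alpha: float = 0.05,
                           stress: str = "AWD", reference: str = "CF",
                           h2: tuple[float, float] | None = None,
                           ) -> tuple[float, float, float]:
    """Genetic correlation between systems with its Fisher CI: (rG, r1, r2).

    The default estimator is the Pearson correlation of adjusted means.
    Passing per-system entry-mean heritabilities ``h2=(h2_stress, h2_ref)``
    disattenuates it by 1/sqrt(h2_1*h2_2), removing the bias caused by
    entry-mean noise (the plain Pearson estimate tends to rho*sqrt(h2_1*h2_2)).
    """
    wide = _wide(means)[[stress, reference]].dropna()
    if n is None:
        n = len(wide)
    r = float(np.corrcoef(wide[stress], wide[reference])[0, 1])
    if h2 is not None:
        att = math.sqrt(h2[0] * h2[1])
        if att <= 0:
            raise ResponseError("non-positive heritability in disattenuation")
        r = float(np.clip(r / att, -1 + 1e-12, 1 - 1e-12))
    r1, r2 = fisher_ci(r, n, alpha)
    return r, r1, r2


def correlated_response_ratio(rg: float, h2_cf: float, h2_awd: float) -> float:
    """CR_CF / DR_AWD = rG * sqrt(H2_CF / H2_AWD)."""
    if h2_awd <= 0:
        raise ResponseError("direct-response heritability must be positive")
    return rg * math.sqrt(h2_cf / h2_awd)


def spearman_between_systems(means: AdjustedMeans | pd.DataFrame,
                             stress: str = "AWD", reference: str = "CF") -> float:
    """Spearman rank correlation of adjusted means between systems (ties mid-ranked)."""
    wide = _wide(means)[[stress, reference]].dropna()
    rho = spearmanr(wide[stress], wide[reference]).statistic
    return float(rho)


def response_profile(means: AdjustedMeans, n: int | None = None,
                     h2: tuple[float, float] | None = None,
                     stress: str = "AWD", reference: str = "CF") -> ResponseProfile:
    """Bundle index, slope, population index, rG with CI and CR/DR."""
    idx = response_index(means, stress, reference)
    jr = joint_regression(means)
    table = jr.join(idx, how="left")[["index", "slope", "intercept"]]
    rg, r1, r2 = genetic_correlation_ci(means, n=n, stress=stress,
                                        reference=reference, h2=h2)
    cr_dr = None
    if h2 is not None:
        cr_dr = correlated_response_ratio(rg, h2_cf=h2[1], h2_awd=h2[0])
    return ResponseProfile(
        trait=means.trait, table=table,
        population_index=population_stress_intensity(means, stress, reference),
        rg=rg, rg_ci=(r1, r2), cr_dr=cr_dr,
    )
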