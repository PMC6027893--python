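"""Synthetic two-environment breeding-trial generator.

Emulates the structure of a managed bi-environment rice trial: a panel of
inbred genotypes scored on biallelic SNPs, phenotyped under a stress and a
control water-management system over several years with replicated plots.
The phenotype model mirrors the variance decomposition assumed downstream:

    y_{gery} = env_mean_e + year_effect_y + g0_g + ge_{g,e} + gy_{g,e,y} + eps

where g0 is a marker-derived genetic main effect shared across environments
(variance ``var_main``), ge a marker-derived environment-specific deviation
(variance ``var_env_specific``), gy a genotype-by-year deviate and eps plot
residual.  The implied cross-environment genetic correlation is

    rho = var_main / (var_main + var_env_specific).

Marker effects are Gaussian i.i.d., scaled against the realized marker
variance so the genetic variances hit their targets exactly in expectation
(infinitesimal model).  Loci are unlinked; genotypes are drawn from
generalized Hardy-Weinberg proportions with an inbreeding coefficient so
that highly homozygous (inbred-line) panels can pass a heterozygosity
filter, as real inbred material does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gxepred.simdata")

#: default marker filters matching the study's working SNP set
MAF_MIN = 0.05
HET_MAX = 0.05

PHENOTYPE_COLUMNS = ["genotype_id", "environment", "year", "replicate", "trait", "value"]


class SimulationError(ValueError):
    """Raised when a generator precondition or filter leaves no usable data."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic trial.

    Defaults are sized like the reference panel of the motivating study:
    284 genotypes, two water-management systems, two years, three replicated
    plots, with variances chosen to give rho = 0.8 and an entry-mean
    broad-sense heritability of ~0.85 per system.
    """

    n_genotypes: int = 284
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_environments: int = 2
    n_years: int = 2
    n_reps: int = 3
    var_main: float = 40.0
    var_env_specific: float = 10.0
    var_gy: float = 5.0
    var_residual: float = 38.0
    env_means: tuple[float, ...] = (100.3, 93.4)
    year_effects: tuple[float, ...] = (1.5, -1.5)
    inbreeding: float = 0.98
    n_subpops: int = 5
    fst: float = 0.2
    admixture: float = 0.3
    family_size: int = 6
    fst_family: float = 0.35
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("var_main", "var_env_specific", "var_gy", "var_residual"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if not (0.0 <= self.inbreeding <= 1.0):
            raise SimulationError("inbreeding coefficient must be in [0, 1]")
        if not (0.0 <= self.fst < 1.0) or self.n_subpops < 1:
            raise SimulationError("need 0 <= fst < 1 and n_subpops >= 1")
        if self.admixture <= 0:
            raise SimulationError("admixture concentration must be positive")
        if self.family_size < 1 or not (0.0 <= self.fst_family < 1.0):
            raise SimulationError("need family_size >= 1 and 0 <= fst_family < 1")
        if self.n_genotypes < 2 or self.n_markers < 1:
            raise SimulationError("need n_genotypes >= 2 and n_markers >= 1")
        if len(self.env_means) != self.n_environments:
            raise SimulationError("env_means length must equal n_environments")
        if len(self.year_effects) != self.n_years:
            raise SimulationError("year_effects length must equal n_years")

    @property
    def rho(self) -> float:
        """Implied cross-environment genetic correlation."""
        tot = self.var_main + self.var_env_specific
        return 1.0 if tot == 0 else self.var_main / tot

    @property
    def genetic_variance(self) -> float:
        """Total per-system genetic variance."""
        return self.var_main + self.var_env_specific

    def implied_h2(self, n_y: float | None = None, n_r: float | None = None) -> float:
        """Entry-mean broad-sense heritability implied by the config."""
        n_y = self.n_years if n_y is None else n_y
        n_r = (self.n_years * self.n_reps) if n_r is None else n_r
        g = self.genetic_variance
        return g / (g + self.var_gy / n_y + self.var_residual / n_r)

    @property
    def environment_labels(self) -> tuple[str, ...]:
        if self.n_environments == 2:
            return ("AWD", "CF")
        return tuple(f"E{i + 1}" for i in range(self.n_environments))


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Coded biallelic SNP matrix: genotypes x markers in {-1, 0, 1}.

    ``1`` is the minor-allele homozygote, ``0`` the heterozygote.  ``maf``
    and ``het_rate`` are realized per-marker statistics.
    """

    codes: np.ndarray
    genotype_ids: list[str]
    marker_ids: list[str]
    maf: np.ndarray = field(default=None)
    het_rate: np.ndarray = field(default=None)

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise SimulationError("codes must be a 2-D matrix")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise SimulationError("genotype codes must be in {-1, 0, 1}")
        if self.codes.shape != (len(self.genotype_ids), len(self.marker_ids)):
            raise SimulationError("codes shape inconsistent with id lists")
        if self.maf is None:
            self.maf = self._realized_maf()
        if self.het_rate is None:
            self.het_rate = (self.codes == 0).mean(axis=0)

    def _realized_maf(self) -> np.ndarray:
        p = (self.codes + 1).mean(axis=0) / 2.0  # frequency of the allele coded +1
        return np.minimum(p, 1.0 - p)

    @property
    def n_genotypes(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def centered(self) -> np.ndarray:
        """Column-centered codes (float), the X of the linear kernel."""
        x = self.codes.astype(float)
        return x - x.mean(axis=0, keepdims=True)

    def filtered(self, maf_min: float = MAF_MIN, het_max: float = HET_MAX) -> "GenotypeMatrix":
        """Return a copy keeping markers with MAF > maf_min and het < het_max."""
        keep = (self.maf > maf_min) & (self.het_rate < het_max)
        if not keep.any():
            raise SimulationError(
                f"no markers pass filters (MAF > {maf_min}, het < {het_max}); "
                f"{(self.maf <= maf_min).sum()} fail MAF, "
                f"{(self.het_rate >= het_max).sum()} fail heterozygosity"
            )
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("filtered %d/%d markers (MAF<=%.3g or het>=%.3g)",
                        n_drop, self.n_markers, maf_min, het_max)
        return GenotypeMatrix(
            codes=self.codes[:, keep],
            genotype_ids=list(self.genotype_ids),
            marker_ids=[m for m, k in zip(self.marker_ids, keep) if k],
            maf=self.maf[keep],
            het_rate=self.het_rate[keep],
        )

    def subset(self, genotype_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {g: i for i, g in enumerate(self.genotype_ids)}
        rows = [index[g] for g in genotype_ids]
        return GenotypeMatrix(
            codes=self.codes[rows],
            genotype_ids=list(genotype_ids),
            marker_ids=list(self.marker_ids),
            maf=self.maf.copy(),
            het_rate=self.het_rate.copy(),
        )

    # -- persistence (CSV matrix: rows genotypes, columns markers) ---------
    def to_csv(self, path) -> None:
        pd.DataFrame(self.codes, index=self.genotype_ids, columns=self.marker_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            codes=df.to_numpy(dtype=int),
            genotype_ids=[str(g) for g in df.index],
            marker_ids=[str(m) for m in df.columns],
        )


@dataclass
class TrialObservations:
    """Plot-level phenotype records in long format.

    ``data`` columns: genotype_id, environment, year, replicate, trait, value.
    ``truth`` (optional) holds the simulated per-(genotype, environment) true
    genetic values; ``masking_log`` records cells removed by masking.
    """

    data: pd.DataFrame
    truth: pd.DataFrame | None = None
    masking_log: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SimulationError(f"phenotype table missing columns {missing}")
        self.data = self.data.reset_index(drop=True)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype_id"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def subset(self, trait: str | None = None, environment: str | None = None) -> pd.DataFrame:
        df = self.data
        if trait is not None:
            df = df[df["trait"] == trait]
        if environment is not None:
            df = df[df["environment"] == environment]
        return df

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialObservations":
        return cls(data=pd.read_csv(path))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw unlinked biallelic SNP genotypes and apply the marker filters.

    Ancestral allele frequencies are uniform on ``config.maf_range``.  The
    panel carries realistic population structure on two levels, mirroring
    what marker kernels exploit in real breeding collections:

    * ``n_subpops`` ancestral groups whose frequencies diverge from the
      ancestral ones by the Balding-Nichols beta model at the configured
      ``fst``, mixed per family by Dirichlet(``admixture``) ancestry
      proportions (continuous relatedness gradients);
    * families of ``family_size`` closely related lines whose frequencies
      drift further from the family base at ``fst_family`` (the tight
      relatedness of breeding lines sharing recent ancestors, without which
      cross-environment genetic covariances are barely identifiable).

    ``fst=0`` together with ``family_size=1`` recovers a fully unstructured
    panel.  Given individual frequencies, genotype classes follow
    generalized Hardy-Weinberg proportions with inbreeding coefficient F
    (heterozygote probability 2pq(1-F)).  Codes are oriented so +1 is the
    realized minor-allele homozygote.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_genotypes, config.n_markers
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, size=p)
    n_fam = max(1, -(-n // config.family_size))  # ceil division
    if config.fst > 0 and config.n_subpops > 1:
        c = (1.0 - config.fst) / config.fst
        sub_freq = np.clip(rng.beta(np.maximum(freq * c, 1e-3),
                                    np.maximum((1 - freq) * c, 1e-3),
                                    size=(config.n_subpops, p)), 1e-4, 1 - 1e-4)
        admix = rng.dirichlet(np.full(config.n_subpops, config.admixture), size=n_fam)
        fam_base = admix @ sub_freq  # per-family base frequency
    else:
        fam_base = np.tile(freq, (n_fam, 1))
    if config.fst_family > 0 and config.family_size > 1:
        cf = (1.0 - config.fst_family) / config.fst_family
        fam_freq = np.clip(rng.beta(np.maximum(fam_base * cf, 1e-3),
                                    np.maximum((1 - fam_base) * cf, 1e-3)),
                           1e-4, 1 - 1e-4)
    else:
        fam_freq = fam_base
    pmat = np.repeat(fam_freq, config.family_size, axis=0)[:n]
    f = config.inbreeding
    # generalized HW class probabilities per individual x marker
    p_hom_minor = pmat**2 + f * pmat * (1 - pmat)
    p_het = 2 * pmat * (1 - pmat) * (1 - f)
    u = rng.random((n, p))
    codes = np.where(u < p_hom_minor, 1, np.where(u < p_hom_minor + p_het, 0, -1)).astype(np.int8)
    # orient to the realized minor allele
    realized = (codes + 1).mean(axis=0) / 2.0
    flip = realized > 0.5
    codes[:, flip] *= -1
    geno = GenotypeMatrix(
        codes=codes,
        genotype_ids=[f"G{i + 1:04d}" for i in range(n)],
        marker_ids=[f"M{j + 1:05d}" for j in range(p)],
    )
    return geno.filtered(MAF_MIN, HET_MAX)


def true_genetic_values(geno: GenotypeMatrix, config: SimConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Marker-derived true genetic values per (genotype, environment).

    Effects are i.i.d. Gaussian scaled by the realized sum of marker
    variances so that Var(g0) = var_main and Var(ge) = var_env_specific in
    expectation over effect draws.
    """
    x = geno.centered()
    col_var = x.var(axis=0)
    c = col_var.sum()
    if c <= 0:
        raise SimulationError("all markers are monomorphic; cannot build genetic values")
    a0 = rng.normal(0.0, np.sqrt(config.var_main / c), size=geno.n_markers)
    g0 = x @ a0
    values = {}
    for e, label in enumerate(config.environment_labels):
        be = rng.normal(0.0, np.sqrt(config.var_env_specific / c), size=geno.n_markers)
        values[label] = g0 + x @ be
    return pd.DataFrame(values, index=geno.genotype_ids)


def simulate_trial(geno: GenotypeMatrix, config: SimConfig, trait: str = "FL") -> TrialObservations:
    """Simulate replicated plot phenotypes for every (genotype, env, year, rep).

    The genotype-by-year deviates are drawn independently per environment
    (the two systems are physically separate trials), so each per-system
    analysis sees genotype-by-year variance ``var_gy``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth = true_genetic_values(geno, config, rng)
    n = geno.n_genotypes
    rows = []
    for e, env in enumerate(config.environment_labels):
        u_e = truth[env].to_numpy()
        gy = rng.normal(0.0, np.sqrt(config.var_gy), size=(n, config.n_years))
        for y in range(config.n_years):
            base = config.env_means[e] + config.year_effects[y] + u_e + gy[:, y]
            for r in range(config.n_reps):
                eps = rng.normal(0.0, np.sqrt(config.var_residual), size=n)
                rows.append(pd.DataFrame({
                    "genotype_id": geno.genotype_ids,
                    "environment": env,
                    "year": y + 1,
                    "replicate": r + 1,
                    "trait": trait,
                    "value": base + eps,
                }))
    data = pd.concat(rows, ignore_index=True)
    return TrialObservations(data=data, truth=truth)


def mask_observations(obs: TrialObservations,
                      genotypes: Iterable[str],
                      environments: Iterable[str] | None = None) -> TrialObservations:
    """Return a copy of ``obs`` with the named cells removed.

    ``environments=None`` masks the genotypes everywhere (M1-style);
    otherwise only records in the listed environments are removed
    (M2-style).  The removed cells are appended to ``masking_log``.
    """
    genotypes = set(genotypes)
    if not genotypes:
        return TrialObservations(data=obs.data.copy(), truth=obs.truth,
                                 masking_log=list(obs.masking_log))
    if environments is None:
        drop = obs.data["genotype_id"].isin(genotypes)
        envs_logged = obs.environments
    else:
        environments = set(environments)
        drop = obs.data["genotype_id"].isin(genotypes) & obs.data["environment"].isin(environments)
        envs_logged = sorted(environments)
    kept = obs.data[~drop]
    if kept.empty:
        raise SimulationError("masking removed every observation; nothing left to train on")
    log = list(obs.masking_log) + [(g, e) for g in sorted(genotypes) for e in envs_logged]
    return TrialObservations(data=kept.copy(), truth=obs.truth, masking_log=log)
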