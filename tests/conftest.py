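"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import gxepred as gp
from gxepred.gxemodels import ModelSpec


@pytest.fixture(scope="session")
def small_panel():
    """60-genotype panel with a complete two-system trial."""
    cfg = gp.SimConfig(n_genotypes=60, n_markers=300, seed=1)
    geno = gp.simulate_genotypes(cfg)
    obs = gp.simulate_trial(geno, cfg)
    return cfg, geno, obs


@pytest.fixture(scope="session")
def medium_panel():
    """100-genotype panel with adjusted means and kernels (shared, heavy)."""
    cfg = gp.SimConfig(n_genotypes=100, n_markers=400, seed=5)
    geno = gp.simulate_genotypes(cfg)
    obs = gp.simulate_trial(geno, cfg)
    means_awd, vc_awd = gp.fit_single_system(obs, "FL", "AWD")
    means_cf, vc_cf = gp.fit_single_system(obs, "FL", "CF")
    means = gp.AdjustedMeans.merge([means_awd, means_cf])
    means.values.index = means.values.index.astype(str)
    ks = gp.KernelSet.build(geno, phenotype=means.values.mean(axis=1).to_numpy())
    return {
        "cfg": cfg, "geno": geno, "obs": obs, "means": means,
        "vc": {"AWD": vc_awd, "CF": vc_cf}, "kernels": ks,
    }


@pytest.fixture()
def short_spec():
    """Chain settings for quick Gibbs fits in unit tests."""
    return ModelSpec(n_iter=3000, burn_in=500, thin=5, seed=7)


def genotype_means(obs: gp.TrialObservations, geno: gp.GenotypeMatrix) -> pd.DataFrame:
    """Per-(genotype, environment) phenotype means, kernel-ordered."""
    dm = obs.data.groupby(["genotype_id", "environment"])["value"].mean().unstack()
    return dm.loc[[str(g) for g in geno.genotype_ids]]
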