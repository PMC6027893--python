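"""Validation designs: partitions, abilities, Z-ANOVA, CDmean, progeny."""

import numpy as np
import pandas as pd
import pytest

import gxepred as gp
from gxepred.evalframe import EvalError, _cdmean, apply_partition
from gxepred.gxemodels import ModelSpec
from gxepred.kernels import KernelSet
from gxepred.simdata import GenotypeMatrix


class TestPartitions:
    def test_reference_panel_sizes(self):
        pop = [f"G{i}" for i in range(284)]
        plans = gp.make_partitions(pop, fraction=0.8, n_reps=3, scheme="M1", seed=0)
        for p in plans:
            assert len(p.training) == 227 and len(p.validation) == 57
            assert set(p.training) | set(p.validation) == set(pop)
            assert not set(p.training) & set(p.validation)

    def test_same_seed_reproducible_and_shared_across_schemes(self):
        pop = [f"G{i}" for i in range(50)]
        a = gp.make_partitions(pop, n_reps=4, scheme="M1", seed=9)
        b = gp.make_partitions(pop, n_reps=4, scheme="M1", seed=9)
        m2 = gp.make_partitions(pop, n_reps=4, scheme="M2", seed=9)
        for x, y, z in zip(a, b, m2):
            assert x.training == y.training == z.training

    def test_m2_masks_exactly_one_environment(self):
        pop = [f"G{i}" for i in range(40)]
        plans = gp.make_partitions(pop, n_reps=2, scheme="M2", seed=1)
        y = pd.DataFrame(1.0, index=pop, columns=["AWD", "CF"])
        for p in plans:
            masked = apply_partition(y, p)
            obs_count = masked.loc[list(p.validation)].notna().sum(axis=1)
            assert (obs_count == 1).all()
            envs = pd.Series(p.observed_env)
            assert abs((envs == "AWD").sum() - (envs == "CF").sum()) <= 1

    def test_bad_fraction_rejected(self):
        with pytest.raises(EvalError):
            gp.make_partitions([f"G{i}" for i in range(20)], fraction=1.2)


class TestPredictiveAbility:
    def test_perfect_and_inverted_predictions(self):
        obs = pd.DataFrame({"AWD": [1.0, 2, 3, 4], "CF": [2.0, 4, 6, 8]},
                           index=list("abcd"))
        assert gp.predictive_ability(obs, obs) == {"AWD": 1.0, "CF": 1.0}
        flipped = gp.predictive_ability(-obs, obs)
        assert flipped["AWD"] == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_toy_pairs(self):
        p = pd.Series([1.0, 2.0, 4.0, 3.0, 5.0], index=list("abcde"))
        o = pd.Series([2.0, 1.0, 3.0, 5.0, 4.0], index=list("abcde"))
        got = gp.predictive_ability(p, o)["r"]
        pc, oc = p - p.mean(), o - o.mean()
        hand = (pc * oc).sum() / np.sqrt((pc**2).sum() * (oc**2).sum())
        assert got == pytest.approx(hand, rel=1e-12)

    def test_degenerate_strata_are_nan(self):
        obs = pd.DataFrame({"E": [1.0, 2, 3]}, index=list("abc"))
        const = pd.DataFrame({"E": [5.0, 5, 5]}, index=list("abc"))
        assert np.isnan(gp.predictive_ability(const, obs)["E"])
        short = obs.iloc[:2]
        assert np.isnan(gp.predictive_ability(short, short)["E"])


class TestZstatAnova:
    def test_single_factor_sum_of_squares_matches_hand_anova(self):
        z = np.array([0.5, 0.6, 0.7, 1.0, 1.1, 1.2])
        rec = pd.DataFrame({"Z": z, "r": np.tanh(z), "model": list("AAABBB")})
        tab = gp.zstat_anova(rec, ["model"])
        row = tab[tab["Source"] == "model"].iloc[0]
        assert row["SS"] == pytest.approx(0.375)   # 3*(0.25^2)*2
        assert row["DF"] == 1
        assert tab.attrs["level_means"]["model"]["A"] == pytest.approx(np.tanh(0.6))

    def test_identical_z_gives_zero_factor_ss(self):
        rec = pd.DataFrame({"Z": [0.4] * 8, "r": [np.tanh(0.4)] * 8,
                            "model": list("AABBAABB"), "scheme": list("CDCDCDCD")})
        tab = gp.zstat_anova(rec, ["model", "scheme"])
        for src in ("model", "scheme"):
            assert tab[tab["Source"] == src]["SS"].iloc[0] == pytest.approx(0.0, abs=1e-20)

    def test_r2_identity(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0.6, 0.2, 40)
        rec = pd.DataFrame({"Z": z, "r": np.tanh(z),
                            "model": rng.choice(list("AB"), 40),
                            "scheme": rng.choice(list("CD"), 40)})
        tab = gp.zstat_anova(rec, ["model", "scheme"], interactions=True)
        ss_tot = tab[tab["Source"] == "Corrected Total"]["SS"].iloc[0]
        ss_err = tab[tab["Source"] == "Error"]["SS"].iloc[0]
        assert tab.attrs["R2"] + ss_err / ss_tot == pytest.approx(1.0)
        assert -1 <= np.tanh(tab.attrs["mean"]) <= 1

    def test_aliased_factors_rejected(self):
        rec = pd.DataFrame({"Z": [0.1, 0.2, 0.3, 0.4], "r": [0.1, 0.2, 0.3, 0.4],
                            "model": list("AABB"), "twin": list("AABB")})
        with pytest.raises(EvalError, match="rank|aliased|levels"):
            gp.zstat_anova(rec, ["model", "twin"])


@pytest.fixture(scope="module")
def kernel150():
    cfg = gp.SimConfig(n_genotypes=150, n_markers=300, seed=9)
    geno = gp.simulate_genotypes(cfg)
    return gp.linear_kernel(geno, scale=True), [f"G{i}" for i in range(150)]


class TestCdmean:
    def test_trace_monotone_and_beats_random_sets(self, kernel150):
        k, ids = kernel150
        sel, cd, trace = gp.cdmean_select(k, ids, target_size=100, lam=1.0,
                                          n_iter=400, seed=4)
        assert len(sel) == 100
        assert all(b >= a for a, b in zip(trace, trace[1:]))
        rng = np.random.default_rng(7)
        rand = []
        for _ in range(200):
            idx = rng.permutation(150)
            rand.append(_cdmean(k, np.sort(idx[:100]), np.sort(idx[100:]), 1.0))
        assert cd >= np.quantile(rand, 0.95)

    def test_full_set_returns_trivially(self, kernel150):
        k, ids = kernel150
        sel, cd, trace = gp.cdmean_select(k, ids, target_size=150)
        assert sel == ids and np.isnan(cd) and trace == []


class TestCvExperiment:
    def test_record_counts_and_pairing(self, medium_panel):
        ks = medium_panel["kernels"]
        y = medium_panel["means"].values
        spec = ModelSpec(n_iter=600, burn_in=100, thin=2, seed=3)
        rec = gp.run_cv_experiment(ks, y, models=("GBLUP-GxE",),
                                   schemes=("M1", "M2"), spec=spec,
                                   n_reps=2, seed=4, trait="FL")
        # reps x schemes x models x environments
        assert len(rec) == 2 * 2 * 1 * 2
        piv = rec.pivot_table(index=["replicate", "environment"],
                              columns="scheme", values="r")
        assert piv.notna().all().all()  # paired by replicate id
        assert ((rec["r"] >= -1) & (rec["r"] <= 1)).all()
        assert np.allclose(rec["Z"], np.arctanh(rec["r"]))

    def test_single_column_response_restricts_to_single_scheme(self, medium_panel):
        ks = medium_panel["kernels"]
        slope = gp.joint_regression(medium_panel["means"])["slope"].to_frame("slope")
        spec = ModelSpec(n_iter=600, burn_in=100, thin=2, seed=3)
        rec = gp.run_cv_experiment(ks, slope, models=("GBLUP",),
                                   schemes=("single", "M1", "M2"), spec=spec,
                                   n_reps=2, seed=4, trait="FL", response="slope")
        assert set(rec["scheme"]) == {"single"}
        assert set(rec["response"]) == {"slope"}

    def test_noise_free_heritable_data_approaches_perfect_ability(self, medium_panel):
        # no noise, perfectly correlated environments: the observed
        # environment pins the genetic value, so M2 ability approaches 1
        ks = medium_panel["kernels"]
        truth = medium_panel["obs"].truth["AWD"]
        y = pd.DataFrame({"AWD": truth, "CF": truth})
        y.index = y.index.astype(str)
        # a weak prior on a noise-scale far below the signal lets the
        # residual variance vanish as the data demand
        spec = ModelSpec(n_iter=4000, burn_in=800, thin=2, seed=5,
                         df_prior=1.0, prior_mode=1.0)
        rec = gp.run_cv_experiment(ks, y, models=("GBLUP-GxE",),
                                   schemes=("M2",), spec=spec,
                                   n_reps=2, seed=6, trait="FL")
        assert rec["r"].mean() > 0.95
        assert (rec["r"] > 0.9).all()


@pytest.fixture(scope="module")
def panel():
    cfg = gp.SimConfig(n_genotypes=120, n_markers=400, seed=17)
    geno = gp.simulate_genotypes(cfg)
    obs = gp.simulate_trial(geno, cfg)
    dm = obs.data.groupby(["genotype_id", "environment"])["value"].mean().unstack()
    dm = dm.loc[[str(g) for g in geno.genotype_ids]]
    return geno, dm


class TestProgenyValidation:
    def test_relabeled_subset_progeny_reaches_within_population_levels(self, panel):
        geno, dm = panel
        ref_ids = list(dm.index)
        prog_src = ref_ids[90:]
        prog_ids = [f"P{i}" for i in range(len(prog_src))]
        combined = GenotypeMatrix(
            codes=np.vstack([geno.codes, geno.subset(prog_src).codes]),
            genotype_ids=ref_ids + prog_ids,
            marker_ids=list(geno.marker_ids))
        ks = KernelSet.build(combined, bandwidth=0.01)
        ref_y = dm
        prog_y = dm.loc[prog_src].set_axis(prog_ids, axis=0)
        spec = ModelSpec(n_iter=2500, burn_in=500, thin=4, seed=2)
        rec = gp.run_progeny_validation(ks, ref_y, prog_y, scenario="S3",
                                        models=("GBLUP-GxE",), spec=spec)
        assert (rec["n_train"] == 120).all()
        assert rec["r"].mean() > 0.8  # clones of training lines: near-CV level

    def test_unrelated_parents_give_low_ability(self, panel):
        geno, dm = panel
        # unstructured panel: no families, no subpopulation signal
        cfg = gp.SimConfig(n_genotypes=120, n_markers=800, seed=18,
                           fst=0.0, family_size=1)
        g2 = gp.simulate_genotypes(cfg)
        obs2 = gp.simulate_trial(g2, cfg)
        dm2 = obs2.data.groupby(["genotype_id", "environment"])["value"].mean().unstack()
        dm2 = dm2.loc[[str(x) for x in g2.genotype_ids]]
        ids = list(dm2.index)
        parents, progeny = ids[:30], ids[60:]
        ks = KernelSet.build(g2, bandwidth=0.01)
        spec = ModelSpec(n_iter=2500, burn_in=500, thin=4, seed=2)
        rec = gp.run_progeny_validation(ks, dm2.loc[ids[:60]], dm2.loc[progeny],
                                        scenario="S1", models=("GBLUP",),
                                        parents=parents, spec=spec)
        assert (rec["n_train"] == 30).all()
        assert rec["r"].abs().mean() < 0.35

    def test_scenario_training_sizes(self, panel):
        geno, dm = panel
        ks = KernelSet.build(geno, bandwidth=0.01)
        ref_ids = list(dm.index)
        spec = ModelSpec(n_iter=400, burn_in=100, thin=2, seed=2)
        prog_y = dm.loc[ref_ids[100:]]
        s2 = gp.run_progeny_validation(ks, dm.loc[ref_ids[:100]], prog_y,
                                       scenario="S2", models=("GBLUP",),
                                       cd_size=40, spec=spec)
        assert (s2["n_train"] == 40).all()
        with pytest.raises(EvalError, match="parental"):
            gp.run_progeny_validation(ks, dm, prog_y, scenario="S1",
                                      models=("GBLUP",), spec=spec)


class TestCommonMarkers:
    def test_intersection_and_failure_threshold(self, small_panel):
        _, geno, _ = small_panel
        half = geno.marker_ids[: geno.n_markers // 2]
        other = GenotypeMatrix(
            codes=geno.codes[:, : geno.n_markers // 2],
            genotype_ids=[f"P{i}" for i in range(geno.n_genotypes)],
            marker_ids=half)
        a, b = gp.common_markers(geno, other)
        assert a.marker_ids == b.marker_ids == half
        tiny = GenotypeMatrix(codes=geno.codes[:, :10],
                              genotype_ids=other.genotype_ids,
                              marker_ids=geno.marker_ids[:10])
        small = GenotypeMatrix(codes=geno.codes[:, -30:],
                               genotype_ids=other.genotype_ids,
                               marker_ids=geno.marker_ids[-30:])
        with pytest.raises(EvalError, match="overlap"):
            gp.common_markers(tiny, small)
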