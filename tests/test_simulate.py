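"""Generator contracts: Mendelian genotypes, methylation sharing,
heritability calibration, anchoring, and determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from famethyl.pedigree import FEMALE, MALE, Individual, Pedigree
from famethyl.simulate import (
    CalibrationError,
    CohortSimulator,
    ConfigError,
    MethylationModel,
    ScenarioConfig,
    SiteSpec,
    build_pedigree,
    calibrate_effect,
    default_gaw20_scenario,
    simulate_genotypes,
    simulate_methylation,
)


def founders_only(n: int) -> Pedigree:
    return Pedigree(
        [Individual(f"I{k}", f"F{k}", sex=MALE if k % 2 else FEMALE) for k in range(n)]
    )


def one_sibship(n_kids: int) -> Pedigree:
    inds = [Individual("d", "F1", sex=MALE), Individual("m", "F1", sex=FEMALE)]
    inds += [
        Individual(f"c{k}", "F1", father="d", mother="m", sex=MALE)
        for k in range(n_kids)
    ]
    return Pedigree(inds)


class TestGenotypes:
    def test_homozygous_parents_force_offspring(self):
        rng = np.random.default_rng(0)
        ped = one_sibship(50)
        for _ in range(40):
            g = simulate_genotypes(ped, 0.5, rng)[:, 0]
            if g[0] == 0 and g[1] == 0:
                assert np.all(g[2:] == 0)
            if g[0] == 2 and g[1] == 2:
                assert np.all(g[2:] == 2)

    def test_founder_dosage_mean_matches_binomial(self):
        rng = np.random.default_rng(1)
        g = simulate_genotypes(founders_only(10_000), 0.3, rng)[:, 0]
        se = math.sqrt(2 * 0.3 * 0.7 / 10_000)
        assert abs(g.mean() - 0.6) < 3 * se

    def test_offspring_marginal_moments(self):
        # offspring of random founders are marginally Binomial(2, maf) too
        rng = np.random.default_rng(2)
        ped = build_pedigree(default_gaw20_scenario(), np.random.default_rng(0))
        offspring = np.array(
            [not ped[i.iid].is_founder() for i in ped.individuals]
        )
        means, vars_ = [], []
        for _ in range(30):
            g = simulate_genotypes(ped, 0.3, rng)[:, 0][offspring]
            means.append(g.mean())
            vars_.append(g.var(ddof=1))
        assert abs(np.mean(means) - 0.6) < 0.01
        assert abs(np.mean(vars_) - 0.42) < 0.015

    def test_mendelian_consistency_property(self):
        rng = np.random.default_rng(3)
        ped = build_pedigree(default_gaw20_scenario(), np.random.default_rng(0))
        ids = [ind.iid for ind in ped.individuals]
        pos = {iid: k for k, iid in enumerate(ids)}
        g = simulate_genotypes(ped, np.array([0.2, 0.5]), rng)
        for ind in ped.individuals:
            if ind.is_founder():
                continue
            for j in range(2):
                child = g[pos[ind.iid], j]
                pa, ma = g[pos[ind.father], j], g[pos[ind.mother], j]
                lo = (pa == 2) + (ma == 2)
                hi = 2 - ((pa == 0) + (ma == 0))
                assert lo <= child <= hi

    def test_bad_maf_rejected(self):
        with pytest.raises(ConfigError):
            simulate_genotypes(founders_only(2), 0.7, np.random.default_rng(0))


class TestMethylation:
    def _cfg(self, f: float) -> ScenarioConfig:
        sites = (
            SiteSpec("c1", True, h2=0.1),
            SiteSpec("n1", False, partner="c1"),
        )
        return ScenarioConfig(sites=sites, cpg_shared_var_frac=f)

    def test_zero_sharing_gives_independence(self):
        m = simulate_methylation(self._cfg(0.0), 10_000, np.random.default_rng(0))
        r = np.corrcoef(m[:, 0], m[:, 1])[0, 1]
        assert abs(r) < 3.0 / math.sqrt(10_000)

    def test_half_sharing_latent_correlation(self):
        m, latent = simulate_methylation(
            self._cfg(0.5), 10_000, np.random.default_rng(1), return_latent=True
        )
        r = np.corrcoef(latent[:, 0], latent[:, 1])[0, 1]
        assert abs(r - math.sqrt(0.5)) < 3.0 / math.sqrt(10_000)

    def test_values_in_unit_interval(self):
        m = simulate_methylation(self._cfg(0.9), 10_000, np.random.default_rng(2))
        assert np.all(m >= 0.0) and np.all(m <= 1.0)

    def test_bad_shared_fraction_rejected(self):
        with pytest.raises(ConfigError):
            self._cfg(1.0)


class TestCalibration:
    def test_uniform_moments_in_closed_form(self):
        u = MethylationModel.uniform()
        assert u.mean_one_minus() == pytest.approx(0.5)
        assert u.second_moment_one_minus() == pytest.approx(1.0 / 3.0)

    def test_zero_heritability_gives_zero_effect(self):
        assert calibrate_effect(0.0, 1.0, MethylationModel.uniform(), 0.3) == 0.0

    @pytest.mark.parametrize("meth", [MethylationModel.uniform(), MethylationModel(2, 2)])
    def test_monte_carlo_variance_matches_target(self, meth):
        h2, var_total, maf, n = 0.125, 1.0, 0.3, 100_000
        b = calibrate_effect(h2, var_total, meth, maf)
        rng = np.random.default_rng(42)
        g = rng.binomial(2, maf, n)
        m = meth.sample(rng, n)
        realized = np.var(b * g * (1.0 - m))
        # Monte-Carlo SE of the sample variance of the causal term
        x = b * g * (1.0 - m)
        se = np.std((x - x.mean()) ** 2) / math.sqrt(n)
        assert abs(realized - h2 * var_total) < 3 * se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_effect(1.2, 1.0, MethylationModel.uniform(), 0.3)
        with pytest.raises(CalibrationError):
            calibrate_effect(0.1, -1.0, MethylationModel.uniform(), 0.3)


class TestScenario:
    def test_default_scenario_shape(self):
        cfg = default_gaw20_scenario()
        assert len(cfg.sites) == 10
        causal = cfg.causal_sites()
        assert len(causal) == 5
        assert [s.h2 for s in causal] == [0.125, 0.10, 0.075, 0.05, 0.025]
        assert cfg.n_replicates == 200

    def test_default_cohort_is_exactly_680(self):
        cfg = default_gaw20_scenario()
        ped = build_pedigree(cfg, np.random.default_rng(0))
        assert len(ped) == 680
        assert len(ped.families()) == 164

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_gaw20_scenario(seed=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert ScenarioConfig.from_yaml(path) == cfg


class TestReplicates:
    def test_determinism_bit_identical(self):
        cfg = default_gaw20_scenario(seed=5, n_replicates=2)
        a = CohortSimulator(cfg).replicate(1)
        b = CohortSimulator(cfg).replicate(1)
        pd.testing.assert_frame_equal(a, b)

    def test_replicates_differ(self):
        cfg = default_gaw20_scenario(seed=5, n_replicates=2)
        sim = CohortSimulator(cfg)
        assert not sim.replicate(0)["tg_post"].equals(sim.replicate(1)["tg_post"])

    def test_null_model_outcome_moments(self):
        # no causal effects, no family effect: log post ~ mu + covariates + noise
        cfg = ScenarioConfig(
            sites=(SiteSpec("s", True, h2=0.0),),
            sigma_family=0.0,
            beta_age=0.0,
            beta_sex=0.0,
            center_effects=(0.0,),
        )
        sim = CohortSimulator(cfg)
        pooled = np.concatenate(
            [np.log(sim.replicate(r)["tg_post"].to_numpy()) for r in range(20)]
        )
        assert abs(pooled.mean() - cfg.mu_post) < 0.01
        assert abs(pooled.std() - cfg.sigma_resid) < 0.01

    def test_within_family_correlation_matches_variance_components(self):
        # sib-pair residual correlation = 0.5 sigma_f^2 / (sigma_f^2 + sigma_e^2)
        cfg = ScenarioConfig(
            sites=(SiteSpec("s", True, h2=0.0),),
            sigma_family=0.4,
            sigma_resid=0.3,
            beta_age=0.0,
            beta_sex=0.0,
            center_effects=(0.0,),
        )
        sim = CohortSimulator(cfg)
        fam = sim.family_ids
        sib_pairs = []
        ped = sim.pedigree
        ids = sim.ids
        for f, sl in sim.kinship.family_slices().items():
            kids = [k for k in range(sl.start, sl.stop) if not ped[ids[k]].is_founder()]
            if len(kids) >= 2:
                sib_pairs.append((kids[0], kids[1]))
        sib_pairs = np.array(sib_pairs)
        xs, ys = [], []
        for r in range(40):
            lp = np.log(sim.replicate(r)["tg_post"].to_numpy())
            xs.append(lp[sib_pairs[:, 0]])
            ys.append(lp[sib_pairs[:, 1]])
        r_obs = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
        expected = 0.5 * cfg.sigma_family**2 / (cfg.sigma_family**2 + cfg.sigma_resid**2)
        n_pairs = sib_pairs.shape[0] * 40
        assert abs(r_obs - expected) < 3.0 / math.sqrt(n_pairs)

    def test_heritability_recovery_in_cohort(self):
        # realized variance of the causal term over replicates ~ h2 * null variance
        cfg = default_gaw20_scenario(seed=9)
        sim = CohortSimulator(cfg)
        fracs = []
        for r in range(25):
            rep = sim.replicate(r)
            g = rep["g_chr1"].to_numpy()
            m = rep["m_chr1"].to_numpy()
            term = sim.beta_causal["chr1"] * g * (1 - m)
            fracs.append(term.var(ddof=1) / cfg.null_variance())
        assert abs(np.mean(fracs) - 0.125) < 3 * np.std(fracs) / math.sqrt(len(fracs))

    def test_baseline_anchoring_excludes_treatment_effect(self):
        # pre log-TG correlates with the family effect but not with the causal term
        cfg = default_gaw20_scenario(seed=3)
        sim = CohortSimulator(cfg)
        cors = []
        for r in range(25):
            rep = sim.replicate(r)
            term = (
                sim.beta_causal["chr1"]
                * rep["g_chr1"].to_numpy()
                * (1 - rep["m_chr1"].to_numpy())
            )
            cors.append(np.corrcoef(np.log(rep["tg_pre"]), term)[0, 1])
        assert abs(np.mean(cors)) < 3 * np.std(cors) / math.sqrt(len(cors)) + 0.01
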