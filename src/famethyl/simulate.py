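"""Synthetic family cohorts with SNP-by-methylation pharmaco-response effects.

The generator emulates a family-clustered drug-response study: a pedigree of
nuclear families, SNP dosages transmitted through the pedigree, per-subject
CpG methylation proportions, and pre/post-treatment triglyceride (TG) values.
Causal SNPs act on post-treatment log-TG through the product ``b * G * (1-M)``:
the SNP effect is fully expressed when the nearby CpG is unmethylated (M=0)
and fully suppressed when it is fully methylated (M=1).  Noncausal CpGs share
a configurable fraction of their variability with the causal CpGs.

Effect sizes are calibrated so that each causal term contributes a configured
fraction ``h2`` (its expected heritability) of the null-model variance of
post-treatment log-TG.

All randomness flows from one master seed; replicate ``i`` uses the child
stream ``SeedSequence((seed, 1, i))`` so replicates are independent and a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .pedigree import FEMALE, MALE, Individual, KinshipMatrix, Pedigree, compute_kinship


class ConfigError(ValueError):
    """Invalid scenario configuration."""


class CalibrationError(ValueError):
    """Requested heritability exceeds what the causal term can contribute."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylationModel:
    """Beta(a, b) distribution for methylation proportions.

    ``uniform()`` is the special case Beta(1, 1).  Moments of (1 - M) are in
    closed form: 1 - M ~ Beta(b, a).
    """

    a: float = 2.0
    b: float = 2.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ConfigError("Beta parameters must be positive")

    @staticmethod
    def uniform() -> "MethylationModel":
        return MethylationModel(1.0, 1.0)

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def var(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))

    def mean_one_minus(self) -> float:
        return self.b / (self.a + self.b)

    def second_moment_one_minus(self) -> float:
        return self.var + self.mean_one_minus() ** 2

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        return rng.beta(self.a, self.b, size=size)


@dataclass(frozen=True)
class SiteSpec:
    """One SNP-CpG pair.

    ``partner`` names the causal site whose CpG variability a noncausal CpG
    shares; causal sites carry the target heritability ``h2``.
    """

    site_id: str
    causal: bool
    maf: float = 0.3
    h2: float | None = None
    partner: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ConfigError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.causal:
            if self.h2 is None or not (0.0 <= self.h2 < 1.0):
                raise ConfigError(f"causal site {self.site_id} needs h2 in [0, 1)")
        elif self.h2 is not None:
            raise ConfigError(f"noncausal site {self.site_id} must not carry h2")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one simulation scenario.

    Variance components are on the log-TG scale.  ``baseline_anchor`` scales
    how strongly pretreatment log-TG tracks the expected (treatment-free)
    posttreatment mean; the causal pharmaco-response term never leaks into
    the baseline.
    """

    n_families: int = 164
    family_size_mean: float = 680.0 / 164.0
    sites: tuple[SiteSpec, ...] = ()
    methylation: MethylationModel = field(default_factory=MethylationModel)
    cpg_shared_var_frac: float = 0.5
    sigma_family: float = 0.3
    sigma_resid: float = 0.45
    sigma_pre: float = 0.35
    baseline_anchor: float = 0.6
    mu_post: float = 4.94
    mu_pre: float = 5.05
    beta_age: float = 0.004
    beta_sex: float = -0.12
    center_effects: tuple[float, ...] = (0.0, 0.05, -0.05)
    age_mean: float = 49.0
    age_sd: float = 16.0
    random_family_sizes: bool = False
    n_replicates: int = 200
    seed: int = 20180917

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ConfigError("need at least 2 families")
        if self.family_size_mean < 3:
            raise ConfigError("nuclear families need mean size >= 3")
        if not (0.0 <= self.cpg_shared_var_frac < 1.0):
            raise ConfigError("cpg_shared_var_frac must be in [0, 1)")
        if self.sigma_resid <= 0 or self.sigma_family < 0 or self.sigma_pre < 0:
            raise ConfigError("invalid variance components")
        total_h2 = sum(s.h2 for s in self.sites if s.causal)
        if total_h2 >= 1.0:
            raise ConfigError("total causal heritability must be < 1")

    # -- analytic variance bookkeeping ------------------------------------

    def covariate_variance(self) -> float:
        """Variance of the fixed covariate contribution to post log-TG."""
        ce = np.asarray(self.center_effects, dtype=float)
        var_center = float(np.mean(ce**2) - np.mean(ce) ** 2)
        return (
            self.beta_age**2 * self.age_sd**2
            + self.beta_sex**2 * 0.25
            + var_center
        )

    def null_variance(self) -> float:
        """Marginal variance of post log-TG with all causal effects removed.

        The family (polygenic) component contributes sigma_family^2 times the
        mean diagonal of 2*Phi, which is exactly 1 for non-inbred pedigrees.
        """
        return self.sigma_family**2 + self.sigma_resid**2 + self.covariate_variance()

    def causal_sites(self) -> list[SiteSpec]:
        return [s for s in self.sites if s.causal]

    def noncausal_sites(self) -> list[SiteSpec]:
        return [s for s in self.sites if not s.causal]

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_families",
                "family_size_mean",
                "cpg_shared_var_frac",
                "sigma_family",
                "sigma_resid",
                "sigma_pre",
                "baseline_anchor",
                "mu_post",
                "mu_pre",
                "beta_age",
                "beta_sex",
                "age_mean",
                "age_sd",
                "random_family_sizes",
                "n_replicates",
                "seed",
            )
        }
        d["center_effects"] = list(self.center_effects)
        d["methylation"] = {"a": self.methylation.a, "b": self.methylation.b}
        d["sites"] = [
            {
                "site_id": s.site_id,
                "causal": s.causal,
                "maf": s.maf,
                "h2": s.h2,
                "partner": s.partner,
            }
            for s in self.sites
        ]
        return d

    @staticmethod
    def from_dict(d: dict) -> "ScenarioConfig":
        d = dict(d)
        meth = d.pop("methylation", {"a": 2.0, "b": 2.0})
        sites = tuple(SiteSpec(**s) for s in d.pop("sites", []))
        d["center_effects"] = tuple(d.get("center_effects", (0.0, 0.05, -0.05)))
        return ScenarioConfig(
            sites=sites, methylation=MethylationModel(**meth), **d
        )

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "ScenarioConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return ScenarioConfig.from_dict(yaml.safe_load(fh))


def default_gaw20_scenario(seed: int = 20180917, n_replicates: int = 200) -> ScenarioConfig:
    """The default study conditions: 164 families, 680 subjects, 10 SNP-CpG pairs.

    Five causal pairs with expected heritabilities 0.125, 0.10, 0.075, 0.05,
    0.025 (site ids name the chromosome analogs) and five noncausal pairs
    whose CpGs share half their variability with the causal CpGs.
    """
    causal = [
        SiteSpec("chr1", True, h2=0.125),
        SiteSpec("chr8", True, h2=0.10),
        SiteSpec("chr6", True, h2=0.075),
        SiteSpec("chr17", True, h2=0.05),
        SiteSpec("chr10", True, h2=0.025),
    ]
    noncausal = [
        SiteSpec(f"null{k+1}", False, partner=causal[k].site_id) for k in range(5)
    ]
    return ScenarioConfig(
        sites=tuple(causal + noncausal), seed=seed, n_replicates=n_replicates
    )


# ---------------------------------------------------------------------------
# pedigree construction
# ---------------------------------------------------------------------------


def build_pedigree(cfg: ScenarioConfig, rng: np.random.Generator) -> Pedigree:
    """Nuclear-family pedigree matching the configured cohort shape.

    With ``random_family_sizes`` off (default) offspring counts are allocated
    deterministically so the total equals round(n_families * family_size_mean)
    exactly; otherwise counts are truncated-Poisson draws with the same mean.
    Offspring sexes are random.
    """
    n_fam = cfg.n_families
    total = int(round(n_fam * cfg.family_size_mean))
    n_offspring = total - 2 * n_fam
    if n_offspring < n_fam:
        raise ConfigError("family_size_mean too small for >=1 offspring each")
    if cfg.random_family_sizes:
        lam = n_offspring / n_fam - 1.0
        counts = 1 + rng.poisson(max(lam, 0.0), size=n_fam)
    else:
        base, extra = divmod(n_offspring, n_fam)
        counts = np.full(n_fam, base, dtype=int)
        counts[:extra] += 1
    individuals: list[Individual] = []
    for f in range(n_fam):
        fid = f"F{f+1:03d}"
        dad, mom = f"{fid}_1", f"{fid}_2"
        individuals.append(Individual(dad, fid, sex=MALE))
        individuals.append(Individual(mom, fid, sex=FEMALE))
        for k in range(counts[f]):
            sex = MALE if rng.random() < 0.5 else FEMALE
            individuals.append(
                Individual(f"{fid}_{k+3}", fid, father=dad, mother=mom, sex=sex)
            )
    return Pedigree(individuals)


# ---------------------------------------------------------------------------
# genotypes, methylation, effect calibration
# ---------------------------------------------------------------------------


def _generation_levels(ped: Pedigree) -> list[list[Individual]]:
    """Partition members into levels with all parents in earlier levels."""
    level: dict[str, int] = {}
    out: list[list[Individual]] = []
    for ind in ped.topological_order():
        if ind.is_founder():
            lv = 0
        else:
            lv = 1 + max(level[ind.father], level[ind.mother])
        level[ind.iid] = lv
        while len(out) <= lv:
            out.append([])
        out[lv].append(ind)
    return out


def simulate_genotypes(
    ped: Pedigree,
    maf: float | np.ndarray,
    rng: np.random.Generator,
    ids: list[str] | None = None,
) -> np.ndarray:
    """Dosages (n, n_sites), founders Binomial(2, maf), offspring Mendelian.

    Each offspring receives one allele from each parent; given a parent's
    dosage d the transmitted allele is the minor allele with probability d/2,
    which is Mendelian transmission with exchangeable parental alleles.
    """
    maf_arr = np.atleast_1d(np.asarray(maf, dtype=float))
    if np.any((maf_arr <= 0) | (maf_arr > 0.5)):
        raise ConfigError("maf must be in (0, 0.5]")
    n_sites = maf_arr.shape[0]
    dosage: dict[str, np.ndarray] = {}
    for members in _generation_levels(ped):
        founders = [ind for ind in members if ind.is_founder()]
        if founders:
            draws = rng.binomial(2, maf_arr, size=(len(founders), n_sites))
            for ind, d in zip(founders, draws):
                dosage[ind.iid] = d.astype(float)
        nonf = [ind for ind in members if not ind.is_founder()]
        if nonf:
            dpat = np.stack([dosage[ind.father] for ind in nonf])
            dmat = np.stack([dosage[ind.mother] for ind in nonf])
            u = rng.random((len(nonf), n_sites, 2))
            pat_allele = (u[..., 0] < dpat / 2.0).astype(float)
            mat_allele = (u[..., 1] < dmat / 2.0).astype(float)
            for ind, row in zip(nonf, pat_allele + mat_allele):
                dosage[ind.iid] = row
    order = ids if ids is not None else [ind.iid for ind in ped.individuals]
    return np.stack([dosage[iid] for iid in order])


def simulate_methylation(
    cfg: ScenarioConfig,
    n_subjects: int,
    rng: np.random.Generator,
    return_latent: bool = False,
):
    """Methylation proportions (n, n_sites) in the order of ``cfg.sites``.

    Causal CpGs are i.i.d. draws from the configured Beta model.  Each
    noncausal CpG mixes the standardized signal of its partner causal CpG
    (variance fraction f = ``cpg_shared_var_frac``) with independent Gaussian
    noise, then maps back to the methylation scale and clamps to [0, 1].
    """
    f = cfg.cpg_shared_var_frac
    model = cfg.methylation
    m = np.empty((n_subjects, len(cfg.sites)))
    latent = np.empty_like(m)
    causal_cols = {s.site_id: j for j, s in enumerate(cfg.sites) if s.causal}
    sd = math.sqrt(model.var)
    for j, site in enumerate(cfg.sites):
        if site.causal:
            m[:, j] = model.sample(rng, n_subjects)
            latent[:, j] = (m[:, j] - model.mean) / sd
    for j, site in enumerate(cfg.sites):
        if site.causal:
            continue
        if site.partner is not None:
            if site.partner not in causal_cols:
                raise ConfigError(
                    f"site {site.site_id} partner {site.partner!r} is not a causal site"
                )
            z = latent[:, causal_cols[site.partner]]
        else:
            z = rng.standard_normal(n_subjects)
        eps = rng.standard_normal(n_subjects)
        latent[:, j] = math.sqrt(f) * z + math.sqrt(1.0 - f) * eps
        m[:, j] = np.clip(model.mean + sd * latent[:, j], 0.0, 1.0)
    if return_latent:
        return m, latent
    return m


def calibrate_effect(
    h2: float,
    var_total: float,
    meth: MethylationModel,
    maf: float,
) -> float:
    """Effect size b with Var(b * G * (1-M)) = h2 * var_total.

    G ~ Binomial(2, maf) in the founder population and M is independent of G,
    so Var(G(1-M)) = E[G^2] E[(1-M)^2] - E[G]^2 E[1-M]^2 in closed form.
    """
    if var_total <= 0:
        raise CalibrationError("var_total must be positive")
    if h2 < 0 or h2 >= 1:
        raise CalibrationError("h2 must be in [0, 1)")
    if not (0.0 < maf <= 0.5):
        raise ConfigError("maf must be in (0, 0.5]")
    eg = 2.0 * maf
    eg2 = 2.0 * maf * (1.0 - maf) + eg**2
    w1 = meth.mean_one_minus()
    w2 = meth.second_moment_one_minus()
    denom = eg2 * w2 - (eg * w1) ** 2
    if denom <= 0:
        raise CalibrationError("degenerate genotype/methylation distribution")
    target = h2 * var_total
    if target / denom > 1e6:
        raise CalibrationError("requested heritability not attainable")
    return math.sqrt(target / denom)


# ---------------------------------------------------------------------------
# replicate generation
# ---------------------------------------------------------------------------


class CohortSimulator:
    """Generates replicates for one scenario with shared pedigree and kinship.

    The pedigree, kinship matrix, covariates (age, sex, center) and the
    calibrated causal effect sizes are fixed across replicates, mirroring a
    study where phenotypes are re-simulated on a fixed cohort; genotypes and
    methylation are redrawn per replicate.
    """

    def __init__(self, cfg: ScenarioConfig, pedigree: Pedigree | None = None):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
        self.pedigree = pedigree if pedigree is not None else build_pedigree(cfg, rng)
        self.kinship: KinshipMatrix = compute_kinship(self.pedigree)
        self.ids = self.kinship.ids
        self.family_ids = np.asarray(self.kinship.family_ids)
        self.n = len(self.ids)
        # block-wise Cholesky of the relationship matrix 2*Phi
        rel = self.kinship.relationship()
        self._chol = np.zeros_like(rel)
        for sl in self.kinship.family_slices().values():
            self._chol[sl, sl] = np.linalg.cholesky(rel[sl, sl])
        # fixed subject covariates
        self.age = np.clip(
            cfg.age_mean + cfg.age_sd * rng.standard_normal(self.n), 18.0, 95.0
        )
        self.sex = np.array(
            [1.0 if self.pedigree[iid].sex == FEMALE else 0.0 for iid in self.ids]
        )
        self.center = rng.integers(0, len(cfg.center_effects), size=self.n)
        self._cov_term = (
            cfg.beta_age * (self.age - cfg.age_mean)
            + cfg.beta_sex * self.sex
            + np.asarray(cfg.center_effects)[self.center]
        )
        var_null = cfg.null_variance()
        self.beta_causal = {
            s.site_id: calibrate_effect(s.h2, var_null, cfg.methylation, s.maf)
            for s in cfg.causal_sites()
        }
        self._maf = np.array([s.maf for s in cfg.sites])

    def replicate_rng(self, index: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.cfg.seed, 1, index)))

    def replicate(self, index: int) -> pd.DataFrame:
        """Tidy per-subject table for replicate ``index`` (0-based)."""
        cfg = self.cfg
        rng = self.replicate_rng(index)
        g = simulate_genotypes(self.pedigree, self._maf, rng, ids=self.ids)
        m = simulate_methylation(cfg, self.n, rng)
        fam_effect = cfg.sigma_family * (self._chol @ rng.standard_normal(self.n))
        causal_term = np.zeros(self.n)
        for j, site in enumerate(cfg.sites):
            if site.causal:
                b = self.beta_causal[site.site_id]
                causal_term += b * g[:, j] * (1.0 - m[:, j])
        log_post = (
            cfg.mu_post
            + self._cov_term
            + causal_term
            + fam_effect
            + cfg.sigma_resid * rng.standard_normal(self.n)
        )
        log_pre = (
            cfg.mu_pre
            + cfg.baseline_anchor * (self._cov_term + fam_effect)
            + cfg.sigma_pre * rng.standard_normal(self.n)
        )
        data = {
            "family": self.family_ids,
            "subject": self.ids,
            "age": self.age,
            "sex": self.sex.astype(int),
            "center": self.center,
            "tg_pre": np.exp(log_pre),
            "tg_post": np.exp(log_post),
        }
        for j, site in enumerate(cfg.sites):
            data[f"g_{site.site_id}"] = g[:, j]
        for j, site in enumerate(cfg.sites):
            data[f"m_{site.site_id}"] = m[:, j]
        return pd.DataFrame(data)


def simulate_replicate(
    cfg: ScenarioConfig, ped: Pedigree | None = None, index: int = 0
) -> pd.DataFrame:
    """One-shot convenience wrapper around :class:`CohortSimulator`."""
    return CohortSimulator(cfg, pedigree=ped).replicate(index)
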