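"""Per-site interaction scans and empirical power / Type I error summaries.

For every replicate and SNP-CpG site, two outcome settings are assembled on
the log-TG scale:

* ``PrePost`` -- posttreatment log-TG as the outcome with pretreatment
  log-TG appended to the covariates (baseline-adjusted analysis);
* ``Change`` -- the post-minus-pre log-TG difference as the outcome.

The design holds an intercept, the standardized SNP dosage, the standardized
CpG methylation, their product (the interaction under test), age, sex and
study-center indicators.  Five model variants are scanned: the kinship LME
(model-based covariance), GEE with the robust sandwich, GEE with the
Mancl-DeRouen correction (GEE-BC), QIF with the plain GMM covariance, and
QIF with the leverage-corrected covariance (QIF-BC).  The BC variants share
their parent's coefficient estimates and differ only in the Wald covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gee as gee_mod
from . import lme as lme_mod
from . import qif as qif_mod
from .simulate import CohortSimulator, ScenarioConfig

logger = logging.getLogger(__name__)

GENOME_WIDE_CPGS = 461281

ESTIMATORS = ("LME", "GEE", "GEE-BC", "QIF", "QIF-BC")
SETTINGS = ("PrePost", "Change")


@dataclass(frozen=True)
class ModelSpec:
    estimator: str
    setting: str

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")


ALL_MODELS = tuple(ModelSpec(e, s) for e in ESTIMATORS for s in SETTINGS)


class ZeroVarianceSite(ValueError):
    """SNP or CpG has no variance in this replicate; the site is skipped."""


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    families: np.ndarray
    interaction_index: int


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    return alpha / n_tests


def _standardize(x: np.ndarray, label: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceSite(f"{label} has zero variance in this replicate")
    return (x - x.mean()) / sd


def build_design(replicate: pd.DataFrame, site_id: str, setting: str) -> Design:
    """Assemble (y, X) for one site and outcome setting.

    TG values are log transformed; SNP and CpG are standardized within the
    replicate (sample SD).  ``PrePost`` appends log pretreatment TG as a
    covariate; ``Change`` uses the log-scale difference as the outcome.
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}")
    g = _standardize(replicate[f"g_{site_id}"].to_numpy(float), f"SNP {site_id}")
    m = _standardize(replicate[f"m_{site_id}"].to_numpy(float), f"CpG {site_id}")
    log_pre = np.log(replicate["tg_pre"].to_numpy(float))
    log_post = np.log(replicate["tg_post"].to_numpy(float))
    age = replicate["age"].to_numpy(float)
    sex = replicate["sex"].to_numpy(float)
    center = replicate["center"].to_numpy(int)
    n = len(replicate)
    cols = [np.ones(n), g, m, g * m, age, sex]
    names = ["intercept", "snp", "cpg", "snp:cpg", "age", "sex"]
    for level in sorted(set(center))[1:]:
        cols.append((center == level).astype(float))
        names.append(f"center_{level}")
    if setting == "PrePost":
        y = log_post
        cols.append(log_pre)
        names.append("log_tg_pre")
    else:
        y = log_post - log_pre
    X = np.column_stack(cols)
    return Design(
        y=y,
        X=X,
        columns=names,
        families=replicate["family"].to_numpy(),
        interaction_index=names.index("snp:cpg"),
    )


def _wald_p(beta_j: float, var_jj: float) -> tuple[float, float]:
    se = math.sqrt(var_jj)
    if se == 0:
        return se, 1.0 if beta_j == 0 else 0.0
    from scipy.stats import norm

    return se, float(2.0 * norm.sf(abs(beta_j / se)))


def run_scan(
    cfg: ScenarioConfig,
    models=ALL_MODELS,
    n_replicates: int | None = None,
    simulator: CohortSimulator | None = None,
) -> pd.DataFrame:
    """Fit every requested model variant across replicates and sites.

    Returns a tidy frame with one row per replicate x site x model variant:
    ``replicate, site, causal, h2, estimator, setting, beta, se, p,
    converged``.  Non-converged fits keep their row but carry ``p = NaN`` so
    power denominators can exclude them.  The kinship eigendecomposition and
    each base fit (GEE, QIF) are shared by their bias-corrected variant.
    """
    models = tuple(models)
    sim = simulator if simulator is not None else CohortSimulator(cfg)
    n_rep = cfg.n_replicates if n_replicates is None else n_replicates
    need = {(m.estimator, m.setting) for m in models}
    settings = sorted({m.setting for m in models})
    need_lme = any(m.estimator == "LME" for m in models)
    need_gee = any(m.estimator.startswith("GEE") for m in models)
    need_qif = any(m.estimator.startswith("QIF") for m in models)
    spectrum = (
        lme_mod.relationship_spectrum(sim.kinship.relationship()) if need_lme else None
    )
    site_info = {s.site_id: s for s in cfg.sites}
    rows: list[tuple] = []

    def emit(rep, site, estimator, setting, beta_j, var_jj, converged):
        if (estimator, setting) not in need:
            return
        se, p = _wald_p(beta_j, var_jj)
        if not converged:
            p = np.nan
        spec = site_info[site]
        rows.append(
            (rep, site, spec.causal, spec.h2, estimator, setting, beta_j, se, p, converged)
        )

    for rep in range(n_rep):
        replicate = sim.replicate(rep)
        for setting in settings:
            for site in site_info:
                try:
                    des = build_design(replicate, site, setting)
                except ZeroVarianceSite as exc:
                    logger.warning("replicate %d: %s", rep, exc)
                    continue
                j = des.interaction_index
                if need_lme:
                    fit = lme_mod.fit_lme_kinship(
                        des.y, des.X, sim.kinship, spectrum=spectrum
                    )
                    emit(rep, site, "LME", setting, fit.beta[j],
                         fit.cov_beta[j, j], fit.converged)
                if need_gee or need_qif:
                    design = gee_mod.ClusteredDesign.from_long(
                        des.y, des.X, des.families
                    )
                if need_gee:
                    gfit = gee_mod.fit_gee(design, structure="exchangeable")
                    emit(rep, site, "GEE", setting, gfit.beta[j],
                         gfit.cov_robust[j, j], gfit.converged)
                    emit(rep, site, "GEE-BC", setting, gfit.beta[j],
                         gfit.cov_bc[j, j], gfit.converged)
                if need_qif:
                    qfit = qif_mod.fit_qif(design)
                    emit(rep, site, "QIF", setting, qfit.beta[j],
                         qfit.cov_plain[j, j], qfit.converged)
                    emit(rep, site, "QIF-BC", setting, qfit.beta[j],
                         qfit.cov_bc[j, j], qfit.converged)
    return pd.DataFrame(
        rows,
        columns=[
            "replicate", "site", "causal", "h2", "estimator", "setting",
            "beta", "se", "p", "converged",
        ],
    )


def summarize_power(
    results: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Empirical power per causal site and pooled Type I error per threshold.

    Power(site) = #{p < t} / #valid replicates at that site; the Type I
    error pools all noncausal sites and replicates.  Output is one row per
    (estimator, setting, threshold label) with per-site power columns, the
    pooled Type I error, and their denominators.
    """
    if thresholds is None:
        thresholds = {
            "nominal": 0.05,
            "genomewide": bonferroni_threshold(0.05, GENOME_WIDE_CPGS),
        }
    valid = results.dropna(subset=["p"])
    causal_sites = [
        s for s in valid.loc[valid["causal"], "site"].unique()
    ]
    out_rows = []
    for (estimator, setting), sub in valid.groupby(["estimator", "setting"], sort=False):
        for label, thr in thresholds.items():
            row: dict = {
                "estimator": estimator,
                "setting": setting,
                "threshold": label,
                "alpha": thr,
            }
            for site in causal_sites:
                ps = sub.loc[sub["site"] == site, "p"]
                row[f"power_{site}"] = float((ps < thr).mean()) if len(ps) else np.nan
                row[f"n_{site}"] = int(len(ps))
            null_ps = sub.loc[~sub["causal"], "p"]
            row["type1_error"] = (
                float((null_ps < thr).mean()) if len(null_ps) else np.nan
            )
            row["n_type1"] = int(len(null_ps))
            out_rows.append(row)
    return pd.DataFrame(out_rows)
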