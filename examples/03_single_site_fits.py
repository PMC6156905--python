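"""Fit all five model variants to one SNP-CpG site of one replicate.

The interaction of interest is the product of the standardized SNP dosage
and the standardized CpG methylation; a negative coefficient means the SNP
effect on the drug response weakens as methylation increases.  The five
variants share the same mean model and differ in how they treat the family
correlation and in the covariance behind the Wald test: kinship LME
(model-based), GEE exchangeable (robust sandwich vs Mancl-DeRouen
bias-corrected), and QIF (plain GMM vs small-sample corrected).
"""

import numpy as np

from famethyl import (
    ClusteredDesign,
    CohortSimulator,
    default_gaw20_scenario,
    fit_gee,
    fit_lme_kinship,
    fit_qif,
    relationship_spectrum,
    wald_fixed_effect,
)
from famethyl.lme import WaldTest
from famethyl.scan import build_design

cfg = default_gaw20_scenario(seed=42)
sim = CohortSimulator(cfg)
rep = sim.replicate(0)
des = build_design(rep, "chr1", "PrePost")
j = des.interaction_index
print(f"design: n={len(des.y)}, p={des.X.shape[1]}, columns={des.columns}")

spectrum = relationship_spectrum(sim.kinship.relationship())
lme = fit_lme_kinship(des.y, des.X, sim.kinship, spectrum=spectrum)
design = ClusteredDesign.from_long(des.y, des.X, des.families)
gee = fit_gee(design, structure="exchangeable")
qif = fit_qif(design)


def report(name, beta, var):
    se = np.sqrt(var)
    z = beta / se
    from scipy.stats import norm
    print(f"  {name:<8} beta={beta:+.4f}  se={se:.4f}  p={2*norm.sf(abs(z)):.2e}")


print("interaction (snp x cpg) Wald tests:")
report("LME", lme.beta[j], lme.cov_beta[j, j])
report("GEE", gee.beta[j], gee.cov_robust[j, j])
report("GEE-BC", gee.beta[j], gee.cov_bc[j, j])
report("QIF", qif.beta[j], qif.cov_plain[j, j])
report("QIF-BC", qif.beta[j], qif.cov_bc[j, j])
print(f"LME variance components: sigma_g^2={lme.sigma2_g:.3f} "
      f"sigma_e^2={lme.sigma2_e:.3f}")
print(f"GEE working correlation alpha={gee.alpha:.3f}, QIF Q={qif.q_stat:.1f}")
w: WaldTest = wald_fixed_effect(lme, j)
print(f"true effect direction is negative (methylation suppresses the SNP); "
      f"LME z={w.z:.2f}")
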