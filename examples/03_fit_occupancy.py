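"""Fit a single-season occupancy model to a simulated survey and predict
district-wide occupancy.

Naive occupancy undercounts true occupancy because detection is imperfect;
the model separates psi (occupancy) from p (per-interview detection).
"""

import pastocc as po
from scipy.special import expit

cfg = po.SimConfig(
    seed=7,
    beta_psi={"(Intercept)": 0.2, "one": 0.8},   # occupancy rises with ONE area
    alpha_p={"(Intercept)": -0.6, "experience": 0.5},
)
landscape = po.simulate_landscape(cfg)
records, truth = po.simulate_survey(cfg, landscape)
m = po.build_detection_matrix(po.prepare_records(records), cfg.species)
cov = po.align_covariates(landscape[1], m)

print(f"{m.n_sites} sites, naive occupancy {po.naive_occupancy(m):.2f} "
      f"(truth: {truth.z.mean():.2f} occupied)")

fit = po.fit_occupancy(
    m, cov, po.ModelSpec(psi_covariates=("one",), p_covariates=("experience",)),
    seed=0,
)
print(f"\nconverged={fit.converged}, logL={fit.log_likelihood:.2f}, K={fit.K}")
print(fit.summary().round(3).to_string(index=False))
print(f"\npsi at average ONE area: {expit(fit.beta_psi['(Intercept)']):.2f} "
      f"(generating value {expit(0.2):.2f})")

# District-wide prediction with delta-method SEs, including unsampled cells.
pred = po.predict_psi(fit, cov.site)
print(f"district mean predicted psi: {pred['psi'].mean():.2f} "
      f"(mean SE {pred['se'].mean():.2f}) over {len(pred)} cells")
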