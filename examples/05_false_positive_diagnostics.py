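"""Why the production path collapses to binary data: the three-state
false-positive model is poorly identified when uncertain detections are rare.

The model lets unoccupied sites emit uncertain detections at rate p10 while
certain detections are error-free.  With p10 near zero the likelihood is
flat in p10 and the MLE sits at the boundary with a huge standard error —
the diagnostic that motivates discarding uncertain records instead.
"""

import pandas as pd

import pastocc as po

# sparse-uncertainty regime: almost every detection is certain
cfg = po.SimConfig(seed=10, false_positive=0.001, certainty=0.97, failed_rate=0.0)
records, truth = po.simulate_survey(cfg)
m = po.build_detection_matrix(po.prepare_records(records), cfg.species)
cov = po.Covariates(site=pd.DataFrame(index=m.site_ids))

print(f"uncertain records in data: {int((m.states == 1).sum())} "
      f"(true FPs: {truth.n_false_positive})")

fit = po.fit_false_positive(m, cov, seed=0)
print(f"\npsi={fit.psi_hat:.3f}  p11={fit.p11_hat:.3f}  "
      f"p10={fit.p10_hat:.5f}  b={fit.b_hat:.3f}")
print(f"boundary flags: {fit.boundary_flags}")
print(f"flat profile: {fit.profile_flat}  (Hessian condition {fit.hessian_cond:.2e})")

# contrast: a regime with plenty of certain/uncertain contrast is estimable
cfg2 = po.SimConfig(seed=12, false_positive=0.10, certainty=0.7,
                    n_grids=900, n_sampled=800, failed_rate=0.0,
                    replicate_probs={4: 1.0})
records2, _ = po.simulate_survey(cfg2)
m2 = po.build_detection_matrix(po.prepare_records(records2), cfg2.species)
fit2 = po.fit_false_positive(m2, po.Covariates(site=pd.DataFrame(index=m2.site_ids)),
                             seed=0)
print(f"\nwith abundant contrast (true p10=0.10, b=0.70): "
      f"p10={fit2.p10_hat:.3f} (SE {fit2.se_p10:.3f}), b={fit2.b_hat:.3f}, "
      f"flat profile: {fit2.profile_flat}")
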