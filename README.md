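# pastocc

Occupancy modelling for large mammals from **key-informant interview
surveys** in agro-pastoral landscapes.

When camera traps or sign surveys are infeasible across a large human-use
landscape, experienced pastoralists can act as survey instruments: each
interview about a 5 × 5 km grid cell is one replicate "visit". `pastocc`
turns such interviews into detection histories and fits single-season
site-occupancy models to them, for ecologists estimating the distribution
of species such as striped hyena, sloth bear, blackbuck, Indian gray wolf
and leopard across district-scale grids.

## The model

For site *i* with occupancy probability Ψᵢ and replicate *j* with detection
probability pᵢⱼ (both logit-linear in standardized covariates), the
single-season likelihood of a binary history *y*ᵢ is

    Lᵢ = Ψᵢ ∏ⱼ pᵢⱼ^yᵢⱼ (1 − pᵢⱼ)^(1−yᵢⱼ)            if any yᵢⱼ = 1
    Lᵢ = Ψᵢ ∏ⱼ (1 − pᵢⱼ) + (1 − Ψᵢ)                   otherwise

with missing replicates skipped (sites have 1–7 interviews). Interview
responses are first classified by an identification flowchart into states
0 (non-detection), 1 (uncertain) and 2 (certain); because certain
detections carry essentially zero false-positive risk, the production path
collapses states to binary (1 iff state 2). A three-state false-positive
model (Ψ, p₁₁, p₁₀, b) is provided as a diagnostic; with rare uncertain
detections its false-positive rate is boundary-trapped with flat profiles,
which is exactly why the collapse is used.

Model selection is two-step (detection structure first, then occupancy),
with overdispersion ĉ from a MacKenzie–Bailey parametric bootstrap,
ranking by QAICc

    QAICc = −2 logL/ĉ + 2K + 2K(K+1)/(n−K−1),   K = #parameters + 1, n = #sites,

retention at ΔQAICc ≤ 2, and model-averaged occupancy surfaces over the
whole district grid (weights renormalized; cells more than ¾ covered by
waterbodies excluded). Covariate pairs with |Pearson r| ≥ 0.6 never enter
the same model.

A synthetic-data module generates landscapes and interview surveys with
the full protocol (subgrid coverage and merging of paired interviews,
certainty misclassification, rare false positives, failed identifications)
plus a complete truth log, so every stage is testable against ground truth.

## Worked example

```python
import pastocc as po
from pastocc.selection import model_average

cfg = po.SimConfig(seed=19,
                   beta_psi={"(Intercept)": 0.1, "one": 0.7},
                   alpha_p={"(Intercept)": -0.5, "experience": 0.5})
landscape = po.simulate_landscape(cfg)
records, truth = po.simulate_survey(cfg, landscape)
m = po.build_detection_matrix(po.prepare_records(records), cfg.species)
cov = po.align_covariates(landscape[1], m)

res = po.two_step_select(m, cov,
                         p_menu=("experience", "grid_covered"),
                         psi_menu=("one", "road", "kharif"),
                         B=100, seed=3)
surf = model_average(res.psi_ladder, cov.site,
                     water_fraction=landscape[0].set_index("grid_id")["water_fraction"])
print(res.best_p_spec, round(surf.district_mean, 2), round(truth.psi.mean(), 2))
```

prints

```
('experience',) 0.49 0.52
```

— the two-step search recovers the generating detection covariate
(respondent experience), and the model-averaged district mean occupancy
(0.49) sits close to the generator's true mean (0.52); the gap is ordinary
estimation error at 119 sampled sites. `examples/` contains one short
script per capability (classification and merging, covariate engineering,
fitting, selection and averaging, false-positive diagnostics, the
file-based pipeline), and `pastocc simulate | run | recover` expose the
pipeline on the command line.

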