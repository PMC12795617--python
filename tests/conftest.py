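import logging

import numpy as np
import pandas as pd
import pytest

import pastocc as po

logging.getLogger("pastocc").setLevel(logging.ERROR)


def make_matrix(states, species="hyena", site_ids=None, det_covs=None):
    """Tiny detection matrix straight from a state array."""
    states = np.asarray(states, dtype=float)
    if site_ids is None:
        site_ids = [f"S{i}" for i in range(states.shape[0])]
    return po.DetectionMatrix(
        species=species,
        site_ids=site_ids,
        states=states,
        detection_covariates=det_covs or {},
    )


def null_covariates(m, **site_cols):
    """Covariates container for intercept-only (or simple) specs."""
    site = pd.DataFrame(site_cols, index=m.site_ids)
    return po.Covariates(site=site)


@pytest.fixture(scope="session")
def default_survey():
    """One simulated survey at the default study scale, with truth log."""
    cfg = po.SimConfig(seed=42)
    landscape = po.simulate_landscape(cfg)
    records, truth = po.simulate_survey(cfg, landscape)
    prepared = po.prepare_records(records)
    m = po.build_detection_matrix(prepared, cfg.species)
    cov = po.align_covariates(landscape[1], m)
    return {
        "cfg": cfg,
        "landscape": landscape,
        "records": records,
        "truth": truth,
        "matrix": m,
        "cov": cov,
    }
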