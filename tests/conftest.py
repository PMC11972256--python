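import numpy as np
import pandas as pd
import pytest
from scipy import special

import vizlit as vz
from vizlit.glmm import GlmmSpec, fit_logistic_glmm, lrt


@pytest.fixture(scope="session")
def bank():
    return vz.combined_bank()


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete synthetic cohort with scored error matrix."""
    cfg = vz.SyntheticConfig(n_participants=80, seed=42, incomplete_rate=0.0)
    responses, demographics, truth = vz.generate_dataset(cfg)
    b = vz.combined_bank()
    recs = [
        vz.ResponseRecord(r.participant_id, r.item_id, r.response)
        for r in responses.itertuples(index=False)
    ]
    matrix = vz.build_error_matrix(b, recs)
    return {
        "bank": b,
        "responses": responses,
        "records": recs,
        "demographics": demographics,
        "truth": truth,
        "matrix": matrix,
    }


@pytest.fixture(scope="session")
def null_lrt_pvalues():
    """LRT p-values from 500 replicates simulated under the null.

    Data: 40 participants x 12 items, random intercepts with sd 1, no effect
    of the binary item-level predictor.  Each replicate compares the
    intercept-only model against the model adding the null predictor.
    Shared by the type-I-error and p-value-uniformity checks.
    """
    n_p, m = 40, 12
    pid = np.repeat(np.arange(n_p), m)
    x = np.tile((np.arange(m) < m // 2).astype(str), n_p)
    pvals = np.empty(500)
    for rep in range(500):
        rng = np.random.default_rng(20_000 + rep)
        u = rng.normal(0.0, 1.0, n_p)
        y = (rng.random(n_p * m) < special.expit(-0.3 + u[pid])).astype(float)
        tab = pd.DataFrame({"participant": pid, "correct": y, "x": x})
        null_fit = fit_logistic_glmm(tab, GlmmSpec(()))
        alt_fit = fit_logistic_glmm(tab, GlmmSpec(("x",)))
        pvals[rep] = lrt(null_fit, alt_fit).p
    return pvals
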