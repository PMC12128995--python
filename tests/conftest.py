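"""Shared fixtures: a small synthetic cohort pushed through the full pipeline.

Session-scoped so the classifier training and injury-space fit run once and
are reused by the io/scoring/model/survival tests.
"""

import numpy as np
import pandas as pd
import pytest

import txinjury as tx


def small_config(n_biopsies=400, seed=7, **kw):
    """Cheap cohort config: 5-member gene sets, ~100 probes."""
    sizes = {name: 5 for name in tx.simulate.INPUT_PBT_SETS + tx.simulate.NEW_GENE_SETS}
    kw.setdefault("gene_set_sizes", sizes)
    kw.setdefault("n_probesets", 100)
    return tx.CohortConfig(n_biopsies=n_biopsies, seed=seed, **kw)


@pytest.fixture(scope="session")
def cohort():
    """400-biopsy cohort with full-size (30/20-member) gene sets."""
    cfg = tx.CohortConfig(n_biopsies=400, n_probesets=500, seed=7)
    expr, meta, sets, truth = tx.generate_cohort(cfg)
    return cfg, expr, meta, sets, truth


@pytest.fixture(scope="session")
def classifier_probs(cohort):
    _, expr, meta, _, _ = cohort
    probs, results = tx.classifiers.classifier_probabilities(
        expr, meta, n_folds=5, seed=1
    )
    return probs, results


@pytest.fixture(scope="session")
def table(cohort, classifier_probs):
    _, expr, _, sets, _ = cohort
    probs, _ = classifier_probs
    return tx.score_table(expr, sets, probs)


@pytest.fixture(scope="session")
def results(table):
    return tx.InjuryModel(table).fit(seed=3, n_restarts=4)


@pytest.fixture()
def toy_expr():
    """2-gene matrix with two controls whose per-gene means are {3, 5}."""
    values = pd.DataFrame(
        {
            "C1": [2.0, 4.0],
            "C2": [4.0, 6.0],
            "S1": [4.0, 7.0],
            "S2": [3.0, 5.0],
        },
        index=["g1", "g2"],
    )
    return tx.ExpressionMatrix(values, control_ids=["C1", "C2"])


def toy_meta(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "kidney_id": [f"K{i}" for i in range(n)],
        "txbx_days": np.full(n, 100.0),
        "egfr": np.full(n, 50.0),
        "donor_age": np.full(n, 40.0),
        "proteinuria_pos": np.zeros(n, dtype=int),
        "ci_score": np.zeros(n, dtype=int),
        "ct_score": np.zeros(n, dtype=int),
        "pct_cortex": np.full(n, 50.0),
        "followup_days": np.full(n, 1000.0),
        "graft_failed": np.zeros(n, dtype=int),
        "died_with_function": np.zeros(n, dtype=int),
    }
    base.update(cols)
    return tx.SampleMetadata(
        pd.DataFrame(base, index=pd.Index([f"B{i}" for i in range(n)], name="sample_id"))
    )
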