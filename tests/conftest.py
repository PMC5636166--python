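import warnings

import numpy as np
import pandas as pd
import pytest

from cssmap.design import build_design_matrix
from cssmap.expression import (
    estimate_surrogates,
    filter_genes,
    fit_expression_models,
)
from cssmap.simulate import (
    ExprSimConfig,
    PhenoSimConfig,
    simulate_counts,
    simulate_phenotypes,
)


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*degenerate bootstrap.*")
        yield


@pytest.fixture(scope="session")
def tiny_pheno():
    """Small two-by-two panel with one planted main effect and one planted
    antagonistic (cancelling) interaction on glucose."""
    cfg = PhenoSimConfig(
        maternal_panel=("3", "6"),
        paternal_panel=("4", "5"),
        exclusions=(),
        cell_sizes=(20, 15, 15),
        main_effects={"glucose_mg_dl": {"F": {"5": 35.0}, "M": {"5": 30.0}}},
        interaction_effects={
            "glucose_mg_dl": {
                "F": {("6", "5"): -35.0},
                "M": {("6", "5"): -30.0},
            }
        },
        outlier_rate=0.0,
        seed=11,
    )
    table, truth = simulate_phenotypes(cfg)
    return table, truth, cfg


@pytest.fixture(scope="session")
def expr_fitted():
    """A simulated expression dataset (with batch factors and planted
    effects) carried through QC-free filtering, surrogate estimation and
    model fitting once per session."""
    cfg = ExprSimConfig(n_genes=500, seed=21, interaction_prob=0.06,
                        cis_prob=0.2)
    ds, truth = simulate_counts(cfg)
    ds = filter_genes(ds)
    sv = estimate_surrogates(ds, build_design_matrix(ds.samples), k=5)
    fits = fit_expression_models(ds, covariates=sv)
    return ds, truth, fits
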