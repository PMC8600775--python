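"""Shared fixtures: small synthetic panels and fitted-model pipelines.

Everything is generated at test time from seeded generators; the
expensive fits (the 4-component mixture on a trimodal panel) are
session-scoped so several tests can share one estimation run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from qlqmap.aldvmm import AldvmmSpec, FitOptions, fit, predict_mean
from qlqmap.data import (COMPARATOR_COVARIATES, COMPONENT_COVARIATES,
                         MEMBERSHIP_COVARIATES, build_design_matrices,
                         filter_complete_cases)
from qlqmap.linear import fit_linear_re, predict_linear
from qlqmap.synthetic import SyntheticConfig, make_dataset


@pytest.fixture(scope="session")
def small_panel():
    """Complete-case utility panel of ~120 patients from the shipped truth."""
    data, truth = make_dataset(SyntheticConfig(seed=5, n_patients=120))
    data, _ = filter_complete_cases(data)
    return data, truth


@pytest.fixture(scope="session")
def trimodal_fits():
    """Linear comparator and 4-component mixture fitted to one trimodal
    panel (~2400 observations); shared by the severity-bias and
    diagnostic tests."""
    data, truth = make_dataset(SyntheticConfig(seed=77, n_patients=400))
    data, _ = filter_complete_cases(data)
    designs = build_design_matrices(data.frame)
    y = data.frame["eq5d"].to_numpy()
    X = designs["component"].to_numpy()
    Z = designs["membership"].to_numpy()
    spec = AldvmmSpec(4, tuple(COMPONENT_COVARIATES),
                      tuple(MEMBERSHIP_COVARIATES))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params, report = fit(y, X, Z, spec, groups=data.frame["patient_id"],
                             options=FitOptions(n_restarts=3, seed=1))
        lin_frame = designs["comparator"].copy()
        lin_frame["eq5d"] = y
        lin_frame["patient_id"] = data.frame["patient_id"].to_numpy()
        lin_params, lin_report = fit_linear_re(lin_frame,
                                               COMPARATOR_COVARIATES)
    return {
        "data": data,
        "truth": truth,
        "designs": designs,
        "y": y,
        "global_health": data.frame["global_health"].to_numpy(),
        "spec": spec,
        "params": params,
        "report": report,
        "pred_aldvmm": predict_mean(params, X, Z, spec),
        "lin_params": lin_params,
        "lin_report": lin_report,
        "pred_linear": predict_linear(lin_params, designs["comparator"]),
    }
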