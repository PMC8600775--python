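"""Synthetic-data generator: determinism, marginals and calibration."""

import numpy as np
import pandas as pd
import pytest

from qlqmap.data import (RESPONSE_COLUMNS, SCALE_COLUMNS, MappingDataset,
                         filter_complete_cases)
from qlqmap.synthetic import (SyntheticConfig, default_aldvmm_truth,
                              default_probit_truth, generate_covariates,
                              generate_responses_latent,
                              generate_utilities_aldvmm, inject_missingness,
                              make_dataset, TABLE_STATS)
from qlqmap.tariff import GAP_LOWER, validate_utilities


def _cluster_se(values, patient_id):
    """SE of the mean under patient-level clustering."""
    frame = pd.DataFrame({"v": values, "p": patient_id})
    cluster_sums = frame.groupby("p")["v"].sum()
    cluster_n = frame.groupby("p")["v"].size()
    n = len(frame)
    mean = frame["v"].mean()
    resid = cluster_sums - mean * cluster_n
    return float(np.sqrt((resid**2).sum()) / n)


def test_generation_is_deterministic():
    c = SyntheticConfig(seed=4, n_patients=60)
    a, ta = make_dataset(c)
    b, tb = make_dataset(c)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    np.testing.assert_array_equal(ta["aldvmm_params"].pack(),
                                  tb["aldvmm_params"].pack())


def test_scores_within_range_and_marginals_near_targets():
    frame = generate_covariates(SyntheticConfig(seed=0))
    for col in SCALE_COLUMNS:
        vals = frame[col]
        assert vals.min() >= 0.0 and vals.max() <= 100.0
        target_mean, target_sd = TABLE_STATS[col]
        se = _cluster_se(vals, frame["patient_id"])
        assert abs(vals.mean() - target_mean) < 3 * se, col
        assert abs(vals.std() - target_sd) < 0.1 * target_sd, col
    assert frame["age"].mean() == pytest.approx(54.0, abs=1.5)
    # age constant within patient
    assert (frame.groupby("patient_id")["age"].nunique() == 1).all()


def test_functional_scales_positively_symptoms_negatively_correlated():
    frame = generate_covariates(SyntheticConfig(seed=1))
    gh = frame["global_health"]
    assert frame["physical_f"].corr(gh) > 0.2
    assert frame["fatigue"].corr(gh) < -0.2


def test_infeasible_scale_targets_rejected():
    stats = dict(TABLE_STATS)
    stats["global_health"] = (2.0, 80.0)  # mass would be mostly off-range
    with pytest.raises(ValueError, match="infeasible"):
        generate_covariates(SyntheticConfig(seed=0, n_patients=30,
                                            scale_stats=stats))


def test_utilities_respect_gap_and_match_shape_anchors():
    frame = generate_covariates(SyntheticConfig(seed=2, n_patients=300))
    y = generate_utilities_aldvmm(frame, seed=3)
    validate_utilities(y)
    assert ((y > GAP_LOWER) & (y < 1.0)).sum() == 0
    assert 0.1 < (y == 1.0).mean() < 0.35
    assert 0.6 < y.mean() < 0.8


def test_default_truth_membership_structure():
    """Average shares are non-degenerate and the full-health-mass /
    poor-health components load onto the right ends of the global
    health scale (the final pooled-moment calibration step trades the
    published per-component shares for exact pooled anchors)."""
    spec, params = default_aldvmm_truth()
    from qlqmap.aldvmm import component_membership
    from qlqmap.data import build_design_matrices

    frame = generate_covariates(SyntheticConfig(seed=6))
    designs = build_design_matrices(frame)
    Z = designs["membership"].to_numpy()
    pi = component_membership(Z, params.gamma)
    shares = pi.mean(axis=0)
    assert shares.sum() == pytest.approx(1.0)
    assert (shares > 0.05).all() and (shares < 0.55).all()
    gh = frame["global_health"].to_numpy()
    top, bottom = gh >= 85, gh <= 25
    # component 2 carries the mass at full health, component 3 the sick tail
    assert pi[top, 1].mean() > 3 * pi[bottom, 1].mean()
    assert pi[bottom, 2].mean() > 3 * pi[top, 2].mean()


def test_responses_levels_and_sparse_level3_rates():
    frame = generate_covariates(SyntheticConfig(seed=7))
    responses = generate_responses_latent(frame, seed=8)
    levels = responses[RESPONSE_COLUMNS]
    assert levels.isin([1, 2, 3]).all().all()
    n = len(levels)
    se = np.sqrt(0.01 * 0.99 / n)
    for dim in ("mobility", "self_care"):
        rate = (levels[dim] == 3).mean()
        assert abs(rate - 0.01) < 3 * se + 0.004, dim
    validate_utilities(responses["eq5d"])


def test_missingness_rate_zero_is_identity_and_one_warns():
    frame = generate_covariates(SyntheticConfig(seed=9, n_patients=40))
    frame["eq5d"] = 0.5
    pd.testing.assert_frame_equal(inject_missingness(frame, 0.0, seed=1),
                                  frame)
    with pytest.warns(UserWarning):
        masked = inject_missingness(frame, 1.0, seed=1)
    with pytest.warns(UserWarning, match="every row"):
        data, report = filter_complete_cases(
            MappingDataset(masked, has_utility=True))
    assert report.n_kept == 0


def test_truth_record_travels_with_dataset():
    data, truth = make_dataset(SyntheticConfig(seed=10, n_patients=50))
    assert truth["mode"] == "aldvmm_truth"
    assert truth["aldvmm_params"].n_components == 4
    data2, truth2 = make_dataset(
        SyntheticConfig(seed=10, n_patients=50, mode="dimension_latent"))
    assert "probit_system" in truth2
    assert data2.has_responses


def test_probit_truth_cutpoints_ordered():
    system = default_probit_truth()
    for dim in system.dims.values():
        assert dim.cut1 < dim.cut2
    assert np.linalg.eigvalsh(system.corr).min() > 0
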