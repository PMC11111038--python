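"""Lagged design, multilevel VAR estimation and node features."""

import numpy as np
import pandas as pd
import pytest

from affectgcn import (
    CohortSpec,
    FixedEffects,
    build_lagged_design,
    compute_node_features,
    fit_multilevel_var,
    generate_cohort,
    subject_networks,
)
from affectgcn.items import FEELINGS

from conftest import constant_panel, make_panel


def test_lagged_rows_count_complete_patient():
    panel = make_panel(constant_panel("p1", 4))
    design = build_lagged_design(panel)
    # 10 beeps -> 9 within-day pairs, days 1-5 only
    assert design.row_counts()["p1"] == 9 * 5
    assert not (design.frame["day"] > 5).any()


def test_missing_beep_removes_both_adjacent_pairs():
    rows = constant_panel("p1", 4)
    rows = [
        (pid, d, b, *([None] * 6 if (d, b) == (2, 5) else vals))
        for (pid, d, b, *vals) in rows
    ]
    design = build_lagged_design(make_panel(rows))
    assert design.row_counts()["p1"] == 45 - 2  # pairs (4,5) and (5,6) of day 2 gone


def test_no_pair_spans_day_boundary():
    panel = make_panel(constant_panel("p1", 4))
    design = build_lagged_design(panel, days=(1, 5))
    counts = design.frame.groupby("day").size()
    assert (counts == 9).all()  # never 10: beep 10 -> next-day beep 1 is not a pair


def test_sparse_patient_excluded_with_warning(caplog):
    rows = constant_panel("p1", 4) + [("p2", 1, b, *[4] * 6) for b in (1, 2, 3)]
    with caplog.at_level("WARNING"):
        design = build_lagged_design(make_panel(rows), min_rows=8)
    assert design.excluded == ["p2"]
    assert "p2" in caplog.text


def _heterogeneous_panel(n=12, seed=13):
    spec = CohortSpec(
        n_patients=n, random_slope_sd=0.05, prone_fraction=0.0,
        day6_negative_shift=0.0, seed=seed,
    )
    return spec, generate_cohort(spec)


def test_constant_predictor_raises_naming_design():
    _, panel = _heterogeneous_panel(6)
    panel = panel.copy()
    panel["cheerful"] = 4  # constant across all rows -> collinear with intercept
    design = build_lagged_design(panel)
    with pytest.raises(ValueError, match="ill-conditioned|cheerful"):
        fit_multilevel_var(design)


def test_two_identical_patients_have_matching_blups():
    _, panel = _heterogeneous_panel(2, seed=21)
    twin = panel[panel["patient_id"] == "p001"].copy()
    twin["patient_id"] = "p002"
    doubled = pd.concat([panel[panel["patient_id"] == "p001"], twin], ignore_index=True)
    design = build_lagged_design(doubled)
    _, deviations = fit_multilevel_var(design)
    # identical data -> identical predicted deviations, and (being mean-zero
    # across 2 identical subjects) essentially none
    assert np.allclose(deviations["p001"], deviations["p002"], atol=1e-8)
    assert np.max(np.abs(deviations["p001"])) < 0.05


def test_subject_networks_identity_and_validation():
    fixed = FixedEffects(coef=np.full((6, 6), 0.1), intercepts=np.zeros(6))
    devs = {"a": np.zeros((6, 6)), "b": np.zeros((6, 6))}
    nets = subject_networks(fixed, devs)
    assert len(nets) == 2
    for net in nets:
        assert net.matrix.shape == (6, 6)
        np.testing.assert_array_equal(net.matrix, fixed.coef)
    with pytest.raises(ValueError, match="6x6"):
        subject_networks(fixed, {"a": np.zeros((3, 3))})


@pytest.fixture(scope="module")
def fitted_cohort(small_cohort):
    """One mixed-model fit of the 20-patient cohort, shared by the checks below."""
    spec, panel = small_cohort
    design = build_lagged_design(panel)
    fixed, deviations = fit_multilevel_var(design)
    return spec, design, fixed, deviations


def test_fixed_effects_near_generating_matrix(fitted_cohort):
    spec, _, fixed, _ = fitted_cohort
    assert np.max(np.abs(fixed.coef - spec.fixed_matrix)) < 0.12


def test_blup_deviations_average_out(fitted_cohort):
    # BLUP shrinkage keeps subject deviations near mean-zero, so the
    # average subject network recovers the fixed effects
    _, _, fixed, deviations = fitted_cohort
    nets = subject_networks(fixed, deviations)
    mean_net = np.mean([n.matrix for n in nets], axis=0)
    assert np.max(np.abs(mean_net - fixed.coef)) < 0.02


def test_estimation_is_deterministic():
    _, panel = _heterogeneous_panel(6, seed=41)
    design = build_lagged_design(panel)
    fixed, deviations = fit_multilevel_var(design)
    fixed2, deviations2 = fit_multilevel_var(build_lagged_design(panel))
    np.testing.assert_array_equal(fixed.coef, fixed2.coef)
    for pid in deviations:
        np.testing.assert_array_equal(deviations[pid], deviations2[pid])


def test_relabeling_feelings_permutes_networks():
    _, panel = _heterogeneous_panel(10, seed=31)
    perm = [2, 0, 1, 5, 3, 4]  # permute within polarity blocks
    renamed = panel.copy()
    renamed[[FEELINGS[j] for j in perm]] = panel[list(FEELINGS)].astype("Int64").to_numpy(dtype=float)
    fixed_a, dev_a = fit_multilevel_var(build_lagged_design(panel))
    fixed_b, dev_b = fit_multilevel_var(build_lagged_design(renamed))
    # equivariance is exact at the REML optimum, but refits after relabeling
    # can settle in nearby optima (variance components are weakly identified
    # at this size), so: fixed effects to 0.05 — enough to flag any
    # orientation/indexing bug, which displaces entries by the coefficient
    # scale — and the BLUP deviations via their permutation structure
    # (misplaced entries would destroy the correlation)
    p = np.asarray(perm)
    np.testing.assert_allclose(fixed_b.coef[np.ix_(p, p)], fixed_a.coef, atol=0.05)
    a = np.concatenate([dev_a[pid].ravel() for pid in dev_a])
    b = np.concatenate([dev_b[pid][np.ix_(p, p)].ravel() for pid in dev_a])
    assert np.corrcoef(a, b)[0, 1] > 0.9


def test_node_features_arithmetic_and_modes():
    rows = constant_panel("p1", 4)
    # overwrite angry ratings of day 1, beeps 1-3 with 1,2,3; remove the rest of day 1
    rows = [r for r in rows if not (r[1] == 1 and r[2] > 3)]
    rows = [
        (pid, d, b, (b if d == 1 else vals[0]), *vals[1:])
        for (pid, d, b, *vals) in rows
    ]
    feats = compute_node_features(make_panel(rows), days=(1, 1))
    assert feats["p1"][0] == pytest.approx(2.0)  # mean of 1,2,3

    const = make_panel(constant_panel("p2", 4))
    np.testing.assert_array_equal(compute_node_features(const)["p2"], np.full(6, 4.0))
    np.testing.assert_array_equal(
        compute_node_features(const, negative_only=True)["p2"],
        np.array([4.0, 4.0, 4.0, 0.0, 0.0, 0.0]),
    )


def test_node_features_error_when_feeling_unobserved():
    rows = [("p1", d, b, None, *[4] * 5) for d in range(1, 6) for b in range(1, 11)]
    with pytest.raises(ValueError, match="p1.*angry|angry.*p1"):
        compute_node_features(make_panel(rows))
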