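"""Adjacency normalization and the GCN graph classifier."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from affectgcn import AugmentConfig, GCNGraphClassifier, GraphSample, augment_samples
from affectgcn.gcn import normalize_adjacency
from affectgcn.samples import pack_samples


def separable_toy(n=40, seed=0):
    """Class determined by the sign of every edge weight."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        label = int(i % 2)
        sign = 1.0 if label else -1.0
        a = sign * 0.3 * np.ones((6, 6)) + rng.normal(0, 0.02, (6, 6))
        samples.append(GraphSample(f"t{i}", 0, a, rng.uniform(2, 6, 6), label))
    return samples


# --------------------------------------------------------------------- normalization


def test_zero_adjacency_normalizes_to_identity():
    for mode in ("signed_rownorm", "abs_rownorm", "sym_norm"):
        np.testing.assert_array_equal(normalize_adjacency(np.zeros((6, 6)), mode), np.eye(6))


def test_signed_rownorm_rows_have_unit_absolute_sum(rng):
    a = rng.normal(0, 0.5, (6, 6))
    out = normalize_adjacency(a, "signed_rownorm")
    np.testing.assert_allclose(np.abs(out).sum(axis=1), np.ones(6))
    # signs of A + I survive
    assert np.all(np.sign(out) == np.sign(a + np.eye(6)))


def test_sym_norm_preserves_symmetry(rng):
    a = np.abs(rng.normal(0, 0.5, (6, 6)))
    a = (a + a.T) / 2
    out = normalize_adjacency(a, "sym_norm")
    np.testing.assert_allclose(out, out.T)


def test_normalization_input_validation(rng):
    with pytest.raises(ValueError, match="mode"):
        normalize_adjacency(np.zeros((6, 6)), "spectral")
    bad = np.zeros((6, 6))
    bad[1, 2] = np.nan
    with pytest.raises(ValueError, match="finite"):
        normalize_adjacency(bad)


# --------------------------------------------------------------------- classifier


def test_outputs_are_probabilities_and_order_invariant(rng):
    samples = separable_toy(20)
    X, y, _ = pack_samples(samples)
    clf = GCNGraphClassifier(epochs=5, random_state=0).fit(X, y)
    proba = clf.predict_proba(X)
    assert np.all((proba > 0) & (proba < 1))
    np.testing.assert_allclose(proba.sum(axis=1), np.ones(len(X)))
    perm = rng.permutation(len(X))
    np.testing.assert_array_equal(clf.predict(X)[perm], clf.predict(X[perm]))


def test_zeroed_model_outputs_one_half_and_ties_go_to_zero():
    X, y, _ = pack_samples(separable_toy(10))
    clf = GCNGraphClassifier(epochs=1, random_state=0).fit(X, y)
    for w in clf.coefs_:
        w[:] = 0.0
    for b in clf.intercepts_:
        b[:] = 0.0
    clf.readout_coef_[:] = 0.0
    clf.readout_intercept_ = 0.0
    proba = clf.predict_proba(X)[:, 1]
    np.testing.assert_array_equal(proba, np.full(len(X), 0.5))
    assert np.all(clf.predict(X) == 0)  # p == 0.5 is not "greater than"


def test_node_permutation_leaves_graph_output_unchanged(rng):
    samples = separable_toy(12)
    X, y, _ = pack_samples(samples)
    clf = GCNGraphClassifier(epochs=10, random_state=1).fit(X, y)
    p = rng.permutation(6)
    for s in samples[:5]:
        permuted = GraphSample(s.patient_id, 0, s.matrix[np.ix_(p, p)], s.features[p], s.label)
        orig = clf.predict_proba(s.flat()[None, :])[0, 1]
        perm = clf.predict_proba(permuted.flat()[None, :])[0, 1]
        assert orig == pytest.approx(perm, abs=1e-12)


def test_learns_linearly_separable_toy_graphs():
    samples = separable_toy(40)
    X, y, _ = pack_samples(samples)
    # oracle: the mean edge weight alone separates the classes perfectly
    mean_edge = X[:, :36].mean(axis=1, keepdims=True)
    assert LogisticRegression().fit(mean_edge, y).score(mean_edge, y) == 1.0
    clf = GCNGraphClassifier(epochs=200, random_state=0).fit(X, y)
    assert np.mean(clf.predict(X) == y) == 1.0
    assert np.all(np.isfinite(clf.loss_trace_)) and len(clf.loss_trace_) == 200
    assert clf.loss_trace_[-1] < clf.loss_trace_[0]


def test_training_is_reproducible_given_seed():
    X, y, _ = pack_samples(separable_toy(30, seed=4))
    a = GCNGraphClassifier(epochs=30, random_state=5).fit(X, y)
    b = GCNGraphClassifier(epochs=30, random_state=5).fit(X, y)
    np.testing.assert_array_equal(a.loss_trace_, b.loss_trace_)
    np.testing.assert_array_equal(a.predict(X), b.predict(X))
    for wa, wb in zip(a.coefs_, b.coefs_):
        np.testing.assert_array_equal(wa, wb)


def test_predictions_stable_under_one_percent_perturbation():
    # the premise of edge augmentation: 1% jitter rarely flips a prediction
    samples = separable_toy(40)
    X, y, _ = pack_samples(samples)
    clf = GCNGraphClassifier(epochs=200, random_state=0).fit(X, y)
    pool = augment_samples(samples, AugmentConfig(factor=20, bound=0.01, seed=9))
    Xp, _, groups = pack_samples(pool)
    pred = dict(zip([f"{g}:{s.replicate}" for g, s in zip(groups, pool)], clf.predict(Xp)))
    agree = np.mean(
        [pred[f"{s.patient_id}:{s.replicate}"] == pred[f"{s.patient_id}:0"] for s in pool]
    )
    assert agree >= 0.95


def test_config_validation_and_single_class_warning():
    X, y, _ = pack_samples(separable_toy(10))
    with pytest.raises(ValueError, match="epochs"):
        GCNGraphClassifier(epochs=0).fit(X, y)
    with pytest.raises(ValueError, match="learning_rate"):
        GCNGraphClassifier(learning_rate=0.0).fit(X, y)
    with pytest.raises(ValueError, match="binary"):
        GCNGraphClassifier(epochs=1).fit(X, np.arange(len(X)))
    with pytest.warns(UserWarning, match="single class"):
        GCNGraphClassifier(epochs=1).fit(X, np.zeros(len(X), dtype=int))
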