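"""SPIB reaction-coordinate learning: labels, training, projection, transfer."""

import warnings

import numpy as np
import pytest

import mlmetad as m
from mlmetad.spib import SPIB
from mlmetad.trajectory import Trajectory


def _traj(cvs, names):
    cvs = np.asarray(cvs, dtype=float)
    return Trajectory(times=np.arange(cvs.shape[0]) * 1.0, cv_matrix=cvs,
                      cv_names=names)


# ---------------------------------------------------------------- labels

def test_labels_all_on_one_side_is_degenerate():
    tr = _traj(np.full((10, 1), -1.0), ["x"])
    lab = m.initial_labels(tr, [("x", ">", 0.0)])
    assert lab.degenerate and lab.vocabulary == [0]


def test_labels_partition_exactly_by_predicate():
    tr = _traj(np.array([[-1.0], [2.0], [-0.5], [3.0]]), ["x"])
    lab = m.initial_labels(tr, [("x", ">", 0.0)])
    assert lab.labels.tolist() == [0, 1, 0, 1]
    assert lab.vocabulary == [0, 1]


def test_labels_ignore_unused_distractor_cv():
    base = _traj(np.array([[-1.0], [2.0]]), ["x"])
    extra = _traj(np.array([[-1.0, 9.0], [2.0, -9.0]]), ["x", "junk"])
    r1 = m.initial_labels(base, [("x", ">", 0.0)])
    r2 = m.initial_labels(extra, [("x", ">", 0.0)])
    assert np.array_equal(r1.labels, r2.labels)


def test_labels_missing_cv_raises():
    tr = _traj(np.zeros((5, 1)), ["x"])
    with pytest.raises(KeyError):
        m.initial_labels(tr, [("y", "<", 1.0)])


# ---------------------------------------------------------------- training

def test_training_is_deterministic(two_state):
    _, traj, labels = two_state
    kw = dict(lag=10, latent_dim=2, epochs=10, random_state=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = SPIB(**kw).fit(traj.cv_matrix, labels.labels)
        b = SPIB(**kw).fit(traj.cv_matrix, labels.labels)
    assert np.array_equal(a.encoder_weights_, b.encoder_weights_)
    assert np.array_equal(a.decoder_params_["U2"], b.decoder_params_["U2"])


def test_informative_cv_dominates(two_state):
    _, traj, labels = two_state
    cfg = m.SPIBConfig(lag=10, latent_dim=2, epochs=30, seed=0)
    model = m.train_spib([traj], [labels], cfg)
    names = traj.cv_names
    imp = dict(zip(names, model.weight_importance_))
    assert imp["d_exit"] >= 0.8
    assert model.converged_


def test_duplicated_cv_shares_the_weight(two_state):
    """Duplicating a CV column: the pair's combined (summed) weight matches
    the single column's weight of a same-seed reference training."""
    _, traj, labels = two_state
    X = traj.cv_matrix
    Xd = np.column_stack([X, X[:, 0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = SPIB(lag=10, epochs=30, random_state=0).fit(X, labels.labels)
        dup = SPIB(lag=10, epochs=30, random_state=0).fit(Xd, labels.labels)
    w_ref = np.linalg.norm(ref.encoder_weights_[:, 0])
    w_dup = np.linalg.norm(dup.encoder_weights_[:, 0]
                           + dup.encoder_weights_[:, -1])
    assert w_dup == pytest.approx(w_ref, rel=0.25)


def test_refinement_never_increases_states_and_is_fixed_point(two_state):
    _, traj, labels = two_state
    cfg = m.SPIBConfig(lag=10, epochs=30, seed=1)
    model = m.train_spib([traj], [labels], cfg)
    assert model.n_states_ <= len(labels.vocabulary)
    # converged labels are a fixed point of the relabeling map
    assert model.converged_
    repredicted = model.predict(traj.cv_matrix)
    frac_changed = np.mean(repredicted != model.classes_[model.labels_.labels])
    assert frac_changed < cfg.refine_tol


def test_single_class_labels_raise(two_state):
    _, traj, _ = two_state
    y = np.zeros(traj.n_frames, dtype=int)
    with pytest.raises(ValueError, match="two label classes"):
        SPIB(lag=10).fit(traj.cv_matrix, y)


def test_lag_longer_than_trajectory_raises():
    X = np.random.default_rng(0).normal(size=(20, 2))
    y = (X[:, 0] > 0).astype(int)
    with pytest.raises(ValueError, match="lag"):
        SPIB(lag=50).fit(X, y)


# ---------------------------------------------------------------- projection

def _manual_model(weights, mean, std, names):
    model = SPIB()
    model.encoder_weights_ = np.asarray(weights, dtype=float)
    model.encoder_bias_ = np.zeros(model.encoder_weights_.shape[0])
    model.noise_logvar_ = np.zeros(model.encoder_weights_.shape[0])
    model.input_mean_ = np.asarray(mean, dtype=float)
    model.input_std_ = np.asarray(std, dtype=float)
    model.cv_names_ = names
    model.decoder_params_ = {"U1": np.zeros((model.encoder_weights_.shape[0], 2)),
                             "c1": np.zeros(2), "U2": np.zeros((2, 2)),
                             "c2": np.zeros(2)}
    model.classes_ = np.array([0, 1])
    return model


def test_projection_identity_weights():
    model = _manual_model([[1.0, 0.0, 0.0]], [0, 0, 0], [1, 1, 1],
                          ["a", "b", "c"])
    rng = np.random.default_rng(2)
    tr = _traj(rng.normal(size=(30, 3)), ["a", "b", "c"])
    rc = m.project_rc(model, tr)
    assert np.allclose(rc[:, 0], tr.cv("a"))


def test_projection_deterministic_and_null_weight_invariant():
    model = _manual_model([[1.0, 0.0]], [0, 0], [1, 1], ["a", "b"])
    rng = np.random.default_rng(3)
    cvs = rng.normal(size=(40, 2))
    t1 = _traj(cvs, ["a", "b"])
    t2 = _traj(np.column_stack([cvs[:, 0], rng.permutation(cvs[:, 1])]),
               ["a", "b"])
    assert np.array_equal(m.project_rc(model, t1), m.project_rc(model, t1))
    # permuting the zero-weight CV leaves the RC unchanged
    assert np.array_equal(m.project_rc(model, t1), m.project_rc(model, t2))


def test_projection_missing_cv_raises():
    model = _manual_model([[1.0]], [0], [1], ["a"])
    tr = _traj(np.zeros((5, 1)), ["z"])
    with pytest.raises(KeyError, match="a"):
        m.project_rc(model, tr)


# ---------------------------------------------------------------- statistics

def test_rc_statistics_arithmetic():
    rc = np.array([0.0, 2.0, 0.0, 2.0])
    mask = np.ones(4, dtype=bool)
    st = m.rc_statistics(rc, mask)
    assert st.mean[0] == pytest.approx(1.0)
    assert st.std[0] == pytest.approx(1.0)  # population std
    assert st.sigma[0] == pytest.approx(0.25)
    st2 = m.rc_statistics(2 * rc, mask)
    assert st2.sigma[0] == pytest.approx(2 * st.sigma[0])


def test_rc_statistics_flags_constant_rc():
    st = m.rc_statistics(np.ones(10), np.ones(10, dtype=bool))
    assert st.degenerate


def test_rc_statistics_empty_mask_raises():
    with pytest.raises(ValueError, match="no frames"):
        m.rc_statistics(np.ones(10), np.zeros(10, dtype=bool))


# ---------------------------------------------------------------- transfer

def test_model_save_load_round_trip(two_state, tmp_path):
    _, traj, labels = two_state
    cfg = m.SPIBConfig(lag=10, epochs=20, seed=0)
    model = m.train_spib([traj], [labels], cfg)
    path = tmp_path / "model.json"
    m.save_model(model, path)
    back = m.load_model(path)
    assert back.cv_names_ == model.cv_names_
    assert np.allclose(back.transform(traj.cv_matrix),
                       model.transform(traj.cv_matrix))


def test_bias_variables_require_matching_roster(trained_funnel):
    sys, _, _, model, _ = trained_funnel
    wrong = list(reversed(sys.cv_defs))
    with pytest.raises(ValueError, match="does not match"):
        model.bias_variables(wrong, sys.surface.dim)


def test_compiled_bias_variables_equal_projection(trained_funnel):
    """The per-system linear compilation of the RC reproduces transform()."""
    sys, traj1, _, model, _ = trained_funnel
    bvars = model.bias_variables(sys.cv_defs, sys.surface.dim)
    rc_direct = m.project_rc(model, traj1)
    rc_compiled = np.column_stack([bv.value(traj1.positions) for bv in bvars])
    assert np.allclose(rc_direct, rc_compiled, atol=1e-10)
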