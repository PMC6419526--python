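import numpy as np
import pandas as pd
import pytest

from salmon.coxnet import (
    BranchSpec,
    SalmonArchitecture,
    SalmonModel,
    TrainConfig,
    architecture_for_bundle,
    count_trainable_weights,
    initialize_model,
    neg_log_partial_likelihood,
    objective,
    partial_likelihood_gradient,
    sigmoid,
    train,
)
from salmon.evaluate import concordance_index

from conftest import make_bundle, make_survival


# -- sigmoid -----------------------------------------------------------------

def test_sigmoid_zero():
    assert sigmoid(0.0) == pytest.approx(0.5)


def test_sigmoid_symmetry():
    for x in (-3.2, 0.7, 12.0):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-15)


def test_sigmoid_large_argument_no_overflow():
    # high-precision reference: 1/(1+e^-50) = 1 - e^-50/(1+e^-50)
    import mpmath

    ref = float(1 / (1 + mpmath.e**-50))
    assert sigmoid(50.0) == pytest.approx(ref, abs=1e-15)
    with np.errstate(over="raise"):
        assert sigmoid(-750.0) == 0.0
        assert sigmoid(750.0) == 1.0


# -- architecture arithmetic -------------------------------------------------

def _full_arch(mrna_dim, mirna_dim):
    return SalmonArchitecture(
        [
            BranchSpec("mrna", mrna_dim, 8),
            BranchSpec("mirna", mirna_dim, 4),
            BranchSpec("burden", 2),
            BranchSpec("clinical", 3),
        ]
    )


def test_count_weights_eigengene_design():
    assert count_trainable_weights(_full_arch(57, 12), include_bias=False) == 521


def test_count_weights_raw_design():
    assert count_trainable_weights(_full_arch(13132, 530), include_bias=False) == 107193


def test_count_weights_single_branch():
    arch = SalmonArchitecture([BranchSpec("a", 1, 1)], use_bias=False)
    assert count_trainable_weights(arch, include_bias=False) == 2


def test_cox_input_dim():
    assert _full_arch(57, 12).cox_input_dim == 17


# -- forward -----------------------------------------------------------------

def _zero_model(arch):
    model = initialize_model(arch, np.random.default_rng(0))
    for name, (w, b) in model.weights.items():
        model.weights[name] = (np.zeros_like(w), None if b is None else np.zeros_like(b))
    model.beta = np.zeros_like(model.beta)
    model.beta0 = 0.0
    return model


def test_forward_zero_weights_gives_half():
    arch = SalmonArchitecture([BranchSpec("x", 3, 2)])
    model = _zero_model(arch)
    bundle = make_bundle(np.random.default_rng(1).normal(size=(5, 3)), [1] * 5, [1] * 5, name="x")
    np.testing.assert_allclose(model.predict_risk(bundle), 0.5)


def test_forward_permutation_equivariance():
    rng = np.random.default_rng(2)
    arch = SalmonArchitecture([BranchSpec("x", 3, 2)])
    model = initialize_model(arch, rng)
    x = rng.normal(size=(6, 3))
    bundle = make_bundle(x, [1] * 6, [1] * 6, name="x")
    perm = rng.permutation(6)
    risk = model.predict_risk(bundle)
    risk_perm = model.predict_risk(bundle.subset_samples(perm))
    np.testing.assert_allclose(risk_perm, risk[perm])


def test_forward_hand_evaluated_toy():
    # one branch (2 -> 1 hidden), no bias, hand-set weights
    arch = SalmonArchitecture([BranchSpec("x", 2, 1)], use_bias=False)
    model = _zero_model(arch)
    model.weights["x"] = (np.array([[0.5, -1.0]]), None)
    model.beta = np.array([2.0])
    x = np.array([[1.0, 1.0], [2.0, 0.0]])
    bundle = make_bundle(x, [1, 2], [1, 1], name="x")
    z = 1 / (1 + np.exp(-(x @ np.array([0.5, -1.0]))))
    expected = 1 / (1 + np.exp(-2.0 * z))
    np.testing.assert_allclose(model.predict_risk(bundle), expected, atol=1e-12)


def test_forward_dim_mismatch_names_branch():
    arch = SalmonArchitecture([BranchSpec("x", 4, 2)])
    model = initialize_model(arch, np.random.default_rng(0))
    bundle = make_bundle(np.zeros((3, 2)), [1] * 3, [1] * 3, name="x")
    with pytest.raises(ValueError, match="'x'"):
        model.predict_risk(bundle)


# -- partial likelihood ------------------------------------------------------

def test_nlpl_all_events_zero_predictors():
    surv = make_survival([1, 2, 3], [1, 1, 1])
    assert neg_log_partial_likelihood(np.zeros(3), surv) == pytest.approx(np.log(6))


def test_nlpl_single_event():
    surv = make_survival([1, 2], [1, 0])
    assert neg_log_partial_likelihood(np.zeros(2), surv) == pytest.approx(np.log(2))


def test_nlpl_shift_invariance():
    rng = np.random.default_rng(3)
    surv = make_survival(rng.uniform(1, 10, 12), rng.integers(0, 2, 12))
    if surv.n_events == 0:
        surv = make_survival(rng.uniform(1, 10, 12), np.ones(12, int))
    eta = rng.normal(size=12)
    a = neg_log_partial_likelihood(eta, surv)
    b = neg_log_partial_likelihood(eta + 5.7, surv)
    assert a == pytest.approx(b, abs=1e-10)


def test_nlpl_no_events_warns_zero():
    surv = make_survival([1, 2], [0, 0])
    with pytest.warns(UserWarning):
        assert neg_log_partial_likelihood(np.ones(2), surv) == 0.0


def test_nlpl_breslow_ties_against_direct_formula():
    # tied event times share the full risk set
    surv = make_survival([2, 2, 3, 5], [1, 1, 0, 1])
    eta = np.array([0.3, -0.2, 0.1, 0.5])
    s_all = np.exp(eta).sum()
    expected = -(
        (eta[0] - np.log(s_all)) + (eta[1] - np.log(s_all)) + (eta[3] - np.log(np.exp(eta[3])))
    )
    assert neg_log_partial_likelihood(eta, surv) == pytest.approx(expected, abs=1e-12)


def test_nlpl_gradient_matches_finite_differences():
    rng = np.random.default_rng(4)
    surv = make_survival([1.0, 3.0, 2.0, 5.0, 4.0], [1, 0, 1, 1, 0])
    eta = rng.normal(size=5)
    grad = partial_likelihood_gradient(eta, surv)
    eps = 1e-6
    for i in range(5):
        ep = eta.copy()
        em = eta.copy()
        ep[i] += eps
        em[i] -= eps
        fd = (
            neg_log_partial_likelihood(ep, surv) - neg_log_partial_likelihood(em, surv)
        ) / (2 * eps)
        assert abs(grad[i] - fd) < 1e-5


def test_objective_l1_zero_equals_nlpl():
    rng = np.random.default_rng(5)
    arch = SalmonArchitecture([BranchSpec("x", 2, 2)])
    model = initialize_model(arch, rng)
    model.scaler = None
    bundle = make_bundle(rng.normal(size=(6, 2)), [1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1], name="x")
    eta = model.linear_predictor(bundle)
    assert objective(model, bundle, 0.0) == pytest.approx(
        neg_log_partial_likelihood(eta, bundle.survival)
    )


def test_objective_zero_model_penalty_zero():
    arch = SalmonArchitecture([BranchSpec("x", 2, 2)])
    model = _zero_model(arch)
    assert model.l1_norm() == 0.0


def test_full_objective_gradient_matches_finite_differences():
    """Central-difference check of every analytic parameter gradient on a
    5-sample toy (l1 off to keep the objective smooth)."""
    from salmon.coxnet import _forward_backward

    rng = np.random.default_rng(6)
    arch = SalmonArchitecture([BranchSpec("x", 2, 2), BranchSpec("c", 1)])
    model = initialize_model(arch, rng)
    xs = {"x": rng.normal(size=(5, 2)), "c": rng.normal(size=(5, 1))}
    surv = make_survival([1, 2, 3, 4, 5], [1, 1, 0, 1, 1])
    _, grads = _forward_backward(model, xs, surv, 0.0)

    def loss_fn():
        outs = model._branch_outputs(xs)
        z = np.concatenate([outs[s.name] for s in arch.branches], axis=1)
        return neg_log_partial_likelihood(z @ model.beta + model.beta0, surv)

    eps = 1e-6

    def check(arr, garr):
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            up = loss_fn()
            arr[idx] = orig - eps
            down = loss_fn()
            arr[idx] = orig
            assert abs(garr[idx] - (up - down) / (2 * eps)) < 1e-5

    check(model.beta, grads["beta"])
    w, b = model.weights["x"]
    gw, gb = grads["x"]
    check(w, gw)
    check(b, gb)


# -- training ----------------------------------------------------------------

def _training_bundle(n=120, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    eta = 1.5 * x[:, 0]
    t_event = -np.log(rng.random(n)) / (0.05 * np.exp(eta))
    c = rng.uniform(0, np.quantile(t_event, 0.85), n)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    return make_bundle(x, time, event, name="mrna", feature_ids=["f1", "f2", "f3"])


def test_train_loss_trace_finite_and_decreasing():
    bundle = _training_bundle()
    arch = architecture_for_bundle(bundle, hidden={"mrna": 2})
    model, trace = train(arch, bundle, TrainConfig(epochs=40, seed=1))
    assert all(np.isfinite(trace))
    assert trace[-1] <= trace[0]


def test_train_deterministic_given_seed():
    bundle = _training_bundle()
    arch = architecture_for_bundle(bundle, hidden={"mrna": 2})
    cfg = TrainConfig(epochs=15, seed=42)
    m1, t1 = train(arch, bundle, cfg)
    m2, t2 = train(arch, bundle, cfg)
    np.testing.assert_array_equal(m1.beta, m2.beta)
    for name in m1.weights:
        np.testing.assert_array_equal(m1.weights[name][0], m2.weights[name][0])
    assert t1 == t2


def test_train_informative_eigengene_cindex():
    bundle = _training_bundle(n=400, seed=7)
    arch = architecture_for_bundle(bundle, hidden={"mrna": 2})
    model, _ = train(arch, bundle, TrainConfig(epochs=100, seed=3))
    risk = model.predict_risk(bundle)
    assert concordance_index(risk, bundle.survival) > 0.65


def test_train_requires_events():
    bundle = make_bundle(np.zeros((4, 2)), [1, 2, 3, 4], [0, 0, 0, 1], name="x")
    arch = architecture_for_bundle(bundle, hidden={})
    with pytest.raises(ValueError, match="events"):
        train(arch, bundle, TrainConfig(epochs=1))


def test_identity_degenerate_recovers_cox_coefficients():
    """With hidden layers removed and identity activation, training matches an
    independent Newton-Raphson Cox fit to within 15%."""
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(5)
    n = 1000
    x = rng.standard_normal((n, 2))
    eta = 1.2 * x[:, 0] - 0.7 * x[:, 1]
    t_event = -np.log(rng.random(n)) / (0.05 * np.exp(eta))
    c = rng.uniform(0, np.quantile(t_event, 0.9), n)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    bundle = make_bundle(x, time, event, name="cov", feature_ids=["x1", "x2"])
    arch = architecture_for_bundle(bundle, hidden={}, activation="identity", use_bias=False)
    model, _ = train(
        arch, bundle, TrainConfig(epochs=300, learning_rate=0.05, full_batch=True, seed=1)
    )
    ours = model.beta / model.scaler["cov"][1]  # back to the raw-covariate scale
    df = pd.DataFrame({"T": time, "E": event, "x1": x[:, 0], "x2": x[:, 1]})
    oracle = CoxPHFitter().fit(df, "T", "E").params_.values
    np.testing.assert_allclose(ours, oracle, rtol=0.15)


def test_monotone_in_positive_path_feature():
    bundle = _training_bundle(n=200, seed=9)
    arch = architecture_for_bundle(bundle, hidden={"mrna": 2})
    model, _ = train(arch, bundle, TrainConfig(epochs=60, seed=2))
    w, _ = model.weights["mrna"]
    # build a feature whose every path weight is positive by construction
    w = np.abs(w)
    model.weights["mrna"] = (w, model.weights["mrna"][1])
    model.beta = np.abs(model.beta)
    rng = np.random.default_rng(0)
    base = rng.normal(size=(20, 3))
    for delta in (0.1, 1.0, 3.0):
        hi = base.copy()
        hi[:, 0] += delta
        b_lo = make_bundle(base, [1] * 20, [1] * 20, name="mrna", feature_ids=["f1", "f2", "f3"])
        b_hi = make_bundle(hi, [1] * 20, [1] * 20, name="mrna", feature_ids=["f1", "f2", "f3"])
        assert np.all(model.predict_risk(b_hi) >= model.predict_risk(b_lo) - 1e-12)


def test_model_json_roundtrip():
    bundle = _training_bundle(n=60, seed=3)
    arch = architecture_for_bundle(bundle, hidden={"mrna": 2})
    model, _ = train(arch, bundle, TrainConfig(epochs=5, seed=0))
    back = SalmonModel.from_dict(model.to_dict())
    np.testing.assert_allclose(back.predict_risk(bundle), model.predict_risk(bundle))
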