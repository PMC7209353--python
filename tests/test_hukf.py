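"""Tests of the hybrid unscented Kalman filter: augmentation, sigma points,
predict/correct against closed-form linear-Gaussian oracles, and parameter
recovery on synthetic observations."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from cafswitch.hukf import (
    AugmentedModel,
    FilterEstimate,
    ParameterModel,
    UkfSettings,
    augment,
    cancer_parameter_model,
    correct,
    estimate_parameters,
    fibroblast_parameter_model,
    joint_parameter_model,
    predict,
    sigma_points,
)
from cafswitch.model_core import CANCER_SPECIES, CancerParameters
from cafswitch.synthetic import ObservationSet, sparse_estimation_set


def assert_covariance_healthy(est: FilterEstimate):
    P = est.cov
    assert np.allclose(P, P.T, atol=1e-10)
    w = np.linalg.eigvalsh(P)
    assert w.min() >= -1e-10 * max(1.0, w.max())


def _linear_model(A):
    d = A.shape[0]
    pm = ParameterModel(
        rhs=lambda t, x, p: A @ x,
        species=tuple(f"s{i}" for i in range(d)),
        defaults={},
        name="linear",
    )
    return AugmentedModel(base=pm, estimate_names=(), fixed_params={})


def _random_stable(rng, d=3):
    A = rng.normal(size=(d, d))
    shift = np.max(np.linalg.eigvals(A).real) + 0.5
    return A - shift * np.eye(d)


def _tight_settings(**kw):
    defaults = dict(propagator="adaptive", rtol=1e-12, atol=1e-14)
    defaults.update(kw)
    return UkfSettings(**defaults)


# ---------------------------------------------------------------------------
# augmentation

def test_augment_adds_zero_dynamics_parameter_coordinates(rng):
    model = cancer_parameter_model()
    aug = augment(model, ["k1"])
    assert aug.dim == 6
    for _ in range(5):
        y = rng.uniform(0, 1, 6)
        assert aug.aug_rhs(0.0, y)[5] == 0.0


def test_augmented_rhs_equals_base_rhs_with_injected_parameters(rng):
    model = cancer_parameter_model(inputs=(0.3, 0.7))
    aug = augment(model, ["k3", "k52"])
    for _ in range(50):
        x = rng.uniform(0, 2, 5)
        theta = rng.uniform(0, 1, 2)
        got = aug.aug_rhs(0.0, np.concatenate([x, theta]))
        params = dict(model.defaults, k3=theta[0], k52=theta[1])
        want = model.rhs(0.0, x, params)
        np.testing.assert_allclose(got[:5], want, rtol=1e-14)
        np.testing.assert_array_equal(got[5:], [0.0, 0.0])


def test_augment_all_cancer_parameters_gives_dim_15():
    aug = augment(cancer_parameter_model(), list(CancerParameters().to_dict()))
    assert aug.dim == 15


def test_augment_rejects_unknown_or_empty_symbols():
    with pytest.raises(KeyError, match="k99"):
        augment(cancer_parameter_model(), ["k99"])
    with pytest.raises(ValueError):
        augment(cancer_parameter_model(), [])


# ---------------------------------------------------------------------------
# sigma points

def test_sigma_points_symmetric_for_identity_covariance():
    pts, wm, wc = sigma_points(np.zeros(2), np.eye(2))
    assert pts.shape == (5, 2)
    np.testing.assert_array_equal(pts[0], [0, 0])
    np.testing.assert_allclose(pts[1:3], -pts[3:5])


def test_sigma_points_reconstruct_mean_and_covariance(rng):
    for _ in range(20):
        d = rng.integers(1, 6)
        mean = rng.normal(size=d)
        L = rng.normal(size=(d, d))
        P = L @ L.T
        pts, wm, wc = sigma_points(mean, P)
        np.testing.assert_allclose(wm @ pts, mean, atol=1e-10)
        diff = pts - wm @ pts
        np.testing.assert_allclose((wc[:, None] * diff).T @ diff, P, atol=1e-10)


def test_sigma_points_collapse_for_zero_covariance():
    mean = np.array([1.0, -2.0, 3.0])
    pts, _, _ = sigma_points(mean, np.zeros((3, 3)))
    np.testing.assert_allclose(pts, np.tile(mean, (7, 1)), atol=1e-4)


def test_sigma_points_reject_indefinite_covariance():
    P = np.diag([1.0, -1.0])
    with pytest.raises(ValueError, match="jitter"):
        sigma_points(np.zeros(2), P)


# ---------------------------------------------------------------------------
# predict

def test_predict_identity_under_zero_dynamics():
    aug = _linear_model(np.zeros((3, 3)))
    s = _tight_settings(Q=np.zeros((3, 3)))
    est = FilterEstimate(mean=np.array([1.0, 2.0, 3.0]), cov=0.5 * np.eye(3))
    out = predict(est, aug, 1.0, s)
    np.testing.assert_allclose(out.mean, est.mean, atol=1e-10)
    np.testing.assert_allclose(out.cov, est.cov, atol=1e-10)
    assert out.t == 1.0


def test_predict_matches_matrix_exponential_for_linear_dynamics(rng):
    A = _random_stable(rng, 3)
    dt = 0.7
    Q = 0.01 * np.eye(3)
    est = FilterEstimate(mean=rng.normal(size=3), cov=np.eye(3))
    out = predict(est, _linear_model(A), dt, _tight_settings(Q=Q))
    F = expm(A * dt)
    np.testing.assert_allclose(out.mean, F @ est.mean, atol=1e-8)
    np.testing.assert_allclose(out.cov, F @ est.cov @ F.T + Q, atol=1e-8)


def test_predict_leaves_parameter_means_unchanged(rng):
    aug = augment(cancer_parameter_model(), ["k3", "k5"])
    est = FilterEstimate(
        mean=np.concatenate([rng.uniform(0.1, 0.5, 5), [0.122, 0.00016]]),
        cov=np.diag([0.1] * 5 + [0.01, 0.01]),
    )
    out = predict(est, aug, 2.0, UkfSettings())
    np.testing.assert_allclose(out.mean[5:], est.mean[5:], atol=1e-12)
    assert_covariance_healthy(out)


# ---------------------------------------------------------------------------
# correct

def test_correct_with_uninformative_measurement_keeps_prior():
    prior = FilterEstimate(mean=np.array([1.0, 2.0]), cov=np.eye(2))
    s = UkfSettings(R=np.array([[1e12]]))
    post = correct(prior, np.array([100.0]), [0], s)
    np.testing.assert_allclose(post.mean, prior.mean, rtol=1e-6, atol=1e-6)
    np.testing.assert_allclose(post.cov, prior.cov, rtol=1e-6, atol=1e-6)


def test_correct_pins_exactly_observed_coordinate():
    prior = FilterEstimate(mean=np.array([1.0, 2.0]), cov=np.eye(2))
    s = UkfSettings(R=np.array([[1e-12]]))
    post = correct(prior, np.array([3.0]), [1], s)
    assert post.mean[1] == pytest.approx(3.0, abs=1e-6)


def test_correct_matches_exact_kalman_update(rng):
    d, m = 4, 2
    L = rng.normal(size=(d, d))
    P = L @ L.T
    H = rng.normal(size=(m, d))
    R = np.diag(rng.uniform(0.1, 1.0, m))
    mean = rng.normal(size=d)
    y = rng.normal(size=m)
    prior = FilterEstimate(mean=mean, cov=P)
    post = correct(prior, y, lambda p: H @ p, UkfSettings(R=R))
    S = H @ P @ H.T + R
    K = P @ H.T @ np.linalg.inv(S)
    np.testing.assert_allclose(post.mean, mean + K @ (y - H @ mean), atol=1e-8)
    np.testing.assert_allclose(post.cov, P - K @ S @ K.T, atol=1e-8)


def test_correct_reduces_observed_subspace_uncertainty(rng):
    prior = FilterEstimate(mean=rng.normal(size=3), cov=np.eye(3))
    s = UkfSettings(R=0.1 * np.eye(2))
    post = correct(prior, rng.normal(size=2), [0, 2], s)
    proj = np.ix_([0, 2], [0, 2])
    assert np.trace(post.cov[proj]) <= np.trace(prior.cov[proj]) + 1e-12
    assert_covariance_healthy(post)


def test_correct_diagnoses_singular_innovation():
    prior = FilterEstimate(mean=np.zeros(2), cov=np.zeros((2, 2)))
    s = UkfSettings(R=np.zeros((1, 1)))
    with pytest.raises(ValueError, match="[Rr]"):
        correct(prior, np.array([1.0]), [0], s)


# ---------------------------------------------------------------------------
# full pass: linear-Gaussian equivalence with an exact discrete Kalman filter

def test_full_pass_matches_exact_kalman_filter_on_random_linear_systems():
    rng = np.random.default_rng(2024)
    for _ in range(10):
        d, m = 3, 2
        A = _random_stable(rng, d)
        H = rng.normal(size=(m, d))
        Lq = 0.1 * rng.normal(size=(d, d))
        Q = Lq @ Lq.T
        R = np.diag(rng.uniform(0.05, 0.5, m))
        dt = 0.25
        F = expm(A * dt)
        s = _tight_settings(Q=Q, R=R)

        aug = _linear_model(A)
        est = FilterEstimate(mean=rng.normal(size=d), cov=np.eye(d), t=0.0)
        km, kP = est.mean.copy(), est.cov.copy()
        for _step in range(15):
            y = rng.normal(size=m)
            est = predict(est, aug, dt, s)
            est = correct(est, y, lambda p: H @ p, s)
            assert_covariance_healthy(est)
            # exact discrete Kalman recursion
            km = F @ km
            kP = F @ kP @ F.T + Q
            S = H @ kP @ H.T + R
            K = kP @ H.T @ np.linalg.inv(S)
            km = km + K @ (y - H @ km)
            kP = kP - K @ S @ K.T
            np.testing.assert_allclose(est.mean, km, atol=1e-8)
            np.testing.assert_allclose(est.cov, kP, atol=1e-6)


# ---------------------------------------------------------------------------
# estimate_parameters

def _cancer_truth_observations(times, k3=0.122, x0=None):
    """Noiseless cancer-agent observations generated straight from the ODE."""
    cp = CancerParameters(k3=k3)
    from cafswitch.model_core import cancer_rhs

    x0 = np.full(5, 0.5) if x0 is None else x0
    sol = solve_ivp(
        lambda t, y: cancer_rhs(y, (0.0, 0.0), cp), (0.0, times[-1]), x0,
        t_eval=times, rtol=1e-10, atol=1e-12, method="LSODA",
    )
    return ObservationSet(
        species=CANCER_SPECIES, times=np.asarray(times, float), values=sol.y,
    )


def test_recovers_single_rate_constant_from_dense_noiseless_data():
    """Estimating k3 alone from 50 noiseless time points lands within 5%."""
    times = np.linspace(1.0, 50.0, 50)
    obs = _cancer_truth_observations(times, k3=0.122)
    s = UkfSettings(R=1e-8 * np.eye(5), q_state=1e-10, q_param=1e-10)
    result = estimate_parameters(
        obs, cancer_parameter_model(), ["k3"], settings=s,
        initial_state=np.full(5, 0.5), param_prior={"k3": 0.08},
    )
    assert result.converged
    assert result.parameters["k3"] == pytest.approx(0.122, rel=0.05)
    for est in result.estimates:
        assert_covariance_healthy(est)


def test_more_observations_do_not_increase_parameter_variance():
    full = np.linspace(1.0, 48.0, 40)
    obs_full = _cancer_truth_observations(full)
    s = UkfSettings(R=1e-4 * np.eye(5), q_param=0.0)
    variances = []
    for stride in (4, 2, 1):  # dyadically nested observation subsets
        idx = np.arange(0, 40, stride)
        sub = ObservationSet(
            species=CANCER_SPECIES, times=full[idx], values=obs_full.values[:, idx]
        )
        r = estimate_parameters(
            sub, cancer_parameter_model(), ["k3"], settings=s,
            initial_state=np.full(5, 0.5), param_prior={"k3": 0.1},
        )
        variances.append(r.parameter_variances["k3"])
    assert variances[0] >= variances[1] >= variances[2]


def test_sparse_4x4_set_completes_with_finite_error(default_truth):
    obs = sparse_estimation_set(seed=5, truth=default_truth)
    result = estimate_parameters(obs, joint_parameter_model(), ["h1"])
    assert np.isfinite(result.total_error)
    assert result.converged
    assert set(result.parameters) == {"h1"}


def test_estimation_preconditions():
    obs = ObservationSet(species=("LIF",), times=[1.0, 2.0], values=[[1.0, 1.0]])
    with pytest.raises(ValueError):
        estimate_parameters(obs, cancer_parameter_model(), [])
    short = ObservationSet(species=("LIF",), times=[1.0], values=[[1.0]])
    with pytest.raises(ValueError):
        estimate_parameters(short, cancer_parameter_model(), ["k1"])
    with pytest.raises(KeyError):
        estimate_parameters(obs, cancer_parameter_model(), ["nope"])
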