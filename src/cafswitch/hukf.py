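"""Hybrid (continuous-discrete) unscented Kalman filter for parameter estimation.

The signaling model is continuous in time while expression measurements
arrive at discrete instants, so the filter propagates its sigma points
through the nonlinear ODE between measurements (the *hybrid* part) and
applies the standard unscented correction at each measurement.  Unknown
rate constants are estimated jointly with the states by augmentation:
each is appended to the state vector as an extra coordinate with zero
time derivative, and the correction step moves it through its
cross-covariance with the observed states.

The filter is deterministic given its inputs; all stochasticity lives in
the synthetic observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .model_core import (
    CANCER_SPECIES,
    FIBROBLAST_SPECIES,
    CancerParameters,
    FibroblastParameters,
)
from .simulate import SPECIES_INDEX
from .synthetic import ObservationSet

__all__ = [
    "AugmentedModel",
    "ParameterModel",
    "FilterEstimate",
    "UkfSettings",
    "EstimationResult",
    "FilterDivergence",
    "augment",
    "sigma_points",
    "predict",
    "correct",
    "estimate_parameters",
    "cancer_parameter_model",
    "fibroblast_parameter_model",
    "joint_parameter_model",
]

InputSpec = Union[Tuple[float, float], Callable[[float], Tuple[float, float]]]


class FilterDivergence(RuntimeError):
    """Raised when the filter mean or covariance becomes non-finite."""

    def __init__(self, message: str, step: Optional[int] = None):
        super().__init__(message)
        self.step = step


@dataclass(frozen=True)
class FilterEstimate:
    """Gaussian belief over the augmented state at one instant.

    ``mean`` has length n + q (states then parameters); ``cov`` is the
    matching covariance, kept symmetric by construction.
    """

    mean: np.ndarray
    cov: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        P = np.asarray(self.cov, dtype=float)
        if P.shape != (len(m), len(m)):
            raise ValueError("covariance shape must match mean length")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", 0.5 * (P + P.T))


@dataclass
class UkfSettings:
    """Tunable knobs of the unscented filter.

    Scaled-unscented sigma-point parameters (alpha, beta, kappa) default to
    the conventional (0.1, 2, 0).  Process noise defaults to 1e-6 on state
    coordinates and 1e-8 on parameter coordinates (an explicit Q overrides
    both); the prior covariance defaults to 1 on states and 0.25 on
    parameters (P0 overrides).  If R is not given the measurement noise is
    scaled to the data: (r_rel x per-species value range)^2 on the diagonal.
    Between measurements sigma points are propagated with classic RK4 at
    ``ode_step`` hours, or adaptively (LSODA at rtol/atol) when
    ``propagator="adaptive"``.
    """

    alpha: float = 0.1
    beta: float = 2.0
    kappa: float = 0.0
    q_state: float = 1e-6
    q_param: float = 1e-8
    Q: Optional[np.ndarray] = None
    r_rel: float = 0.05
    R: Optional[np.ndarray] = None
    p0_state: float = 1.0
    p0_param: float = 0.25
    P0: Optional[np.ndarray] = None
    ode_step: float = 0.02
    propagator: str = "rk4"  # or "adaptive"
    rtol: float = 1e-10
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.propagator not in ("rk4", "adaptive"):
            raise ValueError(f"unknown propagator {self.propagator!r}")
        for name in ("Q", "R", "P0"):
            M = getattr(self, name)
            if M is not None:
                M = np.asarray(M, dtype=float)
                if M.ndim != 2 or M.shape[0] != M.shape[1]:
                    raise ValueError(f"{name} must be a square matrix")
                if not np.allclose(M, M.T, atol=1e-10):
                    raise ValueError(f"{name} must be symmetric")
                setattr(self, name, M)


@dataclass(frozen=True)
class ParameterModel:
    """A parameterised ODE model the filter can estimate.

    ``rhs(t, x, params)`` returns dx/dt for a flat symbol->value mapping;
    ``species`` names the state coordinates; ``defaults`` carries the full
    recognized symbol set with default values.
    """

    rhs: Callable[[float, np.ndarray, Mapping[str, float]], np.ndarray]
    species: Tuple[str, ...]
    defaults: Dict[str, float]
    name: str = "model"

    def coordinate(self, species_name: str) -> int:
        if species_name in self.species:
            return self.species.index(species_name)
        # the joint model also answers to the plain observation vocabulary
        if len(self.species) == 10 and species_name in SPECIES_INDEX:
            return SPECIES_INDEX[species_name]
        raise KeyError(
            f"species {species_name!r} is not a state of model {self.name!r}"
        )


@dataclass(frozen=True)
class AugmentedModel:
    """A ParameterModel with selected parameters promoted to states.

    The augmented state is (x, theta); the augmented derivative is
    (f(x, theta), 0): constant parameters have zero rate of change.
    """

    base: ParameterModel
    estimate_names: Tuple[str, ...]
    fixed_params: Dict[str, float]

    @property
    def n_state(self) -> int:
        return len(self.base.species)

    @property
    def n_param(self) -> int:
        return len(self.estimate_names)

    @property
    def dim(self) -> int:
        return self.n_state + self.n_param

    def split(self, y: np.ndarray) -> Tuple[np.ndarray, Dict[str, float]]:
        x = y[: self.n_state]
        params = dict(self.fixed_params)
        for name, val in zip(self.estimate_names, y[self.n_state:]):
            params[name] = float(val)
        return x, params

    def aug_rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        x, params = self.split(y)
        dx = self.base.rhs(t, x, params)
        return np.concatenate([np.asarray(dx, dtype=float), np.zeros(self.n_param)])


def augment(
    model: ParameterModel,
    estimate_names: Sequence[str],
    fixed_params: Optional[Mapping[str, float]] = None,
) -> AugmentedModel:
    """Promote the named parameters to augmented-state coordinates.

    ``fixed_params`` overrides the model defaults for the non-estimated
    symbols (and supplies prior centres for the estimated ones).  Unknown
    symbols are rejected by name.
    """
    names = tuple(estimate_names)
    if not names:
        raise ValueError("estimate_names must not be empty")
    full = dict(model.defaults)
    if fixed_params:
        for k in fixed_params:
            if k not in full:
                raise KeyError(f"unknown parameter symbol {k!r}")
        full.update({k: float(v) for k, v in fixed_params.items()})
    for n in names:
        if n not in full:
            raise KeyError(f"unknown parameter symbol {n!r}")
    return AugmentedModel(base=model, estimate_names=names, fixed_params=full)


# ---------------------------------------------------------------------------
# model adapters

def _cancer_rhs_flat(x: np.ndarray, p: Mapping[str, float], u1: float, u2: float) -> np.ndarray:
    x1, x2, x3, x4, x5 = x
    return np.array(
        [
            p["k21"] * x1 * x2 - p["k1"] * x1,
            p["k2"] * x2 - p["k21"] * x1 * x2 - p["k24"] * x2 * x4
            - p["k32"] * x2 * x3 - p["k42"] * x4 - p["k52"] * x2 * x5,
            u2 - u1 + p["k32"] * x2 * x3 - p["k3"] * x3,
            p["k24"] * x2 * x4 - p["k4"] * x4,
            p["k52"] * x2 * x5 - p["k5"] * x5,
        ]
    )


def _fibro_rhs_flat(z: np.ndarray, p: Mapping[str, float], v1: float, v2: float,
                    floor: bool) -> np.ndarray:
    z1, z2, z3, z4, z5 = z
    h11 = p["h11_m0"] + p["h11_m1"] * v1 + p["h11_m2"] * v2 + p["h11_m3"] * v1 * v2
    h32 = p["h32_m0"] + p["h32_m1"] * v1 + p["h32_m2"] * v2 + p["h32_m3"] * v1 * v2
    h12 = p["h12_m0"] + p["h12_m1"] * v1 + p["h12_m2"] * v2 + p["h12_m3"] * v1 * v2
    if floor:
        h11 = max(h11, 0.0)
        h32 = max(h32, 0.0)
        h12 = max(h12, 0.0)
    return np.array(
        [
            h11 * z1 - p["h1"] * z1,
            h32 * z2 * z3 - h12 * z2 * z1,
            -h32 * z2 * z3 - p["h34"] * z3 * z4 - p["h42"] * z4
            + p["h35"] * z3 * z5 + v2,
            p["h54"] * z4 * z5 + p["h34"] * z3 * z4 - p["h4"] * z4,
            -p["h54"] * z4 * z5 - p["h35"] * z3 * z5 + v1,
        ]
    )


def _flat_fibro_defaults(fp: FibroblastParameters) -> Dict[str, float]:
    d = {k: getattr(fp, k) for k in ("h1", "h34", "h54", "h42", "h4", "h35")}
    for h in ("h11", "h32", "h12"):
        cc = getattr(fp, h)
        for m in ("m0", "m1", "m2", "m3"):
            d[f"{h}_{m}"] = getattr(cc, m)
    return d


def _resolve_inputs(inputs: InputSpec) -> Callable[[float], Tuple[float, float]]:
    if callable(inputs):
        return inputs
    a, b = float(inputs[0]), float(inputs[1])
    return lambda t: (a, b)


def cancer_parameter_model(
    inputs: InputSpec = (0.0, 0.0),
    base: Optional[CancerParameters] = None,
) -> ParameterModel:
    """The 5-state cancer agent as an estimable model.

    ``inputs`` is the received (u1, u2) = (SLIT2, CXCL12) signal, constant
    or a function of time.  All ten k rate constants are estimable symbols.
    """
    cp = base if base is not None else CancerParameters()
    u_of_t = _resolve_inputs(inputs)

    def rhs(t, x, p):
        u1, u2 = u_of_t(t)
        return _cancer_rhs_flat(x, p, u1, u2)

    return ParameterModel(
        rhs=rhs, species=CANCER_SPECIES, defaults=cp.to_dict(), name="cancer"
    )


def fibroblast_parameter_model(
    inputs: InputSpec = (0.0, 0.0),
    base: Optional[FibroblastParameters] = None,
) -> ParameterModel:
    """The 5-state fibroblast agent as an estimable model.

    ``inputs`` is the received (v1, v2) = (LIF, TGFB) signal, constant or a
    function of time.  The estimable symbols are the six fixed h rates and
    the twelve coupling coefficients h11_m0..h12_m3.
    """
    fp = base if base is not None else FibroblastParameters()
    v_of_t = _resolve_inputs(inputs)
    floor = fp.floor_rates

    def rhs(t, z, p):
        v1, v2 = v_of_t(t)
        return _fibro_rhs_flat(z, p, v1, v2, floor)

    return ParameterModel(
        rhs=rhs, species=FIBROBLAST_SPECIES, defaults=_flat_fibro_defaults(fp),
        name="fibroblast",
    )


def joint_parameter_model(
    cancer_base: Optional[CancerParameters] = None,
    fibro_base: Optional[FibroblastParameters] = None,
) -> ParameterModel:
    """The coupled 10-state system as an estimable model.

    States are the CSV-dialect names X1_LIF..Z5_JAKSTAT (the plain
    observation vocabulary also resolves); the symbol set is the union of
    the cancer k's and the fibroblast h's.  Signals are wired through the
    instantaneous output identities, so no external inputs remain.
    """
    cp = cancer_base if cancer_base is not None else CancerParameters()
    fp = fibro_base if fibro_base is not None else FibroblastParameters()
    floor = fp.floor_rates
    defaults = {**cp.to_dict(), **_flat_fibro_defaults(fp)}
    species = tuple(
        [f"X{i+1}_{s}" for i, s in enumerate(CANCER_SPECIES)]
        + [f"Z{i+1}_{s}" for i, s in enumerate(FIBROBLAST_SPECIES)]
    )

    def rhs(t, y, p):
        x, z = y[:5], y[5:]
        dx = _cancer_rhs_flat(x, p, z[0], z[1])
        dz = _fibro_rhs_flat(z, p, x[0], x[2], floor)
        return np.concatenate([dx, dz])

    return ParameterModel(rhs=rhs, species=species, defaults=defaults, name="joint")


# ---------------------------------------------------------------------------
# unscented machinery

def _sqrt_psd(P: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish square root of a PSD matrix.

    Tries Cholesky first; on failure applies escalating symmetric jitter
    (1e-10*I up to 1e-6*I, relative to the matrix scale) before giving up
    with a hint to regularise.
    """
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        pass
    scale = max(1.0, float(np.max(np.abs(P))))
    jitter = 1e-10
    eye = np.eye(len(P))
    while jitter <= 1e-6 + 1e-18:
        try:
            return np.linalg.cholesky(P + jitter * scale * eye)
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise ValueError(
        "covariance is not positive semidefinite even after jitter up to "
        "1e-6; add diagonal jitter or rescale the problem"
    )


def _weights(d: int, s: UkfSettings) -> Tuple[float, np.ndarray, np.ndarray]:
    lam = s.alpha**2 * (d + s.kappa) - d
    wm = np.full(2 * d + 1, 1.0 / (2.0 * (d + lam)))
    wc = wm.copy()
    wm[0] = lam / (d + lam)
    wc[0] = lam / (d + lam) + (1.0 - s.alpha**2 + s.beta)
    return d + lam, wm, wc


def sigma_points(
    mean: np.ndarray, cov: np.ndarray, settings: Optional[UkfSettings] = None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled-unscented sigma points and weights for a Gaussian belief.

    Returns (points, mean_weights, cov_weights) with points of shape
    (2d+1, d).  The weighted mean of the points reconstructs ``mean`` and
    the weighted scatter reconstructs ``cov`` exactly (to roundoff), which
    is the defining property of the unscented transform.
    """
    s = settings if settings is not None else UkfSettings()
    m = np.asarray(mean, dtype=float)
    P = np.asarray(cov, dtype=float)
    d = len(m)
    c, wm, wc = _weights(d, s)
    if np.all(P == 0.0):
        S = np.zeros_like(P)  # degenerate belief: all points collapse to the mean
    else:
        S = _sqrt_psd(0.5 * (P + P.T))
    spread = math.sqrt(c) * S
    pts = np.empty((2 * d + 1, d))
    pts[0] = m
    pts[1: d + 1] = m + spread.T
    pts[d + 1:] = m - spread.T
    return pts, wm, wc


def _propagate_points(
    model: AugmentedModel, pts: np.ndarray, t0: float, dt: float, s: UkfSettings
) -> np.ndarray:
    """Integrate every sigma point through the augmented ODE over dt."""
    if s.propagator == "adaptive":
        shape = pts.shape

        def batch_rhs(t, yflat):
            Y = yflat.reshape(shape)
            return np.array([model.aug_rhs(t, y) for y in Y]).ravel()

        sol = solve_ivp(
            batch_rhs, (t0, t0 + dt), pts.ravel(), method="LSODA",
            rtol=s.rtol, atol=s.atol,
        )
        if not sol.success:
            raise FilterDivergence(
                f"sigma-point propagation failed near t={sol.t[-1]:.6g} h: {sol.message}"
            )
        return sol.y[:, -1].reshape(shape)

    n_steps = max(1, math.ceil(dt / s.ode_step - 1e-12))
    h = dt / n_steps
    Y = pts.copy()
    t = t0
    for _ in range(n_steps):
        for i in range(len(Y)):
            y = Y[i]
            k1 = model.aug_rhs(t, y)
            k2 = model.aug_rhs(t + h / 2, y + h / 2 * k1)
            k3 = model.aug_rhs(t + h / 2, y + h / 2 * k2)
            k4 = model.aug_rhs(t + h, y + h * k3)
            Y[i] = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    if not np.all(np.isfinite(Y)):
        raise FilterDivergence("non-finite sigma point during propagation")
    return Y


def _process_noise(model: AugmentedModel, s: UkfSettings) -> np.ndarray:
    if s.Q is not None:
        if s.Q.shape != (model.dim, model.dim):
            raise ValueError("Q dimension does not match the augmented state")
        return s.Q
    return np.diag(
        [s.q_state] * model.n_state + [s.q_param] * model.n_param
    )


def predict(
    estimate: FilterEstimate,
    model: AugmentedModel,
    dt: float,
    settings: Optional[UkfSettings] = None,
) -> FilterEstimate:
    """Time-update: propagate the belief through the model over ``dt`` hours.

    Each sigma point is integrated through the augmented ODE (continuous
    propagation -- the hybrid part of the filter), the predicted mean and
    covariance are recombined from the propagated points, and the process
    noise Q is added.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    s = settings if settings is not None else UkfSettings()
    pts, wm, wc = sigma_points(estimate.mean, estimate.cov, s)
    prop = _propagate_points(model, pts, estimate.t, dt, s)
    mean = wm @ prop
    diff = prop - mean
    cov = (wc[:, None] * diff).T @ diff + _process_noise(model, s)
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(cov))):
        raise FilterDivergence("non-finite predicted mean or covariance")
    return FilterEstimate(mean=mean, cov=cov, t=estimate.t + dt)


def _unscented_update(
    prior: FilterEstimate,
    y: np.ndarray,
    obs_map,
    R: np.ndarray,
    s: UkfSettings,
) -> Tuple[FilterEstimate, np.ndarray]:
    pts, wm, wc = sigma_points(prior.mean, prior.cov, s)
    if callable(obs_map):
        Y = np.array([np.atleast_1d(np.asarray(obs_map(p), dtype=float)) for p in pts])
    else:
        idx = np.asarray(obs_map, dtype=int)
        Y = pts[:, idx]
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if Y.shape[1] != len(y) or R.shape != (len(y), len(y)):
        raise ValueError("observation, map and R dimensions are inconsistent")
    yhat = wm @ Y
    dY = Y - yhat
    S = (wc[:, None] * dY).T @ dY + R
    S = 0.5 * (S + S.T)
    C = (wc[:, None] * (pts - prior.mean)).T @ dY
    try:
        cf = cho_factor(S)
    except (LinAlgError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "innovation covariance is numerically singular; consider a larger "
            "measurement noise R"
        ) from exc
    K = cho_solve(cf, C.T).T
    innovation = y - yhat
    mean = prior.mean + K @ innovation
    cov = prior.cov - K @ S @ K.T
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(cov))):
        raise FilterDivergence("non-finite posterior mean or covariance")
    return FilterEstimate(mean=mean, cov=cov, t=prior.t), innovation


def correct(
    prior: FilterEstimate,
    observation: np.ndarray,
    observation_map,
    settings: Optional[UkfSettings] = None,
) -> FilterEstimate:
    """Measurement-update: fold one observation vector into the belief.

    ``observation_map`` either lists augmented-state coordinate indices
    (linear selection) or is a callable h(y_aug) -> observation space.  The
    measurement noise is ``settings.R``, which must be set for a standalone
    correction.
    """
    s = settings if settings is not None else UkfSettings()
    if s.R is None:
        raise ValueError("settings.R must be provided for a standalone correct()")
    post, _ = _unscented_update(prior, observation, observation_map, s.R, s)
    return post


# ---------------------------------------------------------------------------
# full estimation pass

@dataclass
class EstimationResult:
    """Outcome of an HUKF estimation run.

    ``parameters`` maps each estimated symbol to its final posterior mean;
    ``estimates`` is the posterior belief after each measurement (final
    pass); ``innovations`` stacks the per-measurement innovation vectors;
    ``total_error`` is the root-mean-square deviation between the filtered
    estimates of the observed coordinates and the observations, averaged
    over observed species (the scalar used to summarise estimation
    quality); ``parameter_variances`` is the matching posterior variance of
    each estimated symbol at the final measurement.
    """

    parameters: Dict[str, float]
    estimates: List[FilterEstimate]
    innovations: np.ndarray
    total_error: float
    converged: bool
    parameter_variances: Dict[str, float] = field(default_factory=dict)
    n_passes: int = 1
    settings: Optional[UkfSettings] = None
    estimate_names: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "parameters": dict(self.parameters),
            "parameter_variances": dict(self.parameter_variances),
            "total_error": self.total_error,
            "converged": self.converged,
            "n_passes": self.n_passes,
            "n_measurements": len(self.estimates),
        }


def _default_R(obs: ObservationSet, s: UkfSettings) -> np.ndarray:
    if s.R is not None:
        return s.R
    spans = np.ptp(obs.values, axis=1)
    scale = np.maximum(s.r_rel * np.maximum(spans, 1e-3), 1e-4)
    return np.diag(scale**2)


def estimate_parameters(
    observations: ObservationSet,
    model: ParameterModel,
    estimate_names: Sequence[str],
    settings: Optional[UkfSettings] = None,
    initial_state: Optional[Sequence[float]] = None,
    param_prior: Optional[Mapping[str, float]] = None,
    fixed_params: Optional[Mapping[str, float]] = None,
    t0: float = 0.0,
    passes: int = 1,
    seed: Optional[int] = None,
) -> EstimationResult:
    """Run the full hybrid UKF over an observation set.

    Alternates continuous prediction over each inter-measurement interval
    with an unscented correction at each measurement time, starting from
    ``t0``.  ``param_prior`` centres the parameter coordinates (defaulting
    to the model's default values); ``initial_state`` seeds the state
    coordinates (default 0.01 a.u. everywhere, the packaged scenario's
    seed).  With ``passes > 1`` the filter is re-run with the previous
    pass's final parameter means as the new prior centre, stopping early
    when no parameter moves by more than 1e-3 (relative), up to five passes.

    The filter itself is deterministic; ``seed`` is accepted only for
    pipeline-call uniformity and is unused.
    """
    del seed  # determinism: the filter has no randomness of its own
    if len(observations.times) < 2:
        raise ValueError("estimation requires at least 2 observation times")
    s = settings if settings is not None else UkfSettings()
    aug = augment(model, estimate_names, fixed_params)
    if param_prior:
        for k in param_prior:
            if k not in aug.estimate_names:
                raise KeyError(f"prior given for non-estimated symbol {k!r}")
    obs_idx = np.array([model.coordinate(sp) for sp in observations.species])
    R = _default_R(observations, s)

    n, q = aug.n_state, aug.n_param
    if initial_state is None:
        x0 = np.full(n, 0.01)
    else:
        x0 = np.asarray(initial_state, dtype=float)
        if x0.shape != (n,):
            raise ValueError(f"initial_state must have length {n}")
    theta0 = np.array(
        [
            float(param_prior[nm]) if param_prior and nm in param_prior
            else aug.fixed_params[nm]
            for nm in aug.estimate_names
        ]
    )
    if s.P0 is not None:
        if s.P0.shape != (n + q, n + q):
            raise ValueError("P0 dimension does not match the augmented state")
        P0 = s.P0
    else:
        P0 = np.diag([s.p0_state] * n + [s.p0_param] * q)

    max_passes = min(max(1, passes), 5)
    theta_centre = theta0
    result: Optional[EstimationResult] = None
    n_passes_run = 0
    pass_converged = max_passes == 1
    for ip in range(max_passes):
        n_passes_run += 1
        est = FilterEstimate(
            mean=np.concatenate([x0, theta_centre]), cov=P0, t=t0
        )
        estimates: List[FilterEstimate] = []
        innovations: List[np.ndarray] = []
        filtered_obs: List[np.ndarray] = []
        for j, tj in enumerate(observations.times):
            try:
                dt = tj - est.t
                if dt > 0:
                    est = predict(est, aug, dt, s)
                yj = observations.values[:, j]
                est, innov = _unscented_update(est, yj, obs_idx, R, s)
            except FilterDivergence as exc:
                raise FilterDivergence(
                    f"filter diverged at measurement step {j} (t={tj:g} h): {exc}",
                    step=j,
                ) from exc
            estimates.append(est)
            innovations.append(innov)
            filtered_obs.append(est.mean[obs_idx])

        theta_new = est.mean[n:]
        filt = np.array(filtered_obs).T  # (n_species, n_times)
        per_species_rmse = np.sqrt(
            np.mean((filt - observations.values) ** 2, axis=1)
        )
        total_error = float(np.mean(per_species_rmse))
        result = EstimationResult(
            parameters={
                nm: float(v) for nm, v in zip(aug.estimate_names, theta_new)
            },
            estimates=estimates,
            innovations=np.array(innovations),
            total_error=total_error,
            converged=True,
            parameter_variances={
                nm: float(est.cov[n + i, n + i])
                for i, nm in enumerate(aug.estimate_names)
            },
            n_passes=n_passes_run,
            settings=s,
            estimate_names=aug.estimate_names,
        )
        rel_change = np.max(
            np.abs(theta_new - theta_centre) / np.maximum(np.abs(theta_centre), 1e-12)
        )
        theta_centre = theta_new
        if max_passes > 1 and rel_change < 1e-3:
            pass_converged = True
            break
    assert result is not None
    result.converged = pass_converged and bool(
        np.all(np.isfinite(list(result.parameters.values())))
    )
    result.n_passes = n_passes_run
    return result
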