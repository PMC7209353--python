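"""Time integration of the coupled cancer-cell / fibroblast system.

The two five-state agents exchange their signals either continuously (the
joint 10-dimensional ODE, using the instantaneous output identities
V1 = X1, V2 = X3, U1 = Z1, U2 = Z2) or in discrete-exchange mode, where
each agent integrates its own 5-dimensional ODE over an exchange window
with the other agent's signals frozen at their window-start values --
the message-passing reading of the agent-based formulation.  Discrete
exchange converges to the continuous solution as the window shrinks.

:func:`detect_switch` summarises the NAF->CAF switching signature of a
trajectory: SLIT2 rising then falling, CXCL12 and SNAIL ending above their
starting levels, and the time at which CXCL12 first overtakes SLIT2.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    CANCER_SPECIES,
    FIBROBLAST_SPECIES,
    CancerParameters,
    CancerState,
    CouplingCoefficients,
    FibroblastParameters,
    FibroblastState,
    cancer_rhs,
    coupling_rate,
    fibroblast_rhs,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SwitchReport",
    "SimulationError",
    "assemble_joint_rhs",
    "simulate",
    "detect_switch",
    "TRAJECTORY_COLUMNS",
]

#: Column order of the trajectory CSV dialect.
TRAJECTORY_COLUMNS = (
    "time",
    "X1_LIF", "X2_SMAD", "X3_TGFB", "X4_SMAD7", "X5_SNAIL",
    "Z1_SLIT2", "Z2_CXCL12", "Z3_SMAD", "Z4_SMAD7", "Z5_JAKSTAT",
)

#: Plain species names resolved onto joint-state coordinates.  SMAD and
#: SMAD7 exist in both agents; the bare names resolve to the fibroblast copy
#: (the default observation map); the prefixed CSV names are always exact.
SPECIES_INDEX = {
    "X1_LIF": 0, "X2_SMAD": 1, "X3_TGFB": 2, "X4_SMAD7": 3, "X5_SNAIL": 4,
    "Z1_SLIT2": 5, "Z2_CXCL12": 6, "Z3_SMAD": 7, "Z4_SMAD7": 8, "Z5_JAKSTAT": 9,
    "LIF": 0, "TGFB": 2, "SNAIL": 4,
    "SLIT2": 5, "CXCL12": 6, "SMAD": 7, "SMAD7": 8, "JAKSTAT": 9,
}


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries the time of failure."""

    def __init__(self, message: str, t: Optional[float] = None):
        super().__init__(message)
        self.t = t


def _default_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 72.0 + 1e-9, 0.1), 10)


@dataclass
class SimulationConfig:
    """Settings for a coupled-system run.

    Times are hours.  The default scenario starts every species at a small
    positive seed (0.01 a.u.) so that the autocatalytic bilinear terms are
    not pinned at the absorbing origin, and runs 0-72 h on a 0.1 h grid.
    """

    t_start: float = 0.0
    t_end: float = 72.0
    output_times: Optional[np.ndarray] = None
    coupling: str = "continuous"  # or "discrete-exchange"
    exchange_dt: float = 1.0
    integrator: str = "adaptive"  # or "fixed-step"
    step_size: float = 0.01
    rtol: float = 1e-8
    atol: float = 1e-10
    clamp: bool = False
    initial_cancer: CancerState = field(
        default_factory=lambda: CancerState(0.01, 0.01, 0.01, 0.01, 0.01)
    )
    initial_fibro: FibroblastState = field(
        default_factory=lambda: FibroblastState(0.01, 0.01, 0.01, 0.01, 0.01)
    )

    def __post_init__(self) -> None:
        if self.output_times is None:
            if (self.t_start, self.t_end) == (0.0, 72.0):
                self.output_times = _default_grid()
            else:
                self.output_times = np.linspace(self.t_start, self.t_end, 201)
        self.output_times = np.asarray(self.output_times, dtype=float)
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        t = self.output_times
        if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("output_times must be strictly increasing")
        if t[0] < self.t_start - 1e-12 or t[-1] > self.t_end + 1e-12:
            raise ValueError("output_times must lie within [t_start, t_end]")
        if self.coupling not in ("continuous", "discrete-exchange"):
            raise ValueError(f"unknown coupling mode {self.coupling!r}")
        if self.coupling == "discrete-exchange" and not self.exchange_dt > 0:
            raise ValueError("exchange_dt must be positive")
        if self.integrator not in ("adaptive", "fixed-step"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.integrator == "fixed-step" and not self.step_size > 0:
            raise ValueError("step_size must be positive")


@dataclass
class Trajectory:
    """A simulated time course of the joint system.

    ``cancer`` and ``fibro`` are (N, 5) arrays in the X1..X5 / Z1..Z5
    orders; ``signals`` holds (v1, v2, u1, u2) and ``h_eff`` the effective
    (floored, if the policy is on) coupling rates (h11, h32, h12) at each
    output time.  ``negativity_events`` records the first grid time each
    species went negative, if any.
    """

    times: np.ndarray
    cancer: np.ndarray
    fibro: np.ndarray
    signals: np.ndarray
    h_eff: np.ndarray
    negativity_events: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.times)
        if self.cancer.shape != (n, 5) or self.fibro.shape != (n, 5):
            raise ValueError("state arrays must have one row per time point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def joint(self) -> np.ndarray:
        """(N, 10) array of the joint state (cancer then fibroblast)."""
        return np.hstack([self.cancer, self.fibro])

    def species(self, name: str) -> np.ndarray:
        """Series of one species by name (plain or prefixed CSV name)."""
        if name not in SPECIES_INDEX:
            raise KeyError(f"unknown species {name!r}")
        return self.joint[:, SPECIES_INDEX[name]]

    def interp(self, name: str, at_times: Sequence[float]) -> np.ndarray:
        """Linearly interpolate one species onto arbitrary times inside the span."""
        t = np.asarray(at_times, dtype=float)
        if np.any(t < self.times[0] - 1e-12) or np.any(t > self.times[-1] + 1e-12):
            raise ValueError("requested times fall outside the trajectory span")
        return np.interp(t, self.times, self.species(name))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(TRAJECTORY_COLUMNS)
            for i, t in enumerate(self.times):
                w.writerow(
                    [repr(float(v)) for v in (t, *self.cancer[i], *self.fibro[i])]
                )

    @classmethod
    def from_csv(cls, path, fibro_params: Optional[FibroblastParameters] = None) -> "Trajectory":
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            header = tuple(next(r))
            if header != TRAJECTORY_COLUMNS:
                raise ValueError(f"unexpected trajectory CSV header {header!r}")
            rows = np.array([[float(v) for v in row] for row in r])
        times = rows[:, 0]
        cancer = rows[:, 1:6]
        fibro = rows[:, 6:11]
        return _assemble_trajectory(times, cancer, fibro, fibro_params or FibroblastParameters())


@dataclass
class SwitchReport:
    """Summary of the NAF->CAF switching signature of one trajectory.

    Peak fields are None when the SLIT2 maximum sits on the grid boundary
    (no interior peak).  ``cxcl12_crosses_slit2_at`` is the first time
    CXCL12 exceeds SLIT2, found by linear interpolation between bracketing
    grid points (None if it never does).  The two ``*_increased_before_peak``
    flags compare LIF and TGFB at the SLIT2 peak time against their initial
    values -- the cancer-cell ramp-up that drives the switch.
    """

    slit2_peak_time: Optional[float]
    slit2_peak_value: Optional[float]
    slit2_rises_then_falls: bool
    cxcl12_increased: bool
    snail_increased: bool
    cxcl12_crosses_slit2_at: Optional[float]
    lif_increased_before_peak: Optional[bool] = None
    tgfb_increased_before_peak: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "slit2_peak_time": self.slit2_peak_time,
            "slit2_peak_value": self.slit2_peak_value,
            "slit2_rises_then_falls": self.slit2_rises_then_falls,
            "cxcl12_increased": self.cxcl12_increased,
            "snail_increased": self.snail_increased,
            "cxcl12_crosses_slit2_at": self.cxcl12_crosses_slit2_at,
            "lif_increased_before_peak": self.lif_increased_before_peak,
            "tgfb_increased_before_peak": self.tgfb_increased_before_peak,
        }


def assemble_joint_rhs(
    cancer_params: Optional[CancerParameters] = None,
    fibro_params: Optional[FibroblastParameters] = None,
    clamp: bool = False,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the derivative function of the joint 10-dimensional state.

    The first five coordinates are the cancer state, the last five the
    fibroblast state; the intercellular signals are wired through the
    instantaneous output identities.  With ``clamp=True`` the derivative is
    evaluated at the non-negative part of the state and species pinned at
    zero are not allowed to go further negative (exploratory mode).
    """
    cp = cancer_params if cancer_params is not None else CancerParameters()
    fp = fibro_params if fibro_params is not None else FibroblastParameters()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise SimulationError(f"non-finite state at t={t:.6g} h", t)
        ye = np.maximum(y, 0.0) if clamp else y
        x = ye[:5]
        z = ye[5:]
        # signals: v1=x1, v2=x3 (cancer out), u1=z1, u2=z2 (fibroblast out)
        du = cancer_rhs(x, (z[0], z[1]), cp)
        dz = fibroblast_rhs(z, (x[0], x[2]), fp)
        d = np.concatenate([du, dz])
        if clamp:
            d = np.where((y <= 0.0) & (d < 0.0), 0.0, d)
        return d

    return rhs


def _rk4_between(f, t0: float, t1: float, y: np.ndarray, h: float) -> np.ndarray:
    """Classic RK4 from t0 to t1 with step at most h (last step shortened)."""
    t = t0
    while t < t1 - 1e-14:
        step = min(h, t1 - t)
        k1 = f(t, y)
        k2 = f(t + step / 2, y + step / 2 * k1)
        k3 = f(t + step / 2, y + step / 2 * k2)
        k4 = f(t + step, y + step * k3)
        y = y + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += step
        if not np.all(np.isfinite(y)):
            raise SimulationError(f"non-finite state during fixed-step integration at t={t:.6g} h", t)
    return y


def _solve_window(f, t0, t1, y0, t_eval, rtol, atol):
    sol = solve_ivp(
        f, (t0, t1), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else t0
        raise SimulationError(
            f"integrator failed near t={t_fail:.6g} h: {sol.message}", t_fail
        )
    return sol


def _assemble_trajectory(
    times: np.ndarray,
    cancer: np.ndarray,
    fibro: np.ndarray,
    fp: FibroblastParameters,
) -> Trajectory:
    signals = np.column_stack(
        [cancer[:, 0], cancer[:, 2], fibro[:, 0], fibro[:, 1]]
    )
    h_eff = np.array(
        [
            [
                coupling_rate(fp.h11, v1, v2, floor=fp.floor_rates),
                coupling_rate(fp.h32, v1, v2, floor=fp.floor_rates),
                coupling_rate(fp.h12, v1, v2, floor=fp.floor_rates),
            ]
            for v1, v2 in signals[:, :2]
        ]
    )
    events: List[dict] = []
    names = [f"X{i+1}_{s}" for i, s in enumerate(CANCER_SPECIES)] + [
        f"Z{i+1}_{s}" for i, s in enumerate(FIBROBLAST_SPECIES)
    ]
    joint = np.hstack([cancer, fibro])
    for j, name in enumerate(names):
        # ignore sub-roundoff dips (solver atol scale), log genuine negativity
        neg = np.nonzero(joint[:, j] < -1e-9)[0]
        if len(neg):
            i = int(neg[0])
            events.append(
                {"species": name, "time": float(times[i]), "value": float(joint[i, j])}
            )
    return Trajectory(
        times=times, cancer=cancer, fibro=fibro, signals=signals,
        h_eff=h_eff, negativity_events=events,
    )


def simulate(
    config: Optional[SimulationConfig] = None,
    cancer_params: Optional[CancerParameters] = None,
    fibro_params: Optional[FibroblastParameters] = None,
) -> Trajectory:
    """Integrate the coupled system and return its trajectory on the output grid.

    Continuous coupling solves the joint 10-dimensional ODE (adaptive
    stiff-capable solver, or classic fixed-step RK4); discrete-exchange
    coupling alternates per-agent solves over exchange windows with the
    partner's signals held at window-start values.  Deterministic: the same
    config always yields the identical trajectory.
    """
    cfg = config if config is not None else SimulationConfig()
    cp = cancer_params if cancer_params is not None else CancerParameters()
    fp = fibro_params if fibro_params is not None else FibroblastParameters()
    y0 = np.concatenate(
        [cfg.initial_cancer.to_vector(), cfg.initial_fibro.to_vector()]
    )
    grid = cfg.output_times

    if cfg.coupling == "continuous":
        f = assemble_joint_rhs(cp, fp, clamp=cfg.clamp)
        if cfg.integrator == "adaptive":
            # solve_ivp needs the span to start at t_start even if the grid doesn't
            sol = _solve_window(f, cfg.t_start, cfg.t_end, y0, grid, cfg.rtol, cfg.atol)
            states = sol.y.T
        else:
            states = np.empty((len(grid), 10))
            y = y0.copy()
            t_prev = cfg.t_start
            for i, t in enumerate(grid):
                y = _rk4_between(f, t_prev, t, y, cfg.step_size)
                states[i] = y
                t_prev = t
        return _assemble_trajectory(grid, states[:, :5], states[:, 5:], fp)

    # discrete-exchange: per-agent solves with frozen partner signals
    x = cfg.initial_cancer.to_vector()
    z = cfg.initial_fibro.to_vector()
    out = np.empty((len(grid), 10))
    gi = 0
    if len(grid) and abs(grid[0] - cfg.t_start) < 1e-12:
        out[0] = np.concatenate([x, z])
        gi = 1
    t = cfg.t_start
    while t < cfg.t_end - 1e-12:
        t_next = min(t + cfg.exchange_dt, cfg.t_end)
        # snap to a coincident output time so roundoff in the accumulated
        # window edge cannot push an eval point outside the solve span
        j = int(np.searchsorted(grid, t_next))
        for cand in (j - 1, j):
            if 0 <= cand < len(grid) and abs(grid[cand] - t_next) < 1e-9:
                t_next = float(grid[cand])
                break
        u = (z[0], z[1])
        v = (x[0], x[2])
        inner = [g for g in grid[gi:] if t < g <= t_next]
        eval_pts = sorted(set(inner) | {t_next})
        fc = lambda tt, yy: cancer_rhs(yy, u, cp)
        fz = lambda tt, yy: fibroblast_rhs(yy, v, fp)
        solc = _solve_window(fc, t, t_next, x, eval_pts, cfg.rtol, cfg.atol)
        solz = _solve_window(fz, t, t_next, z, eval_pts, cfg.rtol, cfg.atol)
        for k, g in enumerate(eval_pts):
            if gi < len(grid) and abs(g - grid[gi]) < 1e-12:
                out[gi] = np.concatenate([solc.y[:, k], solz.y[:, k]])
                gi += 1
        x = solc.y[:, -1]
        z = solz.y[:, -1]
        t = t_next
    return _assemble_trajectory(grid, out[:, :5], out[:, 5:], fp)


def detect_switch(traj: Trajectory) -> SwitchReport:
    """Extract the NAF->CAF switching signature from a trajectory.

    The SLIT2 peak is the grid argmax (earliest time on ties); it counts as
    a rise-then-fall only when it lies strictly inside the horizon and
    strictly above both endpoint values.  CXCL12/SNAIL growth flags compare
    the endpoints.  The CXCL12-over-SLIT2 crossing time is linearly
    interpolated between the bracketing grid points.
    """
    if len(traj.times) < 3:
        raise ValueError("switch detection needs at least 3 time points")
    t = traj.times
    slit2 = traj.fibro[:, 0]
    cxcl12 = traj.fibro[:, 1]
    snail = traj.cancer[:, 4]
    lif = traj.cancer[:, 0]
    tgfb = traj.cancer[:, 2]

    i_peak = int(np.argmax(slit2))  # argmax returns the earliest tie
    interior = 0 < i_peak < len(t) - 1
    rises_falls = bool(
        interior and slit2[i_peak] > slit2[0] and slit2[i_peak] > slit2[-1]
    )
    peak_time = float(t[i_peak]) if interior else None
    peak_value = float(slit2[i_peak]) if interior else None

    diff = cxcl12 - slit2
    crossing: Optional[float] = None
    if diff[0] > 0:
        crossing = float(t[0])
    else:
        above = np.nonzero(diff > 0)[0]
        if len(above):
            i = int(above[0])
            d0, d1 = diff[i - 1], diff[i]
            crossing = float(t[i - 1] + (t[i] - t[i - 1]) * (-d0) / (d1 - d0))

    lif_up = tgfb_up = None
    if interior:
        lif_up = bool(lif[i_peak] > lif[0])
        tgfb_up = bool(tgfb[i_peak] > tgfb[0])

    return SwitchReport(
        slit2_peak_time=peak_time,
        slit2_peak_value=peak_value,
        slit2_rises_then_falls=rises_falls,
        cxcl12_increased=bool(cxcl12[-1] > cxcl12[0]),
        snail_increased=bool(snail[-1] > snail[0]),
        cxcl12_crosses_slit2_at=crossing,
        lif_increased_before_peak=lif_up,
        tgfb_increased_before_peak=tgfb_up,
    )
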