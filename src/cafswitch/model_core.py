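"""Kinetic core of the fibroblast-cancer cell crosstalk model.

Two agents interact through secreted signals: a cancer cell whose five
intracellular states follow TGFB/SMAD and LIF pathway kinetics, and a
fibroblast whose five states implement the SMAD and JAK/STAT branches plus
the SLIT2/CXCL12 output module that distinguishes a normal-associated
fibroblast (NAF, SLIT2-dominant) from a cancer-associated one (CAF,
CXCL12-dominant).  All rate constants are in hour^-1; concentrations are in
arbitrary units (a.u.); every bilinear term is a law-of-mass-action rate.

The cancer agent emits LIF (V1 = X1) and TGFB (V2 = X3); the fibroblast
emits SLIT2 (U1 = Z1) and CXCL12 (U2 = Z2).  Three fibroblast rates --
SLIT2 expression h11, CXCL12 expression h32, and the SLIT2-on-CXCL12
inhibition h12 -- are not constants but bilinear polynomials in the
received LIF and TGFB signals (see :func:`coupling_rate`), which is what
lets the fibroblast switch from NAF to CAF as the cancer cell ramps up its
outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "CancerState",
    "FibroblastState",
    "SignalBus",
    "CancerParameters",
    "CouplingCoefficients",
    "FibroblastParameters",
    "mass_action_rate",
    "coupling_rate",
    "cancer_rhs",
    "fibroblast_rhs",
    "signals_from_states",
    "load_default_parameters",
    "save_parameters",
    "load_parameters",
    "CANCER_SPECIES",
    "FIBROBLAST_SPECIES",
]

#: Cancer-agent state names in vector order (X1..X5).
CANCER_SPECIES = ("LIF", "SMAD", "TGFB", "SMAD7", "SNAIL")
#: Fibroblast-agent state names in vector order (Z1..Z5).
FIBROBLAST_SPECIES = ("SLIT2", "CXCL12", "SMAD", "SMAD7", "JAKSTAT")


def _require_finite(name: str, values: Iterable[float]) -> None:
    vals = list(values)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"{name} must contain only finite real numbers, got {vals!r}")


@dataclass(frozen=True)
class CancerState:
    """Cancer-cell state: LIF, SMAD, TGFB, SMAD7, SNAIL concentrations (a.u.)."""

    x1: float  # LIF
    x2: float  # SMAD
    x3: float  # TGFB
    x4: float  # SMAD7
    x5: float  # SNAIL

    def __post_init__(self) -> None:
        _require_finite("CancerState", self.to_vector())

    def to_vector(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4, self.x5], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "CancerState":
        v = np.asarray(vec, dtype=float)
        if v.shape != (5,):
            raise ValueError(f"CancerState vector must have length 5, got shape {v.shape}")
        return cls(*v.tolist())


@dataclass(frozen=True)
class FibroblastState:
    """Fibroblast state: SLIT2, CXCL12, SMAD, SMAD7, JAK/STAT concentrations (a.u.)."""

    z1: float  # SLIT2
    z2: float  # CXCL12
    z3: float  # SMAD
    z4: float  # SMAD7
    z5: float  # JAK/STAT

    def __post_init__(self) -> None:
        _require_finite("FibroblastState", self.to_vector())

    def to_vector(self) -> np.ndarray:
        return np.array([self.z1, self.z2, self.z3, self.z4, self.z5], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "FibroblastState":
        v = np.asarray(vec, dtype=float)
        if v.shape != (5,):
            raise ValueError(f"FibroblastState vector must have length 5, got shape {v.shape}")
        return cls(*v.tolist())


@dataclass(frozen=True)
class SignalBus:
    """The four intercellular signals.

    v1 (LIF) and v2 (TGFB) travel cancer -> fibroblast; u1 (SLIT2) and
    u2 (CXCL12) travel fibroblast -> cancer.  When derived from agent
    states the output maps are the identities v1 = x1, v2 = x3, u1 = z1,
    u2 = z2.
    """

    v1: float
    v2: float
    u1: float
    u2: float

    def to_vector(self) -> np.ndarray:
        return np.array([self.v1, self.v2, self.u1, self.u2], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "SignalBus":
        v = np.asarray(vec, dtype=float)
        if v.shape != (4,):
            raise ValueError(f"SignalBus vector must have length 4, got shape {v.shape}")
        return cls(*v.tolist())


def signals_from_states(cancer: CancerState, fibro: FibroblastState) -> SignalBus:
    """Read the four transmitted signals off the two agent states."""
    return SignalBus(v1=cancer.x1, v2=cancer.x3, u1=fibro.z1, u2=fibro.z2)


@dataclass(frozen=True)
class CancerParameters:
    """Rate constants of the cancer-cell dynamics (hour^-1).

    The defaults are the published estimates for this model: k21 LIF
    expression downstream of SMAD, k1 LIF degradation, k2 SMAD expression,
    k24 SMAD7 expression, k32 TGFB autoinduction, k3 TGFB degradation,
    k42 SMAD7 inhibition of SMAD transcription (linear in SMAD7), k4 SMAD7
    degradation, k52 SNAIL expression, k5 SNAIL degradation.
    """

    k21: float = 0.1
    k1: float = 0.0015
    k2: float = 0.0487
    k24: float = 0.012
    k32: float = 0.502
    k3: float = 0.122
    k42: float = 0.0115
    k4: float = 0.0000805
    k52: float = 0.32
    k5: float = 0.00016

    def __post_init__(self) -> None:
        vals = self.to_dict()
        _require_finite("CancerParameters", vals.values())
        bad = {k: v for k, v in vals.items() if v < 0}
        if bad:
            raise ValueError(f"rate constants must be non-negative, got {bad}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CancerParameters":
        return cls(**d)


@dataclass(frozen=True)
class CouplingCoefficients:
    """Coefficients of the input-dependent rate h = m0 + m1*LIF + m2*TGFB + m3*LIF*TGFB.

    m0 is the baseline rate (hour^-1); m1, m2 are the impact factors of the
    received LIF and TGFB signals and m3 the impact of their crosstalk.
    Signs are unconstrained: an inhibitory dependence is a negative m.
    """

    m0: float
    m1: float
    m2: float
    m3: float

    def __post_init__(self) -> None:
        _require_finite("CouplingCoefficients", (self.m0, self.m1, self.m2, self.m3))

    def to_dict(self) -> dict:
        return {"m0": self.m0, "m1": self.m1, "m2": self.m2, "m3": self.m3}

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingCoefficients":
        return cls(**d)


# Reconstructed defaults for the three input-dependent fibroblast rates.
# The published model fitted these by Kalman filtering but the fitted values
# are not part of the public record, so these were calibrated once against
# the qualitative switching signature (SLIT2 rises then falls; CXCL12 and
# SNAIL end higher than they start) and then frozen.  They are NOT fitted
# values; treat them as a documented reconstruction.
_DEFAULT_H11 = CouplingCoefficients(m0=0.053, m1=-0.01, m2=-0.05, m3=-0.1)
_DEFAULT_H32 = CouplingCoefficients(m0=0.05, m1=0.5, m2=0.5, m3=0.0)
_DEFAULT_H12 = CouplingCoefficients(m0=0.05, m1=-0.5, m2=-0.5, m3=-1.0)


@dataclass(frozen=True)
class FibroblastParameters:
    """Rate constants of the fibroblast dynamics (hour^-1).

    Six fixed rates (defaults are the published values): h1 SLIT2
    degradation, h34 SMAD7 expression downstream of SMAD, h54 SMAD7
    expression downstream of JAK/STAT, h42 SMAD7 inhibition of SMAD
    transcription (linear in SMAD7), h4 SMAD7 degradation, h35 JAK/STAT
    enhancement of SMAD transcription.  The three input-dependent rates
    h11 (SLIT2 expression), h32 (CXCL12 expression) and h12 (SLIT2
    inhibition of CXCL12) are bilinear polynomials in the received LIF and
    TGFB signals, parameterised by :class:`CouplingCoefficients`.

    ``floor_rates`` floors the three polynomial rates at zero (a negative
    expression rate has no physical meaning); switch it off to study the
    raw unfloored polynomials.
    """

    h1: float = 0.0514
    h34: float = 0.00008
    h54: float = 0.01
    h42: float = 0.00015
    h4: float = 0.109
    h35: float = 0.0013
    h11: CouplingCoefficients = field(default=_DEFAULT_H11)
    h32: CouplingCoefficients = field(default=_DEFAULT_H32)
    h12: CouplingCoefficients = field(default=_DEFAULT_H12)
    floor_rates: bool = True

    def __post_init__(self) -> None:
        fixed = {k: getattr(self, k) for k in ("h1", "h34", "h54", "h42", "h4", "h35")}
        _require_finite("FibroblastParameters", fixed.values())
        bad = {k: v for k, v in fixed.items() if v < 0}
        if bad:
            raise ValueError(f"fixed rate constants must be non-negative, got {bad}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("h1", "h34", "h54", "h42", "h4", "h35")}
        d["h11"] = self.h11.to_dict()
        d["h32"] = self.h32.to_dict()
        d["h12"] = self.h12.to_dict()
        d["floor_rates"] = self.floor_rates
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FibroblastParameters":
        d = dict(d)
        for key in ("h11", "h32", "h12"):
            if key in d and isinstance(d[key], dict):
                d[key] = CouplingCoefficients.from_dict(d[key])
        return cls(**d)


def mass_action_rate(k: float, concentrations: Sequence[float]) -> float:
    """Law-of-mass-action rate: ``k`` times the product of the concentrations.

    For a reaction A + B -> C the rate of product formation is k[A][B]; the
    one-reactant case k[A] is a first-order (e.g. degradation) term.

    Raises
    ------
    ValueError
        If ``concentrations`` is empty or any value is non-finite.
    """
    conc = list(concentrations)
    if len(conc) == 0:
        raise ValueError("mass_action_rate requires at least one concentration")
    _require_finite("mass_action_rate", [k, *conc])
    return k * math.prod(conc)


def coupling_rate(
    m: CouplingCoefficients, lif: float, tgfb: float, floor: bool = False
) -> float:
    """Evaluate the input-dependent rate h = m0 + m1*lif + m2*tgfb + m3*lif*tgfb.

    ``lif`` and ``tgfb`` are the fibroblast's received signals (the cancer
    cell's V1 and V2).  With ``floor=True`` the result is clipped below at
    zero, the non-negative-rate policy used by default in simulation.
    """
    _require_finite("coupling_rate inputs", (lif, tgfb))
    h = m.m0 + m.m1 * lif + m.m2 * tgfb + m.m3 * lif * tgfb
    if floor and h < 0.0:
        return 0.0
    return h


def _as_vec5(state, cls) -> np.ndarray:
    if isinstance(state, (CancerState, FibroblastState)):
        return state.to_vector()
    v = np.asarray(state, dtype=float)
    if v.shape != (5,):
        raise ValueError(f"state vector must have length 5, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"state must be finite, got {v!r}")
    return v


def cancer_rhs(
    state: CancerState | Sequence[float],
    inputs: Tuple[float, float],
    params: CancerParameters | None = None,
) -> np.ndarray:
    """Time derivative of the cancer-cell state (a.u./hour).

    ``inputs`` is the pair (u1, u2) of received fibroblast signals: SLIT2,
    which enters the TGFB balance with a minus sign (tumor-suppressive),
    and CXCL12, which enters with a plus sign (tumor-promoting).

    The five balances are::

        dx1/dt = k21*x1*x2 - k1*x1                               (LIF)
        dx2/dt = k2*x2 - k21*x1*x2 - k24*x2*x4 - k32*x2*x3
                 - k42*x4 - k52*x2*x5                            (SMAD)
        dx3/dt = u2 - u1 + k32*x2*x3 - k3*x3                     (TGFB)
        dx4/dt = k24*x2*x4 - k4*x4                               (SMAD7)
        dx5/dt = k52*x2*x5 - k5*x5                               (SNAIL)
    """
    if params is None:
        params = CancerParameters()
    x1, x2, x3, x4, x5 = _as_vec5(state, CancerState)
    u1, u2 = float(inputs[0]), float(inputs[1])
    _require_finite("cancer_rhs inputs", (u1, u2))
    p = params
    return np.array(
        [
            p.k21 * x1 * x2 - p.k1 * x1,
            p.k2 * x2 - p.k21 * x1 * x2 - p.k24 * x2 * x4 - p.k32 * x2 * x3
            - p.k42 * x4 - p.k52 * x2 * x5,
            u2 - u1 + p.k32 * x2 * x3 - p.k3 * x3,
            p.k24 * x2 * x4 - p.k4 * x4,
            p.k52 * x2 * x5 - p.k5 * x5,
        ]
    )


def fibroblast_rhs(
    state: FibroblastState | Sequence[float],
    inputs: Tuple[float, float],
    params: FibroblastParameters | None = None,
) -> np.ndarray:
    """Time derivative of the fibroblast state (a.u./hour).

    ``inputs`` is the pair (v1, v2) of received cancer-cell signals (LIF,
    TGFB).  v2 initiates the SMAD branch, v1 the JAK/STAT branch, and both
    modulate the rates h11, h32, h12 through the coupling polynomials.

    The five balances are::

        dz1/dt = h11*z1 - h1*z1                                  (SLIT2)
        dz2/dt = h32*z2*z3 - h12*z2*z1                           (CXCL12)
        dz3/dt = -h32*z2*z3 - h34*z3*z4 - h42*z4 + h35*z3*z5 + v2  (SMAD)
        dz4/dt = h54*z4*z5 + h34*z3*z4 - h4*z4                   (SMAD7)
        dz5/dt = -h54*z4*z5 - h35*z3*z5 + v1                     (JAK/STAT)
    """
    if params is None:
        params = FibroblastParameters()
    z1, z2, z3, z4, z5 = _as_vec5(state, FibroblastState)
    v1, v2 = float(inputs[0]), float(inputs[1])
    _require_finite("fibroblast_rhs inputs", (v1, v2))
    p = params
    h11 = coupling_rate(p.h11, v1, v2, floor=p.floor_rates)
    h32 = coupling_rate(p.h32, v1, v2, floor=p.floor_rates)
    h12 = coupling_rate(p.h12, v1, v2, floor=p.floor_rates)
    return np.array(
        [
            h11 * z1 - p.h1 * z1,
            h32 * z2 * z3 - h12 * z2 * z1,
            -h32 * z2 * z3 - p.h34 * z3 * z4 - p.h42 * z4 + p.h35 * z3 * z5 + v2,
            p.h54 * z4 * z5 + p.h34 * z3 * z4 - p.h4 * z4,
            -p.h54 * z4 * z5 - p.h35 * z3 * z5 + v1,
        ]
    )


def save_parameters(
    path, cancer: CancerParameters, fibro: FibroblastParameters
) -> None:
    """Write both parameter sets to a JSON file keyed by the field symbols."""
    payload = {"cancer": cancer.to_dict(), "fibroblast": fibro.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_parameters(path) -> Tuple[CancerParameters, FibroblastParameters]:
    """Read parameter sets from a JSON file written by :func:`save_parameters`."""
    with open(path) as fh:
        payload = json.load(fh)
    return (
        CancerParameters.from_dict(payload["cancer"]),
        FibroblastParameters.from_dict(payload["fibroblast"]),
    )


def load_default_parameters() -> Tuple[CancerParameters, FibroblastParameters]:
    """Load the packaged default parameter file (published rate constants plus
    the reconstructed coupling coefficients)."""
    ref = resources.files("cafswitch.data").joinpath("default_parameters.json")
    with ref.open() as fh:
        payload = json.load(fh)
    return (
        CancerParameters.from_dict(payload["cancer"]),
        FibroblastParameters.from_dict(payload["fibroblast"]),
    )
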