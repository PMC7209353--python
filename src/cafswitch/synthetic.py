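"""Synthetic gene-expression-like observations of the coupled model.

The estimation data this package is designed around are sparse microarray
time courses: a 4-gene x 4-time-point set (SMAD, SMAD7, SLIT2, CXCL12 --
the default fibroblast observation map) for filtering, and a denser
validation series of LIF, SLIT2, CXCL12 and SNAIL.  This module generates
statistical stand-ins for both from a ground-truth simulation: it is
first-class, tested code, and every generator is a pure function of
(scenario, seed).

Values live in model concentration units (a.u.); no microarray
normalization pipeline is emulated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    CancerParameters,
    CancerState,
    FibroblastParameters,
    FibroblastState,
    load_default_parameters,
)
from .simulate import SPECIES_INDEX, SimulationConfig, Trajectory, simulate

__all__ = [
    "ObservationSet",
    "ScenarioPreset",
    "generate_truth",
    "sample_observations",
    "sparse_estimation_set",
    "validation_series",
    "ESTIMATION_SPECIES",
    "ESTIMATION_TIMES",
    "VALIDATION_SPECIES",
    "VALIDATION_TIMES",
]

#: The four observed genes of the sparse estimation fixture, resolved on the
#: default (fibroblast) observation map, and its four sampling times (hours).
ESTIMATION_SPECIES = ("SMAD", "SMAD7", "SLIT2", "CXCL12")
ESTIMATION_TIMES = (2.0, 4.0, 8.0, 12.0)

#: The validation time-course species and its sampling grid (hours), a
#: typical TGFB-stimulation time-course design.
VALIDATION_SPECIES = ("LIF", "SLIT2", "CXCL12", "SNAIL")
VALIDATION_TIMES = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 72.0)

_NOISE_TYPES = ("none", "additive-gaussian", "multiplicative-lognormal")


@dataclass
class ObservationSet:
    """Noisy samples of named species at discrete times.

    ``values`` has shape (n_species, n_times): exactly one value per
    (species, time) pair.  The noise descriptor records how the values were
    perturbed; ``provenance`` distinguishes generated data ("synthetic")
    from externally supplied measurements ("external").
    """

    species: Tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    noise_type: str = "none"
    noise_sigma: float = 0.0
    seed: Optional[int] = None
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if self.values.shape != (len(self.species), len(self.times)):
            raise ValueError(
                f"values must have shape (n_species, n_times) = "
                f"({len(self.species)}, {len(self.times)}), got {self.values.shape}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_type not in _NOISE_TYPES:
            raise ValueError(f"unknown noise type {self.noise_type!r}")

    def series(self, species: str) -> np.ndarray:
        if species not in self.species:
            raise KeyError(f"species {species!r} not in observation set")
        return self.values[self.species.index(species)]

    def to_csv(self, path) -> None:
        """Write in the long `time,species,value` dialect."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "species", "value"])
            for j, t in enumerate(self.times):
                for i, s in enumerate(self.species):
                    w.writerow([repr(float(t)), s, repr(float(self.values[i, j]))])

    @classmethod
    def from_csv(cls, path, provenance: str = "external") -> "ObservationSet":
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            header = next(r)
            if [c.strip() for c in header] != ["time", "species", "value"]:
                raise ValueError(f"unexpected observation CSV header {header!r}")
            records = [(float(t), s, float(v)) for t, s, v in r]
        times = sorted({t for t, _, _ in records})
        species = tuple(dict.fromkeys(s for _, s, _ in records))
        values = np.full((len(species), len(times)), np.nan)
        for t, s, v in records:
            values[species.index(s), times.index(t)] = v
        if np.any(np.isnan(values)):
            raise ValueError("observation CSV is not a complete species x time grid")
        return cls(species=species, times=np.array(times), values=values,
                   provenance=provenance)


@dataclass
class ScenarioPreset:
    """A named bundle of generating conditions for synthetic data.

    The default preset is the packaged scenario: published rate constants,
    reconstructed coupling coefficients, every species seeded at 0.01 a.u.,
    a 0-72 h horizon, and multiplicative-lognormal noise with sigma = 0.1
    (the character of expression-array noise).
    """

    name: str = "default"
    cancer_params: Optional[CancerParameters] = None
    fibro_params: Optional[FibroblastParameters] = None
    initial_cancer: Optional[CancerState] = None
    initial_fibro: Optional[FibroblastState] = None
    t_start: float = 0.0
    t_end: float = 72.0
    observed_species: Tuple[str, ...] = ESTIMATION_SPECIES
    observation_times: Tuple[float, ...] = ESTIMATION_TIMES
    noise_sigma: float = 0.1
    noise_type: str = "multiplicative-lognormal"

    def __post_init__(self) -> None:
        for s in self.observed_species:
            if s not in SPECIES_INDEX:
                raise ValueError(f"unknown species name {s!r} in scenario")
        if self.noise_type not in _NOISE_TYPES:
            raise ValueError(f"unknown noise type {self.noise_type!r}")

    def resolved_params(self) -> Tuple[CancerParameters, FibroblastParameters]:
        cp, fp = (self.cancer_params, self.fibro_params)
        if cp is None or fp is None:
            dcp, dfp = load_default_parameters()
            cp = cp if cp is not None else dcp
            fp = fp if fp is not None else dfp
        return cp, fp

    def simulation_config(self, **overrides) -> SimulationConfig:
        kw = dict(t_start=self.t_start, t_end=self.t_end)
        if self.initial_cancer is not None:
            kw["initial_cancer"] = self.initial_cancer
        if self.initial_fibro is not None:
            kw["initial_fibro"] = self.initial_fibro
        kw.update(overrides)
        return SimulationConfig(**kw)


def generate_truth(scenario: Optional[ScenarioPreset] = None) -> Trajectory:
    """Simulate the deterministic ground-truth trajectory of a scenario."""
    sc = scenario if scenario is not None else ScenarioPreset()
    cp, fp = sc.resolved_params()
    return simulate(sc.simulation_config(), cp, fp)


def sample_observations(
    traj: Trajectory,
    species: Sequence[str],
    times: Sequence[float],
    noise_sigma: float = 0.0,
    noise_type: str = "additive-gaussian",
    seed: Optional[int] = None,
) -> ObservationSet:
    """Sample a trajectory at given species/times and add measurement noise.

    Values are linearly interpolated onto the requested times (bit-exact at
    trajectory grid points).  Noise models: "additive-gaussian" adds
    N(0, sigma^2); "multiplicative-lognormal" multiplies by a mean-one
    lognormal factor exp(sigma*Z - sigma^2/2).  Reproducible: the same seed
    always yields the same set.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < traj.times[0] - 1e-12) or np.any(t > traj.times[-1] + 1e-12):
        raise ValueError("requested observation times fall outside the trajectory span")
    clean = np.vstack([traj.interp(s, t) for s in species])
    # scalar sigma, or one sigma per species (e.g. a fraction of each range)
    sig = np.broadcast_to(
        np.reshape(np.asarray(noise_sigma, dtype=float), (-1, 1)), clean.shape
    )
    if np.any(sig < 0):
        raise ValueError("noise_sigma must be non-negative")
    if np.all(sig == 0.0) or noise_type == "none":
        values = clean
        noise_type = "none"
    else:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(clean.shape)
        if noise_type == "additive-gaussian":
            values = clean + sig * z
        elif noise_type == "multiplicative-lognormal":
            values = clean * np.exp(sig * z - sig**2 / 2.0)
        else:
            raise ValueError(f"unknown noise type {noise_type!r}")
    return ObservationSet(
        species=tuple(species), times=t, values=values,
        noise_type=noise_type,
        noise_sigma=float(np.max(sig)), seed=seed, provenance="synthetic",
    )


def sparse_estimation_set(
    seed: Optional[int] = None,
    scenario: Optional[ScenarioPreset] = None,
    truth: Optional[Trajectory] = None,
) -> ObservationSet:
    """The sparse 4-gene x 4-time-point estimation fixture.

    Observes fibroblast SMAD, SMAD7, SLIT2 and CXCL12 at (2, 4, 8, 12) h
    of the default scenario under its noise model -- the sparsity regime
    the hybrid UKF is meant to cope with.
    """
    sc = scenario if scenario is not None else ScenarioPreset()
    tr = truth if truth is not None else generate_truth(sc)
    return sample_observations(
        tr, ESTIMATION_SPECIES, ESTIMATION_TIMES,
        noise_sigma=sc.noise_sigma, noise_type=sc.noise_type, seed=seed,
    )


def validation_series(
    seed: Optional[int] = None,
    noise_sigma: float = 0.1,
    noise_type: str = "multiplicative-lognormal",
    scenario: Optional[ScenarioPreset] = None,
    truth: Optional[Trajectory] = None,
) -> ObservationSet:
    """A multi-point validation time course of LIF, SLIT2, CXCL12 and SNAIL.

    Emulates a stimulation time-course dataset on the default 8-point grid
    spanning 0.5-72 h; with ``noise_sigma=0`` it reproduces the truth
    trajectory at the grid exactly.
    """
    sc = scenario if scenario is not None else ScenarioPreset()
    tr = truth if truth is not None else generate_truth(sc)
    return sample_observations(
        tr, VALIDATION_SPECIES, VALIDATION_TIMES,
        noise_sigma=noise_sigma, noise_type=noise_type, seed=seed,
    )
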