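"""Validation metrics and the end-to-end pipeline.

The validation statistic is the root of the mean squared deviation between
simulation samples and data samples, kept under its field name
"normalized RMSE" even though, as defined, no range or mean normalization
is applied; an optional range-normalized variant (divide by the data
max-min) is available but off by default.
"""

from __future__ import annotations

import datetime
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import yaml

from .model_core import load_default_parameters
from .simulate import SPECIES_INDEX, SimulationConfig, Trajectory, detect_switch, simulate
from .synthetic import (
    ObservationSet,
    ScenarioPreset,
    generate_truth,
    sample_observations,
)

__all__ = [
    "ComparisonReport",
    "normalized_rmse",
    "compare",
    "run_pipeline",
    "load_pipeline_config",
]


def normalized_rmse(sim_samples: Sequence[float], data_samples: Sequence[float]) -> float:
    """Root-mean-square deviation between paired simulation and data samples.

    Returns sqrt((1/n) * sum_i (sim_i - data_i)^2).  Despite the
    conventional name no further normalization is applied.
    """
    x = np.asarray(sim_samples, dtype=float)
    d = np.asarray(data_samples, dtype=float)
    if x.ndim != 1 or d.ndim != 1 or x.shape != d.shape:
        raise ValueError("sim and data sample sequences must have identical 1-d shapes")
    if len(x) == 0:
        raise ValueError("normalized_rmse requires at least one sample")
    return float(np.sqrt(np.mean((x - d) ** 2)))


@dataclass
class ComparisonReport:
    """Per-species simulation-vs-data agreement summary.

    ``pairs`` maps each species to its matched (simulation, data) value
    arrays at the observation times; ``overall_pass`` is set only when a
    threshold was configured.
    """

    per_species_rmse: Dict[str, float]
    n_samples: Dict[str, int]
    pairs: Dict[str, Tuple[np.ndarray, np.ndarray]]
    threshold: Optional[float] = None
    overall_pass: Optional[bool] = None
    range_normalized: bool = False

    def to_dict(self) -> dict:
        return {
            "per_species_rmse": {k: float(v) for k, v in self.per_species_rmse.items()},
            "n_samples": dict(self.n_samples),
            "threshold": self.threshold,
            "overall_pass": self.overall_pass,
            "range_normalized": self.range_normalized,
        }


def compare(
    traj: Trajectory,
    obs: ObservationSet,
    species: Optional[Sequence[str]] = None,
    range_normalize: bool = False,
    threshold: Optional[float] = None,
) -> ComparisonReport:
    """Interpolate a simulation onto observation times and score each species.

    ``species`` restricts the report to a subset (default: every observed
    species).  ``range_normalize`` divides each species' RMSE by the data
    max-min (optional variant; plain RMSE by default).  When ``threshold``
    is given, ``overall_pass`` is True iff every reported RMSE is below it.
    """
    wanted = tuple(species) if species is not None else obs.species
    rmse: Dict[str, float] = {}
    ns: Dict[str, int] = {}
    pairs: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for sp in wanted:
        if sp not in obs.species:
            raise KeyError(f"species {sp!r} is absent from the observation set")
        if sp not in SPECIES_INDEX:
            raise KeyError(f"species {sp!r} is absent from the trajectory")
        sim = traj.interp(sp, obs.times)
        data = obs.series(sp)
        val = normalized_rmse(sim, data)
        if range_normalize:
            span = float(np.ptp(data))
            if span == 0.0:
                raise ValueError(f"cannot range-normalize constant data for {sp!r}")
            val /= span
        rmse[sp] = val
        ns[sp] = len(data)
        pairs[sp] = (sim, data)
    overall = None
    if threshold is not None:
        overall = all(v <= threshold for v in rmse.values())
    return ComparisonReport(
        per_species_rmse=rmse, n_samples=ns, pairs=pairs,
        threshold=threshold, overall_pass=overall, range_normalized=range_normalize,
    )


# ---------------------------------------------------------------------------
# pipeline

_DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "cafswitch_run",
    "scenario": {},
    "simulate": {},
    "estimate": {
        "estimate_names": ["h1"],
        "passes": 1,
        "observation": {},
    },
    "validate": {"noise_sigma": 0.1},
}


def load_pipeline_config(path) -> dict:
    """Read a YAML/JSON pipeline config and fill in defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("pipeline config must be a mapping")
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _scenario_from_config(sc_cfg: dict) -> ScenarioPreset:
    from .model_core import CancerState, FibroblastState

    kw = dict(sc_cfg)
    for key, cls in (("initial_cancer", CancerState), ("initial_fibro", FibroblastState)):
        if key in kw and kw[key] is not None and not isinstance(kw[key], cls):
            kw[key] = cls.from_vector(kw[key])
    for key in ("observed_species", "observation_times"):
        if key in kw and kw[key] is not None:
            kw[key] = tuple(kw[key])
    return ScenarioPreset(**kw)


def run_pipeline(config_path, out_dir=None, seed: Optional[int] = None) -> int:
    """Run generate -> simulate -> estimate -> validate and write artifacts.

    Writes trajectory.csv, observations.csv, estimation.json,
    comparison.json and run.log into the output directory.  Returns 0 on
    success, non-zero on invalid config or stage failure (partial artifacts
    are left in place).  Deterministic for a fixed config and seed.
    """
    from . import __version__
    from .hukf import UkfSettings, estimate_parameters, joint_parameter_model

    log_lines = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now(datetime.timezone.utc).strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
        log_lines.append(f"{stamp} {msg}")

    out = None
    try:
        cfg = load_pipeline_config(config_path)
        run_seed = int(seed if seed is not None else cfg.get("seed", 0))
        out = Path(out_dir if out_dir is not None else cfg["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        log(f"cafswitch {__version__} (python {sys.version.split()[0]}) seed={run_seed}")
        log(f"config: {json.dumps(cfg, sort_keys=True, default=str)}")

        scenario = _scenario_from_config(cfg.get("scenario", {}))
        sim_cfg = scenario.simulation_config(**cfg.get("simulate", {}))
        cp, fp = scenario.resolved_params()

        log("stage simulate: integrating coupled system")
        traj = simulate(sim_cfg, cp, fp)
        traj.to_csv(out / "trajectory.csv")
        switch = detect_switch(traj)
        log(f"switch report: {json.dumps(switch.to_dict(), sort_keys=True)}")

        log("stage generate-data: sampling estimation observations")
        est_cfg = cfg["estimate"]
        obs_kw = est_cfg.get("observation", {})
        obs = sample_observations(
            traj,
            obs_kw.get("species", scenario.observed_species),
            obs_kw.get("times", scenario.observation_times),
            noise_sigma=obs_kw.get("noise_sigma", scenario.noise_sigma),
            noise_type=obs_kw.get("noise_type", scenario.noise_type),
            seed=run_seed,
        )
        obs.to_csv(out / "observations.csv")

        log("stage estimate: hybrid UKF")
        settings = UkfSettings(**est_cfg.get("settings", {}))
        model = joint_parameter_model(cp, fp)
        result = estimate_parameters(
            obs,
            model,
            est_cfg.get("estimate_names", ["h1"]),
            settings=settings,
            initial_state=np.concatenate(
                [sim_cfg.initial_cancer.to_vector(), sim_cfg.initial_fibro.to_vector()]
            ),
            passes=est_cfg.get("passes", 1),
        )
        report = result.to_dict()
        report["settings"] = {
            "alpha": settings.alpha, "beta": settings.beta, "kappa": settings.kappa,
            "q_state": settings.q_state, "q_param": settings.q_param,
            "r_rel": settings.r_rel, "ode_step": settings.ode_step,
            "propagator": settings.propagator,
        }
        with open(out / "estimation.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log(f"estimation: total_error={result.total_error:.6g}")

        log("stage validate: comparing simulation with validation series")
        val_cfg = cfg.get("validate", {})
        from .synthetic import VALIDATION_SPECIES, VALIDATION_TIMES

        val_times = val_cfg.get("times")
        if val_times is None:
            # keep the validation grid inside the simulated horizon
            val_times = [t for t in VALIDATION_TIMES if t <= sim_cfg.t_end]
        vobs = sample_observations(
            traj,
            val_cfg.get("val_species", list(VALIDATION_SPECIES)),
            val_times,
            noise_sigma=val_cfg.get("noise_sigma", 0.1),
            noise_type=val_cfg.get("noise_type", "multiplicative-lognormal"),
            seed=run_seed + 1,
        )
        cmp_report = compare(
            traj, vobs,
            species=val_cfg.get("species"),
            range_normalize=val_cfg.get("range_normalize", False),
            threshold=val_cfg.get("threshold"),
        )
        payload = cmp_report.to_dict()
        payload["switch"] = switch.to_dict()
        with open(out / "comparison.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log("pipeline finished")
        return 0
    except Exception as exc:  # stage failure: report, keep partial artifacts
        log(f"ERROR: {type(exc).__name__}: {exc}")
        print(f"pipeline failed: {exc}", file=sys.stderr)
        return 1
    finally:
        if out is not None and out.exists():
            with open(out / "run.log", "w") as fh:
                fh.write("\n".join(log_lines) + "\n")
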