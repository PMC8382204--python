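"""Configuration files, trajectory I/O and the synthetic-fixture generator.

Configs are YAML key-trees.  Times are minutes; circadian entries may carry
an explicit ``_h`` suffix (hours) and are converted on load — unit mistakes
are the main user hazard, so units are always explicit.  Every run's
effective configuration is echoed into output file headers so any output can
be regenerated from its own header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import modelzoo
from .dynalysis import Trajectory
from .modelzoo import (DelaySpec, EmbryonicParams, MassActionParams,
                       ModelSystem, ParameterSchedule, ScheduleWindow,
                       SomaticParams, build_embryonic, build_interlinked,
                       build_mass_action, embryonic_nondim)
from .switchcore import ResponseCurve, ScalingFunction, SwitchModule

__all__ = [
    "ModelConfig",
    "FixtureSpec",
    "ConfigError",
    "load_config",
    "save_config",
    "build_from_config",
    "write_trajectory",
    "read_trajectory",
    "make_fixture",
]

SYSTEM_NAMES = ("ia", "ib", "ii", "iiia", "iiib", "iiic", "interlinked",
                "mass_action")

_SOLVER_DEFAULTS = {"rtol": 1e-8, "atol": 1e-10, "t_span": [0.0, 100.0],
                    "n_out": 2001, "method": "LSODA"}
_ANALYSIS_DEFAULTS = {"transient_fraction": 0.5, "min_peaks": 5,
                      "height_tol": 0.01, "min_amp_frac": 0.01,
                      "cv_tol": 0.05, "mismatch_tol": 0.01,
                      "ratio_tol": 0.02}


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    system: str
    params: dict[str, Any] = field(default_factory=dict)
    solver: dict[str, Any] = field(default_factory=dict)
    analysis: dict[str, Any] = field(default_factory=dict)
    schedule: list[dict[str, Any]] = field(default_factory=list)
    seed: int = 0
    defaulted: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"system": self.system, "params": self.params,
                "solver": self.solver, "analysis": self.analysis,
                "schedule": self.schedule, "seed": self.seed}


_KNOWN_TOP = {"system", "params", "solver", "analysis", "schedule", "seed"}


def _convert_hours(d: dict[str, Any]) -> dict[str, Any]:
    out = {}
    for k, v in d.items():
        if k.endswith("_h"):
            out[k[:-2] + "_min"] = float(v) * 60.0
        else:
            out[k] = v
    return out


def load_config(source) -> ModelConfig:
    """Parse and validate a model configuration (path or YAML string/stream).

    Unknown keys are rejected; defaults for the named system are filled in
    and recorded in ``config.defaulted``.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" in text or ":" in text and not _looks_like_path(text):
            raw = yaml.safe_load(text)
        else:
            with open(text) as fh:
                raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _KNOWN_TOP
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    system = raw.get("system")
    if system not in SYSTEM_NAMES:
        raise ConfigError(
            f"unknown system {system!r}; expected one of {SYSTEM_NAMES}")
    params = _convert_hours(dict(raw.get("params") or {}))
    solver = {**_SOLVER_DEFAULTS, **_convert_hours(dict(raw.get("solver") or {}))}
    analysis = {**_ANALYSIS_DEFAULTS, **dict(raw.get("analysis") or {})}
    schedule = list(raw.get("schedule") or [])
    for w in schedule:
        missing = {"t_start", "t_end", "path", "value"} - set(w)
        if missing:
            raise ConfigError(f"schedule window lacks keys {sorted(missing)}")
    cfg = ModelConfig(system=system, params=params, solver=solver,
                      analysis=analysis, schedule=schedule,
                      seed=int(raw.get("seed", 0)))
    build_from_config(cfg)  # validates parameter domains & fills defaults
    return cfg


def _looks_like_path(text: str) -> bool:
    return "\n" not in text and (text.endswith((".yml", ".yaml"))
                                 or "/" in text)


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _somatic_from_params(p: Mapping[str, Any]) -> SomaticParams:
    known = set(vars(SomaticParams()).keys())
    unknown = set(p) - known
    if unknown:
        raise ConfigError(f"unknown interlinked parameters: {sorted(unknown)}")
    try:
        return SomaticParams(**p)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def build_from_config(cfg: ModelConfig) -> ModelSystem:
    """Instantiate the configured ModelSystem with defaults filled in."""
    p = dict(cfg.params)
    name = cfg.system
    try:
        if name == "interlinked":
            sp = _somatic_from_params(p)
            cfg.defaulted = {k: v for k, v in vars(sp).items() if k not in p}
            system = build_interlinked(sp)
        elif name == "mass_action":
            if "b_syn" not in p or "b_deg" not in p:
                raise ConfigError(
                    "mass_action requires b_syn and b_deg (no published "
                    "defaults exist for the oscillatory time traces)")
            mp = MassActionParams(**p)
            cfg.defaulted = {k: v for k, v in vars(mp).items() if k not in p}
            system = build_mass_action(mp)
        else:
            kwargs = {}
            if name == "ia":
                kwargs = dict(alpha_apc=0.0)
            elif name == "iiia":
                kwargs = dict(alpha_cdk=0.0)
            elif name in ("iiib", "iiic"):
                kwargs = dict(alpha_cdk=p.get("alpha_cdk", 5.0))
            defaults = dict(c=0.5, eps_apc=0.01, n=15.0, r=0.5)
            defaults.update(kwargs)
            allowed = {"c", "alpha_apc", "alpha_cdk", "eps_apc", "eps_cdk",
                       "n", "r", "d", "tau1_min", "tau2_min", "p_delay"}
            unknown = set(p) - allowed
            if unknown:
                raise ConfigError(f"unknown parameters: {sorted(unknown)}")
            merged = {**defaults, **{k: v for k, v in p.items()
                                     if k in ("c", "alpha_apc", "alpha_cdk",
                                              "eps_apc", "eps_cdk", "n", "r",
                                              "d")}}
            if name == "ia":
                merged["alpha_apc"] = 0.0
            if name == "iiib":
                merged.setdefault("alpha_apc", 0.0)
            delay = None
            if name == "ii":
                tau1 = float(p.get("tau1_min", 0.0))
                tau2 = float(p.get("tau2_min", tau1))
                delay = DelaySpec(tau1=tau1, tau2=tau2,
                                  p=float(p.get("p_delay", 5.0)))
            ep = embryonic_nondim(delay=delay, **merged)
            cfg.defaulted = {k: v for k, v in merged.items() if k not in p}
            system = build_embryonic(ep)
        if cfg.schedule:
            windows = tuple(
                ScheduleWindow(float(w["t_start"]), float(w["t_end"]),
                               str(w["path"]), float(w["value"]),
                               str(w.get("mode", "set")))
                for w in cfg.schedule)
            system = system.with_schedule(ParameterSchedule(windows))
        return system
    except (ValueError, KeyError) as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# trajectory I/O


def write_trajectory(traj: Trajectory, path) -> None:
    """TSV with a commented header echoing the effective configuration."""
    with open(path, "w") as fh:
        fh.write("# switchcycle trajectory (time in minutes)\n")
        for k, v in traj.meta.items():
            fh.write(f"# {k} = {v!r}\n")
        df = pd.DataFrame({"time_min": traj.t})
        for i, nm in enumerate(traj.names):
            df[nm] = traj.y[i]
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    meta: dict[str, Any] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if " = " in line:
                k, v = line[1:].split(" = ", 1)
                meta[k.strip()] = v.strip()
            body = i + 1
        else:
            break
    try:
        df = pd.read_csv(io.StringIO("".join(lines[body:])), sep="\t",
                         float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"malformed trajectory file near line {body + 1}: "
                         f"{exc}") from exc
    if "time_min" not in df.columns:
        raise ValueError("trajectory file lacks the 'time_min' column")
    names = tuple(c for c in df.columns if c != "time_min")
    if not names:
        raise ValueError("trajectory file lacks state columns")
    y = np.vstack([df[c].to_numpy() for c in names])
    return Trajectory(df["time_min"].to_numpy(), y, names, meta)


# ---------------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic synthetic data for testing the analysis machinery.

    Kinds: ``response_curve`` (S-curve from a known scaling function, with
    optional seeded multiplicative noise on the input axis),
    ``periodic_series``, ``damped_series`` (exponential decay per cycle),
    ``quasiperiodic_series`` (two incommensurate sinusoids) and
    ``sawtooth_series``.  Identical spec + seed gives bit-identical output.
    """

    kind: str
    seed: int = 0
    noise: float = 0.0
    # series parameters
    period: float = 100.0
    period2: float = 100.0 * np.sqrt(2.0)
    n_cycles: float = 20.0
    samples_per_cycle: int = 200
    amplitude: float = 1.0
    offset: float = 0.0
    decay_per_cycle: float = 0.05
    # response-curve parameters
    xi: Optional[ScalingFunction] = None
    K: float = 1.0
    n: float = 15.0
    correction: float = 1.0
    n_points: int = 200

    def __post_init__(self) -> None:
        kinds = ("response_curve", "periodic_series", "damped_series",
                 "quasiperiodic_series", "sawtooth_series")
        if self.kind not in kinds:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def make_fixture(spec: FixtureSpec):
    """Generate the synthetic table/series described by ``spec``.

    Series come back as a Trajectory with one variable ``x`` and ground
    truth in ``meta``; response curves as a ResponseCurve with fold
    annotations computed from the generating module.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "response_curve":
        from .switchcore import SwitchModule, fold_analysis, invert_response

        xi = spec.xi if spec.xi is not None else ScalingFunction(alpha=5.0)
        module = SwitchModule(K=spec.K, n=spec.n, xi=xi,
                              correction=spec.correction)
        ys = np.linspace(1e-3, spec.correction - 1e-3, spec.n_points)
        xs = np.asarray(invert_response(ys, module), dtype=float)
        if spec.noise > 0:
            xs = xs * (1.0 + spec.noise * rng.standard_normal(len(xs)))
        fa = fold_analysis(module)
        branch = np.array([""] * len(ys), dtype=object)
        if fa.bistable:
            y_lo, y_hi = sorted(f[1] for f in fa.folds)
            branch = np.where(ys < y_lo, "lower",
                              np.where(ys > y_hi, "upper", "middle"))
        curve = ResponseCurve(xs, ys, branch, folds=fa.folds)
        return curve
    n_samples = int(spec.n_cycles * spec.samples_per_cycle) + 1
    t = np.linspace(0.0, spec.n_cycles * spec.period, n_samples)
    w = 2.0 * np.pi / spec.period
    if spec.kind == "periodic_series":
        x = spec.offset + spec.amplitude * np.sin(w * t)
        truth = {"period": spec.period}
    elif spec.kind == "damped_series":
        decay_rate = -np.log(1.0 - spec.decay_per_cycle) / spec.period
        x = spec.offset + spec.amplitude * np.exp(-decay_rate * t) * np.sin(w * t)
        truth = {"period": spec.period,
                 "decay_per_cycle": spec.decay_per_cycle}
    elif spec.kind == "quasiperiodic_series":
        w2 = 2.0 * np.pi / spec.period2
        x = spec.offset + spec.amplitude * (np.sin(w * t) + np.sin(w2 * t))
        truth = {"period": spec.period, "period2": spec.period2}
    else:  # sawtooth
        x = spec.offset + spec.amplitude * ((t / spec.period) % 1.0)
        truth = {"period": spec.period}
    if spec.noise > 0:
        x = x + spec.noise * spec.amplitude * rng.standard_normal(len(x))
    return Trajectory(t, x[None, :], ("x",),
                      meta={"fixture": spec.kind, "seed": spec.seed, **truth})
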