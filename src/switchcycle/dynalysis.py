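"""Integration and dynamical analysis of the assembled model systems.

Non-delayed systems are integrated with stiff-capable SciPy solvers (LSODA by
default, Radau/BDF available; the switch relaxation times make every system
here stiff).  Delayed
systems use a fixed-step classical Runge-Kutta scheme with a cubic-Hermite
interpolated solution history, which handles both constant and
state-dependent delays; for ``t`` before the start of integration the lagged
state equals the initial condition (constant history).

Steady states are located by multi-start root finding with stability read off
numerically differentiated Jacobian eigenvalues.  Multivalued steady-state
response curves are traced by secant-predictor pseudo-arclength continuation.
Oscillation period/amplitude come from local extrema of the late (post
transient) part of a trajectory, with small-amplitude and damped oscillations
filtered out.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .modelzoo import ModelSystem
from .switchcore import (FoldAnalysis, ResponseCurve, SwitchModule,
                         fold_analysis, invert_response)

__all__ = [
    "Trajectory",
    "SteadyState",
    "OscillationSummary",
    "PhaseSegmentation",
    "SweepGrid",
    "IntegrationError",
    "InsufficientDataError",
    "integrate",
    "steady_states",
    "continuation_curve",
    "oscillation_metrics",
    "classify_regime",
    "segment_phases",
    "sweep2d",
]

REGIMES = ("Osc", "Bi", "MonoLow", "MonoTop", "Irregular", "Bi+Osc")


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_time: Optional[float] = None):
        super().__init__(message)
        self.last_time = last_time


class InsufficientDataError(ValueError):
    pass


@dataclass
class Trajectory:
    """Time grid (min), state matrix (variables x times) and run metadata."""

    t: np.ndarray
    y: np.ndarray
    names: tuple[str, ...]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.names), len(self.t)):
            raise ValueError("state matrix must be (n_variables, n_times)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("trajectory contains non-finite values")

    def var(self, name: Union[str, int]) -> np.ndarray:
        if isinstance(name, str):
            return self.y[self.names.index(name)]
        return self.y[name]

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class SteadyState:
    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # stable | unstable | marginal
    residual: float
    branch: str = ""

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class OscillationSummary:
    sustained: bool
    period: float  # min; nan when not sustained
    amplitudes: dict[str, float]
    regular: bool
    natural_frequency: float  # rad/min; nan when not sustained
    n_peaks: int = 0
    peak_times: np.ndarray = field(default_factory=lambda: np.array([]))
    rejected_reason: str = ""


@dataclass
class PhaseSegmentation:
    labels: np.ndarray  # per-sample 'G1' | 'S/G2' | 'M'
    per_cycle: list[dict[str, float]]
    mean_durations: dict[str, float]


@dataclass
class SweepGrid:
    axis1_name: str
    axis2_name: str
    table: pd.DataFrame

    def to_tsv(self, path, settings: Optional[Mapping[str, Any]] = None) -> None:
        with open(path, "w") as fh:
            for k, v in (settings or {}).items():
                fh.write(f"# {k} = {v}\n")
            self.table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# integration


def _solve_ode_segment(rhs, t0, t1, y0, t_eval, rtol, atol, method):
    f = lambda t, y: rhs(t, y, None)
    sol = solve_ivp(f, (t0, t1), y0, method=method, rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}",
                               last_time=sol.t[-1] if len(sol.t) else t0)
    return sol


class _DDEHistory:
    """Stored solution nodes with cubic-Hermite interpolation."""

    def __init__(self, t0: float, y0: np.ndarray, f0: np.ndarray, h: float):
        self.t0 = t0
        self.h = h
        self.ts = [t0]
        self.ys = [np.array(y0, dtype=float)]
        self.fs = [np.array(f0, dtype=float)]

    def append(self, t, y, f) -> None:
        self.ts.append(t)
        self.ys.append(np.array(y, dtype=float))
        self.fs.append(np.array(f, dtype=float))

    def __call__(self, tq: float) -> np.ndarray:
        if tq <= self.t0:
            return self.ys[0]
        last = len(self.ts) - 1
        tl = self.ts[last]
        if tq >= tl:
            # lag shorter than the current step: first-order extrapolation
            return self.ys[last] + self.fs[last] * (tq - tl)
        i = min(int((tq - self.t0) / self.h), last - 1)
        # uniform steps, but guard against float rounding at boundaries
        while self.ts[i + 1] < tq:
            i += 1
        while self.ts[i] > tq:
            i -= 1
        ta, tb = self.ts[i], self.ts[i + 1]
        s = (tq - ta) / (tb - ta)
        ya, yb, fa, fb = self.ys[i], self.ys[i + 1], self.fs[i], self.fs[i + 1]
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s * s * (3 - 2 * s)
        h11 = s * s * (s - 1)
        return (h00 * ya + h10 * (tb - ta) * fa + h01 * yb
                + h11 * (tb - ta) * fb)


def _dde_default_step(system: ModelSystem, span: float) -> float:
    eps = [v for k, v in system.params.items() if k.startswith("eps_")]
    h = min(eps) / 5.0 if eps else span / 1e5
    if system.min_delay > 0:
        h = min(h, system.min_delay / 4.0)
    return min(h, span / 200.0)


def _integrate_dde(system, y0, t_span, t_eval, dde_step):
    t0, t1 = t_span
    h = dde_step or _dde_default_step(system, t1 - t0)
    breaks = system.schedule.breakpoints((t0, t1))
    rhs = None
    seg_idx = 0
    out_t = [t0]
    out_y = [np.array(y0, dtype=float)]
    p = system.schedule.params_at(system.params, t0)
    rhs = system.make_rhs(p, system.time_varying)
    hist = _DDEHistory(t0, y0, rhs(t0, np.asarray(y0, float), lambda tq: y0), h)
    t, y = t0, np.array(y0, dtype=float)
    next_break = iter(breaks[1:])
    nb = next(next_break, t1)
    eval_i = 0
    t_eval = np.asarray(t_eval)
    while t < t1 - 1e-12:
        if t >= nb - 1e-12:
            p = system.schedule.params_at(system.params, nb)
            rhs = system.make_rhs(p, system.time_varying)
            nb = next(next_break, t1)
        step = min(h, nb - t, t1 - t)
        k1 = rhs(t, y, hist)
        k2 = rhs(t + step / 2, y + step / 2 * k1, hist)
        k3 = rhs(t + step / 2, y + step / 2 * k2, hist)
        k4 = rhs(t + step, y + step * k3, hist)
        y = y + step / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t + step
        if not np.all(np.isfinite(y)):
            raise IntegrationError("non-finite state in DDE integration",
                                   last_time=t - step)
        hist.append(t, y, rhs(t, y, hist))
        while eval_i < len(t_eval) and t_eval[eval_i] <= t + 1e-12:
            tq = t_eval[eval_i]
            if tq > out_t[-1]:
                out_t.append(float(tq))
                out_y.append(hist(tq))
            eval_i += 1
    return np.array(out_t), np.array(out_y).T


def integrate(system: ModelSystem, init=None,
              t_span: tuple[float, float] = (0.0, 100.0),
              n_out: int = 2001, rtol: float = 1e-8, atol: float = 1e-10,
              method: str = "LSODA", dde_step: Optional[float] = None,
              ) -> Trajectory:
    """Integrate a model system over ``t_span`` on a uniform output grid.

    Schedules are honoured by restarting the solver at every window boundary
    with the segment's effective parameters.  Delayed systems (``tau > 0``)
    go through the fixed-step DDE integrator; a DelaySpec with
    ``tau1 = tau2 = 0`` falls back to the ODE path.
    """
    y0 = system.init_or_default(init)
    if "validate_init" in system.meta:
        system.meta["validate_init"](y0)
    t0, t1 = t_span
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    t_eval = np.linspace(t0, t1, n_out)
    meta = {"system": system.name, "params": dict(system.params),
            "t_span": t_span, "rtol": rtol, "atol": atol, "method": method,
            "schedule": [vars(w) for w in system.schedule.windows]}
    if system.delayed and system.max_delay > 0:
        tt, yy = _integrate_dde(system, y0, t_span, t_eval, dde_step)
        meta["method"] = "rk4-hermite-dde"
        meta["dde_step"] = dde_step or _dde_default_step(system, t1 - t0)
        return Trajectory(tt, yy, system.state_names, meta)

    breaks = system.schedule.breakpoints(t_span)
    ts_all = [np.array([t0])]
    ys_all = [y0.reshape(-1, 1)]
    y = y0
    for a, b in zip(breaks, breaks[1:]):
        p = system.schedule.params_at(system.params, a)
        rhs = system.make_rhs(p, system.time_varying)
        seg_eval = t_eval[(t_eval > a + 1e-12) & (t_eval <= b + 1e-12)]
        on_grid = len(seg_eval) > 0 and abs(seg_eval[-1] - b) < 1e-12
        seg_eval = np.unique(np.concatenate([seg_eval, [b]]))
        sol = _solve_ode_segment(rhs, a, b, y, seg_eval, rtol, atol, method)
        y = sol.y[:, -1]
        # the segment end is an integration restart point; emit it only when
        # it lies on the requested output grid
        keep = sol.t > ts_all[-1][-1]
        if not on_grid:
            keep &= np.abs(sol.t - b) > 1e-12
        ts_all.append(sol.t[keep])
        ys_all.append(sol.y[:, keep])
    tt = np.concatenate(ts_all)
    yy = np.concatenate(ys_all, axis=1)
    if not np.all(np.isfinite(yy)):
        bad = np.where(~np.all(np.isfinite(yy), axis=0))[0]
        raise IntegrationError("non-finite state encountered",
                               last_time=float(tt[bad[0] - 1]) if bad[0] else t0)
    return Trajectory(tt, yy, system.state_names, meta)


# ---------------------------------------------------------------------------
# steady states


def _numerical_jacobian(f: Callable, y: np.ndarray, scales: np.ndarray
                        ) -> np.ndarray:
    m = len(y)
    J = np.empty((m, m))
    for j in range(m):
        step = 1e-7 * max(scales[j], abs(y[j]), 1e-6)
        yp, ym = y.copy(), y.copy()
        yp[j] += step
        ym[j] -= step
        J[:, j] = (f(yp) - f(ym)) / (2 * step)
    return J


def steady_states(system: ModelSystem, n_random: int = 20, seed: int = 0,
                  tol: float = 1e-11, merge_tol: float = 1e-6,
                  stability_tol: float = 1e-8) -> list[SteadyState]:
    """Locate equilibria by multi-start root finding.

    Delays do not move equilibria; for delayed systems stability refers to
    the ``tau = 0`` reduction (recorded in each SteadyState via the
    ``branch`` field being suffixed only in the system meta, and flagged by
    the caller when needed).
    """
    rhs = system.rhs_at()
    f = lambda y: rhs(0.0, y, None)
    scales = np.asarray(system.state_scales or (1.0,) * system.n_states)
    levels = (0.02, 0.3, 0.7, 1.0)
    starts: list[np.ndarray] = []
    if system.n_states <= 3:
        for combo in itertools.product(levels, repeat=system.n_states):
            starts.append(np.array(combo) * scales)
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        starts.append(rng.uniform(0.0, 1.0, system.n_states) * scales)
    extra = system.meta.get("equilibrium_starts")
    if extra is not None:
        starts.extend(extra(system.params))
    found: list[np.ndarray] = []
    for y0 in starts:
        sol = root(f, y0, method="hybr", tol=tol)
        if not sol.success:
            continue
        y = sol.x
        if np.any(y < -1e-6 * scales):
            continue
        res = float(np.linalg.norm(f(y) / np.maximum(scales, 1e-12)))
        if res > 1e-8:
            continue
        if any(np.linalg.norm((y - g) / scales) < merge_tol for g in found):
            continue
        found.append(y)
    out: list[SteadyState] = []
    for y in found:
        J = _numerical_jacobian(f, y, scales)
        eig = np.linalg.eigvals(J)
        rmax = float(np.max(eig.real))
        if rmax < -stability_tol:
            stab = "stable"
        elif rmax > stability_tol:
            stab = "unstable"
        else:
            stab = "marginal"
        out.append(SteadyState(state=y, eigenvalues=eig, stability=stab,
                               residual=float(np.linalg.norm(f(y)))))
    out.sort(key=lambda s: tuple(s.state))
    return out


# ---------------------------------------------------------------------------
# continuation


def _switch_residual(module: SwitchModule):
    def F(u: np.ndarray, lam: float) -> np.ndarray:
        y = u[0]
        xiK = module.xi(y) * module.K
        num = lam**module.n if lam > 0 else 0.0
        return np.array([module.correction * num / (xiK**module.n + num) - y])

    return F


def continuation_curve(target: Union[SwitchModule, ModelSystem],
                       input_name: str = "",
                       input_range: tuple[float, float] = (0.0, 2.0),
                       output: Union[str, int] = -1,
                       ds0: float = 1e-3, ds_min: float = 1e-4,
                       ds_max: float = 1e-1, max_steps: int = 20000,
                       ) -> ResponseCurve:
    """Trace a (possibly folded) steady-state response curve.

    ``target`` is either a SwitchModule (the input is the Hill input, the
    output its activity fraction) or a ModelSystem with the input clamped as
    the parameter ``input_name``.  Pseudo-arclength continuation with a
    secant predictor; folds are detected as sign changes of the input
    direction along the arc.
    """
    lam_lo, lam_hi = input_range
    lam_scale = max(lam_hi - lam_lo, 1e-12)
    if isinstance(target, SwitchModule):
        F = _switch_residual(target)
        u_scales = np.array([1.0])
        out_idx = 0
        u0 = np.array([0.0])
        in_name = input_name or "input"
        out_name = "output"
    else:
        system = target
        if input_name not in system.params:
            raise KeyError(f"{input_name!r} is not a parameter of {system.name}")
        u_scales = np.asarray(system.state_scales)
        out_idx = (system.state_names.index(output)
                   if isinstance(output, str) else output % system.n_states)

        def F(u: np.ndarray, lam: float) -> np.ndarray:
            rhs = system.make_rhs({**system.params, input_name: lam},
                                  system.time_varying)
            return rhs(0.0, u, None)

        u0 = np.zeros(system.n_states)
        in_name = input_name
        out_name = (output if isinstance(output, str)
                    else system.state_names[out_idx])

    lam0 = lam_lo if lam_lo > 0 else lam_lo + 1e-9 * lam_scale
    sol = root(lambda u: F(u, lam0), u0, method="hybr", tol=1e-13)
    if not sol.success:
        raise IntegrationError("could not locate the starting steady state")
    z = np.concatenate([sol.x / u_scales, [lam0 / lam_scale]])
    zs = [z]
    ds = ds0
    direction = np.zeros(len(z))
    direction[-1] = 1.0  # move into the input range first
    truncated = False
    for _ in range(max_steps):
        z_pred = zs[-1] + ds * direction

        def G(zz):
            u = zz[:-1] * u_scales
            lam = zz[-1] * lam_scale
            return np.concatenate([F(u, lam),
                                   [direction @ (zz - z_pred)]])

        csol = root(G, z_pred, method="hybr", tol=1e-13)
        ok = csol.success and np.linalg.norm(csol.x - z_pred) < 10 * ds
        if not ok:
            ds *= 0.5
            if ds < ds_min:
                truncated = True
                break
            continue
        z_new = csol.x
        sec = z_new - zs[-1]
        nrm = np.linalg.norm(sec)
        if nrm == 0:
            truncated = True
            break
        direction = sec / nrm
        zs.append(z_new)
        ds = min(ds * 1.3, ds_max)
        lam = z_new[-1] * lam_scale
        if lam > lam_hi or lam < lam_lo - 1e-9 * lam_scale:
            break
    Z = np.array(zs)
    lam_arr = Z[:, -1] * lam_scale
    out_arr = Z[:, out_idx] * u_scales[out_idx]
    # folds: sign changes of d(input)/d(arclength)
    dlam = np.diff(lam_arr)
    folds: list[tuple[float, float]] = []
    fold_idx: list[int] = []
    for i in range(len(dlam) - 1):
        if dlam[i] * dlam[i + 1] < 0:
            folds.append((float(lam_arr[i + 1]), float(out_arr[i + 1])))
            fold_idx.append(i + 1)
    branch = np.array([""] * len(lam_arr), dtype=object)
    if len(fold_idx) == 2:
        arcs = [slice(0, fold_idx[0] + 1),
                slice(fold_idx[0] + 1, fold_idx[1] + 1),
                slice(fold_idx[1] + 1, len(lam_arr))]
        order = np.argsort([np.mean(out_arr[a]) for a in arcs])
        names = np.empty(3, dtype=object)
        names[order] = ["lower", "middle", "upper"]
        for a, nm in zip(arcs, names):
            branch[a] = nm
    elif len(fold_idx) == 0:
        branch[:] = "lower"
    return ResponseCurve(lam_arr, out_arr, branch, folds=folds,
                         input_name=in_name, output_name=out_name,
                         truncated=truncated)


# ---------------------------------------------------------------------------
# oscillation metrics


def oscillation_metrics(traj: Trajectory, var: Union[str, int] = 0,
                        transient_fraction: float = 0.5,
                        min_peaks: int = 5, height_tol: float = 0.01,
                        min_amp_frac: float = 0.01, cv_tol: float = 0.05,
                        ) -> OscillationSummary:
    """Period, per-variable amplitude and sustainedness from local extrema.

    The first ``transient_fraction`` of the span is discarded.  Sustained
    requires at least ``min_peaks`` post-transient maxima whose heights vary
    by less than ``height_tol`` (relative) and whose oscillation amplitude
    exceeds ``min_amp_frac`` of the variable's observed range — this filters
    damped and small-amplitude oscillations.  Regular means the coefficient
    of variation of inter-maximum intervals is below ``cv_tol``.
    """
    x_full = traj.var(var)
    cut = traj.t[0] + transient_fraction * traj.span
    mask = traj.t >= cut
    if mask.sum() < 10:
        raise InsufficientDataError("trajectory too short after transient removal")
    t, x = traj.t[mask], x_full[mask]
    full_range = float(np.max(x_full) - np.min(x_full))
    not_sust = lambda why: OscillationSummary(
        sustained=False, period=float("nan"), amplitudes={}, regular=False,
        natural_frequency=float("nan"), rejected_reason=why)
    if full_range <= 0:
        return not_sust("constant signal")
    pk, _ = find_peaks(x)
    tr, _ = find_peaks(-x)
    if len(pk) < min_peaks or len(tr) < 2:
        return not_sust("fewer maxima than required")
    heights = x[pk]
    troughs = x[tr]
    amp_osc = float(np.mean(heights) - np.mean(troughs))
    denom = max(abs(float(np.mean(heights))), amp_osc, 1e-300)
    height_var = float(np.max(heights) - np.min(heights)) / denom
    if amp_osc < min_amp_frac * full_range:
        return not_sust("amplitude below the small-oscillation cutoff")
    if height_var >= height_tol:
        return not_sust("peak heights vary too much (damped or irregular)")
    peak_t = t[pk]
    gaps = np.diff(peak_t)
    period = float(np.mean(gaps))
    cv = float(np.std(gaps) / period) if period > 0 else np.inf
    amplitudes = {nm: float(np.max(traj.y[i][mask]) - np.min(traj.y[i][mask]))
                  for i, nm in enumerate(traj.names)}
    return OscillationSummary(
        sustained=True, period=period, amplitudes=amplitudes,
        regular=cv < cv_tol, natural_frequency=2.0 * np.pi / period,
        n_peaks=len(pk), peak_times=peak_t)


# ---------------------------------------------------------------------------
# regime classification


def _apc_fold_outputs(system: ModelSystem) -> Optional[tuple[float, float]]:
    sw = system.meta.get("apc_switch")
    if sw is None:
        return None
    a = system.params.get("alpha_apc")
    if a is not None and sw.xi.kind in ("cubic", "quadratic", "linear"):
        from .switchcore import ScalingFunction
        sw = sw.with_(xi=ScalingFunction(kind=sw.xi.kind, alpha=a, r=sw.xi.r))
    fa = fold_analysis(sw)
    if not fa.bistable:
        return None
    ys = sorted(f[1] for f in fa.folds)
    return ys[0], ys[-1]


def classify_regime(system: ModelSystem, probe_inits=None,
                    t_span: tuple[float, float] = (0.0, 100.0),
                    n_out: int = 4001, quick: bool = False,
                    switch_output: str = "APC", **osc_kwargs) -> str:
    """Label the long-run behavior: Osc, Bi, MonoLow, MonoTop, Irregular, or
    the composite ``Bi+Osc`` when a limit cycle coexists with stable
    equilibria.

    Combines equilibrium counting with probe simulations started (by
    default) at a low and a high corner of state space.  Mono labels compare
    the equilibrium's switch-output coordinate with the fold outputs of the
    S-shaped response.
    """
    sss = steady_states(system)
    stable = [s for s in sss if s.stable]
    if probe_inits is None:
        scales = np.asarray(system.state_scales or (1.0,) * system.n_states)
        low = 0.02 * scales
        high = np.where(scales <= 1.0, 0.95, 0.8 * scales)
        probe_inits = [low, high]
    if quick and len(stable) >= 2:
        return "Bi"
    summaries = []
    for y0 in probe_inits:
        traj = integrate(system, init=y0, t_span=t_span, n_out=n_out,
                         rtol=1e-7, atol=1e-9)
        try:
            summaries.append(oscillation_metrics(traj, **osc_kwargs))
        except InsufficientDataError:
            summaries.append(None)
        if quick and summaries[-1] is not None and summaries[-1].sustained:
            break
    osc = any(s is not None and s.sustained for s in summaries)
    if len(stable) >= 2:
        return "Bi+Osc" if osc else "Bi"
    if osc:
        return "Osc"
    if len(stable) == 1:
        idx = system.state_names.index(switch_output)
        y_eq = stable[0].state[idx]
        fold_ys = _apc_fold_outputs(system)
        if fold_ys is None:
            return "MonoLow" if y_eq < 0.5 else "MonoTop"
        y_lo, y_hi = fold_ys
        if y_eq <= y_lo:
            return "MonoLow"
        if y_eq >= y_hi:
            return "MonoTop"
        return "Irregular"  # equilibrium between folds but no sustained cycle
    # no stable equilibrium and no sustained oscillation: branch-sticking /
    # irregular variation
    return "Irregular"


# ---------------------------------------------------------------------------
# phase segmentation


def segment_phases(traj: Trajectory, threshold: float = 0.95
                   ) -> PhaseSegmentation:
    """Cell-cycle phase labels: M wherever [APC]* > threshold, S/G2 wherever
    [E2F]* > threshold and [APC]* <= threshold, G1 otherwise (ties resolve
    away from M and S/G2)."""
    for need in ("E2F", "APC"):
        if need not in traj.names:
            raise ValueError(f"trajectory lacks variable {need!r}")
    e2f = traj.var("E2F")
    apc = traj.var("APC")
    labels = np.where(apc > threshold, "M",
                      np.where(e2f > threshold, "S/G2", "G1")).astype(object)
    dt = np.diff(traj.t)
    # cycles delimited by M -> G1 transitions (mitotic exit)
    starts = [i for i in range(1, len(labels))
              if labels[i] == "G1" and labels[i - 1] == "M"]
    per_cycle: list[dict[str, float]] = []
    for a, b in zip(starts, starts[1:]):
        durs = {"G1": 0.0, "S/G2": 0.0, "M": 0.0}
        for i in range(a, b):
            durs[labels[i]] += dt[i - 1] if i > 0 else 0.0
        durs["period"] = float(traj.t[b] - traj.t[a])
        per_cycle.append(durs)
    if per_cycle:
        mean = {k: float(np.mean([c[k] for c in per_cycle]))
                for k in ("G1", "S/G2", "M", "period")}
    else:
        mean = {}
    return PhaseSegmentation(labels=labels, per_cycle=per_cycle,
                             mean_durations=mean)


# ---------------------------------------------------------------------------
# sweeps


def sweep2d(make_system: Callable[[float, float], ModelSystem],
            axis1: tuple[str, Sequence[float]],
            axis2: tuple[str, Sequence[float]],
            evaluate: Callable[[ModelSystem], Mapping[str, Any]],
            ) -> SweepGrid:
    """Evaluate a metric function over a 2-D parameter grid.

    Cells are independent; an exception in one cell is recorded in the
    ``error`` column instead of aborting the sweep.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    records = []
    for v1 in vals1:
        for v2 in vals2:
            rec: dict[str, Any] = {name1: v1, name2: v2, "error": ""}
            try:
                rec.update(evaluate(make_system(v1, v2)))
            except Exception as exc:  # per-cell failures are data
                rec["error"] = f"{type(exc).__name__}: {exc}"
            records.append(rec)
    return SweepGrid(name1, name2, pd.DataFrame.from_records(records))
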