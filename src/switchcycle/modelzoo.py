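"""Cell-cycle model systems assembled from the functional modules.

Systems provided (state variables in parentheses):

* embryonic two-variable oscillator ([Cdk1], [APC]*) — constant cyclin
  synthesis, APC/C-dependent degradation, and an ultrasensitive or S-shaped
  APC/C switch; optionally with a (state-dependent) time delay on the Cdk1
  input of the APC/C equation.
* embryonic three-variable oscillator ([CycB], [Cdk1], [APC]*) — adds the
  CycB -> Cdk1 switch whose Hill term is multiplied by [CycB] and whose
  scaling function is evaluated at the activity ratio [Cdk1]/[CycB].
* interlinked five-variable somatic model ([CycD], [E2F]*, [CycB], [Cdk1],
  [APC]*) — chains the G1/S (E2F), G2/M (Cdk1) and M-exit (APC/C) switches.
* mass-action PP2A-ENSA-GWL oscillator ([Cdk1], [GWLp], [C], [ENSAp],
  [APC]*) — double-negative GWL/PP2A feedback with conservation of the GWL,
  PP2A and ENSA pools, driven by Cdk1 synthesis/degradation.

Concentrations are in nM, time in minutes.  Starred variables are activity
fractions in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Optional, Sequence

import numpy as np

from .switchcore import ScalingFunction, SwitchModule

__all__ = [
    "DelaySpec",
    "EmbryonicParams",
    "NondimParams",
    "MassActionParams",
    "SomaticParams",
    "ParameterSchedule",
    "ScheduleWindow",
    "ModelSystem",
    "build_embryonic",
    "build_delayed",
    "build_interlinked",
    "build_mass_action",
    "build_mass_action_clamped",
    "nondimensionalize",
    "embryonic_nondim",
    "apply_schedule",
]


@dataclass(frozen=True)
class DelaySpec:
    """Activation/inactivation delays blended by a Hill switch on [APC]*.

    ``tau1`` applies while APC/C activity is low (< 0.5), ``tau2`` while it is
    high; ``p`` is the Hill exponent of the blend.  ``tau1 == tau2`` is the
    constant-delay case.
    """

    tau1: float
    tau2: float
    p: float = 5.0

    def __post_init__(self) -> None:
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("delays must be non-negative")

    @property
    def constant(self) -> bool:
        return self.tau1 == self.tau2

    def effective(self, apc: float) -> float:
        if self.constant:
            return self.tau1
        h = apc**self.p / (0.5**self.p + apc**self.p) if apc > 0 else 0.0
        return self.tau1 + (self.tau2 - self.tau1) * h

    @property
    def max_tau(self) -> float:
        return max(self.tau1, self.tau2)

    @property
    def min_tau(self) -> float:
        return min(self.tau1, self.tau2)


@dataclass(frozen=True)
class EmbryonicParams:
    """Parameters of the embryonic (two- or three-variable) oscillator."""

    b_syn: float  # nM/min
    b_deg: float = 0.1  # 1/min
    apc_switch: SwitchModule = field(
        default_factory=lambda: SwitchModule(
            K=20.0, n=15.0, xi=ScalingFunction(alpha=5.0), epsilon=0.1))
    cdk_switch: Optional[SwitchModule] = None
    delay: Optional[DelaySpec] = None

    def __post_init__(self) -> None:
        if self.b_syn <= 0 or self.b_deg <= 0:
            raise ValueError("synthesis and degradation rates must be positive")
        if self.cdk_switch is not None and not self.cdk_switch.multiply_by_input:
            raise ValueError(
                "the CycB->Cdk1 switch must have multiply_by_input=True: its "
                "output is the Hill fraction times [CycB]")


@dataclass(frozen=True)
class NondimParams:
    """Dimensionless groups of the embryonic systems."""

    c: float            # relative synthesis b_syn / (K_cdk,apc * b_deg)
    d: float            # threshold ratio K_cyc,cdk / K_cdk,apc (1 if absent)
    eps_star: dict      # epsilon * b_deg per switch
    tau_star: Optional[tuple[float, float]]  # b_deg * (tau1, tau2)

    def scale_state(self, cdk1_star: float, K_cdk_apc: float) -> float:
        return cdk1_star * K_cdk_apc

    def scale_time(self, t_star: float, b_deg: float) -> float:
        return t_star / b_deg


_TABLE1 = dict(k_pg=0.07, k_dg=7.08, k_pe=3.98, k_pa=0.63, k_da=1.58,
               k_ass=5.01, k_dis=28.18, k_cat=15.85,
               GWL_tot=40.0, ENSA_tot=200.0, PP2A_tot=40.0)


@dataclass(frozen=True)
class MassActionParams:
    """PP2A-ENSA-GWL network constants (defaults screened for an S-shaped
    APC/C response centered near [Cdk1] = 20 nM).

    ``b_syn``/``b_deg`` (Cdk1 synthesis/degradation) have no published default
    and must be supplied.  ``rate_divisor`` uniformly divides the eight
    kinetic constants — but not synthesis/degradation — to reduce timescale
    separation.
    """

    b_syn: float
    b_deg: float
    k_pg: float = _TABLE1["k_pg"]
    k_dg: float = _TABLE1["k_dg"]
    k_pe: float = _TABLE1["k_pe"]
    k_pa: float = _TABLE1["k_pa"]
    k_da: float = _TABLE1["k_da"]
    k_ass: float = _TABLE1["k_ass"]
    k_dis: float = _TABLE1["k_dis"]
    k_cat: float = _TABLE1["k_cat"]
    GWL_tot: float = _TABLE1["GWL_tot"]
    ENSA_tot: float = _TABLE1["ENSA_tot"]
    PP2A_tot: float = _TABLE1["PP2A_tot"]
    rate_divisor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("b_syn", "b_deg", "k_pg", "k_dg", "k_pe", "k_pa", "k_da",
                     "k_ass", "k_dis", "k_cat", "GWL_tot", "ENSA_tot",
                     "PP2A_tot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rate_divisor < 1.0:
            raise ValueError("rate_divisor must be >= 1")

    def effective_rates(self) -> dict[str, float]:
        div = self.rate_divisor
        return {k: getattr(self, k) / div
                for k in ("k_pg", "k_dg", "k_pe", "k_pa", "k_da", "k_ass",
                          "k_dis", "k_cat")}


@dataclass(frozen=True)
class SomaticParams:
    """Interlinked-switch somatic cell-cycle parameters (defaults give
    oscillations with a period of the order of a day)."""

    d_syn: float = 0.15     # nM/min, CycD synthesis
    d_deg: float = 0.009    # 1/min
    delta_d: float = 0.05   # basal (APC-independent) CycD degradation offset
    b_syn: float = 0.03     # nM/min, CycB synthesis (scaled by [E2F]*)
    b_deg: float = 0.003    # 1/min
    delta_b: float = 0.05
    K_cyc_e2f: float = 120.0
    K_cyc_cdk: float = 40.0
    K_cdk_apc: float = 20.0
    alpha_e2f: float = 5.0
    alpha_cdk: float = 5.0
    alpha_apc: float = 5.0
    eps_e2f: float = 0.01   # min
    eps_cdk: float = 0.01
    eps_apc: float = 0.01
    n: float = 15.0
    r: float = 0.5

    def __post_init__(self) -> None:
        for name in ("d_syn", "d_deg", "b_syn", "b_deg", "K_cyc_e2f",
                     "K_cyc_cdk", "K_cdk_apc", "eps_e2f", "eps_cdk",
                     "eps_apc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_d < 0 or self.delta_b < 0:
            raise ValueError("delta offsets must be non-negative")


@dataclass(frozen=True)
class ScheduleWindow:
    t_start: float
    t_end: float
    path: str
    value: float
    mode: str = "set"  # or "multiply"

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start and self.t_end != self.t_start:
            raise ValueError("window end must not precede start")
        if self.mode not in ("set", "multiply"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")


@dataclass(frozen=True)
class ParameterSchedule:
    """Piecewise-constant parameter perturbation windows.

    Outside every window the baseline value applies.  Windows are half-open
    ``[t_start, t_end)`` and must not overlap per parameter.
    """

    windows: tuple[ScheduleWindow, ...] = ()

    def __post_init__(self) -> None:
        by_path: dict[str, list[ScheduleWindow]] = {}
        for w in self.windows:
            by_path.setdefault(w.path, []).append(w)
        for path, ws in by_path.items():
            ws = sorted(ws, key=lambda w: w.t_start)
            for a, b in zip(ws, ws[1:]):
                if b.t_start < a.t_end:
                    raise ValueError(f"overlapping schedule windows for {path!r}")

    @property
    def empty(self) -> bool:
        return len(self.windows) == 0

    def breakpoints(self, t_span: tuple[float, float]) -> list[float]:
        t0, t1 = t_span
        pts = {t0, t1}
        for w in self.windows:
            for t in (w.t_start, w.t_end):
                if t0 < t < t1:
                    pts.add(t)
        return sorted(pts)

    def params_at(self, baseline: Mapping[str, float], t: float
                  ) -> dict[str, float]:
        p = dict(baseline)
        for w in self.windows:
            if w.t_start <= t < w.t_end:
                if w.path not in p:
                    raise KeyError(f"schedule path {w.path!r} not a parameter")
                p[w.path] = w.value if w.mode == "set" else p[w.path] * w.value
        return p


EMPTY_SCHEDULE = ParameterSchedule()


@dataclass
class ModelSystem:
    """An assembled dynamical system.

    ``make_rhs(params, tv)`` returns the right-hand side
    ``rhs(t, y, history)`` where ``history(t_past) -> state`` provides lagged
    values (``None`` for non-delayed systems).  ``tv`` maps parameter names to
    callables of time for continuously time-varying parameters.
    """

    name: str
    state_names: tuple[str, ...]
    params: dict[str, float]
    make_rhs: Callable[..., Callable]
    delayed: bool = False
    max_delay: float = 0.0
    min_delay: float = 0.0
    schedule: ParameterSchedule = field(default_factory=ParameterSchedule)
    time_varying: dict[str, Callable[[float], float]] = field(default_factory=dict)
    state_scales: tuple[float, ...] = ()
    default_init: Optional[np.ndarray] = None
    meta: dict[str, Any] = field(default_factory=dict)

    def rhs_at(self, params: Optional[Mapping[str, float]] = None) -> Callable:
        return self.make_rhs(dict(self.params if params is None else params),
                             self.time_varying)

    def with_params(self, **overrides) -> "ModelSystem":
        p = dict(self.params)
        unknown = set(overrides) - set(p)
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)}")
        p.update(overrides)
        return replace(self, params=p)

    def with_schedule(self, schedule: ParameterSchedule) -> "ModelSystem":
        for w in schedule.windows:
            if w.path not in self.params:
                raise KeyError(f"schedule path {w.path!r} not in {self.name}")
        return replace(self, schedule=schedule)

    def with_time_varying(self, **fns: Callable[[float], float]) -> "ModelSystem":
        for k in fns:
            if k not in self.params:
                raise KeyError(f"time-varying path {k!r} not in {self.name}")
        tv = dict(self.time_varying)
        tv.update(fns)
        return replace(self, time_varying=tv)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def init_or_default(self, init) -> np.ndarray:
        if init is None:
            if self.default_init is not None:
                return np.asarray(self.default_init, dtype=float)
            return np.zeros(self.n_states)
        init = np.asarray(init, dtype=float)
        if init.shape != (self.n_states,):
            raise ValueError(
                f"initial condition must have shape ({self.n_states},)")
        return init


# ---------------------------------------------------------------------------
# scaling-function closures
#
# The analytic scaling kinds are re-materialized from the flat parameter dict
# so that schedules and time-varying forcing can act on the bend strength
# alpha; non-analytic (piecewise / tabulated) kinds are closed over directly.


def _xi_closure(sw: SwitchModule, params: Mapping[str, float], tag: str,
                tv: Mapping[str, Callable]):
    """Return xi(y) or, when alpha is forced in time, xi(y, t)."""
    alpha_key = f"alpha_{tag}"
    kind = sw.xi.kind
    if kind in ("cubic", "quadratic", "linear"):
        r = sw.xi.r
        if alpha_key in tv:
            if kind != "cubic":
                raise ValueError("time-varying alpha requires a cubic scaling")
            afn = tv[alpha_key]

            def xi_t(y: float, t: float) -> float:
                return 1.0 + afn(t) * y * (y - 1.0) * (y - r)

            return xi_t, True
        # scheduled/forced alpha values are deliberately not positivity
        # checked: checkpoint perturbations (alpha_cdk = 30) and strong
        # circadian forcing push xi negative in output regions the relevant
        # branch never visits
        a = params.get(alpha_key, sw.xi.alpha)
        if kind == "cubic":
            def xi(y: float) -> float:
                return 1.0 + a * y * (y - 1.0) * (y - r)
        elif kind == "quadratic":
            def xi(y: float) -> float:
                return 1.0 + a * (y - 1.0) * (y - r)
        else:
            def xi(y: float) -> float:
                return 1.0 - a / (r - 1.0) * (y - 1.0) + a
        return xi, False
    fn = sw.xi
    return (lambda y: float(fn(y))), False


def validate_alpha_lower(alpha: float, r: float = 0.5) -> None:
    """Positivity of the cubic scaling on the lower branch only.

    The CycB -> Cdk1 switch evaluates xi at the activity ratio, and threshold
    perturbations (DNA damage in G2, circadian Wee1 forcing) legitimately use
    bends far beyond the whole-interval positivity bound: only the lower
    branch — where the shifted activation fold lives — must keep a positive
    threshold.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    ys = np.linspace(0.0, 0.5, 501)
    if np.min(1.0 + alpha * ys * (ys - 1.0) * (ys - r)) <= 0.0:
        raise ValueError(
            f"alpha = {alpha} makes the scaled threshold non-positive on the "
            "lower branch")


def _effective_switch(sw: SwitchModule, params: Mapping[str, float],
                      tag: str) -> SwitchModule:
    """Switch with alpha taken from the (possibly perturbed) parameter dict."""
    a = params.get(f"alpha_{tag}")
    if a is not None and sw.xi.kind in ("cubic", "quadratic", "linear"):
        if a != sw.xi.alpha:
            return sw.with_(xi=ScalingFunction(kind=sw.xi.kind, alpha=a,
                                               r=sw.xi.r))
    return sw


# ---------------------------------------------------------------------------
# builders


def build_embryonic(params: EmbryonicParams) -> ModelSystem:
    """Two-variable ([Cdk1], [APC]*) or three-variable ([CycB], [Cdk1],
    [APC]*) embryonic oscillator, depending on whether the CycB -> Cdk1 switch
    is configured."""
    apc, cdk = params.apc_switch, params.cdk_switch
    flat = {
        "b_syn": params.b_syn, "b_deg": params.b_deg,
        "K_cdk_apc": apc.K, "n_apc": apc.n, "eps_apc": apc.epsilon,
        "corr_apc": apc.correction,
    }
    if apc.xi.kind in ("cubic", "quadratic", "linear"):
        flat["alpha_apc"] = apc.xi.alpha
    delay = params.delay
    if cdk is None:
        def make_rhs(p: Mapping[str, float], tv: Mapping) -> Callable:
            xi_apc, forced = _xi_closure(apc, p, "apc", tv)
            b_syn, b_deg = p["b_syn"], p["b_deg"]
            K, n, eps, corr = (p["K_cdk_apc"], p["n_apc"], p["eps_apc"],
                               p["corr_apc"])

            def rhs(t, y, history=None):
                cdk1, apc_a = y
                if history is not None and delay is not None:
                    tau = delay.effective(apc_a)
                    cdk1_in = history(t - tau)[0] if tau > 0 else cdk1
                else:
                    cdk1_in = cdk1
                xv = xi_apc(apc_a, t) if forced else xi_apc(apc_a)
                num = cdk1_in**n if cdk1_in > 0 else 0.0
                h = corr * num / ((xv * K) ** n + num)
                return np.array([
                    b_syn - b_deg * cdk1 * apc_a,
                    (h - apc_a) / eps,
                ])

            return rhs

        def eq_starts(p: Mapping[str, float]) -> list[np.ndarray]:
            # seed along the APC/C nullcline: equilibria of the 2-variable
            # system always lie on the (possibly S-shaped) switch response
            sw = _effective_switch(apc, p, "apc")
            from .switchcore import invert_response

            ys = np.linspace(0.02, 0.98 * sw.correction, 33)
            return [np.array([invert_response(y, sw), y]) for y in ys]

        return ModelSystem(
            name="embryonic2", state_names=("Cdk1", "APC"), params=flat,
            make_rhs=make_rhs, delayed=delay is not None,
            max_delay=delay.max_tau if delay else 0.0,
            min_delay=delay.min_tau if delay else 0.0,
            state_scales=(4.0 * apc.K, 1.0),
            meta={"apc_switch": apc, "delay": delay,
                  "equilibrium_starts": eq_starts})

    flat.update({
        "K_cyc_cdk": cdk.K, "n_cdk": cdk.n, "eps_cdk": cdk.epsilon,
        "corr_cdk": cdk.correction,
    })
    if cdk.xi.kind in ("cubic", "quadratic", "linear"):
        flat["alpha_cdk"] = cdk.xi.alpha

    def make_rhs3(p: Mapping[str, float], tv: Mapping) -> Callable:
        xi_apc, forced_a = _xi_closure(apc, p, "apc", tv)
        xi_cdk, forced_c = _xi_closure(cdk, p, "cdk", tv)
        b_syn, b_deg = p["b_syn"], p["b_deg"]
        Ka, na, ea, ca = p["K_cdk_apc"], p["n_apc"], p["eps_apc"], p["corr_apc"]
        Kc, nc, ec, cc = p["K_cyc_cdk"], p["n_cdk"], p["eps_cdk"], p["corr_cdk"]

        def rhs(t, y, history=None):
            cycb, cdk1, apc_a = y
            if history is not None and delay is not None:
                tau = delay.effective(apc_a)
                cdk1_in = history(t - tau)[1] if tau > 0 else cdk1
            else:
                cdk1_in = cdk1
            ratio = cdk1 / max(cycb, 1e-12)
            xc = xi_cdk(ratio, t) if forced_c else xi_cdk(ratio)
            numc = cycb**nc if cycb > 0 else 0.0
            hc = cc * numc / ((xc * Kc) ** nc + numc)
            xa = xi_apc(apc_a, t) if forced_a else xi_apc(apc_a)
            numa = cdk1_in**na if cdk1_in > 0 else 0.0
            ha = ca * numa / ((xa * Ka) ** na + numa)
            return np.array([
                b_syn - b_deg * cycb * apc_a,
                (hc * cycb - cdk1) / ec,
                (ha - apc_a) / ea,
            ])

        return rhs

    def eq_starts3(p: Mapping[str, float]) -> list[np.ndarray]:
        sw = _effective_switch(apc, p, "apc")
        from .switchcore import invert_response

        ys = np.linspace(0.02, 0.98 * sw.correction, 21)
        starts = []
        for y in ys:
            cdk1 = invert_response(y, sw)
            for cycb in (cdk1, 2.0 * cdk1):
                starts.append(np.array([cycb, cdk1, y]))
        return starts

    return ModelSystem(
        name="embryonic3", state_names=("CycB", "Cdk1", "APC"), params=flat,
        make_rhs=make_rhs3, delayed=delay is not None,
        max_delay=delay.max_tau if delay else 0.0,
        min_delay=delay.min_tau if delay else 0.0,
        state_scales=(4.0 * cdk.K, 4.0 * cdk.K, 1.0),
        meta={"apc_switch": apc, "cdk_switch": cdk, "delay": delay,
              "equilibrium_starts": eq_starts3})


def build_delayed(params: EmbryonicParams) -> ModelSystem:
    """Delayed embryonic oscillator; requires a DelaySpec (``tau1 = tau2 = 0``
    reduces exactly to the undelayed system)."""
    if params.delay is None:
        raise ValueError("build_delayed requires a DelaySpec")
    return build_embryonic(params)


def build_interlinked(params: SomaticParams) -> ModelSystem:
    """Five-variable somatic cell cycle as a chain of bistable switches."""
    q = params
    for a in (q.alpha_e2f, q.alpha_apc):
        ScalingFunction(alpha=a, r=q.r)  # positivity validation
    validate_alpha_lower(q.alpha_cdk, q.r)
    flat = {
        "d_syn": q.d_syn, "d_deg": q.d_deg, "delta_d": q.delta_d,
        "b_syn": q.b_syn, "b_deg": q.b_deg, "delta_b": q.delta_b,
        "K_cyc_e2f": q.K_cyc_e2f, "K_cyc_cdk": q.K_cyc_cdk,
        "K_cdk_apc": q.K_cdk_apc,
        "alpha_e2f": q.alpha_e2f, "alpha_cdk": q.alpha_cdk,
        "alpha_apc": q.alpha_apc,
        "eps_e2f": q.eps_e2f, "eps_cdk": q.eps_cdk, "eps_apc": q.eps_apc,
        "n": q.n, "r": q.r,
    }

    def make_rhs(p: Mapping[str, float], tv: Mapping) -> Callable:
        n, r = p["n"], p["r"]
        d_syn, d_deg, dd = p["d_syn"], p["d_deg"], p["delta_d"]
        b_syn, b_deg, db = p["b_syn"], p["b_deg"], p["delta_b"]
        Ke, Kc, Ka = p["K_cyc_e2f"], p["K_cyc_cdk"], p["K_cdk_apc"]
        ae, aa = p["alpha_e2f"], p["alpha_apc"]
        ee, ec, ea = p["eps_e2f"], p["eps_cdk"], p["eps_apc"]
        ac_fn = tv.get("alpha_cdk")
        ac_const = p["alpha_cdk"]

        def rhs(t, y, history=None):
            cycd, e2f, cycb, cdk1, apc_a = y
            ac = ac_fn(t) if ac_fn is not None else ac_const
            # E2F switch driven by CycD
            xe = 1.0 + ae * e2f * (e2f - 1.0) * (e2f - r)
            nume = cycd**n if cycd > 0 else 0.0
            he = nume / ((xe * Ke) ** n + nume)
            # Cdk1 switch driven by CycB, xi at the activity ratio
            ratio = cdk1 / max(cycb, 1e-12)
            xc = 1.0 + ac * ratio * (ratio - 1.0) * (ratio - r)
            numc = cycb**n if cycb > 0 else 0.0
            hc = numc / ((xc * Kc) ** n + numc)
            # APC/C switch driven by Cdk1
            xa = 1.0 + aa * apc_a * (apc_a - 1.0) * (apc_a - r)
            numa = cdk1**n if cdk1 > 0 else 0.0
            ha = numa / ((xa * Ka) ** n + numa)
            return np.array([
                d_syn - d_deg * cycd * (apc_a + dd),
                (he - e2f) / ee,
                b_syn * e2f - b_deg * cycb * (apc_a + db),
                (hc * cycb - cdk1) / ec,
                (ha - apc_a) / ea,
            ])

        return rhs

    return ModelSystem(
        name="interlinked",
        state_names=("CycD", "E2F", "CycB", "Cdk1", "APC"),
        params=flat, make_rhs=make_rhs,
        state_scales=(q.d_syn / (q.d_deg * max(q.delta_d, 1e-3)), 1.0,
                      q.b_syn / (q.b_deg * max(q.delta_b, 1e-3)),
                      4.0 * q.K_cyc_cdk, 1.0),
        meta={"somatic_params": q})


def build_mass_action(params: MassActionParams) -> ModelSystem:
    """Mass-action PP2A-ENSA-GWL oscillator with Cdk1 synthesis/degradation.

    The free pools are eliminated algebraically:
    ``[GWL] = GWL_tot - [GWLp]``, ``[PP2A] = PP2A_tot - [C]``,
    ``[ENSA] = ENSA_tot - [ENSAp] - [C]``.
    """
    q = params
    flat = {"b_syn": q.b_syn, "b_deg": q.b_deg,
            "GWL_tot": q.GWL_tot, "ENSA_tot": q.ENSA_tot,
            "PP2A_tot": q.PP2A_tot, **q.effective_rates()}

    def make_rhs(p: Mapping[str, float], tv: Mapping) -> Callable:
        kpg, kdg, kpe = p["k_pg"], p["k_dg"], p["k_pe"]
        kpa, kda = p["k_pa"], p["k_da"]
        kass, kdis, kcat = p["k_ass"], p["k_dis"], p["k_cat"]
        gt, et, pt = p["GWL_tot"], p["ENSA_tot"], p["PP2A_tot"]
        b_syn, b_deg = p["b_syn"], p["b_deg"]

        def rhs(t, y, history=None):
            cdk1, gwlp, c, ensap, apc_a = y
            gwl = gt - gwlp
            pp2a = pt - c
            ensa = et - ensap - c
            return np.array([
                b_syn - b_deg * cdk1 * apc_a,
                kpg * gwl * cdk1 - kdg * gwlp * pp2a,
                kass * ensap * pp2a - (kdis + kcat) * c,
                kdis * c + kpe * ensa * gwlp - kass * ensap * pp2a,
                kpa * (1.0 - apc_a) * cdk1 - kda * apc_a * pp2a,
            ])

        return rhs

    def validate_init(y0: np.ndarray) -> None:
        _, gwlp, c, ensap, apc_a = y0
        if not (0.0 <= gwlp <= q.GWL_tot):
            raise ValueError("initial [GWLp] outside [0, GWL_tot]")
        if not (0.0 <= c <= q.PP2A_tot):
            raise ValueError("initial [C] outside [0, PP2A_tot]")
        if ensap < 0 or ensap + c > q.ENSA_tot:
            raise ValueError("initial [ENSAp] + [C] outside [0, ENSA_tot]")
        if not (0.0 <= apc_a <= 1.0):
            raise ValueError("initial [APC]* outside [0, 1]")

    return ModelSystem(
        name="mass_action",
        state_names=("Cdk1", "GWLp", "C", "ENSAp", "APC"),
        params=flat, make_rhs=make_rhs,
        state_scales=(4.0 * 20.0, q.GWL_tot, q.PP2A_tot, q.ENSA_tot, 1.0),
        meta={"mass_action_params": q, "validate_init": validate_init})


def build_mass_action_clamped(params: MassActionParams, cdk1: float
                              ) -> ModelSystem:
    """PP2A-ENSA-GWL subsystem with [Cdk1] clamped as a parameter, used to
    trace the steady-state APC/C response curve."""
    q = params
    flat = {"Cdk1": cdk1, "GWL_tot": q.GWL_tot, "ENSA_tot": q.ENSA_tot,
            "PP2A_tot": q.PP2A_tot, **q.effective_rates()}

    def make_rhs(p: Mapping[str, float], tv: Mapping) -> Callable:
        kpg, kdg, kpe = p["k_pg"], p["k_dg"], p["k_pe"]
        kpa, kda = p["k_pa"], p["k_da"]
        kass, kdis, kcat = p["k_ass"], p["k_dis"], p["k_cat"]
        gt, et, pt = p["GWL_tot"], p["ENSA_tot"], p["PP2A_tot"]
        cdk = p["Cdk1"]

        def rhs(t, y, history=None):
            gwlp, c, ensap, apc_a = y
            gwl = gt - gwlp
            pp2a = pt - c
            ensa = et - ensap - c
            return np.array([
                kpg * gwl * cdk - kdg * gwlp * pp2a,
                kass * ensap * pp2a - (kdis + kcat) * c,
                kdis * c + kpe * ensa * gwlp - kass * ensap * pp2a,
                kpa * (1.0 - apc_a) * cdk - kda * apc_a * pp2a,
            ])

        return rhs

    return ModelSystem(
        name="mass_action_clamped",
        state_names=("GWLp", "C", "ENSAp", "APC"),
        params=flat, make_rhs=make_rhs,
        state_scales=(q.GWL_tot, q.PP2A_tot, q.ENSA_tot, 1.0),
        meta={"mass_action_params": q})


def nondimensionalize(params: EmbryonicParams) -> NondimParams:
    """Dimensionless groups: ``c = b_syn/(K_cdk,apc b_deg)``,
    ``d = K_cyc,cdk/K_cdk,apc``, ``eps* = eps b_deg``, ``tau* = b_deg tau``.

    Rescaling: concentrations by ``K_cdk,apc``, time by ``1/b_deg``; the
    relative synthesis of the three-variable system (CycB scaled by
    ``K_cyc,cdk``) is ``c/d``.
    """
    apc = params.apc_switch
    if params.b_deg <= 0 or apc.K <= 0:
        raise ValueError("b_deg and K must be positive")
    c = params.b_syn / (apc.K * params.b_deg)
    d = (params.cdk_switch.K / apc.K) if params.cdk_switch else 1.0
    eps_star = {"apc": apc.epsilon * params.b_deg}
    if params.cdk_switch:
        eps_star["cdk"] = params.cdk_switch.epsilon * params.b_deg
    tau_star = None
    if params.delay is not None:
        tau_star = (params.b_deg * params.delay.tau1,
                    params.b_deg * params.delay.tau2)
    return NondimParams(c=c, d=d, eps_star=eps_star, tau_star=tau_star)


def embryonic_nondim(c: float, alpha_apc: float = 5.0, eps_apc: float = 0.01,
                     n: float = 15.0, r: float = 0.5,
                     alpha_cdk: Optional[float] = None, d: float = 2.0,
                     eps_cdk: float = 0.01,
                     delay: Optional[DelaySpec] = None) -> EmbryonicParams:
    """Embryonic parameters in non-dimensional form (K = b_deg = 1, so the
    synthesis rate equals the relative synthesis ``c`` and delays are in
    units of 1/b_deg)."""
    apc = SwitchModule(K=1.0, n=n, xi=ScalingFunction(alpha=alpha_apc, r=r),
                       epsilon=eps_apc)
    cdk = None
    if alpha_cdk is not None:
        cdk = SwitchModule(K=d, n=n, xi=ScalingFunction(alpha=alpha_cdk, r=r),
                           epsilon=eps_cdk, multiply_by_input=True)
    return EmbryonicParams(b_syn=c, b_deg=1.0, apc_switch=apc, cdk_switch=cdk,
                           delay=delay)


def apply_schedule(system: ModelSystem, schedule: ParameterSchedule
                   ) -> ModelSystem:
    """Attach a perturbation schedule; integration restarts at window edges."""
    return system.with_schedule(schedule)
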