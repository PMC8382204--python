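"""Biological use-cases built on the interlinked cell-cycle model.

* Restriction point: once [E2F]* has switched on, a tenfold drop in CycD
  synthesis no longer stops the started division round.
* DNA damage in G1: a threefold increase of the basal CycD degradation
  offset keeps [CycD] below the E2F activation threshold and lengthens
  interphase.
* DNA damage in G2: widening the CycB->Cdk1 switch (``alpha_cdk = 30``)
  shifts the Cdk1 activation threshold to higher [CycB]; cells recovering
  from damage enter mitosis with more CycB, while damage repaired before the
  unperturbed threshold crossing leaves interphase unchanged.
* Circadian forcing: the bend strength of the Cdk1 switch follows
  ``alpha_cdk + A + A sin(omega t)`` (a Wee1-mediated, clock-driven shift of
  the mitotic-entry threshold); p:q phase locking between the forced cell
  cycle and the 24 h clock is detected from the repeat period of the [Cdk1]
  series, and Arnold-tongue maps chart the locked regions.

Interphase elongation is measured between successive [APC]* activation
onsets, perturbed minus baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .dynalysis import (InsufficientDataError, SweepGrid, Trajectory,
                        integrate, oscillation_metrics)
from .modelzoo import (ModelSystem, ParameterSchedule, ScheduleWindow,
                       SomaticParams, build_interlinked)

__all__ = [
    "ForcingSpec",
    "LockingResult",
    "restriction_point_run",
    "dna_damage_g1",
    "dna_damage_g2",
    "circadian_run",
    "detect_locking",
    "arnold_map",
    "tune_natural_period",
    "activation_onsets",
]

M_THRESHOLD = 0.95
HOUR = 60.0  # minutes


@dataclass(frozen=True)
class ForcingSpec:
    """Sinusoidal circadian forcing of the Cdk1-switch bend strength.

    The effective bend is ``alpha_cdk + A_cdk + A_cdk * sin(omega t + phase)``,
    oscillating between the basal level and ``alpha_cdk + 2 A_cdk``.
    """

    A_cdk: float
    period_h: float = 24.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.A_cdk < 0:
            raise ValueError("coupling amplitude A_cdk must be >= 0")
        if self.period_h <= 0:
            raise ValueError("forcing period must be positive")

    @property
    def omega(self) -> float:
        """Angular frequency in rad/min."""
        return 2.0 * math.pi / (self.period_h * HOUR)

    def alpha_fn(self, alpha_base: float):
        A, w, ph = self.A_cdk, self.omega, self.phase
        return lambda t: alpha_base + A + A * math.sin(w * t + ph)


@dataclass
class LockingResult:
    locked: bool
    p: Optional[int] = None  # cell cycles per repeat
    q: Optional[int] = None  # forcing cycles per repeat
    forced_period_h: float = float("nan")
    repeat_period_h: float = float("nan")
    mismatch: float = float("nan")


def activation_onsets(traj: Trajectory, var: str = "APC",
                      threshold: float = M_THRESHOLD) -> np.ndarray:
    """Times of upward threshold crossings (linearly interpolated)."""
    x = traj.var(var)
    t = traj.t
    idx = np.where((x[:-1] <= threshold) & (x[1:] > threshold))[0]
    out = []
    for i in idx:
        frac = (threshold - x[i]) / (x[i + 1] - x[i])
        out.append(t[i] + frac * (t[i + 1] - t[i]))
    return np.array(out)


def _baseline_run(system: ModelSystem, t_span, n_out, rtol, atol):
    return integrate(system, t_span=t_span, n_out=n_out, rtol=rtol, atol=atol)


def restriction_point_run(params: SomaticParams,
                          reduction_factor: float = 10.0,
                          window: Optional[tuple[float, float]] = None,
                          t_span: tuple[float, float] = (0.0, 4000.0),
                          n_out: int = 8001, rtol: float = 1e-7,
                          atol: float = 1e-9):
    """Reduce CycD synthesis after E2F activation; the started division round
    should still complete (APC/C reaches its M-phase level).

    Returns ``(trajectory, completed, baseline_trajectory)``.
    """
    system = build_interlinked(params)
    base = _baseline_run(system, t_span, n_out, rtol, atol)
    e2f_on = activation_onsets(base, "E2F")
    apc_on = activation_onsets(base, "APC")
    if len(e2f_on) == 0:
        raise InsufficientDataError("baseline run never activates E2F")
    t_e2f = e2f_on[0]
    if window is None:
        # default: start mid-S/G2.  Commitment is only effective once [CycD]
        # has overshot the E2F inactivation threshold far enough that E2F
        # stays on until mitotic entry; right at the activation knee [CycD]
        # barely exceeds the activation threshold and can still fall back.
        apc_next = apc_on[apc_on > t_e2f]
        mid = (0.5 * (t_e2f + apc_next[0]) if len(apc_next)
               else t_e2f + 0.25 * (t_span[1] - t_e2f))
        window = (mid, t_span[1])
    if window[0] <= t_e2f:
        raise ValueError(
            "window must start after the first E2F activation "
            f"(t = {t_e2f:.1f} min); earlier starts are a different experiment")
    sched = ParameterSchedule((ScheduleWindow(window[0], window[1], "d_syn",
                                              1.0 / reduction_factor,
                                              mode="multiply"),))
    traj = integrate(system.with_schedule(sched), t_span=t_span, n_out=n_out,
                     rtol=rtol, atol=atol)
    apc_first = apc_on[apc_on > t_e2f]
    horizon = (apc_first[0] + 0.5 * (apc_on[1] - apc_on[0])
               if len(apc_on) >= 2 and len(apc_first) else t_span[1])
    pert_on = activation_onsets(traj, "APC")
    completed = bool(np.any((pert_on >= window[0] - 1e-9)
                            & (pert_on <= horizon))
                     or np.any(pert_on <= window[0]))
    # "completed" means the cycle started before the window still reaches M
    completed = bool(len(pert_on) > 0 and pert_on[0] <= horizon)
    return traj, completed, base


def _cycle_elongation(base: Trajectory, pert: Trajectory,
                      window_start: float) -> float:
    """Difference of the APC activation onset ending the perturbed cycle."""
    a = activation_onsets(base, "APC")
    b = activation_onsets(pert, "APC")
    if len(a) == 0:
        raise InsufficientDataError("baseline run never reaches M phase")
    nxt = np.searchsorted(a, window_start)
    if nxt >= len(a):
        raise InsufficientDataError("window lies beyond the last baseline cycle")
    if nxt >= len(b):
        return float(pert.t[-1] - a[nxt])  # lower bound: arrest within span
    return float(b[nxt] - a[nxt])


def dna_damage_g1(params: SomaticParams, delta_d_factor: float = 3.0,
                  window: tuple[float, float] = (0.0, 0.0),
                  t_span: tuple[float, float] = (0.0, 4000.0),
                  n_out: int = 8001, rtol: float = 1e-7, atol: float = 1e-9):
    """Increase basal CycD degradation (delta_d) during a G1 window.

    Returns ``(trajectory, interphase_elongation_min, baseline)``.
    """
    system = build_interlinked(params)
    base = _baseline_run(system, t_span, n_out, rtol, atol)
    if window[1] <= window[0]:
        return base, 0.0, base
    sched = ParameterSchedule((ScheduleWindow(window[0], window[1], "delta_d",
                                              delta_d_factor, mode="multiply"),))
    traj = integrate(system.with_schedule(sched), t_span=t_span, n_out=n_out,
                     rtol=rtol, atol=atol)
    return traj, _cycle_elongation(base, traj, window[0]), base


@dataclass
class G2DamageResult:
    trajectory: Trajectory
    elongation: float          # min
    mitotic_cycb: float        # nM, [CycB] at M-phase onset
    baseline_mitotic_cycb: float
    baseline: Trajectory


def dna_damage_g2(params: SomaticParams, alpha_damage: float = 30.0,
                  window: tuple[float, float] = (0.0, 0.0),
                  t_span: tuple[float, float] = (0.0, 4000.0),
                  n_out: int = 8001, rtol: float = 1e-7, atol: float = 1e-9
                  ) -> G2DamageResult:
    """Widen the CycB->Cdk1 switch (``alpha_cdk = alpha_damage``) during an
    S/G2 window, shifting the Cdk1 activation threshold to higher [CycB]."""
    from .modelzoo import validate_alpha_lower

    validate_alpha_lower(alpha_damage, params.r)
    system = build_interlinked(params)
    base = _baseline_run(system, t_span, n_out, rtol, atol)
    if window[1] <= window[0]:
        cycb0 = _cycb_at_m_onset(base, 0.0)
        return G2DamageResult(base, 0.0, cycb0, cycb0, base)
    sched = ParameterSchedule((ScheduleWindow(window[0], window[1],
                                              "alpha_cdk", alpha_damage),))
    traj = integrate(system.with_schedule(sched), t_span=t_span, n_out=n_out,
                     rtol=rtol, atol=atol)
    elong = _cycle_elongation(base, traj, window[0])
    return G2DamageResult(
        traj, elong,
        mitotic_cycb=_cycb_at_m_onset(traj, window[0]),
        baseline_mitotic_cycb=_cycb_at_m_onset(base, window[0]),
        baseline=base)


def _cycb_at_m_onset(traj: Trajectory, after: float) -> float:
    onsets = activation_onsets(traj, "APC")
    onsets = onsets[onsets >= after]
    if len(onsets) == 0:
        return float("nan")
    return float(np.interp(onsets[0], traj.t, traj.var("CycB")))


# ---------------------------------------------------------------------------
# circadian forcing and phase locking


def circadian_run(params: SomaticParams, forcing: ForcingSpec,
                  t_span: tuple[float, float], n_out: int = 8001,
                  rtol: float = 1e-6, atol: float = 1e-9) -> Trajectory:
    """Integrate the interlinked model with sinusoidally forced alpha_cdk.

    ``A_cdk = 0`` reduces exactly to the autonomous model.
    """
    system = build_interlinked(params)
    if forcing.A_cdk > 0:
        system = system.with_time_varying(
            alpha_cdk=forcing.alpha_fn(params.alpha_cdk))
    traj = integrate(system, t_span=t_span, n_out=n_out, rtol=rtol, atol=atol)
    traj.meta["forcing"] = {"A_cdk": forcing.A_cdk,
                            "period_h": forcing.period_h,
                            "phase": forcing.phase}
    return traj


def detect_locking(traj: Trajectory, forcing: ForcingSpec,
                   transient_fraction: float = 0.5,
                   mismatch_tol: float = 1e-2, ratio_tol: float = 0.02,
                   pq_max: int = 5) -> LockingResult:
    """Detect p:q phase locking from the repeat period of the [Cdk1] series.

    The normalized RMS mismatch between the post-transient series and
    time-shifted copies of itself is scanned over shifts up to ``pq_max``
    forcing periods; the repeat period is the smallest shift whose local
    mismatch minimum falls below ``mismatch_tol``.  The repeat must span an
    integer number ``q <= pq_max`` of forcing cycles (within ``ratio_tol``)
    and contain an integer number ``p <= pq_max`` of [Cdk1] peaks; the
    forced cell-cycle period is repeat/p.
    """
    Tf = forcing.period_h * HOUR
    if traj.span < 2 * pq_max * Tf:
        raise InsufficientDataError(
            "trajectory must span at least twice the maximal repeat period "
            "after transient removal")
    cut = traj.t[0] + transient_fraction * traj.span
    mask = traj.t >= cut
    t, x = traj.t[mask], traj.var("Cdk1")[mask]
    dt = float(np.median(np.diff(t)))
    x = x - np.mean(x)
    denom = float(np.sqrt(np.mean(x**2)))
    if denom <= 0:
        return LockingResult(locked=False)
    k_lo = max(int(0.5 * Tf / dt), 1)
    k_hi = int(min((pq_max + 0.4) * Tf / dt, len(x) // 2))
    if k_hi <= k_lo + 2:
        raise InsufficientDataError("too few samples for the shift scan")
    ks = np.arange(k_lo, k_hi)
    n_cmp = len(x) - k_hi
    mism = np.array([
        np.sqrt(np.mean((x[:n_cmp] - x[k:k + n_cmp]) ** 2)) / denom
        for k in ks])
    # smallest shift that is a local minimum below tolerance
    best = None
    for j in range(1, len(ks) - 1):
        if (mism[j] < mismatch_tol and mism[j] <= mism[j - 1]
                and mism[j] <= mism[j + 1]):
            best = j
            break
    if best is None:
        return LockingResult(locked=False,
                             mismatch=float(np.min(mism)))
    # parabolic refinement of the minimum
    a, b, c = mism[best - 1], mism[best], mism[best + 1]
    shift = ks[best] + (0.5 * (a - c) / (a - 2 * b + c)
                        if (a - 2 * b + c) > 0 else 0.0)
    repeat = float(shift * dt)
    q = round(repeat / Tf)
    if not (1 <= q <= pq_max) or abs(repeat / (q * Tf) - 1.0) > ratio_tol:
        return LockingResult(locked=False, mismatch=float(b),
                             repeat_period_h=repeat / HOUR)
    # count Cdk1 peaks per repeat window
    from scipy.signal import find_peaks

    amp = np.max(x) - np.min(x)
    pk, _ = find_peaks(x, prominence=0.2 * amp)
    if len(pk) == 0:
        return LockingResult(locked=False, mismatch=float(b),
                             repeat_period_h=repeat / HOUR)
    span = t[-1] - t[0]
    peaks_per_repeat = len(pk) * repeat / span
    p = round(peaks_per_repeat)
    if not (1 <= p <= pq_max) or abs(peaks_per_repeat - p) > 0.25:
        return LockingResult(locked=False, mismatch=float(b),
                             repeat_period_h=repeat / HOUR)
    return LockingResult(locked=True, p=p, q=q,
                         forced_period_h=repeat / p / HOUR,
                         repeat_period_h=repeat / HOUR,
                         mismatch=float(b))


def tune_natural_period(target_h: float, params: SomaticParams = SomaticParams(),
                        tol: float = 0.01, max_iter: int = 12,
                        n_cycles: float = 12.0, rtol: float = 1e-6,
                        atol: float = 1e-9, n_out_per_cycle: int = 400,
                        ) -> tuple[SomaticParams, float]:
    """Adjust d_syn by a secant search until the unforced cell-cycle period
    hits ``target_h`` hours within ``tol`` (relative).

    CycD synthesis is the primary period knob of the interlinked model: it
    sets how fast [CycD] climbs to the E2F activation threshold and hence
    the G1 duration.  Returns the tuned parameters and the achieved period.
    """
    target = target_h * HOUR

    def period_of(d_syn: float) -> float:
        p = SomaticParams(**{**vars(params), "d_syn": d_syn})
        system = build_interlinked(p)
        t_end = n_cycles * max(target, 1200.0)
        traj = integrate(system, t_span=(0.0, t_end),
                         n_out=int(n_cycles * n_out_per_cycle) + 1,
                         rtol=rtol, atol=atol)
        summ = oscillation_metrics(traj, var="Cdk1", height_tol=0.05)
        if not summ.sustained:
            raise InsufficientDataError(
                f"no sustained oscillation at d_syn = {d_syn}")
        return summ.period

    d0 = params.d_syn
    P0 = period_of(d0)
    if abs(P0 - target) / target <= tol:
        return SomaticParams(**{**vars(params), "d_syn": d0}), P0 / HOUR
    # period decreases with d_syn; start the secant from a scaled guess
    d1 = d0 * (P0 / target)
    P1 = period_of(d1)
    for _ in range(max_iter):
        if abs(P1 - target) / target <= tol:
            break
        if P1 == P0:
            d1 *= 1.05
            P1 = period_of(d1)
            continue
        d2 = d1 - (P1 - target) * (d1 - d0) / (P1 - P0)
        d2 = min(max(d2, 0.1 * d1), 10.0 * d1)
        d0, P0, d1 = d1, P1, d2
        P1 = period_of(d1)
    return SomaticParams(**{**vars(params), "d_syn": d1}), P1 / HOUR


def scan_coupling_for_lock(params: SomaticParams, natural_period_h: float,
                           A_ladder: Sequence[float] = (2.0, 5.0, 10.0, 15.0,
                                                        20.0, 25.0, 30.0,
                                                        40.0),
                           forcing_period_h: float = 24.0,
                           n_periods: float = 40.0,
                           require_longer: bool = False,
                           n_out: int = 8001, rtol: float = 1e-6,
                           **detect_kwargs
                           ) -> Optional[tuple[float, LockingResult]]:
    """Scan the coupling amplitude ladder and return the first qualifying
    p:q lock.

    With ``require_longer`` the lock must also lengthen the cell cycle
    (forced period strictly above the natural one) — relevant when the
    natural and forcing periods already coincide, where a trivial 1:1 lock
    at the natural period would be reported otherwise.
    """
    t_end = n_periods * forcing_period_h * HOUR
    for A in A_ladder:
        forcing = ForcingSpec(A_cdk=A, period_h=forcing_period_h)
        traj = circadian_run(params, forcing, (0.0, t_end), n_out=n_out,
                             rtol=rtol)
        res = detect_locking(traj, forcing, **detect_kwargs)
        if not res.locked:
            continue
        if require_longer and res.forced_period_h <= 1.02 * natural_period_h:
            continue
        return A, res
    return None


def arnold_map(params: SomaticParams, ratios: Sequence[float],
               A_values: Sequence[float], natural_period_h: float,
               n_periods: float = 40.0, n_out: int = 6001,
               rtol: float = 1e-6, **detect_kwargs) -> SweepGrid:
    """Locking map over (omega_cdk / omega_circadian, A_cdk).

    ``natural_period_h`` is the unforced period of ``params`` (computed by
    the caller, e.g. via :func:`tune_natural_period` or oscillation metrics);
    each ratio sets the forcing period to ``natural_period_h / ratio``.
    """
    records = []
    for ratio in ratios:
        period_h = natural_period_h / ratio
        for A in A_values:
            rec: dict[str, Any] = {"ratio": ratio, "A_cdk": A, "error": ""}
            try:
                forcing = ForcingSpec(A_cdk=A, period_h=period_h)
                t_end = n_periods * period_h * HOUR
                traj = circadian_run(params, forcing, (0.0, t_end),
                                     n_out=n_out, rtol=rtol)
                lock = detect_locking(traj, forcing, **detect_kwargs)
                rec.update(locked=lock.locked, p=lock.p, q=lock.q,
                           forced_period_h=lock.forced_period_h,
                           mismatch=lock.mismatch)
            except Exception as exc:
                rec["error"] = f"{type(exc).__name__}: {exc}"
                rec["locked"] = None
            records.append(rec)
    return SweepGrid("ratio", "A_cdk", pd.DataFrame.from_records(records))
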