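"""Elastic-external-tendon (EET) assistance analysis of the hip.

The EET is modeled as a passive linear torsional spring of stiffness J
(Nm/rad) in parallel with the hip joint.  It engages only during hip
extension (δ < 0), storing energy that assists the subsequent flexion:
the assist moment magnitude is J·|δ| on the engaged set and zero
elsewhere.

The assist moment is debited against the flexor group's biological
moment: while M_J < M_T (the unassisted flexor total), the residual
flexor demand is M_Re = M_T − M_J and the extensors keep their baseline
role; once M_J exceeds M_T the surplus must be resisted by the extensor
group (M_Ex = M_T − M_J < 0).  Group demands are redistributed to
individual muscles in proportion to each muscle's unassisted share
(moment-arm ratio where a group's baseline moment vanishes), forces are
recovered through the moment arms, activations re-back-solved through the
tendon/fiber curves, and mechanical and metabolic work are integrated
over the cycle.  A stiffness sweep summarizes how moments, forces, muscle
moment distribution coefficients (MDC), powers and work shift between the
flexor and extensor groups as the spring stiffens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike

from . import hill_mtu as mtu
from .calibration import (
    CalibrationResult,
    ForwardResult,
    GaitTrajectory,
    back_solve_activation,
    fiber_state_from_force,
    forward_moment,
    periodic_derivative,
)
from .hill_mtu import CurveConfig, DEFAULT_CURVES
from .hip_geometry import EXTENSORS, FLEXORS, MUSCLES, HipAnthropometry

__all__ = [
    "EETConfig",
    "AssistResult",
    "eet_moment",
    "flexor_total",
    "residual_moments",
    "redistribute",
    "mdc",
    "muscle_power",
    "work_components",
    "stiffness_sweep",
    "DEFAULT_SWEEP",
]

#: Default stiffness sweep, Nm/rad.
DEFAULT_SWEEP = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0, 500.0, 600.0, 800.0)


@dataclass(frozen=True)
class EETConfig:
    """Spring stiffness and sweep list for the assistance analysis."""

    stiffness: float = 0.0
    sweep: tuple[float, ...] = DEFAULT_SWEEP

    def __post_init__(self) -> None:
        if self.stiffness < 0 or any(j < 0 for j in self.sweep):
            raise ValueError("stiffness values must be non-negative")
        if list(self.sweep) != sorted(self.sweep):
            raise ValueError("sweep must be sorted ascending")


def eet_moment(delta_series: ArrayLike, stiffness: float):
    """EET assist-moment magnitude M_J(t) = J·|δ| on δ < 0, else 0 (Nm).

    The spring engages only in hip extension; the returned magnitude is
    flexion-assisting and linear in stiffness on the engaged set.
    """
    if stiffness < 0:
        raise ValueError("stiffness must be non-negative")
    d = np.asarray(delta_series, dtype=float)
    out = np.where(d < 0, stiffness * np.abs(d), 0.0)
    return out if out.ndim else float(out)


def flexor_total(baseline: ForwardResult) -> np.ndarray:
    """Unassisted flexor-group moment M_T = M_iliopsoas + M_rectus (Nm)."""
    return baseline.moment["iliopsoas"] + baseline.moment["rectus_femoris"]


def residual_moments(m_t: ArrayLike, m_j: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    """Residual flexor moment M_Re and extensor resistance M_Ex.

    Where M_J < M_T: M_Re = M_T − M_J and M_Ex = 0.  Where M_J > M_T:
    M_Re = 0 and M_Ex = M_T − M_J (negative — the extensors must resist
    the surplus assist).  Both are zero, hence continuous, at M_J = M_T.
    """
    t = np.asarray(m_t, dtype=float)
    j = np.asarray(m_j, dtype=float)
    if t.shape != j.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {j.shape}")
    diff = t - j
    return np.maximum(diff, 0.0), np.minimum(diff, 0.0)


def muscle_power(f_mut: ArrayLike, v_mut: ArrayLike):
    """Muscle power P = F·V, W, with shortening (concentric) positive."""
    f = np.asarray(f_mut, dtype=float)
    v = np.asarray(v_mut, dtype=float)
    if f.shape != v.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {v.shape}")
    out = f * v
    return out if out.ndim else float(out)


def mdc(
    per_muscle_moment: dict[str, np.ndarray],
    grid: np.ndarray,
    window: tuple[float, float],
) -> dict[str, float]:
    """Muscle moment distribution coefficients within one group.

    MDC_i = (∫_window |M_i| dt) / (Σ_k ∫_window |M_k| dt) for the two
    muscles of a functional group; coefficients lie in [0, 1] and sum to
    1.  A window over which the whole group's moment vanishes yields NaN
    coefficients (flagged undefined).
    """
    if len(per_muscle_moment) != 2:
        raise ValueError("a muscle group has exactly two members")
    w0, w1 = window
    if not (0.0 <= w0 < w1 <= 100.0):
        raise ValueError("window must be a non-empty sub-interval of [0, 100]")
    mask = (grid >= w0) & (grid <= w1)
    if mask.sum() < 2:
        raise ValueError("window contains fewer than two grid samples")
    integrals = {
        m: float(np.trapezoid(np.abs(v[mask]), grid[mask]))
        for m, v in per_muscle_moment.items()
    }
    total = sum(integrals.values())
    if total == 0.0:
        return {m: math.nan for m in per_muscle_moment}
    return {m: integrals[m] / total for m in per_muscle_moment}


@dataclass
class AssistResult:
    """Per-stiffness time series and cycle summaries of the assisted hip."""

    stiffness: float
    grid: np.ndarray
    assist_moment: np.ndarray  # M_J(t), Nm (flexion-assisting magnitude)
    residual_flexion: np.ndarray  # M_Re(t), Nm
    extensor_resistance: np.ndarray  # M_Ex(t), Nm (<= 0)
    flexor_total_unassisted: np.ndarray  # M_T(t), Nm
    bio_moment: np.ndarray  # net biological hip moment after assistance, Nm
    moment: dict[str, np.ndarray]
    force: dict[str, np.ndarray]
    power: dict[str, np.ndarray]  # fiber power per muscle, W
    activations: dict[str, np.ndarray]
    mdc_flexor: dict[str, float]
    mdc_extensor: dict[str, float]
    work: dict[str, float]  # J: hip_joint, mtu, fiber, tendon, knee_proxy
    metabolic_work: float  # J
    window: tuple[float, float]


def _engaged_window(gait: GaitTrajectory) -> tuple[float, float]:
    """% GC interval on which the hip is extended (spring engaged)."""
    neg = gait.grid[gait.hip_angle < 0]
    if neg.size < 2:
        return (0.0, 100.0)
    return (float(neg.min()), float(neg.max()))


def _shares(baseline_moments: dict[str, np.ndarray], arms: dict[str, np.ndarray], names):
    """Per-sample within-group shares, with arm-ratio fallback at zero baseline."""
    total = sum(baseline_moments[m] for m in names)
    arm_total = sum(arms[m] for m in names)
    shares = {}
    eps = 1e-12
    for m in names:
        fallback = arms[m] / np.maximum(arm_total, eps)
        shares[m] = np.where(total > eps, baseline_moments[m] / np.where(total > eps, total, 1.0), fallback)
    return shares, total


def redistribute(
    gait: GaitTrajectory,
    calib: CalibrationResult,
    stiffness: float,
    anthro: HipAnthropometry,
    curves: CurveConfig = DEFAULT_CURVES,
    baseline: ForwardResult | None = None,
    window: tuple[float, float] | None = None,
) -> AssistResult:
    """Full single-stiffness assistance analysis.

    Splits the assisted flexor demand M_Re between iliopsoas and rectus
    femoris and the extensor demand (baseline plus surplus resistance
    |M_Ex|) between gluteus maximus and hamstring, each in proportion to
    the muscle's unassisted share at the same sample; recovers forces
    through the moment arms, re-back-solves activations, and integrates
    the power and work accounting.  At zero stiffness every channel
    reproduces the unassisted baseline.
    """
    if stiffness < 0:
        raise ValueError("stiffness must be non-negative")
    base = baseline or forward_moment(gait, calib.model, calib.muscles, anthro, curves)
    dt = gait.dt
    window = window or _engaged_window(gait)

    m_j = eet_moment(gait.hip_angle, stiffness)
    m_t = flexor_total(base)
    m_re, m_ex = residual_moments(m_t, m_j)

    new_moment: dict[str, np.ndarray] = {}
    for names, demand in (
        (FLEXORS, m_re),
        (EXTENSORS, sum(base.moment[m] for m in EXTENSORS) + np.abs(m_ex)),
    ):
        shares, total = _shares(base.moment, base.u, names)
        for m in names:
            # additive form is exact (bit-for-bit) when demand == baseline total
            new_moment[m] = base.moment[m] + shares[m] * (demand - total)

    force: dict[str, np.ndarray] = {}
    power: dict[str, np.ndarray] = {}
    acts: dict[str, np.ndarray] = {}
    fiber_p = np.zeros(gait.n)
    tendon_p = np.zeros(gait.n)
    mtu_p = np.zeros(gait.n)
    metab = 0.0
    times = gait.times
    for m in MUSCLES:
        params = calib.muscles[m]
        fmax_eff = base.fmax_eff[m]
        if stiffness == 0.0:
            f = base.force[m].copy()
        else:
            # force change through the moment arm; the baseline-anchored
            # delta form stays finite (and keeps the baseline force) at
            # samples where the calibrated arm vanishes
            f = base.force[m] + (new_moment[m] - base.moment[m]) / np.maximum(base.u[m], 1e-3)
            f = np.maximum(f, 0.0)
        force[m] = f
        l_mut, v_mut, l_t = fiber_state_from_force(f, base.l_mt[m], params, fmax_eff, dt, curves)
        v_mtu = -periodic_derivative(base.l_mt[m], dt)
        v_t = -periodic_derivative(l_t, dt)
        p_fib = muscle_power(f, math.cos(params.pennation) * v_mut)
        power[m] = p_fib
        fiber_p = fiber_p + p_fib
        tendon_p = tendon_p + muscle_power(f, v_t)
        mtu_p = mtu_p + muscle_power(f, v_mtu)
        b = back_solve_activation(f, base.l_mt[m], params, fmax_eff, dt, curves, clip_velocity=True)
        acts[m] = b
        metab += mtu.metabolic_work(
            mtu.metabolic_power(np.clip(b, 0.0, 1.0), params, v_mut / params.v_max), times
        )

    bio = (new_moment["iliopsoas"] + new_moment["rectus_femoris"]) - (
        new_moment["gluteus_maximus"] + new_moment["hamstring"]
    ) - base.m_p
    hip_w = float(np.trapezoid(bio * gait.hip_velocity, times))
    knee_rate = periodic_derivative(gait.knee_angle, dt)
    knee_moment_proxy = (
        force["hamstring"] * anthro.knee_moment_arms["hamstring"]
        - force["rectus_femoris"] * anthro.knee_moment_arms["rectus_femoris"]
    )
    knee_w = float(np.trapezoid(knee_moment_proxy * knee_rate, times))

    return AssistResult(
        stiffness=float(stiffness),
        grid=gait.grid,
        assist_moment=m_j,
        residual_flexion=m_re,
        extensor_resistance=m_ex,
        flexor_total_unassisted=m_t,
        bio_moment=bio,
        moment=new_moment,
        force=force,
        power=power,
        activations=acts,
        mdc_flexor=mdc({m: new_moment[m] for m in FLEXORS}, gait.grid, window),
        mdc_extensor=mdc({m: new_moment[m] for m in EXTENSORS}, gait.grid, window),
        work={
            "hip_joint": hip_w,
            "mtu": float(np.trapezoid(mtu_p, times)),
            "fiber": float(np.trapezoid(fiber_p, times)),
            "tendon": float(np.trapezoid(tendon_p, times)),
            "knee_proxy": knee_w,
        },
        metabolic_work=metab,
        window=window,
    )


def work_components(assist_result: AssistResult) -> dict[str, float]:
    """Cycle work decomposition {hip_joint, mtu, fiber, tendon, knee_proxy}, J.

    The MTU work equals fiber plus tendon work by construction of the
    series decomposition; over a closed periodic cycle the elastic tendon
    nets approximately zero work.  The knee entry is a proxy — biarticular
    muscle force acting at the knee-level moment arms — since the model
    has no knee muscle mechanics.
    """
    return dict(assist_result.work)


def stiffness_sweep(
    gait: GaitTrajectory,
    calib: CalibrationResult,
    sweep: tuple[float, ...] = DEFAULT_SWEEP,
    anthro: HipAnthropometry | None = None,
    curves: CurveConfig = DEFAULT_CURVES,
    window: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, list[AssistResult]]:
    """One summary row per stiffness value (sorted ascending).

    Reports windowed-mean and peak biological moment, flexor/extensor
    group totals, MDCs, per-muscle peak force, the work decomposition and
    total metabolic work.  Deterministic; the first row at stiffness 0 is
    the unassisted baseline.
    """
    if len(sweep) == 0:
        raise ValueError("sweep must contain at least one stiffness")
    if list(sweep) != sorted(sweep):
        raise ValueError("sweep must be sorted ascending")
    anthro = anthro or HipAnthropometry.default()
    base = forward_moment(gait, calib.model, calib.muscles, anthro, curves)
    results = []
    rows = []
    for j in sweep:
        r = redistribute(gait, calib, j, anthro, curves, baseline=base, window=window)
        results.append(r)
        mask = (gait.grid >= r.window[0]) & (gait.grid <= r.window[1])
        row = {
            "stiffness": j,
            "bio_moment_peak": float(np.max(np.abs(r.bio_moment))),
            "bio_moment_window_mean": float(np.mean(r.bio_moment[mask])),
            "residual_flexor_window_mean": float(np.mean(r.residual_flexion[mask])),
            "extensor_total_window_mean": float(
                np.mean(sum(r.moment[m] for m in EXTENSORS)[mask])
            ),
            "assist_moment_peak": float(r.assist_moment.max()),
            "metabolic_work": r.metabolic_work,
        }
        for m in MUSCLES:
            row[f"peak_force_{m}"] = float(r.force[m].max())
        for m, v in r.mdc_flexor.items():
            row[f"mdc_{m}"] = v
        for m, v in r.mdc_extensor.items():
            row[f"mdc_{m}"] = v
        for k, v in r.work.items():
            row[f"work_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows), results
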