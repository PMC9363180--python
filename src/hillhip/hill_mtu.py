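"""Hill-type muscle-tendon unit (MTU) curve algebra and energetics.

A Hill-type MTU is the standard lumped-parameter muscle actuator: a
contractile element (CE) producing active force as a function of activation,
normalized fiber length and normalized fiber velocity; a parallel elastic
element (PEE) engaging when the fiber is stretched beyond its optimal
length; and a series elastic element (SEE, the tendon) transmitting the
combined fiber force to bone.  All curves here operate on dimensionless,
normalized quantities:

* fiber length is normalized by the optimal fiber length ``l0m``,
* fiber velocity by the maximum shortening velocity ``v_max``
  (shortening is the **positive** direction),
* tendon strain by the tendon slack length,
* forces by the maximum isometric force ``f_max``.

The module also provides the inverse maps needed by EMG-driven inverse
analyses — back-solving activation from a required CE force and tendon
strain from a required tendon force — and the empirical muscle metabolic
power model used to integrate metabolic energy over a gait cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "CurveConfig",
    "MuscleParams",
    "MTUState",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
    "tendon_force_length",
    "invert_tendon_force",
    "active_force",
    "solve_activation",
    "metabolic_rate_factor",
    "metabolic_power",
    "metabolic_work",
]

#: Default specific tension (N/m^2) used to derive f_max from PCSA.
DEFAULT_SPECIFIC_TENSION = 55.0e4  # 55 N/cm^2

#: Default maximum shortening velocity in optimal fiber lengths per second.
DEFAULT_VMAX_L0_PER_S = 10.0


@dataclass(frozen=True)
class CurveConfig:
    """Switches selecting the functional form of the normalized curves.

    ``active_fl_form``
        ``"peak-at-optimum"`` (default): exp(-|(l^0.87 - 1)/0.39|^3.19),
        which peaks at normalized length 1; ``"peak-shifted"`` reads the
        exponent as a divisor, exp(-|(l/0.87 - 1)/0.39|^3.19), peaking at
        0.87.
    ``passive_fl_form``
        ``"offset"`` (default): 0.0238*(exp(5.3*(l-1)) - 1) above optimal
        length, which rises from exactly zero at the onset;
        ``"no-offset"`` drops the trailing -1.
    ``tendon_strain_at_fmax``
        Strain at which the linear tendon curve reaches f_max
        (default 3.3%).
    ``fv_lengthening_const``
        The constant in the eccentric force-velocity branch denominator.
    ``clip_shortening``
        If True, normalized shortening velocities above 1 are clipped so
        the concentric branch saturates at zero force; if False they raise.
    """

    active_fl_form: str = "peak-at-optimum"
    passive_fl_form: str = "offset"
    tendon_strain_at_fmax: float = 0.033
    fv_lengthening_const: float = 30.24
    clip_shortening: bool = False

    def __post_init__(self) -> None:
        if self.active_fl_form not in ("peak-at-optimum", "peak-shifted"):
            raise ValueError(f"unknown active_fl_form {self.active_fl_form!r}")
        if self.passive_fl_form not in ("offset", "no-offset"):
            raise ValueError(f"unknown passive_fl_form {self.passive_fl_form!r}")
        if not self.tendon_strain_at_fmax > 0:
            raise ValueError("tendon_strain_at_fmax must be positive")


DEFAULT_CURVES = CurveConfig()


@dataclass
class MuscleParams:
    """Constant parameters of one muscle-tendon unit.

    Parameters
    ----------
    name
        Muscle identifier.
    f_max
        Maximum isometric force, N.  If not given it is derived as
        ``sigma * pcsa``.
    l0m
        Optimal fiber length, m.
    v_max
        Maximum shortening velocity, m/s.  If not given it defaults to
        ``10 * l0m`` per second.
    pennation
        Pennation angle, rad (angle between fiber and tendon line of
        action).  The fusiform simplification sets this to 0.
    l_slack
        Tendon slack length, m.
    pcsa
        Physiological cross-sectional area, m^2.
    sigma
        Specific tension, N/m^2.
    moment_arm
        Anatomical moment-arm length at the hip, m.
    """

    name: str
    l0m: float
    l_slack: float
    pcsa: float
    f_max: float | None = None
    v_max: float | None = None
    pennation: float = 0.0
    sigma: float = DEFAULT_SPECIFIC_TENSION
    moment_arm: float = 0.0
    vmax_tracks_l0: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.f_max is None:
            self.f_max = self.sigma * self.pcsa
        if self.v_max is None:
            self.v_max = DEFAULT_VMAX_L0_PER_S * self.l0m
        if not (self.f_max > 0 and self.l0m > 0 and self.v_max > 0):
            raise ValueError(f"{self.name}: f_max, l0m, v_max must be positive")
        if self.l_slack < 0:
            raise ValueError(f"{self.name}: l_slack must be non-negative")
        if not self.pcsa > 0:
            raise ValueError(f"{self.name}: pcsa must be positive")
        if not 0.0 <= self.pennation < math.pi / 2:
            raise ValueError(f"{self.name}: pennation must be in [0, pi/2)")

    def with_l0m(self, l0m: float) -> "MuscleParams":
        """Copy with a different optimal fiber length.

        If ``vmax_tracks_l0`` the maximum shortening velocity is rescaled
        proportionally (v_max expressed in optimal lengths per second is
        preserved).
        """
        v_max = self.v_max * (l0m / self.l0m) if self.vmax_tracks_l0 else self.v_max
        return MuscleParams(
            name=self.name,
            l0m=l0m,
            l_slack=self.l_slack,
            pcsa=self.pcsa,
            f_max=self.f_max,
            v_max=v_max,
            pennation=self.pennation,
            sigma=self.sigma,
            moment_arm=self.moment_arm,
            vmax_tracks_l0=self.vmax_tracks_l0,
        )


@dataclass
class MTUState:
    """Instantaneous state of one muscle-tendon unit.

    Lengths in m, velocity in m/s (shortening positive), forces in N.
    The force balance ``f_t = (f_ce + f_pee) * cos(pennation)`` and the
    length relation ``l_mt = l_mut * cos(pennation) + l_t`` must hold.
    """

    l_mt: float
    l_mut: float
    l_t: float
    v_mut: float
    activation: float
    f_ce: float
    f_pee: float
    f_t: float

    def validate(self, params: MuscleParams, tol: float = 1e-9) -> None:
        pen = params.pennation
        if abs(self.l_mt - (self.l_mut * math.cos(pen) + self.l_t)) > tol:
            raise ValueError("length relation l_mt = l_mut*cos(a) + l_t violated")
        if abs(self.f_t - (self.f_ce + self.f_pee) * math.cos(pen)) > tol:
            raise ValueError("force balance f_t = (f_ce + f_pee)*cos(a) violated")
        if min(self.f_ce, self.f_pee, self.f_t) < -tol:
            raise ValueError("forces must be non-negative")
        if not -tol <= self.activation <= 1 + tol:
            raise ValueError("activation must lie in [0, 1]")


# ---------------------------------------------------------------------------
# normalized curves
# ---------------------------------------------------------------------------

def active_force_length(l_norm: ArrayLike, curves: CurveConfig = DEFAULT_CURVES):
    """Normalized active force-length curve f(L̃) ∈ (0, 1].

    Default form ``exp(-|(L̃^0.87 - 1)/0.39|^3.19)``: unit peak at optimal
    fiber length, strictly decreasing away from it.
    """
    l = np.asarray(l_norm, dtype=float)
    if np.any(l <= 0):
        raise ValueError("normalized fiber length must be positive")
    if curves.active_fl_form == "peak-at-optimum":
        arg = (l**0.87 - 1.0) / 0.39
    else:  # peak-shifted
        arg = (l / 0.87 - 1.0) / 0.39
    out = np.exp(-np.abs(arg) ** 3.19)
    return out if out.ndim else float(out)


def force_velocity(v_norm: ArrayLike, curves: CurveConfig = DEFAULT_CURVES):
    """Normalized force-velocity curve, shortening positive.

    Concentric branch (v ≥ 0): ``(1 - v)/(1 + v)``, zero at v = 1.
    Eccentric branch (v < 0): ``1.8 - 0.8*(1 + v)/(1 - c*v)`` with
    c = 30.24; both branches equal 1 at v = 0.
    """
    v = np.asarray(v_norm, dtype=float)
    if np.any(v > 1.0):
        if not curves.clip_shortening:
            raise ValueError("normalized shortening velocity above 1 (clipping disabled)")
        v = np.minimum(v, 1.0)
    c = curves.fv_lengthening_const
    conc = (1.0 - v) / (1.0 + v)
    ecc = 1.8 - 0.8 * (1.0 + v) / (1.0 - c * v)
    out = np.where(v >= 0, conc, ecc)
    return out if out.ndim else float(out)


def passive_force_length(l_norm: ArrayLike, curves: CurveConfig = DEFAULT_CURVES):
    """Normalized passive (PEE) force-length curve.

    Zero at and below optimal fiber length; exponential
    ``0.0238*(exp(5.3*(L̃ - 1)) - 1)`` above it (default form).
    """
    l = np.asarray(l_norm, dtype=float)
    if np.any(l <= 0):
        raise ValueError("normalized fiber length must be positive")
    expo = 0.0238 * np.exp(5.3 * (l - 1.0))
    if curves.passive_fl_form == "offset":
        expo = expo - 0.0238
    out = np.where(l > 1.0, expo, 0.0)
    return out if out.ndim else float(out)


def tendon_force_length(lt_norm: ArrayLike, curves: CurveConfig = DEFAULT_CURVES):
    """Normalized tendon (SEE) force vs. tendon strain.

    The strain is ``(L_T - L_slack)/L_slack``; a slack tendon (strain ≤ 0)
    carries no force.  The default curve is linear with normalized force 1
    at 3.3% strain.
    """
    s = np.asarray(lt_norm, dtype=float)
    out = np.where(s > 0, s / curves.tendon_strain_at_fmax, 0.0)
    return out if out.ndim else float(out)


def invert_tendon_force(ft_norm: ArrayLike, curves: CurveConfig = DEFAULT_CURVES):
    """Tendon strain producing a required normalized tendon force.

    Inverse of :func:`tendon_force_length`; returns 0 for zero force.
    """
    f = np.asarray(ft_norm, dtype=float)
    if np.any(f < 0):
        raise ValueError("normalized tendon force must be non-negative")
    out = f * curves.tendon_strain_at_fmax
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# contractile element force and its inverse
# ---------------------------------------------------------------------------

def active_force(
    activation: ArrayLike,
    l_norm: ArrayLike,
    v_norm: ArrayLike,
    params: MuscleParams,
    curves: CurveConfig = DEFAULT_CURVES,
):
    """Contractile-element force F_CE = f_max · a · f_L(L̃) · f_V(Ṽ), in N."""
    a = np.asarray(activation, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    out = (
        params.f_max
        * a
        * active_force_length(l_norm, curves)
        * force_velocity(v_norm, curves)
    )
    return out if np.ndim(out) else float(out)


def solve_activation(
    f_ce_required: ArrayLike,
    l_norm: ArrayLike,
    v_norm: ArrayLike,
    params: MuscleParams,
    curves: CurveConfig = DEFAULT_CURVES,
):
    """Activation producing a required CE force at given fiber kinematics.

    F_CE is linear in activation, so the inverse is a division by the
    force capacity ``f_max · f_L · f_V``.  The result is returned even when
    it exceeds 1 — feasibility (0 ≤ b ≤ 1) is judged by the caller.
    """
    f = np.asarray(f_ce_required, dtype=float)
    if np.any(f < 0):
        raise ValueError("required CE force must be non-negative")
    capacity = (
        params.f_max
        * active_force_length(l_norm, curves)
        * force_velocity(v_norm, curves)
    )
    if np.any(np.asarray(capacity) <= 0):
        raise ArithmeticError("zero force capacity: activation is unsolvable here")
    out = f / capacity
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# metabolic energetics
# ---------------------------------------------------------------------------

def metabolic_rate_factor(v_norm: ArrayLike):
    """Dimensionless metabolic rate factor of the fiber, by velocity.

    Shortening branch (v ≥ 0): ``0.23 - 0.16*exp(-8 v)``; lengthening
    branch (v < 0): ``0.01 - 0.11 v + 0.06*exp(23 v)``.  Both branches
    evaluate to 0.07 at v = 0.
    """
    v = np.asarray(v_norm, dtype=float)
    short = 0.23 - 0.16 * np.exp(-8.0 * v)
    length = 0.01 - 0.11 * v + 0.06 * np.exp(23.0 * v)
    out = np.where(v >= 0, short, length)
    return out if out.ndim else float(out)


def metabolic_power(
    activation: ArrayLike,
    params: MuscleParams,
    v_norm: ArrayLike,
):
    """Instantaneous metabolic power P_ME = a · f_max · v_max · f_ME(Ṽ), W."""
    a = np.asarray(activation, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    out = a * params.f_max * params.v_max * metabolic_rate_factor(v_norm)
    return out if np.ndim(out) else float(out)


def metabolic_work(power_series: ArrayLike, time_grid: ArrayLike) -> float:
    """Metabolic energy over a cycle: trapezoidal integral of power, J."""
    p = np.asarray(power_series, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: power {p.shape} vs time {t.shape}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return float(np.trapezoid(p, t))
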