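"""Planar (sagittal-plane) hip musculoskeletal geometry.

Four muscles actuate the model hip: two flexors (iliopsoas, rectus
femoris) and two extensors (gluteus maximus, hamstring — the hamstring
lumping semitendinosus, semimembranosus and the long head of biceps
femoris).  Each muscle runs from a pelvis-frame origin to an insertion on
the thigh (monoarticular) or on the shank beyond the knee (biarticular:
rectus femoris, hamstring), so biarticular MTU lengths depend on both the
hip angle δ and the knee angle η.

Joint moments use the vertical-arm formulation M = F · U(β), where
U(β) = r · sin(β_eff): r is the anatomical moment-arm length and β_eff the
muscle's line-of-action angle.  The base angles β1..β6 are calibration
constants; by default each β_eff varies affinely with its joint angle
around the calibrated constant (a "constant-β" mode freezes them).

Sign convention: hip flexion positive; δ < 0 is extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from numpy.typing import ArrayLike

from .hill_mtu import DEFAULT_SPECIFIC_TENSION, MuscleParams

__all__ = [
    "MUSCLES",
    "FLEXORS",
    "EXTENSORS",
    "BETA_BOUNDS_DEG",
    "SCALE_BOUNDS",
    "HipAnthropometry",
    "PassiveMomentParams",
    "HipModelParams",
    "JointState",
    "GeometryError",
    "moment_arm",
    "mtu_length",
    "muscle_moment",
    "passive_joint_moment",
    "net_joint_moment",
    "group_scale",
    "default_muscle_set",
]

MUSCLES = ("iliopsoas", "rectus_femoris", "gluteus_maximus", "hamstring")
FLEXORS = ("iliopsoas", "rectus_femoris")
EXTENSORS = ("gluteus_maximus", "hamstring")
BIARTICULAR = ("rectus_femoris", "hamstring")

#: Bounds on the line-of-action angles β1..β6, degrees (β1 additionally
#: capped at 120°).
BETA_BOUNDS_DEG = (
    (12.0, 120.0),  # β1 iliopsoas
    (12.0, 145.0),  # β2 rectus femoris, hip
    (60.0, 180.0),  # β3 rectus femoris, knee coupling
    (35.0, 165.0),  # β4 gluteus maximus
    (35.0, 165.0),  # β5 hamstring, knee coupling
    (12.0, 145.0),  # β6 hamstring, hip
)
#: Bounds on the flexor/extensor maximum-force scaling variables m, n.
SCALE_BOUNDS = (0.5, 1.5)

# index of each muscle's hip-level β in the 6-vector, and the knee-coupling
# β index for biarticular muscles
_HIP_BETA_INDEX = {
    "iliopsoas": 0,
    "rectus_femoris": 1,
    "gluteus_maximus": 3,
    "hamstring": 5,
}
_KNEE_BETA_INDEX = {"rectus_femoris": 2, "hamstring": 4}


class GeometryError(ValueError):
    """Raised for geometrically impossible musculoskeletal configurations."""


@dataclass
class HipAnthropometry:
    """Segment lengths and per-muscle architecture of the planar hip model.

    Defaults (a 170 cm / 70 kg reference subject) are shipped in
    ``data/default_anthropometry.yaml``.
    """

    body_height: float
    body_mass: float
    thigh_link: float
    single_joint_insertion: float
    attachments: dict[str, np.ndarray]
    moment_arms: dict[str, float]
    knee_moment_arms: dict[str, float]
    pcsa: dict[str, float]  # m^2
    pennation: dict[str, float]  # rad

    def __post_init__(self) -> None:
        for v in (self.body_height, self.body_mass, self.thigh_link, self.single_joint_insertion):
            if not v > 0:
                raise ValueError("all anthropometric lengths/masses must be positive")
        if set(self.attachments) != set(MUSCLES):
            raise ValueError(f"exactly the four muscles {MUSCLES} are required")
        for name in MUSCLES:
            if not self.pcsa[name] > 0 or not self.moment_arms[name] > 0:
                raise ValueError(f"{name}: PCSA and moment arm must be positive")

    @classmethod
    def default(cls) -> "HipAnthropometry":
        raw = yaml.safe_load(
            resources.files("hillhip").joinpath("data/default_anthropometry.yaml").read_text()
        )
        mus = raw["muscles"]
        return cls(
            body_height=raw["body_height"],
            body_mass=raw["body_mass"],
            thigh_link=raw["thigh_link"],
            single_joint_insertion=raw["single_joint_insertion"],
            attachments={m: np.asarray(mus[m]["attachment"], dtype=float) for m in MUSCLES},
            moment_arms={m: float(mus[m]["moment_arm"]) for m in MUSCLES},
            knee_moment_arms={m: float(mus[m].get("knee_moment_arm", 0.0)) for m in MUSCLES},
            pcsa={m: float(mus[m]["pcsa_cm2"]) * 1e-4 for m in MUSCLES},
            pennation={m: math.radians(float(mus[m]["pennation_deg"])) for m in MUSCLES},
        )

    def sagittal_attachment(self, muscle: str) -> np.ndarray:
        """Sagittal-plane (x forward, y up) projection of a muscle origin."""
        return self.attachments[muscle][:2].astype(float)


@dataclass(frozen=True)
class PassiveMomentParams:
    """Joint-level passive elastic moment M_p(δ).

    Disabled by default (M_p ≡ 0) so calibration attributes all moment to
    muscles.  When enabled, a double-exponential restoring moment engages
    beyond a neutral band [band_lo, band_hi] (rad): positive (flexion)
    values of M_p oppose flexion through the net-moment sign convention.
    """

    enabled: bool = False
    k_flexion: float = 2.0  # Nm scale beyond the flexion end of the band
    k_extension: float = 2.0  # Nm scale beyond the extension end
    rate: float = 5.0  # 1/rad
    band_lo: float = math.radians(-10.0)
    band_hi: float = math.radians(25.0)


@dataclass
class HipModelParams:
    """Calibratable hip-model parameters H = [β1..β6, m, n].

    ``betas`` are the six line-of-action angles (rad); ``m_scale`` scales
    the flexor-group maximum isometric forces and ``n_scale`` the
    extensor-group ones.  ``kappa_hip``/``kappa_knee`` set how strongly
    each β_eff follows its joint angle (``constant_beta`` freezes both,
    reproducing a constant-moment-arm model).
    """

    betas: np.ndarray
    m_scale: float = 1.0
    n_scale: float = 1.0
    kappa_hip: float = 1.0
    kappa_knee: float = 0.5
    constant_beta: bool = False
    passive: PassiveMomentParams = field(default_factory=PassiveMomentParams)
    convention: str = "physiological"

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (6,):
            raise ValueError("betas must be a 6-vector [β1..β6]")
        if self.convention not in ("physiological", "literal"):
            raise ValueError(f"unknown convention {self.convention!r}")

    def validate_bounds(self) -> None:
        for i, (lo, hi) in enumerate(BETA_BOUNDS_DEG):
            b = math.degrees(self.betas[i])
            if not lo - 1e-9 <= b <= hi + 1e-9:
                raise ValueError(f"β{i + 1} = {b:.2f}° outside [{lo}°, {hi}°]")
        lo, hi = SCALE_BOUNDS
        for nm, v in (("m", self.m_scale), ("n", self.n_scale)):
            if not lo - 1e-9 <= v <= hi + 1e-9:
                raise ValueError(f"{nm} = {v} outside [{lo}, {hi}]")

    @classmethod
    def neutral(cls, **kw) -> "HipModelParams":
        """Mid-range parameter set (β at bound midpoints, m = n = 1)."""
        betas = np.array([math.radians(0.5 * (lo + hi)) for lo, hi in BETA_BOUNDS_DEG])
        return cls(betas=betas, **kw)


@dataclass(frozen=True)
class JointState:
    """Hip angle δ (rad, flexion positive), knee angle η (rad), hip rate."""

    delta: float
    eta: float = 0.0
    delta_dot: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.delta) > math.pi or abs(self.eta) > math.pi:
            raise ValueError("joint angles must lie within ±π")


def group_scale(muscle: str, model: HipModelParams) -> float:
    """F_max scaling for a muscle: m for flexors, n for extensors."""
    if muscle in FLEXORS:
        return model.m_scale
    if muscle in EXTENSORS:
        return model.n_scale
    raise KeyError(muscle)


def _effective_beta(muscle: str, delta, eta, model: HipModelParams):
    beta = model.betas[_HIP_BETA_INDEX[muscle]]
    if model.constant_beta:
        return np.broadcast_to(np.float64(beta), np.broadcast(np.asarray(delta), np.asarray(eta)).shape).copy() if np.ndim(delta) or np.ndim(eta) else beta
    sign = 1.0 if muscle in FLEXORS else -1.0
    eff = beta + sign * model.kappa_hip * np.asarray(delta, dtype=float)
    if muscle in _KNEE_BETA_INDEX:
        beta_knee = model.betas[_KNEE_BETA_INDEX[muscle]]
        eff = eff + model.kappa_knee * np.asarray(eta, dtype=float) * math.sin(beta_knee)
    return eff


def moment_arm(
    muscle: str,
    joint_state: JointState | tuple[ArrayLike, ArrayLike],
    model: HipModelParams,
    anthro: HipAnthropometry,
):
    """Vertical moment arm U(β) = r · sin(β_eff), m, clamped to [0, r].

    ``joint_state`` may be a :class:`JointState` or a ``(delta, eta)``
    pair of arrays for vectorized evaluation.
    """
    if muscle not in MUSCLES:
        raise KeyError(muscle)
    if isinstance(joint_state, JointState):
        delta, eta = joint_state.delta, joint_state.eta
    else:
        delta, eta = joint_state
    r = anthro.moment_arms[muscle]
    eff = np.clip(_effective_beta(muscle, delta, eta, model), 0.0, math.pi)
    out = r * np.sin(eff)
    return out if np.ndim(out) else float(out)


def _thigh_unit(angle):
    """Unit vector along a limb segment at ``angle`` from straight-down."""
    a = np.asarray(angle, dtype=float)
    return np.stack([np.sin(a), -np.cos(a)], axis=-1)


def mtu_length(
    muscle: str,
    joint_state: JointState | tuple[ArrayLike, ArrayLike],
    anthro: HipAnthropometry,
):
    """Origin-to-insertion MTU length L_MT over the planar two-link chain, m.

    Monoarticular muscles insert on the thigh at the single-joint
    insertion distance and depend on δ only; biarticular muscles insert on
    the shank beyond the knee and depend on δ and η (knee flexion η ≥ 0
    swings the shank backwards).
    """
    if muscle not in MUSCLES:
        raise KeyError(muscle)
    if isinstance(joint_state, JointState):
        delta, eta = joint_state.delta, joint_state.eta
        scalar = True
    else:
        delta, eta = joint_state
        scalar = np.ndim(delta) == 0 and np.ndim(eta) == 0
    delta = np.asarray(delta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    origin = anthro.sagittal_attachment(muscle)
    if muscle in BIARTICULAR:
        knee = anthro.thigh_link * _thigh_unit(delta)
        insertion = knee + anthro.single_joint_insertion * _thigh_unit(delta - eta)
    else:
        insertion = anthro.single_joint_insertion * _thigh_unit(delta)
    d2 = np.sum((insertion - origin) ** 2, axis=-1)
    if np.any(~np.isfinite(d2)) or np.any(d2 < 0):
        raise GeometryError(f"{muscle}: impossible configuration")
    out = np.sqrt(d2)
    return float(out) if scalar else out


def muscle_moment(f_mut: ArrayLike, u: ArrayLike):
    """Joint moment of one muscle, M = F_MUT · U(β), Nm."""
    f = np.asarray(f_mut, dtype=float)
    uu = np.asarray(u, dtype=float)
    if np.any(f < 0) or np.any(uu < 0):
        raise ValueError("force and moment arm must be non-negative")
    out = f * uu
    return out if np.ndim(out) else float(out)


def passive_joint_moment(delta: ArrayLike, params: PassiveMomentParams):
    """Joint-level passive elastic moment M_p(δ), Nm (0 when disabled).

    Positive M_p enters the net moment with a minus sign, so beyond the
    flexion end of the neutral band the passive element resists flexion
    and beyond the extension end it resists extension.
    """
    d = np.asarray(delta, dtype=float)
    if not params.enabled:
        out = np.zeros_like(d)
        return out if out.ndim else 0.0
    flex = params.k_flexion * (np.exp(params.rate * (d - params.band_hi)) - 1.0)
    ext = -params.k_extension * (np.exp(params.rate * (params.band_lo - d)) - 1.0)
    out = np.where(d > params.band_hi, flex, np.where(d < params.band_lo, ext, 0.0))
    return out if out.ndim else float(out)


def net_joint_moment(
    per_muscle_moments: dict[str, ArrayLike],
    m_p: ArrayLike = 0.0,
    convention: str = "physiological",
):
    """Net hip moment M_mo from the four muscle moments and M_p, Nm.

    ``physiological`` (default): flexors positive, extensors negative —
    M_mo = (M_ilio + M_rect) − (M_glut + M_ham) − M_p.  ``literal``
    follows the printed index signs instead:
    M_mo = (M_rect + M_ham) − (M_glut + M_ilio) − M_p.
    """
    if set(per_muscle_moments) != set(MUSCLES):
        raise ValueError(f"moments for exactly the four muscles {MUSCLES} are required")
    m = {k: np.asarray(v, dtype=float) for k, v in per_muscle_moments.items()}
    if convention == "physiological":
        pos, neg = FLEXORS, EXTENSORS
    elif convention == "literal":
        pos, neg = ("rectus_femoris", "hamstring"), ("gluteus_maximus", "iliopsoas")
    else:
        raise ValueError(f"unknown convention {convention!r}")
    out = sum(m[k] for k in pos) - sum(m[k] for k in neg) - np.asarray(m_p, dtype=float)
    return out if np.ndim(out) else float(out)


def default_muscle_set(
    anthro: HipAnthropometry | None = None,
    fusiform: bool = True,
    sigma: float = DEFAULT_SPECIFIC_TENSION,
) -> dict[str, MuscleParams]:
    """Build the four default :class:`MuscleParams` from anthropometry.

    Maximum isometric force is σ·PCSA.  Optimal fiber length defaults to
    45% of the neutral-pose MTU length and tendon slack length to the
    remaining 55%, so at δ = η = 0 the fiber sits at its optimum with the
    tendon just slack.  ``fusiform`` applies the zero-pennation
    simplification (the anthropometry retains the measured pennations for
    use when it is switched off).
    """
    anthro = anthro or HipAnthropometry.default()
    out: dict[str, MuscleParams] = {}
    for name in MUSCLES:
        l_mt0 = mtu_length(name, JointState(0.0, 0.0), anthro)
        l0m = 0.45 * l_mt0
        out[name] = MuscleParams(
            name=name,
            l0m=l0m,
            l_slack=l_mt0 - l0m,
            pcsa=anthro.pcsa[name],
            sigma=sigma,
            pennation=0.0 if fusiform else anthro.pennation[name],
            moment_arm=anthro.moment_arms[name],
        )
    return out
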