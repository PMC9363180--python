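"""Seeded synthetic gait-cycle generator.

Generates one normal-walking gait cycle with the structure the hip
analysis assumes: a periodic hip flexion/extension profile whose extension
(negative-angle) phase spans a configurable mid-stance window, a
double-bump knee flexion profile, a biphasic hip moment (extensor-negative
in early stance, flexor-positive in late stance under the
flexion-positive convention), and per-muscle activation bursts at
physiologically ordered phases — extensors in early stance, flexors around
pre-swing.

The hip angle is built from two half-sine segments pinned to the
extension window, so the sign structure (δ < 0 exactly and only inside
the window) holds by construction; the remaining channels use periodic
gaussian bumps in circular gait-cycle phase.  A second entry point
produces model-consistent data — the hip-moment channel computed by the
forward model at known "true" parameters — for parameter-recovery
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import ForwardResult, GaitTrajectory, forward_moment
from .hill_mtu import CurveConfig, DEFAULT_CURVES, MuscleParams
from .hip_geometry import MUSCLES, HipAnthropometry, HipModelParams

__all__ = ["GaitGenConfig", "ModelTruth", "generate_gait", "generate_from_model"]


def _default_bursts() -> dict[str, tuple[float, float, float]]:
    # (center % GC, width % GC, peak activation)
    return {
        "gluteus_maximus": (10.0, 10.0, 0.55),
        "hamstring": (3.0, 12.0, 0.50),
        "iliopsoas": (58.0, 10.0, 0.60),
        "rectus_femoris": (62.0, 11.0, 0.45),
    }


@dataclass
class GaitGenConfig:
    """Synthetic gait-cycle parameters.

    ``hip_range`` is (max flexion, max extension) in rad; the extension
    magnitude is reached mid-window.  ``extension_window`` is the % GC
    interval on which the hip angle is negative.  ``knee_range`` gives the
    stance and swing knee-flexion peaks (rad).  ``activation_bursts`` maps
    each muscle to a (center %, width %, peak) gaussian burst on top of a
    small tonic floor.  ``noise_sd`` applies multiplicative gaussian noise
    to the hip-moment channel only.
    """

    n_samples: int = 101
    cycle_duration: float = 1.1  # s
    hip_range: tuple[float, float] = (math.radians(30.0), math.radians(-12.0))
    knee_range: tuple[float, float] = (math.radians(15.0), math.radians(60.0))
    extension_window: tuple[float, float] = (30.0, 65.0)
    moment_amplitude: float = 50.0  # Nm, flexor-burst peak scale
    activation_bursts: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_bursts
    )
    activation_floor: float = 0.02
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        w0, w1 = self.extension_window
        if not (0.0 <= w0 < w1 <= 100.0):
            raise ValueError("extension window must lie inside [0, 100] with w0 < w1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for m, (_, w, pk) in self.activation_bursts.items():
            if not 0.0 <= pk <= 1.0 or w <= 0:
                raise ValueError(f"burst of {m}: peak must be in [0,1], width positive")
        if not 0.0 <= self.activation_floor <= 1.0:
            raise ValueError("activation_floor must be in [0, 1]")


def _circ_bump(p: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic gaussian bump in circular % GC phase, unit peak."""
    d = np.abs((p - center + 50.0) % 100.0 - 50.0)
    return np.exp(-0.5 * (d / width) ** 2)


def _hip_profile(p: np.ndarray, cfg: GaitGenConfig) -> np.ndarray:
    flex, ext = cfg.hip_range
    w0, w1 = cfg.extension_window
    inside = (p >= w0) & (p <= w1)
    # extension half-sine inside the window (ext is negative)
    d_in = ext * np.sin(math.pi * (p - w0) / (w1 - w0))
    # flexion half-sine over the wrapped complement
    q = (p - w1) % 100.0
    span = 100.0 - (w1 - w0)
    d_out = flex * np.sin(math.pi * q / span)
    d = np.where(inside, d_in, d_out)
    # snap sin(π) roundoff at the window edges to exact zeros
    return np.where(np.abs(d) < 1e-12, 0.0, d)


def generate_gait(config: GaitGenConfig | None = None) -> GaitTrajectory:
    """Generate one synthetic gait cycle (deterministic for fixed seed)."""
    cfg = config or GaitGenConfig()
    rng = np.random.default_rng(cfg.seed)
    p = np.linspace(0.0, 100.0, cfg.n_samples)

    hip = _hip_profile(p, cfg)
    stance_pk, swing_pk = cfg.knee_range
    knee = stance_pk * _circ_bump(p, 15.0, 10.0) + swing_pk * _circ_bump(p, 73.0, 12.0)
    moment = cfg.moment_amplitude * (
        -0.8 * _circ_bump(p, 12.0, 10.0) + _circ_bump(p, 52.0, 12.0)
    )

    acts: dict[str, np.ndarray] = {}
    for m in MUSCLES:
        c, w, pk = cfg.activation_bursts[m]
        a = cfg.activation_floor + (pk - cfg.activation_floor) * _circ_bump(p, c, w)
        acts[m] = np.clip(a, 0.0, 1.0)

    if cfg.noise_sd > 0:
        noise = 1.0 + cfg.noise_sd * rng.standard_normal(cfg.n_samples - 1)
        moment = moment.copy()
        moment[:-1] *= noise
        moment[-1] = moment[0]  # keep the duplicated endpoint periodic

    return GaitTrajectory(
        grid=p,
        time_scale=cfg.cycle_duration,
        hip_angle=hip,
        knee_angle=knee,
        hip_moment=moment,
        activations=acts,
    )


@dataclass
class ModelTruth:
    """Record of the ground-truth parameters behind model-generated gait."""

    model: HipModelParams
    muscles: dict[str, MuscleParams]
    forward: ForwardResult


def generate_from_model(
    model: HipModelParams,
    muscles: dict[str, MuscleParams],
    anthro: HipAnthropometry,
    base: GaitTrajectory,
    curves: CurveConfig = DEFAULT_CURVES,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[GaitTrajectory, ModelTruth]:
    """Model-consistent gait: the hip moment is the forward model's output.

    Takes the kinematics and activations of ``base``, computes the net
    hip moment at the supplied true parameters, and returns the trajectory
    whose moment channel is exactly that output (optionally with
    multiplicative noise), plus the ground-truth record.  Calibrating
    against the noiseless version must recover the generating parameters.
    """
    fwd = forward_moment(base, model, muscles, anthro, curves)
    moment = fwd.m_mo.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = 1.0 + noise_sd * rng.standard_normal(moment.size - 1)
        moment[:-1] *= noise
        moment[-1] = moment[0]
    gait = GaitTrajectory(
        grid=base.grid.copy(),
        time_scale=base.time_scale,
        hip_angle=base.hip_angle.copy(),
        knee_angle=base.knee_angle.copy(),
        hip_moment=moment,
        activations={m: a.copy() for m, a in base.activations.items()},
    )
    return gait, ModelTruth(model=model, muscles=muscles, forward=fwd)
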