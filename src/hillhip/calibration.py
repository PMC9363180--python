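"""Two-stage constrained calibration of the planar hip muscle model.

Stage 1 fits the geometric/scaling vector H = [β1..β6, m, n] by minimizing
the body-mass-normalized RMSE between the model's net hip moment and the
reference (biological) hip moment over one gait cycle, under box bounds on
every component.  The default optimizer is an in-house real-coded genetic
algorithm (tournament selection, blend crossover, gaussian mutation,
elitism) with an optional bounded local polish; scipy's differential
evolution is available as an alternative.

Stage 2 fits the optimal fiber lengths I = [l01..l04] per muscle: the
stage-1 per-muscle tendon-force traces are inverted through the tendon
curve to fiber kinematics, activation is back-solved sample by sample, and
among the candidate fiber lengths whose reconstructed activation trace is
feasible (0 ≤ b(t) ≤ 1) the one minimizing the cycle-minimum activation is
selected (a "max-margin" objective is available as a flag).

The forward model enforces the fiber/tendon force balance at every grid
sample with a vectorized bisection on fiber length; fiber velocity is
obtained by central finite differences over the periodic grid and relaxed
to self-consistency by damped outer iterations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike
from scipy import optimize as sciopt

from . import hill_mtu as mtu
from . import hip_geometry as geom
from .hill_mtu import CurveConfig, DEFAULT_CURVES, MuscleParams
from .hip_geometry import (
    EXTENSORS,
    FLEXORS,
    MUSCLES,
    HipAnthropometry,
    HipModelParams,
    group_scale,
)

__all__ = [
    "GaitTrajectory",
    "ForwardResult",
    "MTUKinetics",
    "solve_mtu_kinetics",
    "GAConfig",
    "OptHResult",
    "OptIResult",
    "CalibrationResult",
    "SolverError",
    "InfeasibilityError",
    "fiber_state_from_force",
    "back_solve_activation",
    "rmse",
    "r_squared",
    "forward_moment",
    "optimize_H",
    "optimize_I",
    "calibrate",
    "h_bounds",
    "periodic_derivative",
]


class SolverError(RuntimeError):
    """Force-balance failure; carries the offending muscle and sample."""

    def __init__(self, muscle: str, sample: int, detail: str = ""):
        self.muscle, self.sample = muscle, sample
        super().__init__(f"force balance failed for {muscle} at sample {sample} {detail}")


class InfeasibilityError(RuntimeError):
    """No feasible optimal fiber length for a muscle."""

    def __init__(self, muscle: str, detail: str = ""):
        self.muscle = muscle
        super().__init__(f"no feasible optimal fiber length for {muscle} {detail}")


@dataclass
class GaitTrajectory:
    """One gait cycle of joint kinematics, hip moment and activations.

    ``grid`` is percent of gait cycle (0 at the first sample, 100 at the
    last, strictly increasing and uniform); ``time_scale`` is the cycle
    duration in s.  Angles are in rad (flexion positive), the hip moment
    in Nm, activations dimensionless in [0, 1].  All channels are periodic
    (first and last sample equal), the last sample duplicating the first.
    """

    grid: np.ndarray
    time_scale: float
    hip_angle: np.ndarray
    knee_angle: np.ndarray
    hip_moment: np.ndarray
    activations: dict[str, np.ndarray]
    periodicity_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.hip_angle = np.asarray(self.hip_angle, dtype=float)
        self.knee_angle = np.asarray(self.knee_angle, dtype=float)
        self.hip_moment = np.asarray(self.hip_moment, dtype=float)
        self.activations = {k: np.asarray(v, dtype=float) for k, v in self.activations.items()}
        n = self.grid.size
        if n < 3 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing with >= 3 samples")
        if abs(self.grid[0]) > 1e-12 or abs(self.grid[-1] - 100.0) > 1e-12:
            raise ValueError("grid must start at 0 and end at 100 percent of the cycle")
        if not self.time_scale > 0:
            raise ValueError("cycle duration must be positive")
        if set(self.activations) != set(MUSCLES):
            raise ValueError(f"activations for exactly the muscles {MUSCLES} are required")
        for name, ch in self.channels().items():
            if ch.shape != self.grid.shape:
                raise ValueError(f"channel {name}: length {ch.size} != grid {n}")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name}: non-finite values")
            if abs(ch[0] - ch[-1]) > self.periodicity_tol * max(1.0, np.abs(ch).max()):
                warnings.warn(f"channel {name} is not periodic to tolerance", stacklevel=2)
        for m, a in self.activations.items():
            if np.any((a < -1e-12) | (a > 1 + 1e-12)):
                raise ValueError(f"activation of {m} outside [0, 1]")

    def channels(self) -> dict[str, np.ndarray]:
        out = {"hip_angle": self.hip_angle, "knee_angle": self.knee_angle, "hip_moment": self.hip_moment}
        out.update({f"act_{m}": a for m, a in self.activations.items()})
        return out

    @property
    def n(self) -> int:
        return self.grid.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in s."""
        return self.grid / 100.0 * self.time_scale

    @property
    def dt(self) -> float:
        """Uniform sample spacing in s."""
        steps = np.diff(self.times)
        if np.ptp(steps) > 1e-9 * steps.mean():
            raise ValueError("grid is not uniform")
        return float(steps.mean())

    @property
    def hip_velocity(self) -> np.ndarray:
        """Hip angular velocity δ̇ in rad/s (periodic central differences)."""
        return periodic_derivative(self.hip_angle, self.dt)


def periodic_derivative(x: ArrayLike, dt: float) -> np.ndarray:
    """Central finite differences of a periodic series.

    The series carries a duplicated endpoint (x[-1] == x[0]); differences
    wrap around the unique samples and the duplicate is filled back in.
    """
    x = np.asarray(x, dtype=float)
    u = x[..., :-1]  # unique cycle samples
    d = (np.roll(u, -1, axis=-1) - np.roll(u, 1, axis=-1)) / (2.0 * dt)
    return np.concatenate([d, d[..., :1]], axis=-1)


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------

def rmse(model_moment: ArrayLike, reference_moment: ArrayLike, body_mass: float = 1.0) -> float:
    """Root-mean-square error between two series, divided by body mass.

    With ``body_mass`` in kg and moments in Nm the result is in Nm/kg;
    with the default mass of 1 it is the raw RMSE in the series units.
    """
    m = np.asarray(model_moment, dtype=float)
    r = np.asarray(reference_moment, dtype=float)
    if m.shape != r.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {r.shape}")
    if m.size < 1:
        raise ValueError("series must contain at least one sample")
    return float(np.sqrt(np.mean((m - r) ** 2)) / body_mass)


def r_squared(model_moment: ArrayLike, reference_moment: ArrayLike, kind: str = "pearson") -> float:
    """Curve-similarity coefficient r².

    ``pearson`` (default): squared Pearson correlation, in [0, 1] and
    invariant to affine rescaling.  ``cod``: coefficient of determination
    1 − SS_res/SS_tot (may be negative for a poor fit).
    """
    m = np.asarray(model_moment, dtype=float)
    r = np.asarray(reference_moment, dtype=float)
    if m.shape != r.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {r.shape}")
    if np.std(m) == 0 or np.std(r) == 0:
        raise ValueError("zero-variance series: r² is degenerate")
    if kind == "pearson":
        c = np.corrcoef(m, r)[0, 1]
        return float(c * c)
    if kind == "cod":
        ss_res = np.sum((r - m) ** 2)
        ss_tot = np.sum((r - r.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

@dataclass
class ForwardResult:
    """Per-sample output of the forward (activation-driven) hip model."""

    m_mo: np.ndarray
    m_p: np.ndarray
    moment: dict[str, np.ndarray]
    force: dict[str, np.ndarray]  # tendon force F_T = F_MUT, N
    u: dict[str, np.ndarray]  # moment arms, m
    l_mt: dict[str, np.ndarray]
    l_mut: dict[str, np.ndarray]
    v_mut: dict[str, np.ndarray]  # fiber velocity, m/s, shortening positive
    fmax_eff: dict[str, float]
    residual: dict[str, np.ndarray]  # normalized force-balance residual

    def group_moment(self, group: str) -> np.ndarray:
        names = FLEXORS if group == "flexor" else EXTENSORS
        return sum(self.moment[m] for m in names)


@dataclass
class MTUKinetics:
    """Normalized fiber/tendon solution of all four MTUs over one cycle.

    The force balance in normalized form does not involve the maximum
    isometric force, so this solution is independent of the calibration
    vector H — the β angles enter only through moment arms and the m/n
    scales multiply both sides of the balance.  Solving it once lets the
    stage-1 optimizer evaluate candidate H vectors at negligible cost.

    Arrays are stacked (n_muscles, n_samples) in ``MUSCLES`` order.
    """

    f_tilde: np.ndarray  # normalized tendon force
    l_mut: np.ndarray  # fiber length, m
    v_mut: np.ndarray  # fiber velocity, m/s, shortening positive
    l_mt: np.ndarray  # MTU length, m
    residual: np.ndarray  # normalized balance residual at the solution
    v_consistency: float  # max |v - (-dl/dt)| achieved, m/s


# fiber-velocity clip used inside the balance solve; physiological gaits
# stay well inside these normalized bounds
_VNORM_CLIP = (-5.0, 0.95)


def _residual_fn(l_mt, act, v_norm, l0m, l_slack, cosa, curves):
    """Build a fast residual closure with the velocity factor precomputed.

    The force-velocity factor depends only on the frozen velocity, so it
    is evaluated once; the returned closure evaluates the normalized
    tendon-minus-fiber residual at a trial fiber length without input
    validation (the solver guarantees positive lengths).
    """
    k_t = 1.0 / curves.tendon_strain_at_fmax
    v = np.clip(v_norm, *_VNORM_CLIP)
    fv = np.where(v >= 0, (1.0 - v) / (1.0 + v),
                  1.8 - 0.8 * (1.0 + v) / (1.0 - curves.fv_lengthening_const * v))
    act_fv = act * fv
    shifted = curves.active_fl_form == "peak-shifted"
    offset = curves.passive_fl_form == "offset"

    def resid(l_mut):
        strain = (l_mt - l_mut * cosa - l_slack) / l_slack
        f_t = np.where(strain > 0, strain * k_t, 0.0)
        l_norm = l_mut / l0m
        base = l_norm / 0.87 if shifted else l_norm**0.87
        fl = np.exp(-np.abs((base - 1.0) / 0.39) ** 3.19)
        pee = 0.0238 * np.exp(5.3 * (l_norm - 1.0))
        if offset:
            pee = pee - 0.0238
        fpee = np.where(l_norm > 1.0, pee, 0.0)
        return f_t - (act_fv * fl + fpee) * cosa

    return resid


def _balance_residual(l_mut, l_mt, act, v_norm, l0m, l_slack, cosa, curves):
    """Normalized tendon-minus-fiber force residual at fiber length l_mut."""
    return _residual_fn(l_mt, act, v_norm, l0m, l_slack, cosa, curves)(l_mut)


def _solve_fiber_length(
    l_mt, act, v_norm, l0m, l_slack, cosa, curves, guess=None,
) -> np.ndarray:
    """Bisection for the fiber length satisfying the force balance.

    The residual is positive at vanishing fiber length (taut tendon, no
    fiber force) and non-positive at l_mut = L_MT/cosα (slack tendon), so
    a sign-bracketing bisection converges at every sample simultaneously.
    A ``guess`` from a previous velocity iterate narrows the bracket
    (widened back to the full one where the sign condition fails).
    """
    lo_full = np.broadcast_to(1e-6 * l0m, l_mt.shape).astype(float)
    hi_full = l_mt / cosa
    resid = _residual_fn(l_mt, act, v_norm, l0m, l_slack, cosa, curves)

    if guess is None:
        lo, hi = lo_full.copy(), hi_full.copy()
        iters = 52
    else:
        w = 5e-4  # m; root drift between velocity iterates is far smaller
        lo = np.maximum(guess - w, lo_full)
        hi = np.minimum(guess + w, hi_full)
        bad = (resid(lo) < 0) | (resid(hi) > 0)
        lo = np.where(bad, lo_full, lo)
        hi = np.where(bad, hi_full, hi)
        iters = 52 if np.any(bad) else 30
    r_lo = resid(lo)
    if np.any(r_lo < 0):
        flat = int(np.argmax(r_lo < 0))
        raise SolverError("force-balance", flat, "(tendon cannot carry the fiber force)")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        take_hi = resid(mid) >= 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    return 0.5 * (lo + hi)


def _stacked_constants(muscles: dict[str, MuscleParams]):
    """Per-muscle constants as (n_muscles, 1) columns in MUSCLES order."""
    l0m = np.array([[muscles[m].l0m] for m in MUSCLES])
    l_slack = np.array([[muscles[m].l_slack] for m in MUSCLES])
    v_max = np.array([[muscles[m].v_max] for m in MUSCLES])
    cosa = np.array([[math.cos(muscles[m].pennation)] for m in MUSCLES])
    return l0m, l_slack, v_max, cosa


def solve_mtu_kinetics(
    gait: GaitTrajectory,
    muscles: dict[str, MuscleParams],
    anthro: HipAnthropometry,
    curves: CurveConfig = DEFAULT_CURVES,
    picard_iters: int = 6,
    anderson_maxiter: int = 80,
    v_tol: float = 1e-7,
    residual_tol: float = 1e-8,
) -> MTUKinetics:
    """Self-consistent normalized fiber/tendon solution for all muscles.

    At each sample the force balance is enforced by bisection at the
    current fiber-velocity estimate; the velocity must in turn equal the
    periodic central difference of the fiber-length trace.  This fixed
    point is reached by a short damped Picard warm-up followed by
    Anderson-accelerated iteration (the steep eccentric force-velocity
    slope combined with a compliant tendon makes plain relaxation
    oscillate for long-tendon muscles).  The final bisection runs at the
    converged velocity, so the reported balance residual is at machine
    precision there.
    """
    from scipy.optimize import root as _root

    dt = gait.dt
    l0m, l_slack, v_max, cosa = _stacked_constants(muscles)
    l_mt = np.stack([geom.mtu_length(m, (gait.hip_angle, gait.knee_angle), anthro) for m in MUSCLES])
    act = np.stack([gait.activations[m] for m in MUSCLES])
    shape = l_mt.shape
    state: dict = {"l": None}

    def solve_at(v):
        state["l"] = _solve_fiber_length(
            l_mt, act, v / v_max, l0m, l_slack, cosa, curves, guess=state["l"]
        )
        return state["l"]

    def G(vflat):
        l = solve_at(vflat.reshape(shape))
        return (-periodic_derivative(l, dt)).ravel() - vflat

    v = np.zeros(shape)
    for _ in range(picard_iters):
        v = v + 0.5 * G(v.ravel()).reshape(shape)
    sol = _root(G, v.ravel(), method="anderson", options={"maxiter": anderson_maxiter, "fatol": v_tol})
    verr = float(np.max(np.abs(sol.fun)))
    if verr > 100 * v_tol:
        # retry from rest with a longer budget before giving up
        state["l"] = None
        sol = _root(G, np.zeros(shape).ravel(), method="anderson",
                    options={"maxiter": 4 * anderson_maxiter, "fatol": v_tol})
        verr = float(np.max(np.abs(sol.fun)))
        if verr > 100 * v_tol:
            raise SolverError("velocity-consistency", -1, f"(max |Δv| = {verr:.2e} m/s)")
    v = np.asarray(sol.x, dtype=float).reshape(shape)
    l = solve_at(v)

    strain = (l_mt - l * cosa - l_slack) / l_slack
    f_tilde = mtu.tendon_force_length(strain, curves)
    resid = _balance_residual(l, l_mt, act, v / v_max, l0m, l_slack, cosa, curves)
    if np.max(np.abs(resid)) > residual_tol:
        i, j = np.unravel_index(int(np.argmax(np.abs(resid))), resid.shape)
        raise SolverError(MUSCLES[i], int(j), "(residual above tolerance)")
    return MTUKinetics(
        f_tilde=f_tilde, l_mut=l, v_mut=v, l_mt=l_mt, residual=resid, v_consistency=verr
    )


def forward_moment(
    gait: GaitTrajectory,
    model: HipModelParams,
    muscles: dict[str, MuscleParams],
    anthro: HipAnthropometry,
    curves: CurveConfig = DEFAULT_CURVES,
    kinetics: MTUKinetics | None = None,
) -> ForwardResult:
    """Net hip moment from kinematics and measured activations.

    Combines the (H-independent) normalized MTU solution with the
    candidate moment arms U(β) and the flexor/extensor force scalings m
    and n, and sums the per-muscle moments into the net hip moment.  A
    precomputed ``kinetics`` (from :func:`solve_mtu_kinetics`) makes the
    call cheap; otherwise it is solved here.
    """
    kin = kinetics or solve_mtu_kinetics(gait, muscles, anthro, curves)
    delta, eta = gait.hip_angle, gait.knee_angle
    res = ForwardResult(
        m_mo=np.zeros(gait.n), m_p=np.zeros(gait.n), moment={}, force={}, u={},
        l_mt={}, l_mut={}, v_mut={}, fmax_eff={}, residual={},
    )
    moments = {}
    for i, m in enumerate(MUSCLES):
        fmax_eff = muscles[m].f_max * group_scale(m, model)
        u = np.asarray(geom.moment_arm(m, (delta, eta), model, anthro))
        f_t = fmax_eff * kin.f_tilde[i]
        moments[m] = geom.muscle_moment(f_t, u)
        res.moment[m] = moments[m]
        res.force[m] = f_t
        res.u[m] = u
        res.l_mt[m] = kin.l_mt[i]
        res.l_mut[m] = kin.l_mut[i]
        res.v_mut[m] = kin.v_mut[i]
        res.fmax_eff[m] = float(fmax_eff)
        res.residual[m] = kin.residual[i]
    res.m_p = np.asarray(geom.passive_joint_moment(delta, model.passive), dtype=float)
    res.m_mo = np.asarray(
        geom.net_joint_moment(moments, res.m_p, model.convention), dtype=float
    )
    return res


# ---------------------------------------------------------------------------
# stage 1: genetic-algorithm fit of H
# ---------------------------------------------------------------------------

def h_bounds() -> np.ndarray:
    """Box bounds on H = [β1..β6 (rad), m, n] as an (8, 2) array."""
    rows = [(math.radians(lo), math.radians(hi)) for lo, hi in geom.BETA_BOUNDS_DEG]
    rows += [geom.SCALE_BOUNDS, geom.SCALE_BOUNDS]
    return np.asarray(rows, dtype=float)


@dataclass(frozen=True)
class GAConfig:
    """Real-coded genetic-algorithm settings for the stage-1 fit."""

    population: int = 60
    generations: int = 150
    tournament: int = 3
    crossover_prob: float = 0.9
    blend_alpha: float = 0.3
    mutation_prob: float = 1.0 / 9.0
    mutation_sigma: float = 0.08  # fraction of each gene's range
    elitism: int = 2

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1:
            raise ValueError("population must be >= 2 and generations >= 1")


@dataclass
class OptHResult:
    h_opt: np.ndarray
    model: HipModelParams
    rmse: float  # Nm/kg
    rmse_nm: float
    r2: float
    history: np.ndarray  # best objective per generation (Nm/kg)
    n_evals: int
    forward: ForwardResult


def _ga_minimize(objective, bounds: np.ndarray, cfg: GAConfig, rng: np.random.Generator):
    """Bounded real-coded GA; returns (best_x, best_f, history, n_evals)."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    ndim = bounds.shape[0]
    pop = lo + rng.random((cfg.population, ndim)) * span
    fit = np.array([objective(x) for x in pop])
    n_evals = cfg.population
    history = []
    for _ in range(cfg.generations):
        order = np.argsort(fit)
        elite = pop[order[: cfg.elitism]].copy()
        elite_fit = fit[order[: cfg.elitism]].copy()
        children = []
        while len(children) < cfg.population - cfg.elitism:
            idx = rng.integers(0, cfg.population, size=(2, cfg.tournament))
            p1 = pop[idx[0][np.argmin(fit[idx[0]])]]
            p2 = pop[idx[1][np.argmin(fit[idx[1]])]]
            if rng.random() < cfg.crossover_prob:
                # blend (BLX-alpha) crossover
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                d = cmax - cmin
                child = rng.uniform(cmin - cfg.blend_alpha * d, cmax + cfg.blend_alpha * d + 1e-300)
            else:
                child = p1.copy()
            mask = rng.random(ndim) < cfg.mutation_prob
            child = np.where(mask, child + rng.normal(0.0, cfg.mutation_sigma) * span, child)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elite] + children)
        new_fit = np.array([objective(x) for x in pop[cfg.elitism:]])
        n_evals += len(new_fit)
        fit = np.concatenate([elite_fit, new_fit])
        history.append(float(fit.min()))
    best = int(np.argmin(fit))
    return pop[best], float(fit[best]), np.asarray(history), n_evals


def optimize_H(
    gait: GaitTrajectory,
    muscles: dict[str, MuscleParams],
    anthro: HipAnthropometry,
    curves: CurveConfig = DEFAULT_CURVES,
    ga_config: GAConfig | None = None,
    seed: int = 0,
    method: str = "ga",
    polish: bool = True,
    model_template: HipModelParams | None = None,
) -> OptHResult:
    """Fit H = [β1..β6, m, n] minimizing body-mass-normalized moment RMSE.

    ``method``: "ga" (default, in-house genetic algorithm) or "de"
    (scipy differential evolution).  A bounded Powell polish refines the
    best candidate when ``polish`` is set.  Reproducible for fixed seed.
    """
    cfg = ga_config or GAConfig()
    bounds = h_bounds()
    mass = anthro.body_mass
    template = model_template or HipModelParams.neutral()

    def make_model(h: np.ndarray) -> HipModelParams:
        return HipModelParams(
            betas=h[:6], m_scale=float(h[6]), n_scale=float(h[7]),
            kappa_hip=template.kappa_hip, kappa_knee=template.kappa_knee,
            constant_beta=template.constant_beta, passive=template.passive,
            convention=template.convention,
        )

    # the normalized MTU solution does not depend on H: solve it once and
    # evaluate every candidate against it
    kinetics = solve_mtu_kinetics(gait, muscles, anthro, curves)
    n_evals = 0

    def objective(h: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        fwd = forward_moment(gait, make_model(h), muscles, anthro, curves, kinetics=kinetics)
        return rmse(fwd.m_mo, gait.hip_moment, mass)

    rng = np.random.default_rng(seed)
    if method == "ga":
        best_x, best_f, history, _ = _ga_minimize(objective, bounds, cfg, rng)
    elif method == "de":
        r = sciopt.differential_evolution(
            objective, bounds, seed=seed, maxiter=cfg.generations,
            popsize=max(4, cfg.population // bounds.shape[0]), tol=1e-10, polish=False,
        )
        best_x, best_f = r.x, float(r.fun)
        history = np.asarray([best_f])
    else:
        raise ValueError(f"unknown method {method!r}")

    if polish:
        # the RMSE surface has a curved shallow valley (β/m trade-off);
        # bounded least squares on the per-sample residuals descends it
        mass_ = mass

        def residuals(h: np.ndarray) -> np.ndarray:
            nonlocal n_evals
            n_evals += 1
            fwd = forward_moment(gait, make_model(h), muscles, anthro, curves, kinetics=kinetics)
            return (fwd.m_mo - gait.hip_moment) / mass_

        r = sciopt.least_squares(
            residuals, best_x, bounds=(bounds[:, 0], bounds[:, 1]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
        )
        f = float(np.sqrt(np.mean(r.fun**2)))
        if f <= best_f:
            best_x, best_f = np.clip(r.x, bounds[:, 0], bounds[:, 1]), f

    model = make_model(best_x)
    model.validate_bounds()
    fwd = forward_moment(gait, model, muscles, anthro, curves, kinetics=kinetics)
    return OptHResult(
        h_opt=np.asarray(best_x, dtype=float),
        model=model,
        rmse=rmse(fwd.m_mo, gait.hip_moment, mass),
        rmse_nm=rmse(fwd.m_mo, gait.hip_moment),
        r2=r_squared(fwd.m_mo, gait.hip_moment),
        history=history,
        n_evals=n_evals,
        forward=fwd,
    )


# ---------------------------------------------------------------------------
# stage 2: optimal fiber-length fit
# ---------------------------------------------------------------------------

@dataclass
class OptIResult:
    l0: dict[str, float]
    activations: dict[str, np.ndarray]
    b_min: dict[str, float]
    resolution: dict[str, float]


def fiber_state_from_force(
    force: np.ndarray,
    l_mt: np.ndarray,
    params: MuscleParams,
    fmax_eff: float,
    dt: float,
    curves: CurveConfig = DEFAULT_CURVES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fiber kinematics (l_mut, v_mut, l_t) from a tendon-force trace.

    Inverts the tendon curve to the tendon length, splits the MTU length
    into fiber and tendon, and differentiates the fiber length over the
    periodic grid (shortening positive).
    """
    cosa = math.cos(params.pennation)
    strain = mtu.invert_tendon_force(np.maximum(force, 0.0) / fmax_eff, curves)
    l_t = params.l_slack * (1.0 + strain)
    l_mut = (l_mt - l_t) / cosa
    if np.any(l_mut <= 0):
        raise ArithmeticError("non-positive fiber length in back-solve")
    v_mut = -periodic_derivative(l_mut, dt)
    return l_mut, v_mut, l_t


def back_solve_activation(
    force: np.ndarray,
    l_mt: np.ndarray,
    params: MuscleParams,
    fmax_eff: float,
    dt: float,
    curves: CurveConfig = DEFAULT_CURVES,
    clip_velocity: bool = False,
) -> np.ndarray:
    """Activation trace reproducing a tendon-force trace.

    Inverts the tendon curve to obtain tendon length, splits the MTU
    length into fiber kinematics, removes the passive fiber force and
    divides by the CE force capacity.  May return values outside [0, 1];
    feasibility is judged by the caller.  Raises ``ArithmeticError`` when
    the capacity vanishes, or when the fiber shortening rate exceeds
    v_max unless ``clip_velocity`` saturates it instead.
    """
    cosa = math.cos(params.pennation)
    l_mut, v_mut, _ = fiber_state_from_force(force, l_mt, params, fmax_eff, dt, curves)
    l_norm = l_mut / params.l0m
    v_norm = v_mut / params.v_max
    if clip_velocity:
        v_norm = np.clip(v_norm, *_VNORM_CLIP)
    elif np.any(v_norm >= 1.0):
        raise ArithmeticError("fiber shortening exceeds v_max in back-solve")
    f_pee = fmax_eff * mtu.passive_force_length(l_norm, curves)
    f_ce = force / cosa - f_pee
    capacity = fmax_eff * mtu.active_force_length(l_norm, curves) * mtu.force_velocity(v_norm, curves)
    if np.any(capacity <= 0):
        raise ArithmeticError("zero CE force capacity in back-solve")
    return f_ce / capacity


def optimize_I(
    gait: GaitTrajectory,
    model: HipModelParams,
    muscles: dict[str, MuscleParams],
    anthro: HipAnthropometry,
    curves: CurveConfig = DEFAULT_CURVES,
    bounds_frac: tuple[float, float] = (0.6, 1.4),
    grid_points: int = 201,
    refine_rounds: int = 3,
    refine_points: int = 41,
    feas_tol: float = 1e-9,
    objective: str = "match",
    forward: ForwardResult | None = None,
) -> OptIResult:
    """Per-muscle optimal fiber length under activation feasibility.

    For each muscle independently, candidate l0 values on a grid between
    ``bounds_frac`` times the nominal l0 are scored by the reconstructed
    activation trace; infeasible candidates (b outside [0, 1], or
    unsolvable kinematics) are discarded.  Objectives among the feasible
    candidates:

    * ``"match"`` (default): minimize the RMS difference between the
      reconstructed and the measured activation trace — the criterion the
      calibrated model is judged by (per-muscle activation r²/RMSE), and
      the only one that recovers the generating fiber length on
      model-consistent data.
    * ``"min-bmin"``: minimize the cycle-minimum activation.  This
      selects the smallest l0 whose passive fiber force just covers the
      lowest-demand sample (the feasibility edge).
    * ``"max-margin"``: maximize the distance of the trace from both
      activation bounds.

    The winning neighborhood is refined by repeated grid trisection; the
    final step is reported as the search resolution.
    """
    if objective not in ("match", "min-bmin", "max-margin"):
        raise ValueError(f"unknown objective {objective!r}")
    fwd = forward or forward_moment(gait, model, muscles, anthro, curves)
    dt = gait.dt
    out = OptIResult(l0={}, activations={}, b_min={}, resolution={})
    for name in MUSCLES:
        params = muscles[name]
        fmax_eff = fwd.fmax_eff[name]
        force = fwd.force[name]
        l_mt = fwd.l_mt[name]

        measured = gait.activations[name]

        def score(l0: float):
            cand = params.with_l0m(l0)
            try:
                b = back_solve_activation(force, l_mt, cand, fmax_eff, dt, curves)
            except ArithmeticError:
                return None, None
            if np.any(b < -feas_tol) or np.any(b > 1.0 + feas_tol):
                return None, None
            if objective == "match":
                return float(np.sqrt(np.mean((b - measured) ** 2))), b
            if objective == "min-bmin":
                return float(b.min()), b
            return float(-min(b.min(), 1.0 - b.max())), b

        lo = bounds_frac[0] * params.l0m
        hi = bounds_frac[1] * params.l0m
        if not 0 < lo < hi:
            raise ValueError(f"{name}: invalid fiber-length bounds")
        step = (hi - lo) / (grid_points - 1)
        grid = np.linspace(lo, hi, grid_points)
        best = None  # (obj, l0, b)
        for l0 in grid:
            obj, b = score(float(l0))
            if obj is not None and (best is None or obj < best[0]):
                best = (obj, float(l0), b)
        if best is None:
            raise InfeasibilityError(name, f"(searched [{lo:.4f}, {hi:.4f}] m)")
        for _ in range(refine_rounds):
            a = max(lo, best[1] - step)
            c = min(hi, best[1] + step)
            sub = np.linspace(a, c, refine_points)
            for l0 in sub:
                obj, b = score(float(l0))
                if obj is not None and obj < best[0]:
                    best = (obj, float(l0), b)
            step = (c - a) / (refine_points - 1)
        out.l0[name] = best[1]
        out.activations[name] = best[2]
        out.b_min[name] = float(best[2].min())
        out.resolution[name] = step
    return out


# ---------------------------------------------------------------------------
# full calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Outcome of the two-stage fit Q = [H, I] with fit metrics."""

    h_opt: np.ndarray  # [β1..β6 (rad), m, n]
    i_opt: dict[str, float]  # optimal fiber length per muscle, m
    rmse: float  # Nm/kg
    rmse_nm: float
    r2: float
    b_min_per_muscle: dict[str, float]
    model_moment: np.ndarray
    model: HipModelParams
    muscles: dict[str, MuscleParams]  # with i_opt applied
    activations: dict[str, np.ndarray]  # stage-2 reconstructed traces
    history: np.ndarray = field(default_factory=lambda: np.zeros(0))
    i_resolution: dict[str, float] = field(default_factory=dict)


def calibrate(
    gait: GaitTrajectory,
    muscles: dict[str, MuscleParams] | None = None,
    anthro: HipAnthropometry | None = None,
    curves: CurveConfig = DEFAULT_CURVES,
    ga_config: GAConfig | None = None,
    seed: int = 0,
    method: str = "ga",
    **i_kwargs,
) -> CalibrationResult:
    """Run both calibration stages and assemble a CalibrationResult."""
    anthro = anthro or HipAnthropometry.default()
    muscles = muscles or geom.default_muscle_set(anthro)
    stage1 = optimize_H(
        gait, muscles, anthro, curves, ga_config=ga_config, seed=seed, method=method
    )
    stage2 = optimize_I(
        gait, stage1.model, muscles, anthro, curves, forward=stage1.forward, **i_kwargs
    )
    fitted = {m: muscles[m].with_l0m(stage2.l0[m]) for m in MUSCLES}
    return CalibrationResult(
        h_opt=stage1.h_opt,
        i_opt=stage2.l0,
        rmse=stage1.rmse,
        rmse_nm=stage1.rmse_nm,
        r2=stage1.r2,
        b_min_per_muscle=stage2.b_min,
        model_moment=stage1.forward.m_mo,
        model=stage1.model,
        muscles=fitted,
        activations=stage2.activations,
        history=stage1.history,
        i_resolution=stage2.resolution,
    )
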