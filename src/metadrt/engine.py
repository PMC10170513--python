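"""Well-tempered metadynamics engine: hills, walls, deposition loop.

The bias is a sum of repulsive product Gaussians ("hills") deposited along
the collective variables at a fixed stride.  Under well-tempering the height
of each new hill decays exponentially with the bias already accumulated at
the deposition point,

    w = omega0 * exp(-V(s, t) / (k_B * DeltaT)),

where ``k_B * DeltaT`` is the bias factor in energy units (the "kT"
parameter of the protocol).  One-sided harmonic restraints — a *floor*
bounding a CV from below and a *wall* bounding it from above — keep the
dynamics out of unphysical regions; they contribute forces but are excluded
from the recorded V(s, t) that feeds the acceleration-factor estimator
(only deposited hills count as flooding potential).

``run_metad`` drives any system exposing the small :class:`BiasableSystem`
protocol (an overdamped-Langevin toy in this package) and records, at every
deposition time, the CV vector, the bias experienced *before* the new hill
is added, the deposited height and the bound/unbound flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Inconsistent CV dimensionality or invalid engine configuration."""


class NumericalFailureError(RuntimeError):
    """Non-finite energy, force or position encountered during propagation."""


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: centre in CV space, per-CV widths, height."""

    center: tuple[float, ...]
    widths: tuple[float, ...]
    height: float
    deposit_time: float

    def __post_init__(self) -> None:
        center = tuple(float(c) for c in self.center)
        widths = tuple(float(w) for w in self.widths)
        if len(center) != len(widths):
            raise ConfigurationError("hill center and widths differ in length")
        if any(w <= 0 for w in widths):
            raise ConfigurationError("hill widths must be strictly positive")
        if self.height < 0:
            raise ConfigurationError("hill height must be non-negative")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "widths", widths)


@dataclass(frozen=True)
class WellTemperedParams:
    """Initial hill height and bias factor k_B·ΔT (both kcal/mol)."""

    omega0: float
    kb_deltaT: float = 10.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ConfigurationError("omega0 must be positive")
        if self.enabled and self.kb_deltaT <= 0:
            raise ConfigurationError("kb_deltaT must be positive when well-tempered")


@dataclass(frozen=True)
class WallSpec:
    """One-sided harmonic restraint on a CV.

    ``lower_floor`` penalises excursions below ``location``; ``upper_wall``
    penalises excursions above it.  Energy is k·(x − location)² on the
    forbidden side and zero elsewhere.
    """

    cv_index: int
    kind: str
    location: float
    force_constant: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("lower_floor", "upper_wall"):
            raise ConfigurationError(f"unknown wall kind {self.kind!r}")
        if self.force_constant <= 0:
            raise ConfigurationError("wall force constant must be positive")


@dataclass(frozen=True)
class DepositionSchedule:
    """Hill deposition stride, run cap, and stop behaviour (all in ps)."""

    stride: float = 1.0
    max_time: float = 1000.0
    stop_on_unbound: bool = True

    def __post_init__(self) -> None:
        if self.stride <= 0:
            raise ConfigurationError("stride must be positive")


@dataclass
class MetaDTrajectory:
    """Per-deposition-step record of a metadynamics run.

    ``bias_before`` holds V(s, t) — deposited hills only — evaluated at the
    current CV point immediately *before* the hill at that time is added;
    this is the quantity entering the acceleration factor.
    """

    times: np.ndarray
    cvs: np.ndarray
    bias_before: np.ndarray
    heights: np.ndarray
    unbound: np.ndarray
    status: str
    hills: list[Hill] = field(default_factory=list)
    cv_names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_cvs(self) -> int:
        return self.cvs.shape[1] if self.cvs.ndim == 2 else 0


def _wrapped_delta(delta: np.ndarray, periods: np.ndarray) -> np.ndarray:
    per = periods > 0
    if np.any(per):
        delta = delta.copy()
        p = periods[per]
        delta[..., per] -= p * np.round(delta[..., per] / p)
    return delta


def _hill_arrays(hills: Sequence[Hill]):
    centers = np.array([h.center for h in hills], dtype=float)
    widths = np.array([h.widths for h in hills], dtype=float)
    heights = np.array([h.height for h in hills], dtype=float)
    return centers, widths, heights


def bias_value(
    hills: Sequence[Hill], s: Sequence[float], periods: Optional[Sequence[float]] = None
) -> float:
    """Total bias V(s) (kcal/mol) from a hill list at CV point ``s``."""
    s = np.asarray(s, dtype=float)
    if not hills:
        return 0.0
    centers, widths, heights = _hill_arrays(hills)
    if centers.shape[1] != s.shape[0]:
        raise ConfigurationError("hills and CV point differ in dimensionality")
    periods = np.zeros(s.shape[0]) if periods is None else np.asarray(periods, dtype=float)
    delta = _wrapped_delta(s[None, :] - centers, periods)
    return float(np.sum(heights * np.exp(-0.5 * np.sum((delta / widths) ** 2, axis=1))))


def bias_gradient(
    hills: Sequence[Hill], s: Sequence[float], periods: Optional[Sequence[float]] = None
) -> np.ndarray:
    """Gradient dV/ds of the hill sum at ``s`` (kcal/mol per CV unit)."""
    s = np.asarray(s, dtype=float)
    if not hills:
        return np.zeros_like(s)
    centers, widths, heights = _hill_arrays(hills)
    if centers.shape[1] != s.shape[0]:
        raise ConfigurationError("hills and CV point differ in dimensionality")
    periods = np.zeros(s.shape[0]) if periods is None else np.asarray(periods, dtype=float)
    delta = _wrapped_delta(s[None, :] - centers, periods)
    gauss = heights * np.exp(-0.5 * np.sum((delta / widths) ** 2, axis=1))
    return -np.sum(gauss[:, None] * delta / widths**2, axis=0)


def next_hill_height(v_at_center: float, params: WellTemperedParams) -> float:
    """Height of the next hill given the bias at the deposition point."""
    if v_at_center < 0:
        raise ValueError("bias potential must be non-negative")
    if not params.enabled:
        return params.omega0
    return params.omega0 * float(np.exp(-v_at_center / params.kb_deltaT))


def wall_energy(
    s: Sequence[float], walls: Sequence[WallSpec]
) -> tuple[float, np.ndarray]:
    """Energy and gradient of all one-sided harmonic restraints at ``s``."""
    s = np.asarray(s, dtype=float)
    energy = 0.0
    grad = np.zeros_like(s)
    for w in walls:
        if w.cv_index < 0 or w.cv_index >= s.shape[0]:
            raise ConfigurationError(f"wall cv_index {w.cv_index} out of range")
        x = s[w.cv_index]
        excess = x - w.location
        violated = excess < 0 if w.kind == "lower_floor" else excess > 0
        if violated:
            energy += w.force_constant * excess**2
            grad[w.cv_index] += 2.0 * w.force_constant * excess
    return float(energy), grad


class BiasableSystem(Protocol):
    """What ``run_metad`` needs from a dynamical system.

    The state is a flat coordinate vector propagated by overdamped Langevin
    dynamics; CVs are differentiable functions of the state so bias forces
    can be chained back onto the coordinates.
    """

    def initial_state(self) -> np.ndarray: ...

    def force(self, x: np.ndarray) -> np.ndarray:
        """Physical force −dU/dx (kcal/mol/Å)."""

    def cv_and_jacobian(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """CV values and Jacobian ds/dx, shape (n_cv, n_dof)."""

    def is_unbound(self, x: np.ndarray) -> bool: ...

    @property
    def cv_periods(self) -> np.ndarray: ...

    @property
    def langevin(self):  # LangevinParams
        ...


def run_metad(
    system: BiasableSystem,
    params: WellTemperedParams,
    schedule: DepositionSchedule,
    walls: Sequence[WallSpec] = (),
    seed: int = 0,
    unbound_test: Optional[Callable[[np.ndarray], bool]] = None,
) -> MetaDTrajectory:
    """Run a metadynamics simulation and return its deposition record.

    Every ``schedule.stride`` ps the engine evaluates the CVs, records the
    hill bias at that point, deposits a new hill (well-tempered height), and
    checks the unbound predicate; it stops at unbinding (when
    ``stop_on_unbound``) or at ``max_time``.  The same seed and configuration
    reproduce the trajectory exactly.
    """
    lp = system.langevin
    dt = lp.timestep
    n_sub = max(1, int(round(schedule.stride / dt)))
    n_strides = int(np.floor(schedule.max_time / schedule.stride + 1e-9))
    rng = np.random.default_rng(seed)
    unbound_test = unbound_test or system.is_unbound
    periods = np.asarray(system.cv_periods, dtype=float)
    has_period = bool(np.any(periods > 0))
    widths = getattr(system, "cv_widths", None)
    if widths is None:
        raise ConfigurationError("system must provide cv_widths for deposition")
    widths_arr = np.asarray(widths, dtype=float)
    if widths_arr.shape != periods.shape:
        raise ConfigurationError("system must provide one cv_width per CV")
    # identity_cv: CVs are the coordinates themselves (chain rule = identity)
    identity = bool(getattr(system, "identity_cv", False))

    x = np.array(system.initial_state(), dtype=float)
    ndof = x.shape[0]
    mob = 1.0 / (lp.friction * lp.mass)  # mobility, Å²·mol/(kcal·ps)
    noise_scale = np.sqrt(2.0 * lp.kT * dt * mob)
    force_fn = system.force

    hills: list[Hill] = []
    # growing per-hill arrays, rebuilt as views once per stride
    c_rows: list[np.ndarray] = []
    h_vals: list[float] = []
    rec_t, rec_s, rec_v, rec_h, rec_u = [], [], [], [], []
    status = "max_time_reached"

    inv_w2 = 1.0 / widths_arr**2

    def hill_eval(s: np.ndarray, centers: np.ndarray, heights: np.ndarray):
        """Bias value and CV-space bias force (−dV/ds) for cached hill arrays."""
        delta = s[None, :] - centers
        if has_period:
            delta = _wrapped_delta(delta, periods)
        gauss = heights * np.exp(-0.5 * np.sum(delta * delta * inv_w2, axis=1))
        v = float(gauss.sum())
        fcv = np.sum(gauss[:, None] * delta * inv_w2, axis=0)  # = −dV/ds
        return v, fcv

    t = 0.0
    for _ in range(n_strides):
        eta = rng.standard_normal((n_sub, ndof)) * noise_scale
        centers = np.array(c_rows) if c_rows else None
        heights = np.array(h_vals) if h_vals else None
        for k in range(n_sub):
            if identity:
                s = x
                f = force_fn(x)
                if centers is not None:
                    _, fcv = hill_eval(s, centers, heights)
                    f = f + fcv
                if walls:
                    _, wg = wall_energy(s, walls)
                    f = f - wg
            else:
                s, jac = system.cv_and_jacobian(x)
                f = force_fn(x)
                if centers is not None:
                    _, fcv = hill_eval(s, centers, heights)
                    f = f + fcv @ jac
                if walls:
                    _, wg = wall_energy(s, walls)
                    f = f - wg @ jac
            x = x + f * (mob * dt) + eta[k]
        if not np.all(np.isfinite(x)):
            raise NumericalFailureError(f"non-finite position near t={t:.4f} ps")
        t += schedule.stride

        if identity:
            s = x.copy()
        else:
            s, _ = system.cv_and_jacobian(x)
        if c_rows:
            v_here, _ = hill_eval(s, np.array(c_rows), np.array(h_vals))
        else:
            v_here = 0.0
        height = next_hill_height(v_here, params)
        hills.append(Hill(tuple(s), tuple(widths_arr), height, t))
        c_rows.append(np.asarray(s, dtype=float))
        h_vals.append(height)

        flag = bool(unbound_test(x))
        rec_t.append(t)
        rec_s.append(np.array(s))
        rec_v.append(v_here)
        rec_h.append(height)
        rec_u.append(flag)
        if flag and schedule.stop_on_unbound:
            status = "unbound"
            break

    n_cv = len(rec_s[0]) if rec_s else len(system.cv_periods)
    return MetaDTrajectory(
        times=np.array(rec_t),
        cvs=np.array(rec_s).reshape(len(rec_t), n_cv) if rec_t else np.empty((0, n_cv)),
        bias_before=np.array(rec_v),
        heights=np.array(rec_h),
        unbound=np.array(rec_u, dtype=bool),
        status=status,
        hills=hills,
        cv_names=tuple(getattr(system, "cv_names", ())),
    )
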