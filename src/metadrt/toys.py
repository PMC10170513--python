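"""Synthetic dynamical systems with known kinetics.

These desk-scale systems stand in for the all-atom receptor–ligand
simulations that the residence-time estimators were designed for.  The
estimators themselves (acceleration factor, t_META-D) are agnostic to the
underlying dynamics, so an overdamped Langevin particle in an analytic
double-well or funnel potential provides cheap, well-characterised
reference kinetics: the unbiased mean first-passage time (MFPT) over the
barrier is computable by brute force and by the Kramers formula, and the
biased estimates can be judged against it.

Units are physical so that the published metadynamics parameters (hill
heights in kcal/mol, widths in Å, the 1 ps stride, the 15 Å floor) can be
used verbatim: lengths in Å, energies in kcal/mol, times in ps,
temperatures in K.  The friction enters only through the Brownian mobility
μ = 1/(γ·m), taken numerically in Å²·mol·kcal⁻¹·ps⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .geometry import (
    AtomGroup,
    CVSpec,
    Frame,
    cv_value_and_gradient,
    evaluate_cvs,
    is_unbound,
)

KB = 0.0019872041  # Boltzmann constant, kcal/(mol·K)


class CensoringError(RuntimeError):
    """Unbiased first-passage sampling hit the per-replica step cap."""

    def __init__(self, n_censored: int, n_total: int):
        super().__init__(
            f"{n_censored}/{n_total} unbiased replicas did not escape within the step cap"
        )
        self.n_censored = n_censored
        self.n_total = n_total


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped-Langevin parameters.

    ``friction`` (ps⁻¹) and ``mass`` (amu) enter only as the product γ·m,
    interpreted numerically as the inverse mobility in kcal·mol⁻¹·ps·Å⁻².
    """

    temperature: float = 300.0
    friction: float = 3.0
    timestep: float = 0.002
    mass: float = 1.0

    def __post_init__(self) -> None:
        if min(self.temperature, self.friction, self.timestep, self.mass) <= 0:
            raise ValueError("all Langevin parameters must be strictly positive")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse temperature (mol/kcal)."""
        return 1.0 / self.kT

    @property
    def diffusion(self) -> float:
        """D = kT/(γ·m) in Å²/ps."""
        return self.kT / (self.friction * self.mass)


# ---------------------------------------------------------------------------
# analytic potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoubleWell1D:
    """Symmetric quartic double well U(x) = h·((x/x0)² − 1)².

    Minima at ±x0 (Å), saddle at 0, barrier height h (kcal/mol).
    """

    barrier: float
    x0: float = 1.0

    def energy(self, x):
        u = (np.asarray(x, float) / self.x0) ** 2 - 1.0
        return self.barrier * u * u

    def force(self, x):
        x = np.asarray(x, float)
        u = (x / self.x0) ** 2 - 1.0
        return -4.0 * self.barrier * u * x / self.x0**2

    @property
    def minima(self) -> tuple[float, float]:
        return (-self.x0, self.x0)

    @property
    def curvature_min(self) -> float:
        """U'' at the minima (kcal/mol/Å²)."""
        return 8.0 * self.barrier / self.x0**2

    @property
    def curvature_saddle(self) -> float:
        """|U''| at the saddle."""
        return 4.0 * self.barrier / self.x0**2


@dataclass(frozen=True)
class Funnel2D:
    """Double well along the unbinding axis times a harmonic transverse term.

    U(x, y) = h·((x − c)/x0)² − 1)² + ½·k_t·y², with the bound minimum at
    x = c − x0 and the released minimum at x = c + x0.
    """

    barrier: float
    x0: float = 1.0
    center: float = 0.0
    k_transverse: float = 2.0

    def energy(self, xy):
        xy = np.asarray(xy, float)
        u = ((xy[..., 0] - self.center) / self.x0) ** 2 - 1.0
        return self.barrier * u * u + 0.5 * self.k_transverse * xy[..., 1] ** 2

    def force(self, xy):
        xy = np.asarray(xy, float)
        f = np.empty_like(xy)
        dx = xy[..., 0] - self.center
        u = (dx / self.x0) ** 2 - 1.0
        f[..., 0] = -4.0 * self.barrier * u * dx / self.x0**2
        f[..., 1] = -self.k_transverse * xy[..., 1]
        return f


def kramers_mfpt(potential: DoubleWell1D, params: LangevinParams) -> float:
    """High-friction Kramers estimate of the well-to-well MFPT (ps).

    rate = sqrt(U''_min·|U''_saddle|) / (2π·γ·m) · exp(−β·ΔG‡)
    """
    zeta = params.friction * params.mass
    prefactor = np.sqrt(potential.curvature_min * potential.curvature_saddle) / (
        2.0 * np.pi * zeta
    )
    return float(1.0 / (prefactor * np.exp(-params.beta * potential.barrier)))


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def simulate_langevin(
    potential,
    params: LangevinParams,
    n_steps: int,
    x0,
    seed: int = 0,
    bias_force: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    record_stride: int = 1,
) -> np.ndarray:
    """Euler–Maruyama overdamped Langevin trajectory.

    Update: x ← x + F·μ·dt + sqrt(2·kT·μ·dt)·η with μ = 1/(γ·m) and
    η ~ N(0, 1).  Deterministic for a fixed seed.  Returns recorded
    positions, shape ``(n_records, ndim)`` (including the initial point).
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    mob = 1.0 / (params.friction * params.mass)
    dt = params.timestep
    noise = np.sqrt(2.0 * params.kT * dt * mob)
    out = [x.copy()]
    for step in range(n_steps):
        f = np.atleast_1d(np.asarray(potential.force(x), float))
        if bias_force is not None:
            f = f + bias_force(x)
        x = x + f * (mob * dt) + noise * rng.standard_normal(x.shape)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"non-finite position at step {step}")
        if (step + 1) % record_stride == 0:
            out.append(x.copy())
    return np.array(out)


def reference_mfpt(
    potential,
    params: LangevinParams,
    n_replicas: int = 24,
    x_start: Optional[float] = None,
    absorbing: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    max_steps: int = 20_000_000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Unbiased mean first-passage time by brute-force simulation (1-D).

    Replicas are propagated as one vectorised ensemble from the bound
    minimum until each crosses the absorbing boundary (default: the
    midpoint between saddle and product minimum, x ≥ x0/2).  Returns
    ``(mfpt, stderr, first_passage_times)`` in ps.  Raises
    :class:`CensoringError` if any replica survives ``max_steps``.
    """
    if x_start is None:
        x_start = potential.minima[0]
    if absorbing is None:
        x_abs = potential.x0 / 2.0
        absorbing = lambda x: x >= x_abs  # noqa: E731
    rng = np.random.default_rng(seed)
    mob = 1.0 / (params.friction * params.mass)
    dt = params.timestep
    noise = np.sqrt(2.0 * params.kT * dt * mob)
    x = np.full(n_replicas, float(x_start))
    alive = np.ones(n_replicas, dtype=bool)
    fpt = np.full(n_replicas, np.nan)
    # noise drawn in fixed-size blocks so the stream is replica-resolved
    block = 4096
    step = 0
    while alive.any() and step < max_steps:
        eta = rng.standard_normal((block, n_replicas))
        for k in range(block):
            idx = np.nonzero(alive)[0]
            if idx.size == 0:
                break
            xa = x[idx]
            f = potential.force(xa)
            xa = xa + f * (mob * dt) + noise * eta[k, idx]
            x[idx] = xa
            step += 1
            crossed = absorbing(xa)
            if crossed.any():
                hit = idx[crossed]
                fpt[hit] = step * dt
                alive[hit] = False
            if step >= max_steps:
                break
    if alive.any():
        raise CensoringError(int(alive.sum()), n_replicas)
    mfpt = float(fpt.mean())
    stderr = float(fpt.std(ddof=1) / np.sqrt(n_replicas)) if n_replicas > 1 else float("nan")
    return mfpt, stderr, fpt


# ---------------------------------------------------------------------------
# engine adapters
# ---------------------------------------------------------------------------

class DoubleWellSystem:
    """1-D double well wired for :func:`metadrt.engine.run_metad`.

    The single CV is the coordinate itself (identity chain rule).  The
    system counts as "unbound" once the particle has crossed well past the
    saddle, at x ≥ x0/2 — the same absorbing boundary used by the unbiased
    MFPT oracle, so biased and unbiased estimates measure the same event.
    """

    identity_cv = True
    cv_names = ("x",)

    def __init__(
        self,
        potential: DoubleWell1D,
        langevin: LangevinParams,
        cv_width: float = 0.2,
        unbound_at: Optional[float] = None,
    ):
        self.potential = potential
        self.langevin = langevin
        self.cv_widths = np.array([cv_width])
        self.cv_periods = np.array([0.0])
        self.unbound_at = potential.x0 / 2.0 if unbound_at is None else unbound_at

    def initial_state(self) -> np.ndarray:
        return np.array([self.potential.minima[0]])

    def force(self, x: np.ndarray) -> np.ndarray:
        return self.potential.force(x)

    def cv_and_jacobian(self, x: np.ndarray):
        return x.copy(), np.eye(1)

    def is_unbound(self, x: np.ndarray) -> bool:
        return bool(x[0] >= self.unbound_at)


class Funnel2DSystem:
    """2-D funnel wired for the engine; both coordinates are CVs."""

    identity_cv = True
    cv_names = ("x", "y")

    def __init__(
        self,
        potential: Funnel2D,
        langevin: LangevinParams,
        cv_widths=(0.2, 0.2),
        unbound_at: Optional[float] = None,
    ):
        self.potential = potential
        self.langevin = langevin
        self.cv_widths = np.asarray(cv_widths, float)
        self.cv_periods = np.zeros(2)
        self.unbound_at = (
            potential.center + potential.x0 / 2.0 if unbound_at is None else unbound_at
        )

    def initial_state(self) -> np.ndarray:
        return np.array([self.potential.center - self.potential.x0, 0.0])

    def force(self, x: np.ndarray) -> np.ndarray:
        return self.potential.force(x)

    def cv_and_jacobian(self, x: np.ndarray):
        return x.copy(), np.eye(2)

    def is_unbound(self, x: np.ndarray) -> bool:
        return bool(x[0] >= self.unbound_at)


# ---------------------------------------------------------------------------
# pseudo-molecular complex
# ---------------------------------------------------------------------------

@dataclass
class PseudoComplex:
    """A rigid "ligand" cluster inside a fixed "receptor" cage.

    Exercises the geometric CV set (pulling distance, angle, dihedral, two
    RMSDs) on real coordinate frames.  The ligand translates rigidly; its
    centre of mass moves in a radial double-well potential (bound minimum
    inside the cage, released minimum outside), a minimal mimic of a
    binding funnel.
    """

    receptor_coords: np.ndarray
    receptor_masses: np.ndarray
    ligand_template: np.ndarray  # ligand coords when bound (COM at origin offset)
    ligand_masses: np.ndarray
    exit_axis: np.ndarray
    potential: DoubleWell1D  # in the shifted coordinate d − potential_center
    potential_center: float = 6.0
    anchor_groups: dict = field(default_factory=dict)

    def displacement_energy(self, d: float) -> float:
        return float(self.potential.energy(d - self.potential_center))

    def displacement_force(self, d) -> np.ndarray:
        return np.atleast_1d(self.potential.force(np.asarray(d, float) - self.potential_center))

    @property
    def n_receptor(self) -> int:
        return self.receptor_coords.shape[0]

    @property
    def n_ligand(self) -> int:
        return self.ligand_template.shape[0]

    def frame(self, displacement: float = 0.0, time: float = 0.0) -> Frame:
        """Full frame with the ligand shifted along the exit axis (Å)."""
        lig = self.ligand_template + displacement * self.exit_axis
        coords = np.vstack([self.receptor_coords, lig])
        masses = np.concatenate([self.receptor_masses, self.ligand_masses])
        return Frame(coords, masses, time)

    @property
    def ligand_group(self) -> AtomGroup:
        return AtomGroup(range(self.n_receptor, self.n_receptor + self.n_ligand))

    @property
    def receptor_group(self) -> AtomGroup:
        return AtomGroup(range(self.n_receptor))


def generate_pseudo_complex(seed: int = 0) -> tuple[PseudoComplex, list[CVSpec]]:
    """Build a reproducible cage/ligand system plus a 5-CV set.

    The CV set mirrors the published protocol in structure: one pulling
    distance (ligand COM to a deep anchor COM), one angle, one dihedral
    (via lateral anchor COMs), the RMSD of the cage-lining particles plus
    the ligand, and the RMSD of the ligand alone.
    """
    rng = np.random.default_rng(seed)

    # receptor: a ring of cage particles at radius 4 Å around the origin in
    # the yz-plane, plus three anchor clusters mimicking helix bundles
    n_cage = 12
    ang = np.linspace(0, 2 * np.pi, n_cage, endpoint=False)
    cage = np.column_stack([np.zeros(n_cage), 4.0 * np.cos(ang), 4.0 * np.sin(ang)])
    cage += rng.normal(scale=0.15, size=cage.shape)

    deep_anchor = np.array([[-8.0, 0.5, 0.0], [-8.5, -0.5, 0.3], [-8.2, 0.0, -0.6]])
    side_anchor = np.array([[-2.0, 9.0, 0.2], [-2.5, 9.4, -0.3], [-1.6, 9.2, 0.5]])
    far_anchor = np.array([[-3.0, -0.2, 9.0], [-3.4, 0.3, 9.4], [-2.7, -0.5, 9.2]])
    receptor = np.vstack([cage, deep_anchor, side_anchor, far_anchor])
    receptor_masses = np.full(receptor.shape[0], 12.0)

    # rigid 5-particle ligand, bound with COM at the origin (cage centre)
    lig = rng.normal(scale=0.8, size=(5, 3))
    lig_masses = np.array([12.0, 12.0, 14.0, 16.0, 12.0])
    lig -= (lig_masses[:, None] * lig).sum(axis=0) / lig_masses.sum()

    exit_axis = np.array([1.0, 0.0, 0.0])
    # funnel along the exit axis: bound minimum at displacement 0, released
    # minimum at 12 Å, 6 k_BT barrier at 6 Å
    potential = DoubleWell1D(barrier=6.0 * KB * 300.0, x0=6.0)

    complex_ = PseudoComplex(
        receptor_coords=receptor,
        receptor_masses=receptor_masses,
        ligand_template=lig,
        ligand_masses=lig_masses,
        exit_axis=exit_axis,
        potential=potential,
        potential_center=6.0,
        anchor_groups={
            "deep": AtomGroup(range(n_cage, n_cage + 3)),
            "side": AtomGroup(range(n_cage + 3, n_cage + 6)),
            "far": AtomGroup(range(n_cage + 6, n_cage + 9)),
        },
    )

    bound = complex_.frame(0.0)
    lig_group = complex_.ligand_group
    cage_group = AtomGroup(range(n_cage))
    site_group = AtomGroup(list(range(n_cage)) + list(lig_group.indices))
    specs = [
        CVSpec("distance", (lig_group, complex_.anchor_groups["deep"]), name="cv1_pull"),
        CVSpec(
            "angle",
            (lig_group, complex_.anchor_groups["deep"], complex_.anchor_groups["side"]),
            name="cv2_angle",
        ),
        CVSpec(
            "dihedral",
            (
                lig_group,
                complex_.anchor_groups["deep"],
                complex_.anchor_groups["side"],
                complex_.anchor_groups["far"],
            ),
            name="cv3_dihedral",
        ),
        CVSpec("rmsd", (site_group,), reference=bound, name="cv4_site_rmsd"),
        CVSpec("rmsd", (lig_group,), reference=bound, name="cv5_ligand_rmsd"),
    ]
    return complex_, specs


class PseudoComplexSystem:
    """Pseudo-complex wired for the engine.

    The dynamical state is the scalar displacement of the rigid ligand
    along the exit axis; the five geometric CVs are evaluated on the full
    frame and bias forces are chained back analytically:
    d(CV)/d(displacement) = Σ_{ligand atoms} ∇_i CV · axis, using the
    closed-form CV gradients of :mod:`metadrt.geometry`.
    """

    identity_cv = False

    def __init__(
        self,
        complex_: PseudoComplex,
        specs,
        langevin: LangevinParams,
        cv_widths=(0.2, 1.5, 1.5, 0.2, 0.1),
        unbound_cutoff: float = 5.0,
    ):
        self.complex_ = complex_
        self.specs = list(specs)
        self.langevin = langevin
        self.cv_widths = np.asarray(cv_widths, float)
        self.cv_periods = np.array([s.period for s in self.specs])
        self.cv_names = tuple(s.name or s.kind for s in self.specs)
        self.unbound_cutoff = unbound_cutoff
        self._lig_idx = list(complex_.ligand_group.indices)

    def initial_state(self) -> np.ndarray:
        return np.array([0.0])

    def force(self, x: np.ndarray) -> np.ndarray:
        return self.complex_.displacement_force(x)

    def cv_and_jacobian(self, x: np.ndarray):
        frame = self.complex_.frame(float(x[0]))
        values = np.empty(len(self.specs))
        jac = np.empty((len(self.specs), 1))
        axis = self.complex_.exit_axis
        for k, spec in enumerate(self.specs):
            v, grad = cv_value_and_gradient(frame, spec)
            values[k] = v
            jac[k, 0] = float(np.sum(grad[self._lig_idx] @ axis))
        return values, jac

    def is_unbound(self, x: np.ndarray) -> bool:
        frame = self.complex_.frame(float(x[0]))
        return is_unbound(
            frame,
            self.complex_.ligand_group,
            self.complex_.receptor_group,
            cutoff=self.unbound_cutoff,
        )
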