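"""Collective-variable calculators over coordinate frames.

The unbinding protocols bias low-dimensional functions of the atomic
coordinates: a pulling distance between centres of mass (COMs), an angle and
a dihedral built from additional anchor COMs that describe motion orthogonal
to the pulling direction, and positional RMSDs of the ligand and of the
binding-site side chains.  This module provides those calculators on plain
coordinate frames, their analytic gradients (needed to turn the bias
potential into forces on the particles), and the geometric unbound-state
detector (no receptor atom within a cutoff of any ligand atom).

Conventions
-----------
* Coordinates are Cartesian and in Å; angles and dihedrals are reported in
  degrees.  No periodic-boundary minimum-image handling is applied: the model
  systems in this package are non-periodic, and externally supplied
  trajectories must be pre-imaged.
* RMSD is computed in the laboratory frame (no superposition) by default.
  The receptor scaffold in the simulations this mirrors is held by harmonic
  backbone restraints, so the lab frame is the natural reference; an optional
  superposition mode exists for unrestrained inputs.
* The dihedral is the signed torsion in (−180°, 180°], IUPAC sign convention
  (positive when, looking from the second COM towards the third, the far bond
  rotates clockwise relative to the near bond).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation


class InvalidSelectionError(ValueError):
    """An atom group is empty, out of bounds, duplicated or overlapping."""


class DegenerateGeometryError(ValueError):
    """Coincident or collinear COMs make an angular CV undefined."""


@dataclass(frozen=True)
class Frame:
    """A set of particle coordinates (Å) with masses (amu) at a time (ps)."""

    coords: np.ndarray
    masses: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if masses.shape != (coords.shape[0],):
            raise ValueError("masses must have one entry per particle")
        if coords.shape[0] == 0:
            raise ValueError("frame must contain at least one particle")
        if np.any(masses <= 0):
            raise ValueError("masses must be strictly positive")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "masses", masses)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class AtomGroup:
    """An index selection over a frame, used as a COM or RMSD group."""

    indices: tuple[int, ...]

    def __init__(self, indices: Iterable[int]):
        idx = tuple(int(i) for i in indices)
        if len(idx) == 0:
            raise InvalidSelectionError("atom group must be non-empty")
        if len(set(idx)) != len(idx):
            raise InvalidSelectionError("atom group indices must be unique")
        object.__setattr__(self, "indices", idx)

    def validate(self, frame: Frame) -> None:
        if min(self.indices) < 0 or max(self.indices) >= frame.n_atoms:
            raise InvalidSelectionError(
                f"indices {self.indices} out of bounds for frame of "
                f"{frame.n_atoms} particles"
            )

    def __len__(self) -> int:
        return len(self.indices)


CV_KINDS = ("distance", "angle", "dihedral", "rmsd")
#: group count required by each CV kind
_GROUPS_PER_KIND = {"distance": 2, "angle": 3, "dihedral": 4, "rmsd": 1}


@dataclass(frozen=True)
class CVSpec:
    """Specification of one collective variable.

    ``distance`` takes two COM groups, ``angle`` three (vertex at the
    second), ``dihedral`` four, and ``rmsd`` a single group plus a reference
    frame.  Angular CVs are periodic with a 360° period (relevant for the
    dihedral, whose value lives on a circle; the angle itself is confined to
    [0°, 180°]).
    """

    kind: str
    groups: tuple[AtomGroup, ...]
    reference: Optional[Frame] = None
    superpose: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        object.__setattr__(self, "groups", tuple(self.groups))
        need = _GROUPS_PER_KIND[self.kind]
        if len(self.groups) != need:
            raise ValueError(f"{self.kind} CV needs {need} groups, got {len(self.groups)}")
        if self.kind == "rmsd":
            if self.reference is None:
                raise ValueError("rmsd CV requires a reference frame")
            if max(self.groups[0].indices) >= self.reference.n_atoms:
                raise InvalidSelectionError("rmsd reference lacks coordinates for group")

    @property
    def periodic(self) -> bool:
        return self.kind == "dihedral"

    @property
    def period(self) -> float:
        return 360.0 if self.periodic else 0.0


def center_of_mass(frame: Frame, group: AtomGroup) -> np.ndarray:
    """Mass-weighted mean position (Å) of the group members."""
    group.validate(frame)
    idx = list(group.indices)
    m = frame.masses[idx]
    return (m[:, None] * frame.coords[idx]).sum(axis=0) / m.sum()


def cv_distance(frame: Frame, group_a: AtomGroup, group_b: AtomGroup) -> float:
    """Euclidean distance (Å) between two group COMs."""
    return float(np.linalg.norm(center_of_mass(frame, group_a) - center_of_mass(frame, group_b)))


def _angle_from_coms(c1: np.ndarray, c2: np.ndarray, c3: np.ndarray) -> float:
    a = c1 - c2
    b = c3 - c2
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateGeometryError("coincident COMs: angle undefined")
    # atan2 form is stable near 0 and 180 degrees
    cross = np.linalg.norm(np.cross(a, b))
    dot = float(np.dot(a, b))
    return float(np.degrees(np.arctan2(cross, dot)))


def cv_angle(frame: Frame, g1: AtomGroup, g2: AtomGroup, g3: AtomGroup) -> float:
    """Angle (degrees, in [0, 180]) at the COM of ``g2``."""
    coms = [center_of_mass(frame, g) for g in (g1, g2, g3)]
    return _angle_from_coms(*coms)


def _dihedral_from_coms(
    c1: np.ndarray, c2: np.ndarray, c3: np.ndarray, c4: np.ndarray
) -> float:
    b1 = c2 - c1
    b2 = c3 - c2
    b3 = c4 - c3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        raise DegenerateGeometryError("collinear COMs: dihedral undefined")
    # IUPAC sign: positive when the far bond rotates clockwise relative to
    # the near bond viewed from c2 towards c3
    m = np.cross(b2 / nb2, n1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    phi = np.degrees(np.arctan2(y, x))
    # map −180 to +180 so the range is (−180, 180]
    if phi <= -180.0:
        phi += 360.0
    return float(phi)


def cv_dihedral(
    frame: Frame, g1: AtomGroup, g2: AtomGroup, g3: AtomGroup, g4: AtomGroup
) -> float:
    """Signed torsion (degrees, (−180, 180]) over four group COMs."""
    coms = [center_of_mass(frame, g) for g in (g1, g2, g3, g4)]
    return _dihedral_from_coms(*coms)


def cv_rmsd(
    frame: Frame,
    reference: Frame,
    group: AtomGroup,
    superpose: bool = False,
) -> float:
    """Positional RMSD (Å) of the group members against a reference frame.

    By default no superposition is performed (lab-frame RMSD, appropriate
    when the scaffold is positionally restrained).  With ``superpose=True``
    the optimal rigid-body fit (Kabsch) is removed first.
    """
    group.validate(frame)
    if max(group.indices) >= reference.n_atoms:
        raise InvalidSelectionError("reference lacks coordinates for group")
    idx = list(group.indices)
    x = frame.coords[idx]
    r = reference.coords[idx]
    if superpose:
        xc = x - x.mean(axis=0)
        rc = r - r.mean(axis=0)
        rot, _ = Rotation.align_vectors(rc, xc)
        x = rot.apply(xc)
        r = rc
    return float(np.sqrt(np.mean(np.sum((x - r) ** 2, axis=1))))


def evaluate_cv(frame: Frame, spec: CVSpec) -> float:
    if spec.kind == "distance":
        return cv_distance(frame, *spec.groups)
    if spec.kind == "angle":
        return cv_angle(frame, *spec.groups)
    if spec.kind == "dihedral":
        return cv_dihedral(frame, *spec.groups)
    return cv_rmsd(frame, spec.reference, spec.groups[0], superpose=spec.superpose)


def evaluate_cvs(frame: Frame, specs: Sequence[CVSpec]) -> np.ndarray:
    """Evaluate a CV set on a frame, in spec order."""
    return np.array([evaluate_cv(frame, s) for s in specs], dtype=float)


def min_intergroup_distance(frame: Frame, ga: AtomGroup, gb: AtomGroup) -> float:
    """Minimum inter-atomic distance (Å) between two disjoint groups."""
    ga.validate(frame)
    gb.validate(frame)
    if set(ga.indices) & set(gb.indices):
        raise InvalidSelectionError("groups overlap")
    d = cdist(frame.coords[list(ga.indices)], frame.coords[list(gb.indices)])
    return float(d.min())


def is_unbound(
    frame: Frame, ligand: AtomGroup, receptor: AtomGroup, cutoff: float = 5.0
) -> bool:
    """True iff no receptor atom lies within ``cutoff`` Å of any ligand atom.

    This is the geometric exit criterion of the unbinding protocols: the
    ligand counts as unbound (fully solvated) when the number of receptor
    atoms within the cutoff sphere of any of its atoms is zero.
    """
    return min_intergroup_distance(frame, ligand, receptor) > cutoff


# ---------------------------------------------------------------------------
# analytic gradients (chain rule through COMs), used to apply bias forces
# ---------------------------------------------------------------------------

def _com_chain(frame: Frame, group: AtomGroup, grad_com: np.ndarray, out: np.ndarray) -> None:
    idx = list(group.indices)
    m = frame.masses[idx]
    w = m / m.sum()
    out[idx] += w[:, None] * grad_com[None, :]


def _angle_grad_coms(c1, c2, c3):
    a = c1 - c2
    b = c3 - c2
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    ah, bh = a / na, b / nb
    cos_t = float(np.clip(np.dot(ah, bh), -1.0, 1.0))
    sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    if sin_t < 1e-10:
        raise DegenerateGeometryError("angle gradient undefined at 0/180 degrees")
    g1 = (cos_t * ah - bh) / (na * sin_t)
    g3 = (cos_t * bh - ah) / (nb * sin_t)
    return g1, -(g1 + g3), g3


def _dihedral_grad_coms(c1, c2, c3, c4):
    b1 = c2 - c1
    b2 = c3 - c2
    b3 = c4 - c3
    f = np.cross(b1, b2)
    g = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    f2 = float(np.dot(f, f))
    g2 = float(np.dot(g, g))
    if f2 < 1e-20 or g2 < 1e-20 or nb2 < 1e-12:
        raise DegenerateGeometryError("dihedral gradient undefined for collinear COMs")
    d1 = -(nb2 / f2) * f
    d4 = (nb2 / g2) * g
    t = float(np.dot(b1, b2)) / (nb2 * nb2)
    u = float(np.dot(b3, b2)) / (nb2 * nb2)
    d2 = -(1.0 + t) * d1 + u * d4
    d3 = t * d1 - (1.0 + u) * d4
    return d1, d2, d3, d4


def cv_value_and_gradient(frame: Frame, spec: CVSpec) -> tuple[float, np.ndarray]:
    """CV value plus its gradient with respect to every particle coordinate.

    Returns ``(value, grad)`` with ``grad`` of shape ``(n_atoms, 3)``.
    Angular gradients are in degrees per Å.
    """
    grad = np.zeros_like(frame.coords)
    if spec.kind == "distance":
        ca = center_of_mass(frame, spec.groups[0])
        cb = center_of_mass(frame, spec.groups[1])
        diff = ca - cb
        d = float(np.linalg.norm(diff))
        if d < 1e-12:
            # the distance cusp at zero: gradient taken as 0 by convention
            return 0.0, grad
        u = diff / d
        _com_chain(frame, spec.groups[0], u, grad)
        _com_chain(frame, spec.groups[1], -u, grad)
        return d, grad
    if spec.kind == "angle":
        coms = [center_of_mass(frame, g) for g in spec.groups]
        value = _angle_from_coms(*coms)
        for g, gc in zip(spec.groups, _angle_grad_coms(*coms)):
            _com_chain(frame, g, np.degrees(gc), grad)
        return value, grad
    if spec.kind == "dihedral":
        coms = [center_of_mass(frame, g) for g in spec.groups]
        value = _dihedral_from_coms(*coms)
        for g, gc in zip(spec.groups, _dihedral_grad_coms(*coms)):
            _com_chain(frame, g, np.degrees(gc), grad)
        return value, grad
    # rmsd (no superposition: lab-frame gradient is closed form)
    value = cv_rmsd(frame, spec.reference, spec.groups[0], superpose=False)
    idx = list(spec.groups[0].indices)
    n = len(idx)
    if value > 1e-12:
        grad[idx] = (frame.coords[idx] - spec.reference.coords[idx]) / (n * value)
    return value, grad
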