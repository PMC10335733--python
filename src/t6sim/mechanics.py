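"""Geometry, growth, division, and overdamped mechanics of spherocylindrical
cells in a 2D monolayer.

Each cell is a spherocylinder: a cylinder of length ``ell`` capped by two
hemispheres of constant radius, lying flat on a viscous substrate.  Cells
elongate exponentially along their axis and divide by the adder rule (a
fixed length increment ``delta_L`` added since birth triggers division).
Contact forces are Hookean in the overlap of the cap-inflated axes, motion
is overdamped with drag proportional to cell length (translation) and
length cubed (rotation).

Units are micrometres and hours throughout.  The per-cell operations here
are the reference semantics; :mod:`t6sim.population` carries the vectorised
engine used for whole-colony runs and is cross-checked against this module
in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import count as _count
from typing import Sequence

import numpy as np

from t6sim.kinetics import KineticParams

__all__ = [
    "MechanicsParams",
    "Arena",
    "StrainSpec",
    "Cell",
    "PairForce",
    "MechanicsInstabilityError",
    "effective_growth_rate",
    "grow_cell",
    "maybe_divide",
    "segment_min_distance",
    "pair_interaction",
    "step_mechanics",
    "growth_attenuation",
    "min_image",
    "wrap_position",
]

#: default cap radius (µm), typical for Vibrio-scale rods
DEFAULT_RADIUS = 0.5
#: default total length of a newborn cell (µm)
DEFAULT_BIRTH_LENGTH = 2.0

_cell_ids = _count(1_000_000)  # fallback id allocator for standalone division


class MechanicsInstabilityError(RuntimeError):
    """A mechanics sub-step moved a cell further than half a radius."""


@dataclass(frozen=True)
class MechanicsParams:
    """Mechanical constants of the monolayer model.

    k_elastic : contact stiffness (drag-normalised force per µm of overlap).
        With ``zeta = 1`` the ratio ``k_elastic / zeta`` sets the inverse
        contact relaxation time; the default gives ~3 min, far below the
        ~1 h doubling time, so colonies stay close to mechanical
        equilibrium while growing.
    zeta : translational drag per µm of total cell length.
    zeta_rot : rotational drag coefficient scale (drag = zeta_rot * L^3).
    contact_eps : surface gap (µm) below which two cells count as touching
        for T6SS purposes; the default of one cap radius reflects the
        µm-scale reach of a contracting sheath-and-tube structure.
    pressure_star : summed overlap (µm) that fully arrests a cell's growth.
    dt_mech : mechanics sub-step (h); must satisfy the stability bound
        ``dt_mech <= 0.1 * zeta / k_elastic``.
    """

    k_elastic: float = 20.0
    zeta: float = 1.0
    zeta_rot: float = 1.0 / 12.0
    contact_eps: float = 0.5
    pressure_star: float = 0.5
    dt_mech: float = 0.004

    def __post_init__(self) -> None:
        for name in (
            "k_elastic",
            "zeta",
            "zeta_rot",
            "contact_eps",
            "pressure_star",
            "dt_mech",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def stability_dt(self) -> float:
        return 0.1 * self.zeta / self.k_elastic


@dataclass(frozen=True)
class Arena:
    """2D domain: size, boundary type, carrying capacity, mechanics constants.

    ``carrying_capacity`` is the occupied-area fraction at which growth
    stalls; crowding below that attenuates growth smoothly (see
    :func:`growth_attenuation`).
    """

    Lx: float
    Ly: float
    boundary: str = "periodic"
    carrying_capacity: float = 0.9
    mech: MechanicsParams = field(default_factory=MechanicsParams)

    def __post_init__(self) -> None:
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.boundary not in ("periodic", "open"):
            raise ValueError("boundary must be 'periodic' or 'open'")
        if not 0.0 < self.carrying_capacity <= 1.0:
            raise ValueError("carrying_capacity must be in (0, 1]")

    @property
    def periodic(self) -> bool:
        return self.boundary == "periodic"

    @property
    def area(self) -> float:
        return self.Lx * self.Ly


@dataclass(frozen=True)
class StrainSpec:
    """A computational strain: T6SS kinetics, growth economics, lysis time.

    r0 : base growth rate (1/h) of a T6SS-inactive cell.
    c : growth cost per unit of sheath synthesis rate; an activated cell
        grows at ``max(0, r0 - c * lambda_s)``.
    tau_lys : time (h) a killed cell keeps occupying space before it
        disintegrates.
    """

    name: str
    kinetics: KineticParams
    r0: float = 0.7
    c: float = 0.005
    tau_lys: float = 0.5

    def __post_init__(self) -> None:
        if self.r0 < 0 or self.c < 0 or self.tau_lys < 0:
            raise ValueError("r0, c and tau_lys must be >= 0")


def effective_growth_rate(strain: StrainSpec) -> float:
    """Growth rate of a T6SS-active cell: ``max(0, r0 - c * lambda_s)``."""
    return max(0.0, strain.r0 - strain.c * strain.kinetics.lambda_s)


@dataclass
class Cell:
    """One agent: geometry, adder bookkeeping, internal T6SS state, life state."""

    id: int
    strain_id: int
    center: np.ndarray
    theta: float
    ell: float
    radius: float = DEFAULT_RADIUS
    ell_birth: float = 0.0
    added: float = 0.0
    G: bool = False
    N: int = 0
    status: str = "alive"
    lysis_clock: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.ell < 0 or self.added < 0 or self.N < 0:
            raise ValueError("ell, added and N must be >= 0")
        if self.status not in ("alive", "lysing"):
            raise ValueError("status must be 'alive' or 'lysing'")

    @property
    def total_length(self) -> float:
        return self.ell + 2.0 * self.radius

    @property
    def area(self) -> float:
        """Projected (footprint) area: rectangle plus two half-discs."""
        return 2.0 * self.radius * self.ell + math.pi * self.radius**2

    @property
    def axis(self) -> np.ndarray:
        return np.array([math.cos(self.theta), math.sin(self.theta)])

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        h = 0.5 * self.ell * self.axis
        return self.center - h, self.center + h


def min_image(delta: np.ndarray, arena: Arena | None) -> np.ndarray:
    """Minimum-image convention applied to a displacement vector."""
    delta = np.asarray(delta, dtype=float)
    if arena is not None and arena.periodic:
        box = np.array([arena.Lx, arena.Ly])
        delta = delta - box * np.round(delta / box)
    return delta


def wrap_position(pos: np.ndarray, arena: Arena) -> np.ndarray:
    """Wrap a position into [0, L) on each periodic axis."""
    pos = np.asarray(pos, dtype=float)
    if arena.periodic:
        return pos % np.array([arena.Lx, arena.Ly])
    return pos


def grow_cell(
    cell: Cell,
    strain: StrainSpec,
    dt: float,
    attenuation: float,
) -> Cell:
    """Elongate a live cell for ``dt`` hours at the given attenuation factor.

    Elongation is exponential in the total length: the increment is
    ``L_tot * (exp(r * attenuation * dt) - 1)`` with ``r`` the strain's
    active growth rate if the cell is T6SS-active, else its base rate.
    The exact exponential update makes the closed-form doubling test hold
    for any sub-stepping.  Lysing cells never grow.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must be in [0, 1]")
    if cell.status == "lysing":
        return cell
    rate = effective_growth_rate(strain) if cell.G else strain.r0
    increment = cell.total_length * math.expm1(rate * attenuation * dt)
    return replace(cell, ell=cell.ell + increment, added=cell.added + increment)


def maybe_divide(
    cell: Cell,
    delta_L: float,
    rng: np.random.Generator,
    angle_noise_sd: float = 0.05,
    new_ids: tuple[int, int] | None = None,
    arena: Arena | None = None,
) -> list[Cell]:
    """Divide a cell by the adder rule, or return it unchanged.

    Division fires when the length added since birth reaches ``delta_L``.
    The daughters lie end-to-end along the mother's axis, covering her
    extent, each with cylinder length ``(ell - 2 radius) / 2`` (clamped at
    zero).  Both inherit the activation state; the mother's sheaths are
    split Binomial(N, 1/2).  A small independent angular perturbation
    breaks colinearity so growing colonies buckle.
    """
    if delta_L <= 0:
        raise ValueError("delta_L must be > 0")
    if cell.status == "lysing" or cell.added < delta_L:
        return [cell]
    if new_ids is None:
        new_ids = (next(_cell_ids), next(_cell_ids))
    ell_d = max(0.0, (cell.ell - 2.0 * cell.radius) / 2.0)
    offset = cell.total_length / 4.0
    u = cell.axis
    n1 = int(rng.binomial(cell.N, 0.5))
    daughters = []
    for ident, sign, n_sheaths in ((new_ids[0], -1.0, n1), (new_ids[1], 1.0, cell.N - n1)):
        pos = cell.center + sign * offset * u
        if arena is not None:
            pos = wrap_position(pos, arena)
        daughters.append(
            Cell(
                id=ident,
                strain_id=cell.strain_id,
                center=pos,
                theta=cell.theta + rng.normal(0.0, angle_noise_sd),
                ell=ell_d,
                radius=cell.radius,
                ell_birth=ell_d,
                added=0.0,
                G=cell.G,
                N=n_sheaths,
                status="alive",
            )
        )
    return daughters


def segment_min_distance(
    a1: np.ndarray,
    a2: np.ndarray,
    b1: np.ndarray,
    b2: np.ndarray,
    arena: Arena | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between segments (a1,a2) and (b1,b2) and its witnesses.

    Under a periodic arena the second segment is shifted by the minimum-image
    displacement of its midpoint relative to the first's, which is exact
    whenever segments are shorter than half the box.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    mid_a = 0.5 * (a1 + a2)
    mid_b = 0.5 * (b1 + b2)
    shift = min_image(mid_b - mid_a, arena) - (mid_b - mid_a)
    b1 = b1 + shift
    b2 = b2 + shift

    d1 = a2 - a1
    d2 = b2 - b1
    r = a1 - b1
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-14
    if a <= eps and e <= eps:
        s = t = 0.0
    elif a <= eps:
        s = 0.0
        t = np.clip(f / e, 0.0, 1.0)
    elif e <= eps:
        t = 0.0
        s = np.clip(-(d1 @ r) / a, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        b = float(d1 @ d2)
        denom = a * e - b * b
        s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
        t = (b * s + f) / e
        if t < 0.0:
            t = 0.0
            s = np.clip(-c / a, 0.0, 1.0)
        elif t > 1.0:
            t = 1.0
            s = np.clip((b - c) / a, 0.0, 1.0)
    pa = a1 + s * d1
    pb = b1 + t * d2
    return float(np.linalg.norm(pa - pb)), pa, pb


@dataclass(frozen=True)
class PairForce:
    force_a: np.ndarray
    force_b: np.ndarray
    torque_a: float
    torque_b: float
    overlap: float


def pair_interaction(cell_a: Cell, cell_b: Cell, arena: Arena) -> PairForce:
    """Hookean repulsion between two spherocylinders.

    Overlap is ``max(0, 2 radius - d)`` with ``d`` the axis-segment
    distance; the force has magnitude ``k_elastic * overlap``, acts along
    the line joining the witness points, and obeys action--reaction
    exactly.  Torques use the witness points as lever arms.  Exactly
    coincident axes are pushed apart perpendicular to the lower-id cell's
    axis so the outcome is deterministic.
    """
    a1, a2 = cell_a.endpoints()
    b1, b2 = cell_b.endpoints()
    d, pa, pb = segment_min_distance(a1, a2, b1, b2, arena)
    two_r = cell_a.radius + cell_b.radius
    overlap = max(0.0, two_r - d)
    zero = np.zeros(2)
    if overlap == 0.0:
        return PairForce(zero, zero.copy(), 0.0, 0.0, 0.0)
    if d > 1e-9:
        n = (pa - pb) / d
    else:
        lower = cell_a if cell_a.id < cell_b.id else cell_b
        ax = lower.axis
        n = np.array([-ax[1], ax[0]])
    f = arena.mech.k_elastic * overlap * n
    # witness points live in cell_a's frame; b's center there is the
    # minimum-image position of cell_b relative to cell_a
    r_a = pa - cell_a.center
    r_b = pb - (cell_a.center + min_image(cell_b.center - cell_a.center, arena))
    torque_a = float(r_a[0] * f[1] - r_a[1] * f[0])
    torque_b = float(r_b[0] * -f[1] - r_b[1] * -f[0])
    return PairForce(f, -f, torque_a, torque_b, overlap)


def step_mechanics(
    cells: Sequence[Cell], arena: Arena, dt_mech: float | None = None
) -> list[Cell]:
    """One overdamped relaxation sub-step over all cells (O(n^2) reference).

    Velocities are net force over ``zeta * total_length``; angular
    velocities are net torque over ``zeta_rot * total_length^3``.  Lysing
    cells participate fully.  Raises
    :class:`MechanicsInstabilityError` if any displacement exceeds half a
    radius, the signature of too large a time step.
    """
    mech = arena.mech
    if dt_mech is None:
        dt_mech = mech.dt_mech
    if dt_mech > mech.stability_dt * (1 + 1e-9):
        raise MechanicsInstabilityError(
            f"dt_mech={dt_mech} exceeds stability bound {mech.stability_dt}"
        )
    n = len(cells)
    forces = np.zeros((n, 2))
    torques = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            pf = pair_interaction(cells[i], cells[j], arena)
            forces[i] += pf.force_a
            forces[j] += pf.force_b
            torques[i] += pf.torque_a
            torques[j] += pf.torque_b
    out = []
    for i, cell in enumerate(cells):
        ltot = cell.total_length
        disp = forces[i] / (mech.zeta * ltot) * dt_mech
        if np.linalg.norm(disp) > cell.radius / 2.0:
            raise MechanicsInstabilityError(
                f"cell {cell.id} moved {np.linalg.norm(disp):.3g} µm in one sub-step"
            )
        dtheta = torques[i] / (mech.zeta_rot * ltot**3) * dt_mech
        out.append(
            replace(
                cell,
                center=wrap_position(cell.center + disp, arena),
                theta=cell.theta + dtheta,
            )
        )
    return out


def growth_attenuation(
    cell: Cell, overlap_sum: float, occupied_fraction: float, arena: Arena
) -> float:
    """Growth attenuation from local pressure and global crowding.

    ``max(0, 1 - overlap_sum/pressure_star) * max(0, 1 - occupied/capacity)``,
    clamped to [0, 1].
    """
    if overlap_sum < 0 or occupied_fraction < 0:
        raise ValueError("overlap_sum and occupied_fraction must be >= 0")
    local = max(0.0, 1.0 - overlap_sum / arena.mech.pressure_star)
    crowd = max(0.0, 1.0 - occupied_fraction / arena.carrying_capacity)
    return local * crowd
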