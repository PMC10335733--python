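"""Contact graph construction, T6SS firing resolution, and lysis lifecycle.

Firing follows the contact-dependent rules of the model: a fired sheath
selects its target uniformly among a fixed number ``k_max`` of slots around
the shooter, of which the first ``k`` are occupied by the cells currently
in contact and the remainder are empty (a miss into the intercellular
milieu).  A hit on a clonemate has no effect (clonemate immunity); a hit
on a live non-clonal cell kills it instantly, after which the corpse keeps
occupying space for its strain's lysis time ``tau_lys`` before it is
removed.  Hits on already-lysing cells are absorbed (corpses shield).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from t6sim.mechanics import Arena, Cell, StrainSpec, segment_min_distance

__all__ = [
    "ContactGraph",
    "FiringOutcome",
    "DEFAULT_K_MAX",
    "build_contacts",
    "resolve_firing",
    "update_lysis",
]

#: default number of target slots around a shooter -- the typical
#: coordination number of a rod in a dense monolayer (hexagonal packing)
DEFAULT_K_MAX = 6

MISS = "miss"
HIT_CLONEMATE = "hit_clonemate"
KILL = "kill"
HIT_DEAD = "hit_dead"


@dataclass(frozen=True)
class ContactGraph:
    """Symmetric adjacency over live-or-lysing cells, keyed by cell id."""

    adjacency: Mapping[int, tuple[int, ...]]

    def neighbors(self, cell_id: int) -> tuple[int, ...]:
        return self.adjacency.get(cell_id, ())

    def degree(self, cell_id: int) -> int:
        return len(self.neighbors(cell_id))


@dataclass(frozen=True)
class FiringOutcome:
    """Record of one fired sheath: shooter, result, and target if any."""

    shooter: int
    result: str
    target: int | None = None


def build_contacts(cells: Sequence[Cell], arena: Arena) -> ContactGraph:
    """All-pairs contact graph: adjacent iff the surface gap <= contact_eps.

    O(n^2) reference implementation; the engine builds the same graph from
    its binned pair list and is tested against this one.
    """
    eps = arena.mech.contact_eps
    adjacency: dict[int, list[int]] = {c.id: [] for c in cells}
    for i, a in enumerate(cells):
        a1, a2 = a.endpoints()
        for b in cells[i + 1 :]:
            b1, b2 = b.endpoints()
            d, _, _ = segment_min_distance(a1, a2, b1, b2, arena)
            if d - (a.radius + b.radius) <= eps:
                adjacency[a.id].append(b.id)
                adjacency[b.id].append(a.id)
    return ContactGraph({k: tuple(v) for k, v in adjacency.items()})


def resolve_firing(
    shooter: Cell,
    shots: int,
    graph: ContactGraph,
    cells: Mapping[int, Cell],
    strains: Sequence[StrainSpec],
    rng: np.random.Generator,
    k_max: int = DEFAULT_K_MAX,
) -> list[FiringOutcome]:
    """Resolve ``shots`` fired sheaths from one live shooter.

    Each shot independently draws one of ``max(k, k_max)`` slots, where
    ``k`` is the shooter's contact count; slots beyond ``k`` are void
    (miss).  Kills mutate the target cell in place: status becomes
    ``lysing`` and the lysis clock is set to the target strain's
    ``tau_lys``.  A strain with ``lambda_f = 0`` never produces shots
    upstream, so it never appears as a shooter.
    """
    if shots < 0:
        raise ValueError("shots must be >= 0")
    if shooter.status != "alive":
        raise ValueError("only live cells fire")
    outcomes: list[FiringOutcome] = []
    neighbors = graph.neighbors(shooter.id)
    k = len(neighbors)
    n_slots = max(k, k_max)
    for _ in range(shots):
        slot = int(rng.integers(n_slots)) if n_slots > 0 else -1
        if slot < 0 or slot >= k:
            outcomes.append(FiringOutcome(shooter.id, MISS))
            continue
        target = cells[neighbors[slot]]
        if target.status == "lysing":
            outcomes.append(FiringOutcome(shooter.id, HIT_DEAD, target.id))
        elif target.strain_id == shooter.strain_id:
            outcomes.append(FiringOutcome(shooter.id, HIT_CLONEMATE, target.id))
        else:
            target.status = "lysing"
            target.lysis_clock = strains[target.strain_id].tau_lys
            outcomes.append(FiringOutcome(shooter.id, KILL, target.id))
    return outcomes


def update_lysis(cells: Sequence[Cell], dt: float) -> list[Cell]:
    """Advance lysis clocks by ``dt`` and drop cells that have disintegrated.

    Lysing cells stay in the returned population (and hence in mechanics
    and contact graphs) until their clock reaches zero.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    survivors: list[Cell] = []
    for cell in cells:
        if cell.status == "lysing":
            remaining = cell.lysis_clock - dt
            if remaining <= 0:
                continue
            survivors.append(replace(cell, lysis_clock=remaining))
        else:
            survivors.append(cell)
    return survivors
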