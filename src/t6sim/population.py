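"""Vectorised colony engine: struct-of-arrays population plus the coupled
reaction/growth/mechanics step.

The per-cell semantics (growth law, adder division, contact forces, firing
slots, lysis) are defined in :mod:`t6sim.mechanics` and
:mod:`t6sim.combat`; this module implements the same rules over numpy
arrays with numba kernels for the pairwise geometry so that whole-colony
competition runs are tractable.  Parity between the two layers is enforced
by tests.

Within one reaction step of length ``dt`` the cycle is: contact/force
evaluation, activation, sheath synthesis and firing, firing resolution
(simultaneous within the step), overdamped mechanics sub-steps, lysis
bookkeeping, growth with attenuation, adder division.  Mechanics directly
follows firing so it can reuse the step-start force evaluation -- the
internal reactions move nobody -- and newly divided or removed cells are
felt mechanically from the next step on; all reordering effects within a
step are O(dt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from t6sim import _kernels
from t6sim.combat import DEFAULT_K_MAX
from t6sim.kinetics import MAX_RATE_DT
from t6sim.mechanics import (
    DEFAULT_BIRTH_LENGTH,
    DEFAULT_RADIUS,
    Arena,
    Cell,
    MechanicsInstabilityError,
    StrainSpec,
    effective_growth_rate,
)

__all__ = ["StrainTable", "Population", "Simulation"]


class StrainTable:
    """Strain parameters unpacked into aligned arrays, indexed by strain id."""

    def __init__(self, strains: Sequence[StrainSpec]):
        self.specs = list(strains)
        get = lambda f: np.array([f(s) for s in self.specs], dtype=float)
        self.p0 = get(lambda s: s.kinetics.p0)
        self.tau_plus = get(lambda s: s.kinetics.tau_plus)
        self.lambda_plus = get(lambda s: s.kinetics.lambda_plus)
        self.lambda_s = get(lambda s: s.kinetics.lambda_s)
        self.lambda_f = get(lambda s: s.kinetics.lambda_f)
        self.tau_lys = get(lambda s: s.tau_lys)
        self.rate_inactive = get(lambda s: s.r0)
        self.rate_active = get(effective_growth_rate)

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]


@dataclass
class Population:
    """Struct-of-arrays snapshot of a colony."""

    ids: np.ndarray
    strain: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    ell: np.ndarray
    ell_birth: np.ndarray
    added: np.ndarray
    G: np.ndarray
    N: np.ndarray
    lysing: np.ndarray
    lysis_clock: np.ndarray
    radius: float = DEFAULT_RADIUS

    def __len__(self) -> int:
        return self.ids.size

    @property
    def alive(self) -> np.ndarray:
        return ~self.lysing

    @property
    def total_length(self) -> np.ndarray:
        return self.ell + 2.0 * self.radius

    @property
    def area(self) -> np.ndarray:
        """Projected footprint area per cell (µm^2)."""
        return 2.0 * self.radius * self.ell + math.pi * self.radius**2

    @classmethod
    def from_cells(cls, cells: Sequence[Cell]) -> "Population":
        radius = cells[0].radius if cells else DEFAULT_RADIUS
        if any(c.radius != radius for c in cells):
            raise ValueError("the engine assumes a single cap radius")
        arr = lambda f, dtype=float: np.array([f(c) for c in cells], dtype=dtype)
        return cls(
            ids=arr(lambda c: c.id, np.int64),
            strain=arr(lambda c: c.strain_id, np.int64),
            x=arr(lambda c: c.center[0]),
            y=arr(lambda c: c.center[1]),
            theta=arr(lambda c: c.theta),
            ell=arr(lambda c: c.ell),
            ell_birth=arr(lambda c: c.ell_birth),
            added=arr(lambda c: c.added),
            G=arr(lambda c: c.G, bool),
            N=arr(lambda c: c.N, np.int64),
            lysing=arr(lambda c: c.status == "lysing", bool),
            lysis_clock=arr(lambda c: c.lysis_clock),
            radius=radius,
        )

    def to_cells(self) -> list[Cell]:
        return [
            Cell(
                id=int(self.ids[i]),
                strain_id=int(self.strain[i]),
                center=np.array([self.x[i], self.y[i]]),
                theta=float(self.theta[i]),
                ell=float(self.ell[i]),
                radius=self.radius,
                ell_birth=float(self.ell_birth[i]),
                added=float(self.added[i]),
                G=bool(self.G[i]),
                N=int(self.N[i]),
                status="lysing" if self.lysing[i] else "alive",
                lysis_clock=float(self.lysis_clock[i]),
            )
            for i in range(len(self))
        ]

    def compress(self, keep: np.ndarray) -> None:
        for name in (
            "ids",
            "strain",
            "x",
            "y",
            "theta",
            "ell",
            "ell_birth",
            "added",
            "G",
            "N",
            "lysing",
            "lysis_clock",
        ):
            setattr(self, name, getattr(self, name)[keep])


class Simulation:
    """Steps a :class:`Population` forward under the full coupled model."""

    def __init__(
        self,
        pop: Population,
        strains: Sequence[StrainSpec] | StrainTable,
        arena: Arena,
        rng: np.random.Generator,
        dt: float = 0.004,
        k_max: int = DEFAULT_K_MAX,
        delta_L: float = DEFAULT_BIRTH_LENGTH,
        angle_noise_sd: float = 0.05,
        skin: float = 0.5,
        log_events: bool = False,
    ):
        self.pop = pop
        self.table = strains if isinstance(strains, StrainTable) else StrainTable(strains)
        self.arena = arena
        self.rng = rng
        self.dt = float(dt)
        self.k_max = int(k_max)
        self.delta_L = float(delta_L)
        self.angle_noise_sd = float(angle_noise_sd)
        self.skin = float(skin)
        self.t = 0.0

        worst = max(
            self.table.lambda_plus.max(initial=0.0),
            self.table.lambda_s.max(initial=0.0),
            self.table.lambda_f.max(initial=0.0),
        )
        if worst * self.dt > MAX_RATE_DT:
            raise ValueError(
                f"dt={self.dt} violates the tau-leap bound: max rate {worst}/h "
                f"requires dt <= {0.1 / worst:.4g} h"
            )
        mech = arena.mech
        self.n_sub = max(1, math.ceil(self.dt / mech.stability_dt))
        self.dt_mech = self.dt / self.n_sub

        # per-step reaction probabilities by strain
        self._p_switch = -np.expm1(-self.table.lambda_plus * self.dt)
        self._p_synth = -np.expm1(-self.table.lambda_s * self.dt)
        self._p_fire = -np.expm1(-self.table.lambda_f * self.dt)

        self._next_id = int(pop.ids.max()) + 1 if len(pop) else 0
        self._pairs = None  # (pi, pj)
        self._motion = np.inf  # accumulated motion since last pair build
        self.counters = {
            "shots": 0,
            "miss": 0,
            "hit_clonemate": 0,
            "kill": 0,
            "hit_dead": 0,
            "divisions": 0,
            "removed": 0,
        }
        self.kills_by_strain = np.zeros(len(self.table), dtype=np.int64)
        #: optional firing log: (t, shooter_id, shooter_strain, result,
        #: target_id, target_strain); -1 marks "no target" (a miss)
        self.log_events = bool(log_events)
        self.event_log: list[tuple] = []

    # -- geometry ----------------------------------------------------------

    def _ensure_pairs(self) -> None:
        if self._pairs is not None and self._motion <= self.skin / 2.0:
            return
        pop = self.pop
        reach = 2.0 * pop.radius + self.arena.mech.contact_eps + self.skin
        pi, pj = _kernels.build_pairs(
            pop.x,
            pop.y,
            np.cos(pop.theta),
            np.sin(pop.theta),
            pop.ell / 2.0,
            self.arena.Lx,
            self.arena.Ly,
            self.arena.periodic,
            reach,
        )
        self._pairs = (pi, pj)
        self._motion = 0.0

    def _invalidate_pairs(self) -> None:
        self._pairs = None
        self._motion = np.inf

    def _remap_pairs(self, keep: np.ndarray) -> None:
        """Re-index the cached pair list after array compaction."""
        if self._pairs is None:
            return
        pi, pj = self._pairs
        newidx = np.cumsum(keep) - 1
        ok = keep[pi] & keep[pj]
        self._pairs = (newidx[pi[ok]], newidx[pj[ok]])

    def _patch_pairs_after_division(self, idx: np.ndarray, n_old: int) -> None:
        """Extend the cached pair list to cover freshly appended daughters.

        The first daughter reuses the mother's slot and lies inside her
        spherocylinder extent, so the mother's candidate pairs remain a
        conservative superset for it.  The second daughter (appended at
        ``n_old + k``) also lies inside the mother's extent, so copying the
        mother's pairs onto it -- plus the sibling pair -- again yields a
        superset of its true neighbors.
        """
        if self._pairs is None:
            return
        pi, pj = self._pairs
        is_mother = np.zeros(n_old, dtype=bool)
        is_mother[idx] = True
        d2 = np.zeros(n_old, dtype=np.int64)
        d2[idx] = np.arange(n_old, n_old + idx.size)
        mi = is_mother[pi]
        mj = is_mother[pj]
        both = mi & mj
        add_i = (d2[pi[mi]], pj[mi])
        add_j = (pi[mj], d2[pj[mj]])
        add_b = (d2[pi[both]], d2[pj[both]])
        sib = (idx, d2[idx])
        self._pairs = (
            np.concatenate([pi, add_i[0], add_j[0], add_b[0], sib[0]]),
            np.concatenate([pj, add_i[1], add_j[1], add_b[1], sib[1]]),
        )

    def _evaluate(self):
        """Force, torque, overlap-sum and pair-gap arrays at current geometry."""
        self._ensure_pairs()
        pop = self.pop
        n = len(pop)
        pi, pj = self._pairs
        fx = np.zeros(n)
        fy = np.zeros(n)
        tq = np.zeros(n)
        ovl = np.zeros(n)
        gap = np.empty(pi.size)
        _kernels.eval_pairs(
            pi,
            pj,
            pop.x,
            pop.y,
            np.cos(pop.theta),
            np.sin(pop.theta),
            pop.ell / 2.0,
            pop.radius,
            self.arena.Lx,
            self.arena.Ly,
            self.arena.periodic,
            self.arena.mech.k_elastic,
            fx,
            fy,
            tq,
            ovl,
            gap,
        )
        return fx, fy, tq, ovl, gap

    def contact_csr(self, gap: np.ndarray):
        """Symmetric contact adjacency in CSR form from the current pair gaps."""
        pi, pj = self._pairs
        touching = gap <= self.arena.mech.contact_eps
        return _kernels.build_csr(pi, pj, touching, len(self.pop))

    # -- one reaction step --------------------------------------------------

    def step(self) -> None:
        pop = self.pop
        rng = self.rng
        table = self.table
        if len(pop) == 0:
            self.t += self.dt
            return

        fx, fy, tq, ovl, gap = self._evaluate()
        alive = pop.alive

        # activation: inactive live cells past their strain's waiting period
        can_switch = alive & ~pop.G & (self.t >= table.tau_plus[pop.strain])
        idx = np.flatnonzero(can_switch)
        if idx.size:
            flips = rng.random(idx.size) < self._p_switch[pop.strain[idx]]
            pop.G[idx[flips]] = True

        # sheath synthesis then firing, active live cells only
        act = np.flatnonzero(alive & pop.G)
        fired = np.zeros(len(pop), dtype=np.int64)
        if act.size:
            births = rng.random(act.size) < self._p_synth[pop.strain[act]]
            pop.N[act] += births
            shots = rng.binomial(pop.N[act], self._p_fire[pop.strain[act]])
            pop.N[act] -= shots
            fired[act] = shots

        # firing resolution: simultaneous volley against pre-volley status
        total_shots = int(fired.sum())
        if total_shots:
            nbr, off, deg = self.contact_csr(gap)
            shooters = np.flatnonzero(fired)
            rep = np.repeat(shooters, fired[shooters])
            k = deg[rep]
            slot = rng.integers(0, np.maximum(k, self.k_max))
            hit = slot < k
            self.counters["shots"] += total_shots
            self.counters["miss"] += int((~hit).sum())
            if hit.any():
                tgt = nbr[off[rep[hit]] + slot[hit]]
                shooter_strain = pop.strain[rep[hit]]
                was_lysing = pop.lysing[tgt]
                clone = pop.strain[tgt] == shooter_strain
                kill = ~was_lysing & ~clone
                self.counters["hit_dead"] += int(was_lysing.sum())
                self.counters["hit_clonemate"] += int((clone & ~was_lysing).sum())
                self.counters["kill"] += int(kill.sum())
                if self.log_events:
                    self._log_volley(rep, hit, tgt, was_lysing, clone, kill)
                killed = np.unique(tgt[kill])
                pop.lysing[killed] = True
                pop.lysis_clock[killed] = table.tau_lys[pop.strain[killed]]
                np.add.at(self.kills_by_strain, shooter_strain[kill], 1)
            elif self.log_events:
                self._log_volley(rep, hit, None, None, None, None)

        # overdamped mechanics sub-steps; reactions have not moved anyone, so
        # the first sub-step reuses the step-start force evaluation
        for sub in range(self.n_sub):
            if sub > 0:
                fx, fy, tq, _, _ = self._evaluate()
            ltot = pop.total_length
            mech = self.arena.mech
            dx = fx / (mech.zeta * ltot) * self.dt_mech
            dy = fy / (mech.zeta * ltot) * self.dt_mech
            disp = np.sqrt(dx * dx + dy * dy)
            dmax = float(disp.max(initial=0.0))
            if dmax > pop.radius / 2.0:
                raise MechanicsInstabilityError(
                    f"max displacement {dmax:.3g} µm in one mechanics sub-step"
                )
            dtheta = tq / (mech.zeta_rot * ltot**3) * self.dt_mech
            pop.x += dx
            pop.y += dy
            pop.theta += dtheta
            if self.arena.periodic:
                pop.x %= self.arena.Lx
                pop.y %= self.arena.Ly
            # translation plus endpoint swing from rotation
            self._motion += dmax + float((np.abs(dtheta) * ltot / 2.0).max(initial=0.0))

        # lysis bookkeeping and removal of disintegrated corpses
        lysing = pop.lysing
        if lysing.any():
            pop.lysis_clock[lysing] -= self.dt
            gone = lysing & (pop.lysis_clock <= 0.0)
            if gone.any():
                self.counters["removed"] += int(gone.sum())
                keep = ~gone
                pop.compress(keep)
                self._remap_pairs(keep)
                ovl = ovl[keep]

        # growth with local-pressure and carrying-capacity attenuation
        alive = pop.alive
        occupied = float(pop.area.sum()) / self.arena.area
        crowd = max(0.0, 1.0 - occupied / self.arena.carrying_capacity)
        local = np.maximum(0.0, 1.0 - ovl / self.arena.mech.pressure_star)
        rate = np.where(
            pop.G, self.table.rate_active[pop.strain], self.table.rate_inactive[pop.strain]
        )
        factor = np.expm1(rate * local * crowd * self.dt)
        inc = np.where(alive, pop.total_length * factor, 0.0)
        pop.ell += inc
        pop.added += inc
        self._motion = self._motion + float(inc.max(initial=0.0)) / 2.0

        # adder division
        dividing = np.flatnonzero(alive & (pop.added >= self.delta_L))
        if dividing.size:
            self._divide(dividing)

        self.t += self.dt

    def _log_volley(self, rep, hit, tgt, was_lysing, clone, kill) -> None:
        """Append one record per shot of the current volley to the event log."""
        pop = self.pop
        results = np.full(rep.size, "miss", dtype=object)
        target_ids = np.full(rep.size, -1, dtype=np.int64)
        target_strains = np.full(rep.size, -1, dtype=np.int64)
        if tgt is not None:
            classified = np.where(
                was_lysing, "hit_dead", np.where(clone, "hit_clonemate", "kill")
            )
            results[hit] = classified
            target_ids[hit] = pop.ids[tgt]
            target_strains[hit] = pop.strain[tgt]
        shooter_ids = pop.ids[rep]
        shooter_strains = pop.strain[rep]
        for i in range(rep.size):
            self.event_log.append(
                (
                    self.t,
                    int(shooter_ids[i]),
                    int(shooter_strains[i]),
                    results[i],
                    int(target_ids[i]),
                    int(target_strains[i]),
                )
            )

    def _divide(self, idx: np.ndarray) -> None:
        pop = self.pop
        rng = self.rng
        m = idx.size
        n_old = len(pop)
        self.counters["divisions"] += m
        ell_d = np.maximum(0.0, (pop.ell[idx] - 2.0 * pop.radius) / 2.0)
        offset = pop.total_length[idx] / 4.0
        ux = np.cos(pop.theta[idx])
        uy = np.sin(pop.theta[idx])
        n0 = pop.N[idx].copy()
        n1 = rng.binomial(n0, 0.5)
        noise = rng.normal(0.0, self.angle_noise_sd, size=(m, 2))
        theta0 = pop.theta[idx].copy()
        new_ids = np.arange(self._next_id, self._next_id + 2 * m, dtype=np.int64)
        self._next_id += 2 * m

        # first daughter overwrites the mother's slot
        pop.ids[idx] = new_ids[:m]
        pop.x[idx] -= offset * ux
        pop.y[idx] -= offset * uy
        pop.theta[idx] = theta0 + noise[:, 0]
        pop.ell[idx] = ell_d
        pop.ell_birth[idx] = ell_d
        pop.added[idx] = 0.0
        pop.N[idx] = n1

        # second daughter appended
        x2 = pop.x[idx] + 2.0 * offset * ux  # mother's center +offset*u
        y2 = pop.y[idx] + 2.0 * offset * uy
        if self.arena.periodic:
            pop.x[idx] %= self.arena.Lx
            pop.y[idx] %= self.arena.Ly
            x2 %= self.arena.Lx
            y2 %= self.arena.Ly
        pop.ids = np.concatenate([pop.ids, new_ids[m:]])
        pop.strain = np.concatenate([pop.strain, pop.strain[idx]])
        pop.x = np.concatenate([pop.x, x2])
        pop.y = np.concatenate([pop.y, y2])
        pop.theta = np.concatenate([pop.theta, theta0 + noise[:, 1]])
        pop.ell = np.concatenate([pop.ell, ell_d])
        pop.ell_birth = np.concatenate([pop.ell_birth, ell_d])
        pop.added = np.concatenate([pop.added, np.zeros(m)])
        pop.G = np.concatenate([pop.G, pop.G[idx]])
        pop.N = np.concatenate([pop.N, n0 - n1])
        pop.lysing = np.concatenate([pop.lysing, np.zeros(m, dtype=bool)])
        pop.lysis_clock = np.concatenate([pop.lysis_clock, np.zeros(m)])
        self._patch_pairs_after_division(idx, n_old)
        # the angular perturbation swings daughter endpoints slightly outside
        # the mother's extent; charge it to the motion budget
        self._motion += float(np.abs(noise).max(initial=0.0)) * float(
            ell_d.max(initial=0.0)
        ) / 2.0

    # -- summaries ----------------------------------------------------------

    def live_counts(self) -> np.ndarray:
        return np.bincount(
            self.pop.strain[self.pop.alive], minlength=len(self.table)
        )

    def lysing_counts(self) -> np.ndarray:
        return np.bincount(
            self.pop.strain[self.pop.lysing], minlength=len(self.table)
        )
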