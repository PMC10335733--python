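"""Scenario construction and in-silico competition experiments.

Provides seeding of co-incubated populations (unprimed or primed), the
confined duel, lethal-vs-target elimination, range expansion, and the
cost--lethality phase sweep, together with the outcome metrics: per-strain
counts, area occupancy inside a central measurement window, the outcome
statistic ``phi = (N_res - N_comp) / (N_res + N_comp)``, and the
dimensionless competitor lethality ``beta``.

The bundled ``simulated ES401`` and ``simulated FQ-A002`` strains carry the
parameter sets used throughout: ES401 (p0, lambda+, lambda_s, lambda_f,
tau_lys) = (10%, 0.6/h, 21/h, 6/h, 0.5 h), FQ-A002 = (5%, 0.25/h, 21/h,
6/h, 0.5 h), both with tau+ = 1 h; a vasA- mutant is its wildtype with
lambda_f = 0 (cannot fire, still pays the expression cost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from t6sim.combat import DEFAULT_K_MAX
from t6sim.kinetics import KineticParams
from t6sim.mechanics import (
    DEFAULT_BIRTH_LENGTH,
    DEFAULT_RADIUS,
    Arena,
    Cell,
    StrainSpec,
)
from t6sim.population import Population, Simulation, StrainTable

__all__ = [
    "ScenarioConfig",
    "CompetitionResult",
    "SweepPoint",
    "TargetEliminationResult",
    "RangeExpansionResult",
    "PlacementError",
    "NoLiveCellsError",
    "seed_coincubation",
    "run_competition",
    "run_replicates",
    "area_occupancy",
    "competition_outcome",
    "lethality_beta",
    "phase_sweep",
    "run_target_elimination",
    "run_range_expansion",
    "simulated_es401",
    "simulated_fqa002",
    "vasa_mutant",
    "duel_config",
    "default_n_init",
]

#: default initial occupied-area fraction at seeding.  A 5 µl inoculum of
#: an OD600 = 1.0 1:1 mixture (~1e9 CFU/ml) spread over a few-mm spot
#: deposits on the order of 0.1-0.5 cells/µm^2, i.e. an essentially
#: contiguous monolayer in which most cells touch a neighbor from the
#: start; seeding covers about a third of the surface to reflect that.
DEFAULT_INIT_AREA_FRACTION = 0.35

#: measurement window side as a fraction of the arena (200 µm of 388 µm)
WINDOW_FRACTION = 200.0 / 388.0


class PlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping cells."""


class NoLiveCellsError(RuntimeError):
    """Area occupancy is undefined: no live cell inside the window."""


def simulated_es401(vasa: bool = False) -> StrainSpec:
    """The faster-activating computational strain (ES401-like)."""
    return StrainSpec(
        name="ES401-vasA" if vasa else "ES401",
        kinetics=KineticParams(
            p0=0.10, tau_plus=1.0, lambda_plus=0.6, lambda_s=21.0,
            lambda_f=0.0 if vasa else 6.0,
        ),
    )


def simulated_fqa002(vasa: bool = False) -> StrainSpec:
    """The slower-activating computational strain (FQ-A002-like)."""
    return StrainSpec(
        name="FQ-A002-vasA" if vasa else "FQ-A002",
        kinetics=KineticParams(
            p0=0.05, tau_plus=1.0, lambda_plus=0.25, lambda_s=21.0,
            lambda_f=0.0 if vasa else 6.0,
        ),
    )


def vasa_mutant(strain: StrainSpec) -> StrainSpec:
    """Firing-deficient mutant: lambda_f = 0, growth penalty retained."""
    return replace(
        strain,
        name=strain.name + "-vasA",
        kinetics=replace(strain.kinetics, lambda_f=0.0),
    )


def default_n_init(arena: Arena, init_area_fraction: float = DEFAULT_INIT_AREA_FRACTION) -> int:
    """Initial cell number covering ``init_area_fraction`` of the arena."""
    newborn_area = 2.0 * DEFAULT_RADIUS * (DEFAULT_BIRTH_LENGTH - 2 * DEFAULT_RADIUS) + math.pi * DEFAULT_RADIUS**2
    return max(2, int(round(init_area_fraction * arena.area / newborn_area)))


def _default_window(arena: Arena) -> tuple[float, float, float, float]:
    side = min(200.0, WINDOW_FRACTION * min(arena.Lx, arena.Ly))
    cx, cy = arena.Lx / 2.0, arena.Ly / 2.0
    return (cx - side / 2.0, cy - side / 2.0, cx + side / 2.0, cy + side / 2.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one competition scenario.

    ``strains[0]`` is the resident for the purposes of ``phi``.  When
    ``n_init`` is None it is derived from ``init_area_fraction``;
    ``measure_window`` defaults to a centered square spanning the same
    fraction of the arena as 200 µm does of 388 µm.
    """

    arena: Arena
    strains: tuple[StrainSpec, ...]
    mix_ratio: tuple[float, ...] | None = None
    n_init: int | None = None
    primed: bool = False
    t_end: float = 24.0
    dt: float = 0.004
    n_replicates: int = 1
    seed: int = 0
    measure_window: tuple[float, float, float, float] | None = None
    record_every: float = 0.5
    k_max: int = DEFAULT_K_MAX
    delta_L: float = DEFAULT_BIRTH_LENGTH
    init_area_fraction: float = DEFAULT_INIT_AREA_FRACTION

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt <= 0:
            raise ValueError("t_end and dt must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "strains", tuple(self.strains))
        if self.mix_ratio is not None:
            ratio = tuple(float(r) for r in self.mix_ratio)
            if len(ratio) != len(self.strains) or any(r < 0 for r in ratio) or sum(ratio) == 0:
                raise ValueError("mix_ratio must be non-negative, one entry per strain")
            object.__setattr__(self, "mix_ratio", ratio)
        win = self.measure_window
        if win is not None:
            x0, y0, x1, y1 = win
            inside = 0 <= x0 < x1 <= self.arena.Lx and 0 <= y0 < y1 <= self.arena.Ly
            if not inside:
                raise ValueError("measure_window must lie inside the arena")

    @property
    def resolved_n_init(self) -> int:
        return self.n_init if self.n_init is not None else default_n_init(
            self.arena, self.init_area_fraction
        )

    @property
    def resolved_window(self) -> tuple[float, float, float, float]:
        return self.measure_window if self.measure_window is not None else _default_window(self.arena)

    @property
    def resolved_mix_ratio(self) -> tuple[float, ...]:
        return self.mix_ratio if self.mix_ratio is not None else (1.0,) * len(self.strains)


def duel_config(
    arena_size: float = 388.0,
    primed: bool = False,
    vasa: bool = False,
    t_end: float = 24.0,
    n_replicates: int = 100,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """The wildtype (or vasA-) ES401 vs FQ-A002 co-incubation scenario."""
    strains = (simulated_es401(vasa), simulated_fqa002(vasa))
    arena = Arena(Lx=arena_size, Ly=arena_size, boundary="periodic")
    return ScenarioConfig(
        arena=arena,
        strains=strains,
        primed=primed,
        t_end=t_end,
        n_replicates=n_replicates,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Seeding


def _segment_distances_many(cx, cy, ux, uy, h, px, py, qx, qy, arena: Arena):
    """Vectorised distance from one segment (c, u, h) to many segments p-q."""
    # shift each other segment by the minimum image of its midpoint
    mx = 0.5 * (px + qx)
    my = 0.5 * (py + qy)
    dx = mx - cx
    dy = my - cy
    if arena.periodic:
        dx -= arena.Lx * np.round(dx / arena.Lx)
        dy -= arena.Ly * np.round(dy / arena.Ly)
    sx = dx - (mx - cx)
    sy = dy - (my - cy)
    p0x, p0y = px + sx - cx, py + sy - cy  # frame of the candidate center
    q0x, q0y = qx + sx - cx, qy + sy - cy
    a1x, a1y = -h * ux, -h * uy
    d1x, d1y = 2 * h * ux, 2 * h * uy
    d2x, d2y = q0x - p0x, q0y - p0y
    rx, ry = a1x - p0x, a1y - p0y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    c = d1x * rx + d1y * ry
    b = d1x * d2x + d1y * d2y
    denom = a * e - b * b
    eps = 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0.0, 1.0), 0.0)
        if a <= eps:
            s = np.zeros_like(e)
        t = np.where(e > eps, (b * s + f) / np.where(e > eps, e, 1.0), 0.0)
        s = np.where(
            t < 0.0,
            np.clip(-c / max(a, eps), 0.0, 1.0),
            np.where(t > 1.0, np.clip((b - c) / max(a, eps), 0.0, 1.0), s),
        )
        t = np.clip(t, 0.0, 1.0)
    c1x = a1x + s * d1x
    c1y = a1y + s * d1y
    c2x = p0x + t * d2x
    c2y = p0y + t * d2y
    return np.sqrt((c1x - c2x) ** 2 + (c1y - c2y) ** 2)


def _strain_assignment(n: int, ratio: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    weights = np.asarray(ratio, dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * n).astype(int)
    remainder = weights * n - counts
    for k in np.argsort(-remainder)[: n - counts.sum()]:
        counts[k] += 1
    labels = np.repeat(np.arange(len(weights)), counts)
    return rng.permutation(labels)


def seed_coincubation(
    config: ScenarioConfig,
    rng: np.random.Generator,
    disc: tuple[float, float, float] | None = None,
) -> list[Cell]:
    """Place the initial mixed population, non-overlapping, random orientations.

    Strains are assigned by ``mix_ratio``.  If ``primed``, every cell
    starts activated; otherwise each cell is activated with its strain's
    ``p0``.  Activated cells draw their initial sheath count from the
    stationary Poisson law (mean ``lambda_s / lambda_f``; zero for
    non-firing strains), inactive cells start empty and obey the strain's
    waiting clock from t = 0.  ``disc = (cx, cy, R)`` restricts seeding to
    a circular inoculum (range expansion).
    """
    n = config.resolved_n_init
    arena = config.arena
    strains = config.strains
    assignment = _strain_assignment(n, config.resolved_mix_ratio, rng)
    ell0 = config.delta_L - 2.0 * DEFAULT_RADIUS
    half = ell0 / 2.0

    xs = np.empty(n)
    ys = np.empty(n)
    thetas = np.empty(n)
    exs = np.empty((n, 4))  # placed segment endpoints
    budget = 200 * n
    placed = 0
    while placed < n:
        if budget <= 0:
            raise PlacementError(
                f"placed only {placed}/{n} cells; lower n_init or the seeding density"
            )
        budget -= 1
        if disc is None:
            cx = rng.uniform(0.0, arena.Lx)
            cy = rng.uniform(0.0, arena.Ly)
        else:
            r = disc[2] * math.sqrt(rng.random())
            ang = rng.uniform(0.0, 2.0 * math.pi)
            cx = disc[0] + r * math.cos(ang)
            cy = disc[1] + r * math.sin(ang)
        th = rng.uniform(0.0, 2.0 * math.pi)
        ux, uy = math.cos(th), math.sin(th)
        if placed:
            d = _segment_distances_many(
                cx, cy, ux, uy, half,
                exs[:placed, 0], exs[:placed, 1], exs[:placed, 2], exs[:placed, 3],
                arena,
            )
            if d.min() < 2.0 * DEFAULT_RADIUS:
                continue
        xs[placed] = cx
        ys[placed] = cy
        thetas[placed] = th
        exs[placed] = (cx - half * ux, cy - half * uy, cx + half * ux, cy + half * uy)
        placed += 1

    cells = []
    for i in range(n):
        spec = strains[assignment[i]]
        kin = spec.kinetics
        active = config.primed or (rng.random() < kin.p0)
        if active and kin.lambda_f > 0.0:
            n_sheaths = int(rng.poisson(kin.lambda_s / kin.lambda_f))
        else:
            n_sheaths = 0
        cells.append(
            Cell(
                id=i,
                strain_id=int(assignment[i]),
                center=np.array([xs[i], ys[i]]),
                theta=float(thetas[i]),
                ell=ell0,
                ell_birth=ell0,
                added=0.0,
                G=active,
                N=n_sheaths if active else 0,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# Metrics


def competition_outcome(n_res: int, n_comp: int) -> float:
    """Outcome statistic phi = (N_res - N_comp) / (N_res + N_comp)."""
    if n_res < 0 or n_comp < 0:
        raise ValueError("counts must be >= 0")
    if n_res + n_comp == 0:
        raise ValueError("phi is undefined when both counts are zero")
    return (n_res - n_comp) / (n_res + n_comp)


def lethality_beta(lambda_s_comp: float, lambda_s_res: float) -> float:
    """Competitor lethality beta = lambda_s_comp / (lambda_s_res + lambda_s_comp)."""
    if lambda_s_comp < 0 or lambda_s_res < 0:
        raise ValueError("rates must be >= 0")
    if lambda_s_comp + lambda_s_res == 0:
        raise ValueError("beta is undefined when both rates are zero")
    return lambda_s_comp / (lambda_s_res + lambda_s_comp)


def area_occupancy(
    cells: Sequence[Cell], window: tuple[float, float, float, float]
) -> dict[int, float]:
    """Share of live projected cell area per strain inside a window.

    Counts live cells whose center lies in the axis-aligned window
    ``(x0, y0, x1, y1)``; each contributes ``2 r ell + pi r^2``.  The
    fractions sum to one.  Raises :class:`NoLiveCellsError` when no live
    cell is inside.
    """
    x0, y0, x1, y1 = window
    totals: dict[int, float] = {}
    for cell in cells:
        if cell.status != "alive":
            continue
        cx, cy = cell.center
        if x0 <= cx < x1 and y0 <= cy < y1:
            totals[cell.strain_id] = totals.get(cell.strain_id, 0.0) + cell.area
    grand = sum(totals.values())
    if grand == 0.0:
        raise NoLiveCellsError("no live cell inside the measurement window")
    return {k: v / grand for k, v in totals.items()}


# ---------------------------------------------------------------------------
# Runners


@dataclass
class CompetitionResult:
    """Time series and end point of one competition replicate.

    ``area_frac`` is each strain's share of the live cell area inside the
    measurement window (rows sum to 1, NaN when the window is empty);
    ``window_frac`` is the same area divided by the window area, the
    companion occupancy convention.
    """

    times: np.ndarray
    live: np.ndarray
    lysing: np.ndarray
    area_frac: np.ndarray
    window_frac: np.ndarray
    phi: float
    status: str
    seed: int
    strain_names: list[str]
    final_population: Population | None = None

    @property
    def final_live(self) -> np.ndarray:
        return self.live[-1]


def _window_fracs(pop: Population, window, n_strains: int):
    x0, y0, x1, y1 = window
    mask = (
        pop.alive
        & (pop.x >= x0)
        & (pop.x < x1)
        & (pop.y >= y0)
        & (pop.y < y1)
    )
    areas = np.zeros(n_strains)
    np.add.at(areas, pop.strain[mask], pop.area[mask])
    total = areas.sum()
    frac = areas / total if total > 0 else np.full(n_strains, np.nan)
    return frac, areas / ((x1 - x0) * (y1 - y0))


def run_competition(
    config: ScenarioConfig,
    replicate: int = 0,
    disc: tuple[float, float, float] | None = None,
    keep_final_population: bool = False,
) -> CompetitionResult:
    """Run one replicate of a scenario and record its time series.

    The replicate RNG stream is spawned from the scenario master seed, so
    replicates are independent and the whole run is reproducible
    bit-for-bit from ``(config, replicate)``.
    """
    child = np.random.SeedSequence(config.seed).spawn(config.n_replicates)[replicate]
    rng = np.random.Generator(np.random.PCG64(child))
    cells = seed_coincubation(config, rng, disc=disc)
    pop = Population.from_cells(cells)
    table = StrainTable(config.strains)
    sim = Simulation(
        pop,
        table,
        config.arena,
        rng,
        dt=config.dt,
        k_max=config.k_max,
        delta_L=config.delta_L,
    )
    n_steps = int(round(config.t_end / config.dt))
    every = max(1, int(round(config.record_every / config.dt)))
    window = config.resolved_window
    n_strains = len(config.strains)

    times, live, lysing, fracs, wfracs = [], [], [], [], []

    def record():
        times.append(sim.t)
        live.append(sim.live_counts())
        lysing.append(sim.lysing_counts())
        f, w = _window_fracs(sim.pop, window, n_strains)
        fracs.append(f)
        wfracs.append(w)

    record()
    status = "ok"
    margin = config.delta_L + 2.0 * DEFAULT_RADIUS
    for step in range(1, n_steps + 1):
        sim.step()
        if len(sim.pop) == 0:
            status = "extinct"
            record()
            break
        if step % every == 0 or step == n_steps:
            record()
        if not config.arena.periodic and status == "ok":
            if (
                sim.pop.x.min() < margin
                or sim.pop.y.min() < margin
                or sim.pop.x.max() > config.arena.Lx - margin
                or sim.pop.y.max() > config.arena.Ly - margin
            ):
                status = "boundary"

    final = live[-1]
    if n_strains >= 2 and (final[0] + final[1]) > 0:
        phi = competition_outcome(int(final[0]), int(final[1]))
    else:
        phi = float("nan")
    return CompetitionResult(
        times=np.array(times),
        live=np.array(live),
        lysing=np.array(lysing),
        area_frac=np.array(fracs),
        window_frac=np.array(wfracs),
        phi=phi,
        status=status,
        seed=config.seed,
        strain_names=[s.name for s in config.strains],
        final_population=sim.pop if keep_final_population else None,
    )


def run_replicates(config: ScenarioConfig) -> list[CompetitionResult]:
    """All replicates of a scenario, each on its own spawned RNG stream."""
    return [run_competition(config, r) for r in range(config.n_replicates)]


# ---------------------------------------------------------------------------
# The phase sweep


@dataclass(frozen=True)
class SweepPoint:
    """Mean outcome at one (beta, c_hat) grid point."""

    beta: float
    c_hat: float
    phi_mean: float
    phi_sd: float
    n_rep: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 0.5 or not 0.0 <= self.c_hat <= 1.0:
            raise ValueError("beta must be in [0, 0.5] and c_hat in [0, 1]")


def phase_sweep(
    base: ScenarioConfig,
    beta_grid: Sequence[float],
    c_hat_grid: Sequence[float],
    n_replicates: int | None = None,
    lambda_s_res: float = 20.0,
    lambda_f: float = 6.0,
    r0: float = 0.7,
    init_area_fraction: float = 0.04,
) -> list[SweepPoint]:
    """Sweep competitor lethality and normalised cost in primed duels.

    The resident keeps synthesis rate ``lambda_s_res``; at each grid point
    the competitor gets ``lambda_s = lambda_s_res * beta / (1 - beta)`` and
    both strains share the cost coefficient ``c = c_hat * r0 /
    lambda_s_res`` and base rate ``r0``.  Both populations start fully
    activated.  ``phi`` is averaged over the replicates.

    Unlike the dense co-incubation spots, the sweep seeds sparsely (a few
    percent coverage): the growth-versus-weaponry tradeoff only expresses
    itself when populations must first grow into the arena to establish
    contact, and heavily taxed strains may fail to do even that.
    """
    n_rep = n_replicates if n_replicates is not None else base.n_replicates
    points: list[SweepPoint] = []
    for beta in beta_grid:
        if not 0.0 <= beta <= 0.5:
            raise ValueError("beta must be in [0, 0.5]")
        lam_comp = lambda_s_res * beta / (1.0 - beta)
        for c_hat in c_hat_grid:
            cost = c_hat * r0 / lambda_s_res
            mk = lambda lam_s, nm: StrainSpec(
                name=nm,
                kinetics=KineticParams(
                    p0=1.0, tau_plus=0.0, lambda_plus=0.0,
                    lambda_s=lam_s, lambda_f=lambda_f,
                ),
                r0=r0,
                c=cost,
                tau_lys=0.5,
            )
            config = replace(
                base,
                strains=(mk(lambda_s_res, "resident"), mk(lam_comp, "competitor")),
                primed=True,
                n_replicates=n_rep,
                init_area_fraction=init_area_fraction,
                seed=base.seed + 1009 * len(points),
            )
            phis = np.array([r.phi for r in run_replicates(config)])
            points.append(
                SweepPoint(
                    beta=float(beta),
                    c_hat=float(c_hat),
                    phi_mean=float(np.nanmean(phis)),
                    phi_sd=float(np.nanstd(phis)),
                    n_rep=n_rep,
                )
            )
    return points


# ---------------------------------------------------------------------------
# Lethal vs target scenarios


@dataclass
class TargetEliminationResult:
    """Averaged target-strain trajectory in lethal vs non-firing duels."""

    times: np.ndarray
    target_mean: np.ndarray
    target_sd: np.ndarray
    target_index: int
    replicates: list[CompetitionResult]


def run_target_elimination(config: ScenarioConfig) -> TargetEliminationResult:
    """Lethal vs target co-incubation: exactly one strain may fire.

    Returns the target (non-firing) strain's live-count time series,
    averaged over the scenario's replicates.
    """
    firing = [s.kinetics.lambda_f > 0 for s in config.strains]
    if sum(firing) != 1 or len(config.strains) != 2:
        raise ValueError("need exactly one firing strain and one target strain")
    target = firing.index(False)
    results = run_replicates(config)
    length = min(r.live.shape[0] for r in results)
    series = np.stack([r.live[:length, target] for r in results])
    return TargetEliminationResult(
        times=results[0].times[:length],
        target_mean=series.mean(axis=0),
        target_sd=series.std(axis=0),
        target_index=target,
        replicates=results,
    )


@dataclass
class RangeExpansionResult:
    """Range-expansion outcome with a survivor census of the target strain."""

    competition: CompetitionResult
    target_index: int | None
    survivor_count: int
    survivor_radii: np.ndarray
    colony_radius: float


def run_range_expansion(config: ScenarioConfig, inoculum_radius: float) -> RangeExpansionResult:
    """Expand a circular inoculum in an open arena and census the survivors.

    Cells are seeded uniformly in a disc of the given radius at the arena
    center; the colony then grows freely.  Reports the live target-strain
    cells at the end, their radial positions from the inoculum center, and
    the final colony radius.  ``status='boundary'`` flags runs whose colony
    reached the arena bounds before ``t_end``.
    """
    if config.arena.periodic:
        raise ValueError("range expansion needs an open arena")
    cx, cy = config.arena.Lx / 2.0, config.arena.Ly / 2.0
    if inoculum_radius <= 0 or inoculum_radius > min(cx, cy):
        raise ValueError("inoculum must fit inside the arena")

    # window defaults don't fit the expansion use case: measure everywhere,
    # and a default cell number must refer to the inoculum, not the arena
    n_init = config.n_init
    if n_init is None:
        newborn_area = (
            2.0 * DEFAULT_RADIUS * (DEFAULT_BIRTH_LENGTH - 2 * DEFAULT_RADIUS)
            + math.pi * DEFAULT_RADIUS**2
        )
        n_init = max(
            2,
            int(
                round(
                    config.init_area_fraction
                    * math.pi
                    * inoculum_radius**2
                    / newborn_area
                )
            ),
        )
    cfg = replace(
        config,
        n_init=n_init,
        measure_window=(0.0, 0.0, config.arena.Lx, config.arena.Ly),
    )
    result = run_competition(
        cfg, disc=(cx, cy, inoculum_radius), keep_final_population=True
    )

    firing = [s.kinetics.lambda_f > 0 for s in cfg.strains]
    target = firing.index(False) if False in firing else None

    pop = result.final_population
    radii_all = np.sqrt((pop.x - cx) ** 2 + (pop.y - cy) ** 2)
    colony_radius = float(radii_all[pop.alive].max(initial=0.0))
    if target is not None:
        mask = pop.alive & (pop.strain == target)
        survivor_radii = radii_all[mask]
    else:
        survivor_radii = radii_all[pop.alive]
    return RangeExpansionResult(
        competition=result,
        target_index=target,
        survivor_count=int(survivor_radii.size),
        survivor_radii=survivor_radii,
        colony_radius=colony_radius,
    )
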