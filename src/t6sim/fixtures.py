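"""Seeded generators of synthetic inputs with the statistical structure the
analysis operations assume: activation time series with binomial
cell-counting noise, sheath-count histograms drawn by exact stochastic
simulation, and small non-overlapping toy populations for mechanics and
combat tests.  Every generator is a pure function of its arguments and the
RNG state.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from t6sim.experiments import PlacementError, _segment_distances_many
from t6sim.kinetics import (
    ActivationSeries,
    KineticParams,
    SheathHistogram,
    activation_probability,
    sample_sheath_counts,
)
from t6sim.mechanics import DEFAULT_BIRTH_LENGTH, DEFAULT_RADIUS, Arena, Cell

__all__ = [
    "make_activation_series",
    "make_sheath_histogram",
    "make_toy_population",
]


def make_activation_series(
    params: KineticParams,
    times: Sequence[float],
    n_cells: int,
    rng: np.random.Generator,
) -> ActivationSeries:
    """Activated fractions at the given times with binomial counting noise.

    Each observation is ``Binomial(n_cells, P(t)) / n_cells`` -- the noise
    model of counting activated cells in micrographs, not additive Gaussian.
    """
    times = np.asarray(times, dtype=float)
    p = activation_probability(params, times)
    draws = rng.binomial(n_cells, p)
    return ActivationSeries(
        times=times,
        fractions=draws / n_cells,
        n_observed=np.full(times.size, n_cells),
    )


def make_sheath_histogram(
    params: KineticParams,
    t: float,
    n_cells: int,
    rng: np.random.Generator,
    primed: bool = False,
) -> SheathHistogram:
    """Sheath-count histogram of ``n_cells`` reactors at time t (exact SSA)."""
    counts = sample_sheath_counts(params, t, n_cells, rng, primed=primed)
    return SheathHistogram.from_samples(counts)


def make_toy_population(
    n: int,
    arena: Arena,
    strain_ids: Sequence[int] | int,
    rng: np.random.Generator,
    ell: float = DEFAULT_BIRTH_LENGTH - 2 * DEFAULT_RADIUS,
) -> list[Cell]:
    """Non-overlapping random population for mechanics/combat unit tests."""
    if isinstance(strain_ids, int):
        strain_ids = [strain_ids] * n
    if len(strain_ids) != n:
        raise ValueError("need one strain id per cell")
    half = ell / 2.0
    xs, ys, ths = [], [], []
    exs = np.empty((n, 4))
    budget = 500 * n
    while len(xs) < n:
        if budget <= 0:
            raise PlacementError(f"placed only {len(xs)}/{n} cells")
        budget -= 1
        cx = rng.uniform(0.0, arena.Lx)
        cy = rng.uniform(0.0, arena.Ly)
        th = rng.uniform(0.0, 2.0 * np.pi)
        ux, uy = np.cos(th), np.sin(th)
        k = len(xs)
        if k:
            d = _segment_distances_many(
                cx, cy, ux, uy, half,
                exs[:k, 0], exs[:k, 1], exs[:k, 2], exs[:k, 3], arena,
            )
            if d.min() < 2.0 * DEFAULT_RADIUS:
                continue
        exs[k] = (cx - half * ux, cy - half * uy, cx + half * ux, cy + half * uy)
        xs.append(cx)
        ys.append(cy)
        ths.append(th)
    return [
        Cell(
            id=i,
            strain_id=int(strain_ids[i]),
            center=np.array([xs[i], ys[i]]),
            theta=float(ths[i]),
            ell=ell,
            ell_birth=ell,
        )
        for i in range(n)
    ]
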