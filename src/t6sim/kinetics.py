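"""Two-stage stochastic kinetics of T6SS activation and sheath dynamics.

Stage 1 (activation): a cell starts T6SS-inactive (``G-``) and, after an
initial waiting period ``tau_plus``, switches irreversibly to the active
state (``G+``) at constant rate ``lambda_plus``.  A fraction ``p0`` of the
population is already active at time zero.  The activated fraction of an
infinite, non-growing reactor population is then

    P(t) = p0                                          for t <  tau_plus
    P(t) = p0 + (1 - p0) * (1 - exp(-(t - tau_plus) * lambda_plus))
                                                       for t >= tau_plus

Stage 2 (assembly and deployment): once active, sheath structures appear at
constant synthesis rate ``lambda_s`` and each sheath fires independently at
rate ``lambda_f`` -- an immigration--death process in the sheath count N.
Its stationary law is Poisson with mean ``lambda_s / lambda_f``.

The module provides the closed forms, exact per-reactor stochastic
simulation (used as the validation oracle for the tau-leap stepping that
the agent-based model uses), master-equation integration of the joint
(G, N) process, curve fitting for activation time series, and chi-squared
statistics for sheath-count histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import expm
from scipy.optimize import minimize

__all__ = [
    "KineticParams",
    "ReactorState",
    "ActivationSeries",
    "SheathHistogram",
    "DecayFit",
    "ActivationFit",
    "TruncationError",
    "DegenerateDataError",
    "activation_probability",
    "firing_rate_for_mean",
    "steady_state_mean",
    "step_activation",
    "step_sheath_dynamics",
    "transient_pmf",
    "transient_mean_all_active",
    "fit_activation_curve",
    "poisson_gof_test",
    "two_sample_chi2",
    "fit_exponential_decay",
    "simulate_activation_ensemble",
    "sample_sheath_counts",
]

#: Largest per-reaction probability-rate x timestep product accepted by the
#: tau-leap steppers; beyond this the one-event-per-step approximation used
#: for synthesis degrades.
MAX_RATE_DT = 0.1 + 1e-12


class TruncationError(ValueError):
    """State-space truncation of the master equation is too small."""


class DegenerateDataError(ValueError):
    """Input data carry no information for the requested statistic."""


@dataclass(frozen=True)
class KineticParams:
    """Subcellular T6SS rate constants for one strain.

    Parameters
    ----------
    p0 : float
        Initially activated fraction, in [0, 1] (dimensionless).
    tau_plus : float
        Activation waiting period in hours.
    lambda_plus : float
        Activation rate in 1/h.
    lambda_s : float
        Sheath synthesis rate in 1/h.
    lambda_f : float
        Per-sheath firing rate in 1/h.
    """

    p0: float
    tau_plus: float
    lambda_plus: float
    lambda_s: float = 0.0
    lambda_f: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        for name in ("tau_plus", "lambda_plus", "lambda_s", "lambda_f"):
            value = getattr(self, name)
            if value < 0.0 or not math.isfinite(value):
                raise ValueError(f"{name} must be finite and >= 0, got {value}")


@dataclass
class ReactorState:
    """State of a single cell-like reactor: activation flag, sheath count, clock."""

    G: bool = False
    N: int = 0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError(f"sheath count must be >= 0, got {self.N}")
        if self.t < 0.0:
            raise ValueError(f"time must be >= 0, got {self.t}")


@dataclass(frozen=True)
class ActivationSeries:
    """Observed activated fractions over time (e.g. cells with >= 1 sheath)."""

    times: np.ndarray
    fractions: np.ndarray
    n_observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fractions = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fractions", fractions)
        if times.shape != fractions.shape or times.ndim != 1:
            raise ValueError("times and fractions must be 1D of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((fractions < 0) | (fractions > 1)):
            raise ValueError("fractions must be in [0, 1]")
        if self.n_observed is not None:
            n_obs = np.asarray(self.n_observed, dtype=int)
            object.__setattr__(self, "n_observed", n_obs)
            if n_obs.shape != times.shape or np.any(n_obs <= 0):
                raise ValueError("n_observed must be positive, one per time point")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_h": self.times, "fraction": self.fractions})
        if self.n_observed is not None:
            df["n_cells"] = self.n_observed
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivationSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        n = df["n_cells"].to_numpy() if "n_cells" in df.columns else None
        return cls(df["time_h"].to_numpy(), df["fraction"].to_numpy(), n)


@dataclass(frozen=True)
class SheathHistogram:
    """Occurrences of sheath counts 0..K in a population snapshot."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.size == 0 or np.any(counts < 0):
            raise ValueError("counts must be a 1D non-negative array")

    @classmethod
    def from_samples(cls, samples: Sequence[int]) -> "SheathHistogram":
        samples = np.asarray(samples, dtype=int)
        return cls(np.bincount(samples))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def mean(self) -> float:
        if self.total == 0:
            raise DegenerateDataError("empty histogram has no mean")
        return float(np.arange(self.counts.size) @ self.counts) / self.total

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"sheaths": np.arange(self.counts.size), "count": self.counts}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SheathHistogram":
        df = pd.read_csv(path).sort_values("sheaths")
        k = df["sheaths"].to_numpy(dtype=int)
        counts = np.zeros(k.max() + 1, dtype=int)
        counts[k] = df["count"].to_numpy(dtype=int)
        return cls(counts)


@dataclass(frozen=True)
class DecayFit:
    """Exponential decay fit a * exp(-b t)."""

    a: float
    b: float


@dataclass(frozen=True)
class ActivationFit:
    """Result of fitting the delayed-exponential activation curve."""

    p0: float
    tau_plus: float
    lambda_plus: float
    rss: float

    def as_params(self) -> KineticParams:
        return KineticParams(self.p0, self.tau_plus, self.lambda_plus)


# ---------------------------------------------------------------------------
# Closed forms


def activation_probability(params: KineticParams, t):
    """Activated population fraction P(t) of the delayed-exponential model.

    Accepts a scalar or array of times (hours, >= 0) and returns the matching
    shape. The result lies in [p0, 1] and is non-decreasing in t.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    dt = np.maximum(t_arr - params.tau_plus, 0.0)
    out = params.p0 + (1.0 - params.p0) * -np.expm1(-dt * params.lambda_plus)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def steady_state_mean(params: KineticParams) -> float:
    """Stationary mean sheath number lambda_s / lambda_f of an active reactor."""
    if params.lambda_f <= 0.0:
        raise ValueError("no finite steady state: lambda_f must be > 0")
    return params.lambda_s / params.lambda_f


def firing_rate_for_mean(lambda_s: float, n_inf: float) -> float:
    """Firing rate that yields stationary mean ``n_inf`` at synthesis rate ``lambda_s``."""
    if n_inf <= 0.0:
        raise ValueError("target mean must be > 0")
    return lambda_s / n_inf


def transient_mean_all_active(params: KineticParams, t) -> float:
    """Mean sheath count at time t for reactors active since t=0 with N(0)=0.

    Closed form of the immigration--death process:
    ``(lambda_s/lambda_f) * (1 - exp(-lambda_f t))``, with the
    ``lambda_s * t`` limit when ``lambda_f == 0``.
    """
    t = np.asarray(t, dtype=float)
    if params.lambda_f == 0.0:
        return params.lambda_s * t
    nbar = params.lambda_s / params.lambda_f
    return nbar * -np.expm1(-params.lambda_f * t)


# ---------------------------------------------------------------------------
# Tau-leap single-reactor stepping (the form used inside the ABM)


def step_activation(
    state: ReactorState, params: KineticParams, dt: float, rng: np.random.Generator
) -> ReactorState:
    """Advance the activation stage of one reactor by ``dt`` hours.

    An inactive reactor whose clock has passed ``tau_plus`` switches on with
    probability ``1 - exp(-lambda_plus * dt)``; active reactors stay active
    (no deactivation). The reactor clock always advances.
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    if params.lambda_plus * dt > MAX_RATE_DT:
        raise ValueError("lambda_plus * dt exceeds the tau-leap validity bound 0.1")
    g = state.G
    if not g and state.t >= params.tau_plus:
        g = bool(rng.random() < -math.expm1(-params.lambda_plus * dt))
    return ReactorState(G=g, N=state.N, t=state.t + dt)


def step_sheath_dynamics(
    state: ReactorState, params: KineticParams, dt: float, rng: np.random.Generator
) -> tuple[ReactorState, int]:
    """Advance the sheath stage of one reactor by ``dt``; return fired count.

    Only active (``G+``) reactors synthesise and fire.  Within a step the
    order is synthesis then firing: at most one sheath is added (probability
    ``1 - exp(-lambda_s dt)``), then each of the resulting sheaths fires
    independently with probability ``1 - exp(-lambda_f dt)``.  The ordering
    bias is O(dt^2) under the rate*dt <= 0.1 precondition.
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    if state.N < 0:
        raise ValueError("sheath count must be >= 0")
    if params.lambda_s * dt > MAX_RATE_DT or params.lambda_f * dt > MAX_RATE_DT:
        raise ValueError("lambda_s*dt and lambda_f*dt must not exceed 0.1")
    if not state.G:
        return ReactorState(G=state.G, N=state.N, t=state.t + dt), 0
    n = state.N
    if rng.random() < -math.expm1(-params.lambda_s * dt):
        n += 1
    fired = int(rng.binomial(n, -math.expm1(-params.lambda_f * dt))) if n else 0
    return ReactorState(G=True, N=n - fired, t=state.t + dt), fired


def simulate_activation_ensemble(
    params: KineticParams,
    n_reactors: int,
    t_end: float,
    dt: float,
    rng: np.random.Generator,
) -> float:
    """Tau-leap an ensemble of reactors and return the final activated fraction.

    Vectorised over reactors; matches :func:`activation_probability` within
    binomial sampling error (used as a consistency check of the stepping).
    """
    if params.lambda_plus * dt > MAX_RATE_DT:
        raise ValueError("lambda_plus * dt exceeds the tau-leap validity bound 0.1")
    active = rng.random(n_reactors) < params.p0
    p_switch = -math.expm1(-params.lambda_plus * dt)
    n_steps = int(round(t_end / dt))
    for k in range(n_steps):
        if k * dt >= params.tau_plus:
            inactive = ~active
            flips = rng.random(int(inactive.sum())) < p_switch
            active[np.flatnonzero(inactive)[flips]] = True
    return float(active.mean())


def sample_sheath_counts(
    params: KineticParams,
    t: float,
    n_reactors: int,
    rng: np.random.Generator,
    primed: bool = False,
) -> np.ndarray:
    """Exact stochastic simulation of ``n_reactors`` independent reactors to time t.

    Each reactor starts with N = 0.  Unless ``primed``, a reactor is active
    at t = 0 with probability ``p0``; otherwise it activates at
    ``tau_plus + Exp(lambda_plus)``.  From its activation time the
    immigration--death sheath process is simulated event by event
    (Gillespie), so the returned counts are exact draws of the two-stage
    model.  This is the validation oracle for the tau-leap stepping.
    """
    from t6sim._kernels import ssa_sheath_ensemble

    if t < 0:
        raise ValueError("t must be >= 0")
    seed = int(rng.integers(0, 2**31 - 1))
    p0 = 1.0 if primed else params.p0
    return ssa_sheath_ensemble(
        n_reactors,
        p0,
        params.tau_plus,
        params.lambda_plus,
        params.lambda_s,
        params.lambda_f,
        float(t),
        seed,
    )


# ---------------------------------------------------------------------------
# Master equation


def default_n_max(params: KineticParams, t: float | None = None) -> int:
    """Truncation level keeping the neglected tail mass far below 1e-10."""
    if params.lambda_f > 0.0:
        nbar = params.lambda_s / params.lambda_f
    else:
        nbar = params.lambda_s * (t if t is not None else 1.0)
    return int(math.ceil(nbar + 10.0 * math.sqrt(max(nbar, 1.0)) + 10.0))


def transient_pmf(
    params: KineticParams,
    t: float,
    n_max: int | None = None,
    init: str = "steady",
) -> np.ndarray:
    """Marginal sheath-count distribution at time t from the master equation.

    The joint process tracks one inactive state (N frozen at 0) and active
    states N = 0..n_max.  Initially a fraction ``p0`` is active, holding
    either Poisson(lambda_s/lambda_f) sheaths (``init='steady'``, the
    seeding rule used in the competition scenarios) or zero sheaths
    (``init='zero'``); the rest are inactive with N = 0.  Activation is off
    before ``tau_plus`` and runs at ``lambda_plus`` afterwards; newly active
    reactors enter at N = 0.  The generator is truncated reflectively at
    ``n_max`` so probability is conserved exactly; a
    :class:`TruncationError` is raised if mass accumulates in the top state.

    Returns the probability vector over N = 0..n_max (inactive reactors
    counted at N = 0), summing to 1 within 1e-8.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if init not in ("steady", "zero"):
        raise ValueError("init must be 'steady' or 'zero'")
    if n_max is None:
        n_max = default_n_max(params, t)
    if n_max < 1:
        raise TruncationError("n_max must be >= 1")

    m = n_max + 2  # state 0: inactive; states 1..n_max+1: active N=0..n_max
    p = np.zeros(m)
    p[0] = 1.0 - params.p0
    if params.p0 > 0.0:
        if init == "steady" and params.lambda_f > 0.0:
            nbar = params.lambda_s / params.lambda_f
            pois = stats.poisson.pmf(np.arange(n_max + 1), nbar)
            tail = 1.0 - pois.sum()
            if tail > 1e-10:
                raise TruncationError(
                    f"initial Poisson tail mass {tail:.2e} beyond n_max={n_max}"
                )
            pois[-1] += tail  # keep exact normalisation
            p[1:] = params.p0 * pois
        else:
            p[1] = params.p0

    def generator(lam_plus: float) -> np.ndarray:
        q = np.zeros((m, m))
        q[1, 0] += lam_plus  # activation enters the active chain at N = 0
        q[0, 0] -= lam_plus
        for n in range(n_max + 1):
            i = n + 1
            if n < n_max:  # synthesis; reflecting at the truncation boundary
                q[i + 1, i] += params.lambda_s
                q[i, i] -= params.lambda_s
            if n > 0:  # firing
                q[i - 1, i] += n * params.lambda_f
                q[i, i] -= n * params.lambda_f
        return q

    t1 = min(t, params.tau_plus)
    if t1 > 0.0:
        p = expm(generator(0.0) * t1) @ p
    if t > params.tau_plus:
        p = expm(generator(params.lambda_plus) * (t - params.tau_plus)) @ p

    out = np.maximum(p[1:], 0.0)
    out[0] += max(p[0], 0.0)
    out /= out.sum()
    if out[-1] > 1e-9:
        raise TruncationError(
            f"mass {out[-1]:.2e} in the top truncated state; increase n_max"
        )
    return out


# ---------------------------------------------------------------------------
# Fitting


def fit_activation_curve(series: ActivationSeries) -> ActivationFit:
    """Fit (p0, tau_plus, lambda_plus) of the delayed-exponential activation curve.

    ``p0`` is fixed to the mean of the two earliest observations (the
    pre-waiting-period plateau); ``tau_plus`` and ``lambda_plus`` then
    minimise the sum of squared residuals over all points, subject to both
    being non-negative.  Because the objective is non-smooth in ``tau_plus``
    (the curve has a kink there), a coarse 20x20 grid search seeds a
    bounded derivative-free local refinement.
    """
    times, fracs = series.times, series.fractions
    if times.size < 4:
        raise ValueError("need at least 4 time points")
    p0 = float(fracs[:2].mean())
    t_max = float(times[-1])
    lam_max = 5.0

    def rss(tau: float, lam: float) -> float:
        model = KineticParams(p0, tau, lam)
        r = activation_probability(model, times) - fracs
        return float(r @ r)

    taus = np.linspace(0.0, t_max, 20)
    lams = np.linspace(0.0, lam_max, 20)
    best = min(((rss(tau, lam), tau, lam) for tau in taus for lam in lams))
    res = minimize(
        lambda x: rss(x[0], x[1]),
        x0=[best[1], best[2]],
        method="Powell",
        bounds=[(0.0, t_max), (0.0, 2.0 * lam_max)],
        options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 2000},
    )
    tau, lam = (res.x if res.fun <= best[0] else (best[1], best[2]))
    return ActivationFit(p0=p0, tau_plus=float(tau), lambda_plus=float(lam), rss=float(min(res.fun, best[0])))


def fit_exponential_decay(
    times: Sequence[float], counts: Sequence[float], t_min: float = 2.0
) -> DecayFit:
    """Least-squares fit of ``a * exp(-b t)`` to counts with t >= t_min.

    The fit is linear in log-counts; early points (default: before 2 h) are
    excluded, mirroring how killing-phase decay rates are estimated from
    CFU time courses whose initial drop is unrelated to killing.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    keep = times >= t_min
    if keep.sum() < 2:
        raise ValueError(f"need >= 2 points with t >= {t_min}")
    if np.any(counts[keep] <= 0):
        raise ValueError("counts in the fit window must be positive")
    slope, intercept = np.polyfit(times[keep], np.log(counts[keep]), 1)
    return DecayFit(a=float(np.exp(intercept)), b=float(-slope))


# ---------------------------------------------------------------------------
# Histogram statistics


def _pool_expected(observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0):
    """Pool bins from the top, then the bottom, until every expected >= min_expected."""
    obs = list(observed.astype(float))
    exp = list(expected.astype(float))
    while len(exp) > 1 and exp[-1] < min_expected:
        e, o = exp.pop(), obs.pop()
        exp[-1] += e
        obs[-1] += o
    while len(exp) > 1 and exp[0] < min_expected:
        e, o = exp.pop(0), obs.pop(0)
        exp[0] += e
        obs[0] += o
    return np.array(obs), np.array(exp)


def poisson_gof_test(hist: SheathHistogram) -> tuple[float, float]:
    """Chi-squared goodness of fit of a sheath histogram to a Poisson law.

    The reference Poisson uses the histogram's own mean.  Expected counts
    below 5 are pooled (upper tail first, then the lowest bins) and the
    degrees of freedom are reduced by 2: one for the total and one for the
    estimated mean.  Returns ``(chi2, p)`` with an upper-tail p-value.
    """
    n = hist.total
    if n < 20:
        raise ValueError("need a total count of at least 20")
    mu = hist.mean
    if mu == 0.0:
        raise DegenerateDataError("all-zero histogram: Poisson fit is degenerate")
    k = hist.counts.size
    expected = n * stats.poisson.pmf(np.arange(k), mu)
    expected[-1] = n * stats.poisson.sf(k - 2, mu)  # lump the open upper tail
    obs, exp = _pool_expected(hist.counts, expected)
    df = obs.size - 2
    if df < 1:
        raise DegenerateDataError("fewer than 3 pooled bins: no degrees of freedom")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df))


def two_sample_chi2(
    hist_a: SheathHistogram, hist_b: SheathHistogram
) -> tuple[float, float]:
    """Contingency chi-squared test that two sheath histograms share one law."""
    if hist_a.total < 20 or hist_b.total < 20:
        raise ValueError("both histograms need a total count of at least 20")
    k = max(hist_a.counts.size, hist_b.counts.size)
    a = np.zeros(k)
    b = np.zeros(k)
    a[: hist_a.counts.size] = hist_a.counts
    b[: hist_b.counts.size] = hist_b.counts
    grand = a + b
    keep = grand > 0
    a, b, grand = a[keep], b[keep], grand[keep]
    # pool columns whose smaller expected count is below 5
    n_tot = a.sum() + b.sum()
    row_min = min(a.sum(), b.sum())
    expected_min = grand * row_min / n_tot
    a, _ = _pool_expected(a, expected_min)
    b, _ = _pool_expected(b, expected_min)
    if a.size < 2:
        raise DegenerateDataError("fewer than 2 pooled bins")
    if np.array_equal(a, b):
        return 0.0, 1.0
    res = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(res.statistic), float(res.pvalue)
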