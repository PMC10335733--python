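# Methods

## The subcellular weapon model

`t6sim` models the type VI secretion system (T6SS) of surface-activated
bacteria (the motivating system is *Vibrio fischeri* light-organ isolates)
as a two-stage stochastic process per cell:

**Activation.** A cell starts T6SS-inactive (G−). A fraction `p0` of a
population freshly transferred from liquid culture is already active; every
other cell waits a deterministic period `tau_plus` and then switches
irreversibly G− → G+ at constant rate `lambda_plus`. For an infinite,
non-growing reactor population the activated fraction is the delayed
exponential

    P(t) = p0,                                          t <  tau_plus
    P(t) = p0 + (1 − p0)(1 − e^{−(t − tau_plus) lambda_plus}),  t ≥ tau_plus

(`kinetics.activation_probability`). There is no deactivation in scope.

**Assembly and firing.** Once active, sheath structures appear at a
constant synthesis rate `lambda_s` (limited by a low-copy structural
protein, hence zeroth order) and each of the `N` sheaths fires
independently at rate `lambda_f` — a linear immigration–death process.
Its stationary law is Poisson with mean `N̄∞ = lambda_s / lambda_f`; the
all-active transient mean from `N(0) = 0` is
`N̄∞ (1 − e^{−lambda_f t})`. The joint (G, N) law is integrated by a dense
matrix exponential of the truncated master equation
(`kinetics.transient_pmf`); truncation is reflective (probability is
conserved exactly) at `n_max = ceil(N̄∞ + 10 √N̄∞ + 10)`, and mass reaching
the top state raises an error rather than being silently renormalised.

Two simulation routes exist deliberately. The agent-based model advances
every cell with per-step (tau-leap) updates — switch with probability
`1 − e^{−lambda_plus dt}`, at most one synthesis event per step, binomial
firing — valid under `rate × dt ≤ 0.1`, with the within-step order
activation → synthesis → firing (ordering bias O(dt²)). Independently, an
exact event-driven (Gillespie) sampler (`kinetics.sample_sheath_counts`)
provides the reference distribution; the tests require the two routes to
agree and both to match the master equation.

**Statistics.** Activation time series are fitted by fixing `p0` to the
mean of the two earliest observations and least-squares fitting
`(tau_plus, lambda_plus)` over all points (20×20 grid start, then bounded
Powell refinement; the objective is kinked in `tau_plus`, so a
derivative-free polish is used). Sheath histograms are compared with a
Poisson reference by a chi-squared test with expected counts pooled to
≥ 5 (upper tail first, then the lowest bins) and degrees of freedom
reduced by 2 (total and estimated mean); two histograms are compared by a
standard contingency chi-squared with the same pooling. Killing-phase
decay rates are fitted log-linearly on `a e^{−bt}` restricted to
`t ≥ 2 h`, mirroring how CFU time courses are analysed when the early
liquid-to-surface transient must be excluded.

## The agent-based model

Cells are spherocylinders of constant cap radius 0.5 µm in a 2D monolayer
(units: µm, hours). The defaults place a newborn at 2 µm total length.

- **Growth** is exponential elongation of the total length at the strain's
  rate, with the exact update `ΔL = L (e^{r a dt} − 1)` so closed-form
  tests hold under any sub-stepping. Only T6SS-active cells pay the
  production cost: their rate is `max(0, r0 − c·lambda_s)`; inactive cells
  grow at `r0`. Defaults `r0 = 0.7 h⁻¹` (≈1 h doubling, rich medium at
  24 °C) and `c = 0.005` (a ~15% penalty at `lambda_s = 21 h⁻¹`).
- **Attenuation**: growth is scaled by
  `max(0, 1 − overlap_sum/pressure_star) · max(0, 1 − occupied/capacity)` —
  a local contact-pressure term and a mean-field carrying-capacity term
  (default capacity: 0.9 occupied-area fraction). Pressure-limited interior
  growth makes colonies expand linearly at the rim, as real monolayers do.
- **Division** follows the adder rule: a cell divides on adding `delta_L`
  (default: one newborn length, so division ≈ doubling) since birth.
  Daughters lie end-to-end inside the mother's extent, inherit G, split the
  sheaths Binomial(N, ½), and receive independent angular noise
  (SD 0.05 rad) so colonies buckle instead of forming perfect lines.
- **Mechanics** is overdamped: Hookean repulsion `k δ` on the overlap δ of
  the cap-inflated axes, applied at the witness points (action–reaction
  exact, torques from the lever arms); translational drag `zeta·L`,
  rotational drag `zeta_rot·L³`. With `k/zeta = 20 h⁻¹` the contact
  relaxation time (~3 min) is far below the doubling time, and the
  stability bound `dt ≤ 0.1 zeta/k = 0.005 h` admits a single mechanics
  sub-step per reaction step at the default `dt = 0.004 h`. Larger
  per-step displacements than half a radius raise an error.
- **Combat**: two cells are "in contact" when their surface gap is at most
  `contact_eps = 0.5 µm` (one cap radius — the reach of a contracting
  sheath). Each fired sheath draws one of `max(k, k_max)` slots around the
  shooter (`k` = current contacts, `k_max = 6`, the coordination number of
  a rod in a dense monolayer); void slots are misses into the medium.
  Clonemates are immune; a live non-clonal target dies on a single hit and
  its corpse keeps occupying space — and absorbing shots — for its
  strain's `tau_lys` (default 0.5 h) before disappearing. A strain with
  `lambda_f = 0` (the *vasA*-disruption analogue) never fires but still
  pays the expression cost while active.

Within a step of `dt` the cycle is: pair/contact evaluation → activation →
synthesis and firing → simultaneous firing resolution → mechanics →
lysis bookkeeping → growth → division; all intra-step ordering effects are
O(dt). The engine is a struct-of-arrays population with numba kernels for
neighbor binning (minimum-image convention in periodic arenas) and pair
evaluation; a skin-buffered pair list is reused across steps, re-indexed on
corpse removal and extended conservatively on division (daughter segments
lie inside the mother's extent, so her candidate pairs form a superset).
The per-cell reference implementations in `mechanics`/`combat` define the
semantics and the engine is tested for exact parity against them. Runs are
bit-reproducible: one PCG64 stream per replicate, spawned from the master
seed.

## Scenarios and their seeding densities

The bundled computational strains carry `(p0, lambda_plus, lambda_s,
lambda_f, tau_lys)` = (10%, 0.6 h⁻¹, 21 h⁻¹, 6 h⁻¹, 0.5 h) for the faster
activator (ES401-like) and (5%, 0.25 h⁻¹, 21 h⁻¹, 6 h⁻¹, 0.5 h) for the
slower (FQ-A002-like), both with `tau_plus = 1 h`. The activation rates
are the curve-fit estimates scaled five-fold (their ratio preserved) to
match open-plate rather than sealed-dish oxygenation; `lambda_f` follows
from `lambda_s / N̄∞` with a common `N̄∞ = 3.5`.

Seeding density is scenario-specific, because the emulated experiments
differ:

- **Co-incubation duels** (confined, periodic arena; reference 388 µm with
  a central 200 µm measurement window, scaled proportionally for smaller
  arenas): a 5 µl drop of an OD600 = 1.0 1:1 mixture deposits an
  essentially contiguous monolayer, so seeding covers 35% of the surface —
  neighbors touch from the start, and the activation-speed asymmetry acts
  immediately. Unprimed runs draw each cell active with its `p0`; primed
  runs start everyone active. Activated cells at seeding carry stationary
  Poisson(`N̄∞`) arsenals (primed inocula come from hours of surface
  growth; for non-firing strains the arsenal is irrelevant and set to 0).
- **Lethal vs target** (non-firing) batteries and **range expansions**
  seed sparsely (4% coverage; expansions seed a circular inoculum and an
  open boundary), since these scenarios concern growth-then-kill dynamics:
  the target grows into free space until the activated lethal strain
  reaches it.
- The **cost–lethality sweep** (resident `lambda_s = 20 h⁻¹`, competitor
  `lambda_s` set by the lethality `beta`, shared normalised cost `c_hat`,
  both primed, 10 h) also seeds at 4%: the growth-versus-weaponry tradeoff
  only expresses itself when populations must grow to establish contact,
  and the heavily taxed corner (high `c_hat`, matched `beta`) coexists
  precisely because colonies barely reach each other.

Outcomes are reported as live-count time series, the outcome statistic
`phi = (N_res − N_comp)/(N_res + N_comp)` on live cells (corpses are
dead), and window area occupancy in two conventions: each strain's share
of the live cell area in the window (the primary metric) and the same
area divided by the window area.

## What the synthetic data do and do not capture

The fixture generators produce activation series with binomial
cell-counting noise (how micrographs are actually scored — not additive
Gaussian), sheath histograms by exact simulation, and non-overlapping toy
populations. They emulate the statistical structure of the assay outputs,
not their biology: there is no imaging noise, no mis-segmentation, no
cell-cycle coupling of sheath counts, and the in-silico strains differ
only in the parameters listed above. Passing tests therefore demonstrate
internal consistency of estimator and model, not field accuracy of any
fitted rate.

## Numerical choices and scale

Default `dt = 0.004 h` keeps every `rate × dt ≤ 0.084` (bound 0.1);
scenarios with faster rates must shrink `dt` and the constructor enforces
this. Chi-squared pooling uses the ≥ 5 expected-count rule. Coincident
contact axes are pushed apart perpendicular to the lower-id cell's axis
(deterministic tie-break). Acceptance-level runs use reduced problem
sizes chosen as the smallest at which the compared quantities are well
resolved: 150 µm duels × 10 replicates (reference: 388 µm × 100), a
100 µm arena for the mutant control, and a 3×3 sweep grid at 60 µm × 10
replicates.

## Known limitations

- The mechanical constants (stiffness, drags, pressure scale) and the
  seeding densities are this package's own calibration; published values
  for the original assays are not available at this resolution. All are
  exposed in `MechanicsParams` / `ScenarioConfig`.
- The miss model (fixed slot count `k_max`) is one concrete reading of
  "shots can miss"; `k_max` is configurable, and small `k_max` approaches
  never-miss behavior when crowded.
- One hit kills; there is no multi-hit threshold, no tit-for-tat
  retaliation, no toxin/immunity diversity, no contact-independent
  effects, no sheath degradation or deactivation, and no 3D growth.
- `lambda_s` and `lambda_f` are not separately identifiable from
  activation curves and sheath histograms; only their ratio is pinned by
  the stationary mean, and the curve fitter deliberately estimates only
  `(p0, tau_plus, lambda_plus)`.
- At the reduced arena sizes the primed-duel outcome fluctuates more than
  at full scale (domain coarsening noise grows as the arena shrinks);
  means over replicates remain centered but individual runs can deviate
  far from parity.
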