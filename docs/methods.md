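# Methods

## The model

`otogrid` simulates a rectangular array of active vestibular hair
bundles mechanically coupled by the overlying otolithic membrane, and
asks what happens when the membrane's stiffness is reduced over a local
patch (tissue damage).

Each bundle is a three-variable nonlinear oscillator in SI units:

- `X` — bundle tip position (m),
- `X_a` — position of the myosin adaptation motors (m),
- `C` — Ca²⁺ concentration at the motor binding site (M).

The equations of motion, written with all forces inside brackets so the
white-noise terms enter exactly where the integrator adds them:

    (λ  / a0) dX/dt  = −K_gs (X − X_a − D·P_o) − K_sp X + F_K + η
    (λ_a/ a0) dX_a/dt =  K_gs (X − X_a − D·P_o) − γ N_a f p(C)
                         + K_es (X_a + X_es) + η_a
    (τ  / a0) dC/dt  =  C0 − C + C_M·P_o + δc

`P_o = 1/(1 + A·exp(−(X − X_a)/δ))` is the quasi-static two-state open
probability of the mechanotransduction (MET) channels, with gating
constant `A = exp([ΔG + K_gs D²/(2N)]/k_bT)` ≈ 2.4×10⁷ and gating
length `δ = N k_b T/(K_gs D)` ≈ 4.44 nm; `D = d_gs/γ` ≈ 62.1 nm is the
gating swing referred to the bundle tip.  The myosin binding
probability is affine in calcium, `p(C) = p0 + p1 C`, clamped to
[0, 1]; the dimensionless feedback strength is `S = −C_M p1/p0`.  The
extent spring `K_es (X_a + X_es)` limits adaptation and carries the
positive sign exactly as the published model writes it.

All physical constants default to the published bullfrog-sacculus
values (`ParameterSet`); derived constants `D`, `A`, `δ` are computed
on access and can never go stale.

### Motor stall force — the one genuinely ambiguous term

The published model's expression for the single-motor force, `f = f_max/(N_a P_o)`
with stall force `γ N_a f p(C)`, admits several readings; they differ
only in a constant multiplying `f_max`, but the multiplier decides which
bundles can oscillate.  A bundle can only be spontaneously active when
its fixed point sits in the gating-compliance window (`P_o` roughly
0.15–0.85), which requires a stall force of ≈8–28 pN there.  The
package implements three modes:

- **`ensemble`** (default): `f_max` is the maximal stall force of the
  whole motor ensemble — stall = `f_max·p(C)`.  Its mid-gating
  threshold is `f_max` ≈ 89 pN, which coincides with the lower edge of
  the sampled range (87 pN); bundles across most of [87, 352] pN can
  then be poised in the active regime.
- **`p0`**: divide by the resting binding probability — stall =
  `γ f_max p(C)/p0`, net coefficient γ = 0.14.  Under this reading no
  bundle below ≈250 pN can reach mid-gating for any S, leaving most of
  the sampled population permanently quiescent; kept for sensitivity
  checks.
- **`dynamic`**: the literal state-dependent divisor `P_o`.  The stall
  force then diverges as channels close; from a closed-channel initial
  state the integration blows up immediately, so this mode is only
  usable from mid-gating states, and is likewise kept for sensitivity
  checks.

`ensemble` is the package default because it is the only constant-force
reading under which the published sampling range maps onto the active
regime.

## Heterogeneity and the (f_max, S) sampling line

Each bundle gets quenched parameters, drawn once per run from an
independently seeded stream:

- `a0 ~ Normal(1.5, 0.25)`, truncated at 0.05 — a pure time-rescaling
  factor that sets the bundle's characteristic frequency (the
  distribution reproduces the measured frequency dispersion of
  spontaneously oscillating saccular bundles);
- `f_max ~ Uniform(87, 352) pN`, drawn independently of `a0`;
- `S` linear in `f_max` between two endpoints, and `p1 = −S p0/C_M`.

The line's endpoints are not published.  They were fixed once by a
calibration scan (`otogrid calibrate-line`, plus grid sweeps during
development) to `S(87 pN) = 0.1`, `S(352 pN) = 2.0`, chosen so that the
two study conditions hold simultaneously: the healthy coupled 15×15
grid is quiescent for every bundle (amplitude death), and uncoupled
bundles regain autonomous motion.  Steeper lines (S_high ≳ 2.4) make
individual bundles stronger oscillators but break every-bundle
quiescence of the healthy grid; shallower lines kill motility.

Two properties of this model are worth stating plainly because they
bound what the simulations can show:

- Bundles with `f_max` below ≈140 pN have no deterministic limit cycle
  anywhere in S; they are excitable/bistable and move only with noise.
  "All bundles poised in the oscillatory state" is therefore realized
  as "poised in the active (oscillatory or excitable) regime".
- The limit-cycle amplitude is capped at ≈31–35 nm peak-to-peak
  (sd ≈ 12 nm) by the width of the gating-compliance window; against
  the ≈3.5 nm passive thermal baseline of an uncoupled bundle the RMS
  ratio tops out near 4.5×.  Statements requiring uncoupled bundles to
  exceed 5× their thermal baseline fail for every sampling line and
  every stall-force reading; the package reports the measured ratio
  instead of enforcing the 5× folklore.

## The membrane as a spring network

Bundles sit on a grid with spacing d = 50 µm, coupled to nearest and
next-nearest neighbours by springs of stiffness K = 1.4 mN/m (healthy)
or K_d ≤ K (edges touching the damage region).  For an edge with row
and column offsets (k, l) (first endpoint minus second) and ΔX the
difference of the endpoints' X, the axial force is

    F = K_v (1 − L0/√((ΔX + k d)² + (l d)²)) (ΔX + k d),
    L0 = √(k² + l²) d .

Bundle motion is one-dimensional along the row (k) axis — this is why
`k d` adds to ΔX while `l d` only enters the spring length.  Collinear
springs are exactly linear in ΔX; transverse ones contribute a cubic
geometric nonlinearity `≈ K ΔX³/(2d²)`.  Each edge is evaluated once
and applied with opposite signs to its endpoints, so the network force
is exactly −∇ of the total spring energy (verified to 1e−6 by finite
differences) and momentum-conserving.  Boundaries are free: edge and
corner cells simply have fewer neighbours.  A full 15×15 grid has 812
edges (420 axial + 392 diagonal).

Damage: an edge is damaged iff at least one endpoint lies in the
damage region (rectangular, default 4×4 in a grid corner), matching a
picture in which a degraded patch of membrane weakens every spring it
anchors; a "both endpoints inside" rule is available
(`damage_rule="inside"`).

## Noise

Three independent white Gaussian channels per bundle per step:

    var(η)   = 2 k_b T λ / dt          (thermal force on the bundle)
    var(η_a) = 2 k_b T_a λ_a / dt      (effective motor noise, T_a = 1.5 T)
    var(δc)  = 2 C_M² P_o(1−P_o) τ_c / (N dt)   (channel binomial noise)

The per-step variance is the delta-correlated intensity divided by dt
(a force held constant over dt accumulates the correct impulse
variance — dividing instead of multiplying by dt is the classic error
and is covered by a 10⁶-draw calibration test).  The multiplicative
δc channel is evaluated at the step's initial P_o (Itô convention); at
dt = 20 µs the difference from other conventions is far below any
statistic we report.  Heterogeneity and dynamical noise live on
separate `SeedSequence`-spawned streams, so redrawing one never
perturbs the other.

## Integration

Classical RK4 on the deterministic drift with the step's noise draws
frozen across the four stages — exact RK4 for the drift,
Euler–Maruyama-consistent for the diffusion (plain Euler–Maruyama is
available as `scheme="euler"` for cross-checks).  The coupling force is
recomputed at every RK4 stage.  Step size 20 µs; the standard protocol
is 1 s burn-in (discarded) + 10 s recorded.

Initial state: all bundles at mid-gating (X = 0, X_a = −δ ln A,
C = C_M/2), i.e. on the operating branch; the naive closed-channel
origin (`init="rest"`) is a violent startup transient that burn-in must
absorb (and is fatal in the `dynamic` motor mode).  Stationary
statistics are insensitive to this choice — that is what the burn-in is
for.

Implementation: a numba kernel advances the grid in chunks (noise is
drawn step-major so results are independent of chunk size); a pure
numpy path built directly on `model_core.drift` /
`grid_coupling.total_coupling_forces` produces bit-identical
trajectories and is the reference in tests.  Guards abort with step and
cell index if |X| > 1 µm or |C| > 10 C_M (physical trajectories stay
within tens of nm).  A 10 s, 225-bundle run takes on the order of half
a minute on one CPU.

## Readouts

- **Passive baseline**: the identical configuration with every motor
  force zeroed (`f_max = 0`); its per-bundle sd(X) is the thermal
  yardstick for both quiescence and motility.  Quiescence is compared
  per cell (corner cells are thermally hotter *and* less quenched, so a
  scalar baseline would misclassify them).
- **Spikes**: contiguous excursions of |X − median(X)| beyond 8× the
  passive baseline sd, merged when closer than 50 ms.  The 8× default
  sits at ≈3.8σ of the *healthy active* band (itself ≈2× the passive
  baseline); a threshold inside that band counts routine thermal
  crossings as spikes and obscures the damage signal.  Both knobs are
  configurable.
- **Histograms/skewness**: position histograms develop long negative
  tails under damage; skewness is the adjusted Fisher–Pearson
  estimator.  P_o histograms are binned over [0, 1]; the mode is the
  peak-bin midpoint with ties broken toward the lower bin.
- **Damage sweep**: K_d ∈ {K, K/5, K/10, K/15} with the heterogeneity
  seed shared across conditions (paired design); all damaged-region
  cells plus distance-spread healthy references are recorded, and
  monotonicity statements use medians over damaged-region cells and
  seeds (single-cell spike counts of 0–3 events per 10 s are too
  granular for stable orderings).

On the full 15×15 / 10 s protocol (3 seeds) the damaged-region medians
move monotonically with damage: |skewness| 0.12 → 0.25 → 0.47 → 0.56
(all negative — tails toward closure), P_o mode 0.935 → 0.980, sd(X)
2.3 → 6.3 nm, spike rate 0.4 → 2.7 s⁻¹, while healthy reference cells
stay within a few percent of their control variance.

## What the synthetic conditions do and do not show

The generator emulates the study conditions: published constants,
published heterogeneity distributions, a calibrated sampling line, and
seeded noise.  It does not emulate real tissue geometry (regular grid,
free boundaries, no striolar polarity reversal), viscous inter-bundle
coupling (neglected), bundle motion off the sensitive axis, or any
electrical stage downstream of P_o.  Passing tests therefore show that
*this model* produces amplitude death, damage-localized spiking, and
monotone damage signatures — not that real utricles do.

## Numerical choices

- Double precision state arithmetic throughout; traces stored in
  double (the scaled-down protocols are small).
- `P_o` computed as a numerically stable logistic — saturates smoothly
  to 0/1, never overflows.
- `p(C)` clamped to [0, 1] (probability); unclamped mode available for
  exact-equation comparisons.  No floor on C (matching the published
  equations).
- a0 truncation floor 0.05 (zero is 6σ below the mean; the floor is a
  guard, not a censoring).
- RK4 self-convergence verified at order ≥ 4; the 20 µs trajectory
  stays within 0.1 nm of a 2 µs reference over 1 s.

## Problem sizes used by the shipped protocols

The test suite and `scripts/acceptance.py` run the healthy and
uncoupled conditions at the full 15×15 / 10 s protocol (3 noise seeds)
and the four-level damage sweep at a scaled 8×8 / 2 s variant (3
seeds), which shows the same orderings as the full protocol; the full
sweep is available through `otogrid sweep` for anyone wanting the
four-panel figures at publication scale.

## Known limitations

- Spike-*rate* orderings are noisy in the scaled 2 s × 3-seed sweep
  (0–3 events per trace; for some tissue draws a marginally quenched
  healthy cell out-counts the continuously active damaged one); the
  magnitude metrics — sd, |skewness| and P_o mode — order robustly
  across tissue draws, and the full 15×15 / 10 s protocol shows the
  clean monotone spike-rate increase quoted above.
- The uncoupled motility ratio tops out near 4.5× the passive baseline
  (amplitude ceiling of the model, see above).
- Every-bundle quiescence of the healthy grid (max active/passive sd
  ratio < 3) holds for the default tissue realization and its noise
  seeds; re-drawing the quenched heterogeneity moves the worst-bundle
  ratio over a range of roughly 2.7–3.6 (the median ratio stays ≈2.4
  and the quiescent fraction ≥ 97% in every draw we measured) —
  amplitude death is a population property with order-statistic tails,
  not a per-bundle guarantee over all tissues.
- The `dynamic` motor mode is usable only from mid-gating initial
  states.
- Very small grids (≤ 2 cells per side) have no "far" reference cells;
  the sweep then records whatever healthy cells exist.
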