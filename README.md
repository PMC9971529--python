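# otogrid

Stochastic simulation of a grid of active vestibular hair bundles,
elastically coupled by the otolithic membrane, with locally weakened
coupling modeling membrane damage.

## The problem

Vestibular hair bundles of the utricle and saccule are spontaneously
motile: an energy-consuming myosin/calcium feedback loop can drive each
bundle onto a limit cycle of tens of nanometres.  In healthy tissue the
overlying otolithic membrane couples neighbouring bundles elastically;
because the bundles' characteristic frequencies are widely dispersed,
strong coupling quenches the autonomous motion (*amplitude death*) and
the organ rests quietly.  If a patch of membrane is damaged — its local
stiffness reduced — the quenching fails there, and bundles in the
damaged region produce large, abrupt position spikes.  Since bundle
deflection gates the mechanotransduction (MET) channels, such spikes
translate into channel-open-probability excursions and hence spurious
afferent signals: a candidate mechanism for vestibular drop attacks.

`otogrid` is for modellers who want to reproduce and extend this
coupled-oscillator account: it simulates the full grid, sweeps damage
levels, and quantifies the resulting spikes, histogram tails and
open-probability shifts.

## The model in brief

Per bundle (position `X`, motor position `X_a`, calcium `C`, SI units):

    (λ/a0)   dX/dt  = −K_gs(X − X_a − D·P_o) − K_sp·X + F_K + η
    (λ_a/a0) dX_a/dt =  K_gs(X − X_a − D·P_o) − γN_a·f·p(C) + K_es(X_a + X_es) + η_a
    (τ/a0)   dC/dt  =  C0 − C + C_M·P_o + δc

with two-state MET channels `P_o = [1 + A·e^{−(X−X_a)/δ}]^{−1}`,
calcium-controlled motor binding `p(C) = p0 + p1·C`, elastic coupling
`F_K` from nearest and next-nearest neighbour springs (stiffness K
healthy, K_d on damaged edges), and white Gaussian noise η, η_a, δc.
Per-bundle heterogeneity: rate factor `a0 ~ N(1.5, 0.25)`, maximal
motor force `f_max ~ U(87, 352) pN`, feedback strength `S` linear in
`f_max` (`S = −C_M·p1/p0`).  Integration is fourth-order Runge–Kutta at
20 µs with stage-frozen noise; the standard protocol is 10 s after a
1 s burn-in.  See `docs/methods.md` for the full account, including the
motor stall-force reading and the calibration of the (f_max, S)
sampling line.

## Worked example

Healthy membrane versus a strongly damaged patch (K_d = K/15) on a
scaled 8×8 grid, 2 s of simulated time, three noise seeds, identical
bundles across conditions:

```python
import otogrid as og

run = og.RunConfig(n_steps=100_000, burn_in_steps=25_000, record_stride=2, seed=0)
grid = og.GridSpec(n_rows=8, n_cols=8)
damage = og.DamageRegion(0, 2, 0, 2)        # 3x3 corner patch
het = og.HeterogeneitySpec(seed=42)

res = og.run_damage_sweep(run, grid, damage, het, factors=(1, 15), seeds=(0, 1, 2))
print(res.damaged_region_medians())
```

prints

```
           spike_rate  abs_skewness  mode_Po          sd_X
Kd_factor
1                 0.5      0.455830    0.885  2.860404e-09
15                1.0      0.631638    0.975  9.014341e-09
```

Reading the damaged-region medians: weakening the patch coupling from K
to K/15 doubles the spike rate (0.5 → 1.0 events/s beyond 8× the
1.37 nm passive thermal baseline), deepens the negative tail of the
position histogram (|skewness| 0.46 → 0.63), shifts the P_o histogram
peak right (0.885 → 0.975), and triples the position fluctuation
(sd 2.9 → 9.0 nm) — while bundles outside the patch stay at their
healthy variance.

The same study at publication scale (15×15, 10 s, K, K/5, K/10, K/15):

```
otogrid sweep --factors 1,5,10,15 --seeds 5 --out sweep.csv
```

Other CLI entry points: `otogrid simulate` (one condition → HDF5/CSV
trace), `otogrid analyze` (trace → per-cell statistics table),
`otogrid fixture` (deterministic tiny-grid tables), and
`otogrid calibrate-line` (sampling-line calibration scan).

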