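# samp

Modelling and analysis toolkit for **skin-strain-actuated microfluidic
pumps** — valveless wearable pumps that rectify cyclic skin strain into a
unidirectional liquid displacement, so that a single photograph of a
meniscus records how many times a joint has moved.

The package is for device designers and wearable-sensing researchers who
need to (i) predict pumping performance from channel geometry before
fabricating, (ii) simulate the pump's transient response to realistic
actuation protocols, and (iii) reduce benchtop and on-body measurements
(meniscus series, DIC strain fields) to the standard summary statistics.

## The model

A strain ε applied orthogonally to a rectangular microchannel (width *w*,
height *h*, aspect ratio AR = *h*/*w*) deforms it as *w*′ = *w*(1 + ε),
*h*′ = *h*(1 − νε).  With the rectangular-duct resistance
R = 12 μL / [(1 − 0.63 a/b) a³b] (a = min(w, h), b = max(w, h)), the
relative resistance change R′/R decreases monotonically with AR: under
strain a high-AR channel becomes relatively less resistive than its low-AR
partner.  Feeding a stroke volume V_total through the two channels as a
flow divider — suction through the strained resistances, discharge through
the rest ones — yields a per-cycle pumping efficiency

```
PE = R′_LAR/(R′_LAR + R′_HAR) − R_LAR/(R_LAR + R_HAR) = V_net / V_total
```

which is zero only for equal aspect ratios and always transports liquid
from the high-AR toward the low-AR branch.  A transient lumped-network
model (compliant dilating actuator chamber, strain- and meniscus-dependent
branch resistances, fixed-step RK4) covers what the quasi-static picture
cannot: stabilization time constants, back-to-back actuation losses, and
long-run linearity with and without observation channels.  See
`docs/methods.md` for the full account.

## Worked example

```python
from samp import (ChannelGeometry, PumpConfig, ActuatorModel, StrainWaveform,
                  pumping_efficiency, simulate, per_cycle_pe, pe_sweep)

har = ChannelGeometry(width=200, height=600, length=5000)   # AR = 3
lar = ChannelGeometry(width=600, height=200, length=5000)   # AR = 1/3
pump = PumpConfig(left=har, right=lar, stroke_volume=0.1)

print(f"quasi-static PE at 10% strain (exact):        {pumping_efficiency(pump, 0.10):.4f}")
print(f"quasi-static PE at 10% strain (first-order):  {pumping_efficiency(pump, 0.10, model='approximate'):.4f}")

grid = pe_sweep(strain=0.1)
print(f"heat-map max |PE| over AR in [0.1, 10]:       {grid['pe'].abs().max():.4f}")

wf = StrainWaveform(amplitude=0.05, ramp_time=0, hold_time=40,
                    release_time=0, wait_time=40, n_cycles=3)
trace = simulate(pump, ActuatorModel(), wf)
print(f"transient per-cycle PE at 5% strain:          {per_cycle_pe(trace)[0]:.4f}")
print(f"quasi-static PE at 5% strain:                 {pumping_efficiency(pump, 0.05):.4f}")
```

prints

```
quasi-static PE at 10% strain (exact):        0.0535
quasi-static PE at 10% strain (first-order):  0.0488
heat-map max |PE| over AR in [0.1, 10]:       0.0633
transient per-cycle PE at 5% strain:          0.0272
quasi-static PE at 5% strain:                 0.0272
```

Reading the numbers: the antisymmetric AR 3 / (1/3) pair moves ~5% of the
actuator stroke per cycle at 10% strain (≈0.05 under either resistance
model); the best geometry in the decade AR range reaches |PE| ≈ 0.06; and
with ideal strain steps and 40 s (20 time constants) of stabilization the
transient simulation reproduces the quasi-static divider prediction — at
5% strain, PE ≈ 0.027 per cycle, i.e. 2.7 nL of the 0.1 μL stroke.

The same pipeline is scriptable from a shell: `samp pe-sweep`,
`samp simulate`, `samp analyze-series`, `samp project-strain` and
`samp make-fixtures`, all driven by one validated YAML config
(`--config`), with `--seed`/`--out` overrides and a run manifest written
next to every artifact.

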