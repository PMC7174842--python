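# dotstripe

A reaction–diffusion simulator for **joint patterning in tetrapod
digits**: two coupled Turing subsystems — a *dot*-forming
activator–substrate pair (phalanx centres) that locally suppresses a
*stripe*-forming activator–inhibitor pair (joints) — solved on a
growing, digit-shaped domain, plus an equivalent generic Swift–Hohenberg
formulation and the pattern-analysis toolbox needed to interpret the
results.

It is written for computational and developmental biologists who want to
explore how the number, spacing and orientation of joints follow from a
dot-stripe mechanism: wild-type digits, hyperphalangy under prolonged
growth, misoriented joints when the dot spacing shrinks below the digit
width, and polygonal joint lattices on wide domains.

## The model

Inside the digit domain Ω (a growing stadium shape), with all species
diffusing:

```
dA/dt = h_A + k_A A²S − μ_A A                        # dot activator
dS/dt = h_S − k_S A²S                                # substrate
dB/dt = kb(S) B² / (I (1 + κ(A) B²)) − μ_B B         # stripe activator (joint marker)
dI/dt = k_I B² − μ_I I                               # stripe inhibitor
```

with `kb(S) = k_B (S/S*)^s_act` increasing in the substrate and
`κ(A) = κ_B (1 + s_thr A/A*)` increasing in the dot activator, so stripe
self-organization switches on only far from dots and stripes bisect the
dot chain perpendicular to its spacing. Outside Ω only `A` decays
(`k_deg`), which pins dots to the digit midline. The generic variant
replaces each subsystem by a Swift–Hohenberg equation
(`du/dt = α u − (1 + ℓ²∇²)² u + γu² − u³`, quadratic term → dots;
additive bias `h` → stripes) with `α_stripe` and `h_stripe` both
decreasing functions of the dot field.

The solver is operator splitting: backward-Euler diffusion (or the SH
biharmonic operator) computed exactly in the DCT-II basis — reflective
boundaries — followed by forward-Euler reactions, with committed-zone
freezing and tip/uniform growth events. See `docs/methods.md` for the
full account.

## Worked example

```
$ python examples/01_wildtype_digit.py
dot maxima (phalanx centres) : 4
transverse joint bands       : 5
stripe orientation           : 90.0 deg (90 = transverse)
max dot deviation from midline: 0.5 bins (digit half-width 5)
```

Four evenly spaced dot maxima sit on the digit midline (deviation half a
bin); five joint bands — one between each adjacent dot pair plus one at
each cap — run at 90° to the digit axis, i.e. transversely, exactly the
wild-type arrangement of phalanges and joints. The other examples cover
linear stability (`02`), sequential patterning on a growing digit
(`03`), wide-domain joint lattices and their Voronoi geometry (`04`),
the clamp experiments (`05`), the generic Swift–Hohenberg mechanism
(`06`) and the stripe-only / dot-hole alternative models (`07`).

## Command line

A thin CLI wraps the library for batch use:

```
dotstripe preset-list
dotstripe simulate --preset fig2B_growth --seed 1 --out run.h5
dotstripe analyze run.h5 --out metrics.json
dotstripe render run.h5 --out run.png
dotstripe dispersion --preset fig1F_wildtype
```

Trajectories are HDF5 (fields + masks + config metadata), metrics JSON
or CSV, configs YAML/JSON validated against a strict schema. The preset
catalogue (`dotstripe.presets`) pins one configuration per patterning
regime.

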