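# Methods

## The model

Joints within a digit form an iterative pattern: evenly spaced interzones
(the future joints) separating phalanges. `dotstripe` models this as two
coupled Turing subsystems on a shared 2-D domain.

**Dot subsystem (activator–substrate).** The activator `A` marks phalanx
centres and self-organizes dots; the substrate `S` forms the
complementary holes:

    ∂A/∂t = D_A ∇²A + h_A + k_A A²S − μ_A A
    ∂S/∂t = D_S ∇²S + h_S − k_S A²S

`A` autocatalyses itself at rate `k_A` while consuming `S` (which
requires `D_S ≫ D_A` for a Turing instability), is degraded at `μ_A`, and
both species have constant production (`h_A`, `h_S`). The homogeneous
steady state is closed-form: `A* = (h_A + k_A h_S / k_S) / μ_A`,
`S* = h_S / (k_S A*²)`.

**Stripe subsystem (saturating activator–inhibitor).** The interzone
marker `B` and its fast-diffusing inhibitor `I`:

    ∂B/∂t = D_B ∇²B + kb_eff(S) B² / ( I (1 + κ_eff(A) B²) ) − μ_B B
    ∂I/∂t = D_I ∇²I + k_I B² − μ_I I

Self-activation of `B` is repressed by `I` and self-limited at high `B`
(the saturation constant); saturation is what makes this circuit prefer
stripes over spots. `(B*, I*)` comes from the unique positive root of the
cubic `B (1 + κ B²) = kb μ_I / (k_I μ_B)` (Brent root-finding on a
bracketing interval).

**Coupling.** Stripes must form *between* dots and *perpendicular* to
dot spacing. The substrate activates stripe self-activation, and the dot
activator raises the stripe saturation threshold:

    kb_eff(S) = k_B (S / S*)^s_act          (increasing in S, zero at S = 0)
    κ_eff(A)  = κ_B (1 + s_thr · A / A*)    (increasing in A)

The functional forms deserve a note. With `B²/I` kinetics, *reducing*
the activation rate reduces `B*`, which reduces the effective saturation
`κ B*²` and therefore *destabilizes* the uniform state — a linear
`kb_eff ∝ S` coupling makes the stripe system self-organize preferentially
at dot centres, the opposite of the intended behaviour, for every
parameter combination we scanned with the dispersion-relation oracle. A
weak power-law sensitivity (`s_act = 0.2`) combined with a strong
threshold coupling (`s_thr = 6`) gives the intended switch: at dot-centre
conditions (A high, S low) the stripe subsystem is linearly stable
(σ_max ≈ −0.33 at the default parameters), at the homogeneous steady
state it is weakly stable (σ_max ≈ −0.10, so stripes do not pre-empt
dots), and far from dots (A low, S high) it is unstable (σ_max ≈ +0.47)
with wavelength ≈ 10 — about half the dot wavelength. The clamp
experiments (below) verify this switch behaviourally.

**Outside the digit.** The digit interior Ω produces the molecules; they
diffuse freely across the boundary, and outside Ω only `A` is degraded
(rate `k_deg`, default 0.2) — this suffices to pin dots to the digit
midline. `B` and `I` are inert outside by default
(`outside_decay_BI = False`); growth presets enable their outside decay,
which both prevents accumulation during long runs and means freshly
incorporated tip tissue enters with `B ≈ I ≈ 0`, from which the `B²/I`
autocatalysis re-ignites quickly (with residual inhibitor and collapsed
`B`, the `B = 0` state is nearly absorbing and fresh gaps can fail to
form bands).

**Digital crescent.** A strip of thickness 3 bins hugging the distal cap
boundary carries a local `A` source (`h_A_DC`) and a local `B` sink
(`−h_B_DC · B`, default rate 4 in growth presets). The sink prevents
transient stripe ignition right at the advancing tip, which would
otherwise make the joint count flicker during growth.

## Geometry and growth

The digit is a stadium: a rectangle of length `L` and width `W` with
half-ellipse caps of along-axis extent `ε` *appended* at both ends
(total extent `L + 2ε`; the growth schedule drives the rectangle length,
so the distal cap advances with it). A bin belongs to Ω iff its centre
lies inside the continuous shape. Growth modes:

- `static` — mask fixed at final size.
- `tip` — rectangle length rises linearly from `L0` to `L` between the
  settling time `T_i` and the schedule end; only the distal cap moves,
  and newly inside bins keep their prior (outside) values.
- `tip_and_stretch` — each length increment is split: a fraction
  `stretch_ratio` is realized by uniform stretching (linear resampling of
  all fields about the proximal anchor) and the rest by tip extension.

Geometry is refreshed every `growth_every` solver steps with the new
length rounded to bin resolution.

**Committed zone.** Bins further than `L_P` along the axis from the
distal-most occupied column (strict inequality) are frozen: they keep
the values they had when committed, are reset after every step, but
still diffuse into their active neighbours. Commitment activates only
after `T_i`, otherwise it would freeze initial noise. Under stretching,
the freeze store is transported by the same resampling as the fields —
committed pattern is material and moves with the tissue. `L_P` must
exceed the patterning lag behind the tip (≈ 2 pattern wavelengths at the
default growth speed); the committed presets use `L_P = 40–50` with dot
wavelength ≈ 19.5.

## Generic Swift–Hohenberg formulation

Any pattern-forming mechanism near onset reduces to the Swift–Hohenberg
normal form, so the dot-stripe logic can be stated without molecules:

    ∂u/∂t   = α_dot u − (1 + ℓ_dot² ∇²)² u + γ u² − u³
    τ ∂v/∂t = α_eff(u) v − (1 + ℓ_stripe² ∇²)² v − v³ + h_eff(u)

with `α_eff = α₀ − s_α rect(u)`, `h_eff = h₀ − s_h rect(u)`, and
`rect(u) = max(u, 0)/max|u|` (the normalization scale floored at 1e-8).
`α_dot > 0` guarantees dots; `ℓ` sets the spacing (selected wavelength
`2π ℓ`); the quadratic `γ` breaks the up/down symmetry toward dots —
dots require `α_dot` small relative to `γ` (defaults 0.2 and 1.2; by
`α ≈ 0.3–0.5` the same `γ` yields labyrinths). Outside a masked domain
the dot field decays (`k_deg_sh`) and the stripe equation keeps only its
`−v³` and operator terms, so both relax to zero there; the biharmonic
operator itself is applied globally for spectral solvability. We expose
separate `ℓ_stripe` (default 2.0 ≈ ℓ_dot/1.6); coupling through `h` alone
produces holes, through `α` alone stripes of arbitrary (usually wrong)
orientation, and both together the transverse-joint phenomenology.

## Solver

Operator splitting, first order in time, per step:

1. **Implicit linear step** in the type-II DCT basis. Bin-centred
   cosine modes satisfy reflective (zero-flux) boundaries exactly at the
   grid faces; mode `m` of `n` has discrete Laplacian eigenvalue
   `(2/h²)(1 − cos(πm/n))`. Diffusion solves
   `(1 − Δt D ∇²) u⁺ = u`, exactly for the discrete operator and
   mass-conserving to round-off; the Swift–Hohenberg step solves
   `(1 + Δt (1 + ℓ²∇²)²) u⁺ = u`.
2. **Explicit (forward-Euler) reactions** with the mask-dependent local
   rates; `Δt` is limited only by this step (default 0.05 at rate
   constants of order 1–2).
3. **Negative clipping** for the four-species model (concentrations;
   also applied after the spectral step, which preserves positivity only
   up to ~1e-16 round-off). Disabled for the sign-indefinite SH fields.
4. **Committed-bin freeze**, then the freeze store is refreshed from the
   active bins.
5. **Geometry update** every `growth_every` steps (growth events), with
   optional stretching first.

Noise enters only through the initial condition: uniform (default,
amplitude 0.02 for the four-species model, 0.05 for SH) or Gaussian,
from a seeded generator; a run is bit-reproducible from its config and
seed. An overflow guard (10⁶ × the initial scale) aborts with advice to
reduce `Δt`. Halving `Δt` on the wild-type preset changes the final
fields by ≈ 0.3% (L2), comfortably first-order-consistent.

## Default parameters

The quantitative parameter tables of the original study are not
reproduced here; defaults were fixed once by the following procedure and
are version-pinned in `presets.py`:

1. dot kinetics with a closed-form steady state and a stable well-mixed
   root (`h_A = 0.1`, `h_S = k_A = k_S = μ_A = 1` → `A* = 1.1`,
   `S* ≈ 0.826`);
2. `(D_A, D_S) = (2.5, 50)` from the dispersion scan for
   σ_max > 0 with dot wavelength ≈ 19.5 ≈ 2 × digit width;
3. stripe rates doubled (`k_B = μ_B = k_I = μ_I = 2`) so bands form on
   the timescale of tip growth; `κ_B = 0.15`, `(D_B, D_I) = (1.2, 54)`
   and the coupling strengths from the clamp-sign scan described above,
   with stripe wavelength ≈ 10 ≈ half the dot wavelength.

Everything presets vary — geometry, schedule, diffusivity *scale* at
fixed ratio, boundary rates — mirrors the parameter-variation protocol
of the study design: `fig3B_jaws` scales `(D_A, D_S)` by 0.25 (halved
dot wavelength → off-midline dot packing → misoriented joints);
`fig4_lattice` scales them by 1.5 (wider inter-dot corridors, so the
joint network closes into a lattice).

## Pattern analysis

- **Dot maxima**: 3×3 local maxima inside Ω with prominence above the
  minimum of a 3-bin disk; plateaus collapse to their centroid bin.
- **Voronoi agreement**: stripe ridges = skeletonized top-decile bins of
  the joint-marker field; score = median distance from ridge bins to the
  nearest edge of the Voronoi diagram of the dot maxima (semi-infinite
  ridges clipped far outside the domain), divided by the pattern
  wavelength. Coincident constructions score < 0.02; a half-cell-shifted
  lattice scores ≈ 0.3.
- **Wavelength**: peak of the radially averaged power spectrum of the
  mean-subtracted, Ω-windowed field; an error is raised unless the peak
  exceeds 8× the median radial power (flat-spectrum guard).
- **Orientation**: gradient structure tensor averaged over the (eroded)
  domain; ridge angle relative to the digit axis folded into [0°, 90°],
  with 90° = transverse; a coherence below 0.2 means no dominant
  orientation.
- **Joint count**: threshold at mean + 1 SD inside Ω, one-step 3×3
  binary closing (bridges single-bin pinches where a band crosses the
  dot field's saddle), then count connected components touching both
  lateral halves of the digit.
- **Joint positions** (for spacing statistics): prominence-based peaks
  of the width-averaged profile — robust to the amplitude differences
  between frozen-then-stretched proximal bands and fresh distal bands.
- **Pattern class**: decision rule on the standardized in-domain field —
  strong negative skew with ≥3 compact sub-threshold components → holes;
  a connected positive phase enclosing ≥3 cells → lattice; strong
  positive skew with ≥3 compact components → dots; elongated components →
  stripes; else none. (Holes is tested before lattice: both share the
  positive-phase topology and only the skew separates them.)
- **Ridge curvature**: mean absolute level-set curvature
  `(f_xx f_y² − 2 f_xy f_x f_y + f_yy f_x²)/|∇f|³` over the ridge
  skeleton after Gaussian smoothing (σ = 2) — separates the straight
  bands of the full model from the curved arcs of the dot-hole model.
- **Clamps**: the solver's frozen-species mechanism holds (A, S) at
  prescribed uniform values or a linear gradient while (B, I) evolve;
  the readouts are the final spatial SD of B and the dominant stripe
  orientation relative to the gradient.

Analysis constants (ridge quantile 0.90, joint threshold mean + 1 SD,
skew threshold 0.3, elongation threshold 2.5, spectrum peak ratio 8,
coherence threshold 0.2) are module constants in `analysis.py`.

## What the synthetic conditions do and do not show

All inputs are generated: homogeneous steady states plus seeded noise on
idealized stadium geometries with piecewise-linear growth. Tests passing
under these conditions show the *mechanism* is implemented correctly —
they do not show the model fits any particular limb: real digits have
curved, tapering geometries, molecular noise throughout development (not
only initially), anisotropic growth, and gene products whose kinetics
are not literally `A²S` or `B²/I`. Problem sizes were chosen at desk
scale (grids 144×48 to 200×48 for digits, 144×144 to 192×192 for wide
domains; 3 000–12 000 steps per run) — large enough for 4–7 pattern
repeats, the minimum for meaningful wavelength and topology statistics.

## Known limitations

- One straight, axis-aligned digit per run; no curved or branching rays,
  no anisotropic grids.
- The dot→stripe coupling is one-way (the study reports bidirectional
  coupling behaves qualitatively the same).
- First-order splitting; no adaptive time stepping — a too-large `Δt`
  is caught by the overflow guard, not corrected.
- The committed zone freezes values, not fluxes: a frozen bin still
  exchanges mass with active neighbours (by design — committed tissue
  keeps signalling), so total mass is not conserved at the committed
  boundary.
- `fig2C`-style commitment needs `L_P` ≳ the patterning lag; much
  smaller values freeze tissue before its bands have formed and delete
  joints relative to control.

## Symbol table

| here    | role                                      | also seen as |
|---------|-------------------------------------------|--------------|
| `mu_A`  | degradation rate of A                     | a second use of `k_A` |
| `mu_I`  | degradation rate of I                     | a second use of `k_I` |
| `mu_B`  | degradation rate of B                     | `k_B⁰`       |
| `s_act` | sensitivity of stripe activation to S     | —            |
| `s_thr` | strength of A's saturation-threshold push | —            |
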