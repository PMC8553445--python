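# Methods

## Physical model

A rectangular-ended MLC leaf in a diverging heavy-ion beam does not cast a
sharp shadow: rays grazing the leaf end traverse a finite slant chord of
material and are attenuated exponentially, N = N_B·e^(−x/λ), where λ is the
interaction mean free path of the beam nuclei in the leaf material (for
carbon ions this is governed by nuclear interactions and is commonly quoted
as the straggling range).  The radiation field edge — the on-axis point
receiving 50% of the *central-axis* (open-field) dose — is therefore the
projection of the ray whose chord equals the half-value path d₅₀ = λ·ln 2.

Geometry: the effective source is the origin of the beam axis; the isocenter
lies at the source-to-axis distance (SAD); the leaf occupies the axial slab
`[z_b − T, z_b]` with a vertical end face at lateral position
x_leaf = h·z_b/SAD (so the ray through the leaf-bottom inner corner projects
exactly to the nominal half-field h — the light-field edge X_tang).  For a
ray at angle t with θ < t < θ″ (θ, θ″ the angles to the bottom and top inner
corners), the chord through the end face is

    chord(t) = (z_b − x_leaf/tan t)/cos t,

monotone from 0 at θ to T/cos θ″ at θ″.  The p-fraction dose point is
X_p = SAD·tan(t*) with chord(t*) = d_p = −λ·ln p.  The planning offset is
(X₅₀ − X_mlc)·10 mm/cm, with X_mlc the projection of the leaf-end midpoint
(the position the planning system stores); the light-radiation agreement is
(X_tang − X₅₀)·10.  Both are negative for opening leaves: X₅₀ always falls
strictly between X_tang and X_mlc, because d₅₀ < T/2 for every shipped
material.

The chord is measured along the ray (vertical depth divided by cos t), the
physically correct length; at this beamline's angles (< 0.04 rad) the
obliquity correction is below 0.07%.

## Assumptions and what is not modelled

- Single-exponential survival with one material constant λ; no energy-loss /
  stopping-power physics, no scatter, no secondary particles, and no
  effective-source-size convolution.  Consequently `model_penumbra` (the
  20–80% width of the pure attenuation edge, ≈1.17 mm for tungsten at
  half-field 6 cm) is a *model* quantity: measured penumbras, which fold in
  the source size, are several times wider and scale with field size.
- One leaf edge in 1-D; no leaf banks, interleaf leakage or tongue-and-groove.
- The leaf end face is exactly vertical (beam-parallel) and flat.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| SAD | 263.3 | cm | machine isocenter distance |
| source_to_leaf_bottom | 196.8 | cm | 263.3 − (257.8 − 191.3): keeps the measured virtual-source-to-leaf gap while projecting from the nominal SAD plane; reproduces the reference plan positions to 4 decimals |
| max_half_field | 6 | cm | 12 cm × 12 cm maximum field; larger settings warn (hard error above 10 cm) |
| λ (tungsten) | 2.7 | cm | published attenuation length at 400 MeV/n |
| λ (others) | = straggling range | cm | no published attenuation lengths exist for the alloys; the tabulated straggling range is the closest stated constant and reproduces the reference offsets within 0.5%. Overridable per material via `lambda_cm` |

All internal lengths are cm; offsets are reported in mm.

## Numerical choices

- **Chord solve.** Fixed point z_enter ← z_b − d_p·cos(atan(x_leaf/z_enter)),
  iterated to |Δz| < 1e-12 cm (a contraction at these angles; converges in a
  few iterations).  The returned solution satisfies |chord − d_p| < 1e-8 cm,
  enforced.  Tests cross-check against an independent bracketed Brent solve
  and against ray-traced profiles.
- **Degenerate input.** half_field = 0 is the exact zero limit: every
  projection and offset is 0 (no root-finding attempted).  Leaf travel
  toward/across the axis (direction −1) is handled by mirror symmetry with
  the same X₅₀ − X_mlc sign convention.
- **Unattainable survival levels.** If d_p exceeds the maximum end-face
  chord T/cos θ″ the solver raises "insufficient leaf thickness" naming the
  material — there is no ray through the end face with that chord.
- **Angles** use exact atan/tan throughout.  The optional `--paper-rounding`
  mode quantizes only the 50%-ray angle α to 4-decimal radians before
  projecting (X₅₀ = SAD·tan(round(α, 4))), emulating a tabulated-radian
  pipeline; the quantization injects up to ~0.13 mm of jitter into offsets.
  Comparisons against 4-decimal-radian reference tables use an absolute
  ±0.04 mm envelope for dose-point columns (the observed model-to-table
  scatter is ≤0.022 mm) and print precision for pure-geometry columns.
- **Edge extraction** interpolates linearly between profile samples; with
  multiple crossings of a level the outermost is used and a warning emitted.
  The 50/20/80% levels are fractions of the central-axis (open-field) dose,
  not of a local plateau.
- **Calibration** uses a shape-preserving monotone cubic (PCHIP) through the
  (dose, net-OD) knots, exact at knots, no extrapolation.

## Synthetic profiles

`generate_fixture_profiles` ray-traces leaf-edge transmission on a 0.001 cm
grid spanning the open field through the full-shadow plateau, with optional
additive Gaussian noise on relative dose (σ configurable, seeded NumPy
generator; byte-reproducible per seed).  These fixtures emulate the *shape*
the attenuation model predicts — they deliberately omit source-size blur,
detector response, scatter and film-digitisation artefacts — so edge-recovery
tests validate the extraction numerics and the solver/oracle agreement, not
the fidelity of the model to measured film profiles.  Noiseless fixtures
recover the generator-truth X₅₀ to <1e-4 cm; at σ = 0.005 recovery is within
0.02 cm.

## Problem sizes

The betweenness sweep uses all nine materials × 60 half-fields in (0, 6];
solver-versus-trace cross-checks use 50 random (material, half-field) cases
on the 0.001 cm grid; the acceptance script re-runs 5 such cases plus both
gap signs of the virtual-source round trip before reporting.  The whole
suite runs in a few seconds on one core.

## Known limitations

- λ for non-tungsten materials is an inference (straggling range), not a
  measured attenuation length; offsets for those materials inherit that
  uncertainty.
- The model penumbra is not comparable to measured 20–80% penumbras (see
  above).
- Reference-table agreement for half-fields ≤ 1.5 cm is sign-and-trend only:
  at small fields the tables' own rounding noise exceeds the signal.
- The virtual-source estimator assumes a point source; finite source size
  biases the magnification method in ways not modelled here.
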