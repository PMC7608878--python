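# Methods

This note records the models implemented in `leafecho`, the parameters that
matter, and the design choices made where the problem was genuinely open.

## L-system trees

A grammar is the tuple (variables A, axiom ω, specials Ω = {(, ), +, [},
productions P), with parallel (simultaneous) rewriting — the standard
L-system semantics. The notation writes an end-branch variable together
with its end marker: `g)` is one token, and rewriting `g` consumes the
marker because the production's own output carries markers for each of its
end branches. This tokenisation is what makes the canonical rule
`g → d(g)[g)+g)` expand to `d(g)[g)+g)` and then to
`d(d(g)[g)+g)[d(g)[g)+g)+d(g)[g)+g)` without doubled markers.

The turtle interpretation is a flat stack machine: `d`/`g` draw one tapered
segment each (so segment count always equals the number of variable
tokens); `(`, `[` and `+` push the state and open a contracted child
branch; an end marker pops. `[` advances the attachment point up the parent
and `+` mirrors the previous branch's azimuth, both lifting the attachment
by a uniform draw from `raise_fraction_range`; when the lifted point would
pass the parent's endpoint the parent segment is extended in place (the
trunk "grows" as branches stack up), which keeps the skeleton connected.
The bracket notation is inherently ambiguous for deep expansions — a
closing marker cannot distinguish "end of this child" from "end of the
whole sub-branch" — and the flat-stack reading is one admissible
resolution. In the intended pipeline this does not matter: tree assembly
uses a **single** rewriting iteration (the "first-level branching"
structure), where the notation is unambiguous; deeper expansions are useful
for visualising the grammar itself.

Default geometry (all configurable): initial length 2 m, initial radius
0.15 m, length contraction 0.7, radius contraction 0.6, branch tilt 35°,
contraction noise sd 0.05 (redrawn to stay in (0, 1)), tilt noise sd 5°,
raise fraction U(0.2, 0.5), golden-angle azimuth sequence. These are chosen
for a natural silhouette at desk scale; nothing downstream depends on them.
With all noise off (sds 0, a degenerate raise interval, golden-angle rule)
the interpretation is seed-independent.

## Branch templates and leaf discs

Templates are the unit of foliage reuse: a mesh, a set of faces marked as
leaves, and a root point/axis. The procedural generator builds a curved
tapered tube (quadratic centreline bend), a few sub-branch tubes, and
equilateral triangular leaf facets scattered along them; any user STL can
serve instead (leaf faces designated by an index list, or by loading a
dedicated leaf mesh). STL I/O handles both dialects through `trimesh`, with
vertex welding, degenerate-face dropping, and an explicit structural check
that rejects truncated files (the underlying reader is lenient about them).

Attachment follows the count rule: with as many templates as first-level
branches the match is one-to-one with slight angular jitter; otherwise each
branch reuses a randomly selected template under a similarity transform —
rotation aligning the root axis to the branch direction, a uniform spin
about that axis, isotropic scale drawn log-uniformly from [0.8, 1.25], and
the translation that puts the template root exactly on the attachment
point.

Each leaf facet becomes a circular disc: centre at the triangle centroid,
normal equal to the face normal, radius ~ Normal(mean, sd) truncated to
(0, ∞) by redrawing (defaults 5 cm ± 1 cm). Discs are two-sided; the
incidence angle is folded to [0, π/2] via |cos|.

## Forest point process

The intensity λ(s) = Σ Cᵢ exp{−(x−cxᵢ)²/hᵢ² − (y−cyᵢ)²/lᵢ²} uses scale
denominators h², l² with **no** factor 2 — one scale length from a centre
the kernel is at e⁻¹, not e^(−1/2). The mean count ∫_D λ is evaluated with
the exact separable Gaussian × erf closed form per component (well inside
the 10⁻⁶ relative tolerance a quadrature would target). Sampling is exact
thinning with the global bound λ_max = Σ Cᵢ: always valid, mildly
conservative, and trivial to verify. A homogeneous intensity is provided as
its own class since the mixture form cannot express it.

Species merge by a simple deterministic rule: any tree of a later-listed
species closer than `min_spacing` (default 1 m) to a surviving
earlier-species tree is deleted, with deletions logged. This is one
admissible realisation of "different species are not too close"; the
threshold and resolution order are configuration, not science.

## Echo synthesis

The sonar is monostatic. The Gaussian mainlobe uses the 20·log₁₀ amplitude
convention throughout: σ = (θ/2)/√((3/10)·ln 10) for a −3 dB full width θ,
so the gain at θ/2 off boresight is 10^(−3/20) ≈ 0.708, and the −3 dB
culling contour is the ellipse az²/(2σ_az²) + el²/(2σ_el²) = (3/20)·ln 10
(boundary inclusive). Reflectors behind the sonar are always culled, no
matter the beamwidth.

Per disc and frequency, the amplitude is
A = S(az, el) · L(β, a, f) · (v/f)/(2π r²). The disc beampattern is the
fitted cosine L = P1(c)·cos(P2(c)·β), c = 2πaf/v, with
P1(c) = 0.5003c² + 0.6867 and P2(c) = 0.3999c^(−0.9065) + 0.9979 —
polynomial fits to numerically evaluated disc scattering. Beyond the first
cosine zero the fit is an extrapolation and goes negative; it is clamped at
0 by default (switchable), since a negative gain would flip arrival signs
unphysically. The c → 0 limit is excluded (P2 diverges); the large-c regime
(leaf ≫ wavelength) is likewise extrapolation.

The phase is the round-trip propagation phase φ = 2πf·2r/v. Under the
e^(+j2πft) inverse-transform convention of numpy (and MATLAB), a positive
delay corresponds to a **negative** phase ramp, so the spectrum carries
A·e^(−jφ); each arrival then lands at sample fs·2r/v of the impulse
response. The emission weighting is flat over 60–80 kHz (an optional
raised-cosine edge taper suppresses ringing; default off). The one-sided
spectrum is mirrored with exact conjugate symmetry before the inverse FFT;
the imaginary residue is verified below 10⁻¹⁰ of the peak.

Grid defaults: fs = 400 kHz, n_fft = 4096, v = 343 m/s. Note the record is
n_fft/fs = 10.24 ms, i.e. ≈ 1.76 m of unambiguous one-way range; arrivals
beyond it wrap (circular convolution). For scenes deeper than ~1.7 m raise
`n_fft` (a power of two) — the README example uses 16384 for a 6 m
standoff.

Not modelled, by design: leaf shading/occlusion (superposition is therefore
exactly linear), Doppler shifts, multiple scattering, atmospheric
absorption, and non-leaf reflectors (trunks, branches, ground).

## Scenarios

The static scenario fixes the pose and sweeps the beamwidth; the in-lobe
count m is non-decreasing in beamwidth by construction (the culling ellipse
grows monotonically). The dynamic scenario flies a closed-form Gerono
lemniscate (x = ℓ·sin t, y = ℓ·sin t·cos t) at fixed height — a pose
schedule, not a dynamical model, since only the sampled poses matter for
echo generation — aiming each pose at the nearest canopy centroid, with the
beamwidth drawn per pose from U[30°, 65°]. Per-pose randomness comes from a
`SeedSequence` keyed by (master seed, pose index), so outputs are
reproducible pose-by-pose and independent of evaluation order.

## What the synthetic data does and does not show

The procedural templates stand in for species-specific CAD assets: they
reproduce the *statistical* features that drive foliage echoes (leaf count,
size distribution, spatial clustering along branches, orientation spread)
but not the morphology of any real species. Passing tests therefore
demonstrate the correctness of the geometry, point-process and acoustics
machinery — delays, 1/r² scaling, beampattern culling, superposition — not
that simulated echoes match recordings of a particular maple. Validation
against measured echoes requires real sensor data and is out of scope here.

## Problem sizes

The test suite and the acceptance script run at desk scale: trees of
~100–200 leaf discs, forests of ~10–20 trees on a 20 m × 20 m field,
2000-replicate count statistics, ≥ 2000 pooled points for the
distributional test, and 12-pose fly-throughs at n_fft = 4096. These sizes
give stable statistics (3-standard-error bands; KS at α = 0.01) while the
whole suite completes in seconds.
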