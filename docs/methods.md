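# Methods

`sharpmax` chooses how strongly to sharpen (or blur) a cryo-EM density map
by maximizing the *adjusted surface area* of a fixed-volume iso-contour:
a measure of map detail penalized for fragmentation.  This note records the
model, the numerical choices, what the synthetic fixtures do and do not
emulate, and the known limitations.

## The sharpening model

A map is represented as a Fourier series.  Sharpening multiplies each
amplitude by the four-parameter scale

    A(d) = w_s(d) * A_sharpen(d) + w_b(d) * A_blur(d)

    A_sharpen(d) = exp(+B_sharpen / (4 d^2))
    A_blur(d)    = exp(-B_blur   / (4 d^2))
    w_s(d)       = 1 / (1 + exp(-k (d - d_cut))),   w_b = 1 - w_s

with `d` the resolution of a term in Å.  `B_sharpen` (Å²) is the only
parameter normally optimized; positive values sharpen, negative blur, and
when the map is blurred overall no additional high-resolution blur is
applied (`A = A_sharpen` everywhere).  Defaults:

| parameter | default | meaning |
|---|---|---|
| `B_blur` | 200 Å² | soft high-resolution limit; attenuates a 3 Å term ~259-fold |
| `d_cut` | nominal map resolution | sharpen-to-blur crossover |
| `k` | 10 Å⁻¹ | crossover steepness; the weight transition reaches ~88 % completion at `d_cut` ± 0.2 Å and crosses 90 % at ln 9 / k = 0.22 Å |

The overall sharpness of a map is summarized by the Wilson-style isotropic
B of its amplitude falloff, `F(d) ∝ exp(-B_iso/(4 d²))`, obtained from an
amplitude-weighted least-squares fit of `ln F` against `1/(4 d²)` over the
retained Fourier terms.  Terms in the lowest-resolution shell are excluded
when at least three shells exist: the strongest low-order terms reflect the
molecular envelope, not the Wilson-like falloff, and would otherwise bias
the slope.  Anisotropy is removed first by fitting a symmetric 3×3 B tensor
to the log amplitudes (linear least squares in the six tensor entries plus
a scale) and rescaling so the residual falloff is isotropic with
`B_iso = trace/3`.

## The objective

For each candidate overall B (default scan −100 … +300 Å² in 20 Å² steps)
the map is rescaled so its fitted overall B equals the candidate, then
contoured at the threshold that encloses 20 % of the molecular volume.  The
score is

    SA_adjusted = SA - C_scale * N_regions

where `SA` counts grid points just outside the contour that are
face-adjacent to an inside point, and `N_regions` counts contiguous
above-threshold regions under 6-connectivity (both conventions are isolated
in one function and can be switched to 26-connectivity).  Points exactly at
the threshold are inside; beyond-edge points are below threshold.
`C_scale` is calibrated per map so the most- and least-sharpened candidates
score equally; the optimum is the interior maximum, ties broken toward
higher B (less sharpening).

The procedure declines a map (returns it unchanged) when the score at the
scan point nearest B = 50 Å² falls below the common end-point value, or
when the signal (peak minus end point) is less than three times the noise
(r.m.s. deviation of interior points from the linear interpolation of their
neighbours).

## Molecular volume estimation

The contour threshold needs the volume occupied by the molecule.  The local
r.m.s. density is computed as the square root of a Gaussian-smoothed squared
deviation from the map mean (kernel radius 1.5× the resolution by default;
sigma = radius/√3 so the kernel's radius of gyration matches the nominal
radius, truncated at 3 sigma).  Whether the field carries molecular contrast
at all is decided by a null-calibrated detector: a quantile split of *any*
field produces a between-class mean gap by selection alone, and for a
featureless Gaussian field that gap is analytically
`phi(z_f)(1/f + 1/(1-f))` standard deviations; the observed gap must exceed
1.3× that value at some probe fraction.  Featureless maps therefore keep the
caller's initial volume-fraction guess — the documented fixed point.  With
contrast present, each initial guess is refined by isodata iteration
(threshold at the midpoint of the two class means, fraction = volume above
it, iterated to a fixed point); the square-root transform matters here
because the squared field is strongly right-skewed and would bias the
midpoint upward.  The median over the starting guesses is used, with a
warning when the guesses disagree by more than 0.1.

## Alternative targets

* **Kurtosis** — the same scan, maximizing the fourth standardized moment
  `m4/m2²` of map values (raw convention, Gaussian = 3; only the argmax
  matters, so the convention is immaterial).
* **Half-map** — per resolution shell, the half-map FSC is converted to an
  estimate of the full-map/true-map correlation, CC\* = sqrt(2 CC/(1+CC)),
  and amplitudes are scaled by `R·CC*` where `R` is the ratio of the mean
  zero-B model-map amplitude to the mean map amplitude in the shell.
  Negative FSC is clipped to zero (no usable signal).  A model is required
  for the `R` normalization; half-map sharpening without any model is not
  supported in this version.
* **Model-based** — as above with CC the map-model FSC, corrected for
  assumed coordinate error by `CC* = CC·exp(+B_eff/(4 d²))` (clipped to
  [0, 1]) with `B_eff = 8π² rmse²/3`, the standard equivalence between an
  isotropic B and a total positional r.m.s. displacement; `rmse` defaults
  to a quarter of the map resolution.

Map quality is measured throughout as the real-space Pearson correlation,
within 3 Å of any model atom, between the map and a model map computed with
all atomic B values set to zero and truncated at the same resolution
(the zero-B convention avoids any dependence on refined B values).  The
3 Å metric radius is deliberately distinct from the 5 Å radius used to box
a deposited map around its model.

## Local sharpening

The masked region is tiled with overlapping cubic boxes (default edge 40
grid units, 50 % overlap; an edge box is clipped, but never below half the
nominal edge — a sliver box has too little density to sharpen, so its
origin shifts inward instead).  Each box is analyzed together with a margin
of surrounding context (a quarter of the box edge, clipped at the map
boundary) so that the cut through density does not distort its spectrum;
only the central nominal region enters the blend.  Each box is sharpened
independently with the chosen global method at the global resolution
cutoff; boxes the applicability test declines fall back to their
unsharpened contents with a warning.  Output points covered by no box
(solvent corners) pass through the input map unchanged.  Boxes are blended with weights `w = exp(-d/d_o)`, `d` the
distance to the box center in Å and `d_o` the mean nearest-neighbour
distance between box centers, making the combination exact for constant
fields and free of seams.

## Synthetic fixtures

The generator builds pseudo-molecules of single-Gaussian atoms (electron
count weights), renders them through analytic structure factors truncated
at `d_min`, and derives every test input from them: an overall-B blur
applied in reciprocal space, white real-space noise, half-map pairs with
independent noise, resolution-dependent phase randomization (amplitudes
exactly preserved, Hermitian symmetry maintained), and coordinate-jittered
models.  All generators are bit-reproducible from a seed.

Layouts: a bonded chain (1.5 Å steps with direction persistence, ~3.8 Å
between second neighbours, ≥1 Å non-bonded clearance), a uniform globule
packed at protein interior density (~0.06 atoms/Å³), and a two-domain
variant with separate per-domain B values.  Packing density matters: a
sparse chain fragments into per-atom islands at the 20 %-volume contour and
produces region counts the method never sees on real maps, so fixtures that
exercise the contour objective use protein-like packing.  The default
noise (sigma 0.008 map units against a zero-B map standard deviation of
~0.15) emulates a mid-quality reconstruction with a zero-B map-model
correlation around 0.8, mid-range for deposited maps.  Test pipelines box
each map to within 5 Å of its model first, as is done for deposited
map-model pairs.

What the fixtures do **not** emulate: multi-Gaussian electron scattering
factors, CTF effects, non-uniform local resolution, masking artifacts from
reconstruction software, or solvent density.  Passing tests demonstrate the
optimization machinery, not microscope realism.

## Numerical choices

* Fourier terms live on the full FFT grid with the cell attached;
  resolution is `1/|s|`, `s = (h/a, k/b, l/c)` (orthogonal cells, P1).
  Truncation zeroes terms below `d_min` and is idempotent.
* Resolution shells are equal-count in terms (approximately equal volume in
  1/d³), boundary ties going to the lower-resolution shell; shell midpoints
  are `1/sqrt(<1/d²>)`, consistent with the Wilson fit.  Default 20 shells.
* Thresholds for a target volume pick the smallest map value whose
  above-count does not exceed the target (ties resolved downward, so the
  achieved volume can fall below target by the tie multiplicity).
* Optima over candidate B are scan argmaxima (ties toward higher B).  Where
  a test needs sub-step precision the continuum optimum is estimated from
  the parabola through the three points around the discrete maximum.
* Exponentials are clipped at |exponent| = 60 to stay finite.

## Known limitations

* At desk-scale problem sizes the smoothing halo around a small molecule is
  a significant fraction of the molecular volume itself, which inflates the
  estimated volume and can bias the chosen B by tens of Å²; the effect
  shrinks as the molecule grows and is negligible at real map sizes.
* Under direct iid Gaussian coordinate jitter of half the map resolution,
  the zero-B map-model CC optimum moves by roughly
  `B_eff = 8π² rmse²/3 ≈ 60 Å²` or slightly more (~65–70 Å² measured).
  Errors in actually refined models are correlated with the density and are
  less damaging at the same nominal r.m.s.d., so this is a conservative
  bound on the metric's tolerance to model error.
* Non-orthogonal cells, symmetry other than P1, per-box local resolution
  estimation, and optimization of `d_cut`/`k` are out of scope.
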