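# Methods

## Model and procedure

### Gradient interval histogram (GIH)

The GIH of an image with `L` gray levels is a length-`L` count vector.
For every pixel, the minimum and maximum gray value `k_min ≤ k_max` over
its 3×3 window are found and every bin in `[k_min, k_max]` is
incremented. Two conventions are deliberate and configurable:

* **Center pixel included** (default). The window is the full 3×3 block,
  so `k_min ≤ v ≤ k_max` always holds, every pixel contributes at least
  its own level, and the GIH is a pointwise superset of the ordinary
  histogram (for a constant image the two coincide and GIHE degenerates
  to plain HE). `include_center=False` gives the strict 8-neighborhood
  for comparison.
* **Borders clipped.** Corner pixels use a 2×2 window, edge pixels a
  2×3/3×2 window. No padding values are fabricated. (The vectorized
  implementation uses replicate-padding min/max filters, which is
  exactly equivalent to clipping for extrema.)

Total mass is `Σ_pixels (k_max − k_min + 1) ≥ H·W`; exact agreement with
a brute-force per-pixel oracle is asserted in the tests.

### GIHE

`p(k) = gih(k)/Σ gih`, `c(k) = Σ_{i≤k} p(i)`, lookup table
`F(k) = round(255·c(k))`. The derivative of the map is `255·p(k)`, so
levels with `p(k) > 1/255` are stretched. Because spot *edges* dominate
the GIH, the stretch lands on spot boundaries — especially the faint
boundaries of weak spots — while the background's enormous pixel count
no longer buys it enhancement gain.

**Rounding.** The source formulation leaves the integer rounding of
`255·c(k)` open; we round half up (`floor(x+0.5)`) and clamp, which is
deterministic, symmetric and matches common HE implementations. Gray
values produced by other implementations may differ by ±1 level.

### GIHM

Brightness matching of a test gel `T` onto a reference `R`:
`I = GIHE(R)`, `J = GIHE(T)`, then each gray level `w` of `J` is mapped
to the level `v` of `I` minimizing `|C_I(v) − C_J(w)|`, where `C_I, C_J`
are the ordinary pixel-count CDFs of the equalized images. Ties —
including runs of zero-mass levels sharing a CDF value — resolve to the
smallest level, which makes the map deterministic and monotone
(property-tested, and verified against an exhaustive argmin oracle).
Monotonicity guarantees the relative ordering of pixel gray values is
unchanged; matching a gel against itself reproduces the equalized
reference exactly. After matching, the sup-distance between the two
CDFs is bounded by the largest single-level masses of the two
distributions (the discreteness floor); `apply_gihe=False` gives plain
histogram matching for ablation.

The implementation uses a vectorized binary search with
first-occurrence canonicalization rather than a linear two-pointer
sweep; the two are equivalent under the stated tie rule.

### Quantification

* Gray-value difference: mean over the spot-center pixels minus mean
  over a local-background ring (negative for dark spots).
* Spot volume: `Σ intensities = area × mean_intensity` over the
  segmented region (exact identity, enforced on the record type).
* Normalization: `G' = 127 + (G − M)·sqrt(127/V)` with *population*
  mean `M` and variance `V` over all `H·W` pixels (matching the printed
  definition; sample variance would differ in the last digits).
  Output stays real-valued — spot quantities are compared on the
  continuous scale; re-quantizing first would add avoidable noise.
  Constant images have no defined normalization and raise.
* CPS error: `D_k = (Q_A − Q_B)/((Q_A+Q_B)/2)·100 %`, bounded by
  ±200 % by construction, antisymmetric under swapping the images.
  Averages use `|D_k|` (signed values are kept per pair); this is the
  only convention consistent with reported positive averages alongside
  signed per-spot profiles.
* Enhancement heat map: per-pixel density `p(img(x,y))`. Since the
  equalization slope is `255·p(k)`, the map shows where the correction
  stretches contrast (spot edges under the GIH; background under a
  plain histogram).

## Spot detection (supporting machinery)

Detection is evaluation plumbing, not the contribution; defaults are
chosen so the synthetic fixtures are recovered perfectly.

* **Centers.** The image is smoothed (Gaussian, σ=1 px) and subtracted
  from a background estimate — a grayscale closing (max-then-min filter,
  41 px window, larger than any spot) — to give a drift-free *depth*
  map. Peaks of morphological prominence ≥ h (default h=10 gray levels,
  via h-maxima/grayscale reconstruction) become centers; each is
  expanded to the connected cap of its h-dome above h/2. Flattening
  first matters: on a drifting background the raw inverted image has
  broad drift basins whose prominence exceeds h, which would produce
  spurious "spots". A flat image, or a spot shallower than h, yields no
  centers.
* **Contours.** A marker-controlled watershed floods the lightly
  smoothed image (σ=0.7 px; spots are catchment basins) from the center
  markers plus one background marker (pixels within 0.5 gray level of
  the background estimate). Each basin is then trimmed to the connected
  component, around its deepest pixel, of pixels deeper than
  `exp(−2) ≈ 13.5 %` of the peak depth below the local background (the
  median of a ring around the first-pass region — the closing estimate
  alone is biased a little high on noisy backgrounds, which would
  inflate weak-spot regions). For an ideal Gaussian spot this contour
  is exactly the 2σ ellipse. A gradient-magnitude watershed was
  considered and rejected: the gradient of a Gaussian spot crests at
  r = σ, so watershed lines on the gradient surface systematically halve
  the spot radius relative to the 2σ extent used for ground truth.
* **Weak flag.** A spot is weak when its mean gray value exceeds 90 —
  low-abundance spots sit close to the bright background.
* **Pairing.** CPS pairs are formed by greedy mutual-nearest-centroid
  matching within 5 px (synthetic pairs share spot geometry exactly, so
  pairing is trivial there; real gels would need spatial registration,
  which is out of scope).

## Synthetic gels

The generator emulates the structure the method assumes: a bright
background (base 200) with a low-order polynomial drift (±15), dark
Gaussian spots, additive Gaussian noise (σ=2), and — between the two
images of a pair — a global monotone brightness shift (default
gamma 0.8 composed with offset −20, plus fresh σ=2 noise on the shifted
copy). Everything is rendered in real arithmetic, clamped to [0, 255]
and quantized once (round half up).

Defaults (one 512×512 gel): 40 spots with ≥45 px center separation;
30 strong spots (amplitude 460–560, σ 3–6 px — deep, saturated cores,
mean gray over the support ≈ 60–85) and 10 weak spots (amplitude 18–35,
σ 2.5–4 px, mean gray ≈ 170–200). The two classes sit far on either
side of the weak-spot threshold of 90, so flagging is unambiguous.
Ground truth per spot: the support (pixels whose noiseless depth exceeds
`exp(−2)` of the peak depth — the 2σ ellipse for unsaturated spots,
consistently wider where the core clips at 0), the true mean intensity
and volume over that support, and the weak label.

What the generator does **not** emulate: streaks, cracks, saturation
artifacts beyond simple clipping, spatially varying (non-global) shifts,
and gel-to-gel geometric distortion. Passing tests therefore demonstrate
correctness of the algorithms under the stated image model, not
performance on real scanned gels, whose spot counts and error tables
depend on hand-confirmed spot pairs and are not reproducible from
synthetic data.

## Numerical choices and degenerate inputs

* Rounding is half-up everywhere (`floor(x+0.5)`), never banker's.
* PDFs must sum to 1 within 1e−9; CDFs are non-decreasing with final
  value 1 within 1e−9; mapping tables are validated monotone at
  construction.
* 1×1 and single-row images are legal; windows clip (an exclusive
  8-neighborhood with no neighbors falls back to the pixel's own level).
* Empty images, all-zero histograms, constant images under
  normalization, level-count mismatches, non-monotone shift parameters
  and out-of-range slope queries raise `ValueError` with a message.
* Seeds: every stochastic component (gel layout, drift, noise, shift
  noise) is driven by `numpy.random.default_rng` with explicit seeds;
  fixed seeds reproduce images bit for bit.

## Evaluation protocol and problem sizes

The end-to-end experiment mirrors the quantification protocol: correct
a pair (or leave it uncorrected for the baseline), normalize both images
to mean 127/variance 127, measure each spot's mean intensity over the
same pixel sets in both images, and average |D_k|. The test suite and
the acceptance script use 20 seeded default-fixture pairs (512×512,
40 spots ⇒ 800 CPS pairs), which keeps the full run under a minute on
one CPU while averaging enough spots for a stable mean.

## Known limitations

* The discrete nearest-CDF match cannot do better than the largest
  single-level probability masses of the two images; GIHE coarsens this
  floor by design (it collapses weakly-populated background levels into
  single output levels). On pairs whose shift is nearly affine — which
  the mean/variance normalization removes anyway — the uncorrected
  error can be so small (≲0.7 %) that full GIHM, while comfortably
  below 3 %, does not beat the uncorrected baseline on every seed;
  plain histogram matching has a lower floor in this regime. The
  method's advantage is specific to shifts with substantial
  nonlinearity.
* When the shifted copy of a pair carries its own fresh noise on top of
  the rendered reference's noise, the test image is noisier than the
  reference; quantile matching then pulls weak-spot means slightly
  toward the background in the noisier image — a small systematic bias
  visible in the per-spot error sign.
* Detection assumes isolated, roughly Gaussian spots; heavily
  overlapping spots are separated only as well as the watershed allows,
  and no gel-to-gel warping is performed.
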