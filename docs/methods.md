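# Methods

## Scope and data model

`spinequant` analyses 2-D single- or dual-channel photon-count images of
dendritic spines acquired at a known pixel size (20 nm by default). All
positions are physical (nanometres) under a pixel-centre convention: pixel
(row *i*, col *j*) has its centre at ((j+0.5)p, (i+0.5)p). Images travel as
`Image2D` (non-negative finite counts + pixel size); 16-bit grayscale TIFF
I/O records the pixel size in resolution tags and a JSON sidecar.

## PSF model and deconvolution

The STED effective spot is a 2-D radial Lorentzian h(r) = γ²/(r²+γ²),
γ = FWHM/2, with FWHM 40 nm by default; the tail shape beyond the stated
FWHM is a declared convention (it is the simplest radial profile with that
half width). A Gaussian option (exp(−4 ln2 r²/FWHM²)) covers confocal data.
Kernels are rendered at pixel centres on an odd support (default 11 px =
±100 nm at 20 nm pixels, over five half-widths of the core), truncated and
renormalised to unit sum. Note the 2-D Lorentzian integral grows
logarithmically with radius, so an appreciable fraction of its flux lies in
tails outside any finite kernel; this matters for interpreting brightness,
not for restoration quality at these supports (support 11 vs 41 changes
measured sizes by < 2 nm).

Richardson–Lucy deconvolution uses the standard multiplicative update with
the mirrored-kernel correlation step, initialised from a flat image at the
input mean (flux-matched), with reflective boundary handling and a 1e-12
division guard. 20 iterations is the default. Non-negativity is enforced
each iteration; total flux is conserved to well under 0.1 %. An all-zero
image is returned unchanged with a warning.

## Detection and sizing

Candidate centres are local maxima of the deconvolved image above
median + k·(1.4826·MAD) (default k = 5), with a Euclidean exclusion radius
(default 60 nm ≈ one cluster-sized profile, so sub-structure within one
profile stays one detection; spacing analyses near the resolution limit use
40 nm, the resolution floor, to avoid truncating the distance
distribution). Because Richardson–Lucy redistributes Poisson noise
nonlinearly, a maximum in the deconvolved image only counts if the *raw*
counts at its position exceed background + max(k·noise, 16): 16 counts is
half the 32-count single-antibody calibration peak, below which a maximum
cannot correspond to even one labelled complex. Accepted maxima are refined
by an intensity-weighted centroid in a 5×5 window.

Cluster size is the arithmetic mean FWHM of line profiles through the
centre at 20 angles evenly spaced over [0, π) (each profile covers both
directions, so a half turn suffices). Profiles are sampled every
pixel_size/4 out to ±200 nm by cubic-spline interpolation — bilinear
sampling at 20 nm pixels systematically narrows a 40 nm Lorentzian peak by
~3 nm, cubic is accurate to ~0.4 nm. The half level is
background + (peak − background)/2 with the peak read from the same
interpolant at the centre; crossings are located by walking outward from
the peak and interpolating linearly between samples. Angles with no
crossing yield NaN and flag the cluster. Peak intensities for
stoichiometry are read from the raw (non-deconvolved) image by bilinear
interpolation, where counts keep their detector calibration.

## Nearest-neighbor statistics

Within-channel: each detected centre's Euclidean distance to its closest
other centre (ties broken toward the lowest index). Cross-channel: each
channel-A centre's distance to the closest channel-B centre (A→B,
asymmetric; B→A is available by swapping arguments). Distances are
computed per spine image and pooled across spines, never across fields.
Summaries report mean, sample SD (n−1) and SEM — published "±" values are
ambiguous between the two, so both are printed — and fixed-origin
histograms (default 20 nm bins).

## Stoichiometry

Labelled complexes per cluster = cluster peak / mean single-antibody peak,
rounded, clamped at 1; peak ratio (not integrated intensity) is the
default because the calibration is quoted as peak counts — it
underestimates for extended clusters, and integrated intensity is left as
an option. The labelling efficiency is unknown, so totals carry an
`unlabeled_fraction_unknown` flag. The independent geometric estimate is
V = (π/6)D³ + π(w/2)²L (sphere head + cylinder neck; 300/300/100 nm
defaults give 1.65 × 10⁻¹⁷ L), times concentration (default 50 µM) times
Avogadro's number, rounded to the nearest integer. The rounded published
volume 2 × 10⁻¹⁷ L gives 602 ≈ 600 copies; the exact geometry gives 497 —
both are reported and labelled.

## Synthetic data

The simulator is the package's ground truth. It emulates: a mushroom spine
projected to 2-D (head disc ∪ neck rectangle, areas exactly
π(D/2)² + L·w); 2–6 clusters per spine of 2–6 immunocomplexes each
(configurable conventions — the source imagery constrains these only to "a
couple" and "a handful"); cluster extent defined as the FWHM of the
emitter-density profile, i.e. the diameter of the uniform disc emitters
are drawn from; an isotropic antibody-linkage displacement of 15–20 nm per
complex; per-complex lognormal brightness calibrated to mean 32 / SD 12
peak counts; image formation as the sum of per-emitter PSF profiles (peak
scaled to the drawn brightness) plus flat background (default 2
counts/pixel) and per-pixel Poisson noise; 64×64 fields of 20 nm pixels.
Placement options cover uniform positions with a minimum pairwise
separation, exact-separation pairs (for spacing-recovery experiments,
where the pair realises the drawn nearest-neighbor distance exactly), and
dual-colour layouts in which channel-B aggregates are placed head-biased
(probability 0.8) and each channel-A cluster is placed so its
nearest-B distance equals a draw from a target distribution. Rejection
sampling is capped at 1000 retries; exceeding the cap raises an error
rather than silently relaxing a constraint. Fixed seeds give bit-identical
images and truth tables; per-spine streams are derived as
`default_rng([seed, spine_index])`.

What the simulator does *not* emulate: axial (3-D) structure, detector
afterpulsing or drift, photobleaching/blinking, structured cellular
background, or chromatic misregistration (channel registration is assumed
perfect, with an optional constant offset correction). Passing recovery
tests therefore demonstrates correctness of the measurement chain under
the stated forward model, not robustness to every property of real
specimens.

## Reproduction experiments and problem sizes

Each preset simulates 200 spines (a size chosen to put the standard error
of pooled means near 2 nm) and runs the full pipeline:

- **cluster_size** — 2–4 clusters/spine, ground-truth emitter-density FWHM
  52 nm (linkage folded into the disc for this preset, so the labelled
  density is exactly the stated width), clusters ≥150 nm apart so each
  profile is attributable; pooled mean measured FWHM vs 52 ± 6 nm.
- **within_nn** — cluster pairs at separations drawn from Normal(110, 40)
  truncated at 0; pooled NN mean vs 110 nm within 3 SEM; detection uses
  the 40 nm exclusion radius (see above).
- **cross_nn** — one head-biased channel-B aggregate, two channel-A
  clusters at nearest-B distances from Normal(70, 40) truncated at 0;
  pooled A→B mean vs the realised truth mean (3 SEM) and vs 70 ± 15 nm.
- **resolution_floor** — one noiseless point source, sized without
  deconvolution; 40 ± 2 nm.
- **stoichiometry**, **copies** — the printed-calibration arithmetic above.

## Known limitations

**Sizes near the resolution floor are compressed after 20 RL iterations.**
With a 40 nm Lorentzian PSF the optical transfer function decays
exponentially, so restoring objects only ~2.6 pixels across is severely
ill-posed. On a noiseless 52 nm disc the measured width passes through the
true value at roughly 7 iterations and keeps contracting (66 nm raw → 58
at 5 → 47 at 10 → 40 at 20 → 36 at 50); `skimage.restoration`'s
independent implementation reproduces the same numbers, and a perfectly
restored 52 nm disc raster measures 50.8 nm, so neither the implementation
nor the 20-angle estimator is at fault — the fixed 20-iteration schedule
is. Consequently the cluster_size preset reports ~41 nm for 52 nm truth:
the pipeline's measured size for near-resolution objects is a resolution-
floor-limited lower bound, not an unbiased estimate, and measured means
near 40–45 nm should be read as "at or near the floor". Spacing and
stoichiometry results are unaffected.

Other limitations: peak-ratio complex counting underestimates for extended
clusters; the A→B cross analysis is asymmetric by construction; the
geometric copy-number route inherits the crudeness of the sphere+cylinder
model and the assumed bulk concentration.
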