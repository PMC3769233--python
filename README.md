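# spinequant

Quantitative analysis of STED super-resolution images of dendritic spines:
where do protein nanoclusters sit, how big are they, how far apart are they,
and how many protein copies do they hold?

STED microscopy resolves the interior of a dendritic spine (a ~600 nm
mushroom-shaped protrusion: ~300 nm head, ~300 × 100 nm neck) into discrete
nanoclusters of immunolabelled protein — for example the signalling hub
DARPP-32 and the dopamine D1 receptor in striatal neurons. `spinequant`
implements the full measurement chain for such images and, because no real
dataset ships with it, a forward simulator that generates ground-truth spine
images against which every stage is validated.

## The measurement chain

1. **Deconvolution.** The effective STED focal spot is modelled as a 2-D
   radial Lorentzian `h(r) = γ²/(r² + γ²)` with `γ = FWHM/2` (FWHM 40 nm;
   a Gaussian model covers confocal data). Images are restored with 20
   iterations of the Richardson–Lucy scheme
   `f⁽ᵏ⁺¹⁾ = f⁽ᵏ⁾ · [ (g / (f⁽ᵏ⁾ ⊗ h)) ⊗ ȟ ]`,
   flat-initialised and flux-conserving with reflective boundaries.
2. **Detection.** Cluster centres are local maxima above a robust
   (median + k·MAD) threshold, validated against the raw counts, refined to
   sub-pixel precision by intensity-weighted centroids.
3. **Sizing.** Each cluster's size is the mean full width at half maximum of
   line profiles through its centre at 20 angles spanning a half turn.
4. **Spatial statistics.** Nearest-neighbor distances within one channel and
   from channel A to channel B (e.g. DARPP-32 → D1R), pooled across spines.
5. **Stoichiometry.** Labelled complexes per cluster from the ratio of
   cluster peak intensity to the single-antibody calibration (~32 counts),
   and an independent copy-number estimate
   `N = V·c·N_A` with `V = (π/6)D³ + π(w/2)²L`.

The simulator renders each immunocomplex as a PSF profile scaled to a
lognormal brightness (mean 32, SD 12 counts), draws cluster positions over
the head∪neck mask, applies a 15–20 nm antibody linkage displacement, adds
background and per-pixel Poisson noise, and is bit-reproducible under a
fixed seed.

## Worked example

`python examples/deconvolve_and_size.py` simulates a two-cluster spine and
runs the full chain:

```
ground truth (x, y, complexes):
  ( 512.8,  499.8) nm  6 complexes
  ( 384.8,  662.7) nm  3 complexes
detected clusters (x, y, FWHM, raw peak):
  ( 509.4,  503.7) nm   39.4 nm   105.9 counts
  ( 378.4,  654.1) nm   44.7 nm    64.5 counts
```

Both clusters are found and localised to within about one 20 nm pixel; the
measured sizes sit near the instrument's 40 nm resolution floor (see
`docs/methods.md` on why post-deconvolution sizes of near-resolution objects
are compressed toward that floor). `python examples/copy_number.py` prints
the stoichiometry arithmetic: a 3.78× (~4×) cluster-to-single-antibody
brightness ratio, a 1.65 × 10⁻¹⁷ L spine volume, and ~600 copies at 50 µM
for the rounded 2 × 10⁻¹⁷ L volume. The other examples cover nearest-neighbor
analysis, the resolution floor, and writing a simulated TIFF dataset.

A thin CLI wraps the same library:
`spinequant simulate|analyze|reproduce --help`.

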