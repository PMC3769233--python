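"""Simulate one dendritic spine, deconvolve it, and size its nanoclusters.

Builds a two-cluster spine image (52 nm ground-truth cluster extent, 40 nm
Lorentzian STED PSF, 20 nm pixels, Poisson noise), runs 20 Richardson-Lucy
iterations, detects the emission profiles and measures each cluster's mean
FWHM over 20 angles.
"""

import numpy as np

from spinequant import AnalysisConfig, SimulationConfig, SpineGeometry
from spinequant.pipeline import analyze_image
from spinequant.simulate import place_clusters, render_image

rng = np.random.default_rng(7)
sim = SimulationConfig(seed=7)
truth = place_clusters(SpineGeometry(), 2, 52.0,
                       lambda r: int(r.integers(2, 7)), rng,
                       min_separation_nm=150.0, linkage_offset_nm=(0.0, 0.0),
                       channel="DARPP-32")
image = render_image(truth, sim, "DARPP-32", rng=rng)

clusters, _ = analyze_image(image, AnalysisConfig())

print("ground truth (x, y, complexes):")
for c in truth.clusters:
    print(f"  ({c.x_nm:6.1f}, {c.y_nm:6.1f}) nm  {c.n_complexes} complexes")
print("detected clusters (x, y, FWHM, raw peak):")
for c in clusters:
    print(f"  ({c.x_nm:6.1f}, {c.y_nm:6.1f}) nm  {c.fwhm_nm:5.1f} nm  "
          f"{c.peak_counts:6.1f} counts")
print("\nCentres localise to within about one 20 nm pixel of the truth; the")
print("measured FWHM sits near the 40 nm resolution floor because 20 RL")
print("iterations compress near-resolution objects (see docs/methods.md).")
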