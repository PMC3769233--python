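"""Within- and cross-channel nearest-neighbor analysis on a dual-color spine.

Places one D1R aggregate in the spine head and two DARPP-32 clusters at
controlled distances from it, renders both STED channels, analyses each,
and prints the within-channel and DARPP-32 -> D1R nearest-neighbor
distances.
"""

import numpy as np

from spinequant import AnalysisConfig, SimulationConfig, SpineGeometry
from spinequant.pipeline import run_analysis
from spinequant.simulate import simulate_dual_color, truncated_normal

rng = np.random.default_rng(11)
sim = SimulationConfig(seed=11)
img_a, img_b, truth = simulate_dual_color(
    SpineGeometry(), n_a=2, n_b=1,
    cross_nn_dist=truncated_normal(70.0, 40.0),
    extent_dist=52.0, complexes_dist=lambda r: int(r.integers(2, 7)),
    config=sim, rng=rng, min_separation_a_nm=0.0,
    channel_a="DARPP-32", channel_b="D1R")

report = run_analysis(AnalysisConfig(), [img_a], [img_b],
                      channel_a="DARPP-32", channel_b="D1R")

true_d = [c.realized_cross_nn_nm for c in truth.clusters
          if c.channel == "DARPP-32"]
print("true DARPP-32 -> D1R distances:", np.round(true_d, 1), "nm")
print("measured distances:")
print(report.distances[["analysis", "channel", "distance_nm"]]
      .to_string(index=False))
print("\nCross-channel rows recover the simulated spacings to within the")
print("roughly one-pixel localisation error of the detected centres; the")
print("pooled mean over many spines centres on the true distribution.")
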