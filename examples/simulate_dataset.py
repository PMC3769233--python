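"""Write a small simulated dataset to disk: TIFF images + ground-truth CSV.

Produces five single-channel spine images (16-bit grayscale TIFF with the
pixel size in the resolution tags and a JSON sidecar) and the ground-truth
cluster table the analysis never sees.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spinequant import SimulationConfig, SpineGeometry, write_tiff
from spinequant.simulate import place_clusters, render_image

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)
sim = SimulationConfig(seed=5)
tables = []
for i in range(5):
    rng = np.random.default_rng([5, i])
    truth = place_clusters(SpineGeometry(), int(rng.integers(2, 5)), 52.0,
                           lambda r: int(r.integers(2, 7)), rng,
                           min_separation_nm=60.0, channel="DARPP-32")
    write_tiff(render_image(truth, sim, "DARPP-32", rng=rng),
               out / f"spine_{i:02d}.tif")
    tables.append(truth.truth_table(spine_id=i))
pd.concat(tables, ignore_index=True).to_csv(out / "ground_truth.csv",
                                            index=False)
print(f"wrote 5 TIFFs + ground_truth.csv to {out}/")
print("analyse them with:  spinequant analyze", out / "spine_*.tif",
      "--out", out / "run")
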