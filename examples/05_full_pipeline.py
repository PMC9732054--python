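"""The whole two-date analysis in one call.

Runs synthesis → radiometry → surface products → classification →
accuracy → areas → change → LST–NDVI regression for two dates and prints
the resulting change table.  All outputs (rasters, CSV tables, manifest)
land in ./scratch/example_run.
"""

import pandas as pd

import lulcst as L

cfg = L.RunConfig(shape=(150, 150), seed=42, out_dir="scratch/example_run")
manifest = L.run_pipeline(cfg)

print("manifest:", manifest["manifest_path"])
chg = pd.read_csv("scratch/example_run/change.csv")
print(chg[["class", "change_ha", "pct_change", "annual_rate_pct"]]
      .round(2).to_string(index=False))
print("\nThe two dates were synthesized with different class area "
      "fractions (urban growth scenario); the change table recovers those "
      "constructed shifts from the classified maps. Re-running with the "
      "same seed reproduces every file bit-for-bit.")
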