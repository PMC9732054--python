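"""Per-class LST/NDVI means and the LST-on-NDVI regression.

Builds a synthetic scene, retrieves LST and NDVI, then summarises each
land-cover class (zonal means) and fits LST = slope·NDVI + intercept at 20
random pixels per class.
"""

import lulcst as L

specs = L.default_class_specs()
truth = L.generate_truth_map((150, 150), specs, seed=8)
scene = L.generate_scene(truth, specs, seed=9)

ndvi = L.ndvi(scene.red, scene.nir)
radiance = L.toa_radiance(scene.thermal_band, scene.meta)
bt = L.brightness_temperature(radiance, scene.meta)
lst = L.land_surface_temperature(
    bt, L.emissivity(L.proportion_vegetation(ndvi)), scene.meta)

print("zonal means per class:")
print(L.class_means(lst, ndvi, truth).round(3).to_string(index=False))
print("\nper-class OLS of LST on NDVI (20 points each):")
print(L.fit_per_class(lst, ndvi, truth, n_per_class=20, seed=10)
      .round(3).to_string(index=False))
print("\nCool, green classes (forests, agricultural) sit at high NDVI and "
      "low LST; hot, sparse classes (urbanized, bare) at the opposite "
      "corner. Within a class, R-squared says how much of the LST spread "
      "the 20 sampled NDVI values explain.")
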