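"""Thermal chain on a tiny grid: DN → radiance → BT → NDVI → PV → E → LST.

Builds a 3×3 thermal-band grid of digital numbers with Landsat-5 TM
calibration constants (K1 = 607.76, K2 = 1260.56, λ = 11.5 µm) and walks
it through the full single-channel LST retrieval.
"""

import numpy as np

import lulcst as L

meta = L.landsat5_tm_meta()
dn = L.BandGrid(values=np.array([[60.0, 120.0, 180.0],
                                 [80.0, 140.0, 200.0],
                                 [100.0, 160.0, 220.0]]), band_id="B6")
red = L.BandGrid(values=np.array([[90.0, 60.0, 95.0]] * 3))
nir = L.BandGrid(values=np.array([[100.0, 140.0, 100.0]] * 3))

radiance = L.toa_radiance_tm(dn, meta)
bt = L.brightness_temperature(radiance, meta)
ndvi = L.ndvi(red, nir)
pv = L.proportion_vegetation(ndvi)
emis = L.emissivity(pv)
lst = L.land_surface_temperature(bt, emis, meta)

print("radiance (W m-2 sr-1 um-1):\n", radiance.values.round(3))
print("brightness temperature (C):\n", bt.values.round(2))
print("NDVI:\n", ndvi.values.round(3))
print("emissivity:\n", emis.values.round(4))
print("LST (C):\n", lst.values.round(2))
print("\nEach DN maps linearly to radiance between LMin and LMax; BT "
      "inverts the Planck relation; LST then corrects BT upward for the "
      "surface's sub-blackbody emissivity — the drier, lower-NDVI pixels "
      "(E closer to 0.986) get the larger correction. Hotter DNs give "
      "hotter LST throughout.")
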