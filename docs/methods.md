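# Methods

## Scope and model

`lulcst` implements a post-classification change analysis for two
co-registered multispectral scenes with one thermal band, plus the
single-channel LST retrieval that accompanies it.  Every stage operates on
plain 2-D grids (`BandGrid`) with an explicit nodata mask and a square
pixel size in metres; there is no coordinate-reference-system handling,
reprojection or resampling — scenes are assumed already gridded to a
common raster.  Any operation applied to a nodata cell yields nodata.

### Radiometric chain

Thermal DNs are rescaled linearly to TOA spectral radiance.  For
TM-style metadata the two-point endpoint form is used,

    Lλ = (LMaxλ − LMinλ)/(QcalMax − QcalMin) · (Qcal − QcalMin) + LMinλ,

which satisfies the identities Qcal = QcalMin → LMinλ and
Qcal = QcalMax → LMaxλ.  An alternative parenthesization that multiplies
`(Qcal − QcalMin) + LMinλ` by the gain circulates in print; it breaks both
identities, so it is available only behind `literal_eq2=True` for
comparison.  DNs outside `[QcalMin, QcalMax]` are clamped with a logged
count rather than dropped, preserving grid completeness.

Brightness temperature inverts the Planck relation,
`BT = K2 / ln(K1/Lλ + 1) − 273.15` (°C).  Pixels with a nonpositive
logarithm argument become nodata with a logged count.  BT is strictly
increasing in radiance, which the suite verifies on a radiance ramp.

### Surface products

NDVI is computed directly on DN values by default (a reflectance grid can
be passed identically — the ratio is scale-free per band pair but not
across calibrations; the choice is the caller's).  `NDVImin`/`NDVImax`
for the PV scaling default to the observed scene extremes over non-nodata
pixels and can be overridden, since fixed literature thresholds
(e.g. 0.2/0.5) are a different convention.  PV clips the scaled ratio to
[0, 1] *before* squaring, so PV itself is always in [0, 1] and emissivity
E = 0.004·PV + 0.986 is always in [0.986, 0.990].

The LST correction `LST = BT / (1 + (λ·BT/c2)·ln E)` mixes units unless
BT is in kelvin (c2 = 14388 µm·K).  The default mode
(`celsius_literal`) evaluates the formula with BT in °C — the convention
under which the downstream per-class contrasts are usually reported — and
a `kelvin_physical` mode evaluates it in kelvin and converts back.  The
mode is recorded in the output band id.  In the literal mode, for
BT > 0 °C and E < 1, LST > BT and LST decreases with E; both are property
tests.

### Classification

Supervised Gaussian maximum-likelihood on the 3-band composite: per-class
sample mean and covariance (denominator n−1) at the training pixels, then
per-pixel argmax of `ln pᵢ − ½ln|Σᵢ| − ½(x−μᵢ)ᵀΣᵢ⁻¹(x−μᵢ)`.  Priors are
equal by default (per-class priors are accepted); ties break to the lowest
class index; training points on nodata pixels are skipped with a logged
count.  Covariances are regularized by adding ε to the diagonal when the
smallest eigenvalue is below ε, with ε = 1e-6 × the mean diagonal entry —
small enough to leave well-conditioned signatures untouched — floored at
1e-6 so that fully degenerate samples (identical training pixels) still
produce a usable ε·I covariance.  The applied ε is stored on the
signature.  No post-classification smoothing is applied.

### Accuracy, change, regression

The error matrix is oriented rows = predicted, columns = reference, stated
in every output since the literature uses both conventions.  Producer's
accuracy is the column-normalized diagonal (100% − omission error),
user's the row-normalized diagonal (100% − commission error), overall
accuracy trace/total, and kappa the Cohen form
(pₒ − pₑ)/(1 − pₑ).  Zero marginals yield missing values, not errors.

Areas are pixel counts × pixel_size²/10⁴ ha, percentages relative to the
non-nodata total.  Change per class is `Ca = A₂ − A₁`, `Ce = Ca/A₁`,
percent = 100·Ce, and the **simple** annual rate percent/Δt — the form
that reproduces published two-date tabulations of this kind; a compound
rate `((A₂/A₁)^(1/Δt) − 1)·100` is available via `compound=True`.  A class
with A₁ = 0 reports Ca only.  Computation is full precision; rounding to
two decimals happens at presentation.

The LST–NDVI relationship is OLS with LST as the response (the direction
the fitted equations are conventionally printed in), at 20 random pixels
per class by default, seeded and without replacement.  R² is the squared
Pearson correlation and is reported unsigned; the slope carries the sign.

## Synthetic scenes

The generator emulates a six-class tropical coastal mosaic.  Truth maps
are built by painting seeded random rectangles (side ≈ `region_scale`)
over the largest class until each class hits its target pixel count
exactly, giving contiguous blocky regions whose realized fractions match
the targets to within a pixel.  Optical DNs are drawn per pixel from the
class's trivariate normal (bands ordered NIR, RED, GREEN), thermal DNs
from a univariate normal, all clipped to `[QcalMin, QcalMax]`; all draws
come from per-class substreams of one seed, so scenes are
bit-reproducible.

The default spectral library places class-mean NDVI at roughly
{forests 0.56, agricultural 0.40, urbanized 0.05, bare 0.02, rocks 0.00,
water −0.40} and thermal DNs so retrieved LST orders
urbanized > bare > rocks > agricultural > forests ≈ water — the
qualitative structure repeatedly observed over urbanizing tropical
islands.  Within-class spread defaults to a spherical 5-DN standard
deviation, leaving neighbouring class means ≥ 6 standard deviations apart;
classification on such scenes is nearly perfect by construction.  The
default two-date area fractions encode an urban-growth scenario
(urbanized 19.9% → 29.0%, agricultural 34.1% → 22.7%, etc.).

What the synthetic scenes deliberately lack: sensor noise models, mixed
pixels, topographic and atmospheric effects, spatially correlated
within-class texture, clouds, and any radiative-transfer link between the
optical and thermal draws.  Passing tests therefore demonstrate the
correctness of the *computations* (formulas, bookkeeping, estimator
behaviour), not classification skill or LST accuracy on real imagery,
where class overlap and atmosphere dominate.

## Numerical and design choices

- Raster files are plain TIFFs; pixel size, nodata value and band label
  travel in the ImageDescription tag as JSON, so integer grids round-trip
  bit-exactly.  Polygon masks rasterize by centre-of-pixel inclusion.
- Metadata files are a flat `KEY = value` dialect (an MTL-style subset),
  case-insensitive, `#` comments allowed; missing required keys are
  reported by name.
- Pipeline runs derive every stage's seed from the one run seed via
  hashed substreams, making reruns bit-identical; the manifest records
  configuration, seeds and package version.  Test and acceptance runs use
  scene sizes of 100–256 pixels per side, which exercise every code path
  while keeping the whole suite near a second.
- Degenerate inputs fail loudly with typed exceptions (`ArgumentError`,
  `ConfigError`, `NumericalError`) naming the offending class or key;
  per-pixel pathologies (zero NDVI denominator, nonpositive log
  arguments) become nodata with logged counts instead.

## Known limitations

- No atmospheric correction beyond the TOA chain, and no split-window or
  emissivity-lookup LST variants.
- The bundled Penang Island tabulation reproduces its published change
  statistics for five of six classes; the published water-bodies change
  row is internally inconsistent with the published areas
  (385.27 − 189.12 = 196.15 ha, not 24.46 ha), and the implementation
  follows the arithmetic, not the printed row.
- File-based ingestion expects bands already co-registered on one grid;
  there is no reprojection, cloud masking or gap filling.
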