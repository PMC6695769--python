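# Methods

This note documents the models, numerical choices and limitations of
`vinespec`. It is written for a reader who wants to know *why* the
pipeline behaves as it does, not just what its functions are called.

## 1. The measurement problem

Grape ripeness is tracked through total soluble solids (TSS, °Brix),
anthocyanins (mg per fresh berry) and total polyphenols (absorbance units
at 280 nm per berry). Reference assays are destructive and slow, so a
contactless spectrometer on a moving vehicle is attractive: it sees a
~1.9 cm circular spot (area 2.835 cm²) on the fruiting zone at 18 Hz while
driving at 5 km/h, i.e. about 64 spectra per five-vine block pass
(⌊5 m / 1.389 m s⁻¹ × 18 Hz⌋). The raw stream mixes grape clusters with
leaves, wood and canopy gaps, which is what the signature filter removes.

## 2. Synthetic vineyard generator

### What it emulates

* **Geometry** — 3 rows × 12 blocks of 5 vines (36 blocks), 2.20 m row
  spacing, 1.0 m vine spacing, arbitrary row azimuth and origin.
* **Chemistry** — per-block, per-date values for the three analytes.
  Each analyte has a latent Gaussian-process field over the block
  centroids (squared-exponential covariance, correlation length 15 m by
  default), drawn **once** and reused across dates so the spatial pattern
  evolves coherently; a monotone per-date mean shift carries the ripening
  trend; independent noise is added per block × date; values are clipped
  to the analyte's global range (defaults: TSS 10.7–25.2 °Brix,
  anthocyanins 0.09–4.64 mg/berry, polyphenols 0.14–4.70 AU/berry, the
  span a full veraison-to-harvest season produces in a red variety).
  The anthocyanin and polyphenol latent fields share a common component
  with correlation 0.8, since the pigments dominate the phenolic pool and
  their spatial patterns track each other.
* **Spectra** — absorbance over 215 evenly spaced channels on
  [570, 990] nm. (The instrument reports 215 channels for that range at
  "2 nm resolution", which would arithmetically give 211; the channel
  count is treated as authoritative because it is the data dimensionality
  the models consume, so the actual step is 420/214 ≈ 1.963 nm.) Each
  spectrum in a block pass draws its scene class from a mixture (defaults
  cluster 0.35, leaf 0.40, wood 0.10, gap 0.15 — the cluster fraction of a
  defoliated fruiting zone is not something the literature pins down, so
  this is a fixed design choice). Class endmembers are smooth, stylised
  but physically motivated shapes: the berry spectrum is pigment-dominated
  in the visible with a water feature near 970 nm; leaves show the
  chlorophyll band at 678 nm; wood is a flat declining absorber; gaps
  return weak background.
* **Analyte imprint** — a cluster spectrum is the berry endmember plus one
  Gaussian absorption band (or band pair) per analyte whose amplitude is
  `spectral_snr × scaled concentration` (concentration mapped to [−1, 1]
  over the global range). Band positions: TSS on the 910–960 nm
  sugar/water overtone shoulder, anthocyanins at 600/545 nm, and total
  polyphenols on *the same* 600/545 nm profile — the phenolic pool reaches
  this window only through its pigment fraction, so the two analytes are
  spectrally confounded by construction.
* **Degradations** — per-spectrum multiplicative gain (sd 0.05), additive
  offset (sd 0.02), white channel noise (sd 0.008), and per-spectrum
  **berry jitter** (`berry_sd`): the spot sees a couple of berries whose
  composition scatters around the block reference value that the assay
  averages over a 100-berry sample. Berry jitter is the irreducible
  optical-vs-reference mismatch and the main reason the recovered R² is
  below 1.

### What the defaults encode

The default `spectral_snr` and `berry_sd` per analyte (TSS 0.12 / 3.5,
anthocyanins 0.045 / 2.6, polyphenols 0.012 / 1.5) encode the
well-established difficulty ordering of these analytes for VIS+SW-NIR
calibration: strong direct sugar/water features, weaker pigment features,
and an only-indirect phenolic signal. On the default campaign this yields
external-validation R²p of roughly 0.92–0.97 for TSS, 0.78–0.92 for
anthocyanins and 0.47–0.71 for polyphenols across seeds, with the ordering
TSS > anthocyanins > polyphenols holding in every tested seed — the
qualitative pattern a real campaign of this design produces, without
claiming to reproduce any particular field numbers.

### What it does *not* emulate

No radiative transfer or berry optics, no 3-D canopy geometry, no
illumination/temperature drift, no GPS error, no weather. Passing tests
therefore demonstrate that the *processing chain* is correct and that
parameter recovery behaves as designed under the stated noise model — not
that any specific field accuracy is attainable.

## 3. Processing chain choices

* **Block allocation** — nearest centroid, discarding spectra farther than
  `max_distance`. The function default (1.10 m, half the row spacing)
  suits streams recorded per block; the pipeline passes half the block
  length (2.5 m) because a full 5 m pass puts spectra up to ~2.5 m
  along-row from their own centroid. Ties go to the smaller block id.
* **Signature filtering** — plain (uncentered) cosine on raw absorbance,
  threshold 0.993; similarity is computed before any preprocessing,
  matching the field processing order. Which exact variant a vendor
  comparison tool uses is generally undocumented, so a mean-centered
  variant is available behind `centered=True`. Blocks retaining fewer than
  `min_count = 5` spectra are dropped with a warning — an average of a
  handful of possibly-misclassified spectra is not a trustworthy block
  measurement. The whole pipeline aborts only if *no* block survives.
* **Preprocessing** — treatment codes `DnWm` (Savitzky–Golay n-th
  derivative, window m), `SNV`, `DT`, chained left to right.
  Savitzky–Golay polynomial order defaults to 2 and detrend degree to 2
  (the classic pairings for first-derivative spectra); both configurable.
  Edges are filled by evaluating the nearest full window's fitted
  polynomial (scipy's `mode="interp"`), keeping the 215-channel shape.
  Derivatives are scaled by the channel step (absorbance per nm); this
  changes coefficients, not model R², since PLS is scale-equivariant
  after centering.
* **Outlier screening** — PCA with the smallest component count capturing
  ≥ 95 % variance; a sample is flagged when **both** Q and T² exceed their
  99 % limits (conservative joint rule, single pass), **or** when either
  statistic alone exceeds 10× its limit. The second clause exists because
  a gross amplitude anomaly inflates a principal component of its own and
  then shows an extreme T² with an unremarkable residual, which the joint
  rule cannot see. T² limit: `k(n−1)/(n−k)·F_α(k, n−k)`; Q limit:
  Jackson–Mudholkar approximation from the discarded eigenvalues (with an
  h₀ floor of 10⁻⁴ when the eigenvalue spectrum makes h₀ non-positive).
  On clean default campaigns zero samples are flagged.
* **Split** — calibration size `ceil(0.8 n)` (144 → 116/28). Samples are
  ranked by the response, the rank order is cut into `n − n_cal` near-equal
  bins, and one random sample per bin goes to validation, so both sets
  span the range. The global response extremes stay in calibration
  whenever their bin offers an alternative, so the model never
  extrapolates; with only extreme candidates (e.g. n = 2) the bin still
  contributes one validation sample.
* **PLS** — NIPALS with X deflation, univariate response; fully
  deterministic; chosen over kernel/SIMPLS variants for transparency and
  oracle-testability (full-rank PLS must reproduce least squares, which
  the tests assert). X is mean-centered only — all channels share
  absorbance units, so variance scaling would amplify noise channels.
* **Cross-validation** — 10-fold venetian blinds on dataset order
  (block-major, date-minor, as assembled from the acquisition table);
  fold label = index mod 10. The fold assignment intentionally depends on
  dataset order. The selected latent-variable count is the smallest
  attaining the minimum RMSECV. Because NIPALS components are nested, one
  fit per fold at the maximum count serves every truncation.
* **R²** — explained variance `1 − SSE/SST` about the evaluated set's own
  mean (squared-correlation mode available via `r2_mode="corr"`); the two
  conventions differ for biased predictions and the explained-variance
  form is the stricter, more common choice in validation tables.

## 4. Mapping

Multilevel B-spline approximation: uniform cubic B-spline control lattices
fitted with the local weighted least-squares control-point assignment of
the BA algorithm, cascaded over residuals on lattices that double in
resolution per level (default 8 levels from a 4×4 start). Two departures
from the textbook construction:

* the data mean is carried as a constant offset level, so a constant field
  is reproduced exactly everywhere (the plain BA lattice decays to zero
  away from data support);
* each level's surface is scaled by the step length in [0, 1] minimising
  the new maximum residual (`max|r − γs|` is convex in γ). On elongated
  vineyard-shaped point sets the undamped cascade can transiently
  *increase* the max-norm residual at coarse levels; the damped update
  makes the residual non-increasing by construction and leaves fine-level
  convergence untouched (~10⁻¹⁵ residual at 8 levels on 36 blocks).

Rasters default to 1 m cells over the layout bounding box padded by one
row spacing; cells farther than 2× the row spacing (4.40 m) from every
block centroid are no-data so maps never extrapolate beyond the plot.
A date series shares one grid and one colour-scale range per analyte so
temporal evolution is comparable. Writers: ESRI ASCII grid and GeoJSON
cell polygons (plain JSON).

## 5. Problem sizes and determinism

The default campaign is 36 blocks × 4 dates × 64 spectra = 9 216 spectra
of 215 channels; a full simulate→train→map run takes on the order of a
second, and the 10-seed parameter-recovery study a few seconds. All
randomness flows from one integer seed through `numpy`'s `SeedSequence`;
identical configuration and seed give bit-identical streams, chemistry,
models and rasters.

## 6. Known limitations

* The generator's linear absorbance mixture ignores nonlinear scatter
  (which real SNV/derivative preprocessing exists to fight); the
  preprocessing steps are therefore exercised but not stress-tested.
* The cosine filter's operating point is far cleaner than field reality:
  synthetic class endmembers are well separated, so precision/recall at
  threshold 0.993 are near 1. The threshold's selectivity curve, not its
  field difficulty, is what the tests probe.
* Venetian-blinds CV on spatially and temporally structured samples is
  optimistic compared with leave-block-out validation; it is used here
  because it is the standard protocol for this instrument class.
* Total-polyphenol recovery depends strongly on the assumed
  pigment–phenolics coupling (latent correlation 0.8); real vineyards vary.
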