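# Methods

## Decay model and simulator

A TCSPC acquisition at 80 MHz repetition rate histograms photon arrival
times into `n` channels of width `Δt` over a window of at most one
repetition period `T = 12.5 ns`. The simulator models the per-pixel
fluorescence as a mono- or bi-exponential decay rising as a step at the
decay-peak position `t₀` (1.33 ns in all default geometries):

    I(t) ∝ Σᵢ aᵢ · exp(−((t − t₀) mod T)/τᵢ) / (1 − exp(−T/τᵢ))

The `mod T` wrap and the `1/(1 − e^(−T/τ))` gain implement the periodic
steady state: fluorescence emitted after the end of one excitation period
re-enters at t = 0 (for τ = 2.2 ns about 0.3% of the decay wraps; for
τ = 2.73 ns about 1%). No instrument response function is modeled — every
analysis here bins or fits relative to the decay maximum, so a finite IRF
would only blur the first channel; the rise is a step and an IRF hook is a
deliberate no-op extension point.

Channel expectations are exact integrals of this shape (no sampling
approximation), normalized so the fluorescence expectations over the
acquired window sum to `total_photons`, plus a uniform
`background_rate` per channel (noise photons are detected uniformly in
time, including before the rising edge). Observed counts are independent
Poisson draws from these expectations; all randomness flows through a
single seeded `numpy` generator, so outputs are bit-reproducible.

Default acquisition geometries mirror the three experimental regimes the
package targets: 3128 × 4 ps channels (in vitro 2D), 256 × 48.8 ps
(in vivo 2D), and 4 × 2.08 ns channels with 0.255 µm pixels and 2.346 µm
z-step (in vivo 3D clinical stacks).

### Reference species

* `species_a` (τ = 0.1 ns) and `species_b` (τ = 2.2 ns): canonical fast and
  slow mono-exponential fluorophores; `mixed_ab` is their 90%/10%
  relative-amplitude mixture, the decay shape of melanin-containing pixels.
  The mixture's intensity fraction of the fast species is
  a₁τ₁/(a₁τ₁ + a₂τ₂) = 0.09/0.31 ≈ 0.29 — the value the phasor fraction
  analysis recovers.
* `melanin_species` (τ = 66 ps / 1.59 ns, a₁ = 99%): a melanosome-packed
  pixel, matching measured synthetic-melanin decays. Its noiseless
  Pseudo-FLIM slope is ≈ 175 arb. u., consistent with measured values for
  such samples (~179).
* `keratinocyte_species` (τ = 419 ps / 2.73 ns, a₁ = 60%): the
  free/bound-NAD(P)H + FAD mixture of non-melanized keratinocytes; slope
  ≈ 36 arb. u., far below the 70 threshold.

The photon budget and background of simulated decays are free parameters
(no canonical values exist); the acceptance computations use 2×10⁵ photons
with 0.02 background counts/channel, comfortably above the regime where
fit bias matters, and the phantom uses clinical-scale budgets (below).

## Skin phantom

The 3D phantom is a (z, y, x) grid of columns with per-column surface and
DEJ depth maps. Normalized epidermal depth is
u = (depth − surface)/(DEJ − surface), u = 0 at the surface, u = 1 at the
DEJ. Voxels above the surface carry background only; epidermal voxels are
melanin-species with probability `melanin_fraction_profile(u)` and
keratinocyte-species otherwise; voxels below the DEJ are dermis
(keratinocyte-like, dimmer). Ground truth records every melanized voxel,
the species labels and the segmentation.

Defaults (chosen once, as the phantom's study conditions):

* **Geometry** 40 × 64 × 64 at the clinical pixel size/z-step: the lateral
  field of view is ~16 µm, over which real surface/DEJ relief is small —
  the maps undulate by 0.5 µm (surface, around 7 µm) and 2 µm (DEJ, around
  65 µm), giving a ~58 µm epidermis, typical of forearm skin.
* **Melanin distribution** a basal band: p(u) = 0.85 for u ≥ 0.85, else 0.
  This emulates strongly pigmented basal/suprabasal keratinocytes whose
  melanosome caps cover most of the cell cross-section, the regime in
  which dark-skin z-profiles concentrate melanin density at the DEJ.
  Melanization is drawn per voxel independently — there is no melanosome
  clustering model (a documented non-goal), which matters for what the
  phantom can show (below).
* **Brightness** 300 expected photons/pixel for melanin vs 80 for
  keratinocytes and 60 for dermis: melanin is the dominant emitter in the
  basal layer at these excitation conditions.

**What passing phantom tests show, and what they do not.** The phantom
validates the analysis chain — binning, blurring, regression, thresholds,
area filter, layer bookkeeping — against exact ground truth. It does not
model melanosome clustering, scattering or depth-dependent excitation
loss, hemoglobin in capillaries, or stratum-corneum keratin; real-data
specificity against those confounders is outside what these tests can
demonstrate. Because melanization is voxel-independent while the blur
pools a ~1 µm² neighborhood, sparse melanin (fractions below ~10%) is
intentionally hard for the phantom: the pipeline detects melanized
*regions*, so per-voxel Dice is only meaningful where melanin is locally
dense, as in the default basal band.

## Bi-exponential analysis

Per-pixel tail fit of `offset + a₁e^(−t/τ₁) + a₂e^(−t/τ₂)` on the channels
from the first complete channel after the decay maximum (an optional
integer channel shift mimics a fixed calibration shift and is meant to be
set once per dataset). Numerical choices:

* **Estimator** maximum likelihood via Poisson deviance residuals in a
  trust-region least-squares loop. Neyman-weighted least squares
  (weights max(count, 1)) is available as `estimator="wls"` but is not the
  default: at 2×10⁵ photons over 3128 channels it underestimates τ₂ by
  ~4–5% because near-empty tail channels get unit weight; the deviance
  estimator recovers (τ₁, τ₂, a₁) = (0.100, 2.20, 90.0) on the same decay.
* **Initialization** two-segment log-linear heuristic: a line fit to
  ln(counts) over the late tail seeds (τ₂, a₂); the early-tail residual
  seeds (τ₁, a₁). Bounds τ₁ ∈ [0.01, 0.8] ns, τ₂ ∈ [0.3, 6] ns span all
  lifetimes relevant in skin (tens of ps to a few ns).
* **Degeneracy** components are reported ordered τ₁ ≤ τ₂ with amplitudes as
  percentages of a₁ + a₂; if the fitted lifetimes come within one channel
  width of each other the pixel is refit mono-exponentially and reported
  with a₂ = 0. A pure slow mono-exponential input instead degenerates with
  a₁ → 0 (the fast component vanishes); both ends are exercised in tests.
* **Photon starvation** pixels whose tail holds fewer than `min_photons`
  (default 100) return a flagged result rather than raising; starved and
  non-converged pixels are invalid in the parametric maps.

Bi-exponential fitting of stacks with fewer than 8 time channels is
refused with a capability error: a 5-parameter model against 4 samples is
meaningless, and that regime is precisely what the slope method is for.

## Phasor analysis

First harmonic of the repetition period, ω = 2π/T. For each decay,
g + i·s = Σ I_k e^(iωt_k) / Σ I_k with t_k measured from the peak channel
(plus the optional fixed shift). A mono-exponential lies on the universal
semicircle s² + (g − ½)² = ¼ at g = 1/(1+(ωτ)²); mixtures lie on chords
with intensity-fraction weights, which is what `mixture_fractions`
inverts by orthogonal projection onto the reference chord.

Finite channel width distorts the discrete phasor. Two corrections are
provided, toggleable per call:

* `sinc` (default): multiply by e^(iωΔt/2)·sinc(ωΔt/2). A constant complex
  factor, so phasor linearity (mixture = weighted sum) is preserved
  exactly; a residual of order ωΔt²/(12τ) remains, negligible except for
  lifetimes comparable to the channel width.
* `mono`: exact inversion of the discrete geometric-sum phasor. For counts
  sampled over a full period the uncorrected phasor of an exponential is
  w = (1−a)/(1−a·z) with a = e^(−Δt/τ), z = e^(iωΔt); solving
  a = (1−w)/(1−w·z) and mapping back through 1/(1 − iωτ) restores the
  semicircle to rounding precision. Exact only for mono-exponentials
  (a must be real), hence not the default for mixture work; it is the
  correction used when validating the semicircle identity and the
  τ_φ/τ_m = τ recovery.

Zero-count pixels are invalid (never imputed); the (g, s) histogram is
restricted to [0, 1] × [0, 0.6] and conserves valid-pixel mass.

## Pseudo-FLIM slope analysis

Fixed processing order: temporal binning → per-slice 2D Gaussian blur →
+1 photon → natural log → OLS over the first `n` binned channels
(n = 3 default, n = 2 subtraction variant) → ×(−100) → round → clip
[0, 255] → threshold → open-area filter.

* **Binning** raw channel k (center (k+½)Δt) joins bin ⌊center/width⌋;
  only complete bins are kept so photons are conserved exactly over the
  covered range. A stack whose channel width is already within 15% of the
  requested bin (clinical 2.08 ns channels vs the 2 ns default) passes
  through unchanged, with the true channel width recorded as the
  effective bin width; a genuinely finer bin request is a validation
  error. The decay peak belongs in the first bin (1.33 ns < 2 ns); a peak
  outside it triggers a warning, not an error, since the sensitivity to
  peak position is a legitimate thing to study.
* **Blur** σ = r = √((A/dx²)/π) pixels with A the 1 µm² melanin filter
  area — the Fiji Gaussian-Blur "radius = sigma" convention, truncated at
  3σ, applied within each slice and binned channel only (no z or t
  smoothing). An FWHM reading of "radius" would be a one-line config
  change.
* **Regression** abscissa is the dimensionless channel index, so the
  −100-scaled slope is in the established arbitrary units; dividing the
  raw slope by the bin width gives 1/ns, and for a noiseless
  mono-exponential aligned to a bin edge it equals −1/τ exactly (the
  consecutive-bin integral ratio is e^(−w/τ)). With `add_photon=0`
  (diagnostic mode) the slope is exactly invariant under intensity
  scaling; the default +1 photon, needed for empty pixels, biases toward
  0 only at very low counts.
* **Rounding and threshold** round-half-away-from-zero before the [0, 255]
  clip; the melanin threshold is strict (> 70). Both are stated because
  neither convention is canonical.
* **Area filter** 8-connected components per 2D slice whose physical area
  (pixels × dx²) falls below the melanosomal 1 µm² are removed; the filter
  is idempotent and never adds pixels, so raising the threshold can only
  shrink the mask.
* **Two-channel variant** the OLS slope over two points is exactly
  y₁ − y₀, i.e. twice the magnitude of the three-channel slope for a decay
  concentrated in the first bin; fast pixels therefore saturate the 8-bit
  scale earlier. The variant's mask agrees with the three-channel mask on
  ≥ 90% of true melanin voxels of the default phantom.

## 3D quantification

Density is the voxel-fraction percentage — 100 × melanin voxels / region
voxels — the only density a binary mask supports, stated prominently
because "density" is otherwise ambiguous. The segmentation (per-column
surface and DEJ depths, optional SC/living-epidermis boundary) is an
input: produced by the phantom, or supplied as JSON from any external
segmentation; re-implementing automatic 3D skin-layer segmentation is out
of scope.

The z-profile assigns each epidermal voxel (voxel-center depth,
0 ≤ u ≤ 1) to layer 12 − ⌊12u⌋ clamped to [1, 12]: layer 1 contains the
DEJ (u = 1 by clamping), layer 12 the surface; bins are half-open so the
assignment is a partition, and the voxel-weighted mean of the 12 layer
densities equals the global density exactly. Voxels are pooled across
columns before densities are computed (per-column averaging, the other
defensible choice, can be had by reporting per-column profiles through
`profile_report`). Columns with missing surfaces are excluded, not
imputed; degenerate columns (DEJ = surface) are excluded and counted in
the profile's QC field. The depth axis may run in either direction as
long as the orientation is uniform — a z-flipped stack with consistently
flipped maps yields the identical profile.

Group summaries report per-layer mean ± 95% normal CI of the mean
(undefined for a single profile).

## Problem sizes

The test suite and acceptance computations run on one CPU in well under
the package's own CI budget: the acceptance decay uses 2×10⁵ photons over
3128 channels; recovery statistics use 200 replicates at 10⁴ photons on
the 256-channel geometry; the end-to-end phantom is 40 × 64 × 64 × 4. All
are desk-scale stand-ins for the corresponding instrument regimes; none
of the clinical cohort statistics are reproduced here.

## Known limitations

* No IRF, so the simulator cannot probe shift-calibration errors beyond
  the integer channel shift; the first-channel partial integral is the
  only rise artifact modeled.
* Phasor corrections assume a window of one full repetition period; the
  8.33 ns 4-channel window never reaches the phasor path (capability
  error), but intermediate windows would carry a truncation bias.
* Vendor TCSPC container formats (.sdt, .ptu) are not read; data arrive
  as multi-page TIFF + JSON sidecar.
* The phantom's independent-voxel melanization understates the spatial
  coherence of real melanosome distributions; detection metrics on sparse
  diffuse melanin are pessimistic relative to real clustered melanin.
* Discrimination of fast-decaying keratinized/degraded-melanin pixels in
  the stratum corneum from melanin proper is an open question in the
  field and is not attempted.
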