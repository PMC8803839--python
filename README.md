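# melaflim

Melanin detection and 3D epidermal quantification from multiphoton
fluorescence-lifetime (FLIM) data.

## The problem

Melanin autofluorescence decays much faster than the other endogenous skin
fluorophores: a melanized pixel shows a bi-exponential TCSPC decay with a
dominant (> 90% relative amplitude) ~0.1 ns component, against the
free/bound NAD(P)H, FAD and keratin decays of hundreds of ps to a few ns.
Per-pixel bi-exponential fitting and phasor analysis both exploit this, but
they need enough photons per pixel that acquisition is confined to 2D
images at selected depths — incompatible with in vivo 3D z-stacks on human
volunteers.

`melaflim` implements all three analyses plus the machinery to compare them
on synthetic data with known ground truth:

* **Bi-exponential fitting** — per-pixel tail fit of
  I(t) = a₁e^(−t/τ₁) + a₂e^(−t/τ₂) + offset; reports τ₁, τ₂,
  a₁[%] = 100·a₁/(a₁+a₂), the amplitude-weighted average
  τ_AvAmp = (a₁τ₁+a₂τ₂)/(a₁+a₂) and the intensity-weighted
  τ_AvInt = (a₁τ₁²+a₂τ₂²)/(a₁τ₁+a₂τ₂), plus melanin masks from lifetime
  thresholds (τ₁ < 80/100/150 ps, a₁[%] > 90, τ_AvAmp < 400 ps).
* **Phasor analysis** — first-harmonic Fourier coordinates
  g = ΣI cos(ωt)/ΣI, s = ΣI sin(ωt)/ΣI at ω = 2π/rep period; modulation m,
  phase φ, phase/modulation lifetimes τ_φ = tan(φ)/ω, τ_m = √(1/m²−1)/ω;
  two-component intensity fractions from phasor-chord distances; masks
  (g > 0.5 & s < 0.3, τ_φ < 1.1 ns).
* **Pseudo-FLIM** — the fast-acquisition method: bin the decay into ~2 ns
  time channels, Gaussian-blur each channel at the melanosome scale
  (r = √((A/dx²)/π) px, A = 1 µm²), add 1 photon, take the natural log, and
  OLS-fit the first 3 binned channels. The slope × (−100), clipped to
  [0, 255], is the parametric image; slope > 70 plus a 1 µm² open-area
  filter gives the melanin mask. Works on 4-time-channel clinical z-stacks
  where fitting and phasors are impossible.
* **3D quantification** — melanin mask ∩ epidermis segmentation → global
  (and SC/living-epidermis) voxel-fraction densities and the z-profile of
  melanin density in 12 thickness-normalized epidermal layers (layer 1 at
  the dermal–epidermal junction, layer 12 at the stratum corneum).
* **Simulator** — analytic-expectation TCSPC decays (mono/bi-exponential,
  80 MHz periodic wrap, Poisson noise, uniform background), 2D FLIM images
  and 3D skin phantoms with surface/DEJ geometry, a depth-dependent melanin
  fraction and full voxel-level ground truth.

## Worked example

```python
import melaflim as mf

# --- a two-component decay: A (0.1 ns) and B (2.2 ns), 90/10 amplitudes ---
metadata = mf.metadata_invitro_2d()          # 3128 channels x 4 ps, 12.5 ns
decay = mf.simulate_decay(mf.mixed_ab(total_photons=2e5), metadata, seed=7)

fit = mf.fit_decay(decay)
print(f"tau1 = {fit.tau1*1000:.0f} ps   tau2 = {fit.tau2:.2f} ns   "
      f"a1 = {fit.a1_pct:.1f} %   tauAvAmp = {fit.tau_av_amp:.3f} ns")

phasor = mf.decay_to_phasor(decay)
print(f"g = {phasor.g:.3f}   s = {phasor.s:.3f}   tau_phi = {phasor.tau_phi:.2f} ns")

# --- a clinical-style 3D skin phantom, 4 time channels x 2.08 ns ---
spec = mf.default_phantom_spec(seed=0)       # 40 x 64 x 64, basal melanin band
stack, truth = mf.simulate_skin_stack(spec, mf.metadata_invivo_3d())
slope, mask = mf.run_pseudoflim_stack(stack)
profile = mf.z_profile(mask.mask, truth.segmentation)
print(f"global epidermal melanin density = {profile.global_density:.1f} %")
```

prints

```
tau1 = 100 ps   tau2 = 2.19 ns   a1 = 89.9 %   tauAvAmp = 0.311 ns
g = 0.609   s = 0.368   tau_phi = 1.20 ns
global epidermal melanin density = 15.4 %
```

The fit recovers the simulated lifetimes and amplitude ratio; the phasor of
the mixture falls inside the universal semicircle between the two species
(its phase lifetime 1.2 ns is an apparent, mixture-weighted value); and on
the phantom the Pseudo-FLIM mask (slope > 70, 1 µm² filter) recovers the
injected basal melanin band — layers 1–2 near 100% / 87%, zero above, with
a voxel-level Dice of 0.87 against the ground truth.

The same pipeline is scriptable from the shell:

```bash
melaflim simulate -o phantom --seed 1
melaflim detect   -i phantom/stack.tif -s phantom/stack.json -o detection
melaflim quantify -m detection/melanin_mask.tif -g phantom/segmentation.json -o quant
```

`quant/z_profile.csv` holds the 12-layer profile, `quant/summary.json` the
global density, and each directory a provenance record (config + seed) that
makes reruns bit-identical.

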