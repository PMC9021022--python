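# paleohabitat

Climate-envelope habitat-suitability modelling for Pleistocene hominins on
gridded palaeoclimate trajectories.

`paleohabitat` is a Python library for palaeoecologists and palaeoclimate
modellers who want to connect a long transient climate simulation (or a
statistically equivalent synthetic trajectory) with a database of dated,
located hominin fossils and archaeological layers. It covers the full
chain: topographic downscaling of coarse model output, an a-posteriori net
primary productivity (NPP) diagnostic, a Mahalanobis climate-envelope
model with Monte-Carlo propagation of dating uncertainty, habitat
suitability maps and overlap diagnostics, and a scrambled-trajectory null
model that tests whether the actual orbital-scale climate sequence shaped
the fossil record.

## The model

Each occurrence is characterised by a four-dimensional climate vector
sampled at its site and age:

    C = (T*_am, P*_am, P*_min, N*)

annual mean temperature (°C), annual mean precipitation (mm yr⁻¹), minimum
monthly precipitation (mm month⁻¹) and NPP (gC m⁻² yr⁻¹), all from
1,000-year climate slices downscaled to a ~1° grid:

* temperature: `T* = T − g·Δh` with lapse rate g = 6 °C km⁻¹ and Δh the
  height difference between the fine topography and the model orography;
* precipitation: `p* = p · exp[aT*/(T*+b) − aT/(T+b)]` (Clausius–Clapeyron
  moisture scaling, a = 17.625, b = 243.04 °C);
* NPP: an empirical blend of a grass term and min(FP, FT) forest terms
  weighted by a tree fraction τ ∈ [0, 1], times a logarithmic CO₂
  fertilization factor `1 + 0.4·ln(CO₂/280)/ln 2`.

For each species the occurrence rows D (n records × n Monte-Carlo age
draws) define the envelope: sample mean ⟨D⟩ and covariance S. Habitat
suitability at any grid cell and time is the upper chi-squared tail of the
Mahalanobis squared distance,

    ζ² = (C − ⟨D⟩)ᵀ S⁻¹ (C − ⟨D⟩),     H = 1 − χ²_CDF(ζ²; 4) ∈ [0, 1],

interpreted as the probability of finding evidence of the species under
climate C (for 4 variables, H = e^(−ζ²/2)(1 + ζ²/2)). The
scrambled-trajectory null refits the envelope after permuting the time
axis jointly across the four variables at each cell — preserving each
cell's mean state and cross-variable covariance exactly — and compares
real and null suitability with a per-cell paired t-test (significance at
p < 0.05 with an effect-size floor |ΔH| > 0.05).

Because 2-Myr climate-model output is terabyte-scale server data, the
package ships a first-class synthetic generator (`paleohabitat.synthetic`)
producing trajectories with Milankovitch sinusoids (21/41/100/405 ka),
cross-correlated AR(1) noise, topography pairs, CO₂ series and fossil
databases drawn by rejection sampling against a known true envelope — so
every stage is testable end to end with known ground truth.

## Worked example

`examples/04_envelope_suitability.py` generates a 300-ka trajectory,
places 300 fossils against a known envelope, refits, and prints:

```
generated 300 fossil records over 1-300 ka
envelope fitted on 3000 Monte-Carlo rows
  t_am   centroid true    17.88  fitted    17.51  (true sd 4.23)
  p_am   centroid true   903.19  fitted   896.61  (true sd 202.19)
  p_min  centroid true    25.29  fitted    25.00  (true sd 8.63)
  npp    centroid true   552.00  fitted   556.00  (true sd 108.66)
suitability at the true centroid: 1.000 (1.0 = centre of the fitted envelope)
4x4-degree regional series: mean 0.457, range [0.032, 0.832]
presence-probability curve peaks at 252 ka (superposed dating-uncertainty kernels, normalised to 1)
```

The fitted centroid lands well within one true standard deviation of the
generating centroid on every component, and the true centroid sits at the
centre of the fitted envelope (H ≈ 1). The regional series is the
4°×4° land average of H through time; the presence curve superposes each
record's dating-uncertainty kernel. The other examples cover the
synthetic climate generator, species-database scenario resolution,
downscaling + NPP, and overlap/null-model diagnostics.

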