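# Methods

`hpwave` implements, as a reproducible desk-scale toolkit, the computational
chain of a multi-bistatic microwave breast-imaging device and its
diagnostic-accuracy study protocol: signal synthesis on breast phantoms,
Huygens-principle image reconstruction, image-homogeneity feature
extraction, a median-calibrated binary decision rule, and the study's
statistical machinery.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Acquisition model

Both antennas rotate azimuthally on a ring of radius `antenna_radius`
(default 0.10 m, chosen to clear the largest 135 mm cup; the true ring
radius of the hardware is not public).  The receiver steps by 4.5°
(80 positions); ten transmitters are grouped into five doublet sections with
centres at 0°, 72°, 144°, 216° and 288°.  The intra-doublet spacing is not
public either; we place the two members symmetrically at centre ± 4.5° so
they land on the receiver grid, and keep the offset configurable.  The
sweep covers 1–9 GHz; the hardware's frequency-point count is not public,
so the default grid is 81 uniform points (configurable; most tests thin it
for speed, which only coarsens the incoherent frequency sum).

## Forward model (synthetic data)

The generator uses a 2D scalar Born (single-scattering) model:

    S21[t, m, f] = Σ_s a_s · G(k_b, |r_t − r_s|) · G(k_b, |r_s − r_m|)
                   + a_art · A(f) + circular complex Gaussian noise,

with `G(k, d) = −(j/4) H0⁽²⁾(kd)` the outgoing-wave 2D Green's function
under the e^{+jωt} convention and `k_b` the background wavenumber
(default free space).  The scatterer strength `a_s` is a lumped
dimensionless quantity (dielectric contrast × cross-section): lesions draw
`a ~ U(1, 3)`, while fibroglandular "clutter" specks are an order of
magnitude weaker individually (A: 0.02, B: 0.04, C: 0.08, D: 0.15, each
× U(0.5, 1.5), with 15/25/35/45 specks per density class), so single specks
sit well below a lesion but aggregate heterogeneity grows A < B < C < D —
the reason detection is expected to be density-dependent.  The
rotation-invariant artifact `A(f)` (antenna coupling / skin-ring response)
is a pure frequency response, identical at every transmitter and receiver
index; its default strength (0.01) dominates typical scatterer responses,
as coupling does in measured data.  A frequency-only artifact is the
strongest form of rotation invariance and is nulled exactly by the
rotation subtraction below; an artifact varying with transmitter–receiver
separation would only be attenuated, not nulled.

The Born model is linear in each contrast, single-scattering only, 2D, and
single-height; it does not emulate skin refraction, antenna patterns,
dispersion, or tissue permittivity (the in-breast background is the
imaging medium's free space).  Cohort-level conclusions from it speak to
the *pipeline's* behaviour, not to clinical performance.

## Reconstruction

Artifact removal subtracts the signal at a receiver offset by δ = 9°
(an index shift of 2 on the 4.5° grid):

    ΔS21[t, m, f] = S21[t, m, f] − S21[t, m + δ/step, f].

Any component constant across receiver index cancels exactly; a point
target survives but acquires a "ghost" — the same target rotated by −δ.

Back-propagation treats the subtracted samples as secondary sources.  Each
pixel ρ is imaged by a coherent receiver sum, then an incoherent (power)
sum over transmitters and frequencies:

    I(ρ) = Σ_f Σ_t | Σ_m ΔS21[t, m, f] · K_f(m, ρ) |²,

with the kernel matched to the subtracted point-target response,

    h_f(m, ρ) = G(k_f, |r_m − ρ|) − G(k_f, |r_{m+δ/step} − ρ|),
    K_f(m, ρ) = conj(h_f(m, ρ)) / ‖h_f(·, ρ)‖.

Three choices here were genuinely open and deserve their rationale:

* **Conjugation.**  Multiplying by the raw Green's factor adds propagation
  phase instead of compensating it; the receiver sum is then never
  coherent at the target and a point scatterer does not reconstruct at its
  location.  The conjugated kernel is back-propagation in the
  time-reversal sense and focuses to sub-pixel accuracy on a 64×64 grid.
* **Difference-matched kernel.**  Imaging subtracted data with an
  unsubtracted kernel superposes the target's focal spot with its ghost's
  negative; at this band the spots are broad compared with the ghost
  separation (δ·r ≈ 4 mm at mid-radius), and they largely cancel, pushing
  the argmax centimetres away.  Applying the same receiver-shift
  difference to the kernel makes the filter matched to the actual
  subtracted response, keeping the peak centred on the target.
* **Unit-norm weighting.**  The raw kernel energy grows toward the ring
  and vanishes on the rotation axis, biasing the argmax outward;
  normalising each pixel's kernel to unit receiver-energy removes the
  radial bias.  A consequence worth knowing: targets very close to the
  axis are intrinsically dim (their rotation-subtracted signature tends to
  zero) — a real blind spot of receiver-shift subtraction, not an
  implementation artifact.

The imaging wavenumber is conductivity-weighted,

    k = ω √(μ0 ε0 εr) √(1 − j σ/(ω ε0 εr)),   Im k ≤ 0,

with εr = 1 and σ = 0.3 S/m by default: no patient-specific dielectric
knowledge enters, matching the clinical algorithm.  In free space σ = 0.3
is a large perturbation at the low end of the band (loss tangent ≈ 5.4 at
1 GHz, inflating Re k by ~1.8×), so when the forward background is plain
free space the low-frequency sub-band is deliberately defocused — the
model-mismatch regime the clinical device also operates in.  Localization
accuracy is therefore a property of the *matched* pair (forward background
= imaging medium) and is tested as such; the mismatched default is
exercised by the cohort-level detection tests, where homogeneity features,
not pinpoint localization, carry the decision.

Images are restricted to the in-cup disk (breast mask), reported in linear
arbitrary units, and normalised to unit mean over the mask (making all
full-image features scale-free; note that on a unit-mean image the
max-to-mean ratio equals the maximum itself).  The default grid is 64×64
over the breast radius, keeping pixel spacing under a quarter of the 9 GHz
wavelength; a maximum-intensity projection is available when multi-plane
signal sets are supplied, the default being a single coronal plane.

## Features and decision rule

Ten base statistics (MAX, MIN, MEA, MED, population-variance VAR,
mean-absolute-deviation MAD0 about the mean, median-absolute-deviation
MAD1 about the median, M2AVG = MAX/MEA, ROS1 = (MAX−MIN)/(MEA−MIN),
ROS2 = (MAX−MIN)/(MED−MIN)) are computed on the in-breast pixels (`_i`).
The peak region (`_p`) is the 8-connected component of the super-level set
at MAX/√2 that contains the global argmax (row-major tie-break); a bare
threshold would merge distant peaks.  The in-breast complement is `_c` and
the elementwise `_p`/`_c` ratios are `_r`; ROS1/ROS2 are full-image only,
giving 34 features.  Undefined values (zero denominators, empty
complement) are NaN-flagged, never imputed; the classifier scores them 0
(toward "no finding").

Per site, thresholds are the medians of each selected feature over the
site's lesion-free calibration breasts (protocol: the first 15 volunteers
per site; even counts use the mean-of-middle-two).  A breast scores
S = 1 per selected feature on *strict* exceedance, and is called WF when
the number of S = 1 reaches `min_positives`.  The default selected set is
(M2AVG_i, MAX_i, VAR_p, MAD0_p, VAR_r) with `min_positives = 5`, i.e. all
five must fire — an unusually strict rule, kept configurable.  Scoring
never sees the reference-standard label.

## Study statistics

Welch's two-sample two-tailed t-test (unpooled variances,
Welch–Satterthwaite degrees of freedom, α = 0.05) compares NF vs WF
evaluation breasts per feature, with no multiple-testing correction by
default (per-feature α is the protocol's specification; a Bonferroni flag
exists).  ROC curves sweep all distinct thresholds with the classifier's
strict-exceedance convention; AUC handles ties as the Mann–Whitney
statistic.  Sensitivity and specificity use exact Clopper–Pearson 95%
intervals (Wilson via flag), stratified by BI-RADS density, excluding the
calibration subjects.  The sample-size machinery is exact-binomial, not
normal-approximate: the critical value is the smallest k with
P(Bin(n, p0) ≥ k) ≤ α, power is P(Bin(n, p1) ≥ k), and the required
lesion-arm size is found by direct scan (exact power is sawtoothed in n,
so no bisection).  The design point p0 = 0.60, p1 = 0.70, α = 0.05
one-sided, power 0.80 at ~50% prevalence is *validated as sufficient* at a
lesion arm of 175 (exact power 83.9%, achieved size 3.7%); the protocol's
own derivation method being unstated, the exact minimum (143 by this
machinery) is not claimed to reproduce it.  Sidedness is one-sided by
default ("verify p > p0"), configurable.

## Problem sizes and tolerances

Tests and the acceptance script run on one CPU in well under a minute by
thinning what does not change the mathematics: 11–16 frequency points
instead of 81, 16–24 pixel grids for cohort runs (64×64 where localization
is asserted), cohorts of ~165 breasts (3 sites × (15 calibration + 40
evaluation)), and a shared per-geometry Green operator (the Hankel
evaluations dominate cost).  Key numerical tolerances: unit-mean
normalisation to 1e−12; feature oracle equivalence to 1e−12; localization
within 2 pixel spacings on 64×64; artifact residual ≤ 1e−6 of the
unsubtracted maximum; Monte-Carlo checks at 3 standard errors.
Degenerate inputs (all-zero signal sets) propagate as flagged degenerate
images and NaN feature rows rather than errors, so a cohort run survives
pathological records.

## Known limitations

2D single-plane geometry; Born single scattering with free-space in-breast
background (no dielectric realism, no skin layer); frequency-only artifact
(separation-dependent coupling would survive subtraction partially);
axis-adjacent lesions are structurally hard for receiver-shift
subtraction; the generator's density classes modulate clutter only, not
breast size or shape; synthetic performance figures characterise the
pipeline under these assumptions and carry no clinical meaning.
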