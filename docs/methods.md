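# Methods

`forcespec` analyzes single-molecule force spectroscopy (AFM) pulling
experiments on a receptor–ligand system in which a mechanically weak
protein subdomain can unfold before the complex dissociates, plus the
accompanying solution-binding (MST) measurement. Because raw instrument
data for such experiments are rarely deposited, the package ships a
Monte-Carlo generator that synthesizes pulling curves and titrations with
known ground truth; every analysis routine is validated as a round trip
against that ground truth.

## Polymer elasticity

All force–extension fitting uses the Marko–Siggia interpolation of the
worm-like chain (WLC),

    F(x) = (kB*T/p) * [ 1/4 (1 − x/Lc)^−2 − 1/4 + x/Lc ],

with the persistence length fixed at p = 0.4 nm, the standard value for a
stretched polypeptide. The contour length Lc is the only free mechanical
parameter of every fit. kB = 0.0138065 pN·nm/K; the default temperature is
298 K (25 °C), giving kB·T = 4.114 pN·nm. The inverse map (extension at a
given force) is solved by safeguarded Brent root finding on the monotone
forward map, bracketed on [0, Lc(1 − 1e−12)], to 1e−9 relative tolerance.
The stiffness dF/dx is the analytic derivative and is unit-tested against
central finite differences.

Contour-length bookkeeping is additive: the PEG24 linker pair contributes
19 nm, the folded complex 5.5 nm, and each unstructured residue 0.4 nm.
Converting a length to a residue count rounds half away from zero; the
convention is exposed as a parameter (`rounding="none"` returns the raw
quotient) because published residue counts are quoted under more than one
convention.

## Frame conversion

Raw retractions are recorded as piezo displacement and cantilever
deflection versus time. Force is spring constant × deflection,
tensile-positive. The force zero is the mean of the final 20% of the
retraction (far from the surface); the distance zero is the hard-contact
point, estimated by fitting a line to the most repulsive 25% of the
contact wall (samples beyond −25 pN) and taking its zero-force intercept.
Tip–sample separation is piezo − deflection − contact offset. Curves with
no detectable wall (e.g. pre-zeroed force input) keep a zero contact
offset and are flagged. No smoothing is applied to the deflection before
zeroing.

## Event detection and per-event fitting

Rupture candidates are prominent negative excursions of the
Savitzky–Golay first derivative of force (window 11 samples, order 2),
with prominence at least 3× the robust (MAD-based) noise scale of the
derivative, that also drop the smoothed force by at least 20 pN measured
one window to either side. The 20 pN minimum-drop floor keeps 5 pN
Gaussian noise from triggering (a pure-noise trace yields zero
candidates); its flip side is that unfolding events occurring below
roughly 35 pN produce sub-threshold drops and are not detected — on
synthetic wild-type data roughly a fifth of unfolding events fall there
and those curves classify as single-rupture, as they would in a manual
analysis. Modal statistics are unaffected.

Each candidate's rising edge runs from the previous smoothed-force
minimum (or the last baseline crossing, whichever is later) to half a
smoothing window before the drop; ties break toward the longer window.
The edge is fitted by bounded scalar least squares over Lc with p fixed.
The rupture force FU is read from the last pre-rupture sample (not the
WLC value there) and the rupture extension x_r is the corresponding
separation. The loading rate at rupture is the WLC stiffness (analytic
derivative at the fitted Lc and x_r) times the retraction velocity.

Acceptance filters, applied in order with every rejection recorded:

* `below_min_separation` — x_r < 10 nm (non-specific tip–sample adhesion);
* `contour_below_linker` — fitted Lc ≤ 19 nm (shorter than the PEG pair);
* `linear_profile` — the WLC fit must beat a straight-line fit by ≥ 0.01
  in R², and x_r/Lc must exceed 0.2 (a WLC loaded only in its linear
  regime is indistinguishable from adhesion);
* `residual_too_large` — RMS fit residual above 30 pN.

Filtering is total: accepted + rejected-with-reason = detected. The hit
rate is the fraction of cycles with at least one accepted event.

## Ensemble statistics

Most probable values (FU, Lc, dLc) are the means of single Gaussians
fitted by unweighted least squares to raw-count histograms — FU at 10 pN
bins, Lc and dLc at 2 nm bins (the scatter density uses 5 nm × 10 pN).
Histograms are padded with three empty bins per side, and the fitted sigma
is bounded below at a quarter bin, so distributions narrower than the
binning cannot collapse the fit. The estimator is unbiased on symmetric
samples to better than half a bin at n = 10^4.

Contour-length increments are computed **per curve** — differences of the
fitted Lc values on the same curve, ordered by separation — and then
histogrammed. They are never computed as a difference of ensemble modal
Lc values, which is a different (and generally unequal) quantity.
dLc_total = Lc_last − Lc_first is exactly the sum of successive
increments. Replicate conditions aggregate as the mean of replicate modes
± half the range (not SEM).

Hotspots of the Lc–FU scatter (the specificity diagnostic) are connected
clusters of 2-D histogram bins whose counts exceed 5× the spatial median
density (median over the whole grid, empty bins included) and at least 2%
of the total point count; the second guard keeps Poisson fluctuations of
a diffuse scatter from registering. Centroids are count-weighted
bin-center means.

## Dynamic force spectrum and Bell–Evans kinetics

Each velocity condition contributes a point: modal FU versus the natural
log of the mean per-event loading rate. Linear regression gives the
Bell–Evans line; the transition-state distance is x_beta = kB·T/slope and
the intrinsic off-rate follows from evaluating the modal-force relation
F* = (kB·T/x_beta)·ln(x_beta·r/(k0·kB·T)) at the regression intercept. A
non-positive slope rejects the fit (non-Bell behaviour). Both the raw
regression coefficients and the derived kinetic parameters are reported.

A caveat established with the simulator: the conventional loading-rate
rule (WLC slope × velocity) neglects cantilever compliance. In the series
geometry the true force ramp is set by the series stiffness
(1/kc + 1/k_WLC)^−1 × velocity, which at rupture forces near 100 pN with a
30 pN/nm lever is roughly half the WLC-only value, and the discrepancy
grows with force. Consequently the apparent x_beta extracted from
full-pipeline synthetic spectra overestimates the generating value
(≈ 0.6 nm apparent for 0.35 nm generated). The quantitative recovery
check therefore uses exact constant-loading-rate rupture ensembles
(inverse-transform sampling of the Bell first-passage distribution),
where the regression recovers x_beta within 10% and k0 within a factor
of two.

## MST binding analysis

The normalized fluorescence is modelled as a linear two-state reporter,
Fnorm = Fnorm_unbound + FB·(Fnorm_bound − Fnorm_unbound), with FB the
exact 1:1 law-of-mass-action fraction bound including depletion of the
labeled species A:

    FB = (A + L + KD − sqrt((A + L + KD)^2 − 4AL)) / (2A).

The physical decomposition of the MST amplitude (temperature-jump
sensitivity, Soret coefficient) is not identifiable from a titration and
only the composite amplitudes are fitted. The fit is unweighted nonlinear
least squares over (log10 KD, both amplitudes), initialized at the
concentration of half signal amplitude, with a seeded 200-round residual
bootstrap for a 95% CI. Fits are rejected when the amplitude is
indistinguishable from the residual noise, and a warning is issued when
the fitted KD is not bracketed by at least a decade of concentrations on
each side.

## The synthetic-data generator

The pulling simulator models the tether as a serial mechanical network: a
cantilever (default 30 pN/nm) in series with a single effective WLC whose
contour length is the sum of the intact segments — the PEG24 pair
(19 nm), a structured linker-domain conformation (22.5 nm), the folded
complex (5.5 nm) — plus 0.4 nm per already-released residue. Lumping the
PEG and polypeptide into one WLC mirrors the additive contour-length
bookkeeping; PEG-specific two-state elasticity is deliberately out of
scope. At piezo position z = v·t the force solves z = F/kc + x_WLC(F),
via dense monotone interpolation refined by two vectorized Newton steps
(series balance holds to < 1e−6 nm on noise-free traces).

Each rupturable segment carries Bell kinetics k(F) = k0·exp(F·x_beta/kBT).
Rupture times are drawn by the exponential-threshold method on the
cumulative hazard of the discretized force ramp (sampling interval
1/20 kHz), which is exact for the piecewise force profile and free of
per-step Bernoulli bias; the sampling rate only limits the rupture-force
resolution (~0.5 pN at 1,000 nm/s). Unfolding a subdomain adds
released_residues × 0.4 nm of contour; rupture of the terminating
(unbinding) segment drops the force to baseline. Gaussian noise (default
σ = 5 pN, an assumption exposed in the config — no instrument noise
figure is available) is added to the force channel, along with optional
baseline and contact offsets for exercising the frame conversion.

Default kinetics (generator conveniences, not measured claims): unbinding
k0 = 0.1 s⁻¹, x_beta = 0.35 nm (modal force ≈ 105 pN at 10^4 pN/s);
weak-subdomain unfolding k0 = 1 s⁻¹, x_beta = 0.5 nm (≈ 60 pN) — chosen so
unfolding precedes unbinding at experimental loading rates, preserving
the observed mechanical hierarchy. Scenario presets encode the construct
variants: wild-type (50 residues release, dLc = 20 nm), XL_barrel
(unfolding blocked by a plug-to-barrel crosslink; single ruptures at the
intact 47 nm contour), XL_loop (a covalent 15-residue loop shortens the
release to 35 residues, dLc = 14 nm), 3A (a destabilized second subdomain
releasing 64 residues, k0 = 0.3 s⁻¹, x_beta = 0.45 nm, giving triple
ruptures), and a binding-deficient control (no specific events).

Force maps mix specific, adhesion, and empty cycles (defaults 7.5% /
10% / 82.5%). Adhesion curves are linear ramps (20–60 pN/nm) detaching at
a uniform 2–9 nm separation — the classic sub-10-nm, linear-profile
rejection class. All generators are bit-reproducible under their seed.

What the generator does **not** emulate: instrument drift and 1/f noise,
PEG's two-state elasticity, refolding between pulls, multiple parallel
tethers, hydrodynamic drag on the lever, and surface-position
heterogeneity. Passing round trips therefore demonstrate the correctness
and calibration of the analysis chain under idealized single-tether
conditions, not performance on any particular instrument's data.

## Problem sizes

The shipped studies use sizes chosen to keep every result statistically
stable: 250 wild-type pulls (≥ 150 double-rupture records) for the dLc
round trip; 150 pulls per crosslink scenario; 600 mixed cycles for the
hit-rate study; 80 pulls per velocity at four velocities for the dynamic
force spectrum; 1,500 ruptures per rate for the constant-rate Bell–Evans
cross-check; triplicate 16-point titrations for the KD study, aggregated
as the replicate mean ± half-range.

## Known limitations

* Event detection misses ruptures whose force drop is below the 20 pN
  floor (see above); lowering the floor trades noise robustness directly
  for sensitivity.
* The x_beta/k0 extracted from pulling-geometry spectra inherit the
  compliance bias of the loading-rate rule; they are comparable across
  conditions analyzed identically, not absolute.
* The Gaussian modal fit assumes a unimodal, roughly symmetric peak;
  rupture-force distributions are mildly skewed, which shifts the
  intercept (hence k0) but barely the slope.
* The hotspot report is a density heuristic for specificity screening,
  not a clustering method; at small n a broad cluster can split across a
  density gap.
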