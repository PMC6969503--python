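# Methods

## The measurement and the model

Slice bioluminescence microscopy integrates photons over 30-min camera
exposures, giving one frame per 0.5 h; a 72-h recording is a 144-frame
T × Y × X stack.  Explanted-tissue rhythms damp over days and ride on a
drifting baseline (substrate depletion, settling, slice death), so each
trace — a pixel bin or an ROI mean — is modelled as an exponentially damped
cosinor with linear drift:

    y(t) = b + d·t + A·e^(−λt)·cos(2πt/τ + φ),

A ≥ 0 photons/frame, τ > 0 h, φ ∈ [0, 2π) (acrophase referenced to the
recording start, i.e. the oscillation peaks when 2πt/τ + φ ≡ 0 mod 2π),
λ ≥ 0 h⁻¹, b ≥ 0 photons/frame, d photons/frame/h.  Expected photon flux is
clipped at zero.  This is the minimal model that the fitting stage can
invert exactly, which is what makes generator → fit round-trip validation
meaningful.

## Detrending

The baseline estimate at sample i is the mean over a centered window of
nominally 24 h.  When the window is an exact multiple of the frame interval
its frame count is kept as-is — for 0.5-h frames that is 48 frames, an
*even* count spanning exactly one nominal period, which is precisely the
window that annihilates a 24-h cosine (the discrete mean of a cosine over
one full period of samples is identically zero).  A window that is not an
exact multiple is rounded to the nearest odd frame count for a symmetric
center; the effective frame count is recorded in the output.  At the edges
the window is truncated to the available samples so the detrended trace
keeps the full movie length (time-to-first-peak needs the early frames).
Truncated windows systematically distort the first and last half-window
(~12 h each), enough to bias a period fit by several tenths of an hour;
detrended traces therefore carry an `edge_frames` flag and the periodogram
and cosinor fit exclude those samples whenever the interior still spans
≥ 36 h.  Detrending is linear, so region differences commute with it.

## Period estimation and fitting

The period is the argmax of the normalized Lomb–Scargle periodogram over a
0.05-h grid in [18, 32] h (brackets the circadian range, excludes the 12-h
harmonic).  The damped cosinor is then fitted by bounded trust-region least
squares: τ constrained to the search band, λ ∈ [0, 0.2] h⁻¹, A ≥ 0;
initialisation uses the periodogram period, half the peak-to-trough range,
the projection phase atan2(−Σy sin ωt, Σy cos ωt), and λ = 0.01 h⁻¹.
Non-convergence is reported as a non-rhythmic fit with a diagnostic
message, never an exception.

A trace counts as rhythmic only if r² ≥ 0.6, relative amplitude
A / max(b_ref, ε) ≥ 0.05 (b_ref is the raw pre-detrend bin mean when the
fitted trace is detrended, since the fitted baseline of a detrended trace
is ~0 and meaningless as a reference), τ is strictly inside the search band
and λ is not pinned at its *upper* bound — λ = 0 is the legitimate undamped
case, not a degenerate fit — and, in map mode, the periodogram peak exceeds
the 95th percentile of a per-movie null built from 1000 randomly permuted
bin traces.  Permutation destroys temporal order while keeping each trace's
marginal distribution, so the null is calibrated to the movie's own noise
and the false-positive rate of the power criterion is checkable (a
white-noise trace falls below the threshold ~95% of the time by
construction).

Time-to-first-peak — the phase proxy used for across-region comparisons —
is the first local maximum of the detrended trace after a centered 2.5-h
(5-frame) moving mean, with prominence ≥ 0.5 trace SD; ties resolve toward
earlier time, and "no qualifying peak" is a valid result.  The 2.5-h window
suppresses shot noise without displacing a 24-h peak by more than one
frame.  At single-bin signal-to-noise the frame-level jitter of a broad
cosine maximum exceeds ±1 h; first-peak times are therefore meant to be
read from section-level ROI traces (tens of pooled cells), where recovery
is within ±1 h in ≥ 90% of simulated traces.

## Synchrony and region statistics

Phases of QC-passing bins are summarised per region by the resultant
length R, circular mean, circular SD √(−2 ln R) (∞ sentinel at R = 0) and
the Rayleigh statistic z = nR² with Zar's small-sample-corrected
exponential p-value; the type-I error at n = 20 calibrates to 5% ± 1%.
Region contrasts use one-way ANOVA plus Dunnett's many-to-one comparisons
against a named control region (scipy's exact Dunnett distribution; the
per-contrast unadjusted p uses the same pooled-variance t statistic so
adjusted ≥ unadjusted holds structurally; if Dunnett is unavailable the
code falls back to Holm-adjusted Welch tests and records the method).
All-constant input is flagged degenerate and no p-value is emitted.

The fibrotic-vs-nonfibrotic bioluminescence difference over 3 days is
operationalised as d(t) = detrended fibrotic trace − detrended nonfibrotic
trace over the first 72 h, summarised by the mean per-cycle (24-h)
peak-to-trough range of d(t): one number per movie, comparable across
animals and genotypes.

Paired phase shifts (pre/post stimulus) are reduced to (−π, π], averaged
circularly, and given a seeded 1000-resample bootstrap percentile CI.

## The synthetic tissue generator

The generator defines the experimental conditions the pipeline is
validated under.  Geometry is procedural on a 256 × 256 default grid
(128 × 128 in the reduced-scale validation runs): an elliptical slice of
parenchyma, fibrotic foci as a thresholded correlated random field (~30% of
tissue in bleomycin presets), and six bronchiole cross-sections labeled by
the surrounding parenchymal state.  Oscillators are placed at a uniform
surface density of one per 16 px² of tissue with continuous jittered
positions; their expected fluxes are deposited by bilinear splatting,
blurred by a Gaussian PSF (σ = 2 px), and observed through Poisson shot
noise plus Gaussian read noise (SD 2 counts), clipped at zero and rounded
to integer camera counts.  One root seed splits into independent substreams
(geometry, parameters, density, noise), so identical configurations are
bit-identical and geometry can be held fixed while noise varies.

Per-region oscillator distributions (amplitudes and baselines lognormal;
periods and damping normal, damping clipped at [0, 0.05] h⁻¹; phases von
Mises):

| preset | region | A mean (CV) | phase mean, κ |
|---|---|---|---|
| wt_bleomycin | parenchyma, nonfibrotic | 200 (0.5) | 0.5 rad, κ=40 |
| wt_bleomycin | parenchyma, fibrotic | 1000 (0.5) | 0.8 rad, κ=1.8 |
| wt_bleomycin | bronchioles | 500 (0.4) | 0.4 rad, κ=30 |
| healthy / stretch | parenchyma | 40 (0.5) | 0.5 rad, κ=10 |
| healthy / stretch | bronchioles | 500 (0.4) | 0.4 rad, κ=30 |

All rhythmic cells share τ ~ N(24, 0.5²) h (fibrosis amplifies and
desynchronises but does not change the period), λ ~ N(0.01, 0.005²) h⁻¹,
b lognormal mean 1600 (CV 0.1) photons/frame and drift N(−3, 1²)
photons/frame/h.  The κ values encode the central phenotype: fibrotic
parenchyma is high-amplitude (5× nonfibrotic at the cell level, ≥ 2× after
rendering and fitting) but dispersed (circular SD ~0.9 rad vs ~0.16).
`pdgfrb_bmal1_ko` draws fibrotic-parenchyma cells from the nonfibrotic
distribution (the infiltrating fibroblast lineage is clock-dead);
`ccsp_bmal1_ko` zeroes bronchiolar amplitudes and leaves fibrosis
untouched; `stretch` multiplies every amplitude by a mechanical gain
(default 1.5); `tgfb_pulse` tightens synchrony (κ = 50) and strengthens
parenchyma (A = 400) so a phase-response experiment starts from a
well-defined phase.

**Cellularity channel.**  Two notions of density are deliberately
distinct.  The oscillators are the luminescent reporter sources and sit at
uniform surface density, so rendered per-area flux reflects per-cell
oscillation parameters rather than cell counts.  The `density_field` is a
separate total-cellularity channel — the analog of a Hoechst nuclear stain
— built as a spatially correlated lognormal texture (CV 1.0, correlation
length 4 px) renormalised within each region to an exact regional mean,
elevated 1.10× in fibrotic tissue, and sampled independently of every
oscillator's amplitude.  This encodes the observation the pipeline must
reproduce: fibroblast infiltration raises nuclear staining, but staining
intensity does not predict oscillation amplitude.  The residual pooled
correlation between the two (both are region-structured) stays below the
checked bounds (|r| < 0.1 at the cell level, < 0.15 at the map level) by
this parameter choice.  When correlating the density channel against fit
maps, density is block-averaged over *tissue* pixels only; averaging over
whole tiles would dilute boundary bins by background zeros and manufacture
a spurious positive correlation with amplitude via the tissue fraction.

**TGFβ phase response.**  A pulse of dose D at time t shifts each cell's
acrophase by Δφ = −k_max·D/(D + D₅₀)·sin(θ − φ_ref), where θ is the cell's
instantaneous phase at the pulse.  The sine PRC with Michaelis-type dose
saturation is the canonical first-order choice for a dose- and
phase-dependent resetting stimulus; it guarantees zero shift at zero dose
and at the reference phase, |Δφ| ≤ k_max, and monotone dose dependence.

What the generator does *not* emulate: oscillator coupling (cells are
independent; no Kuramoto term), cell migration or proliferation, bleomycin
pathology dynamics, photobleaching nonlinearity, vendor metadata.  Passing
tests therefore demonstrate correct recovery of independent damped
oscillators under photon-counting noise — not robustness to coupled or
nonstationary rhythms.

## Problem sizes and numerical choices

The headline recovery run uses the full 256 × 256 field at bin factor 4
(~2900 tissue bins); the preset-contrast and knockout validation runs use
128 × 128 fields at bin factor 8, which preserves region-level statistics
at ~200 tissue bins per slice and keeps the whole validation suite fast.
Monte-Carlo calibrations are seeded; bootstrap and permutation seeds are
recorded in their outputs.  Bins within a region are treated as
exchangeable: no spatial-autocorrelation correction is applied (the PSF
correlates neighboring bins slightly; at bin 8 with σ = 2 px the effect is
small), and no mixed-effects modeling across animals is attempted — both
are documented limitations.  Degenerate inputs follow explicit rules:
all-zero movies yield an empty QC mask; flat traces are non-rhythmic;
constant-valued region comparisons are flagged degenerate with no p-value.
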