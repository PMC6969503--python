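# pclsrhythm

Spatially resolved circadian rhythm analysis for bioluminescence time-lapse
movies of living tissue slices, built around the phenomenon of pulmonary
fibrosis: in precision-cut lung slices (PCLS) from PER2::LUC reporter mice,
fibrotic parenchyma shows **high-amplitude but phase-asynchronous** circadian
oscillations, while healthy alveolar parenchyma is weakly rhythmic and
bronchioles oscillate strongly and in phase.  `pclsrhythm` turns raw movies
into amplitude/phase/period heat maps, detrended traces, time-to-first-peak
estimates, and region-level statistics that make that phenotype quantitative
— and ships a synthetic tissue-movie generator so that every stage of the
pipeline can be validated by parameter recovery against known ground truth.

Intended users: chronobiologists and tissue-imaging labs analysing
luciferase-reporter slice movies (lung, SCN, any organotypic culture), and
method developers who need a controlled test bed for rhythm-detection
pipelines.

## Model

Each cell (or pixel bin) is treated as a damped cosinor on a drifting
baseline:

```
y(t) = b + d·t + A·e^(−λt)·cos(2πt/τ + φ)
```

with amplitude `A` (photons/frame), period `τ` (h), acrophase `φ` (rad,
referenced to recording start), damping `λ` (1/h), baseline `b` and linear
drift `d`.  The analysis chain per trace is:

1. spatial binning (non-overlapping tiles) or ROI averaging;
2. subtraction of a centered 24-h moving-average baseline (edge windows
   truncated; edge samples flagged and excluded from fitting);
3. period estimation by a normalized least-squares (Lomb–Scargle)
   periodogram on a 0.05-h grid inside 18–32 h;
4. bounded nonlinear least-squares fit of the damped cosinor;
5. rhythmicity QC: `r² ≥ 0.6`, relative amplitude `A/b ≥ 0.05`, period not
   pinned at a search bound, and periodogram peak power above the 95th
   percentile of a per-movie permutation null.

Phase synchrony within a region is summarised by the resultant length
`R = |⟨e^{iφ}⟩|`, circular SD `√(−2 ln R)`, and the Rayleigh test
(`z = nR²`).  Region contrasts use one-way ANOVA with Dunnett many-to-one
post hoc comparisons.  TGFβ phase-shifting is modelled by a sinusoidal
phase-response curve with saturating dose dependence,
`Δφ = −k_max·D/(D+D₅₀)·sin(φ−φ_ref)`.

## Worked example

Simulate a fibrotic wild-type slice, analyse it, and compare regions:

```bash
pclsrhythm simulate --preset wt_bleomycin --hours 72 --interval 0.5 \
    --seed 1 --size 128 --out demo/run1
pclsrhythm analyze --movie demo/run1/movie.tif --mask demo/run1/mask.tif \
    --labels demo/run1/labels.csv --interval 0.5 --bin 8 --out demo/run1
pclsrhythm compare --runs demo/run1 --control parenchyma_nonfibrotic \
    --out demo/stats
```

which prints:

```
wrote movie (144 frames), mask and ground truth to demo/run1
analyzed 144-frame movie: 207 tissue bins, QC pass rate 1.00; maps and tables in demo/run1
== run run1 ==
amplitude ANOVA F=166 p=2.73e-27 (post hoc: dunnett)
  parenchyma_fibrotic vs parenchyma_nonfibrotic: diff=25.2 adj p=2.73e-27 [significant]
  synchrony parenchyma_fibrotic: R=0.951 circ SD=0.318 rad, Rayleigh p=3.43e-19
  synchrony parenchyma_nonfibrotic: R=0.986 circ SD=0.170 rad, Rayleigh p=5.86e-53
  fibrotic-nonfibrotic difference, mean per-cycle range: 35.7
  density-amplitude correlation: r=0.062 (n=206)
```

Reading the numbers: fibrotic parenchyma bins carry ~25 counts/frame more
oscillation amplitude than nonfibrotic parenchyma (Dunnett-adjusted
p ≪ 0.05) while being *less* synchronous (circular SD 0.32 vs 0.17 rad);
the detrended fibrotic-minus-nonfibrotic difference trace swings through
~36 counts per circadian cycle; and the cellularity (nuclear-stain analog)
channel is uncorrelated with oscillation amplitude (r = 0.06) even though
fibrotic regions are denser — amplitude gain is a per-cell property, not a
cell-count artifact.  Knockout presets invert the logic: `pdgfrb_bmal1_ko`
(clock deleted in the fibroblast/pericyte lineage) abolishes the amplitude
contrast, `ccsp_bmal1_ko` (club cells) silences bronchioles but leaves it
intact.

`analyze` also writes `amplitude_map.tif`, `phase_map.tif`,
`period_map.tif`, `r2_map.tif`, `qc_mask.tif`, a per-bin `fits.csv` and
per-region raw/detrended traces; every command records a manifest with the
full effective configuration and its hash.

Real movies enter at `analyze`: supply any multi-page TIFF plus a labeled
region mask (TIFF) and a `label,region` CSV using the region vocabulary
`parenchyma_fibrotic`, `parenchyma_nonfibrotic`, `bronchiole_fibrotic`,
`bronchiole_nonfibrotic`, `other`, `background`.

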