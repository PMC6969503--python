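"""Synthetic lung-slice tissue models and bioluminescence movie rendering.

This module generates ground-truth fields of damped single-cell circadian
oscillators arranged in a procedurally drawn slice geometry (nonfibrotic
parenchyma, fibrotic parenchyma patches, bronchiole cross-sections,
background) and renders them into noisy photon-counting movies, emulating
luciferase time-lapse microscopy of precision-cut lung slices (PCLS) from
PER2::LUC reporter mice after bleomycin-induced fibrosis.

Presets encode the experimental conditions the analysis pipeline is
validated against:

``wt_bleomycin``
    Fibrotic parenchyma carries high-amplitude but phase-dispersed
    oscillators (infiltrating rhythmic fibroblasts); nonfibrotic parenchyma
    is weakly rhythmic and well synchronised; bronchioles oscillate strongly.
``ccsp_bmal1_ko``
    Clock knocked out in club cells: bronchiolar amplitude collapses to
    zero while the fibrotic parenchyma behaves as in ``wt_bleomycin``.
``pdgfrb_bmal1_ko``
    Clock knocked out in the pericyte/fibroblast lineage: fibrotic
    parenchyma oscillator parameters are drawn from the nonfibrotic
    distribution, abolishing the fibrotic amplitude excess.
``healthy``
    No fibrosis; weak parenchymal rhythms, strong bronchioles.
``tgfb_pulse``
    Well-synchronised rhythmic parenchyma prepared for phase-response
    experiments (a TGFβ pulse is applied via :func:`apply_tgfb_pulse`).
``stretch``
    As ``healthy`` but with every amplitude multiplied by a mechanical
    stretch gain (default 1.5), emulating lung-inflation experiments.

Two deliberately distinct notions of density coexist.  The *oscillators*
(``TissueModel.cells``) are the luminescent reporter sources; they are
placed at a uniform surface density across all tissue so that rendered
per-area flux reflects per-cell oscillation parameters, not cell counts.
The *density field* is a separate total-cellularity channel (the analog of
a Hoechst nuclear stain): a spatially correlated lognormal field whose
regional mean is elevated in fibrotic tissue but which is sampled
independently of every oscillator's amplitude.  Fibroblast infiltration
raises nuclear staining without raising per-area reporter flux, which is
exactly the decoupling the analysis pipeline is asked to detect.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .movie_io import MovieStack, RegionMask
from .oscillators import TWO_PI, PhaseResponse, expected_flux, wrap_phase

# Integer labels used by the generated region geometry.
LABEL_MAP = {
    1: "parenchyma_nonfibrotic",
    2: "parenchyma_fibrotic",
    3: "bronchiole_nonfibrotic",
    4: "bronchiole_fibrotic",
}

PRESETS = (
    "wt_bleomycin",
    "ccsp_bmal1_ko",
    "pdgfrb_bmal1_ko",
    "healthy",
    "tgfb_pulse",
    "stretch",
)

#: Presets whose geometry contains fibrotic patches (bleomycin-treated mice).
FIBROTIC_PRESETS = frozenset({"wt_bleomycin", "ccsp_bmal1_ko", "pdgfrb_bmal1_ko"})

# Per-region oscillator parameter distributions.  Amplitudes and baselines
# are lognormal (mean, CV); periods and damping normal (mean, SD; damping
# clipped at 0); phases von Mises (mean, concentration kappa).  Units as in
# ``oscillators``: photons/frame, hours, radians, 1/h.
_WT_REGION_PARAMS = {
    "parenchyma_nonfibrotic": dict(
        amplitude_mean=200.0, amplitude_cv=0.5,
        phase_mean=0.5, phase_kappa=40.0,
    ),
    "parenchyma_fibrotic": dict(
        amplitude_mean=1000.0, amplitude_cv=0.5,
        phase_mean=0.8, phase_kappa=1.8,
    ),
    "bronchiole_nonfibrotic": dict(
        amplitude_mean=500.0, amplitude_cv=0.4,
        phase_mean=0.4, phase_kappa=30.0,
    ),
    "bronchiole_fibrotic": dict(
        amplitude_mean=500.0, amplitude_cv=0.4,
        phase_mean=0.4, phase_kappa=30.0,
    ),
}

_COMMON_REGION_PARAMS = dict(
    period_mean=24.0, period_sd=0.5,
    damping_mean=0.01, damping_sd=0.005,
    baseline_mean=1600.0, baseline_cv=0.1,
    drift_mean=-3.0, drift_sd=1.0,
    density_mean=0.06,  # cellularity channel, cells per pixel
)

_HEALTHY_REGION_PARAMS = {
    "parenchyma_nonfibrotic": dict(
        amplitude_mean=40.0, amplitude_cv=0.5,
        phase_mean=0.5, phase_kappa=10.0,
    ),
    "bronchiole_nonfibrotic": dict(
        amplitude_mean=500.0, amplitude_cv=0.4,
        phase_mean=0.4, phase_kappa=30.0,
    ),
}

#: Fibrotic cellularity excess in the density channel (nuclear-stain analog).
FIBROTIC_DENSITY_FACTOR = 1.10
#: Coefficient of variation of the lognormal density field.
DENSITY_CV = 1.0
#: Correlation length (pixels) of the density field's spatial texture.
DENSITY_CORR_LENGTH = 4.0
#: One luminescent oscillator per this many pixels of tissue, all regions.
OSCILLATOR_PIXELS_PER_CELL = 16.0


def _preset_region_params(preset: str) -> dict[str, dict]:
    """Region -> full parameter dict for a preset."""
    if preset in ("wt_bleomycin", "tgfb_pulse"):
        base = copy.deepcopy(_WT_REGION_PARAMS)
    elif preset == "ccsp_bmal1_ko":
        base = copy.deepcopy(_WT_REGION_PARAMS)
        for reg in ("bronchiole_nonfibrotic", "bronchiole_fibrotic"):
            base[reg]["amplitude_mean"] = 0.0
    elif preset == "pdgfrb_bmal1_ko":
        base = copy.deepcopy(_WT_REGION_PARAMS)
        # Arrhythmic fibroblast lineage: fibrotic parenchyma falls back to
        # the nonfibrotic oscillator distribution.
        base["parenchyma_fibrotic"] = copy.deepcopy(
            base["parenchyma_nonfibrotic"]
        )
    elif preset in ("healthy", "stretch"):
        base = copy.deepcopy(_HEALTHY_REGION_PARAMS)
    else:
        raise ValueError(
            f"unknown preset {preset!r}; valid presets: {', '.join(PRESETS)}"
        )
    if preset == "tgfb_pulse":
        # Tight synchrony so a phase-response experiment starts from a
        # well-defined phase; parenchyma made strongly rhythmic.
        for reg in base:
            base[reg]["phase_kappa"] = 50.0
        base["parenchyma_nonfibrotic"]["amplitude_mean"] = 400.0
        base["parenchyma_fibrotic"]["amplitude_mean"] = 400.0
        base["parenchyma_fibrotic"]["phase_mean"] = base[
            "parenchyma_nonfibrotic"
        ]["phase_mean"]
    out = {}
    for reg, pars in base.items():
        full = dict(_COMMON_REGION_PARAMS)
        full.update(pars)
        if reg.endswith("_fibrotic"):
            full["density_mean"] = (
                _COMMON_REGION_PARAMS["density_mean"] * FIBROTIC_DENSITY_FACTOR
            )
        out[reg] = full
    return out


@dataclass
class SimulationConfig:
    """Everything needed to build and render one synthetic slice movie."""

    preset: str = "wt_bleomycin"
    duration: float = 72.0            # hours
    frame_interval: float = 0.5       # hours; 30-min camera integration
    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    psf_sigma: float = 2.0            # pixels, optical blur
    poisson_noise: bool = True
    read_noise_sd: float = 2.0        # counts, camera read noise
    stretch_gain: float = 1.5         # amplitude gain for the stretch preset
    tgfb_dose: float = 0.0            # concentration, arbitrary units
    tgfb_time: float = 0.0            # hours, pulse application time
    tgfb_k_max: float = 0.5           # radians, saturating PRC magnitude
    tgfb_half_dose: float = 1.0       # dose of half-maximal sensitivity
    tgfb_reference_phase: float = 0.0  # radians, neutral stimulus phase
    region_params: dict = field(default_factory=dict)  # preset overrides

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; valid presets: "
                f"{', '.join(PRESETS)}"
            )
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if self.duration < 48.0:
            raise ValueError(
                "rhythm-analysis presets need >= 48 h (two full cycles), "
                f"got {self.duration} h"
            )
        n = self.duration / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"frame_interval {self.frame_interval} h must divide "
                f"duration {self.duration} h"
            )
        if self.tgfb_dose < 0:
            raise ValueError(f"tgfb_dose must be >= 0, got {self.tgfb_dose}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    def effective_region_params(self) -> dict[str, dict]:
        pars = _preset_region_params(self.preset)
        for reg, over in self.region_params.items():
            pars.setdefault(reg, dict(_COMMON_REGION_PARAMS)).update(over)
        return pars

    def phase_response(self) -> PhaseResponse:
        return PhaseResponse(
            k_max=self.tgfb_k_max,
            half_dose=self.tgfb_half_dose,
            reference_phase=self.tgfb_reference_phase,
        )


@dataclass
class TissueModel:
    """Simulator ground truth: oscillators, geometry, cellularity channel.

    ``x``/``y`` are continuous pixel coordinates (col, row); ``region`` holds
    each cell's integer region label; the parameter arrays follow
    :class:`~pclsrhythm.oscillators.OscillatorParams` semantics.
    """

    shape: tuple[int, int]
    x: np.ndarray
    y: np.ndarray
    region: np.ndarray
    amplitude: np.ndarray
    period: np.ndarray
    phase: np.ndarray
    damping: np.ndarray
    baseline: np.ndarray
    drift: np.ndarray
    region_labels: np.ndarray          # Y x X integer geometry
    label_map: dict[int, str]
    density_field: np.ndarray          # Y x X cellularity channel, >= 0
    psf_sigma: float = 2.0

    def __post_init__(self) -> None:
        h, w = self.shape
        n = len(self.x)
        for name in ("y", "region", "amplitude", "period", "phase",
                     "damping", "baseline", "drift"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"cell array {name!r} length mismatch")
        if n and (
            self.x.min() < 0 or self.x.max() >= w
            or self.y.min() < 0 or self.y.max() >= h
        ):
            raise ValueError("cell positions must lie inside the field")
        if self.region_labels.shape != self.shape:
            raise ValueError("region_labels shape must equal field shape")
        if self.density_field.shape != self.shape:
            raise ValueError("density_field shape must equal field shape")
        if self.density_field.min(initial=0.0) < 0:
            raise ValueError("density_field must be nonnegative")
        known = set(self.label_map)
        if n and not set(np.unique(self.region)).issubset(known):
            raise ValueError("every cell's region label must exist in label_map")
        self.phase = wrap_phase(np.asarray(self.phase, dtype=float))

    @property
    def n_cells(self) -> int:
        return len(self.x)

    def mask(self) -> RegionMask:
        return RegionMask(self.region_labels, self.label_map)

    def density_at_cells(self) -> np.ndarray:
        """Density-channel value sampled at each cell's (rounded) position."""
        rr = np.clip(np.round(self.y).astype(int), 0, self.shape[0] - 1)
        cc = np.clip(np.round(self.x).astype(int), 0, self.shape[1] - 1)
        return self.density_field[rr, cc]

    def ground_truth(self) -> pd.DataFrame:
        names = [self.label_map[int(r)] for r in self.region]
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x": self.x,
                "y": self.y,
                "region": names,
                "amplitude": self.amplitude,
                "period": self.period,
                "phase": self.phase,
                "damping": self.damping,
                "baseline": self.baseline,
                "drift": self.drift,
            }
        )


def _smooth_unit_field(rng, shape, corr_length) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field with spatial correlation."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, corr_length, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _build_geometry(rng, shape, fibrotic: bool) -> np.ndarray:
    """Procedural slice geometry: elliptical tissue, fibrotic patches, airways."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tissue = ((rr - cy) / (0.48 * h)) ** 2 + ((cc - cx) / (0.48 * w)) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    labels[tissue] = 1  # parenchyma_nonfibrotic

    if fibrotic:
        # Fibrotic foci: thresholded smooth random field, ~30% of tissue.
        fld = _smooth_unit_field(rng, shape, corr_length=max(6.0, min(h, w) / 20))
        thr = np.quantile(fld[tissue], 0.70)
        labels[tissue & (fld > thr)] = 2

    # Bronchiole cross-sections: disks dropped inside the tissue; label
    # follows the surrounding parenchymal state.
    n_airways = 6
    placed = 0
    for _ in range(200):
        if placed >= n_airways:
            break
        r0 = rng.uniform(0.15 * h, 0.85 * h)
        c0 = rng.uniform(0.15 * w, 0.85 * w)
        rad = rng.uniform(0.02 * min(h, w), 0.035 * min(h, w))
        ri, ci = int(round(r0)), int(round(c0))
        if labels[ri, ci] not in (1, 2):
            continue
        surrounding = labels[ri, ci]
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        labels[disk & (labels > 0)] = 3 if surrounding == 1 else 4
        placed += 1
    return labels


def _sample_region_cells(rng, pars: dict, n: int) -> dict[str, np.ndarray]:
    """Draw n oscillator parameter sets from one region's distributions."""

    def lognormal(mean, cv, size):
        if mean <= 0:
            return np.zeros(size)
        sigma2 = np.log(1.0 + cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size)

    return dict(
        amplitude=lognormal(pars["amplitude_mean"], pars["amplitude_cv"], n),
        period=np.clip(
            rng.normal(pars["period_mean"], pars["period_sd"], n), 16.0, 34.0
        ),
        phase=wrap_phase(rng.vonmises(pars["phase_mean"], pars["phase_kappa"], n)),
        damping=np.clip(
            rng.normal(pars["damping_mean"], pars["damping_sd"], n), 0.0, 0.05
        ),
        baseline=lognormal(pars["baseline_mean"], pars["baseline_cv"], n),
        drift=rng.normal(pars["drift_mean"], pars["drift_sd"], n),
    )


def build_tissue(config: SimulationConfig) -> TissueModel:
    """Construct the ground-truth tissue model for a preset.

    Deterministic for a given ``(config, seed)``: the root seed is split into
    independent substreams for geometry, oscillator parameters and the
    density channel, so geometry can be held fixed while other draws vary.
    """
    ss = np.random.SeedSequence(config.seed)
    geo_ss, par_ss, den_ss, _noise_ss = ss.spawn(4)
    geo_rng = np.random.default_rng(geo_ss)
    par_rng = np.random.default_rng(par_ss)
    den_rng = np.random.default_rng(den_ss)

    fibrotic = config.preset in FIBROTIC_PRESETS
    labels = _build_geometry(geo_rng, config.shape, fibrotic)
    region_params = config.effective_region_params()

    # Uniform oscillator surface density over all tissue regions.
    h, w = config.shape
    cells = {k: [] for k in (
        "x", "y", "region", "amplitude", "period", "phase",
        "damping", "baseline", "drift",
    )}
    for lab, name in LABEL_MAP.items():
        pix = np.flatnonzero(labels.ravel() == lab)
        if pix.size == 0:
            continue
        if name not in region_params:
            raise ValueError(f"preset {config.preset!r} lacks parameters for {name}")
        n = int(round(pix.size / OSCILLATOR_PIXELS_PER_CELL))
        if n == 0:
            continue
        chosen = par_rng.choice(pix, size=n, replace=False)
        ry, rx = np.divmod(chosen, w)
        jitter = par_rng.uniform(0.0, 1.0, size=(2, n))
        y = np.minimum(ry + jitter[0], h - 1.0 - 1e-9)
        x = np.minimum(rx + jitter[1], w - 1.0 - 1e-9)
        drawn = _sample_region_cells(par_rng, region_params[name], n)
        cells["x"].append(x)
        cells["y"].append(y)
        cells["region"].append(np.full(n, lab, dtype=np.int32))
        for k, v in drawn.items():
            cells[k].append(v)

    arrays = {
        k: (np.concatenate(v) if v else np.empty(0)) for k, v in cells.items()
    }

    if config.preset == "stretch":
        arrays["amplitude"] = arrays["amplitude"] * config.stretch_gain

    # Cellularity channel: correlated lognormal texture scaled so that each
    # region's mean density is exactly its preset value (the texture is
    # renormalised to unit mean within each region), independent of the
    # oscillator draws.
    g = _smooth_unit_field(den_rng, config.shape, DENSITY_CORR_LENGTH)
    sigma = np.sqrt(np.log(1.0 + DENSITY_CV**2))
    texture = np.exp(sigma * g - sigma**2 / 2.0)
    density = np.zeros(config.shape)
    for lab, name in LABEL_MAP.items():
        sel = labels == lab
        if name in region_params and sel.any():
            tex = texture[sel]
            density[sel] = region_params[name]["density_mean"] * tex / tex.mean()

    return TissueModel(
        shape=config.shape,
        region_labels=labels,
        label_map={lab: name for lab, name in LABEL_MAP.items()
                   if (labels == lab).any()},
        density_field=density,
        psf_sigma=config.psf_sigma,
        **arrays,
    )


def apply_tgfb_pulse(
    tissue: TissueModel, prc: PhaseResponse, dose: float, time: float = 0.0
) -> TissueModel:
    """Phase-shift every oscillator as if a TGFβ pulse arrived at ``time`` h.

    Each cell's instantaneous phase at the pulse is
    ``theta = 2*pi*time/tau + phi``; its acrophase parameter is advanced by
    the PRC shift ``-k(dose)*sin(theta - reference_phase)``.  All other
    parameters are untouched and a new model is returned.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    theta = wrap_phase(TWO_PI * time / tissue.period + tissue.phase)
    dphi = prc.shift(theta, dose)
    return replace(tissue, phase=wrap_phase(tissue.phase + dphi))


def _splat_matrix(tissue: TissueModel) -> sparse.csr_matrix:
    """(pixels x cells) bilinear deposition matrix for continuous positions."""
    h, w = tissue.shape
    x0 = np.floor(tissue.x).astype(int)
    y0 = np.floor(tissue.y).astype(int)
    fx = tissue.x - x0
    fy = tissue.y - y0
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    cell_idx = np.tile(np.arange(tissue.n_cells), 4)
    pix_idx = np.concatenate(
        [y0 * w + x0, y0 * w + x1, y1 * w + x0, y1 * w + x1]
    )
    weights = np.concatenate(
        [(1 - fy) * (1 - fx), (1 - fy) * fx, fy * (1 - fx), fy * fx]
    )
    return sparse.csr_matrix(
        (weights, (pix_idx, cell_idx)), shape=(h * w, tissue.n_cells)
    )


def simulate_movie(
    tissue: TissueModel, config: SimulationConfig
) -> tuple[MovieStack, RegionMask, pd.DataFrame]:
    """Render a tissue model into a bioluminescence movie.

    Per frame, every cell's expected photon count is deposited at its
    position by bilinear splatting, the field is blurred by a Gaussian PSF,
    and (if enabled) replaced by a Poisson draw plus Gaussian read noise,
    clipped at zero and rounded to integer camera counts.  Returns the movie,
    the region mask and the ground-truth cell table.
    """
    t = np.arange(config.n_frames) * config.frame_interval
    # (T, N) expected flux per cell
    flux = expected_flux(
        t[:, None],
        tissue.amplitude[None, :],
        tissue.period[None, :],
        tissue.phase[None, :],
        tissue.damping[None, :],
        tissue.baseline[None, :],
        tissue.drift[None, :],
    )
    splat = _splat_matrix(tissue)
    frames = (splat @ flux.T).T.reshape(config.n_frames, *tissue.shape)
    if tissue.psf_sigma > 0:
        frames = ndimage.gaussian_filter(
            frames, sigma=(0.0, tissue.psf_sigma, tissue.psf_sigma),
            mode="constant",
        )
    if config.poisson_noise or config.read_noise_sd > 0:
        noise_ss = np.random.SeedSequence(config.seed).spawn(4)[3]
        noise_rng = np.random.default_rng(noise_ss)
        if config.poisson_noise:
            frames = noise_rng.poisson(frames).astype(float)
        if config.read_noise_sd > 0:
            frames = frames + noise_rng.normal(
                0.0, config.read_noise_sd, size=frames.shape
            )
        frames = np.rint(np.maximum(frames, 0.0))
    stack = MovieStack(frames, config.frame_interval)
    return stack, tissue.mask(), tissue.ground_truth()
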