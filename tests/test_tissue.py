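"""Synthetic tissue generator: presets, perturbations, rendering contracts."""

import numpy as np
import pytest

from pclsrhythm.oscillators import PhaseResponse
from pclsrhythm.stats import circular_sd
from pclsrhythm.tissue import (
    LABEL_MAP,
    SimulationConfig,
    TissueModel,
    apply_tgfb_pulse,
    build_tissue,
    simulate_movie,
)

SMALL = dict(shape=(96, 96))


def single_cell_tissue(shape=(32, 32), **params):
    """One oscillator in the middle of an otherwise empty field."""
    defaults = dict(amplitude=0.0, period=24.0, phase=0.0, damping=0.0,
                    baseline=100.0, drift=0.0)
    defaults.update(params)
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    labels[h // 2, w // 2] = 1
    return TissueModel(
        shape=shape,
        x=np.array([w / 2.0]),
        y=np.array([h / 2.0]),
        region=np.array([1]),
        amplitude=np.array([defaults["amplitude"]]),
        period=np.array([defaults["period"]]),
        phase=np.array([defaults["phase"]]),
        damping=np.array([defaults["damping"]]),
        baseline=np.array([defaults["baseline"]]),
        drift=np.array([defaults["drift"]]),
        region_labels=labels,
        label_map={1: "parenchyma_nonfibrotic"},
        density_field=np.zeros(shape),
        psf_sigma=2.0,
    )


NOISELESS = dict(poisson_noise=False, read_noise_sd=0.0)


class TestBuildTissue:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            SimulationConfig(preset="wt_bleo_typo")

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError, match="48"):
            SimulationConfig(duration=24.0)

    def test_wt_fibrotic_amplitude_and_dispersion_excess(self):
        tissue = build_tissue(
            SimulationConfig(preset="wt_bleomycin", seed=1, **SMALL)
        )
        amp = tissue.amplitude
        fib, non = tissue.region == 2, tissue.region == 1
        assert amp[fib].mean() >= 2.0 * amp[non].mean()
        assert circular_sd(tissue.phase[fib]) >= 2.0 * circular_sd(
            tissue.phase[non]
        )

    def test_bleomycin_geometry_has_both_parenchymal_regions(self):
        tissue = build_tissue(
            SimulationConfig(preset="wt_bleomycin", seed=3, **SMALL)
        )
        names = set(tissue.label_map.values())
        assert {"parenchyma_fibrotic", "parenchyma_nonfibrotic"} <= names

    def test_pdgfrb_knockout_abolishes_amplitude_contrast(self):
        tissue = build_tissue(
            SimulationConfig(preset="pdgfrb_bmal1_ko", seed=1, **SMALL)
        )
        amp = tissue.amplitude
        fib = amp[tissue.region == 2].mean()
        non = amp[tissue.region == 1].mean()
        assert abs(fib - non) / non <= 0.1

    def test_ccsp_knockout_silences_bronchioles_only(self):
        tissue = build_tissue(
            SimulationConfig(preset="ccsp_bmal1_ko", seed=1, **SMALL)
        )
        wt = build_tissue(SimulationConfig(preset="wt_bleomycin", seed=1, **SMALL))
        bronchiole = np.isin(tissue.region, (3, 4))
        assert np.all(tissue.amplitude[bronchiole] == 0.0)
        # fibrotic parenchyma untouched by the club-cell knockout
        assert tissue.amplitude[tissue.region == 2].mean() == pytest.approx(
            wt.amplitude[wt.region == 2].mean()
        )

    def test_stretch_preset_scales_amplitudes_by_gain(self):
        healthy = build_tissue(SimulationConfig(preset="healthy", seed=7, **SMALL))
        stretched = build_tissue(SimulationConfig(preset="stretch", seed=7, **SMALL))
        assert np.allclose(stretched.amplitude, 1.5 * healthy.amplitude)

    def test_density_elevated_in_fibrosis_but_independent_of_amplitude(self):
        tissue = build_tissue(
            SimulationConfig(preset="wt_bleomycin", seed=1, shape=(128, 128))
        )
        assert tissue.n_cells >= 500
        dens = tissue.density_field
        lab = tissue.region_labels
        assert dens[lab == 2].mean() > dens[lab == 1].mean()
        r = np.corrcoef(tissue.density_at_cells(), tissue.amplitude)[0, 1]
        assert abs(r) < 0.1

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(preset="wt_bleomycin", seed=42, **SMALL)
        a, b = build_tissue(cfg), build_tissue(cfg)
        assert np.array_equal(a.amplitude, b.amplitude)
        assert np.array_equal(a.region_labels, b.region_labels)
        assert np.array_equal(a.density_field, b.density_field)


class TestTgfbPulse:
    def prc(self, k_max=1.0):
        return PhaseResponse(k_max=k_max, half_dose=1.0, reference_phase=0.0)

    def test_zero_dose_is_identity(self):
        tissue = build_tissue(SimulationConfig(preset="tgfb_pulse", seed=1, **SMALL))
        out = apply_tgfb_pulse(tissue, self.prc(), dose=0.0, time=10.0)
        assert np.array_equal(out.phase, tissue.phase)

    def test_reference_phase_cells_unshifted(self):
        tissue = single_cell_tissue(phase=0.0)  # phase == reference at t=0
        out = apply_tgfb_pulse(tissue, self.prc(), dose=5.0, time=0.0)
        assert out.phase[0] == pytest.approx(tissue.phase[0])

    def test_quadrature_half_dose_shift(self):
        tissue = single_cell_tissue(phase=np.pi / 2)
        out = apply_tgfb_pulse(tissue, self.prc(k_max=1.0), dose=1.0, time=0.0)
        assert out.phase[0] - tissue.phase[0] == pytest.approx(-0.5)

    def test_input_not_mutated_and_other_params_unchanged(self):
        tissue = build_tissue(SimulationConfig(preset="tgfb_pulse", seed=2, **SMALL))
        before = tissue.phase.copy()
        out = apply_tgfb_pulse(tissue, self.prc(), dose=2.0, time=12.0)
        assert np.array_equal(tissue.phase, before)
        assert out is not tissue
        assert np.array_equal(out.amplitude, tissue.amplitude)
        assert np.array_equal(out.period, tissue.period)

    def test_negative_dose_rejected(self):
        tissue = single_cell_tissue()
        with pytest.raises(ValueError, match="dose"):
            apply_tgfb_pulse(tissue, self.prc(), dose=-1.0)


class TestSimulateMovie:
    def test_constant_source_conserves_total_flux(self):
        cfg = SimulationConfig(preset="healthy", duration=48.0,
                               shape=(32, 32), **NOISELESS)
        tissue = single_cell_tissue(amplitude=0.0, baseline=100.0)
        stack, _, _ = simulate_movie(tissue, cfg)
        totals = stack.data.sum(axis=(1, 2))
        assert np.allclose(totals, 100.0, rtol=1e-6)

    def test_cosine_extrema_land_on_expected_frames(self):
        cfg = SimulationConfig(preset="healthy", duration=72.0,
                               shape=(32, 32), **NOISELESS)
        tissue = single_cell_tissue(amplitude=50.0, baseline=100.0, phase=0.0)
        stack, _, _ = simulate_movie(tissue, cfg)
        trace = stack.data[:, 16, 16]
        t = stack.times
        for peak in (0.0, 24.0, 48.0):
            window = np.abs(t - peak) <= 6.0
            assert t[window][np.argmax(trace[window])] == pytest.approx(peak)
        for trough in (12.0, 36.0, 60.0):
            window = np.abs(t - trough) <= 6.0
            assert t[window][np.argmin(trace[window])] == pytest.approx(trough)

    def test_noise_seeding_contract(self):
        cfg = SimulationConfig(preset="wt_bleomycin", seed=1, **SMALL)
        tissue = build_tissue(cfg)
        a, _, _ = simulate_movie(tissue, cfg)
        b, _, _ = simulate_movie(tissue, cfg)
        assert np.array_equal(a.data, b.data)
        cfg2 = SimulationConfig(preset="wt_bleomycin", seed=2, **SMALL)
        c, _, _ = simulate_movie(build_tissue(cfg2), cfg2)
        assert not np.array_equal(a.data, c.data)

    def test_undamped_driftless_pixels_average_to_baseline(self):
        # over whole periods the cosine term integrates to zero, so the
        # time-average image equals the rendered baseline image
        cfg = SimulationConfig(preset="healthy", duration=72.0,
                               shape=(32, 32), **NOISELESS)
        rng = np.random.default_rng(0)
        n = 5
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[...] = 1
        tissue = TissueModel(
            shape=(32, 32),
            x=rng.uniform(8, 24, n), y=rng.uniform(8, 24, n),
            region=np.ones(n, dtype=np.int32),
            amplitude=rng.uniform(20, 60, n),
            period=np.full(n, 24.0),
            phase=rng.uniform(0, 2 * np.pi, n),
            damping=np.zeros(n),
            baseline=rng.uniform(80, 120, n),
            drift=np.zeros(n),
            region_labels=labels,
            label_map={1: "parenchyma_nonfibrotic"},
            density_field=np.zeros((32, 32)),
            psf_sigma=2.0,
        )
        stack, _, _ = simulate_movie(tissue, cfg)
        baseline_only = TissueModel(
            **{**tissue.__dict__, "amplitude": np.zeros(n)}
        )
        ref, _, _ = simulate_movie(baseline_only, cfg)
        mean_img = stack.data.mean(axis=0)
        scale = ref.data[0].max()
        assert np.allclose(mean_img, ref.data[0], atol=1e-6 * scale)

    def test_ground_truth_table_lists_every_cell(self):
        cfg = SimulationConfig(preset="wt_bleomycin", seed=1, **SMALL)
        tissue = build_tissue(cfg)
        _, mask, truth = simulate_movie(tissue, cfg)
        assert len(truth) == tissue.n_cells
        assert set(truth["region"]) <= set(LABEL_MAP.values())
        assert mask.labels.shape == cfg.shape
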