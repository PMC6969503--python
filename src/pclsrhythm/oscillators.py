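"""Damped-cosine oscillator model and the TGFβ phase-response curve.

The luminescence of a single cell expressing a PER2::LUC reporter is modelled
as an exponentially damped cosine riding on a slowly drifting baseline::

    f(t) = max(0, b + d*t + A * exp(-lam*t) * cos(2*pi*t/tau + phi))

with amplitude ``A`` (photons/frame), period ``tau`` (h), acrophase ``phi``
(radians, referenced to recording start, so the oscillation peaks whenever
``2*pi*t/tau + phi`` is a multiple of ``2*pi``), damping rate ``lam`` (1/h),
baseline ``b`` (photons/frame) and linear baseline drift ``d``
(photons/frame/h).  Damping of explanted-tissue rhythms and baseline drift
(substrate depletion, settling) are both routine features of slice
luminometry, which is why they are part of the minimal model.

Phase-shifting by the profibrotic cytokine TGFβ is modelled by a first-order
sinusoidal phase-response curve (PRC) with a saturating (Michaelis-type) dose
dependence: a pulse of dose ``D`` delivered when a cell sits at instantaneous
phase ``theta`` advances its phase by::

    dphi = -k(D) * sin(theta - reference_phase),   k(D) = k_max * D / (D + half_dose)

so the shift vanishes at zero dose and at the reference phase, saturates at
``k_max``, and is monotone in dose at any fixed phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(phi):
    """Reduce a phase (scalar or array) into [0, 2*pi)."""
    return np.mod(phi, TWO_PI)


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of one damped-cosine cellular oscillator.

    Units: amplitude/baseline in photons per frame, period in hours,
    phase in radians (stored reduced modulo 2*pi), damping per hour,
    drift in photons/frame/hour.
    """

    amplitude: float
    period: float
    phase: float
    damping: float = 0.0
    baseline: float = 0.0
    drift: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.period) or self.period <= 0:
            raise ValueError(f"period must be finite and > 0, got {self.period}")
        for name in ("amplitude", "baseline", "damping"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.phase):
            raise ValueError("phase must be finite")
        object.__setattr__(self, "phase", float(wrap_phase(self.phase)))

    def flux(self, t):
        """Expected photon flux at time(s) ``t`` hours."""
        return expected_flux(
            np.asarray(t, dtype=float),
            self.amplitude,
            self.period,
            self.phase,
            self.damping,
            self.baseline,
            self.drift,
        )


def expected_flux(t, amplitude, period, phase, damping, baseline, drift):
    """Vectorised damped-cosine flux; broadcasts ``t`` against parameter arrays.

    Negative expected counts are clipped at zero (a photon flux cannot be
    negative; clipping only engages when drift or damping drive the model
    below zero).
    """
    t = np.asarray(t, dtype=float)
    osc = amplitude * np.exp(-damping * t) * np.cos(TWO_PI * t / period + phase)
    return np.maximum(0.0, baseline + drift * t + osc)


@dataclass(frozen=True)
class PhaseResponse:
    """Sinusoidal PRC with saturating dose dependence.

    ``k_max`` is the saturating shift magnitude (radians), ``half_dose`` the
    dose producing half-maximal sensitivity (same arbitrary concentration
    units as the applied dose), ``reference_phase`` the circadian phase at
    which the stimulus is neutral.
    """

    k_max: float
    half_dose: float
    reference_phase: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k_max) or self.k_max < 0:
            raise ValueError(f"k_max must be finite and >= 0, got {self.k_max}")
        if not np.isfinite(self.half_dose) or self.half_dose <= 0:
            raise ValueError(f"half_dose must be finite and > 0, got {self.half_dose}")
        object.__setattr__(
            self, "reference_phase", float(wrap_phase(self.reference_phase))
        )

    def sensitivity(self, dose: float) -> float:
        """Saturating dose response k(D) = k_max * D / (D + half_dose)."""
        if dose < 0:
            raise ValueError(f"dose must be >= 0, got {dose}")
        return self.k_max * dose / (dose + self.half_dose)

    def shift(self, phase_at_stimulus, dose: float):
        """Phase shift (radians, sign = advance/delay) for cells at the given
        instantaneous phase(s) when a pulse of ``dose`` arrives."""
        k = self.sensitivity(dose)
        return -k * np.sin(np.asarray(phase_at_stimulus, dtype=float) - self.reference_phase)
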