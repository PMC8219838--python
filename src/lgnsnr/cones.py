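"""Cone outer-segment photocurrent model and its ideal-observer bound.

Each cone's photocurrent response to a cone-contrast waveform ``c(t)``
is modeled as a linear temporal filter (a biphasic difference of two
gamma kernels) plus additive stationary Gaussian noise with a
sum-of-two-Lorentzians power spectral density, independent of the
signal and independent across cones.  Under that model the best
possible detector of a known signal ``s(t)`` is the matched filter,
whose per-cone performance is

    d'^2 = 2 * integral |S(f)|^2 / PSD(f) df        (one-sided PSD)

and the array bound over the cones in the stimulus aperture adds in
d'^2, using the same squared-envelope effective count as the LGN
population model so the two stages are directly comparable.  This bound
caps the SNR any downstream stage (LGN, behavior) can achieve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import gamma as gamma_fn

from lgnsnr.stimuli import StimulusSpec, cone_contrast_waveforms

__all__ = [
    "ConeMosaicModel",
    "ConeCurrentTrace",
    "GapResult",
    "cone_impulse_response",
    "noise_psd",
    "simulate_cone_current",
    "cone_array_dprime",
    "snr_gap",
]


@dataclass(frozen=True)
class ConeMosaicModel:
    """Canonical cone mosaic: density, temporal kernel, noise spectrum.

    Kernel: ``h(t) = g1 * gam(t; tau1, n1) - g2 * gam(t; tau2, n2)``
    with unit-area gamma kernels (n >= 2 gives h(0) = 0 and a delayed
    peak); the slower subtractive lobe produces the biphasic undershoot
    of measured photocurrents.  Noise PSD (one-sided, current^2/Hz):
    ``a1 / (1 + (f/f1)^2) + a2 / (1 + (f/f2)^2)``.

    ``mean_light_level`` is photoisomerizations/s.  Kernel time
    constants scale as ``(L / L_cal)^(-tau_light_exponent)``; the default
    exponent of 0 applies no extrapolation beyond the calibration light
    level, and the mismatch between the operating and calibration levels
    is surfaced via :meth:`light_level_mismatch`.
    """

    density_at_ref: float = 8000.0  # cones/deg^2 at reference eccentricity
    density_slope: float = 0.06  # log10 units per degree
    reference_eccentricity: float = 5.0
    lm_ratio: float = 1.5  # L:M cone ratio (does not affect the bound)
    g1: float = 1.0  # current units per unit contrast
    tau1: float = 0.008  # s
    n1: int = 4
    g2: float = 0.25
    tau2: float = 0.016
    n2: int = 6
    psd_a1: float = 0.012  # current^2/Hz
    psd_f1: float = 8.0  # Hz
    psd_a2: float = 0.004
    psd_f2: float = 60.0
    mean_light_level: float = 8000.0  # R*/s, operating point
    calibration_light_level: float = 5000.0  # R*/s, model provenance
    tau_light_exponent: float = 0.0
    dt: float = 0.001  # s, native simulation step

    def density(self, eccentricity: float) -> float:
        return self.density_at_ref * 10.0 ** (
            -self.density_slope * (eccentricity - self.reference_eccentricity)
        )

    def light_level_mismatch(self) -> float:
        """Ratio of operating to calibration light level (1 = matched)."""
        return self.mean_light_level / self.calibration_light_level

    def effective_taus(self) -> tuple[float, float]:
        scale = self.light_level_mismatch() ** (-self.tau_light_exponent)
        return self.tau1 * scale, self.tau2 * scale


@dataclass(frozen=True)
class ConeCurrentTrace:
    """A simulated photocurrent trace (arbitrary current units)."""

    sample_times: np.ndarray
    current: np.ndarray
    is_noise_free: bool


def _gamma_kernel(t: np.ndarray, tau: float, n: int) -> np.ndarray:
    """Unit-area cascaded-low-pass (gamma) impulse response."""
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = (tp / tau) ** (n - 1) * np.exp(-tp / tau) / (tau * gamma_fn(n))
    return out


def cone_impulse_response(
    model: ConeMosaicModel, dt: float, length: float
) -> np.ndarray:
    """Discrete photocurrent impulse response sampled at ``dt``.

    Biphasic: zero at t = 0, a positive lobe peaking after a short
    delay, then an undershoot.  Raises if ``length`` truncates more than
    1% of the kernel's energy.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau1, tau2 = model.effective_taus()
    t = np.arange(0.0, length, dt)
    kern = model.g1 * _gamma_kernel(t, tau1, model.n1) - model.g2 * _gamma_kernel(
        t, tau2, model.n2
    )
    # energy check on a generous reference support
    t_ref = np.arange(0.0, max(length, 20 * max(tau1 * model.n1, tau2 * model.n2)), dt)
    ref = model.g1 * _gamma_kernel(t_ref, tau1, model.n1) - model.g2 * _gamma_kernel(
        t_ref, tau2, model.n2
    )
    e_ref = float(np.sum(ref**2))
    e_here = float(np.sum(kern**2))
    if e_ref > 0 and e_here < 0.99 * e_ref:
        raise ValueError(
            f"kernel length {length}s truncates energy to {e_here / e_ref:.3f} "
            "of total; increase length"
        )
    return kern


def noise_psd(model: ConeMosaicModel, frequency_hz: np.ndarray) -> np.ndarray:
    """One-sided photocurrent noise PSD (sum of two Lorentzians)."""
    f = np.asarray(frequency_hz, dtype=float)
    return model.psd_a1 / (1.0 + (f / model.psd_f1) ** 2) + model.psd_a2 / (
        1.0 + (f / model.psd_f2) ** 2
    )


def _colored_noise(
    n: int, dt: float, model: ConeMosaicModel, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Gaussian noise with the model's one-sided PSD."""
    freqs = np.fft.rfftfreq(n, dt)
    psd = noise_psd(model, freqs)
    fs = 1.0 / dt
    n_f = len(freqs)
    w = np.empty(n_f, dtype=complex)
    re = rng.standard_normal(n_f)
    im = rng.standard_normal(n_f)
    # interior bins: complex Gaussian; DC and (even-n) Nyquist are real
    w = np.sqrt(psd * fs * n / 4.0) * (re + 1j * im)
    w[0] = np.sqrt(psd[0] * fs * n / 2.0) * re[0]
    if n % 2 == 0:
        w[-1] = np.sqrt(psd[-1] * fs * n / 2.0) * re[-1]
    return np.fft.irfft(w, n=n)


def filter_contrast(
    contrast_waveform: np.ndarray, model: ConeMosaicModel, dt: float
) -> np.ndarray:
    """Noise-free photocurrent: kernel convolved with the contrast."""
    c = np.asarray(contrast_waveform, dtype=float)
    tau1, tau2 = model.effective_taus()
    length = 12 * max(tau1 * model.n1, tau2 * model.n2)
    kern = cone_impulse_response(model, dt, length)
    return np.convolve(c, kern)[: len(c)] * dt


def simulate_cone_current(
    contrast_waveform: np.ndarray,
    model: ConeMosaicModel,
    seed: int | np.random.Generator = 0,
    dt: float | None = None,
    noise: bool = True,
) -> ConeCurrentTrace:
    """Simulate one cone's photocurrent in response to ``c(t)``.

    The signal path is linear filtering by the photocurrent kernel; the
    noise is additive, stationary, Gaussian, signal-independent, with
    the configured PSD.  Deterministic given ``seed``.
    """
    if dt is None:
        dt = model.dt
    signal = filter_contrast(contrast_waveform, model, dt)
    t = np.arange(len(signal)) * dt
    if not noise:
        return ConeCurrentTrace(sample_times=t, current=signal, is_noise_free=True)
    rng = np.random.default_rng(seed)
    current = signal + _colored_noise(len(signal), dt, model, rng)
    return ConeCurrentTrace(sample_times=t, current=current, is_noise_free=False)


def matched_filter_dprime(
    signal: np.ndarray, model: ConeMosaicModel, dt: float
) -> float:
    """Matched-filter d' for one known signal in the model's noise.

    With a two-sided noise spectrum the whitened-correlator result is
    ``d'^2 = integral |S(f)|^2 / N(f) df`` over all frequencies; folding
    onto positive frequencies against the model's one-sided PSD gives
    ``d'^2 = 4 * sum_k |S(f_k)|^2 / PSD(f_k) * df`` with ``S`` the
    (continuous-time, via rfft * dt) Fourier transform of the signal.
    """
    s = np.asarray(signal, dtype=float)
    n = len(s)
    freqs = np.fft.rfftfreq(n, dt)
    spec = np.fft.rfft(s) * dt
    psd = noise_psd(model, freqs)
    df = 1.0 / (n * dt)
    return float(np.sqrt(4.0 * np.sum(np.abs(spec) ** 2 / psd) * df))


def cone_array_dprime(
    spec: StimulusSpec, model: ConeMosaicModel, dt: float | None = None
) -> float:
    """Ideal-observer d' of the cone array for one stimulus condition.

    Per-cone matched-filter d'^2 values add across the (independent)
    cones under the aperture; a cone at spatial offset x sees contrast
    scaled by the Gaussian envelope, so the sum equals the central
    cone's d'^2 times the energy-weighted cone count
    ``density * pi * sigma^2``.  L and M cones see equal-magnitude
    contrast in both color directions, so both contribute identically
    to the bound.  Blanks give d' = 0.
    """
    if dt is None:
        dt = model.dt
    if spec.is_blank or spec.cone_contrast == 0:
        return 0.0
    c_l, _ = cone_contrast_waveforms(spec, dt)
    signal = filter_contrast(c_l, model, dt)
    d_center = matched_filter_dprime(signal, model, dt)
    n_cones = model.density(spec.eccentricity) * np.pi * spec.aperture_sigma**2
    return float(d_center * np.sqrt(n_cones))


class GapResult(NamedTuple):
    """SNR gap between an upstream and a downstream stage."""

    difference: float
    fraction: float  # NaN when the upstream d' is 0
    fraction_defined: bool
    unphysical: bool  # downstream exceeded upstream


def snr_gap(d_upstream: float, d_downstream: float) -> GapResult:
    """Difference and transmitted fraction of d' across a stage boundary.

    SNR cannot physically increase along the visual pathway, but model
    error can make a measured downstream d' exceed the modeled upstream
    bound; such cases are reported as-is with ``unphysical=True`` rather
    than clamped.
    """
    if d_upstream < 0 or d_downstream < 0:
        raise ValueError("d' values must be nonnegative")
    difference = d_upstream - d_downstream
    if d_upstream == 0:
        return GapResult(difference, float("nan"), False, d_downstream > 0)
    return GapResult(
        difference,
        d_downstream / d_upstream,
        True,
        d_downstream > d_upstream,
    )
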