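"""Stimulus definitions and the behavioral sensitivity model.

Stimuli are drifting Gabors defined in cone-contrast space: the L and M
cone contrasts are always equal in magnitude and are either in phase
(L+M, a luminance modulation) or in counterphase (L-M, a chromatic
modulation).  A trapezoidal temporal envelope with slow contrast ramps
avoids onset transients.  The behavioral model is a temporal contrast
sensitivity function (TCSF) per color direction; inverting it places
every stimulus at the observer's detection threshold, up to the display
gamut limit for that direction.  Percent correct in the 2AFC detection
task maps to d' through the standard ideal-observer relation
``pc = Phi(d'/sqrt(2))``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

__all__ = [
    "ColorDirection",
    "GAMUT_CAPS",
    "StimulusSpec",
    "TemporalEnvelope",
    "TCSFFilterParams",
    "TCSFModel",
    "ThresholdResult",
    "EnvelopeError",
    "GamutError",
    "make_envelope",
    "cone_contrast_waveforms",
    "threshold_contrast",
    "pc_to_dprime",
    "dprime_to_pc",
]


class ColorDirection(str, enum.Enum):
    """Direction of joint L/M cone modulation."""

    L_PLUS_M = "L+M"
    L_MINUS_M = "L-M"
    BLANK = "blank"

    @classmethod
    def parse(cls, value: "ColorDirection | str") -> "ColorDirection":
        if isinstance(value, cls):
            return value
        s = str(value).strip()
        aliases = {
            "L+M": cls.L_PLUS_M,
            "L_PLUS_M": cls.L_PLUS_M,
            "LUM": cls.L_PLUS_M,
            "L-M": cls.L_MINUS_M,
            "L_MINUS_M": cls.L_MINUS_M,
            "CHROM": cls.L_MINUS_M,
            "BLANK": cls.BLANK,
        }
        key = s.upper().replace(" ", "")
        if key in aliases:
            return aliases[key]
        raise ValueError(f"unknown color direction: {value!r}")


#: Maximum fractional cone contrast realizable on the display, per direction.
GAMUT_CAPS: dict[ColorDirection, float] = {
    ColorDirection.L_PLUS_M: 0.86,
    ColorDirection.L_MINUS_M: 0.19,
}


class EnvelopeError(ValueError):
    """Raised for an impossible trapezoidal envelope (2*ramp > duration)."""


class GamutError(ValueError):
    """Raised when a requested cone contrast exceeds the display gamut."""


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus condition.

    Parameters
    ----------
    color_direction
        L+M (in-phase), L-M (counterphase) or blank.
    temporal_frequency
        Drift frequency in Hz; ignored (conventionally 0) for blanks.
    cone_contrast
        Fractional cone contrast, identical for the L and M cones.
    duration, ramp
        Total presentation time and linear on/off ramp time, seconds.
    eccentricity
        Retinal eccentricity of the stimulus center, degrees.
    aperture_sigma
        SD of the Gaussian spatial envelope of the Gabor, degrees.
    """

    color_direction: ColorDirection
    temporal_frequency: float = 0.0
    cone_contrast: float = 0.0
    duration: float = 1.0
    ramp: float = 0.166
    eccentricity: float = 5.0
    aperture_sigma: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "color_direction", ColorDirection.parse(self.color_direction)
        )
        if self.color_direction is not ColorDirection.BLANK:
            if self.temporal_frequency <= 0:
                raise ValueError("temporal_frequency must be > 0 for non-blank stimuli")
            cap = GAMUT_CAPS[self.color_direction]
            if not 0 <= self.cone_contrast <= cap:
                raise GamutError(
                    f"cone contrast {self.cone_contrast} outside [0, {cap}] "
                    f"for {self.color_direction.value}"
                )
        if self.ramp < 0 or 2 * self.ramp > self.duration + 1e-12:
            raise EnvelopeError("require 0 <= 2*ramp <= duration")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def is_blank(self) -> bool:
        return self.color_direction is ColorDirection.BLANK


@dataclass(frozen=True)
class TemporalEnvelope:
    """Piecewise-linear trapezoidal contrast gain over the presentation."""

    sample_times: np.ndarray
    gain: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_times.shape != self.gain.shape:
            raise ValueError("sample_times and gain must have matching shapes")


def make_envelope(duration: float, ramp: float, dt: float) -> TemporalEnvelope:
    """Trapezoidal contrast envelope: linear 0->1 over ``ramp``, unity
    plateau, linear 1->0 over the final ``ramp`` seconds.

    ``ramp = 0`` gives a rectangular envelope; ``2*ramp = duration`` a
    triangle.  Raises :class:`EnvelopeError` when ``2*ramp > duration``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if ramp < 0 or 2 * ramp > duration + 1e-12:
        raise EnvelopeError(f"2*ramp ({2 * ramp}) exceeds duration ({duration})")
    t = np.arange(0.0, duration + dt / 2, dt)
    if ramp == 0:
        gain = np.ones_like(t)
    else:
        gain = np.minimum.reduce(
            [np.ones_like(t), t / ramp, (duration - t) / ramp]
        )
        gain = np.clip(gain, 0.0, 1.0)
    return TemporalEnvelope(sample_times=t, gain=gain)


def cone_contrast_waveforms(
    spec: StimulusSpec, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """L and M cone contrast time courses ``(c_L(t), c_M(t))``.

    ``c_L(t) = contrast * gain(t) * sin(2 pi f t)``; the M cone follows
    in phase for L+M and in counterphase for L-M.  Blanks return zeros.
    """
    env = make_envelope(spec.duration, spec.ramp, dt)
    if spec.is_blank:
        z = np.zeros_like(env.sample_times)
        return z, z.copy()
    c_l = (
        spec.cone_contrast
        * env.gain
        * np.sin(2 * np.pi * spec.temporal_frequency * env.sample_times)
    )
    sign = 1.0 if spec.color_direction is ColorDirection.L_PLUS_M else -1.0
    return c_l, sign * c_l


@dataclass(frozen=True)
class TCSFFilterParams:
    """Difference-of-cascaded-low-pass-filters sensitivity model.

    ``sensitivity(f) = |xi1 (i 2 pi f tau1 + 1)^(-n1)
                        - xi2 (i 2 pi f tau2 + 1)^(-n2)|``

    The subtractive second stage produces the bandpass shape of the
    luminance TCSF; with ``xi2 = 0`` the form is a pure cascade low-pass,
    appropriate for the chromatic TCSF.
    """

    xi1: float
    tau1: float
    n1: int
    xi2: float = 0.0
    tau2: float = 1.0
    n2: int = 1

    def sensitivity(self, frequency_hz: float | np.ndarray) -> float | np.ndarray:
        s = 2j * np.pi * np.asarray(frequency_hz, dtype=float)
        h = self.xi1 * (s * self.tau1 + 1) ** (-self.n1)
        if self.xi2 != 0.0:
            h = h - self.xi2 * (s * self.tau2 + 1) ** (-self.n2)
        out = np.abs(h)
        return float(out) if out.ndim == 0 else out


# Defaults calibrated to reproduce the canonical ordering of macaque
# luminance/chromatic temporal contrast sensitivity: chromatic sensitivity
# dominates at 1 Hz, luminance at 20 Hz, with the luminance TCSF bandpass
# (peak near 10 Hz) and the chromatic TCSF low-pass.
DEFAULT_TCSF_PARAMS: dict[ColorDirection, TCSFFilterParams] = {
    ColorDirection.L_PLUS_M: TCSFFilterParams(
        xi1=40.0, tau1=0.008, n1=3, xi2=35.0, tau2=0.016, n2=3
    ),
    ColorDirection.L_MINUS_M: TCSFFilterParams(xi1=90.0, tau1=0.020, n1=3),
}


@dataclass(frozen=True)
class TCSFModel:
    """Behavioral temporal contrast sensitivity per color direction.

    Sensitivity declines log-linearly with eccentricity around a
    reference eccentricity: ``sensitivity *= 10**(-slope * (ecc - ref))``.
    """

    params: dict[ColorDirection, TCSFFilterParams] = field(
        default_factory=lambda: dict(DEFAULT_TCSF_PARAMS)
    )
    eccentricity_slope: float = 0.025  # log10 units per degree
    reference_eccentricity: float = 5.0  # degrees

    def sensitivity(
        self,
        direction: ColorDirection | str,
        frequency_hz: float | np.ndarray,
        eccentricity: float = 5.0,
    ) -> float | np.ndarray:
        direction = ColorDirection.parse(direction)
        if direction is ColorDirection.BLANK:
            raise ValueError("blank stimuli have no contrast sensitivity")
        base = self.params[direction].sensitivity(frequency_hz)
        atten = 10.0 ** (
            -self.eccentricity_slope * (eccentricity - self.reference_eccentricity)
        )
        return base * atten


class ThresholdResult(NamedTuple):
    """Threshold contrast with a flag marking display-gamut clipping."""

    contrast: float
    clipped: bool


def threshold_contrast(
    model: TCSFModel,
    direction: ColorDirection | str,
    frequency_hz: float,
    eccentricity: float = 5.0,
) -> ThresholdResult:
    """Detection-threshold cone contrast ``1/sensitivity``, clipped to the
    direction's gamut cap.

    Clipping is a valid, flagged outcome: the physical display cannot
    produce arbitrarily high cone contrasts, so conditions whose
    threshold exceeds the cap are presented at the cap.
    """
    direction = ColorDirection.parse(direction)
    sens = model.sensitivity(direction, frequency_hz, eccentricity)
    raw = 1.0 / float(sens)
    cap = GAMUT_CAPS[direction]
    if raw > cap:
        return ThresholdResult(contrast=cap, clipped=True)
    return ThresholdResult(contrast=raw, clipped=False)


def pc_to_dprime(pc: float) -> float:
    """Convert 2AFC proportion correct to d' via ``pc = Phi(d'/sqrt 2)``.

    Defined for ``pc`` strictly between 0.5 (chance) and 1.
    """
    if not 0.5 < pc < 1.0:
        raise ValueError(f"proportion correct must lie in (0.5, 1), got {pc}")
    return float(np.sqrt(2.0) * norm.ppf(pc))


def dprime_to_pc(dprime: float) -> float:
    """Inverse of :func:`pc_to_dprime`: expected 2AFC proportion correct."""
    if dprime < 0:
        raise ValueError(f"d' must be nonnegative, got {dprime}")
    return float(norm.cdf(dprime / np.sqrt(2.0)))
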