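"""2D pair-correlation (pCF) between the central detector and detectors at
the four hexagonal radii: diffusion anisotropy and connectivity.

The pair-correlation function between the central element and an element at
distance r and angle theta,

    G_theta(tau, r) = <I(t, 0) I(t + tau, r)> / (<I(t, 0)> <I(t, r)>) - 1,

is computed (analog-corrected) for every element of a distance group.  A
barrier between the two positions suppresses and delays the correlation in
that direction, so comparing amplitudes across angles reads out local
anisotropy, and comparing them against a free-diffusion reference on the
same geometry yields a connectivity value per direction (1 unobstructed,
-> 0 disconnected).

Amplitudes are windowed over one lag decade centered on the expected
transit time r^2/(4 D) and normalized by the concurrent central-detector
autocorrelation amplitude, so that concentration (and excluded-volume)
differences between sample and reference cancel and the ratio isolates
transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlator import (
    DarkCalibration,
    MultiTauScheme,
    TimeTrace,
    autocorrelate_multitau,
    correct_analog,
    crosscorrelate_multitau,
)
from .detector import DetectorArray

__all__ = [
    "PCFResult",
    "compute_pcf",
    "windowed_amplitude",
    "anisotropy_index",
    "build_connectivity_map",
    "distance_group",
]

#: Distance levels -> canonical detector indices (center-to-element distance
#: pitch, sqrt(3) pitch, 2 pitch, sqrt(7) pitch).
_DISTANCE_GROUPS = {
    1: tuple(range(1, 7)),
    2: tuple(range(7, 13)),
    3: tuple(range(13, 19)),
    4: tuple(range(19, 31)),
}


def distance_group(array: DetectorArray, level: int) -> tuple:
    """Detector indices at pCF distance level 1..4."""
    if level not in _DISTANCE_GROUPS:
        raise ValueError(f"distance level must be 1..4, got {level}")
    return _DISTANCE_GROUPS[level]


@dataclass
class PCFResult:
    """Center-to-ring pair correlations at one distance."""

    distance_level: int
    distance_nm: float
    angles: np.ndarray  # radians, per curve
    curves: list  # CorrelationCurve per angle
    center_auto: object  # corrected central-detector autocorrelation
    center_G0: float  # early-lag amplitude of the central autocorrelation
    t_sample: float

    @property
    def lags(self) -> np.ndarray:
        return self.curves[0].lags


def _early_amplitude(curve, n: int = 5) -> float:
    return float(np.mean(curve.values[:n]))


def compute_pcf(
    trace: TimeTrace,
    array: DetectorArray,
    dark: DarkCalibration | None,
    distance_level: int,
    scheme: MultiTauScheme | None = None,
) -> PCFResult:
    """Analog-corrected pCF from the center to every element of one group."""
    scheme = scheme or MultiTauScheme()
    members = distance_group(array, distance_level)
    try:
        for m in (0, *members):
            trace._column(m)
    except KeyError as exc:
        raise ValueError(
            f"trace lacks channels for distance level {distance_level}: {exc}"
        ) from None
    curves = []
    angles = []
    for m in members:
        raw = crosscorrelate_multitau(trace, 0, m, scheme)
        curves.append(correct_analog(raw, dark))
        x, y = array.positions[m]
        angles.append(np.arctan2(y, x))
    auto = correct_analog(autocorrelate_multitau(trace, 0, scheme), dark)
    return PCFResult(
        distance_level=distance_level,
        distance_nm=float(array.radii[members[0]]),
        angles=np.asarray(angles),
        curves=curves,
        center_auto=auto,
        center_G0=_early_amplitude(auto),
        t_sample=trace.t_sample,
    )


def windowed_amplitude(curve, center_lag: float) -> float:
    """Mean G over the lag decade centered (log-wise) on ``center_lag``."""
    lo, hi = center_lag / np.sqrt(10.0), center_lag * np.sqrt(10.0)
    m = (curve.lags >= lo) & (curve.lags <= hi)
    if not m.any():
        raise ValueError("no lags inside the amplitude window")
    return float(curve.values[m].mean())


def _transit_lag(result: PCFResult, D_hat: float) -> float:
    r_um = result.distance_nm * 1e-3
    return r_um**2 / (4.0 * D_hat)


def pcf_amplitudes(result: PCFResult, D_hat: float, normalize: bool = True):
    """Per-angle windowed amplitudes at the transit lag r^2/(4 D_hat).

    With ``normalize`` the amplitudes are divided by the central-detector
    autocorrelation amplitude of the same run (concentration control).
    """
    t0 = _transit_lag(result, D_hat)
    amps = np.array([windowed_amplitude(c, t0) for c in result.curves])
    if normalize:
        if result.center_G0 == 0:
            raise ValueError("central autocorrelation amplitude is zero")
        amps = amps / result.center_G0
    return amps


def anisotropy_index(result: PCFResult, D_hat: float) -> float:
    """1 - min/max of the per-angle windowed amplitudes, clipped to [0, 1].

    0 for isotropic diffusion; -> 1 when one direction is fully blocked.
    Returns NaN when every amplitude is consistent with zero.
    """
    if len(result.curves) < 3:
        raise ValueError("anisotropy needs >= 3 angles")
    amps = pcf_amplitudes(result, D_hat, normalize=False)
    mx = amps.max()
    if mx <= 0:
        return float("nan")
    mn = max(amps.min(), 0.0)
    return float(np.clip(1.0 - mn / mx, 0.0, 1.0))


def build_connectivity_map(
    result: PCFResult, reference: PCFResult, D_hat: float
) -> np.ndarray:
    """Per-direction connectivity: normalized amplitude over the matched
    free-diffusion reference amplitude (1 unobstructed, -> 0 disconnected)."""
    if result.distance_level != reference.distance_level or len(
        result.curves
    ) != len(reference.curves):
        raise ValueError("reference geometry does not match result geometry")
    if not np.allclose(result.angles, reference.angles):
        raise ValueError("reference angles do not match result angles")
    a = pcf_amplitudes(result, D_hat, normalize=True)
    b = pcf_amplitudes(reference, D_hat, normalize=True)
    if np.any(b <= 0):
        raise ValueError("reference amplitudes must be positive")
    return a / b
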