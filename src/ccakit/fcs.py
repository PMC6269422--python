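"""Single-component diffusion fits, number, and brightness.

The corrected autocorrelation of molecules diffusing through a 3D Gaussian
observation volume of lateral waist w and axial/lateral ratio A is

    G(tau) = G0 * (1 + tau/tau_D)^-1 * (1 + tau/(A^2 tau_D))^-1/2,

with tau_D = w^2 / (4 D).  From the amplitude follow the mean occupancy
<N> = gamma / G0 (gamma is the observation-volume shape factor, 2^-3/2 for a
3D Gaussian) and the apparent per-molecule brightness

    B_analog = <I1> * G0 / t_sample        (counts / s / molecule)

which, unlike G0, still carries the detector gain; dividing by the
calibrated gain S_detector = <I1>/N_photons yields the gain-free
B_app = B_analog / S_detector = B_real * QE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

from .correlator import CorrelationCurve

__all__ = [
    "GAMMA_3D_GAUSSIAN",
    "FCSFit",
    "BrightnessModel",
    "diffusion_model",
    "fit_diffusion_model",
    "number_from_amplitude",
    "brightness_analog",
    "apparent_brightness",
    "estimate_detector_gain",
    "FitFailureError",
]

#: Shape factor of a 3D Gaussian observation volume, 2^(-3/2).
GAMMA_3D_GAUSSIAN = 2.0 ** -1.5


class FitFailureError(RuntimeError):
    pass


@dataclass
class FCSFit:
    """Result of a single-component diffusion fit of one correlation curve."""

    G0: float
    tau_D: float  # s
    N: float
    gamma: float
    A: float
    G0_err: float = np.nan
    tau_D_err: float = np.nan
    fit_rms: float = np.nan
    B_analog: float = np.nan  # counts/s per molecule
    B_app: float = np.nan
    fit_range: tuple = ()
    success: bool = True

    def to_dict(self) -> dict:
        return {
            "G0": self.G0,
            "G0_err": self.G0_err,
            "tau_D_s": self.tau_D,
            "tau_D_err_s": self.tau_D_err,
            "N": self.N,
            "gamma": self.gamma,
            "A": self.A,
            "fit_rms": self.fit_rms,
            "B_analog": self.B_analog,
            "B_app": self.B_app,
            "fit_range_s": list(self.fit_range),
            "success": self.success,
        }


@dataclass
class BrightnessModel:
    """Detector gain and optical yield linking analog to real brightness.

    B_app = B_analog / S_detector and B_app = B_real * QE; B_real is only
    resolvable with an external probe calibration, so it defaults to NaN.
    """

    S_detector: float  # counts per photon
    QE: float = np.nan
    B_real: float = np.nan

    def __post_init__(self) -> None:
        if not self.S_detector > 0:
            raise ValueError("S_detector must be positive (run gain calibration)")


def diffusion_model(tau: np.ndarray, G0: float, tau_D: float, A: float) -> np.ndarray:
    """Single-component 3D diffusion correlation model."""
    return G0 / ((1.0 + tau / tau_D) * np.sqrt(1.0 + tau / (A * A * tau_D)))


def fit_diffusion_model(
    curve: CorrelationCurve,
    A: float,
    fit_range: tuple[float, float] | None = None,
    gamma: float = GAMMA_3D_GAUSSIAN,
    weight_floor: float = 1e-6,
    baseline: bool = True,
) -> FCSFit:
    """Weighted least-squares fit of the single-component diffusion model.

    Weights are 1/stderr^2 with stderr floored at ``weight_floor`` (lags with
    NaN stderr get the median weight).  ``fit_range`` defaults to
    [2 * t_sample, 0.1 * longest lag * 8] i.e. the usual reliable window.

    With ``baseline`` a free additive constant is fitted alongside the
    model (standard FCS practice).  Besides slow drifts it absorbs the
    exactly-constant negative offset a closed system imposes on the
    correlation — for N molecules conserved in a volume V the correlation
    is C*(f(tau) - V_eff/V), and without the baseline term tau_D comes out
    low by an amount that grows with V_eff.  G0 reports the amplitude of
    the decaying part only.
    """
    lags = curve.lags
    if fit_range is None:
        fit_range = (2.0 * curve.t_sample, 0.8 * lags[-1])
    lo, hi = fit_range
    mask = (lags >= lo) & (lags <= hi)
    if mask.sum() < 10:
        raise FitFailureError(
            f"only {int(mask.sum())} lags in fit range {fit_range}; need >= 10"
        )
    t = lags[mask]
    g = curve.values[mask]
    se = curve.stderr[mask] if curve.stderr is not None else np.full(t.size, np.nan)
    se = np.where(np.isfinite(se) & (se > 0), se, np.nan)
    med = np.nanmedian(se)
    se = np.where(np.isfinite(se), se, med if np.isfinite(med) else 1.0)
    se = np.maximum(se, weight_floor)

    g0_guess = max(float(np.mean(g[: max(3, t.size // 20)])), 1e-8)
    # crude tau_D guess: first lag where G falls below half the early amplitude
    below = np.flatnonzero(g < 0.5 * g0_guess)
    tau_guess = t[below[0]] if below.size else t[t.size // 2]

    params = lmfit.Parameters()
    params.add("G0", value=g0_guess, min=0.0)
    params.add("tau_D", value=float(tau_guess), min=t[0] * 1e-3, max=t[-1] * 1e3)
    params.add("B", value=0.0, vary=baseline)

    def resid(p):
        model = diffusion_model(t, p["G0"].value, p["tau_D"].value, A)
        return (model + p["B"].value - g) / se

    res = lmfit.minimize(resid, params, method="leastsq")
    if not res.success:
        raise FitFailureError(f"diffusion fit failed: {res.message}")
    G0 = float(res.params["G0"].value)
    tau_D = float(res.params["tau_D"].value)
    fit = FCSFit(
        G0=G0,
        tau_D=tau_D,
        N=number_from_amplitude(G0, gamma) if G0 > 0 else np.nan,
        gamma=gamma,
        A=A,
        G0_err=float(res.params["G0"].stderr or np.nan),
        tau_D_err=float(res.params["tau_D"].stderr or np.nan),
        fit_rms=float(np.sqrt(np.mean((diffusion_model(t, G0, tau_D, A) - g) ** 2))),
        fit_range=(lo, hi),
        success=G0 > 0,
    )
    if curve.mean_a is not None and G0 > 0:
        fit.B_analog = brightness_analog(curve.mean_a, G0, curve.t_sample)
    return fit


def number_from_amplitude(G0: float, gamma: float = GAMMA_3D_GAUSSIAN) -> float:
    """Mean number of molecules in the observation volume, <N> = gamma / G0."""
    if G0 <= 0:
        raise ValueError(f"amplitude must be positive, got {G0}")
    return gamma / G0


def brightness_analog(mean_I1: float, G0: float, t_sample: float) -> float:
    """Apparent molecular brightness in detector counts: <I1> * G0 / t_sample."""
    if t_sample <= 0:
        raise ValueError("t_sample must be positive")
    return mean_I1 * G0 / t_sample


def apparent_brightness(B_analog: float, model: BrightnessModel) -> float:
    """Gain-free apparent brightness B_app = B_analog / S_detector."""
    return B_analog / model.S_detector


def estimate_detector_gain(
    trace_values: np.ndarray,
    dark_mean: float = 0.0,
    dark_var: float = 0.0,
) -> BrightnessModel:
    """Calibrate S_detector from a Poisson-reference acquisition.

    For pure shot noise, photons P have var(P) = mean(P); an analog record
    I = S*P + offset + dark noise then satisfies

        (var(I) - var_dark) / (mean(I) - mean_dark) = S_detector.
    """
    x = np.asarray(trace_values, dtype=np.float64).ravel()
    m = x.mean() - dark_mean
    v = x.var() - dark_var
    if m <= 0 or v <= 0:
        raise ValueError("reference trace not above dark level; cannot calibrate")
    return BrightnessModel(S_detector=float(v / m))
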