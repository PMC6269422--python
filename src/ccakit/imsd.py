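"""iMSD from the amplitude decay of ring-detector spatiotemporal
correlations, with free and confined diffusion model fits.

The spatiotemporal correlation of 2D diffusion observed through Gaussian
volumes is G(xi, eta, tau) ~ exp(-(xi^2 + eta^2)/sigma^2(tau)) with
amplitude

    G(0, 0, tau) = gamma / (N pi sigma^2(tau)),

so the mean-square-displacement proxy sigma^2(tau) can be read off the
amplitude alone:

    sigma_theta^2(tau) = C * <G(0)>_Ring / G_theta(0, tau),

where <G(0)>_Ring is the mean fitted amplitude over the ring detectors
(N = 1 / <G(0)>_Ring) and C is a scale factor fixed once on a
free-diffusion calibration with known sigma^2(0) (the squared detector
waist, in the exp(-xi^2/sigma^2) convention, so free diffusion gives
sigma^2(tau) = sigma^2(0) + 4 D tau).

Ring 2 is used by default: its twelve elements have comparable waists (the
requirement for an unbiased iMSD) and span the ROI, sampling nine signed
spatial lags {-4..4} * pitch along each of the three hexagonal axes.
sigma^2 rises linearly for free diffusion and saturates for confinement at
sigma^2(0) + L_conf^2 / 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

from .correlator import (
    DarkCalibration,
    MultiTauScheme,
    TimeTrace,
    autocorrelate_multitau,
    correct_analog,
    crosscorrelate_multitau,
)
from .detector import DetectorArray
from .fcs import fit_diffusion_model

__all__ = [
    "IMSDResult",
    "Carpet",
    "hex_directions",
    "direction_pairs",
    "compute_ring_correlations",
    "mean_ring_G0",
    "imsd_from_amplitude",
    "calibrate_scale_factor",
    "fit_imsd",
    "run_imsd",
]

#: The three hexagonal axes (radians).
HEX_DIRECTIONS = (0.0, np.pi / 3.0, 2.0 * np.pi / 3.0)


def hex_directions() -> tuple:
    return HEX_DIRECTIONS


@dataclass
class Carpet:
    """G_theta(chi, tau): spatial-lag x temporal-lag correlation matrix."""

    theta: float
    chis: np.ndarray  # signed spatial lags, nm
    lags: np.ndarray  # s
    G: np.ndarray  # (n_chi, n_lag)
    stderr: np.ndarray
    members: tuple  # participating detector indices


def _is_hex_axis(theta: float, tol: float = 1e-6) -> bool:
    return any(abs(theta - t) < tol for t in HEX_DIRECTIONS)


def direction_pairs(
    array: DetectorArray, ring: int, theta: float, tol_nm: float = 1.0
) -> dict:
    """Ordered detector pairs of ``ring`` separated along the axis ``theta``.

    Returns {chi_nm: [(i, j), ...]} where chi is the signed separation of j
    relative to i projected on theta; pairs whose separation has a
    perpendicular component > ``tol_nm`` are excluded.  chi = 0 holds the
    self-pairs (autocorrelations).
    """
    if not _is_hex_axis(theta):
        raise ValueError(f"direction {theta} is not one of the hex axes")
    members = [int(i) for i in np.flatnonzero(array.ring_index == ring)]
    u = np.array([np.cos(theta), np.sin(theta)])
    out: dict = {0.0: [(i, i) for i in members]}
    for i in members:
        for j in members:
            if i == j:
                continue
            d = array.positions[j] - array.positions[i]
            par = float(d @ u)
            perp = abs(float(d[0] * u[1] - d[1] * u[0]))
            if perp <= tol_nm:
                out.setdefault(round(par, 3), []).append((i, j))
    return dict(sorted(out.items()))


def _corrected_pair(trace, i, j, dark, scheme, cache=None):
    """Analog-corrected (cross-)correlation of channels i, j with memoization."""
    key = (int(i), int(j))
    if cache is not None and key in cache:
        return cache[key]
    if i == j:
        raw = autocorrelate_multitau(trace, i, scheme)
    else:
        raw = crosscorrelate_multitau(trace, i, j, scheme)
    cur = correct_analog(raw, dark)
    if cache is not None:
        cache[key] = cur
    return cur


def compute_ring_correlations(
    trace: TimeTrace,
    array: DetectorArray,
    dark: DarkCalibration | None,
    theta: float,
    ring: int = 2,
    scheme: MultiTauScheme | None = None,
    _cache: dict | None = None,
) -> Carpet:
    """Analog-corrected carpet G_theta(chi, tau) for one hex direction.

    Each spatial-lag column averages the corrected cross-correlations of all
    ring pairs with that signed separation along ``theta`` (the chi = 0
    column averages the member autocorrelations).
    """
    scheme = scheme or MultiTauScheme()
    pairs = direction_pairs(array, ring, theta)
    chis = np.array(sorted(pairs.keys()))
    cols = []
    errs = []
    lags = None
    for chi in chis:
        acc = None
        var = None
        for (i, j) in pairs[chi]:
            cur = _corrected_pair(trace, i, j, dark, scheme, _cache)
            lags = cur.lags
            acc = cur.values if acc is None else acc + cur.values
            v = np.square(cur.stderr)
            var = v if var is None else var + v
        n = len(pairs[chi])
        cols.append(acc / n)
        errs.append(np.sqrt(var) / n)
    members = tuple(int(i) for i in np.flatnonzero(array.ring_index == ring))
    return Carpet(
        theta=theta,
        chis=chis,
        lags=lags,
        G=np.vstack(cols),
        stderr=np.vstack(errs),
        members=members,
    )


def ring_member_fits(
    trace: TimeTrace,
    array: DetectorArray,
    dark: DarkCalibration | None,
    ring: int = 2,
    A: float | None = None,
    scheme: MultiTauScheme | None = None,
    _cache: dict | None = None,
) -> list:
    """Single-component diffusion fits of every usable ring member.

    Members whose fit fails are dropped with a warning; fewer than six
    usable members is an error.
    """
    import warnings

    scheme = scheme or MultiTauScheme()
    A = A if A is not None else array.aspect_ratio
    fits = []
    for i in np.flatnonzero(array.ring_index == ring):
        try:
            cur = _corrected_pair(trace, int(i), int(i), dark, scheme, _cache)
            fit = fit_diffusion_model(cur, A)
            if fit.success and fit.G0 > 0:
                fits.append(fit)
            else:
                raise RuntimeError("non-positive amplitude")
        except Exception as exc:  # noqa: BLE001 - member dropped, not fatal
            warnings.warn(f"ring member {i} amplitude fit dropped: {exc}",
                          stacklevel=2)
    if len(fits) < 6:
        raise RuntimeError(f"only {len(fits)} usable ring members; need >= 6")
    return fits


def mean_ring_G0(
    trace: TimeTrace,
    array: DetectorArray,
    dark: DarkCalibration | None,
    ring: int = 2,
    A: float | None = None,
    scheme: MultiTauScheme | None = None,
) -> tuple[float, float]:
    """(<G(0)>_Ring, N): mean fitted amplitude over ring members and the
    ring-average occupancy N = 1/<G(0)>_Ring."""
    fits = ring_member_fits(trace, array, dark, ring, A, scheme)
    mean_g0 = float(np.mean([f.G0 for f in fits]))
    return mean_g0, 1.0 / mean_g0


def axial_decay_factor(lags: np.ndarray, tau_D: float, A: float) -> np.ndarray:
    """sqrt(1 + tau / (A^2 tau_D)): the axial part of the amplitude decay.

    The amplitude of a 3D Gaussian observation decays through lateral
    broadening (the 2D quantity iMSD targets) *and* axial escape.  Dividing
    the amplitude by this factor, with tau_D taken from the concurrent ring
    FCS fits, removes the axial contamination so sigma^2(tau) reflects
    lateral transport alone.
    """
    return np.sqrt(1.0 + lags / (A * A * tau_D))


def imsd_from_amplitude(
    G0_row: np.ndarray,
    lags: np.ndarray,
    mean_G0_ring: float,
    C: float = 1.0,
    stderr: np.ndarray | None = None,
    snr_floor: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """sigma^2(tau) = C <G(0)>_Ring / G_theta(0, tau) on the retained range.

    Lags after the first point where the amplitude falls below
    ``snr_floor`` * stderr (or below zero) are truncated.
    """
    G0_row = np.asarray(G0_row, dtype=float)
    lags = np.asarray(lags, dtype=float)
    keep = G0_row > 0
    if stderr is not None:
        se = np.asarray(stderr, dtype=float)
        keep &= ~(np.isfinite(se) & (G0_row < snr_floor * se))
    n = int(np.argmin(keep)) if not keep.all() else keep.size
    if n == 0:
        raise ValueError("no usable amplitudes: G(0, tau) <= noise everywhere")
    return lags[:n], C * mean_G0_ring / G0_row[:n]


def _free_model(tau, s0, D):
    return s0 + 4.0 * D * tau


def _confined_model(tau, s0, L2, tau_c):
    return s0 + (L2 / 3.0) * (1.0 - np.exp(-tau / tau_c))


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_imsd(
    lags: np.ndarray,
    sigma2: np.ndarray,
    delta_aicc: float = 2.0,
) -> dict:
    """Fit free (sigma0^2 + 4 D tau) and confined
    (sigma0^2 + L^2/3 (1 - exp(-tau/tau_c))) models; pick by corrected AIC.

    "confined" is preferred only when its AICc is lower by ``delta_aicc``.
    Returns model, D_free (um^2/s), L_conf (um), sigma2_0 (um^2), and the
    per-model fit details.
    """
    tau = np.asarray(lags, dtype=float)
    y = np.asarray(sigma2, dtype=float)
    if tau.size < 8:
        raise ValueError(f"need >= 8 retained lags, got {tau.size}")

    # Amplitude-derived sigma^2 has roughly constant *relative* noise, so
    # residuals are weighted by 1/y.
    slope0 = max((y[-1] - y[0]) / (tau[-1] - tau[0]), 1e-12)
    p_free = lmfit.Parameters()
    p_free.add("s0", value=max(y[0], 1e-9), min=0.0)
    p_free.add("D", value=slope0 / 4.0, min=0.0)
    res_free = lmfit.minimize(
        lambda p: (_free_model(tau, p["s0"].value, p["D"].value) - y) / y, p_free
    )

    p_conf = lmfit.Parameters()
    p_conf.add("s0", value=max(y[0], 1e-9), min=0.0)
    p_conf.add("L2", value=max(3.0 * (y[-1] - y[0]), 1e-9), min=0.0)
    p_conf.add("tau_c", value=max(tau[tau.size // 2], tau[0]), min=tau[0] * 1e-3)
    res_conf = lmfit.minimize(
        lambda p: (_confined_model(tau, p["s0"].value, p["L2"].value,
                                   p["tau_c"].value) - y) / y,
        p_conf,
    )

    if not res_free.success and not res_conf.success:
        raise RuntimeError("both iMSD model fits failed to converge")
    rss_free = float(np.sum(res_free.residual**2))
    rss_conf = float(np.sum(res_conf.residual**2))
    aicc_free = _aicc(rss_free, tau.size, 2)
    aicc_conf = _aicc(rss_conf, tau.size, 3)
    model = "confined" if aicc_conf < aicc_free - delta_aicc else "free"

    L2 = float(res_conf.params["L2"].value)
    tau_c = float(res_conf.params["tau_c"].value)
    out = {
        "model": model,
        "D_free": float(res_free.params["D"].value),
        "L_conf": float(np.sqrt(max(L2, 0.0))),
        "sigma2_0": float(
            res_conf.params["s0"].value if model == "confined"
            else res_free.params["s0"].value
        ),
        "tau_c": tau_c,
        # initial slope of the confined model = L^2/(3 tau_c) = 4 D
        "D_confined_initial": L2 / (3.0 * tau_c) / 4.0,
        "aicc": {"free": aicc_free, "confined": aicc_conf},
        "rss": {"free": rss_free, "confined": rss_conf},
    }
    yhat = _free_model(tau, float(res_free.params["s0"].value), out["D_free"])
    tss = max(float(np.sum((y - y.mean()) ** 2)), 1e-300)
    out["r2_linear"] = 1.0 - float(np.sum((yhat - y) ** 2)) / tss
    return out


def calibrate_scale_factor(
    lags: np.ndarray,
    sigma2_uncalibrated: np.ndarray,
    known_sigma2_0: float,
    r2_floor: float = 0.9,
) -> float:
    """Scale factor C from a free-diffusion calibration run.

    Fits the C = 1 curve with the free model and rescales so its tau -> 0
    intercept equals ``known_sigma2_0`` (the squared calibration waist).  A
    poorly linear calibration curve (R^2 below ``r2_floor``) is rejected.
    """
    fit = fit_imsd(lags, sigma2_uncalibrated)
    if fit["r2_linear"] < r2_floor:
        raise RuntimeError(
            f"calibration curve not linear (R^2 = {fit['r2_linear']:.3f}); "
            "use a free-diffusion dataset"
        )
    s0 = fit["sigma2_0"] if fit["model"] == "free" else None
    if s0 is None or s0 <= 0:
        # fall back to the free-model intercept even if AICc preferred confined
        p = np.polyfit(lags, sigma2_uncalibrated, 1)
        s0 = float(p[1])
    if s0 <= 0:
        raise RuntimeError("calibration intercept non-positive")
    return float(known_sigma2_0 / s0)


@dataclass
class IMSDResult:
    directions: tuple
    carpets: list  # Carpet per direction
    sigma2: list  # (lags, sigma2) per direction
    sigma2_mean: tuple  # (lags, sigma2) averaged over directions
    C: float
    mean_G0_ring: float
    N_ring: float
    model: str
    D_free: float  # um^2/s
    L_conf: float  # um
    sigma2_0: float  # um^2
    fits: list  # per-direction fit dicts
    fit_mean: dict

    def to_dict(self) -> dict:
        return {
            "directions_rad": list(self.directions),
            "C": self.C,
            "mean_G0_ring": self.mean_G0_ring,
            "N_ring": self.N_ring,
            "model": self.model,
            "D_free_um2_s": self.D_free,
            "L_conf_um": self.L_conf,
            "sigma2_0_um2": self.sigma2_0,
            "per_direction": [
                {"theta": c.theta, "model": f["model"], "D_free": f["D_free"],
                 "L_conf": f["L_conf"]}
                for c, f in zip(self.carpets, self.fits)
            ],
        }


def run_imsd(
    trace: TimeTrace,
    array: DetectorArray,
    dark: DarkCalibration | None,
    C: float = 1.0,
    ring: int = 2,
    scheme: MultiTauScheme | None = None,
    max_lag_s: float | None = None,
    amp_floor: float = 0.25,
    axial_correction: bool = True,
) -> IMSDResult:
    """Full iMSD analysis on one trace: carpets along the three hex axes,
    sigma^2(tau) per direction and averaged, and the model fit.

    Lags are retained while the amplitude stays above ``amp_floor`` times
    the ring mean amplitude (sigma^2 growth up to ~1/amp_floor of its
    starting value; beyond that the inversion no longer reflects local
    transport) and above 3x its standard error.  With ``axial_correction``
    the amplitude is divided by the known axial decay factor (tau_D from the
    ring FCS fits) so the resulting sigma^2 is purely lateral.
    """
    scheme = scheme or MultiTauScheme()
    cache: dict = {}
    member_fits = ring_member_fits(trace, array, dark, ring, scheme=scheme,
                                   _cache=cache)
    mean_g0 = float(np.mean([f.G0 for f in member_fits]))
    n_ring = 1.0 / mean_g0
    tau_D_ring = float(np.median([f.tau_D for f in member_fits]))
    carpets = []
    sigmas = []
    fits = []
    for theta in HEX_DIRECTIONS:
        carpet = compute_ring_correlations(trace, array, dark, theta, ring,
                                           scheme, _cache=cache)
        i0 = int(np.argmin(np.abs(carpet.chis)))
        row = carpet.G[i0]
        if axial_correction:
            row = row * axial_decay_factor(
                carpet.lags, tau_D_ring, array.aspect_ratio
            )
        keep = row > amp_floor * mean_g0
        n_keep = int(np.argmin(keep)) if not keep.all() else keep.size
        lags, s2 = imsd_from_amplitude(
            row[:n_keep], carpet.lags[:n_keep], mean_g0, C,
            carpet.stderr[i0][:n_keep],
        )
        if max_lag_s is not None:
            m = lags <= max_lag_s
            lags, s2 = lags[m], s2[m]
        carpets.append(carpet)
        sigmas.append((lags, s2))
        fits.append(fit_imsd(lags, s2))
    n_min = min(len(s[0]) for s in sigmas)
    lag_mean = sigmas[0][0][:n_min]
    s2_mean = np.mean([s[1][:n_min] for s in sigmas], axis=0)
    fit_mean = fit_imsd(lag_mean, s2_mean)
    return IMSDResult(
        directions=HEX_DIRECTIONS,
        carpets=carpets,
        sigma2=sigmas,
        sigma2_mean=(lag_mean, s2_mean),
        C=C,
        mean_G0_ring=mean_g0,
        N_ring=n_ring,
        model=fit_mean["model"],
        D_free=fit_mean["D_free"],
        L_conf=fit_mean["L_conf"],
        sigma2_0=fit_mean["sigma2_0"],
        fits=fits,
        fit_mean=fit_mean,
    )
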