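"""Spot-variation FCS: diffusion-time and number laws across nested
virtual pinholes, and the intercept-plot classification.

FCS is run at the four nested virtual-pinhole volumes obtained by summing
detector subsets.  Two straight lines are then fitted:

* tau_D versus w^2 — the diffusion law.  Its intercept tau_D(0) at w^2 = 0
  is zero for free diffusion, positive for microdomain-like trapping and
  negative for meshwork-like hindrance.
* N versus V_eff — the number law.  Its x-axis intercept V_eff(0) (where the
  fitted line reaches N = 0) is zero for a uniform concentration, positive
  when part of the volume is inaccessible (exclusion) and negative when the
  probe is enriched at the center (aggregation).

The pair (V_eff(0), tau_D(0)) places a measurement on the intercept plot;
an axis whose confidence interval covers zero is read as zero, so pure
noise classifies as free/unstructured rather than over-committing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .correlator import (
    DarkCalibration,
    MultiTauScheme,
    TimeTrace,
    autocorrelate_multitau,
    correct_analog,
)
from .detector import DetectorArray, pinhole_configuration
from .fcs import FCSFit, fit_diffusion_model

__all__ = [
    "SpotVariationResult",
    "run_spot_variation",
    "fit_diffusion_law",
    "fit_number_law",
    "classify_intercept_plot",
    "QUADRANTS",
]

QUADRANTS = (
    "free/unstructured",
    "microdomain/exclusion",
    "microdomain/aggregation",
    "meshwork/exclusion",
    "meshwork/aggregation",
)


@dataclass
class LevelResult:
    level: int
    w: float  # nm
    w2: float  # nm^2
    V_eff: float  # um^3
    fit: FCSFit | None
    failed: bool = False


@dataclass
class SpotVariationResult:
    levels: list
    tauD_intercept: float  # s
    tauD_intercept_ci: tuple  # (lo, hi), 95%
    tauD_slope: float  # s / nm^2
    Veff_intercept: float  # um^3 (x-intercept of the number law)
    Veff_intercept_ci: tuple
    quadrant: str
    S_conf_proxy: float  # |tauD_intercept|, s

    def to_dict(self) -> dict:
        return {
            "levels": [
                {
                    "level": l.level,
                    "w_nm": l.w,
                    "V_eff_um3": l.V_eff,
                    "tau_D_s": None if l.fit is None else l.fit.tau_D,
                    "N": None if l.fit is None else l.fit.N,
                    "failed": l.failed,
                }
                for l in self.levels
            ],
            "tauD_intercept_s": self.tauD_intercept,
            "tauD_intercept_ci_s": list(self.tauD_intercept_ci),
            "tauD_slope_s_per_nm2": self.tauD_slope,
            "Veff_intercept_um3": self.Veff_intercept,
            "Veff_intercept_ci_um3": list(self.Veff_intercept_ci),
            "quadrant": self.quadrant,
            "S_conf_proxy_s": self.S_conf_proxy,
        }


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares y = a + b x; returns a, b, cov (chi2-scaled)."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ y)
    resid = y - X @ beta
    dof = x.size - 2
    chi2red = float(resid @ W @ resid) / dof if dof > 0 else np.nan
    # Scale the covariance up when the points scatter more than their stated
    # errors, but never down: with only two residual degrees of freedom a
    # lucky alignment would otherwise collapse the confidence interval.
    cov = np.linalg.inv(XtWX) * max(chi2red, 1.0)
    return float(beta[0]), float(beta[1]), cov, dof


def fit_diffusion_law(
    tauD: np.ndarray, w2: np.ndarray, weights: np.ndarray | None = None,
    confidence: float = 0.95,
) -> dict:
    """Weighted linear fit of tau_D against w^2; intercept at w^2 = 0.

    The confidence interval uses the t distribution on n - 2 degrees of
    freedom with the covariance scaled by reduced chi-square, which with only
    four volumes gives deliberately wide (conservative) intervals.
    """
    tauD = np.asarray(tauD, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if tauD.size < 3:
        raise ValueError("diffusion-law fit needs at least 3 points")
    w = np.ones_like(tauD) if weights is None else np.asarray(weights, float)
    a, b, cov, dof = _wls_line(w2, tauD, w)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    return {
        "intercept": a,
        "slope": b,
        "intercept_se": se,
        "ci": (a - tcrit * se, a + tcrit * se),
        "dof": dof,
    }


def fit_number_law(
    N: np.ndarray, V_eff: np.ndarray, weights: np.ndarray | None = None,
    confidence: float = 0.95,
) -> dict:
    """Weighted linear fit of N against V_eff; x-intercept where N = 0.

    x0 = -a/b with first-order (delta-method) error propagation from the
    joint covariance of intercept a and slope b.
    """
    N = np.asarray(N, dtype=float)
    V = np.asarray(V_eff, dtype=float)
    if N.size < 3:
        raise ValueError("number-law fit needs at least 3 points")
    w = np.ones_like(N) if weights is None else np.asarray(weights, float)
    a, b, cov, dof = _wls_line(V, N, w)
    if b == 0 or abs(b) < 1e-12 * max(abs(a), 1.0):
        return {
            "slope": b,
            "x_intercept": np.nan,
            "x_intercept_se": np.nan,
            "ci": (np.nan, np.nan),
            "dof": dof,
            "undefined": True,
        }
    x0 = -a / b
    # var(x0) ~ (dx0/da)^2 var(a) + (dx0/db)^2 var(b) + 2 cross
    da = -1.0 / b
    db = a / b**2
    var = da * da * cov[0, 0] + db * db * cov[1, 1] + 2 * da * db * cov[0, 1]
    se = float(np.sqrt(max(var, 0.0)))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    return {
        "slope": b,
        "x_intercept": float(x0),
        "x_intercept_se": se,
        "ci": (x0 - tcrit * se, x0 + tcrit * se),
        "dof": dof,
        "undefined": False,
    }


def classify_intercept_plot(
    tauD0: float, tauD0_ci: tuple, Veff0: float, Veff0_ci: tuple
) -> str:
    """Quadrant label from the two intercepts and their confidence intervals.

    y axis (tau_D(0)): + microdomain, - meshwork; x axis (V_eff(0)):
    + exclusion, - aggregation.  An axis whose CI covers zero is neutral;
    both neutral reads free/unstructured.
    """
    def sign(v, ci):
        lo, hi = ci
        if not np.isfinite(v) or (lo <= 0.0 <= hi):
            return 0
        return 1 if v > 0 else -1

    sy = sign(tauD0, tauD0_ci)
    sx = sign(Veff0, Veff0_ci)
    if sy == 0 and sx == 0:
        return "free/unstructured"
    names_y = {1: "microdomain", -1: "meshwork", 0: "neutral"}
    names_x = {1: "exclusion", -1: "aggregation", 0: "neutral"}
    return f"{names_y[sy]}/{names_x[sx]}"


def run_spot_variation(
    trace: TimeTrace,
    array: DetectorArray,
    dark: DarkCalibration | None,
    A: float | None = None,
    scheme: MultiTauScheme | None = None,
    fit_range: tuple | None = None,
    use_weights: bool = True,
) -> SpotVariationResult:
    """FCS at the four nested virtual pinholes, both laws, and the quadrant.

    ``trace`` must carry all the detector channels of the level-4
    configuration in canonical order.  Levels whose FCS fit fails are
    flagged and excluded from the law fits (>=3 levels required).
    """
    A = A if A is not None else array.aspect_ratio
    scheme = scheme or MultiTauScheme()
    levels: list[LevelResult] = []
    for level in (1, 2, 3, 4):
        conf = pinhole_configuration(array, level)
        lr = LevelResult(
            level=level,
            w=conf.effective_waist,
            w2=conf.effective_waist**2,
            V_eff=conf.effective_volume,
            fit=None,
        )
        try:
            raw = autocorrelate_multitau(trace, list(conf.member_indices), scheme)
            cur = correct_analog(raw, dark)
            lr.fit = fit_diffusion_model(cur, A, fit_range=fit_range)
            lr.failed = not lr.fit.success
        except Exception:
            lr.failed = True
        levels.append(lr)

    ok = [l for l in levels if not l.failed and l.fit is not None]
    if len(ok) < 3:
        raise RuntimeError(
            f"only {len(ok)} usable pinhole levels; spot variation needs >= 3"
        )
    w2 = np.array([l.w2 for l in ok])
    tauD = np.array([l.fit.tau_D for l in ok])
    V = np.array([l.V_eff for l in ok])
    N = np.array([l.fit.N for l in ok])
    if use_weights:
        tau_err = np.array(
            [l.fit.tau_D_err if np.isfinite(l.fit.tau_D_err) and l.fit.tau_D_err > 0
             else np.nan for l in ok]
        )
        med = np.nanmedian(tau_err)
        tau_err = np.where(np.isfinite(tau_err), tau_err, med if np.isfinite(med) else 1.0)
        wt_tau = 1.0 / np.maximum(tau_err, 1e-12) ** 2
        # propagate G0 error into N = gamma/G0
        n_err = np.array(
            [abs(l.fit.N) * (l.fit.G0_err / l.fit.G0)
             if np.isfinite(l.fit.G0_err) and l.fit.G0 > 0 else np.nan for l in ok]
        )
        med = np.nanmedian(n_err)
        n_err = np.where(np.isfinite(n_err) & (n_err > 0), n_err,
                         med if np.isfinite(med) else 1.0)
        wt_n = 1.0 / np.maximum(n_err, 1e-12) ** 2
    else:
        wt_tau = wt_n = None

    dl = fit_diffusion_law(tauD, w2, wt_tau)
    nl = fit_number_law(N, V, wt_n)
    quadrant = classify_intercept_plot(
        dl["intercept"], dl["ci"], nl["x_intercept"], nl["ci"]
    )
    return SpotVariationResult(
        levels=levels,
        tauD_intercept=dl["intercept"],
        tauD_intercept_ci=dl["ci"],
        tauD_slope=dl["slope"],
        Veff_intercept=nl["x_intercept"],
        Veff_intercept_ci=nl["ci"],
        quadrant=quadrant,
        S_conf_proxy=abs(dl["intercept"]),
    )
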