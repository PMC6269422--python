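"""Temporal auto/cross-correlation and the analog-detector correction.

All estimators share one internal convention,

    G(tau) = <dI(t) dI(t+tau)> / <I>^2,

estimated per lag k (in samples) with symmetric normalization:

    num(k) = mean(I_a[t] * I_b[t+k]) - mean(I_a[:T-k]) * mean(I_b[k:])
    G(k)   = num(k) / (mean(I_a[:T-k]) * mean(I_b[k:]))

which is algebraically the "<I I>/(<I><I>) - 1" form of the pair-correlation
literature.  Because a constant gain A multiplies the numerator by A^2 and
the mean product by A^2, G is exactly gain-invariant up to rounding.

Analog detectors add an offset process I0(t) (electronic offset + dark
noise + cross-talk) to the photon-driven signal I1(t).  Assuming I0 and I1
are uncorrelated, the corrected correlation of the clean signal is

    G1(tau) = (<dI dI>(tau) - <dI0 dI0>(tau)) / (<I> - <I0>)^2,

where the dark numerators and means come from a dark acquisition
(excitation off), characterized once per instrument/run and reused for every
auto- and cross-curve (the cross extension subtracts the per-pair dark
cross numerator, which captures detector cross-talk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "TimeTrace",
    "CorrelationCurve",
    "DarkCalibration",
    "MultiTauScheme",
    "autocorrelate_direct",
    "autocorrelate_multitau",
    "crosscorrelate_multitau",
    "sum_channels",
    "characterize_dark",
    "correct_analog",
    "ZeroMeanChannelError",
    "SignalBelowDarkError",
]


class ZeroMeanChannelError(ZeroDivisionError):
    """A channel mean is zero; the normalized correlation is undefined."""


class SignalBelowDarkError(ValueError):
    """Signal mean does not exceed the dark mean; correction impossible."""


@dataclass
class TimeTrace:
    """A T x C intensity record with uniform sampling.

    ``values`` are analog counts (arbitrary units) or photon counts;
    ``t_sample`` is the time per row in seconds.
    """

    values: np.ndarray
    t_sample: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError("values must be a (T>=2, C) array")
        if not np.isfinite(self.t_sample) or self.t_sample <= 0:
            raise ValueError("t_sample must be positive")
        self.values = v

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def channel_count(self) -> int:
        return self.values.shape[1]

    def _column(self, canonical: int) -> int:
        """Map a canonical detector index to a column of ``values``.

        Traces carrying only a detector subset list the canonical indices of
        their columns under ``metadata["channels"]``.
        """
        chans = self.metadata.get("channels")
        if chans is None:
            if not 0 <= int(canonical) < self.values.shape[1]:
                raise KeyError(
                    f"channel {canonical} out of range for "
                    f"{self.values.shape[1]}-channel trace"
                )
            return int(canonical)
        try:
            return chans.index(int(canonical))
        except ValueError:
            raise KeyError(
                f"detector {canonical} not present in this trace "
                f"(channels: {chans})"
            ) from None

    def channel(self, spec) -> np.ndarray:
        """Resolve a channel spec (int or iterable of ints = summed set)."""
        if np.isscalar(spec):
            return np.asarray(
                self.values[:, self._column(spec)], dtype=np.float64
            )
        idx = [self._column(i) for i in spec]
        if not idx:
            raise ValueError("empty channel set")
        return np.asarray(self.values[:, idx], dtype=np.float64).sum(axis=1)


def sum_channels(trace: TimeTrace, indices: Iterable[int]) -> TimeTrace:
    """Per-timepoint sum of the selected channels as a new single-channel trace."""
    if not list(indices):
        raise ValueError("empty channel index set")
    idx = [trace._column(i) for i in indices]
    return TimeTrace(
        values=trace.values[:, idx].sum(axis=1, dtype=np.float64)[:, None],
        t_sample=trace.t_sample,
        metadata={
            **{k: v for k, v in trace.metadata.items() if k != "channels"},
            "summed_channels": tuple(int(i) for i in indices),
        },
    )


@dataclass
class MultiTauScheme:
    """Quasi-logarithmic lag grid: ``points_per_cascade`` linear lags, then
    repeated 2x rebinning.  ``lag_cap_s`` defaults to min(1 s, T/8 * dt)."""

    points_per_cascade: int = 16
    n_cascades: int | None = None
    lag_cap_s: float | None = None

    def cap_samples(self, n: int, t_sample: float) -> int:
        cap = n // 8
        if self.lag_cap_s is not None:
            cap = min(cap, int(self.lag_cap_s / t_sample))
        else:
            cap = min(cap, int(1.0 / t_sample))
        return max(cap, 1)


@dataclass
class CorrelationCurve:
    """G(tau) on a lag grid, with the raw pieces needed for the correction.

    ``numerator`` holds the covariance numerators <dI dI>(tau) and
    ``mean_left``/``mean_right`` the windowed means, so that the analog
    correction can be applied after the fact.  ``stderr`` is the
    standard error across trace segments (NaN where segments are too short).
    """

    lags: np.ndarray  # seconds, strictly increasing
    values: np.ndarray
    stderr: np.ndarray
    corrected: bool
    kind: str  # "auto" | "cross"
    channel_spec: object
    t_sample: float
    numerator: np.ndarray | None = None
    mean_left: np.ndarray | None = None
    mean_right: np.ndarray | None = None
    mean_a: float | None = None
    mean_b: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.lags[0] < self.t_sample * (1 - 1e-9):
            raise ValueError("first lag must be >= t_sample")


def _check_mean(x: np.ndarray, what: str) -> float:
    m = float(x.mean())
    if m == 0.0:
        raise ZeroMeanChannelError(
            f"{what} has zero mean; G = <dI dI>/<I>^2 is undefined. "
            "Check channel selection and offset handling."
        )
    return m


def _multitau_raw(
    x: np.ndarray,
    y: np.ndarray,
    t_sample: float,
    scheme: MultiTauScheme,
):
    """Multi-tau numerators/means for a channel pair (x correlated with later y)."""
    m = scheme.points_per_cascade
    if x.size < 2 * m:
        raise ValueError(
            f"trace too short for multi-tau: {x.size} < 2*{m} samples"
        )
    cap = scheme.cap_samples(x.size, t_sample)
    lags_s, nums, mls, mrs = [], [], [], []
    # Work on fluctuations around the global means: num(k) then reduces to
    # mean(dx_L dy_R) - mean(dx_L) mean(dy_R) exactly, avoiding the large
    # <I>^2-scale cancellation that would amplify rounding (and break exact
    # gain invariance) when computed from the raw products.
    gx = float(np.asarray(x, dtype=np.float64).mean())
    gy = float(np.asarray(y, dtype=np.float64).mean())
    xa = np.asarray(x, dtype=np.float64) - gx
    ya = np.asarray(y, dtype=np.float64) - gy
    bin_width = 1
    cascade = 0
    while True:
        ks = range(1, m + 1) if cascade == 0 else range(m // 2 + 1, m + 1)
        done = False
        for k in ks:
            lag_samples = k * bin_width
            if lag_samples > cap or lag_samples >= xa.size * bin_width:
                done = True
                break
            n = xa.size - k
            if n < 1:
                done = True
                break
            num = float(np.dot(xa[:n], ya[k:])) / n
            dml = float(xa[:n].mean())
            dmr = float(ya[k:].mean())
            lags_s.append(lag_samples * t_sample)
            nums.append(num - dml * dmr)
            mls.append(gx + dml)
            mrs.append(gy + dmr)
        if done:
            break
        # 2x rebinning with averaged (not summed) bins: keeps values on the
        # intensity scale so gain cancellation stays exact.
        n2 = (xa.size // 2) * 2
        xa = 0.5 * (xa[0:n2:2] + xa[1:n2:2])
        ya = 0.5 * (ya[0:n2:2] + ya[1:n2:2])
        bin_width *= 2
        cascade += 1
        if scheme.n_cascades is not None and cascade >= scheme.n_cascades:
            break
        if xa.size < m + 1:
            break
    return (
        np.asarray(lags_s),
        np.asarray(nums),
        np.asarray(mls),
        np.asarray(mrs),
    )


def _segment_stderr(
    x: np.ndarray,
    y: np.ndarray,
    t_sample: float,
    scheme: MultiTauScheme,
    lags: np.ndarray,
    n_segments: int = 8,
) -> np.ndarray:
    """Standard error of G across ``n_segments`` equal trace segments.

    Lags beyond the longest segment-supported lag inherit the last available
    estimate (long-lag weights are then conservative, not missing).
    """
    seg_len = x.size // n_segments
    if seg_len < 2 * scheme.points_per_cascade:
        return np.full(lags.size, np.nan)
    curves = []
    for s in range(n_segments):
        sl = slice(s * seg_len, (s + 1) * seg_len)
        try:
            l_s, num, ml, mr = _multitau_raw(x[sl], y[sl], t_sample, scheme)
        except (ValueError, ZeroMeanChannelError):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            g = num / (ml * mr)
        curves.append((l_s, g))
    if len(curves) < 3:
        return np.full(lags.size, np.nan)
    min_len = min(len(c[1]) for c in curves)
    gmat = np.vstack([c[1][:min_len] for c in curves])
    se = gmat.std(axis=0, ddof=1) / np.sqrt(gmat.shape[0])
    out = np.empty(lags.size)
    n_avail = min(min_len, lags.size)
    out[:n_avail] = se[:n_avail]
    out[n_avail:] = se[n_avail - 1] if n_avail else np.nan
    return out


def autocorrelate_direct(
    trace: TimeTrace,
    channel_spec=0,
    max_lag: int | None = None,
) -> CorrelationCurve:
    """Exact linear-lag autocorrelation (the oracle for the multi-tau grid).

    Evaluates G at every integer lag 1..max_lag (default T/8 capped at 1 s).
    O(T * max_lag); intended for traces up to ~2^16 points.
    """
    x = trace.channel(channel_spec)
    if x.size < 4:
        raise ValueError("trace too short for direct correlation (need >= 4)")
    _check_mean(x, f"channel {channel_spec}")
    cap = MultiTauScheme().cap_samples(x.size, trace.t_sample)
    if max_lag is not None:
        cap = min(cap, max_lag)
    lags = np.arange(1, cap + 1)
    gm = float(x.mean())
    d = x - gm
    num_cov = np.empty(cap)
    mls = np.empty(cap)
    mrs = np.empty(cap)
    for i, k in enumerate(lags):
        n = x.size - k
        dml = d[:n].mean()
        dmr = d[k:].mean()
        num_cov[i] = np.dot(d[:n], d[k:]) / n - dml * dmr
        mls[i] = gm + dml
        mrs[i] = gm + dmr
    values = num_cov / (mls * mrs)
    stderr = _segment_stderr(
        x, x, trace.t_sample, MultiTauScheme(), lags * trace.t_sample
    )
    return CorrelationCurve(
        lags=lags * trace.t_sample,
        values=values,
        stderr=stderr,
        corrected=False,
        kind="auto",
        channel_spec=channel_spec,
        t_sample=trace.t_sample,
        numerator=num_cov,
        mean_left=mls,
        mean_right=mrs,
        mean_a=float(x.mean()),
        mean_b=float(x.mean()),
    )


def _correlate_multitau(
    trace: TimeTrace,
    spec_a,
    spec_b,
    scheme: MultiTauScheme,
    kind: str,
) -> CorrelationCurve:
    x = trace.channel(spec_a)
    y = x if (kind == "auto" or spec_b is None) else trace.channel(spec_b)
    _check_mean(x, f"channel {spec_a}")
    if y is not x:
        _check_mean(y, f"channel {spec_b}")
    lags, num, ml, mr = _multitau_raw(x, y, trace.t_sample, scheme)
    values = num / (ml * mr)
    stderr = _segment_stderr(x, y, trace.t_sample, scheme, lags)
    return CorrelationCurve(
        lags=lags,
        values=values,
        stderr=stderr,
        corrected=False,
        kind=kind,
        channel_spec=spec_a if kind == "auto" else (spec_a, spec_b),
        t_sample=trace.t_sample,
        numerator=num,
        mean_left=ml,
        mean_right=mr,
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
    )


def autocorrelate_multitau(
    trace: TimeTrace,
    channel_spec=0,
    scheme: MultiTauScheme | None = None,
) -> CorrelationCurve:
    """Multi-tau autocorrelation of one channel or a summed channel set."""
    return _correlate_multitau(
        trace, channel_spec, None, scheme or MultiTauScheme(), "auto"
    )


def crosscorrelate_multitau(
    trace: TimeTrace,
    channel_a,
    channel_b,
    scheme: MultiTauScheme | None = None,
) -> CorrelationCurve:
    """Multi-tau cross-correlation of channel_a(t) with channel_b(t+tau)."""
    return _correlate_multitau(
        trace, channel_a, channel_b, scheme or MultiTauScheme(), "cross"
    )


class DarkCalibration:
    """Offset/dark statistics from an excitation-off acquisition.

    Stores the per-channel dark means eagerly and computes dark correlation
    numerators lazily (cached) for whatever channel spec or pair the analysis
    requests, on the same multi-tau grid as the signal curves.  With 32
    channels the 528 possible pair numerators would mostly go unused, so lazy
    evaluation keeps calibration cheap without changing any result.
    """

    def __init__(
        self,
        dark: TimeTrace,
        scheme: MultiTauScheme | None = None,
        min_length: int = 10_000,
    ):
        if dark.n_timepoints < min_length:
            warnings.warn(
                f"dark trace has only {dark.n_timepoints} points "
                f"(< {min_length}); dark numerators will be noisy",
                stacklevel=2,
            )
        self._trace = dark
        self.scheme = scheme or MultiTauScheme()
        self.mean_offsets = dark.values.mean(axis=0)
        self.source_length = dark.n_timepoints
        self.t_sample = dark.t_sample
        self.is_zero = not np.any(dark.values)
        self._cache: dict = {}

    @classmethod
    def zeros_like(cls, trace: TimeTrace, scheme=None) -> "DarkCalibration":
        """An identity calibration (no offset, no dark correlation)."""
        z = TimeTrace(
            np.zeros((max(2 * (scheme or MultiTauScheme()).points_per_cascade, 64),
                      trace.channel_count)),
            trace.t_sample,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(z, scheme)

    def _key(self, spec):
        if np.isscalar(spec):
            return int(spec)
        return tuple(int(i) for i in spec)

    def mean_offset(self, spec) -> float:
        if np.isscalar(spec):
            return float(self.mean_offsets[self._trace._column(spec)])
        return float(
            self.mean_offsets[[self._trace._column(i) for i in spec]].sum()
        )

    def numerators(self, spec_a, spec_b=None):
        """Dark covariance numerators <dI0 dI0>(tau) on the analysis grid."""
        key = (self._key(spec_a), None if spec_b is None else self._key(spec_b))
        if key not in self._cache:
            x = self._trace.channel(spec_a)
            y = x if spec_b is None else self._trace.channel(spec_b)
            lags, num, _, _ = _multitau_raw(x, y, self.t_sample, self.scheme)
            self._cache[key] = (lags, num)
        return self._cache[key]

    # Spec-named views
    def dark_autocorr(self, spec):
        return self.numerators(spec, None)

    def dark_crosscorr(self, spec_a, spec_b):
        return self.numerators(spec_a, spec_b)


def characterize_dark(
    dark: TimeTrace,
    scheme: MultiTauScheme | None = None,
    min_length: int = 10_000,
) -> DarkCalibration:
    """Characterize a dark dataset for later analog correction."""
    return DarkCalibration(dark, scheme, min_length)


def correct_analog(
    raw: CorrelationCurve, dark_cal: DarkCalibration | None
) -> CorrelationCurve:
    """Apply the analog-detector correction to a raw correlation curve.

    Subtracts the matched dark numerator per lag and re-normalizes by the
    offset-subtracted means:

        G1(tau) = (num(tau) - num_dark(tau)) / ((mL - <I0_a>)(mR - <I0_b>))

    For cross-curves the per-pair dark cross numerator is used, which removes
    detector cross-talk as well as offset and dark variance.
    """
    if raw.numerator is None:
        raise ValueError("curve lacks raw numerators; cannot correct")
    if dark_cal is None or dark_cal.is_zero:
        dark_num = np.zeros_like(raw.numerator)
        off_a = off_b = 0.0
    else:
        if abs(dark_cal.t_sample - raw.t_sample) > 1e-12 * raw.t_sample:
            raise ValueError("dark calibration sampling time differs from signal")
        if raw.kind == "auto":
            spec_a = spec_b = raw.channel_spec
            dlags, dnum = dark_cal.numerators(raw.channel_spec, None)
        else:
            spec_a, spec_b = raw.channel_spec
            dlags, dnum = dark_cal.numerators(spec_a, spec_b)
        if dlags.size < raw.lags.size or not np.allclose(
            dlags[: raw.lags.size], raw.lags, rtol=1e-9
        ):
            raise ValueError(
                "dark lag grid does not cover the signal lag grid; "
                "use the same scheme and a dark trace at least as long"
            )
        dark_num = dnum[: raw.lags.size]
        off_a = dark_cal.mean_offset(spec_a)
        off_b = dark_cal.mean_offset(spec_b)
    ml = raw.mean_left - off_a
    mr = raw.mean_right - off_b
    if raw.mean_a - off_a <= 0 or raw.mean_b - off_b <= 0:
        raise SignalBelowDarkError(
            "signal mean does not exceed dark mean; nothing to correct"
        )
    num1 = raw.numerator - dark_num
    values = num1 / (ml * mr)
    # stderr: segment variability of the raw curve dominates; rescale by the
    # change of normalization so weights stay consistent.
    with np.errstate(invalid="ignore"):
        scale = (raw.mean_left * raw.mean_right) / (ml * mr)
    stderr = raw.stderr * scale
    return CorrelationCurve(
        lags=raw.lags.copy(),
        values=values,
        stderr=stderr,
        corrected=True,
        kind=raw.kind,
        channel_spec=raw.channel_spec,
        t_sample=raw.t_sample,
        numerator=num1,
        mean_left=ml,
        mean_right=mr,
        mean_a=raw.mean_a - off_a,
        mean_b=raw.mean_b - off_b,
    )
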