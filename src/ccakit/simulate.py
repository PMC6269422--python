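"""Synthetic detector-array fluctuation data with known ground truth.

The generator reproduces the physical chain the analysis assumes: point
emitters doing Brownian motion in a periodic 3D box, observed by Gaussian
detection volumes centered on the hexagonal array elements (lateral 1/e^2
waist w_i per element, axial waist A*w_i), Poisson photon statistics, and an
analog detector model

    I = gain * photons + offset + Normal(0, dark_sigma).

The hidden clean photon trace is always returned alongside the analog trace
so correction and brightness claims can be checked against ground truth.

Structured environments (microdomains, meshworks, barriers, excluded
volumes, confinement cells) act per step: disallowed boundary crossings are
reflected, crossings are accepted with the stated probability, and excluded
regions reject the step.  Defaults follow the instrument conditions the
analysis targets: 2.46 us sampling, D = 30 um^2/s (free GFP-scale mobility),
100 particles in a 1 x 1 x 2 um box (~2 molecules in the largest virtual
pinhole), PMT gain 750 counts/photon, offset 200 counts, dark noise
sigma 20 counts (a dark fluctuation is a small fraction of a photon pulse,
as for a real analog PMT at high gain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .correlator import TimeTrace
from .detector import DetectorArray, build_airyscan_layout

__all__ = [
    "EnvironmentSpec",
    "AnalogModel",
    "SimulationConfig",
    "simulate_trajectories",
    "render_detector_trace",
    "simulate_trace",
    "simulate_dark_trace",
]

_ENV_CODES = {
    "free": K.ENV_FREE,
    "microdomain": K.ENV_MICRODOMAIN,
    "meshwork": K.ENV_MESHWORK,
    "barrier": K.ENV_BARRIER,
    "excluded": K.ENV_EXCLUDED,
    "confined": K.ENV_CONFINED,
}


@dataclass(frozen=True)
class EnvironmentSpec:
    """A diffusion environment; construct via the class-method factories."""

    kind: str = "free"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _ENV_CODES:
            raise ValueError(f"unknown environment kind {self.kind!r}")
        for key in ("escape_prob", "passage_prob", "permeability", "hop_prob"):
            v = self.params.get(key)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{key} must be in [0, 1], got {v}")

    @classmethod
    def free(cls) -> "EnvironmentSpec":
        return cls("free")

    @classmethod
    def microdomain(
        cls, radius: float = 0.1, escape_prob: float = 0.01, grid_pitch: float = 0.5
    ) -> "EnvironmentSpec":
        """Trapping disks of ``radius`` (um) on a square grid; exits from a
        domain are accepted with ``escape_prob`` per attempt, entries freely."""
        return cls(
            "microdomain",
            {"radius": radius, "escape_prob": escape_prob, "grid_pitch": grid_pitch},
        )

    @classmethod
    def meshwork(cls, pitch: float = 0.25, passage_prob: float = 0.05) -> "EnvironmentSpec":
        """Square lateral mesh of line obstacles every ``pitch`` um; crossings
        are accepted with ``passage_prob``, otherwise reflected."""
        return cls("meshwork", {"pitch": pitch, "passage_prob": passage_prob})

    @classmethod
    def barrier(
        cls, x0: float = 0.025, thickness: float = 0.05, permeability: float = 0.0
    ) -> "EnvironmentSpec":
        """A planar barrier x = x0 of finite ``thickness`` (an excluded slab the
        probe cannot enter), crossed with probability ``permeability``.

        Real diffusion obstacles (membranes, fiber bundles) have tens of nm
        of physical extent; a zero-width reflecting line would be nearly
        invisible to amplitude-based readouts because the ~150 nm detection
        volumes overlap both sides of it.
        """
        return cls(
            "barrier",
            {"x0": x0, "thickness": thickness, "permeability": permeability},
        )

    @classmethod
    def excluded_sphere(
        cls, radius: float = 0.08, center: tuple = (0.0, 0.0, 0.0)
    ) -> "EnvironmentSpec":
        """A sphere the probe cannot enter, default centered in the ROI."""
        return cls("excluded", {"radius": radius, "center": tuple(center)})

    @classmethod
    def confined(cls, side: float = 0.4, hop_prob: float = 0.01) -> "EnvironmentSpec":
        """Corral cells of ``side`` um tiling space (one cell centered on the
        ROI); boundary crossings hop with probability ``hop_prob``.

        A small nonzero hop rate is what makes confinement observable to a
        time-averaged correlation estimator: permanently trapped particles
        contribute a static intensity pattern that the mean subtraction
        removes, whereas slow inter-corral exchange re-randomizes cell
        occupancies within the acquisition so the correlation amplitude
        plateaus at the confinement level before the (much slower) hop
        decay.
        """
        return cls("confined", {"side": side, "hop_prob": hop_prob})

    def _packed(self) -> tuple[int, np.ndarray]:
        p = self.params
        kind = self.kind
        if kind == "free":
            arr = np.zeros(1)
        elif kind == "microdomain":
            arr = np.array([p["grid_pitch"], p["radius"], p["escape_prob"]])
        elif kind == "meshwork":
            arr = np.array([p["pitch"], p["passage_prob"]])
        elif kind == "barrier":
            arr = np.array([p["x0"], 0.5 * p["thickness"], p["permeability"]])
        elif kind == "excluded":
            cx, cy, cz = p["center"]
            arr = np.array([cx, cy, cz, p["radius"]])
        else:  # confined
            arr = np.array([p["side"], p.get("hop_prob", 0.01)])
        return _ENV_CODES[kind], arr

    def min_feature(self) -> float:
        """Smallest geometric feature (um) for the step-stability check."""
        p = self.params
        return {
            "free": np.inf,
            "microdomain": p.get("radius", np.inf),
            "meshwork": p.get("pitch", np.inf),
            "barrier": p.get("thickness", np.inf) or np.inf,
            "excluded": p.get("radius", np.inf),
            "confined": p.get("side", np.inf),
        }[self.kind]


@dataclass(frozen=True)
class AnalogModel:
    """Analog conversion I = gain * photons + offset + N(0, dark_sigma)."""

    gain: float = 750.0  # counts per photon (PMT pulse height)
    offset: float = 200.0  # counts
    dark_sigma: float = 20.0  # counts

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.dark_sigma < 0:
            raise ValueError("gain must be > 0 and dark_sigma >= 0")


@dataclass
class SimulationConfig:
    D: float = 30.0  # um^2/s
    n_particles: int = 100
    box: tuple = (1.0, 1.0, 2.0)  # um, periodic
    brightness: float = 0.2  # photons / particle / timepoint at PSF center
    t_sample: float = 2.46e-6  # s
    n_steps: int = 250_000
    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec.free)
    detector: DetectorArray | None = None
    channels: tuple | None = None  # canonical indices to render (None = all)
    analog: AnalogModel = field(default_factory=AnalogModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0 or self.n_particles < 1 or self.brightness < 0:
            raise ValueError("rates and sizes must be positive")
        if self.t_sample <= 0 or self.n_steps < 2:
            raise ValueError("t_sample must be > 0 and n_steps >= 2")
        if self.detector is None:
            self.detector = build_airyscan_layout()
        idx = self.channel_indices()
        wmax = float(self.detector.waists[idx].max()) * 1e-3
        bx, by, bz = self.box
        if bx < 4 * wmax or by < 4 * wmax or bz < 4 * wmax:
            raise ValueError(
                "box must exceed 4x the largest detection waist per axis"
            )

    @property
    def step_sigma(self) -> float:
        return float(np.sqrt(2.0 * self.D * self.t_sample))

    def channel_indices(self) -> np.ndarray:
        if self.channels is None:
            return np.arange(self.detector.n_detectors)
        return np.asarray(list(self.channels), dtype=int)


def _detector_arrays(config: SimulationConfig):
    det = config.detector
    idx = config.channel_indices()
    x = det.positions[idx, 0] * 1e-3  # nm -> um
    y = det.positions[idx, 1] * 1e-3
    w = det.waists[idx] * 1e-3
    wz = det.aspect_ratio * w
    return (
        np.ascontiguousarray(x),
        np.ascontiguousarray(y),
        np.ascontiguousarray(1.0 / w**2),
        np.ascontiguousarray(1.0 / wz**2),
    )


def _initial_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    bx, by, bz = config.box
    n = config.n_particles
    pos = (rng.random((n, 3)) - 0.5) * np.array([bx, by, bz])
    env = config.environment
    if env.kind == "excluded":
        cx, cy, cz = env.params["center"]
        R = env.params["radius"]
        for _ in range(1000):
            bad = (
                (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2 + (pos[:, 2] - cz) ** 2
            ) < R**2
            if not bad.any():
                break
            pos[bad] = (rng.random((int(bad.sum()), 3)) - 0.5) * np.array([bx, by, bz])
    elif env.kind == "barrier":
        x0 = env.params["x0"]
        h = 0.5 * env.params["thickness"]
        for _ in range(1000):
            bad = (pos[:, 0] > x0 - h) & (pos[:, 0] < x0 + h)
            if not bad.any():
                break
            pos[bad, 0] = (rng.random(int(bad.sum())) - 0.5) * bx
    return pos


def _check_stability(config: SimulationConfig) -> None:
    feat = config.environment.min_feature()
    if np.isfinite(feat) and config.step_sigma > 0.5 * feat:
        warnings.warn(
            f"rms step {config.step_sigma:.4f} um exceeds half the smallest "
            f"environment feature ({feat:.4f} um); boundary rules may be "
            "poorly resolved",
            stacklevel=3,
        )


def simulate_trajectories(config: SimulationConfig) -> np.ndarray:
    """Particle paths (n_steps, n_particles, 3) in um, reproducible from seed.

    Materializes every position; intended for tests and small runs.  Use
    :func:`simulate_trace` for long acquisitions.
    """
    _check_stability(config)
    rng = np.random.default_rng(config.seed)
    pos = _initial_positions(config, rng)
    n = config.n_particles
    env_code, env_p = config.environment._packed()
    out = np.empty((config.n_steps, n, 3))
    steps = rng.normal(0.0, config.step_sigma, (config.n_steps, n, 3))
    u = rng.random((config.n_steps, n, 2))
    K.walk_record(pos, steps, u, np.asarray(config.box, dtype=float),
                  env_code, env_p, out)
    return out


def _analog_convert(photons: np.ndarray, analog: AnalogModel,
                    rng: np.random.Generator) -> np.ndarray:
    out = analog.gain * photons + analog.offset
    if analog.dark_sigma > 0:
        out = out + rng.normal(0.0, analog.dark_sigma, photons.shape)
    return out


def render_detector_trace(
    paths: np.ndarray, config: SimulationConfig
) -> tuple[TimeTrace, TimeTrace]:
    """Render recorded paths into (analog_trace, clean_photon_trace)."""
    if paths.shape[1] != config.n_particles:
        raise ValueError("paths second axis must match n_particles")
    det_x, det_y, inv_w2, inv_wz2 = _detector_arrays(config)
    rates = np.zeros((paths.shape[0], det_x.size))
    bright = np.full(config.n_particles, config.brightness)
    K.render_positions(np.ascontiguousarray(paths), det_x, det_y,
                       inv_w2, inv_wz2, bright, rates)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E3779B9]))
    photons = rng.poisson(rates).astype(np.float64)
    analog = _analog_convert(photons, config.analog, rng)
    meta = {"seed": config.seed, "channels": config.channel_indices().tolist()}
    return (
        TimeTrace(analog, config.t_sample, dict(meta, signal="analog")),
        TimeTrace(photons, config.t_sample, dict(meta, signal="photons")),
    )


def simulate_trace(
    config: SimulationConfig, chunk: int = 40_000
) -> tuple[TimeTrace, TimeTrace]:
    """Simulate and render in chunks: (analog_trace, clean_photon_trace)."""
    _check_stability(config)
    rng = np.random.default_rng(config.seed)
    pos = _initial_positions(config, rng)
    env_code, env_p = config.environment._packed()
    det_x, det_y, inv_w2, inv_wz2 = _detector_arrays(config)
    box = np.asarray(config.box, dtype=float)
    bright = np.full(config.n_particles, config.brightness)
    T = config.n_steps
    C = det_x.size
    photons = np.empty((T, C), dtype=np.float64)
    analog = np.empty((T, C), dtype=np.float64)
    done = 0
    while done < T:
        S = min(chunk, T - done)
        steps = config.step_sigma * rng.standard_normal((S, config.n_particles, 3), dtype=np.float32)
        u = rng.random((S, config.n_particles, 2), dtype=np.float32)
        rates = np.zeros((S, C))
        K.walk_render(pos, steps, u, box, env_code, env_p,
                      det_x, det_y, inv_w2, inv_wz2, bright, rates)
        ph = rng.poisson(rates).astype(np.float64)
        photons[done : done + S] = ph
        analog[done : done + S] = _analog_convert(ph, config.analog, rng)
        done += S
    meta = {"seed": config.seed, "channels": config.channel_indices().tolist()}
    return (
        TimeTrace(analog, config.t_sample, dict(meta, signal="analog")),
        TimeTrace(photons, config.t_sample, dict(meta, signal="photons")),
    )


def simulate_dark_trace(
    config: SimulationConfig, n_steps: int | None = None
) -> TimeTrace:
    """Excitation-off acquisition: offset + dark noise only, same layout."""
    T = n_steps or config.n_steps
    C = config.channel_indices().size
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDA12C0DE]))
    photons = np.zeros((T, C))
    analog = _analog_convert(photons, config.analog, rng)
    return TimeTrace(
        analog,
        config.t_sample,
        {
            "seed": config.seed,
            "signal": "dark",
            "channels": config.channel_indices().tolist(),
        },
    )
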