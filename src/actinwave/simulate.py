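"""Synthetic oscillatory traces and traveling-wave TIRF scenes.

Cortical actin waves appear in TIRF time-lapse data as pulse-like intensity
oscillations with periods of roughly 5-100 s that propagate across the
ventral membrane.  Different reporters share the scene's phase up to a
fixed per-channel lag of a few seconds and differ in morphology: formin-type
channels are diffuse "clouds", Arp2/3-type channels are clusters of
stationary puncta whose loci never move during their lifetime.

This module generates such data with exact ground truth so every analysis
stage (extraction, normalization, classification, peak/IPI statistics,
cross-correlation lag, kymograph slope) can be validated without external
recordings.

The intensity model for a channel ``c`` at pixel ``x`` and time ``t`` is::

    I_c(x, t) = bg_c + B(t) * mask(x) * [base_c + amp_c * g(phi - 2*pi*lag_c/P)] * m_c(x)

with phase field ``phi(x, t) = 2*pi*(t/P - d(x)/(v*P))`` (``d`` the planar
or radial propagation coordinate in um, ``v`` the wave speed in um/s,
``P`` the period), ``B(t) = exp(-k_bleach*t)`` the bleaching envelope
(applied to the signal, not to the camera-offset background), and ``m_c``
the morphology factor (1 for diffuse; a fixed sum of Gaussians for puncta).
Noise is a Poisson camera model (gain-scaled shot noise) plus additive
Gaussian read noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidConfigError
from .imaging import ImageStack
from .traces import IntensityTrace

__all__ = [
    "TraceConfig",
    "ChannelSpec",
    "WaveSceneConfig",
    "SceneTruth",
    "make_trace",
    "make_paired_traces",
    "make_wave_scene",
    "save_scene",
]


# ---------------------------------------------------------------------------
# Waveforms.  Both peak at phase 0 with unit height and have zero minimum,
# so `baseline` is exactly the trough level and `baseline + amplitude` the
# peak level of the noiseless signal.
# ---------------------------------------------------------------------------

def _sinusoid(phi: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.cos(phi))


def _raised_cosine_pulse(phi: np.ndarray, duty: float) -> np.ndarray:
    u = np.mod(phi / (2 * np.pi), 1.0)
    dist = np.minimum(u, 1.0 - u)  # distance to nearest pulse center, cycles
    out = np.zeros_like(dist)
    inside = dist < duty / 2
    out[inside] = 0.5 * (1.0 + np.cos(2 * np.pi * dist[inside] / duty))
    return out


def _waveform(phi: np.ndarray, kind: str, duty: float) -> np.ndarray:
    if kind == "sinusoid":
        return _sinusoid(phi)
    if kind == "pulse":
        return _raised_cosine_pulse(phi, duty)
    raise InvalidConfigError(f"unknown waveform {kind!r}")


@dataclass(frozen=True)
class TraceConfig:
    """Parameters of a single synthetic oscillatory trace.

    Defaults describe a typical wave recording: a 300 s acquisition at 1 s
    intervals with a 30 s pulse-train oscillation riding on a cellular
    baseline above a camera-offset background.
    """

    duration: float = 300.0          # s
    frame_interval: float = 1.0      # s
    period: float = 30.0             # s; 0 disables the oscillation
    amplitude: float = 4.0           # intensity units (peak above baseline)
    baseline: float = 5.0            # intensity units (trough level of signal)
    background: float = 1.0          # intensity units (camera offset)
    noise_sd: float = 0.0            # Gaussian noise SD, intensity units
    bleach_rate: float = 0.0         # 1/s exponential decay of the signal
    waveform: Literal["sinusoid", "pulse"] = "pulse"
    duty: float = 0.5                # pulse width as a fraction of the period

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.duration <= 0:
            raise InvalidConfigError("duration and frame_interval must be positive")
        if self.period < 0 or self.amplitude < 0 or self.noise_sd < 0:
            raise InvalidConfigError("period, amplitude, noise_sd must be >= 0")
        if self.period > 0 and self.duration < 2 * self.period:
            raise InvalidConfigError(
                f"duration {self.duration} s must cover >= 2 periods "
                f"({2 * self.period} s)"
            )
        if not 0 < self.duty <= 1:
            raise InvalidConfigError("duty must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.duration / self.frame_interval)) + 1

    def clean_values(self, times: np.ndarray, phase_shift_s: float = 0.0) -> np.ndarray:
        """Noiseless signal at the given times, optionally delayed."""
        t = np.asarray(times, dtype=float) - phase_shift_s
        bleach = np.exp(-self.bleach_rate * np.asarray(times, dtype=float))
        sig = np.full_like(t, self.baseline)
        if self.period > 0:
            sig = sig + self.amplitude * _waveform(
                2 * np.pi * t / self.period, self.waveform, self.duty
            )
        return self.background + bleach * sig


def make_trace(config: TraceConfig, seed: int) -> IntensityTrace:
    """Generate one synthetic trace; identical (config, seed) pairs are
    bit-identical."""
    rng = np.random.default_rng(seed)
    times = np.arange(config.n_samples) * config.frame_interval
    vals = config.clean_values(times)
    if config.noise_sd > 0:
        vals = vals + rng.normal(0.0, config.noise_sd, size=vals.shape)
    return IntensityTrace(times, vals, config.frame_interval)


def make_paired_traces(
    config: TraceConfig, lag: float, seed: int
) -> tuple[IntensityTrace, IntensityTrace]:
    """Two traces whose noiseless parts differ by a pure time shift.

    The second trace is the first delayed by ``lag`` seconds (positive lag:
    its features occur later, i.e. the first channel *precedes* the second).
    Noise realizations are independent.  ``|lag|`` must stay below half a
    period so the shift is identifiable from cross-correlation.
    """
    if config.period <= 0:
        raise InvalidConfigError("paired traces require an oscillatory config")
    if abs(lag) >= config.period / 2:
        raise InvalidConfigError(
            f"|lag| = {abs(lag)} s must be < period/2 = {config.period / 2} s"
        )
    rng_a, rng_b = np.random.default_rng(seed).spawn(2)
    times = np.arange(config.n_samples) * config.frame_interval
    a = config.clean_values(times)
    b = config.clean_values(times, phase_shift_s=lag)
    if config.noise_sd > 0:
        a = a + rng_a.normal(0.0, config.noise_sd, size=a.shape)
        b = b + rng_b.normal(0.0, config.noise_sd, size=b.shape)
    return (
        IntensityTrace(times, a, config.frame_interval),
        IntensityTrace(times, b, config.frame_interval),
    )


# ---------------------------------------------------------------------------
# 2-D + time scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """One reporter channel of a simulated scene.

    ``lag`` is the signed phase offset in seconds relative to the scene
    phase (positive = this channel peaks later).  ``morphology`` selects the
    diffuse "cloud" pattern or a fixed set of stationary Gaussian puncta.
    The noise model is Poisson shot noise at the stated camera ``gain``
    (electrons per count; 0 disables) plus Gaussian read noise.
    """

    name: str
    lag: float = 0.0                     # s
    morphology: Literal["diffuse", "puncta"] = "diffuse"
    puncta_count: int = 30
    puncta_sigma: float = 2.0            # px
    amplitude: float = 40.0              # counts
    baseline: float = 50.0               # counts
    background: float = 10.0             # counts (camera offset)
    gain: float = 1.0                    # counts per photon; 0 = no shot noise
    read_noise_sd: float = 2.0           # counts
    bleach_rate: float = 0.0             # 1/s

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.baseline < 0:
            raise InvalidConfigError("amplitude and baseline must be >= 0")
        if self.morphology == "puncta" and self.puncta_count < 1:
            raise InvalidConfigError("puncta morphology needs puncta_count >= 1")


@dataclass(frozen=True)
class WaveSceneConfig:
    """Full parameterization of a simulated traveling-wave scene.

    The cell is a hard binary ellipse strictly inside the frame so an
    off-cell region always exists for background estimation.  The wave
    phase travels along +x (``planar``) or outward from the mask center
    (``radial``) at ``wave_speed`` um/s.  No quantitative wave speed is
    established for this system; the 0.3 um/s default is a placeholder on
    the scale of one cell diameter per couple of periods.
    """

    frame_count: int = 300
    height_px: int = 128
    width_px: int = 128
    frame_interval: float = 0.6          # s
    pixel_size: float = 0.11             # um/px
    center: tuple[float, float] = (64.0, 64.0)   # (x, y) px
    semi_axes: tuple[float, float] = (50.0, 40.0)  # (a_x, a_y) px
    period: float = 25.0                 # s
    wave_speed: float = 0.3              # um/s
    mode: Literal["planar", "radial"] = "planar"
    waveform: Literal["sinusoid", "pulse"] = "pulse"
    duty: float = 0.5
    channels: tuple[ChannelSpec, ...] = (ChannelSpec("ch0"),)

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise InvalidConfigError("need at least 2 frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise InvalidConfigError("frame_interval and pixel_size must be positive")
        if not 5.0 <= self.period <= 100.0:
            raise InvalidConfigError(
                f"period {self.period} s outside the 5-100 s wave band"
            )
        if self.wave_speed <= 0:
            raise InvalidConfigError("wave_speed must be positive")
        cx, cy = self.center
        ax, ay = self.semi_axes
        if (cx - ax <= 0 or cx + ax >= self.width_px - 1
                or cy - ay <= 0 or cy + ay >= self.height_px - 1):
            raise InvalidConfigError(
                "cell mask must lie strictly inside the frame "
                "(an off-cell background region is required)"
            )
        if not self.channels:
            raise InvalidConfigError("at least one channel required")
        for ch in self.channels:
            if abs(ch.lag) >= self.period / 2:
                raise InvalidConfigError(
                    f"channel {ch.name!r}: |lag| must be < period/2"
                )

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(ch.name for ch in self.channels)


@dataclass
class SceneTruth:
    """Ground truth of a simulated scene, for validating the pipeline."""

    period: float
    wave_speed: float
    mode: str
    lags: dict[str, float]
    cell_mask: np.ndarray
    puncta: dict[str, np.ndarray]        # name -> (n, 2) array of (x, y) px
    clean: dict[str, np.ndarray]         # name -> noiseless T x Y x X field
    seed: int
    config: WaveSceneConfig

    def to_json(self) -> str:
        """Truth record without the bulky arrays (for the sidecar file)."""
        cfg = self.config
        return json.dumps(
            {
                "period_s": self.period,
                "wave_speed_um_s": self.wave_speed,
                "mode": self.mode,
                "lags_s": self.lags,
                "seed": self.seed,
                "frame_interval_s": cfg.frame_interval,
                "pixel_size_um": cfg.pixel_size,
                "cell_ellipse": {
                    "center_xy_px": list(cfg.center),
                    "semi_axes_px": list(cfg.semi_axes),
                },
                "puncta_xy_px": {k: v.tolist() for k, v in self.puncta.items()},
            },
            indent=2,
        )


def _ellipse_mask(cfg: WaveSceneConfig) -> np.ndarray:
    yy, xx = np.mgrid[0:cfg.height_px, 0:cfg.width_px]
    cx, cy = cfg.center
    ax, ay = cfg.semi_axes
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _propagation_coordinate(cfg: WaveSceneConfig) -> np.ndarray:
    """Distance field d(x) in micrometres."""
    yy, xx = np.mgrid[0:cfg.height_px, 0:cfg.width_px]
    if cfg.mode == "planar":
        d_px = xx.astype(float)
    else:  # radial
        cx, cy = cfg.center
        d_px = np.hypot(xx - cx, yy - cy)
    return d_px * cfg.pixel_size


def _puncta_field(
    cfg: WaveSceneConfig, ch: ChannelSpec, rng: np.random.Generator,
    mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed sum-of-Gaussians morphology; loci uniform inside the mask."""
    cx, cy = cfg.center
    ax, ay = cfg.semi_axes
    pts = []
    while len(pts) < ch.puncta_count:
        x = rng.uniform(cx - ax, cx + ax)
        y = rng.uniform(cy - ay, cy + ay)
        if ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 0.81:  # keep off the rim
            pts.append((x, y))
    pts_arr = np.array(pts)
    yy, xx = np.mgrid[0:cfg.height_px, 0:cfg.width_px]
    fld = np.zeros((cfg.height_px, cfg.width_px))
    s2 = 2.0 * ch.puncta_sigma ** 2
    for x, y in pts_arr:
        fld += np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / s2)
    return fld, pts_arr


def make_wave_scene(
    config: WaveSceneConfig, seed: int
) -> tuple[ImageStack, SceneTruth]:
    """Render a multi-channel traveling-wave scene with full ground truth.

    Returns a ``T x Y x X x C`` stack and the matching :class:`SceneTruth`
    (exact per-channel lags, period, puncta loci, cell mask, and per-channel
    noiseless fields).  All randomness derives from one generator seeded by
    ``seed``; identical (config, seed) pairs are bit-identical.
    """
    rng = np.random.default_rng(seed)
    mask = _ellipse_mask(config)
    d_um = _propagation_coordinate(config)
    times = np.arange(config.frame_count) * config.frame_interval
    # phase(x, t), shape T x Y x X
    phi = 2 * np.pi * (
        times[:, None, None] / config.period
        - d_um[None, :, :] / (config.wave_speed * config.period)
    )

    data = np.empty(
        (config.frame_count, config.height_px, config.width_px,
         len(config.channels)),
        dtype=float,
    )
    lags: dict[str, float] = {}
    puncta: dict[str, np.ndarray] = {}
    clean: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(config.channels):
        ch_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        bleach = np.exp(-ch.bleach_rate * times)[:, None, None]
        if ch.morphology == "puncta":
            # each punctum is one structure blinking coherently with the
            # wave phase at its own locus, so its argmax never moves
            _, pts = _puncta_field(config, ch, ch_rng, mask)
            puncta[ch.name] = pts
            yy, xx = np.mgrid[0:config.height_px, 0:config.width_px]
            s2 = 2.0 * ch.puncta_sigma ** 2
            signal = np.zeros_like(phi)
            for x, y in pts:
                if config.mode == "planar":
                    d_i = x * config.pixel_size
                else:
                    d_i = math.hypot(x - config.center[0],
                                     y - config.center[1]) * config.pixel_size
                phi_i = 2 * np.pi * (
                    times / config.period
                    - d_i / (config.wave_speed * config.period)
                    - ch.lag / config.period
                )
                g_i = _waveform(phi_i, config.waveform, config.duty)
                gauss = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / s2)
                signal += (
                    (ch.baseline + ch.amplitude * g_i)[:, None, None]
                    * gauss[None, :, :]
                )
            signal *= bleach * mask[None, :, :]
        else:
            g = _waveform(
                phi - 2 * np.pi * ch.lag / config.period,
                config.waveform, config.duty,
            )
            signal = bleach * mask[None, :, :] * (ch.baseline + ch.amplitude * g)
        field_clean = ch.background + signal
        clean[ch.name] = field_clean
        noisy = field_clean
        if ch.gain > 0:
            noisy = ch_rng.poisson(field_clean / ch.gain) * ch.gain
        if ch.read_noise_sd > 0:
            noisy = noisy + ch_rng.normal(0.0, ch.read_noise_sd, size=field_clean.shape)
        data[..., ci] = noisy
        lags[ch.name] = ch.lag

    stack = ImageStack(
        data, config.frame_interval, config.pixel_size, config.channel_names
    )
    truth = SceneTruth(
        period=config.period,
        wave_speed=config.wave_speed,
        mode=config.mode,
        lags=lags,
        cell_mask=mask,
        puncta=puncta,
        clean=clean,
        seed=seed,
        config=config,
    )
    return stack, truth


def save_scene(stack: ImageStack, truth: SceneTruth, directory) -> None:
    """Write the scene as a multi-channel TIFF plus a JSON truth sidecar."""
    from pathlib import Path

    from .imaging import write_stack

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(stack, directory / "scene.tif")
    (directory / "truth.json").write_text(truth.to_json())
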