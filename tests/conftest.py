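import numpy as np
import pytest

from actinwave.imaging import ImageStack
from actinwave.simulate import ChannelSpec, WaveSceneConfig, make_wave_scene
from actinwave.traces import NormalizedTrace


def brute_force_peaks(values, w: int) -> list[int]:
    """O(n*w) reference peak caller: strict local maxima within +/-w samples."""
    values = np.asarray(values, dtype=float)
    out = []
    for i in range(len(values)):
        lo, hi = max(0, i - w), min(len(values), i + w + 1)
        if all(values[i] > values[j] for j in range(lo, hi) if j != i):
            out.append(i)
    return out


def as_normalized(trace) -> NormalizedTrace:
    """Wrap a raw trace's samples as a NormalizedTrace without rescaling."""
    return NormalizedTrace(trace.times, trace.values, trace.frame_interval)


@pytest.fixture
def random_stack():
    rng = np.random.default_rng(42)
    data = rng.integers(0, 4096, size=(10, 32, 32)).astype(np.uint16)
    return ImageStack(data, frame_interval=1.0, pixel_size=0.11)


@pytest.fixture(scope="session")
def two_channel_scene():
    """Noisy two-channel scene: diffuse lead channel, puncta channel +2.4 s."""
    cfg = WaveSceneConfig(
        frame_count=300,
        height_px=96,
        width_px=96,
        frame_interval=0.6,
        center=(48.0, 48.0),
        semi_axes=(38.0, 30.0),
        period=25.0,
        channels=(
            ChannelSpec("lead", lag=0.0, morphology="diffuse"),
            ChannelSpec("trail", lag=2.4, morphology="puncta",
                        puncta_count=25, puncta_sigma=2.5),
        ),
    )
    stack, truth = make_wave_scene(cfg, seed=11)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    """Single diffuse channel, all noise sources off."""
    cfg = WaveSceneConfig(
        frame_count=300,
        height_px=96,
        width_px=96,
        frame_interval=0.6,
        center=(48.0, 48.0),
        semi_axes=(38.0, 30.0),
        period=25.0,
        channels=(ChannelSpec("a", gain=0.0, read_noise_sd=0.0),),
    )
    stack, truth = make_wave_scene(cfg, seed=5)
    return cfg, stack, truth
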