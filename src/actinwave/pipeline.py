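"""End-to-end runs: simulate/load -> extract -> analyze -> phase -> report.

A run is fully described by a :class:`RunConfig` (typically loaded from a
YAML file) plus a seed; identical (config, seed) pairs produce
byte-identical CSV outputs.  Every analysis parameter is resolved to an
explicit value and echoed in the run manifest, so a manifest suffices to
replay a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidConfigError
from .imaging import ImageStack, RoiSpec, read_stack, reslice
from .oscillation import (
    BAND_DEFAULT,
    DOMINANCE_FACTOR,
    HALF_WINDOW_DEFAULT,
    POWER_RATIO_THRESHOLD,
    classify_oscillation,
    detect_peaks,
    oscillation_stats,
)
from .phase import align_cycles, crosscorr_lag
from .simulate import ChannelSpec, WaveSceneConfig, make_wave_scene, save_scene
from .traces import (
    DEFAULT_N_BASELINE,
    estimate_background,
    extract_roi_trace,
    normalize_trace,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "load_config"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    simulate: WaveSceneConfig | None = None
    input_path: str | None = None
    frame_interval: float | None = None      # override for external TIFFs
    pixel_size: float | None = None
    channel_names: tuple[str, ...] | None = None
    rois: tuple[RoiSpec, ...] = ()
    background_roi: RoiSpec | None = None
    band: tuple[float, float] = BAND_DEFAULT
    power_ratio_threshold: float = POWER_RATIO_THRESHOLD
    dominance: float = DOMINANCE_FACTOR
    half_window: float = HALF_WINDOW_DEFAULT
    n_baseline: int = DEFAULT_N_BASELINE
    max_lag: float | None = None             # None: half the dominant period
    align_window: float | None = None        # None: one dominant period
    reference_channel: str | None = None     # None: first channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_path is None:
            raise InvalidConfigError("config needs either 'simulate' or 'input'")
        if self.simulate is not None and self.input_path is not None:
            raise InvalidConfigError("'simulate' and 'input' are exclusive")


@dataclass
class RunResult:
    outdir: Path
    traces_csv: Path
    oscillation_csv: Path
    lags_csv: Path
    profiles_csv: Path | None
    kymograph_csv: Path
    manifest: Path


def _parse_roi(d: dict[str, Any]) -> RoiSpec:
    return RoiSpec(x=int(d["x"]), y=int(d["y"]), size=int(d.get("size", 20)))


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulate" in raw:
        s = dict(raw["simulate"])
        chans = tuple(ChannelSpec(**c) for c in s.pop("channels", [{"name": "ch0"}]))
        for key in ("center", "semi_axes"):
            if key in s:
                s[key] = tuple(s[key])
        sim = WaveSceneConfig(channels=chans, **s)
    inp = raw.get("input", {})
    if inp and "path" in inp and inp.get("frame_interval") is None and sim is None:
        # the TIFF itself may carry metadata; read_stack enforces presence
        pass
    kwargs: dict[str, Any] = {}
    for key in (
        "band", "power_ratio_threshold", "dominance", "half_window",
        "n_baseline", "max_lag", "align_window", "reference_channel", "seed",
    ):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "band" else raw[key]
    return RunConfig(
        simulate=sim,
        input_path=inp.get("path"),
        frame_interval=inp.get("frame_interval"),
        pixel_size=inp.get("pixel_size"),
        channel_names=tuple(inp["channel_names"]) if inp.get("channel_names") else None,
        rois=tuple(_parse_roi(r) for r in raw.get("rois", [])),
        background_roi=_parse_roi(raw["background_roi"]) if raw.get("background_roi") else None,
        **kwargs,
    )


def _default_rois(stack: ImageStack, sim: WaveSceneConfig | None) -> tuple[RoiSpec, ...]:
    h, w = stack.shape_yx
    if sim is not None:
        cx, cy = sim.center
    else:
        cx, cy = w / 2, h / 2
    size = 20 if min(h, w) >= 24 else max(1, min(h, w) // 2)
    return (RoiSpec(int(cx - size / 2), int(cy - size / 2), size),)


def _default_background_roi(stack: ImageStack, sim: WaveSceneConfig | None) -> RoiSpec:
    # top-left corner; the simulator guarantees the mask clears the frame edge
    size = min(10, *stack.shape_yx)
    return RoiSpec(0, 0, size)


def _obtain_stack(cfg: RunConfig, outdir: Path):
    if cfg.simulate is not None:
        stack, truth = make_wave_scene(cfg.simulate, cfg.seed)
        save_scene(stack, truth, outdir)
        return stack, truth
    if cfg.input_path is None:
        raise InvalidConfigError("no input configured")
    stack = read_stack(
        cfg.input_path,
        frame_interval=cfg.frame_interval,
        pixel_size=cfg.pixel_size,
        channel_names=cfg.channel_names,
    )
    return stack, None


def run_pipeline(cfg: RunConfig, outdir) -> RunResult:
    """Execute a full run and write tidy CSV outputs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, truth = _obtain_stack(cfg, outdir)
    names = list(stack.channel_names or [f"ch{i}" for i in range(stack.n_channels)])
    rois = cfg.rois or _default_rois(stack, cfg.simulate)
    bg_roi = cfg.background_roi or _default_background_roi(stack, cfg.simulate)

    duration = (stack.n_frames - 1) * stack.frame_interval
    band = cfg.band
    band_clamped = False
    if duration < 2 * band[1]:
        band = (band[0], duration / 2)
        band_clamped = True
        if band[1] <= band[0]:
            raise InvalidConfigError(
                f"trace duration {duration:.1f} s too short for band {cfg.band}"
            )

    cell_mask = truth.cell_mask if truth is not None else None
    trace_rows, osc_rows, lag_rows = [], [], []
    profiles_frames = []
    ntraces: dict[tuple[int, str], Any] = {}
    calls: dict[tuple[int, str], Any] = {}
    peaks_by: dict[tuple[int, str], Any] = {}

    for ri, roi in enumerate(rois):
        for ch in names:
            bg = estimate_background(stack, bg_roi, channel=ch, cell_mask=cell_mask)
            raw = extract_roi_trace(stack, roi, channel=ch)
            nt = normalize_trace(raw, bg, n_baseline=cfg.n_baseline)
            ntraces[(ri, ch)] = nt
            trace_rows.append(pd.DataFrame({
                "roi": ri, "channel": ch, "time_s": raw.times,
                "raw": raw.values, "relative_intensity": nt.values,
            }))
            call = classify_oscillation(
                nt, band=band,
                power_ratio_threshold=cfg.power_ratio_threshold,
                dominance=cfg.dominance,
            )
            calls[(ri, ch)] = call
            pk = detect_peaks(nt, half_window=cfg.half_window)
            peaks_by[(ri, ch)] = pk
            st = oscillation_stats(nt, pk)
            osc_rows.append({
                "roi": ri, "channel": ch,
                "is_oscillatory": call.is_oscillatory,
                "dominant_period_s": call.dominant_period,
                "peak_power_ratio": call.peak_power_ratio,
                "n_peaks": st.n_peaks,
                "ipi_mean_s": st.ipi_mean, "ipi_sd_s": st.ipi_sd,
                "amp_mean": st.amp_mean, "amp_sd": st.amp_sd,
                "background_used": nt.background_used,
                "baseline_used": nt.baseline_used,
            })

        ref = cfg.reference_channel or names[0]
        ref_call = calls[(ri, ref)]
        period = ref_call.dominant_period
        max_lag = cfg.max_lag if cfg.max_lag is not None else (
            period / 2 if period else band[0] / 2
        )
        for a in names:
            for b in names:
                if a >= b:
                    continue
                est = crosscorr_lag(ntraces[(ri, a)], ntraces[(ri, b)], max_lag)
                lag_rows.append({
                    "roi": ri, "channel_a": a, "channel_b": b,
                    "lag_s": est.lag, "peak_correlation": est.peak_correlation,
                    "max_lag_s": est.max_lag, "method": est.method,
                })
        if len(names) >= 2 and len(peaks_by[(ri, ref)]) > 0:
            window = cfg.align_window if cfg.align_window is not None else (
                period if period else band[0]
            )
            for fol in names:
                if fol == ref:
                    continue
                try:
                    pr, pf = align_cycles(
                        ntraces[(ri, ref)], peaks_by[(ri, ref)],
                        ntraces[(ri, fol)], window,
                    )
                except Exception:
                    continue
                profiles_frames.append(pd.DataFrame({
                    "roi": ri, "reference": ref, "follower": fol,
                    "relative_time_s": pr.rel_times,
                    "mean_ref": pr.mean, "sd_ref": pr.sd,
                    "mean_follower": pf.mean, "sd_follower": pf.sd,
                    "n_cycles": pr.n_cycles,
                }))

    # kymograph along the horizontal midline, first channel
    h, w = stack.shape_yx
    y_mid = (cfg.simulate.center[1] if cfg.simulate else h / 2)
    kymo = reslice(stack.channel(names[0]), (0, y_mid), (w - 1, y_mid), width=1)
    kymo_df = pd.DataFrame(
        kymo.data,
        index=pd.Index(kymo.distances_um, name="distance_um"),
        columns=[f"t_{t:.4g}" for t in kymo.times_s],
    )

    traces_csv = outdir / "traces.csv"
    osc_csv = outdir / "oscillation.csv"
    lags_csv = outdir / "lags.csv"
    prof_csv = outdir / "profiles.csv" if profiles_frames else None
    kymo_csv = outdir / "kymograph.csv"
    pd.concat(trace_rows, ignore_index=True).to_csv(
        traces_csv, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    pd.DataFrame(osc_rows).to_csv(
        osc_csv, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    pd.DataFrame(
        lag_rows,
        columns=["roi", "channel_a", "channel_b", "lag_s",
                 "peak_correlation", "max_lag_s", "method"],
    ).to_csv(lags_csv, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    if prof_csv is not None:
        pd.concat(profiles_frames, ignore_index=True).to_csv(
            prof_csv, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    kymo_df.to_csv(kymo_csv, float_format=_FLOAT_FMT, lineterminator="\n")

    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({
        "actinwave_version": __version__,
        "seed": cfg.seed,
        "input": cfg.input_path,
        "simulated": cfg.simulate is not None,
        "frame_interval_s": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
        "channels": names,
        "rois": [dataclasses.asdict(r) for r in rois],
        "background_roi": dataclasses.asdict(bg_roi),
        "band_s": list(band),
        "band_clamped_to_duration": band_clamped,
        "power_ratio_threshold": cfg.power_ratio_threshold,
        "dominance": cfg.dominance,
        "half_window_s": cfg.half_window,
        "n_baseline": cfg.n_baseline,
        "max_lag_s": cfg.max_lag,
        "align_window_s": cfg.align_window,
        "outputs": [p.name for p in
                    (traces_csv, osc_csv, lags_csv, kymo_csv)
                    ] + ([prof_csv.name] if prof_csv else []),
    }, indent=2))
    return RunResult(outdir, traces_csv, osc_csv, lags_csv, prof_csv,
                     kymo_csv, manifest)
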