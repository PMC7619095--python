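"""Plain-text / WAV serialization of the pipeline's data objects."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .analysis import TrialSet
from .encoder import SpikeRaster
from .neuron import SimResult
from .stimuli import AudioClip


def save_clip(clip: AudioClip, path: str | Path,
              metadata: dict | None = None) -> None:
    """Write a clip as float32 WAV plus a JSON sidecar with label/rate."""
    path = Path(path)
    wavfile.write(path, int(clip.rate), clip.samples.astype(np.float32))
    sidecar = {"label": clip.label, "rate_hz": clip.rate,
               "units": "Pa", **(metadata or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_clip(path: str | Path) -> AudioClip:
    path = Path(path)
    rate, samples = wavfile.read(path)
    label = ""
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label", "")
        rate = meta.get("rate_hz", rate)
    return AudioClip(np.asarray(samples, dtype=float), rate=float(rate),
                     label=label)


def save_raster(raster: SpikeRaster, path: str | Path,
                seed: int | None = None) -> None:
    """Two-column CSV (channel_id, spike_time_ms) + JSON header."""
    path = Path(path)
    rows = [(c, t) for c, times in enumerate(raster.spikes) for t in times]
    pd.DataFrame(rows, columns=["channel_id", "spike_time_ms"]).to_csv(
        path, index=False)
    header = {"n_channels": raster.n_channels,
              "duration_ms": raster.duration_ms,
              "cf_khz": raster.cf_khz.tolist()}
    if seed is not None:
        header["seed"] = seed
    path.with_suffix(".json").write_text(json.dumps(header))


def load_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    n = header["n_channels"]
    spikes = [np.array([], dtype=float) for _ in range(n)]
    for c, grp in df.groupby("channel_id"):
        spikes[int(c)] = np.sort(grp["spike_time_ms"].to_numpy(dtype=float))
    return SpikeRaster(spikes=spikes,
                       cf_khz=np.asarray(header["cf_khz"]),
                       duration_ms=header["duration_ms"])


def save_trial_set(trials: TrialSet, path: str | Path) -> None:
    """Two-column CSV (trial_id, time_ms) of per-trial spike times."""
    rows = [(i, t) for i, times in enumerate(trials.trials) for t in times]
    pd.DataFrame(rows, columns=["trial_id", "time_ms"]).to_csv(
        Path(path), index=False)


def load_trial_set(path: str | Path, window_ms: tuple[float, float],
                   n_trials: int | None = None,
                   spont_window_ms: tuple[float, float] = (-500.0, 0.0),
                   stimulus_id: str = "") -> TrialSet:
    """Read (trial_id, time_ms) CSV into a TrialSet.

    ``n_trials`` forces the trial count (trials without spikes would
    otherwise be dropped when they are the last ones).
    """
    df = pd.read_csv(path)
    n = int(n_trials if n_trials is not None
            else df["trial_id"].max() + 1 if len(df) else 1)
    trials = [np.array([], dtype=float) for _ in range(n)]
    for i, grp in df.groupby("trial_id"):
        trials[int(i)] = grp["time_ms"].to_numpy(dtype=float)
    return TrialSet(trials=trials, window_ms=window_ms,
                    spont_window_ms=spont_window_ms,
                    stimulus_id=stimulus_id)


def save_sim_result(result: SimResult, out_prefix: str | Path) -> None:
    """Spike-time CSV, long-format voltage table, conductance summaries."""
    prefix = Path(out_prefix)
    pd.DataFrame({"spike_time_ms": result.spike_times_ms}).to_csv(
        Path(f"{prefix}_spikes.csv"), index=False)
    n_steps, n_comp = result.v_m.shape
    v_long = pd.DataFrame({
        "time_ms": np.repeat(result.t_ms, n_comp),
        "comp_id": np.tile(np.arange(n_comp), n_steps),
        "v_mv": result.v_m.ravel(),
    })
    v_long.to_csv(Path(f"{prefix}_voltage.csv"), index=False)
    cond = pd.DataFrame(result.s_ampa,
                        columns=[f"s_ampa_d{d}" for d in
                                 range(result.n_dendrites)])
    cond.insert(0, "time_ms", result.t_ms)
    cond.to_csv(Path(f"{prefix}_conductance.csv"), index=False)
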