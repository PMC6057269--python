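"""File interchange: TIFF movies, key-value config sidecars, CSV tables.

Movies are written as one multi-page TIFF per channel plus a flat
``config.txt`` sidecar and a ``ground_truth.csv`` with one row per event;
cytometry populations and particle tracks round-trip through CSV with
documented headers.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synth import (
    ChannelModel,
    CytometryPopulation,
    EventSpec,
    ImagingConfig,
    MovieStack,
    ParticleTrackSet,
)

__all__ = [
    "write_movie",
    "read_movie",
    "write_cytometry",
    "read_cytometry",
    "write_tracks",
    "read_tracks",
    "write_provenance",
]

_CONFIG_FILE = "config.txt"
_TRUTH_FILE = "ground_truth.csv"


def _format_value(v) -> str:
    if isinstance(v, (tuple, list)):
        return ",".join(str(x) for x in v)
    return str(v)


def write_movie(stack: MovieStack, directory: str | Path) -> Path:
    """Write one multi-page TIFF per channel plus a key-value config sidecar
    and the ground-truth event table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, channel in enumerate(stack.channels):
        tifffile.imwrite(
            directory / f"{channel.name}.tif",
            stack.intensities[i].astype(np.float32),
        )
    lines = [f"{k}={_format_value(v)}" for k, v in asdict(stack.config).items()]
    lines.append(f"channels={','.join(c.name for c in stack.channels)}")
    lines.append(
        f"z_sensitive={','.join(str(int(c.z_sensitive)) for c in stack.channels)}"
    )
    (directory / _CONFIG_FILE).write_text("\n".join(lines) + "\n")
    truth = pd.DataFrame([asdict(e) for e in stack.ground_truth])
    truth.to_csv(directory / _TRUTH_FILE, index=False)
    return directory


def _parse_config(text: str) -> tuple[ImagingConfig, tuple[ChannelModel, ...]]:
    raw = {}
    for line in text.strip().splitlines():
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()
    names = raw.pop("channels").split(",")
    flags = [bool(int(x)) for x in raw.pop("z_sensitive").split(",")]
    channels = tuple(ChannelModel(n, f) for n, f in zip(names, flags))
    kwargs = {
        "pixel_size_um": float(raw["pixel_size_um"]),
        "frame_interval_s": float(raw["frame_interval_s"]),
        "n_frames": int(raw["n_frames"]),
        "height_px": int(raw["height_px"]),
        "width_px": int(raw["width_px"]),
        "psf_sigma_px": float(raw["psf_sigma_px"]),
        "evanescent_depth_nm": float(raw["evanescent_depth_nm"]),
        "channel_gains": tuple(float(x) for x in raw["channel_gains"].split(",")),
        "background_level": float(raw["background_level"]),
        "photon_scale": float(raw["photon_scale"]),
        "read_noise_sd": float(raw["read_noise_sd"]),
        "rng_seed": int(raw["rng_seed"]),
    }
    return ImagingConfig(**kwargs), channels


def _parse_truth(table: pd.DataFrame) -> list[EventSpec]:
    events = []
    for _, row in table.iterrows():
        scission = row["scission_time_s"]
        fall_start = row.get("fall_start_s", np.nan)
        events.append(
            EventSpec(
                event_id=int(row["event_id"]),
                x_px=float(row["x_px"]),
                y_px=float(row["y_px"]),
                t_start_s=float(row["t_start_s"]),
                lifetime_s=float(row["lifetime_s"]),
                amplitudes=tuple(
                    float(x) for x in str(row["amplitudes"]).strip("()").split(",") if x
                ),
                channel_offsets_s=tuple(
                    float(x)
                    for x in str(row["channel_offsets_s"]).strip("()").split(",")
                    if x
                ),
                rise_tau_s=float(row["rise_tau_s"]),
                fall_tau_s=float(row["fall_tau_s"]),
                fall_start_s=None if pd.isna(fall_start) else float(fall_start),
                scission_time_s=None if pd.isna(scission) else float(scission),
                z_speed_nm_per_s=float(row["z_speed_nm_per_s"]),
                z_offset_nm=float(row.get("z_offset_nm", 0.0)),
                retention_class=str(row["retention_class"]),
                coloc_partner=bool(row["coloc_partner"]),
            )
        )
    return events


def read_movie(directory: str | Path) -> MovieStack:
    """Round-trip reader for :func:`write_movie` output."""
    directory = Path(directory)
    config, channels = _parse_config((directory / _CONFIG_FILE).read_text())
    frames = np.stack(
        [tifffile.imread(directory / f"{c.name}.tif").astype(float) for c in channels]
    )
    truth_path = directory / _TRUTH_FILE
    events = []
    if truth_path.exists():
        table = pd.read_csv(truth_path)
        if len(table):
            events = _parse_truth(table)
    return MovieStack(frames, config, channels, events)


def write_cytometry(populations: list[CytometryPopulation], path: str | Path) -> Path:
    """One row per cell: condition, replicate_id, measurement, fluorescence,
    ground_truth_median."""
    rows = []
    for pop in populations:
        for v in pop.per_cell_fluorescence:
            rows.append(
                {
                    "condition": pop.condition,
                    "replicate_id": pop.replicate_id,
                    "measurement": pop.measurement,
                    "fluorescence": v,
                    "ground_truth_median": pop.ground_truth_median,
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_cytometry(path: str | Path) -> list[CytometryPopulation]:
    table = pd.read_csv(path)
    pops = []
    keys = ["condition", "replicate_id", "measurement"]
    for (cond, rep, meas), grp in table.groupby(keys, sort=False):
        pops.append(
            CytometryPopulation(
                str(cond),
                int(rep),
                str(meas),
                grp["fluorescence"].to_numpy(),
                float(grp["ground_truth_median"].iloc[0]),
            )
        )
    return pops


def write_tracks(trackset: ParticleTrackSet, path: str | Path) -> Path:
    """One row per localization: particle, t_s, x_um, y_um, plus per-particle
    ground-truth diameter when known."""
    rows = []
    for i, (pid, track) in enumerate(zip(trackset.particle_ids, trackset.tracks)):
        gt = (
            trackset.ground_truth_diameter_nm[i]
            if trackset.ground_truth_diameter_nm is not None
            else np.nan
        )
        for t, x, y in track:
            rows.append(
                {
                    "particle": pid,
                    "t_s": t,
                    "x_um": x,
                    "y_um": y,
                    "modality": trackset.modality,
                    "temperature_K": trackset.temperature_K,
                    "viscosity_Pa_s": trackset.viscosity_Pa_s,
                    "frame_rate_hz": trackset.frame_rate_hz,
                    "ground_truth_diameter_nm": gt,
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_tracks(path: str | Path) -> ParticleTrackSet:
    table = pd.read_csv(path)
    tracks, ids, diameters = [], [], []
    for pid, grp in table.groupby("particle", sort=False):
        grp = grp.sort_values("t_s")
        tracks.append(grp[["t_s", "x_um", "y_um"]].to_numpy())
        ids.append(pid)
        diameters.append(grp["ground_truth_diameter_nm"].iloc[0])
    first = table.iloc[0]
    return ParticleTrackSet(
        tracks,
        np.asarray(ids),
        str(first["modality"]),
        float(first["temperature_K"]),
        float(first["viscosity_Pa_s"]),
        float(first["frame_rate_hz"]),
        ground_truth_diameter_nm=np.asarray(diameters, dtype=float),
    )


def write_provenance(path: str | Path, parameters: dict, seed: int | None = None) -> Path:
    """Record run parameters, seed and library versions next to outputs."""
    import cmequant

    record = {
        "parameters": parameters,
        "seed": seed,
        "python": sys.version.split()[0],
        "cmequant": cmequant.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path
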