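"""File contracts: TIFF movie stacks, timestamp sidecars, and result CSVs.

Movies are written as one multi-page 16-bit TIFF per channel with per-frame
timestamps in a sidecar CSV (columns ``frame_index, channel, t_start_s``),
ground truth as CSV plus a JSON trajectory dump.  Real data following the
same sidecar convention can be read back with :func:`read_movies`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import DriftTrace, Movie, SpotRecord
from .optics import CHANNELS, SyntheticDataset


def write_movies(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write one TIFF stack per channel plus the timestamp sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    rows = []
    for channel in CHANNELS:
        movie = dataset.movies[channel]
        path = out / f"{channel}.tif"
        tifffile.imwrite(path, movie.frames.astype(np.uint16))
        paths[channel] = path
        rows.extend(
            {"frame_index": i, "channel": channel, "t_start_s": float(t)}
            for i, t in enumerate(movie.timestamps)
        )
    pd.DataFrame(rows).to_csv(out / "timestamps.csv", index=False)
    return paths


def read_movies(indir: str | Path) -> dict[str, Movie]:
    """Read channel TIFF stacks and the timestamp sidecar back into movies."""
    indir = Path(indir)
    ts = pd.read_csv(indir / "timestamps.csv")
    movies = {}
    for channel, grp in ts.groupby("channel"):
        frames = tifffile.imread(indir / f"{channel}.tif")
        grp = grp.sort_values("frame_index")
        movies[channel] = Movie(
            frames=frames, timestamps=grp["t_start_s"].to_numpy(), channel=str(channel)
        )
    return movies


def write_ground_truth(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Ground-truth CSV plus a JSON dump of the underlying trajectories."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    dump = {
        "scenario": dataset.scenario,
        "seed": dataset.seed,
        "fiducials_xy": dataset.fiducials_xy.tolist(),
        "trajectories": [
            {
                "structure_id": int(row.structure_id),
                "events": [
                    [float(t), list(site), int(new)]
                    for t, site, new in dataset_traj_events(dataset, int(row.structure_id))
                ],
            }
            for row in dataset.ground_truth.itertuples()
        ],
    }
    path = out / "trajectories.json"
    path.write_text(json.dumps(dump, sort_keys=True))
    return path


def dataset_traj_events(dataset: SyntheticDataset, structure_id: int):
    """Per-frame conformation changes reconstructed for the JSON dump."""
    series = dataset.state_series[structure_id]
    events = []
    for channel in CHANNELS:
        s = series[channel]
        times = dataset.movies[channel].timestamps
        for i in np.flatnonzero(np.diff(s.astype(int)) != 0) + 1:
            events.append((float(times[i]), (channel,), int(s[i])))
    return sorted(events)


def write_spots(spots: list[SpotRecord], path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "spot_id": range(len(spots)),
            "channel": [s.channel for s in spots],
            "x": [s.x for s in spots],
            "y": [s.y for s in spots],
            "first_frame": [s.first_frame for s in spots],
            "is_fiducial": [s.is_fiducial for s in spots],
        }
    )
    df.to_csv(path, index=False, float_format="%.4f")
    return Path(path)


def write_drift(drift: DriftTrace, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "frame": range(len(drift.shifts)),
            "dx_px": drift.shifts[:, 0],
            "dy_px": drift.shifts[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.4f")
    return Path(path)
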