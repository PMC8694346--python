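"""Plain-text marker-table and track-table readers/writers.

Marker tables are TSV files with header columns ``image_index``,
``tilt_angle`` (degrees), ``x``, ``y`` (pixels), one row per detected
marker. Track tables are TSV with columns ``track_id``, ``image_index``,
``marker_index``, ``x``, ``y``. Truth tables (simulator output) add a
``specimen_id`` column (-1 marks a spurious detection).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import MarkerSet
from .tracking import Track

__all__ = [
    "read_marker_table",
    "write_marker_table",
    "read_truth_table",
    "write_truth_table",
    "read_tracks",
    "write_tracks",
    "write_correspondences",
    "read_correspondences",
]

MARKER_COLUMNS = ["image_index", "tilt_angle", "x", "y"]
TRACK_COLUMNS = ["track_id", "image_index", "marker_index", "x", "y"]
TRUTH_COLUMNS = ["image_index", "marker_index", "specimen_id"]
CORR_COLUMNS = ["image_i", "image_j", "index_i", "index_j", "residual"]


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_marker_table(path) -> list[MarkerSet]:
    """Read a marker table, grouping rows by image index.

    Rejects non-finite coordinates (reported with their line number) and
    images whose rows disagree on the tilt angle. An empty file yields an
    empty list.
    """
    df = _read_tsv(path, MARKER_COLUMNS)
    if df.empty:
        return []
    values = df[["x", "y", "tilt_angle"]].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.all(np.isfinite(values), axis=1))
    if bad.size:
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    out = []
    for image_index, group in df.groupby("image_index", sort=True):
        tilts = group["tilt_angle"].unique()
        if len(tilts) != 1:
            raise ValueError(
                f"{path}: image {image_index} mixes tilt angles {sorted(tilts)}"
            )
        out.append(
            MarkerSet(
                group[["x", "y"]].to_numpy(dtype=float),
                tilt_angle=float(tilts[0]),
                image_index=int(image_index),
            )
        )
    return out


def write_marker_table(series: Sequence[MarkerSet], path) -> None:
    rows = []
    for ms in series:
        for x, y in ms.points:
            rows.append((ms.image_index, ms.tilt_angle, x, y))
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_truth_table(labels: Sequence[np.ndarray], path) -> None:
    rows = []
    for image_index, lab in enumerate(labels):
        for marker_index, specimen_id in enumerate(lab):
            rows.append((image_index, marker_index, int(specimen_id)))
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> list[np.ndarray]:
    df = _read_tsv(path, TRUTH_COLUMNS)
    out = []
    if df.empty:
        return out
    for _, group in df.groupby("image_index", sort=True):
        group = group.sort_values("marker_index")
        out.append(group["specimen_id"].to_numpy(dtype=int))
    return out


def write_tracks(tracks: Sequence[Track], path) -> None:
    """Write tracks in deterministic (track_id, image_index) order."""
    rows = []
    for track in sorted(tracks, key=lambda t: t.track_id):
        for image_index in sorted(track.observations):
            marker, (x, y) = track.observations[image_index]
            rows.append((track.track_id, image_index, marker, x, y))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_tracks(path) -> list[Track]:
    df = _read_tsv(path, TRACK_COLUMNS)
    tracks: dict[int, Track] = {}
    for row in df.itertuples(index=False):
        track = tracks.setdefault(int(row.track_id), Track(int(row.track_id)))
        key = int(row.image_index)
        if key in track.observations:
            raise ValueError(f"{path}: duplicate (track, image) ({row.track_id}, {key})")
        track.observations[key] = (int(row.marker_index), (float(row.x), float(row.y)))
    return [tracks[k] for k in sorted(tracks)]


def write_correspondences(matches, path) -> None:
    rows = []
    for match in matches:
        corr = match.correspondence
        for (m, n), res in zip(corr.pairs, corr.residuals):
            rows.append((match.image_i, match.image_j, int(n), int(m), res))
    pd.DataFrame(rows, columns=CORR_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_correspondences(path) -> pd.DataFrame:
    return _read_tsv(path, CORR_COLUMNS)
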