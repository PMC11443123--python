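"""Decoding activation time series to nearest cognitive terms.

Per-frame activation maps (t statistics from a first-level GLM, one per
second of stimulus) are z-transformed, thresholded and parcellated like the
meta-analytic maps, projected into a fitted morphospace, and decoded by
assigning each frame the term of its Euclidean-nearest training map.  A
hemodynamic delay and a post-offset inclusion window govern how decoded
frames are attributed to stimulus events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import t_to_z
from .embedding import Morphospace, transform_new
from .maps_io import (
    AtlasParcellation,
    ParcelMatrix,
    ThresholdPolicy,
    VolumeMap,
    parcellate,
    stack,
    threshold,
)

UNDECODABLE = "undecodable"
REST_LABEL = "REST"

#: BOLD responses peak seconds after the stimulus; activity up to this many
#: seconds after an event's offset is still attributed to the event.
DEFAULT_POST_OFFSET_WINDOW = 5.0


@dataclass
class FrameActivationSeries:
    """Ordered per-frame statistical maps with their timestamps.

    ``glm_df`` is the residual degrees of freedom of the GLM that produced
    the per-frame t maps; it is required for the t->z conversion and must be
    supplied as metadata (pass frames with ``stat_kind='z'`` to skip the
    conversion).
    """

    frames: Sequence[VolumeMap]
    timestamps: np.ndarray
    run_id: str = "run"
    repetition_time: float = 1.0
    glm_df: Optional[float] = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one map per timestamp required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def prepare_frames(series: FrameActivationSeries, atlas: AtlasParcellation,
                   policy: ThresholdPolicy = ThresholdPolicy()
                   ) -> Tuple[ParcelMatrix, pd.Series]:
    """z-transform, threshold and parcellate every frame.

    t-statistic frames are converted voxelwise to z (requires ``glm_df``);
    z frames pass through unchanged.  Frames whose thresholded volume is
    entirely zero are flagged undecodable (their parcel vector is kept, all
    zeros).

    Returns the frames ParcelMatrix (rows ``<run>_f<i>``) and a boolean
    undecodable flag per frame.
    """
    vectors, flags, ids = [], [], []
    for i, frame in enumerate(series.frames):
        if frame.stat_kind == "t":
            if series.glm_df is None:
                raise ValueError("glm_df metadata is required to convert t frames to z")
            zvals = np.asarray(t_to_z(frame.values.ravel(), series.glm_df)).reshape(frame.dims)
            frame = VolumeMap(zvals, frame.affine, stat_kind="z",
                              term=frame.term, source=frame.source)
        thr = threshold(frame, policy)
        flags.append(bool(np.all(thr.values == 0)))
        vectors.append(parcellate(thr, atlas))
        ids.append(f"{series.run_id}_f{i:05d}")
    matrix = stack(vectors, map_ids=ids)
    return matrix, pd.Series(flags, index=ids, name="undecodable")


def decode(frames: ParcelMatrix, space: Morphospace, *,
           timestamps: Optional[np.ndarray] = None,
           undecodable: Optional[pd.Series] = None,
           coords: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Assign each frame the term of its nearest embedded training map.

    Frames are projected with UMAP transform (or taken from ``coords`` if the
    embedding coordinates were already computed); the nearest training map is
    found by exact Euclidean scan, ties broken by map order.  Undecodable
    frames receive the sentinel term and NaN distance instead of an error.

    Returns a table (frame_id, timestamp, term, distance, dim_1..dim_k).
    """
    if coords is None:
        coords = transform_new(space, frames)
    train = space.coordinates.to_numpy(dtype=float)
    if timestamps is None:
        timestamps = np.arange(frames.n_maps, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) != frames.n_maps:
        raise ValueError("one timestamp per frame required")
    rows = []
    for i, frame_id in enumerate(frames.map_ids):
        rec = {"frame_id": frame_id, "timestamp": float(timestamps[i])}
        if undecodable is not None and bool(undecodable.loc[frame_id]):
            rec.update({"term": UNDECODABLE, "distance": np.nan})
            for c in space.coordinates.columns:
                rec[c] = np.nan
        else:
            point = coords.loc[frame_id].to_numpy(dtype=float)
            d = np.linalg.norm(train - point, axis=1)
            j = int(np.argmin(d))  # first minimum = map_id order on ties
            rec.update({"term": space.map_ids[j], "distance": float(d[j])})
            for c, v in zip(space.coordinates.columns, point):
                rec[c] = float(v)
        rows.append(rec)
    return pd.DataFrame(rows)


def read_events_tsv(path) -> pd.DataFrame:
    """FSL-style 3-column timing file: onset, duration, label (TSV)."""
    events = pd.read_csv(path, sep="\t", header=None,
                         names=["onset", "duration", "label"])
    return events


def align_to_stimulus(results: pd.DataFrame, events: pd.DataFrame, *,
                      delay: float = 0.0,
                      post_offset_window: float = DEFAULT_POST_OFFSET_WINDOW
                      ) -> pd.DataFrame:
    """Attribute each decoded frame to the stimulus event driving it.

    A frame at time ``ts`` reflects the stimulus at ``ts - delay``.  It is
    attributed to the event whose interval contains that instant; if it
    falls after an event's offset but within ``post_offset_window`` seconds
    of it (and inside no other event), it still belongs to that event —
    accommodating the lingering haemodynamic response.  Anything else is
    labelled REST.  Every frame receives exactly one label.
    """
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    ev = events.sort_values("onset").reset_index(drop=True)
    onsets = ev["onset"].to_numpy(dtype=float)
    offsets = onsets + ev["duration"].to_numpy(dtype=float)
    if np.any(onsets[1:] < offsets[:-1]):
        raise ValueError("stimulus intervals must be non-overlapping")
    labels = []
    for ts in results["timestamp"].to_numpy(dtype=float):
        t_eff = ts - delay
        inside = np.flatnonzero((onsets <= t_eff) & (t_eff < offsets))
        if len(inside):
            labels.append(ev["label"].iloc[inside[0]])
            continue
        lingering = np.flatnonzero((offsets <= t_eff) &
                                   (t_eff <= offsets + post_offset_window))
        if len(lingering):
            # most recently ended event wins
            labels.append(ev["label"].iloc[lingering[np.argmax(offsets[lingering])]])
        else:
            labels.append(REST_LABEL)
    out = results.copy()
    out["stimulus"] = labels
    return out
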