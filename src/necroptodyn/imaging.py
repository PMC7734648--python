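"""Minimal NECtrack front end: segment, track, measure.

Produces per-cell mean nuclear death-marker intensity traces from a
two-channel time-lapse movie (nuclear stain + death marker), which the
:mod:`necroptodyn.kinetics` module turns into death calls and rates.

Segmentation is nuclear-stain-only: background subtraction, Gaussian
smoothing, Otsu (or user) thresholding, and watershed splitting of touching
nuclei seeded at smoothed local maxima.  Tracking is greedy nearest-centroid
linking under a hard displacement gate; unmatched detections start new
tracks and lapsed tracks are closed (no gap bridging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from . import kinetics

__all__ = [
    "MovieStack",
    "NucleusTrack",
    "NectrackConfig",
    "segment_nuclei",
    "track_nuclei",
    "measure_traces",
    "run_nectrack",
]


@dataclass
class MovieStack:
    """Two-channel time-lapse movie (nuclear stain + death marker)."""

    nuclear: np.ndarray  # (frames, H, W)
    death_marker: np.ndarray  # (frames, H, W)
    frame_interval_min: float = 1.5
    pixel_size_um: float = 0.65

    def __post_init__(self) -> None:
        if self.nuclear.shape != self.death_marker.shape:
            raise ValueError("channels must share (frames, height, width)")
        if self.nuclear.ndim != 3:
            raise ValueError("movie channels must be 3-D (frames, height, width)")

    @property
    def n_frames(self) -> int:
        return self.nuclear.shape[0]

    @property
    def shape(self):
        return self.nuclear.shape

    def save(self, nuclear_path, death_path) -> None:
        import tifffile

        tifffile.imwrite(nuclear_path, np.asarray(self.nuclear, dtype=np.uint16))
        tifffile.imwrite(death_path, np.asarray(self.death_marker, dtype=np.uint16))

    @classmethod
    def load(cls, nuclear_path, death_path, frame_interval_min=1.5, pixel_size_um=0.65):
        import tifffile

        return cls(
            tifffile.imread(nuclear_path),
            tifffile.imread(death_path),
            frame_interval_min=frame_interval_min,
            pixel_size_um=pixel_size_um,
        )


@dataclass
class NucleusTrack:
    """One tracked nucleus: frame span, centroids and mask labels per frame."""

    track_id: int
    start_frame: int
    centroids: List[np.ndarray] = field(default_factory=list)  # (y, x) per present frame
    labels: List[int] = field(default_factory=list)  # mask label per present frame
    parent_id: Optional[int] = None

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.centroids) - 1

    @property
    def n_frames(self) -> int:
        return len(self.centroids)


def segment_nuclei(
    frame: np.ndarray,
    smooth_sigma: float = 2.0,
    min_area: int = 9,
    min_distance: int = 5,
    threshold: Optional[float] = None,
) -> np.ndarray:
    """Segment nuclei in a single nuclear-stain frame.

    Background is estimated as the image median and subtracted; the frame is
    Gaussian-smoothed, thresholded (Otsu by default) and touching nuclei are
    split by a watershed seeded at smoothed local maxima.

    Returns an integer label mask (0 = background).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_nuclei expects a single 2-D frame")
    sm = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    bg = np.median(sm)
    sm = sm - bg
    if np.ptp(sm) == 0:
        warnings.warn("segment_nuclei: blank frame, no labels", stacklevel=2)
        return np.zeros_like(img, dtype=np.int32)
    if threshold is None:
        try:
            threshold = threshold_otsu(sm)
        except ValueError:
            warnings.warn("segment_nuclei: degenerate histogram, no labels", stacklevel=2)
            return np.zeros_like(img, dtype=np.int32)
    mask = sm > threshold
    if not mask.any():
        warnings.warn("segment_nuclei: nothing above threshold", stacklevel=2)
        return np.zeros_like(img, dtype=np.int32)
    peaks = peak_local_max(sm, min_distance=min_distance, labels=mask, exclude_border=False)
    seeds = np.zeros_like(img, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        labels, _ = ndi.label(mask)
    else:
        labels = watershed(-sm, seeds, mask=mask)
    # minimum-area filter and relabel compactly
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for p in regionprops(labels):
        if p.area >= min_area:
            out[labels == p.label] = nxt
            nxt += 1
    return out


def track_nuclei(label_masks: List[np.ndarray], max_displacement: float = 10.0) -> List[NucleusTrack]:
    """Greedy nearest-centroid linking of per-frame label masks.

    Detections are linked to the closest open track from the previous frame
    if within ``max_displacement`` pixels (each track claims at most one
    detection, closest pair first).  Unmatched detections start new tracks;
    tracks with no match are closed.
    """
    tracks: List[NucleusTrack] = []
    open_tracks: List[NucleusTrack] = []
    next_id = 0
    for f, mask in enumerate(label_masks):
        props = regionprops(mask)
        cents = np.array([p.centroid for p in props]) if props else np.empty((0, 2))
        labs = [p.label for p in props]
        assigned = np.full(len(props), -1, dtype=int)
        if open_tracks and len(props):
            prev = np.array([t.centroids[-1] for t in open_tracks])
            tree = cKDTree(prev)
            dists, nearest = tree.query(cents, k=1)
            order = np.argsort(dists)
            used_tracks = set()
            for di in order:
                if dists[di] > max_displacement:
                    break
                ti = int(nearest[di])
                if ti in used_tracks:
                    # closest track taken; try remaining open tracks
                    d2 = np.linalg.norm(prev - cents[di], axis=1)
                    d2[list(used_tracks)] = np.inf
                    ti = int(np.argmin(d2))
                    if d2[ti] > max_displacement:
                        continue
                used_tracks.add(ti)
                assigned[di] = ti
        still_open: List[NucleusTrack] = []
        matched = set(assigned[assigned >= 0].tolist())
        for ti, t in enumerate(open_tracks):
            if ti in matched:
                still_open.append(t)
        for di in range(len(props)):
            ti = assigned[di]
            if ti >= 0:
                t = open_tracks[ti]
                t.centroids.append(cents[di])
                t.labels.append(labs[di])
            else:
                t = NucleusTrack(track_id=next_id, start_frame=f)
                next_id += 1
                t.centroids.append(cents[di])
                t.labels.append(labs[di])
                tracks.append(t)
                still_open.append(t)
        open_tracks = [t for t in tracks if t.end_frame == f]
    return tracks


def measure_traces(
    tracks: List[NucleusTrack],
    label_masks: List[np.ndarray],
    channel: np.ndarray,
) -> pd.DataFrame:
    """Mean intensity over each track's nuclear mask per frame.

    Returns a long-format DataFrame (cell_id, frame, value); frames where a
    track is absent are omitted.
    """
    if len(label_masks) != channel.shape[0]:
        raise ValueError("masks and channel must share the frame grid")
    # per-frame mean intensity by label, computed once per frame
    rows = []
    per_frame_means = []
    for f, mask in enumerate(label_masks):
        if mask.max() > 0:
            means = ndi.mean(channel[f], labels=mask, index=np.arange(1, mask.max() + 1))
        else:
            means = np.empty(0)
        per_frame_means.append(means)
    for t in tracks:
        for k, lab in enumerate(t.labels):
            f = t.start_frame + k
            means = per_frame_means[f]
            if lab < 1 or lab > means.size:
                raise IndexError(f"track {t.track_id} references missing label {lab} in frame {f}")
            rows.append((t.track_id, f, float(means[lab - 1])))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "value"])


@dataclass
class NectrackConfig:
    threshold: Optional[float] = None  # death-marker threshold; Otsu default
    min_run: int = 6
    window_hours: float = 5.0
    max_displacement: Optional[float] = None  # default 3x expected motion
    smooth_sigma: float = 2.0
    min_area: int = 9
    min_track_fraction: float = 0.5  # drop tracks spanning < this fraction of frames


@dataclass
class NectrackResult:
    matrix: kinetics.AliveDeadMatrix
    table: kinetics.DeathTimeTable
    rates: Optional[kinetics.RateSeries]
    traces: pd.DataFrame
    tracks: List[NucleusTrack]


def run_nectrack(movie: MovieStack, config: Optional[NectrackConfig] = None) -> NectrackResult:
    """Segment, track and measure a movie, then call deaths and rates.

    Tracks must span at least ``min_track_fraction`` of the movie to be
    scored (short fragments carry no death-time information); traces are
    padded with their edge values so every scored cell covers the full frame
    grid.
    """
    config = config or NectrackConfig()
    masks = [
        segment_nuclei(movie.nuclear[f], smooth_sigma=config.smooth_sigma, min_area=config.min_area)
        for f in range(movie.n_frames)
    ]
    gate = config.max_displacement if config.max_displacement is not None else 10.0
    tracks = track_nuclei(masks, max_displacement=gate)
    keep = [t for t in tracks if t.n_frames >= config.min_track_fraction * movie.n_frames]
    traces = measure_traces(keep, masks, movie.death_marker)

    if traces.empty:
        empty = kinetics.DeathTimeTable.from_arrays(np.empty(0))
        mat = kinetics.AliveDeadMatrix(
            np.zeros((0, movie.n_frames), dtype=np.int8),
            frame_interval_min=movie.frame_interval_min,
        )
        return NectrackResult(matrix=mat, table=empty, rates=None, traces=traces, tracks=keep)

    wide = traces.pivot(index="cell_id", columns="frame", values="value")
    wide = wide.reindex(columns=range(movie.n_frames))
    wide = wide.ffill(axis=1).bfill(axis=1)

    threshold = config.threshold
    if threshold is None:
        threshold = threshold_otsu(np.asarray(movie.death_marker, dtype=float).ravel()[::7])
    matrix, table = kinetics.call_deaths(
        wide.to_numpy(),
        threshold=threshold,
        min_run=config.min_run,
        frame_interval_min=movie.frame_interval_min,
        cell_ids=wide.index.to_numpy(),
    )
    rates = None
    if matrix.n_cells:
        try:
            rates = kinetics.death_rate(matrix, window_hours=config.window_hours)
        except ValueError:
            rates = None
    return NectrackResult(matrix=matrix, table=table, rates=rates, traces=traces, tracks=keep)
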