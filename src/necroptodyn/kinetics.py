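"""Death-kinetics statistics for single-cell necroptosis time courses.

This module turns per-cell death-marker intensity traces into the population
statistics used to characterise TNF-induced necroptosis: a latched binary
alive/dead matrix, a table of first-death times, sliding-window death rates
normalised to the at-risk population, pdf-normalised death-time histograms,
and Hartigan's dip significance test for unimodality of death times.

Conventions
-----------
* A cell is called dead from the first frame of the first run of at least
  ``min_run`` consecutive frames with intensity strictly above threshold;
  the call is latched (never reverts).
* Death rates use a forward-anchored window: the rate reported at time *t*
  counts deaths in ``(t, t + window]`` divided by cells alive at *t*,
  expressed per hour by dividing by the window length.  The series stops
  once the alive population drops below ``stop_fraction`` of the starting
  population.
* The dip test's null distribution is Monte-Carlo sampled from uniform(0,1)
  samples of the same size, the standard calibration for the test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._dip import dip_statistic

logger = logging.getLogger(__name__)

__all__ = [
    "AliveDeadMatrix",
    "DeathTimeTable",
    "RateSeries",
    "DipResult",
    "DeathTimeHistogram",
    "call_deaths",
    "death_rate",
    "death_time_histogram",
    "dip_test",
    "compare_unimodality",
    "proliferative_index",
    "fractional_survival_from_matrix",
    "phase_rate_ratio",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class AliveDeadMatrix:
    """Binary cells x frames matrix; 0 = alive, 1 = death has occurred.

    Rows are non-decreasing left to right (death is latched).
    """

    values: np.ndarray
    frame_interval_min: float = 1.5
    start_hours: float = 0.0
    cell_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2 or v.shape[1] < 1:
            raise ValueError("alive/dead matrix must be 2-D with >= 1 frame")
        if np.any(np.diff(v.astype(np.int16), axis=1) < 0):
            raise ValueError("death status must be latched (rows non-decreasing)")
        self.values = v
        if self.cell_ids is None:
            self.cell_ids = np.arange(v.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def frame_times_hours(self) -> np.ndarray:
        return self.start_hours + np.arange(self.n_frames) * self.frame_interval_min / 60.0

    @classmethod
    def from_death_times(
        cls,
        death_times_hours,
        n_frames: int,
        frame_interval_min: float = 1.5,
        start_hours: float = 0.0,
        cell_ids=None,
    ) -> "AliveDeadMatrix":
        """Build a latched matrix from per-cell death times (NaN = censored)."""
        dt = np.asarray(death_times_hours, dtype=float)
        dt_h = frame_interval_min / 60.0
        m = np.zeros((dt.size, n_frames), dtype=np.int8)
        for i, d in enumerate(dt):
            if np.isfinite(d):
                f = int(round((d - start_hours) / dt_h))
                if f < n_frames:
                    m[i, max(f, 0):] = 1
        return cls(m, frame_interval_min=frame_interval_min, start_hours=start_hours,
                   cell_ids=cell_ids)

    def alive_counts(self) -> np.ndarray:
        """Number of alive cells at each frame."""
        return self.n_cells - self.values.sum(axis=0)


@dataclass
class DeathTimeTable:
    """Per-cell first death time in hours (NaN when censored)."""

    data: pd.DataFrame
    provenance: str = ""

    REQUIRED = ("cell_id", "death_time", "censored")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"death-time table missing columns {missing}")

    @classmethod
    def from_arrays(cls, death_times, censored=None, cell_ids=None, provenance=""):
        death_times = np.asarray(death_times, dtype=float)
        if censored is None:
            censored = ~np.isfinite(death_times)
        censored = np.asarray(censored, dtype=bool)
        if cell_ids is None:
            cell_ids = np.arange(death_times.size)
        df = pd.DataFrame(
            {
                "cell_id": np.asarray(cell_ids),
                "death_time": np.where(censored, np.nan, death_times),
                "censored": censored,
            }
        )
        return cls(df, provenance=provenance)

    @property
    def times(self) -> np.ndarray:
        """Observed (non-censored) death times in hours."""
        return self.data.loc[~self.data["censored"], "death_time"].to_numpy()

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, provenance=""):
        return cls(pd.read_csv(path), provenance=provenance)


@dataclass
class RateSeries:
    """Forward-window death rates per hour on a frame-aligned time grid."""

    times_hours: np.ndarray
    rate_per_hour: np.ndarray
    window_hours: float
    stop_index: Optional[int] = None

    def window_fraction(self) -> np.ndarray:
        return self.rate_per_hour * self.window_hours


@dataclass
class DipResult:
    """Hartigan dip statistic with a Monte-Carlo probability of unimodality."""

    dip: float
    p_unimodal: float
    n: int
    n_boot: int
    seed: Optional[int] = None


@dataclass
class DeathTimeHistogram:
    bin_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    n_deaths: int
    n_out_of_range: int = 0

    @property
    def empty(self) -> bool:
        return self.n_deaths == 0


# ---------------------------------------------------------------------------
# death calling
# ---------------------------------------------------------------------------


def _first_run_start(above: np.ndarray, min_run: int) -> int:
    """Index of the first frame of the first run of >= min_run True; -1 if none."""
    idx = np.flatnonzero(above)
    if idx.size < min_run:
        return -1
    # run-length encode the True positions
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_run:
            return int(idx[s])
    return -1


def call_deaths(
    traces,
    threshold: float,
    min_run: int = 6,
    frame_interval_min: float = 1.5,
    start_hours: float = 0.0,
    cell_ids=None,
    provenance: str = "",
):
    """Call per-cell death events from death-marker intensity traces.

    A cell is declared dead at the first frame of the first run of at least
    ``min_run`` consecutive frames with intensity strictly greater than
    ``threshold``; the binary status is latched thereafter.

    Parameters
    ----------
    traces : ndarray (cells, frames) or DataFrame with cell_id/frame/value
        Per-cell death-marker intensity time series on a common frame grid.
    threshold : float
        Intensity threshold; "crossed" means strictly greater.
    min_run : int
        Minimum number of consecutive above-threshold frames (default 6).

    Returns
    -------
    (AliveDeadMatrix, DeathTimeTable)
    """
    if isinstance(traces, pd.DataFrame):
        wide = traces.pivot(index="cell_id", columns="frame", values="value")
        cell_ids = wide.index.to_numpy()
        arr = wide.to_numpy(dtype=float)
    else:
        arr = np.asarray(traces, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if cell_ids is None:
            cell_ids = np.arange(arr.shape[0])
    if arr.size == 0:
        raise ValueError("empty trace set")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    bad = np.flatnonzero(~np.isfinite(arr).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite trace values for cell(s) {np.asarray(cell_ids)[bad].tolist()}")

    n_cells, n_frames = arr.shape
    matrix = np.zeros((n_cells, n_frames), dtype=np.int8)
    death_frames = np.full(n_cells, -1, dtype=int)
    above = arr > threshold
    for i in range(n_cells):
        f = _first_run_start(above[i], min_run)
        death_frames[i] = f
        if f >= 0:
            matrix[i, f:] = 1

    dt_h = frame_interval_min / 60.0
    censored = death_frames < 0
    death_times = np.where(censored, np.nan, start_hours + death_frames * dt_h)
    table = DeathTimeTable.from_arrays(
        death_times, censored=censored, cell_ids=cell_ids, provenance=provenance
    )
    table.data["death_frame"] = np.where(censored, -1, death_frames)
    adm = AliveDeadMatrix(
        matrix, frame_interval_min=frame_interval_min, start_hours=start_hours, cell_ids=cell_ids
    )
    return adm, table


# ---------------------------------------------------------------------------
# rates and summaries
# ---------------------------------------------------------------------------


def death_rate(
    matrix: AliveDeadMatrix,
    window_hours: float = 5.0,
    stop_fraction: float = 1.0 / 3.0,
) -> RateSeries:
    """Sliding-window death rate per hour, normalised to the at-risk population.

    At each frame time *t* the window rate is the number of new deaths in
    ``(t, t + window]`` divided by the number of cells alive at *t*; the
    per-hour rate divides that fraction by the window length.  The series
    ends at the earlier of the last full window and the frame at which the
    alive population drops below ``stop_fraction`` of the starting
    population (the matrix's first frame).
    """
    dt_h = matrix.frame_interval_min / 60.0
    w = int(round(window_hours / dt_h))
    if w < 1 or w >= matrix.n_frames:
        raise ValueError("window must be positive and within the observation span")
    dead = matrix.values.sum(axis=0).astype(float)
    n = matrix.n_cells
    alive = n - dead
    if alive[0] <= 0:
        raise ValueError("no cells alive at the start of the matrix")

    n_windows = matrix.n_frames - w
    stop = n_windows
    # stop rule on the *starting* population
    below = np.flatnonzero(alive < stop_fraction * n)
    if below.size and below[0] < stop:
        stop = int(below[0])
    zero = np.flatnonzero(alive[:n_windows] <= 0)
    if zero.size and zero[0] < stop:
        stop = int(zero[0])
        logger.info("death_rate: alive population reached zero; series truncated at frame %d", stop)

    t_idx = np.arange(stop)
    new_deaths = dead[t_idx + w] - dead[t_idx]
    window_rate = new_deaths / alive[t_idx]
    times = matrix.start_hours + t_idx * dt_h
    return RateSeries(
        times_hours=times,
        rate_per_hour=window_rate / window_hours,
        window_hours=window_hours,
        stop_index=stop,
    )


def death_time_histogram(
    table: DeathTimeTable,
    t_start: float = 0.5,
    t_stop: float = 24.5,
    bin_width: float = 2.0,
) -> DeathTimeHistogram:
    """Pdf-normalised histogram of death times (2-h bins, 0.5 h to 24.5 h).

    Density integrates to 1 over the observed deaths; censored cells are
    excluded.  Deaths outside the bin range are counted and logged.
    """
    edges = np.arange(t_start, t_stop + 0.5 * bin_width, bin_width)
    times = table.times
    if times.size == 0:
        warnings.warn("death_time_histogram: no death events", stacklevel=2)
        return DeathTimeHistogram(edges, np.zeros(edges.size - 1), np.zeros(edges.size - 1, int), 0)
    in_range = (times >= edges[0]) & (times <= edges[-1])
    n_out = int(np.sum(~in_range))
    if n_out:
        logger.info("death_time_histogram: %d death times outside [%g, %g] h", n_out, edges[0], edges[-1])
    counts, _ = np.histogram(times[in_range], bins=edges)
    n_deaths = int(counts.sum())
    density = counts / (n_deaths * bin_width) if n_deaths else np.zeros_like(counts, dtype=float)
    return DeathTimeHistogram(edges, density, counts, n_deaths, n_out)


# ---------------------------------------------------------------------------
# dip test
# ---------------------------------------------------------------------------

_NULL_DIP_CACHE: dict = {}


def _null_dips(n: int, n_boot: int, seed) -> np.ndarray:
    key = (n, n_boot, seed)
    cached = _NULL_DIP_CACHE.get(key)
    if cached is None:
        rng = np.random.default_rng(seed)
        u = rng.random((n_boot, n))
        u.sort(axis=1)
        from ._dip import _dip_sorted

        cached = np.sort([_dip_sorted(row) for row in u])
        _NULL_DIP_CACHE[key] = cached
    return cached


def dip_test(sample, n_boot: int = 10000, seed: Optional[int] = None) -> DipResult:
    """Hartigan's dip significance test for unimodality.

    The dip statistic is the sup-norm distance between the empirical CDF and
    the nearest unimodal CDF.  ``p_unimodal`` is the Monte-Carlo fraction of
    uniform(0,1) samples of the same size whose dip is at least as large as
    the observed one; large values mean the sample is consistent with a
    unimodal distribution.
    """
    x = np.asarray(sample, dtype=float).ravel()
    x = x[np.isfinite(x)] if np.isnan(x).any() else x
    if x.size < 4:
        raise ValueError("dip test requires at least 4 finite values")
    if np.ptp(x) == 0:
        warnings.warn("dip test: all values identical; returning p = 1", stacklevel=2)
        return DipResult(dip=0.0, p_unimodal=1.0, n=int(x.size), n_boot=n_boot, seed=seed)
    d = dip_statistic(x)
    null = _null_dips(int(x.size), n_boot, seed)
    p = 1.0 - np.searchsorted(null, d, side="left") / n_boot
    return DipResult(dip=float(d), p_unimodal=float(p), n=int(x.size), n_boot=n_boot, seed=seed)


def compare_unimodality(p_values_a: Sequence[float], p_values_b: Sequence[float]):
    """Two-sample t-test on per-replicate probabilities of unimodality.

    Returns ``(t_statistic, p_value)``.
    """
    a = np.asarray(p_values_a, dtype=float)
    b = np.asarray(p_values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# ancillary population statistics
# ---------------------------------------------------------------------------


def proliferative_index(
    division_times_hours,
    matrix: AliveDeadMatrix,
    window_hours: float = 4.0,
) -> pd.DataFrame:
    """Divisions per alive cell in consecutive non-overlapping windows.

    Division events are time stamps in hours; each window's count is
    normalised to the number of alive cells at the window start.  Windows
    with zero alive cells yield NaN and are flagged.
    """
    div = np.sort(np.asarray(division_times_hours, dtype=float))
    t = matrix.frame_times_hours()
    dt_h = matrix.frame_interval_min / 60.0
    span = t[-1] - t[0] + dt_h
    n_windows = int(np.floor(span / window_hours))
    alive = matrix.alive_counts()
    rows = []
    for k in range(n_windows):
        w0 = t[0] + k * window_hours
        w1 = w0 + window_hours
        frame0 = int(round((w0 - t[0]) / dt_h))
        n_alive = int(alive[frame0])
        n_div = int(np.sum((div >= w0) & (div < w1)))
        if n_alive == 0:
            value = np.nan
            if n_div:
                logger.warning("proliferative_index: %d divisions in window with 0 alive cells", n_div)
        else:
            value = n_div / n_alive
        rows.append({"window_start": w0, "divisions": n_div, "alive_at_start": n_alive, "index": value})
    return pd.DataFrame(rows)


def fractional_survival_from_matrix(matrix: AliveDeadMatrix, t_hours: float) -> float:
    """Fraction of cells alive at time ``t_hours``."""
    times = matrix.frame_times_hours()
    if not (times[0] <= t_hours <= times[-1]):
        raise ValueError("t outside observation span")
    frame = int(np.searchsorted(times, t_hours, side="right")) - 1
    return float(matrix.alive_counts()[frame] / matrix.n_cells)


@dataclass
class PhaseRates:
    early_mean: float
    late_mean: float
    ratio: float


def phase_rate_ratio(rates: RateSeries, split_hours: float = 12.0) -> PhaseRates:
    """Mean per-hour death rate before/after ``split_hours`` and their ratio."""
    early = rates.rate_per_hour[rates.times_hours < split_hours]
    late = rates.rate_per_hour[rates.times_hours >= split_hours]
    if early.size == 0 or late.size == 0:
        raise ValueError("rate series does not span both phases")
    e, l = float(early.mean()), float(late.mean())
    return PhaseRates(early_mean=e, late_mean=l, ratio=l / e if e > 0 else np.inf)
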