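"""Synthetic data generators with machine-readable ground truth.

Every analysis stage in this package can be exercised without any external
download: this module fabricates (a) two-channel time-lapse movies with
planted death events, (b) per-cell death-marker intensity traces (the same
death model without pixels), (c) smFISH image sets with planted
diffraction-limited spots and a responder/non-responder cell mixture, and
(d) death-time samples from Gaussian mixtures.

Emulated study conditions: imaging every 1.5 min for 24 h (961 frames,
inclusive endpoint grid); death-marker (PI-like) nuclear intensity stepping
up at death; an A20 "responder" fraction of 0.76.  Nuclei are isotropic
Gaussian blobs on a constant background with additive Gaussian noise;
divisions are off by default.

All generators are deterministic for a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .imaging import MovieStack
from .kinetics import DeathTimeTable
from .smfish import FishImageSet

__all__ = [
    "MixtureSpec",
    "CountLaw",
    "SceneSpec",
    "FishSceneSpec",
    "GroundTruth",
    "make_movie",
    "make_trace_fixtures",
    "make_fish_images",
    "make_death_time_samples",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixture of death times (weights, means and sds in hours)."""

    weights: Tuple[float, ...]
    means_h: Tuple[float, ...]
    sds_h: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means_h) == len(self.sds_h)):
            raise ValueError("mixture components must align")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(s < 0 for s in self.sds_h):
            raise ValueError("mixture sds must be >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        means = np.asarray(self.means_h)[comp]
        sds = np.asarray(self.sds_h)[comp]
        return rng.normal(means, sds)


DeathLaw = Union[str, MixtureSpec, None]


def _as_mixture(law: DeathLaw) -> Optional[MixtureSpec]:
    if law is None or law == "none":
        return None
    if isinstance(law, MixtureSpec):
        return law
    if isinstance(law, dict):
        return MixtureSpec(
            tuple(law["weights"]), tuple(law["means_h"]), tuple(law["sds_h"])
        )
    raise TypeError(f"unsupported death_time_law: {law!r}")


@dataclass(frozen=True)
class CountLaw:
    """Nonnegative-integer transcript-count distribution per cell."""

    family: str = "poisson"  # poisson | negbin | constant
    mean: float = 1.0
    dispersion: float = 4.0  # negbin shape r (smaller -> more overdispersed)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mean < 0:
            raise ValueError("count mean must be >= 0")
        if self.family == "constant":
            return np.full(n, int(round(self.mean)))
        if self.family == "poisson":
            return rng.poisson(self.mean, size=n)
        if self.family == "negbin":
            r = self.dispersion
            p = r / (r + self.mean) if self.mean > 0 else 1.0
            return rng.negative_binomial(r, p, size=n) if self.mean > 0 else np.zeros(n, int)
        raise ValueError(f"unknown count family {self.family!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Time-lapse movie / trace fixture specification."""

    n_cells: int = 50
    field_size: int = 512
    frame_interval_min: float = 1.5
    duration_hours: float = 24.0
    motion_sigma: float = 0.3  # px / frame
    division_rate: float = 0.0  # events / cell / hour
    death_time_law: DeathLaw = "none"
    pi_step_amplitude: float = 600.0
    pi_rise_frames: int = 4
    noise_sigma: float = 20.0
    nucleus_radius: float = 4.0
    background: float = 100.0
    nuclear_amplitude: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.noise_sigma < 0 or self.motion_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        _as_mixture(self.death_time_law)  # validates

    @property
    def n_frames(self) -> int:
        # inclusive endpoint grid: 961 frames for 24 h at 1.5 min
        return int(round(self.duration_hours * 60.0 / self.frame_interval_min)) + 1

    def frame_times_hours(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min / 60.0


@dataclass(frozen=True)
class FishSceneSpec:
    """smFISH image-set specification."""

    n_cells: int = 100
    field_size: int = 1024
    responder_fraction: float = 0.76
    count_laws: Optional[Dict[str, Dict[str, CountLaw]]] = None
    psf_sigma: float = 1.2
    background: float = 100.0
    noise_sigma: float = 40.0
    spot_amplitude: float = 400.0
    nucleus_radius: float = 5.0
    cell_area_mean: float = 600.0  # px^2, lognormal
    cell_area_sigma: float = 0.25  # lognormal sigma of log-area
    autofluorescence_amplitude: float = 800.0
    nuclear_amplitude: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.psf_sigma >= self.nucleus_radius:
            raise ValueError("spots must be diffraction-limited: psf_sigma < nucleus_radius")
        if self.cell_area_mean <= 0:
            raise ValueError("cell areas must be > 0")

    def laws(self) -> Dict[str, Dict[str, CountLaw]]:
        if self.count_laws is not None:
            return self.count_laws
        return {
            "A20": {
                "responder": CountLaw("negbin", mean=10.0, dispersion=4.0),
                "nonresponder": CountLaw("poisson", mean=0.1),
            },
            "IkBa": {
                "responder": CountLaw("negbin", mean=12.0, dispersion=5.0),
                "nonresponder": CountLaw("negbin", mean=12.0, dispersion=5.0),
            },
        }


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every generated artifact."""

    death_frames: Optional[np.ndarray] = None  # -1 = censored
    death_times_hours: Optional[np.ndarray] = None  # NaN = censored
    centroids: Optional[np.ndarray] = None  # (frames, cells, 2) as (y, x)
    birth_frames: Optional[np.ndarray] = None
    parents: Optional[np.ndarray] = None  # -1 = founder
    recommended_threshold: Optional[float] = None
    spots: Optional[pd.DataFrame] = None  # x, y, gene, cell_id
    responder: Optional[np.ndarray] = None
    true_counts: Optional[pd.DataFrame] = None
    cell_labels: Optional[np.ndarray] = None
    division_times_hours: Optional[np.ndarray] = None

    def deaths_to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "cell_id": np.arange(len(self.death_frames)),
                "death_frame": self.death_frames,
                "death_time_hours": self.death_times_hours,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# death-time sampling
# ---------------------------------------------------------------------------


def make_death_time_samples(
    law: DeathLaw, n: int, seed: int, provenance: str = "synthetic"
) -> DeathTimeTable:
    """Sample ``n`` death times from a Gaussian mixture."""
    mix = _as_mixture(law)
    if mix is None:
        raise ValueError("death-time sampling needs a mixture law")
    rng = np.random.default_rng(seed)
    times = mix.sample(n, rng)
    return DeathTimeTable.from_arrays(times, censored=np.zeros(n, bool), provenance=provenance)


def _plant_deaths(spec: SceneSpec, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell death frame (-1 censored) and death time (NaN censored)."""
    mix = _as_mixture(spec.death_time_law)
    n = spec.n_cells
    if mix is None:
        return np.full(n, -1, int), np.full(n, np.nan)
    t = mix.sample(n, rng)
    dt_h = spec.frame_interval_min / 60.0
    frames = np.round(t / dt_h).astype(int)
    ok = (t >= 0) & (frames < spec.n_frames) & (frames >= 0)
    frames = np.where(ok, frames, -1)
    times = np.where(ok, frames * dt_h, np.nan)
    return frames, times


# ---------------------------------------------------------------------------
# trace fixtures
# ---------------------------------------------------------------------------


def _death_step(spec: SceneSpec, death_frame: int) -> np.ndarray:
    """Noise-free death-marker amplitude profile for one cell."""
    prof = np.zeros(spec.n_frames)
    if death_frame < 0:
        return prof
    rise = max(1, spec.pi_rise_frames)
    # jump to 60% of the step at the death frame (so a half-amplitude
    # threshold is crossed immediately), then ramp to the full amplitude
    ramp = (0.6 + 0.4 * np.arange(1, rise + 1) / rise) * spec.pi_step_amplitude
    end = min(spec.n_frames, death_frame + rise)
    prof[death_frame:end] = ramp[: end - death_frame]
    prof[end:] = spec.pi_step_amplitude
    return prof


def _cap_noise_runs(trace: np.ndarray, limit_mask: np.ndarray, threshold: float,
                    max_run: int, reset_value: float) -> None:
    """Break runs of > max_run consecutive above-threshold frames (in place).

    Only frames flagged by ``limit_mask`` (pre-death / censored region) are
    modified; every (max_run+1)-th frame of an offending run is reset.
    """
    above = (trace > threshold) & limit_mask
    run = 0
    for i in range(above.size):
        if above[i]:
            run += 1
            if run > max_run:
                trace[i] = reset_value
                run = 0
        else:
            run = 0


def make_trace_fixtures(spec: SceneSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Per-cell death-marker intensity traces (no pixels).

    Traces sit at the background level with additive Gaussian noise and step
    to ``pi_step_amplitude`` over ``pi_rise_frames`` at the planted death
    frame.  Pre-death noise excursions above the recommended threshold are
    capped at runs of at most 5 consecutive frames, so a 6-frame persistence
    rule never fires early on fixture noise.
    """
    rng = np.random.default_rng(spec.seed)
    frames, times = _plant_deaths(spec, rng)
    threshold = spec.background + 0.5 * spec.pi_step_amplitude
    traces = np.empty((spec.n_cells, spec.n_frames))
    for i in range(spec.n_cells):
        noise = rng.normal(0.0, spec.noise_sigma, spec.n_frames)
        tr = spec.background + noise + _death_step(spec, frames[i])
        pre = np.ones(spec.n_frames, bool)
        if frames[i] >= 0:
            pre[frames[i]:] = False
        _cap_noise_runs(tr, pre, threshold, max_run=5, reset_value=spec.background)
        # the trace is guaranteed above threshold from the death frame on
        if frames[i] >= 0:
            post = np.zeros(spec.n_frames, bool)
            post[frames[i]:] = True
            tr = np.where(post & (tr <= threshold), threshold + max(spec.noise_sigma, 1.0), tr)
        traces[i] = tr
    gt = GroundTruth(
        death_frames=frames,
        death_times_hours=times,
        recommended_threshold=threshold,
    )
    return traces, gt


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


def _grid_positions(n: int, field: int, min_sep: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered grid placement guaranteeing pairwise separation >= min_sep."""
    if n == 0:
        return np.empty((0, 2))
    margin = min_sep
    usable = field - 2 * margin
    g = int(np.ceil(np.sqrt(n)))
    cell = usable / g
    if cell < min_sep:
        limit = int((usable / min_sep) ** 2)
        raise ValueError(
            f"cannot place {n} nuclei in a {field}x{field} field at separation "
            f">= {min_sep:.1f} px; packing limit is {limit} cells"
        )
    jitter = (cell - min_sep) / 2.0
    idx = rng.permutation(g * g)[:n]
    rows, cols = np.divmod(idx, g)
    y = margin + (rows + 0.5) * cell + rng.uniform(-jitter, jitter, n)
    x = margin + (cols + 0.5) * cell + rng.uniform(-jitter, jitter, n)
    return np.column_stack([y, x])


def _render_gaussians(img: np.ndarray, positions: np.ndarray, amplitudes: np.ndarray,
                      sigma: float) -> None:
    """Add isotropic Gaussians (in place); positions are (y, x)."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    for (y, x), a in zip(positions, amplitudes):
        if a == 0 or not np.isfinite(y):
            continue
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None] - y
        xx = np.arange(x0, x1)[None, :] - x
        img[y0:y1, x0:x1] += a * np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))


def make_movie(spec: SceneSpec) -> Tuple[MovieStack, GroundTruth]:
    """Render a two-channel movie with planted deaths (and optional divisions).

    Nuclei are Gaussian blobs (sigma = nucleus_radius / 1.1774, so the
    half-maximum contour sits at the nominal radius) performing bounded
    random walks; the death-marker channel steps up at each planted death.
    Divisions spawn a daughter nucleus adjacent to the parent.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    min_sep = 4.0 * spec.nucleus_radius
    pos0 = _grid_positions(spec.n_cells, spec.field_size, min_sep, rng)
    death_frames, death_times = _plant_deaths(spec, rng)

    # divisions (founders only, one daughter per event)
    birth_frames = np.zeros(spec.n_cells, int)
    parents = np.full(spec.n_cells, -1, int)
    div_times = []
    extra_pos0 = []
    if spec.division_rate > 0 and spec.n_cells > 0:
        for i in range(spec.n_cells):
            t_div = rng.exponential(1.0 / spec.division_rate)
            limit = death_times[i] if np.isfinite(death_times[i]) else spec.duration_hours
            if t_div < limit:
                div_times.append(t_div)
                f = int(round(t_div * 60.0 / spec.frame_interval_min))
                birth_frames = np.append(birth_frames, f)
                parents = np.append(parents, i)
                ang = rng.uniform(0, 2 * np.pi)
                extra_pos0.append(pos0[i] + 2.2 * spec.nucleus_radius * np.array([np.sin(ang), np.cos(ang)]))
                death_frames = np.append(death_frames, -1)
                death_times = np.append(death_times, np.nan)
    n_total = birth_frames.size
    positions0 = np.vstack([pos0] + [np.asarray(extra_pos0)]) if extra_pos0 else pos0

    # bounded random walks
    margin = 2.0 * spec.nucleus_radius
    lo, hi = margin, spec.field_size - margin
    centroids = np.full((n_frames, n_total, 2), np.nan)
    cur = positions0.copy()
    steps = rng.normal(0.0, spec.motion_sigma, size=(n_frames, n_total, 2)) if spec.motion_sigma > 0 else None
    for f in range(n_frames):
        if f > 0 and steps is not None:
            cur = cur + steps[f]
            cur = np.clip(cur, lo, hi)  # bounded walk
        present = birth_frames <= f
        centroids[f, present] = cur[present]

    sigma = spec.nucleus_radius / 1.1774
    nuclear = np.empty((n_frames, spec.field_size, spec.field_size), dtype=np.uint16)
    death = np.empty_like(nuclear)
    nuc_amp = np.full(n_total, spec.nuclear_amplitude)
    for f in range(n_frames):
        base_n = np.full((spec.field_size, spec.field_size), spec.background, dtype=float)
        base_d = np.full((spec.field_size, spec.field_size), spec.background, dtype=float)
        present = birth_frames <= f
        _render_gaussians(base_n, centroids[f, present], nuc_amp[present], sigma)
        # death-marker amplitude per cell at this frame
        amps = np.zeros(n_total)
        dead = (death_frames >= 0) & (death_frames <= f)
        rise = np.maximum(1, spec.pi_rise_frames)
        frac = 0.6 + 0.4 * np.clip((f - death_frames[dead] + 1) / rise, 0.0, 1.0)
        amps[dead] = frac * spec.pi_step_amplitude
        _render_gaussians(base_d, centroids[f, present], amps[present], sigma)
        if spec.noise_sigma > 0:
            base_n += rng.normal(0.0, spec.noise_sigma, base_n.shape)
            base_d += rng.normal(0.0, spec.noise_sigma, base_d.shape)
        nuclear[f] = np.clip(base_n, 0, 65535).astype(np.uint16)
        death[f] = np.clip(base_d, 0, 65535).astype(np.uint16)

    movie = MovieStack(nuclear, death, frame_interval_min=spec.frame_interval_min)
    gt = GroundTruth(
        death_frames=death_frames,
        death_times_hours=death_times,
        centroids=centroids,
        birth_frames=birth_frames,
        parents=parents,
        division_times_hours=np.asarray(div_times),
        recommended_threshold=None,
    )
    return movie, gt


# ---------------------------------------------------------------------------
# smFISH image sets
# ---------------------------------------------------------------------------


def make_fish_images(spec: FishSceneSpec) -> Tuple[FishImageSet, GroundTruth]:
    """Render a four-channel smFISH field with planted spots.

    Channels: nuclear (DAPI-like), cytoplasmic autofluorescence filling each
    cell footprint, and one channel per transcript where each true molecule
    is a 2-D Gaussian of ``psf_sigma`` placed uniformly inside its cell's
    footprint.  Per-cell counts come from the responder mixture.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    laws = spec.laws()

    # cell geometry: disks on a jittered grid, radii from the area law
    mu = np.log(spec.cell_area_mean) - 0.5 * spec.cell_area_sigma**2
    areas = np.exp(rng.normal(mu, spec.cell_area_sigma, n)) if n else np.empty(0)
    radii = np.sqrt(areas / np.pi)
    max_r = float(radii.max()) if n else 0.0
    centers = _grid_positions(n, spec.field_size, max(2.2 * max_r, 4 * spec.nucleus_radius), rng)

    labels = np.zeros((spec.field_size, spec.field_size), dtype=np.int32)
    yy, xx = np.mgrid[0 : spec.field_size, 0 : spec.field_size]
    for i in range(n):
        d2 = (yy - centers[i, 0]) ** 2 + (xx - centers[i, 1]) ** 2
        labels[d2 <= radii[i] ** 2] = i + 1

    responder = rng.random(n) < spec.responder_fraction if n else np.empty(0, bool)

    nuclear = np.full((spec.field_size, spec.field_size), spec.background, dtype=float)
    auto = np.full_like(nuclear, spec.background)
    if n:
        _render_gaussians(nuclear, centers, np.full(n, spec.nuclear_amplitude), spec.nucleus_radius)
        for i in range(n):
            _render_gaussians(auto, centers[i : i + 1], np.array([spec.autofluorescence_amplitude]),
                              radii[i] / 1.6)

    counts: Dict[str, np.ndarray] = {}
    spot_rows = []
    transcripts: Dict[str, np.ndarray] = {}
    for gene, bylaw in laws.items():
        cnt = np.zeros(n, dtype=int)
        if n:
            n_resp = int(responder.sum())
            cnt[responder] = bylaw["responder"].sample(n_resp, rng)
            cnt[~responder] = bylaw["nonresponder"].sample(n - n_resp, rng)
        counts[gene] = cnt
        img = np.full_like(nuclear, spec.background)
        for i in range(n):
            for _ in range(cnt[i]):
                r = radii[i] * 0.9 * np.sqrt(rng.random())
                ang = rng.uniform(0, 2 * np.pi)
                y = centers[i, 0] + r * np.sin(ang)
                x = centers[i, 1] + r * np.cos(ang)
                _render_gaussians(img, np.array([[y, x]]), np.array([spec.spot_amplitude]),
                                  spec.psf_sigma)
                spot_rows.append((x, y, gene, i + 1))
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        transcripts[gene] = np.clip(img, 0, 65535).astype(np.uint16)

    if spec.noise_sigma > 0:
        nuclear = nuclear + rng.normal(0.0, spec.noise_sigma, nuclear.shape)
        auto = auto + rng.normal(0.0, spec.noise_sigma, auto.shape)

    images = FishImageSet(
        nuclear=np.clip(nuclear, 0, 65535).astype(np.uint16),
        autofluorescence=np.clip(auto, 0, 65535).astype(np.uint16),
        transcripts=transcripts,
    )
    gt = GroundTruth(
        spots=pd.DataFrame(spot_rows, columns=["x", "y", "gene", "cell_id"]),
        responder=responder,
        true_counts=pd.DataFrame(counts, index=np.arange(1, n + 1)),
        cell_labels=labels,
    )
    return images, gt
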