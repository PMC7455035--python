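"""Ground-truthed synthetic two-photon angiograms and capillary line scans.

The generator emulates the data a plasma-labeled in-vivo two-photon
experiment produces: 3D image stacks acquired one z-plane per second in
which capillary lumens are bright and red blood cells cast dark shadows
(static shadows = stalled segment, moving shadows = flowing segment), and
space-time images from repetitive line scans along a capillary centerline
in which each transiting RBC draws a diagonal streak whose slope encodes
its speed.

Every simulated object carries its ground truth so downstream stages
(segmentation, stall scoring, velocimetry) can be tested for recovery
without any real data.

Conventions
-----------
* Arrays are indexed ``(z/frame, y, x)``; voxel sizes are given per axis in
  the same order, in μm.  Physical coordinates are μm at voxel centers,
  0-based.
* Each z-plane of a stack is a snapshot at its own acquisition time
  (``frame_interval`` apart).  A capillary whose tube spans k planes is
  therefore sampled k times, which is what makes stall scoring from a
  single stack possible.
* Cell shadows darken the lumen as a function of arclength along the
  centerline only, so a stalled vessel's shadow pattern is identical in
  every plane in which it is visible (frame-to-frame lumen correlation is
  exactly 1 in the noise-free limit).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "SegmentTruth",
    "GroundTruth",
    "AngiogramStack",
    "LineScanTruth",
    "SpaceTimeImage",
    "SEPARATION_MARGIN",
    "simulate_stack",
    "simulate_ground_truth",
    "simulate_linescan",
    "rasterize_tube",
    "straight_polyline",
    "arc_polyline",
    "helix_polyline",
    "write_stack",
    "read_stack",
]

# Declared stall/flow separation on noise-free stacks at default study
# conditions: the motion statistic (1 - mean frame-to-frame lumen
# correlation) of every flowing segment exceeds that of every stalled
# segment by at least this margin, and exceeds the margin itself.
SEPARATION_MARGIN = 0.15

_BACKGROUND = 20.0  # baseline intensity (arbitrary detector units)
_SHADOW_DEPTH = 0.85  # fractional lumen darkening at an RBC shadow center


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Signal-dependent photon noise plus additive Gaussian read noise.

    ``photon_scale`` is the number of detected photons per intensity unit
    (larger = less shot noise); ``read_noise_sd`` is the sd of the additive
    read noise in intensity units.
    """

    photon_scale: float = 10.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be strictly positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = rng.poisson(image * self.photon_scale) / self.photon_scale
        noisy = noisy + rng.normal(0.0, self.read_noise_sd, size=image.shape)
        return np.clip(noisy, 0.0, None)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic angiogram stack.

    Defaults mirror the imaging protocol the analysis assumes: frames
    acquired at 1 frame/s with 1 μm axial spacing, capillary diameters
    below the 10 μm cutoff, RBC speeds of order 1 mm/s.
    """

    volume_extent: tuple[float, float, float] = (60.0, 150.0, 150.0)  # (z, y, x) μm
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x) μm
    frame_interval: float = 1.0  # s between successive z-planes
    n_vessels: int = 30
    diameter_range: tuple[float, float] = (3.0, 9.0)  # μm
    stall_fraction: float = 0.02
    mean_speed: float = 0.8  # mm/s, typical cortical capillary RBC speed
    speed_dispersion: float = 0.5  # coefficient of variation of speed
    flux_range: tuple[float, float] = (30.0, 120.0)  # RBC/s
    contrast: float = 4.0  # lumen-to-background intensity ratio
    noise_model: NoiseModel | None = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stall_fraction <= 1.0:
            raise ValueError("stall_fraction must lie in [0, 1]")
        if any(e <= 0 for e in self.volume_extent):
            raise ValueError("volume_extent components must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        if self.diameter_range[0] <= 0 or self.diameter_range[1] < self.diameter_range[0]:
            raise ValueError("diameter_range must be positive and ordered")
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be strictly positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be strictly positive")
        if self.contrast <= 1:
            raise ValueError("contrast must exceed 1 (lumen brighter than background)")
        if min(self.volume_extent[1:]) < 4 * self.diameter_range[0]:
            raise ValueError(
                "volume too small to contain a vessel of the minimum diameter"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(e / v)) for e, v in zip(self.volume_extent, self.voxel_size)
        )


@dataclass
class SegmentTruth:
    """Ground truth for one generated capillary segment."""

    segment_id: int
    centerline_um: np.ndarray  # (N, 3) in (z, y, x) μm
    diameter_um: float
    length_um: float
    tortuosity: float
    state: str  # "flowing" | "stalled"
    speed_mm_s: float
    flux_rbc_s: float

    def __post_init__(self) -> None:
        if self.tortuosity < 1.0 - 1e-9:
            raise ValueError("tortuosity must be >= 1")
        if self.state == "stalled" and self.speed_mm_s != 0.0:
            raise ValueError("stalled segments must have speed 0")


@dataclass
class GroundTruth:
    """All per-segment truth records for one simulated stack."""

    segments: list[SegmentTruth]

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_stalled(self) -> int:
        return sum(s.state == "stalled" for s in self.segments)

    @property
    def stall_fraction(self) -> float:
        return self.n_stalled / len(self.segments) if self.segments else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments:
            d = dataclasses.asdict(s)
            d.pop("centerline_um")
            rows.append(d)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        records = []
        for s in self.segments:
            d = dataclasses.asdict(s)
            d["centerline_um"] = np.asarray(s.centerline_um).tolist()
            records.append(d)
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)


@dataclass
class AngiogramStack:
    """Frame-sequential 3D fluorescence stack with acquisition metadata."""

    data: np.ndarray  # (n_frames, ny, nx), non-negative
    voxel_size: tuple[float, float, float]  # (z, y, x) μm
    frame_interval: float  # s
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-dimensional (frame, y, x)")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def imaged_depth_um(self) -> float:
        return self.n_frames * self.voxel_size[0]


@dataclass
class LineScanTruth:
    """Ground truth attached to a simulated space-time image."""

    speed_mm_s: float
    flux_rbc_s: float  # configured Poisson rate
    realized_count: int  # streaks crossing the reference position
    crossing_times_s: np.ndarray
    n_files: int  # 1 = single-file geometry

    @property
    def single_file(self) -> bool:
        return self.n_files == 1


@dataclass
class SpaceTimeImage:
    """Repetitive line-scan record (time x position) from one capillary."""

    data: np.ndarray  # (n_lines, n_pixels)
    line_rate: float  # Hz
    pixel_size: float  # μm
    segment_id: int = -1
    truth: LineScanTruth | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("space-time image needs >= 2 lines and >= 2 positions")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.line_rate

    @property
    def scan_length_um(self) -> float:
        return self.data.shape[1] * self.pixel_size


# --------------------------------------------------------------------------
# centerline primitives (analytic geometry for recovery tests)
# --------------------------------------------------------------------------

def straight_polyline(start, stop, step_um: float = 0.5) -> np.ndarray:
    """Straight centerline from start to stop, (z, y, x) μm, tortuosity 1."""
    start = np.asarray(start, float)
    stop = np.asarray(stop, float)
    n = max(2, int(np.ceil(np.linalg.norm(stop - start) / step_um)) + 1)
    return np.linspace(start, stop, n)


def arc_polyline(center, radius_um: float, angle_span: float = np.pi,
                 plane: str = "yx", step_um: float = 0.5) -> np.ndarray:
    """Circular-arc centerline (default a semicircle: tortuosity = π/2).

    The arc lies in a coordinate plane at the given (z, y, x) μm center.
    """
    center = np.asarray(center, float)
    n = max(2, int(np.ceil(radius_um * angle_span / step_um)) + 1)
    theta = np.linspace(0.0, angle_span, n)
    pts = np.tile(center, (n, 1))
    axes = {"yx": (1, 2), "zy": (0, 1), "zx": (0, 2)}[plane]
    pts[:, axes[0]] += radius_um * np.cos(theta)
    pts[:, axes[1]] += radius_um * np.sin(theta)
    return pts


def helix_polyline(start, radius_um: float, pitch_um: float, n_turns: float,
                   step_um: float = 0.5) -> np.ndarray:
    """Helical centerline along x with analytic tortuosity.

    Path length per turn = sqrt((2πr)² + pitch²); chord per turn = pitch.
    """
    start = np.asarray(start, float)
    total_angle = 2 * np.pi * n_turns
    arc_per_rad = np.hypot(radius_um, pitch_um / (2 * np.pi))
    n = max(2, int(np.ceil(total_angle * arc_per_rad / step_um)) + 1)
    theta = np.linspace(0.0, total_angle, n)
    pts = np.empty((n, 3))
    pts[:, 2] = start[2] + pitch_um * theta / (2 * np.pi)
    pts[:, 1] = start[1] + radius_um * np.sin(theta)
    pts[:, 0] = start[0] + radius_um * (np.cos(theta) - 1.0)
    return pts


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def rasterize_tube(polyline_um: np.ndarray, radius_um: float,
                   shape: tuple[int, int, int],
                   voxel_size: Sequence[float] = (1.0, 1.0, 1.0)):
    """Rasterize a circular tube around a centerline into a voxel grid.

    Returns ``(indices, arclength)``: the (N, 3) integer voxel indices
    (z, y, x) inside the tube and the centerline arclength (μm) of the
    nearest centerline point for each voxel.  Physical positions are voxel
    centers: ``x_um = index * voxel_size``.
    """
    polyline_um = np.asarray(polyline_um, float)
    voxel_size = np.asarray(voxel_size, float)
    s = _polyline_arclength(polyline_um)
    # bounding box in voxel indices, padded by the radius
    pad = radius_um + 1.0
    lo = np.floor((polyline_um.min(axis=0) - pad) / voxel_size).astype(int)
    hi = np.ceil((polyline_um.max(axis=0) + pad) / voxel_size).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape))
    if np.any(hi <= lo):
        return np.empty((0, 3), int), np.empty(0)
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    vox = np.stack([g.ravel() for g in grids], axis=1)
    pos = vox * voxel_size
    tree = cKDTree(polyline_um)
    dist, _ = tree.query(pos, workers=-1)
    inside = dist <= radius_um
    # arclength is assigned from the nearest centerline point in the (y, x)
    # projection, so a static occlusion pattern is identical in every
    # z-plane the tube crosses (frame-to-frame correlation exactly 1 for a
    # stalled vessel in the noise-free limit)
    tree2d = cKDTree(polyline_um[:, 1:])
    _, nearest2d = tree2d.query(pos[inside, 1:], workers=-1)
    return vox[inside], s[nearest2d]


# --------------------------------------------------------------------------
# stack simulation
# --------------------------------------------------------------------------

def _random_vessel_polyline(rng: np.random.Generator, extent, margin: float,
                            step_um: float = 2.0) -> np.ndarray:
    """Smooth random 3D polyline, mostly in-plane with gentle z-drift."""
    extent = np.asarray(extent, float)
    lo = np.array([margin, margin, margin])
    hi = extent - margin
    start = lo + rng.random(3) * (hi - lo)
    phi = rng.uniform(0, 2 * np.pi)
    direction = np.array([rng.uniform(-0.08, 0.08), np.sin(phi), np.cos(phi)])
    direction /= np.linalg.norm(direction)
    target_len = rng.uniform(40.0, 90.0)
    pts = [start]
    p = start.copy()
    traveled = 0.0
    while traveled < target_len:
        # gentle random curvature; z-component damped to keep vessels shallow
        # enough that most of a segment is visible in each frame it spans
        kick = rng.normal(0.0, 0.12, size=3)
        kick[0] *= 0.15
        direction = direction + kick
        direction[0] *= 0.98
        direction /= np.linalg.norm(direction)
        p = p + direction * step_um
        if np.any(p < lo) or np.any(p > hi):
            break
        pts.append(p.copy())
        traveled += step_um
    pts = np.asarray(pts)
    if len(pts) < 2:
        return pts
    # resample finely for accurate rasterization and arclength
    s = _polyline_arclength(pts)
    fine = np.arange(0.0, s[-1], 0.5)
    return np.stack([np.interp(fine, s, pts[:, k]) for k in range(3)], axis=1)


def _cell_half_length(radius_um: float, v_rbc_um3: float = 45.0) -> float:
    """Half-length of an RBC shadow modeled as an ellipsoid of volume 45 μm³
    filling the lumen cross-section (a = 3V / (4 π r²)).

    The rendered shadow is capped at 3 μm half-length: in the narrowest
    capillaries an elongated cell's tapering ends still transmit
    fluorescence, so only the dense mid-body casts a full shadow.
    """
    return float(np.clip(3.0 * v_rbc_um3 / (4.0 * np.pi * radius_um ** 2), 0.8, 3.0))


def _occlusion(s_vox: np.ndarray, cell_pos: np.ndarray, half_len: float) -> np.ndarray:
    """Darkening fraction at arclength positions given cell centers."""
    if cell_pos.size == 0:
        return np.zeros_like(s_vox)
    d = np.abs(s_vox[:, None] - cell_pos[None, :])
    profile = np.exp(-((d / half_len) ** 4))  # super-Gaussian: flat core, sharp edge
    return _SHADOW_DEPTH * profile.max(axis=1)


def _cell_positions_over_frames(rng: np.random.Generator, length: float,
                                density: float, v_um_s: float,
                                frame_interval: float, n_frames: int
                                ) -> list[np.ndarray]:
    """Single-file cell positions at each frame time (renewal process).

    Cells advance by ``v x frame_interval`` between frames, leave at the
    downstream end, and fresh cells enter upstream as a Poisson process, so
    the configuration is stationary with linear density ``density``
    (cells/μm) at every frame.  A stalled vessel (v = 0) keeps its initial
    configuration in every frame.
    """
    positions = rng.uniform(0.0, length, max(1, rng.poisson(density * length)))
    out = [positions.copy()]
    adv = v_um_s * frame_interval
    for _ in range(1, n_frames):
        if adv > 0:
            positions = positions + adv
            positions = positions[positions < length]
            fill = min(adv, length)
            n_new = rng.poisson(density * fill)
            positions = np.concatenate(
                [positions, rng.uniform(0.0, fill, n_new)]
            )
        out.append(positions.copy())
    return out


class _SpatialHash:
    """Coarse-cell point store for fast minimum-distance rejection tests."""

    _OFFSETS = [(dz, dy, dx)
                for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]

    def __init__(self, cell: float):
        self.cell = cell
        self.cells: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def _group(self, points: np.ndarray):
        keys = np.floor(points / self.cell).astype(int)
        groups: dict[tuple[int, int, int], list[np.ndarray]] = {}
        for p, key in zip(points, map(tuple, keys)):
            groups.setdefault(key, []).append(p)
        return groups

    def too_close(self, points: np.ndarray, min_dist: float) -> bool:
        if not self.cells:
            return False
        d2min = min_dist ** 2
        for key, pts in self._group(points[::2]).items():
            neigh = []
            for off in self._OFFSETS:
                chunk = self.cells.get((key[0] + off[0], key[1] + off[1], key[2] + off[2]))
                if chunk:
                    neigh.extend(chunk)
            if not neigh:
                continue
            arr = np.vstack(neigh)
            cand = np.asarray(pts)
            d2 = ((cand[:, None, :] - arr[None, :, :]) ** 2).sum(axis=-1)
            if d2.min() < d2min:
                return True
        return False

    def add(self, points: np.ndarray) -> None:
        for key, pts in self._group(points).items():
            self.cells.setdefault(key, []).append(np.asarray(pts))


def simulate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Generate vessel geometry and flow states without rendering images.

    This is the geometry/state stage of :func:`simulate_stack`; it is exposed
    separately so that vote-aggregation and triage experiments can run on
    large segment populations at negligible cost.
    """
    rng = np.random.default_rng(config.seed)
    segments = []
    sigma_log = np.sqrt(np.log(1.0 + config.speed_dispersion ** 2))
    mu_log = np.log(config.mean_speed) - 0.5 * sigma_log ** 2
    margin = config.diameter_range[1] / 2 + 2.0
    d_max = config.diameter_range[1]
    occupancy = _SpatialHash(cell=d_max + 2.0)
    sid = 0
    attempts = 0
    while sid < config.n_vessels and attempts < 50 * config.n_vessels:
        attempts += 1
        poly = _random_vessel_polyline(rng, config.volume_extent, margin)
        if len(poly) < 2:
            continue
        s = _polyline_arclength(poly)
        length = float(s[-1])
        if length < 20.0:
            continue
        diameter = rng.uniform(*config.diameter_range)
        # keep lumen surfaces well clear of each other so neighboring
        # vessels stay resolvable after the morphological closing the
        # segmenter needs to bridge cell shadows
        if occupancy.too_close(poly, (diameter + d_max) / 2 + 6.5):
            continue
        occupancy.add(poly[::2])
        chord = float(np.linalg.norm(poly[-1] - poly[0]))
        stalled = rng.random() < config.stall_fraction
        if stalled:
            speed = 0.0
            flux = 0.0
        else:
            speed = float(rng.lognormal(mu_log, sigma_log))
            flux = float(rng.uniform(*config.flux_range))
            # flux and speed are coupled through linear cell density
            # (f = density x v); keep density in a physiological band so
            # single-file geometry holds and a snapshot of the lumen is
            # never systematically empty of cells
            density = np.clip(flux / (speed * 1000.0), 0.05, 0.15)
            flux = float(density * speed * 1000.0)
        segments.append(
            SegmentTruth(
                segment_id=sid,
                centerline_um=poly,
                diameter_um=float(diameter),
                length_um=length,
                tortuosity=max(1.0, length / chord),
                state="stalled" if stalled else "flowing",
                speed_mm_s=speed,
                flux_rbc_s=flux,
            )
        )
        sid += 1
    return GroundTruth(segments=segments)


def simulate_stack(config: SimulationConfig) -> tuple[AngiogramStack, GroundTruth]:
    """Render a synthetic plasma-labeled angiogram stack with ground truth.

    Each vessel is a bright tube containing dark cell shadows; shadows are
    static across frames for stalled vessels and advance by
    ``speed x frame_interval`` between successive frames for flowing ones.
    Identical configs (including seed) give bit-identical stacks.
    """
    truth = simulate_ground_truth(config)
    # cells and rendering use a child seed so geometry and rendering draws
    # are decoupled but jointly reproducible
    rng = np.random.default_rng([config.seed, 1])
    shape = config.shape
    vol = np.full(shape, _BACKGROUND, dtype=float)
    lumen_amp = _BACKGROUND * (config.contrast - 1.0)
    vz = config.voxel_size[0]
    mean_density = np.mean(config.flux_range) / (config.mean_speed * 1000.0)

    per_vessel = []  # (vox by plane, s by plane, per-frame cells, half_len)
    for seg in truth.segments:
        radius = seg.diameter_um / 2.0
        vox, s_vox = rasterize_tube(seg.centerline_um, radius, shape, config.voxel_size)
        if len(vox) == 0:
            continue
        half_len = _cell_half_length(radius)
        if seg.state == "flowing":
            density = seg.flux_rbc_s / (seg.speed_mm_s * 1000.0)  # cells/μm
        else:
            density = mean_density
        frame_cells = _cell_positions_over_frames(
            rng, seg.length_um, density, seg.speed_mm_s * 1000.0,
            config.frame_interval, shape[0],
        )
        order = np.argsort(vox[:, 0], kind="stable")
        vox, s_vox = vox[order], s_vox[order]
        zs, starts = np.unique(vox[:, 0], return_index=True)
        bounds = np.append(starts, len(vox))
        by_plane = {
            int(z): (vox[a:b], s_vox[a:b])
            for z, a, b in zip(zs, bounds[:-1], bounds[1:])
        }
        per_vessel.append((by_plane, frame_cells, half_len))

    for z in range(shape[0]):
        for by_plane, frame_cells, half_len in per_vessel:
            if z not in by_plane:
                continue
            vox, s_vox = by_plane[z]
            occ = _occlusion(s_vox, frame_cells[z], half_len)
            intensity = _BACKGROUND + lumen_amp * (1.0 - occ)
            plane = vol[z]
            flat = plane[vox[:, 1], vox[:, 2]]
            plane[vox[:, 1], vox[:, 2]] = np.maximum(flat, intensity)

    if config.noise_model is not None:
        vol = config.noise_model.apply(vol, rng)

    stack = AngiogramStack(
        data=vol,
        voxel_size=config.voxel_size,
        frame_interval=config.frame_interval,
        bit_depth=16,
    )
    return stack, truth


# --------------------------------------------------------------------------
# line-scan simulation
# --------------------------------------------------------------------------

def simulate_linescan(speed: float, flux: float, duration: float,
                      line_rate: float = 2000.0, pixel_size: float = 0.5,
                      scan_length_um: float = 60.0, noise: float = 0.0,
                      cell_length_um: float = 4.0, n_files: int = 1,
                      seed: int = 0, segment_id: int = -1) -> SpaceTimeImage:
    """Simulate a space-time image of single-file RBC transit.

    Parameters
    ----------
    speed : mm/s. Cells advance ``speed / line_rate`` μm per scanned line,
        producing diagonal streaks; 0 gives streaks parallel to the time axis.
    flux : RBC/s. Poisson arrival rate of cells at the scan window.
    duration : s. Record length; ``duration * line_rate`` must be >= 2 lines.
    noise : sd of additive Gaussian noise relative to the unit lumen intensity.
    n_files : 1 for single-file geometry; 2 simulates a second, slightly
        faster stream whose streaks cross the first (non-single-file record).

    The realized streak count (streaks crossing the center of the scan during
    the record) is stored in ``SpaceTimeImage.truth``.
    """
    if speed < 0 or flux < 0:
        raise ValueError("speed and flux must be non-negative")
    n_lines = int(round(duration * line_rate))
    if n_lines < 2:
        raise ValueError("duration x line_rate must be >= 2 lines")
    n_px = int(round(scan_length_um / pixel_size))
    v_um_s = speed * 1000.0
    disp_per_line = v_um_s / line_rate
    if disp_per_line > scan_length_um:
        raise ValueError(
            f"aliasing: per-line displacement {disp_per_line:.1f} μm exceeds the "
            f"scanned length {scan_length_um:.1f} μm; raise line_rate or shorten "
            "the record"
        )
    rng = np.random.default_rng(seed)
    t_lines = np.arange(n_lines) / line_rate
    x_um = (np.arange(n_px) + 0.5) * pixel_size
    img = np.ones((n_lines, n_px))
    x_ref = scan_length_um / 2.0

    speeds = [v_um_s] + ([v_um_s * 1.15] if n_files >= 2 else [])
    all_crossings = []
    for stream_v in speeds:
        stream_flux = flux / len(speeds)
        if stream_v > 0:
            # cells enter at x=0; extend the arrival window so streaks already
            # in the window at t=0 (and those entering late) are represented
            lead = scan_length_um / stream_v
            window = duration + lead
            n_cells = rng.poisson(stream_flux * window)
            t0 = rng.uniform(-lead, duration, size=n_cells)
            crossings = t0 + x_ref / stream_v
        else:
            n_cells = rng.poisson(stream_flux * duration)
            t0 = np.zeros(n_cells)
            crossings = np.full(n_cells, np.nan)  # static cells never cross
        if stream_v > 0:
            positions0 = np.zeros(n_cells)
        else:
            positions0 = rng.uniform(0.0, scan_length_um, size=n_cells)
        half = cell_length_um / 2.0
        for j in range(n_cells):
            xc = positions0[j] + stream_v * (t_lines - t0[j])
            visible = (xc > -2 * half) & (xc < scan_length_um + 2 * half)
            if not np.any(visible):
                continue
            d = np.abs(x_um[None, :] - xc[visible, None])
            img[visible] -= _SHADOW_DEPTH * np.exp(-((d / half) ** 4))
        if stream_v > 0:
            all_crossings.append(crossings[(crossings >= 0) & (crossings < duration)])
        else:
            # a static streak "counts" once if it overlaps the reference column
            static_hit = np.abs(positions0 - x_ref) <= half
            all_crossings.append(np.zeros(int(static_hit.sum())))

    img = np.clip(img, 0.05, None)
    if noise > 0:
        img = img + rng.normal(0.0, noise, size=img.shape)
    crossing_times = np.sort(np.concatenate(all_crossings)) if all_crossings else np.empty(0)
    truth = LineScanTruth(
        speed_mm_s=speed,
        flux_rbc_s=flux,
        realized_count=int(crossing_times.size),
        crossing_times_s=crossing_times,
        n_files=n_files,
    )
    return SpaceTimeImage(
        data=img,
        line_rate=line_rate,
        pixel_size=pixel_size,
        segment_id=segment_id,
        truth=truth,
    )


# --------------------------------------------------------------------------
# TIFF I/O
# --------------------------------------------------------------------------

def write_stack(stack: AngiogramStack, path) -> None:
    """Write a stack as a multi-page TIFF (one page per frame) with
    voxel size and frame interval stored in the image description."""
    meta = {
        "voxel_size_um": list(stack.voxel_size),
        "frame_interval_s": stack.frame_interval,
        "bit_depth": stack.bit_depth,
    }
    scale = (2 ** stack.bit_depth - 1) / max(stack.data.max(), 1e-9)
    data = (stack.data * min(scale, 1.0)).astype(
        np.uint16 if stack.bit_depth > 8 else np.uint8
    )
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_stack(path) -> AngiogramStack:
    """Read a multi-page TIFF written by :func:`write_stack` (metadata in the
    description tag; sensible defaults when absent)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    return AngiogramStack(
        data=data,
        voxel_size=tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0))),
        frame_interval=float(meta.get("frame_interval_s", 1.0)),
        bit_depth=int(meta.get("bit_depth", 16)),
    )
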