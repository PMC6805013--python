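"""Ground-truthed synthetic inputs for every stage of the pipeline.

Three generators emulate the statistical structure the analyses assume:

* :func:`generate_cell_movie` — a two-channel movie of a moving, roughly
  convex cell. Channel 1 is a filled cell body (for segmentation/tracking);
  channel 2 carries a cytosolic background plus a boundary-localized
  biosensor focus whose angular spread follows a von-Mises profile. The
  focus amplitude is calibrated per frame, on the actual pixel grid,
  so that the normalized-distance polarity of the noise-free image equals
  the requested target — the ground truth is exact by construction.
* :func:`generate_kymograph_pair` — matched edge-velocity / edge-
  fluorescence kymographs containing a protrusive band that travels along
  the periodic position axis and reverses at planned frames; the
  fluorescence map is the smoothed velocity map delayed by a known lag.
* :func:`generate_vesicle_mesh` — a relaxed, closed genus-0 triangulated
  vesicle with exactly the requested vertex count.

All randomness comes from one explicit seed per call; equal seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .movie import Movie
from .membrane.mesh import TriMesh, make_vesicle_mesh

__all__ = [
    "SyntheticMovieSpec",
    "GroundTruth",
    "generate_cell_movie",
    "generate_kymograph_pair",
    "generate_vesicle_mesh",
]


@dataclass
class SyntheticMovieSpec:
    """Recipe for a two-channel synthetic cell movie.

    ``motion_model`` is ``("stationary",)``, ``("straight", speed_um_s)``
    (motion along +x) or ``("random_walk", step_sd_um)``.
    ``polarity_profile`` maps a frame index to the target normalized-
    distance polarity in [0, 1); a bare float means a constant target.
    ``focus_width`` (radians) sets the angular spread of the biosensor
    focus; ``bleb_track`` is an optional list of ``(frame, angle_rad)``
    protrusion events rendered as transient rim bumps.
    """

    n_frames: int = 10
    frame_interval: float = 10.0  # s
    pixel_size: float = 0.2  # μm/px
    image_shape: tuple[int, int] = (128, 128)
    cell_radius: float = 5.0  # μm
    motion_model: tuple = ("stationary",)
    polarity_profile: Callable[[int], float] | float = 0.0
    focus_width: float = 0.25  # rad
    focus_angle: float = 0.0  # rad, direction of the biosensor focus
    bleb_track: Sequence[tuple[int, float]] | None = None
    sensor_noise_sd: float = 0.0
    background_level: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.focus_width <= 0:
            raise ValueError("focus_width must be positive")

    def target_polarity(self, t: int) -> float:
        p = self.polarity_profile(t) if callable(self.polarity_profile) else self.polarity_profile
        if not 0.0 <= p < 1.0:
            raise ValueError(f"target polarity {p} outside [0, 1)")
        return float(p)


@dataclass
class GroundTruth:
    """What the generator actually put into its output."""

    centroids: np.ndarray | None = None  # (T, 2) true centers, (row, col) px
    polarity: np.ndarray | None = None  # (T,) true normalized-distance score
    lag_frames: int = 0  # velocity -> fluorescence delay
    reversals: list = field(default_factory=list)  # (frame, boundary fraction)
    zone_intervals: list = field(default_factory=list)  # per frame (lo, hi) fractions


def _motion_path(spec: SyntheticMovieSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_shape
    start = np.array([h / 2.0, w / 2.0])
    kind = spec.motion_model[0]
    path = np.tile(start, (spec.n_frames, 1))
    if kind == "stationary":
        pass
    elif kind == "straight":
        speed_px = spec.motion_model[1] * spec.frame_interval / spec.pixel_size
        path[:, 1] += speed_px * np.arange(spec.n_frames)
    elif kind == "random_walk":
        sd_px = spec.motion_model[1] / spec.pixel_size
        steps = rng.normal(0.0, sd_px, size=(spec.n_frames - 1, 2))
        path[1:] += np.cumsum(steps, axis=0)
    else:
        raise ValueError(f"unknown motion model {kind!r}")
    r_px = spec.cell_radius / spec.pixel_size
    margin = r_px + 2.0
    if (
        path[:, 0].min() < margin
        or path[:, 1].min() < margin
        or path[:, 0].max() > h - 1 - margin
        or path[:, 1].max() > w - 1 - margin
    ):
        raise ValueError("cell would exit the field of view; shrink motion or enlarge the frame")
    return path


def generate_cell_movie(spec: SyntheticMovieSpec) -> tuple[Movie, GroundTruth]:
    """Render the movie described by ``spec`` with exact ground truth.

    Channel ``"body"`` is a bright filled disk on a dim background;
    channel ``"sensor"`` is a cytosolic background plus a von-Mises rim
    focus whose amplitude is solved per frame so that the noise-free
    normalized-distance polarity equals ``spec.polarity_profile(t)``.
    """
    rng = np.random.default_rng(spec.seed)
    path = _motion_path(spec, rng)
    h, w = spec.image_shape
    r_px = spec.cell_radius / spec.pixel_size
    kappa_vm = 1.0 / spec.focus_width**2
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    body = np.empty((spec.n_frames, h, w))
    sensor = np.empty((spec.n_frames, h, w))
    truth = GroundTruth(
        centroids=path.copy(),
        polarity=np.zeros(spec.n_frames),
        lag_frames=0,
    )
    blebs = list(spec.bleb_track or [])
    for frame, angle in blebs:
        if not 0 <= frame < spec.n_frames:
            raise ValueError("bleb_track frame outside the movie")
        truth.reversals.append((int(frame), float((angle / (2 * np.pi)) % 1.0)))
    for t in range(spec.n_frames):
        cr, cc = path[t]
        dr, dc = rows - cr, cols - cc
        r = np.hypot(dr, dc)
        theta = np.arctan2(dr, dc)  # angle in (x=col, y=row) axes
        r_local = np.full(r.shape, r_px)
        for frame, angle in blebs:
            if abs(frame - t) <= 1:
                dtheta = np.angle(np.exp(1j * (theta - angle)))
                r_local += 3.0 * np.exp(-0.5 * (dtheta / 0.25) ** 2)
        body_soft = np.clip(r_local + 0.5 - r, 0.0, 1.0)  # anti-aliased disk
        body[t] = 20.0 + 130.0 * body_soft
        # rim focus, masked by the body so no signal leaks outside the cell
        ring = (
            np.exp(-0.5 * ((r - 0.92 * r_px) / 2.0) ** 2)
            * np.exp(kappa_vm * (np.cos(theta - spec.focus_angle) - 1.0))
            * body_soft
        )
        p_target = spec.target_polarity(t)
        alpha = 0.0
        if p_target > 0:
            footprint = body_soft >= 0.5
            prop = regionprops(footprint.astype(np.uint8))[0]
            half_l = 0.5 * prop.axis_major_length
            c_b = np.asarray(prop.centroid)
            s_ring = ring.sum()
            c_r = np.array(ndi.center_of_mass(ring))
            d_ring = float(np.linalg.norm(c_r - c_b))
            if p_target * half_l >= 0.98 * d_ring:
                raise ValueError(
                    f"target polarity {p_target:.2f} unreachable with focus_width="
                    f"{spec.focus_width}; narrow the focus"
                )
            s_bg = spec.background_level * body_soft.sum()
            alpha = p_target * half_l * s_bg / (s_ring * (d_ring - p_target * half_l))
        sensor[t] = 2.0 + spec.background_level * body_soft + alpha * ring
        truth.polarity[t] = p_target
        lo = ((spec.focus_angle - spec.focus_width) / (2 * np.pi)) % 1.0
        hi = ((spec.focus_angle + spec.focus_width) / (2 * np.pi)) % 1.0
        truth.zone_intervals.append((lo, hi))
    if spec.sensor_noise_sd > 0:
        body += rng.normal(0.0, spec.sensor_noise_sd, body.shape)
        sensor += rng.normal(0.0, spec.sensor_noise_sd, sensor.shape)
        np.clip(body, 0.0, None, out=body)
        np.clip(sensor, 0.0, None, out=sensor)
    movie = Movie(
        channels={"body": body, "sensor": sensor},
        pixel_size=spec.pixel_size,
        frame_interval=spec.frame_interval,
    )
    return movie, truth


def generate_kymograph_pair(
    P: int,
    T: int,
    lag: int,
    reversal_plan: Sequence[int] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
    speed: float = 1.5,
    band_width: float | None = None,
    amplitude: float = 0.3,
    frame_interval: float = 1.0,
    smooth_sigma: tuple[float, float] = (2.0, 1.0),
):
    """Matched velocity/fluorescence kymographs with a known lag.

    A Gaussian protrusive band of peak ``amplitude`` (μm/s) travels at
    ``speed`` index/frame along the periodic position axis, flipping its
    direction at the frames in ``reversal_plan``. The fluorescence map is
    the Gaussian-smoothed velocity map shifted *forward* in time by ``lag``
    frames (fluorescence lags velocity when ``lag`` > 0), plus noise, so the
    lagged cross-correlation of the pair peaks at offset −``lag``.

    Returns ``(vel_map, fluo_map, truth)`` as :class:`~blebkit.edges.EdgeMap`
    objects plus the ground truth (band reversals, per-frame zone interval).
    """
    from .edges import EdgeMap  # local import to avoid a cycle

    if P < 4 or T < 4:
        raise ValueError("P and T must both be at least 4")
    if abs(lag) >= T / 4:
        raise ValueError("|lag| must be below T/4")
    plan = sorted(int(f) for f in reversal_plan)
    if plan and (plan[0] < 0 or plan[-1] >= T):
        raise ValueError("reversal_plan frames must lie in [0, T)")
    rng = np.random.default_rng(seed)
    if band_width is None:
        band_width = P / 20.0
    pad = abs(lag)
    ext = T + 2 * pad
    center = np.empty(ext)
    c = P / 2.0
    direction = 1.0
    flips = set(plan)
    truth = GroundTruth(lag_frames=lag)
    for te in range(ext):
        t = te - pad  # observed-frame clock
        if t in flips:
            direction = -direction
            truth.reversals.append((t, (c % P) / P))
        center[te] = c
        c += direction * speed
    idx = np.arange(P)[:, None]
    dcirc = np.abs(idx - center[None, :] % P)
    dcirc = np.minimum(dcirc, P - dcirc)
    vel_ext = amplitude * np.exp(-0.5 * (dcirc / band_width) ** 2)
    svel = ndi.gaussian_filter(vel_ext, sigma=smooth_sigma, mode=("wrap", "nearest"))
    vel = vel_ext[:, pad : pad + T].copy()
    fluo = np.empty((P, T))
    for t in range(T):
        fluo[:, t] = svel[:, pad + t - lag]
    if noise_sd > 0:
        vel += rng.normal(0.0, noise_sd, vel.shape)
        fluo += rng.normal(0.0, noise_sd, fluo.shape)
    half_w = band_width * np.sqrt(2.0 * np.log(2.0))  # half-max half-width
    for t in range(T):
        ct = center[pad + t] % P
        truth.zone_intervals.append(
            (((ct - half_w) % P) / P, ((ct + half_w) % P) / P)
        )
    vel_map = EdgeMap(values=vel, kind="velocity", frame_interval=frame_interval, perimeter_um=float(P))
    fluo_map = EdgeMap(values=fluo, kind="fluorescence", frame_interval=frame_interval, perimeter_um=float(P))
    return vel_map, fluo_map, truth


def generate_vesicle_mesh(n_vertices: int, radius: float | None = None, seed: int = 0) -> TriMesh:
    """Closed genus-0 vesicle mesh with exactly ``n_vertices`` vertices.

    Thin alias of :func:`blebkit.membrane.mesh.make_vesicle_mesh`; see
    there for the construction and the bond-window guarantees.
    """
    return make_vesicle_mesh(n_vertices, radius=radius, seed=seed)
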