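"""Protrusion detection, direction-reversal calling and the rotation null.

Protrusive regions are connected components of the thresholded,
Gaussian-smoothed edge-velocity kymograph (default threshold 0.15 μm/s),
labeled with 8-connectivity that wraps across the periodic position axis.
Each component's circular center of mass is tracked over time; a reversal
is a sign change of the center-of-mass displacement between consecutive
frames, and only components with at least three reversals over their
lifetime are analyzed (suppresses spurious calls). The Rac-activity zone is
the Otsu-binarized smoothed fluorescence kymograph, whose per-frame edge
positions serve as the reference set; each reversal's circular distance to
the nearest zone edge (as % of perimeter) is compared against a null built
by randomly rotating the zone (default 20 rotations, pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .edges import EdgeMap

__all__ = [
    "ProtrusionComponent",
    "ReversalEvent",
    "ZoneEdgeSet",
    "detect_protrusion_components",
    "track_component_com",
    "call_reversals",
    "rac_zone_edges",
    "reversal_zone_distance",
    "rotation_null",
]


@dataclass
class ProtrusionComponent:
    """One supra-threshold protrusive region of the velocity kymograph."""

    component_id: int
    members: np.ndarray  # (N, 2) int array of (position index, frame)
    P: int  # size of the periodic position axis

    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.members[:, 1])

    @property
    def lifetime(self) -> int:
        f = self.frames
        return int(f.max() - f.min() + 1)


@dataclass
class ReversalEvent:
    """A direction change of a protrusion's center of mass."""

    component_id: int
    frame: int
    position_frac: float  # boundary fraction in [0, 1)
    prev_direction: int  # ±1
    new_direction: int  # ±1


@dataclass
class ZoneEdgeSet:
    """Per-frame circular edge positions of the binary Rac-activity zone.

    ``edges[t]`` is an array of boundary fractions in [0, 1); empty when the
    whole boundary is in a single state at frame t.
    """

    edges: list[np.ndarray]
    perimeter_um: float = np.nan
    binary: np.ndarray | None = field(default=None, repr=False)


def _smooth_periodic(values: np.ndarray, sigma: tuple[float, float]) -> np.ndarray:
    """Gaussian smoothing, periodic in the position axis, clamped in time."""
    return ndi.gaussian_filter(values, sigma=sigma, mode=("wrap", "nearest"))


def detect_protrusion_components(
    vel: EdgeMap,
    smooth_sigma: tuple[float, float] = (5.0, 2.0),
    v_thresh: float = 0.15,
) -> list[ProtrusionComponent]:
    """Label protrusions in a velocity kymograph, wrapping the position axis.

    NaN entries (e.g. the first/last velocity columns) never belong to a
    component. Components split by the array seam at position index 0 are
    merged, so a band crossing the wrap is a single component.
    """
    values = np.where(np.isfinite(vel.values), vel.values, -np.inf)
    smoothed = _smooth_periodic(np.where(np.isfinite(vel.values), vel.values, 0.0), smooth_sigma)
    binary = (smoothed > v_thresh) & np.isfinite(values)
    lab, n = ndi.label(binary, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return []
    # merge labels that touch across the periodic seam (8-connectivity)
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    P, T = lab.shape
    top, bot = lab[0], lab[-1]
    for t in range(T):
        for dt in (-1, 0, 1):
            u = t + dt
            if 0 <= u < T and top[t] and bot[u]:
                union(int(top[t]), int(bot[u]))
    merged = np.array([find(i) for i in range(n + 1)])
    lab = merged[lab]
    comps = []
    for cid, lval in enumerate(np.unique(lab[lab > 0])):
        members = np.argwhere(lab == lval)
        comps.append(ProtrusionComponent(component_id=cid, members=members, P=P))
    return comps


def track_component_com(comp: ProtrusionComponent) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped circular center-of-mass trajectory of a component.

    Returns ``(frames, trajectory)`` where the trajectory is in (continuous,
    unwrapped) position-index units: per frame, the circular mean of member
    positions on the unit circle, unwrapped over time so crossings of the
    periodic seam do not produce jumps. Frames inside the lifetime with no
    members are filled by linear interpolation.
    """
    frames = comp.frames
    if len(frames) < 2:
        raise ValueError("component must span at least 2 frames")
    all_frames = np.arange(frames.min(), frames.max() + 1)
    angles = np.full(all_frames.shape, np.nan)
    for i, f in enumerate(all_frames):
        pos = comp.members[comp.members[:, 1] == f, 0]
        if len(pos) == 0:
            continue
        theta = 2.0 * np.pi * pos / comp.P
        angles[i] = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    good = ~np.isnan(angles)
    unwrapped = np.empty_like(angles)
    unwrapped[good] = np.unwrap(angles[good])
    if (~good).any():
        unwrapped[~good] = np.interp(
            all_frames[~good], all_frames[good], unwrapped[good]
        )
    traj = unwrapped * comp.P / (2.0 * np.pi)
    return all_frames, traj


def call_reversals(
    frames: np.ndarray,
    traj: np.ndarray,
    P: int,
    component_id: int = 0,
    min_reversals: int = 3,
) -> list[ReversalEvent]:
    """Sign changes of consecutive center-of-mass displacements.

    Zero displacement inherits the previous travel direction (plateaus do
    not chatter). Components with fewer than ``min_reversals`` reversals
    contribute no events at all.
    """
    disp = np.diff(traj)
    directions = np.zeros(len(disp), dtype=int)
    current = 0
    for i, d in enumerate(disp):
        if d > 0:
            current = 1
        elif d < 0:
            current = -1
        directions[i] = current
    events = []
    for i in range(1, len(directions)):
        if directions[i] != 0 and directions[i - 1] != 0 and directions[i] != directions[i - 1]:
            events.append(
                ReversalEvent(
                    component_id=component_id,
                    frame=int(frames[i]),
                    position_frac=float((traj[i] % P) / P),
                    prev_direction=int(directions[i - 1]),
                    new_direction=int(directions[i]),
                )
            )
    if len(events) < min_reversals:
        return []
    return events


def rac_zone_edges(
    fluo: EdgeMap,
    smooth_sigma: tuple[float, float] = (5.0, 2.0),
) -> ZoneEdgeSet:
    """Binarize the fluorescence kymograph (one Otsu over the whole map) and
    extract per-frame circular edge positions of the resulting zone.

    An edge sits at the midpoint between two consecutive positions whose
    binary states differ (periodic in position). Frames entirely in one
    state yield an empty edge set.
    """
    finite = np.isfinite(fluo.values)
    filled = np.where(finite, fluo.values, np.nanmean(fluo.values))
    smoothed = _smooth_periodic(filled, smooth_sigma)
    thr = threshold_otsu(smoothed)
    binary = smoothed > thr
    P = binary.shape[0]
    edges = []
    for t in range(binary.shape[1]):
        col = binary[:, t]
        flips = np.nonzero(col != np.roll(col, -1))[0]
        edges.append((flips + 0.5) / P % 1.0)
    return ZoneEdgeSet(edges=edges, perimeter_um=fluo.perimeter_um, binary=binary)


def _circular_distance_frac(a: float, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % 1.0
    return np.minimum(d, 1.0 - d)


def reversal_zone_distance(
    events: list[ReversalEvent], zones: ZoneEdgeSet
) -> tuple[np.ndarray, dict]:
    """Distance from each reversal to the nearest zone edge at its frame.

    Returned in percent of perimeter (bounded by 50%). Events whose frame
    has an empty edge set are skipped and counted in the stats dict, which
    also carries the median, SD and MAD of the distances.
    """
    dists = []
    skipped = 0
    for ev in events:
        edge = zones.edges[ev.frame]
        if len(edge) == 0:
            skipped += 1
            continue
        dists.append(100.0 * float(np.min(_circular_distance_frac(ev.position_frac, edge))))
    arr = np.asarray(dists)
    info = {
        "n_events": len(events),
        "n_skipped": skipped,
        "median_pct": float(np.median(arr)) if arr.size else np.nan,
        "sd_pct": float(np.std(arr, ddof=1)) if arr.size > 1 else np.nan,
        "mad_pct": float(np.median(np.abs(arr - np.median(arr)))) if arr.size else np.nan,
    }
    return arr, info


def rotation_null(
    events: list[ReversalEvent],
    zones: ZoneEdgeSet,
    n_rotations: int = 20,
    rng: np.random.Generator | int | None = None,
    P: int = 1000,
) -> np.ndarray:
    """Pooled event–edge distances after random circular rotations of the zone.

    Each rotation applies one uniform random integer offset (out of P
    boundary positions) to every zone edge and recomputes all event
    distances; the pooled output has n_rotations × n_events entries minus
    skips at empty-edge frames.
    """
    if not events:
        raise ValueError("no events to randomize")
    rng = np.random.default_rng(rng)
    pooled = []
    for _ in range(n_rotations):
        offset = rng.integers(0, P) / P
        shifted = ZoneEdgeSet(
            edges=[(e + offset) % 1.0 for e in zones.edges],
            perimeter_um=zones.perimeter_um,
        )
        d, _ = reversal_zone_distance(events, shifted)
        pooled.append(d)
    return np.concatenate(pooled)
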