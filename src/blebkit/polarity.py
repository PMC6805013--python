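"""Single-cell polarity scores from a biosensor intensity image.

Two scores are computed per cell per timepoint:

* **normalized distance** — the distance *d* between the intensity-weighted
  centroid of the biosensor signal and the centroid of its binary footprint,
  divided by half the major-axis length *L* of the ellipse with the same
  normalized second central moments as the footprint. 0 = signal distributed
  symmetrically about the cell center; ≈1 = all signal at the rim.
* **angular distribution** — the intensity-weighted mean cosine of the angle
  between each footprint pixel (seen from the geometric cell center) and the
  direction of the intensity-weighted centroid. 1 = all signal on one ray
  from the center; 0 = no net angular bias.

Both scores are dimensionless and invariant to uniform intensity rescaling
and to rigid translation; the angular score is also rotation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops

from .movie import CellTrack, LabeledMaskStack, Movie

__all__ = [
    "polarity_distance",
    "polarity_angular",
    "polarity_timecourse",
    "PolarityTrace",
]


def _check_inputs(footprint: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    footprint = np.asarray(footprint, dtype=bool)
    intensity = np.asarray(intensity, dtype=float)
    if footprint.shape != intensity.shape:
        raise ValueError("footprint and intensity shapes differ")
    if not footprint.any():
        raise ValueError("empty footprint")
    if np.any(intensity[footprint] < 0):
        raise ValueError("negative intensity inside footprint")
    return footprint


def _weighted_centroid(footprint: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    w = np.where(footprint, intensity, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total intensity on footprint")
    rows, cols = np.nonzero(footprint)
    wv = w[rows, cols]
    return np.array([np.dot(wv, rows), np.dot(wv, cols)]) / total


def _binary_centroid(footprint: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(footprint)
    return np.array([rows.mean(), cols.mean()])


def major_axis_length(footprint: np.ndarray, weighted_by: np.ndarray | None = None) -> float:
    """Major-axis length (pixels) of the moment-equivalent ellipse.

    By default the binary footprint's second central moments are used, so
    the normalization is independent of the signal being scored; pass the
    intensity image in ``weighted_by`` for intensity-weighted moments.
    """
    footprint = np.asarray(footprint, dtype=bool)
    if weighted_by is None:
        prop = regionprops(footprint.astype(np.uint8))[0]
        return float(prop.axis_major_length)
    rows, cols = np.nonzero(footprint)
    w = np.asarray(weighted_by, dtype=float)[rows, cols]
    total = w.sum()
    mu = np.array([np.dot(w, rows), np.dot(w, cols)]) / total
    dr, dc = rows - mu[0], cols - mu[1]
    cov = np.array(
        [
            [np.dot(w, dr * dr) / total, np.dot(w, dr * dc) / total],
            [np.dot(w, dr * dc) / total, np.dot(w, dc * dc) / total],
        ]
    )
    lam = np.linalg.eigvalsh(cov)[-1]
    return float(4.0 * np.sqrt(lam))


def polarity_distance(
    footprint: np.ndarray,
    intensity: np.ndarray,
    weighted_L: bool = False,
) -> float:
    """Normalized-distance polarity score d / (0.5 L)."""
    footprint = _check_inputs(footprint, intensity)
    d = float(np.linalg.norm(_weighted_centroid(footprint, intensity) - _binary_centroid(footprint)))
    L = major_axis_length(footprint, weighted_by=intensity if weighted_L else None)
    return d / (0.5 * L)


def polarity_angular(footprint: np.ndarray, intensity: np.ndarray) -> float:
    """Angular-distribution polarity score Σ I·cosθ / Σ I.

    The reference vector runs from the geometric (unweighted) footprint
    center to the intensity-weighted centroid. If the two coincide there is
    no reference direction and the score is defined as 0. Pixels lying
    exactly at the geometric center have no angle and are excluded from the
    numerator and denominator.
    """
    footprint = _check_inputs(footprint, intensity)
    center = _binary_centroid(footprint)
    ref = _weighted_centroid(footprint, intensity) - center
    nref = np.linalg.norm(ref)
    if nref == 0:
        return 0.0
    ref = ref / nref
    rows, cols = np.nonzero(footprint)
    vec = np.stack([rows - center[0], cols - center[1]], axis=1)
    norms = np.linalg.norm(vec, axis=1)
    ok = norms > 0
    w = intensity[rows, cols][ok]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total intensity on footprint")
    cosines = (vec[ok] @ ref) / norms[ok]
    return float(np.dot(w, cosines) / total)


@dataclass
class PolarityTrace:
    """Per-cell scores and a population summary, aligned to the stimulus.

    ``cells`` has one row per (track, frame) with columns ``track_id``,
    ``frame``, ``t_s`` (time since stimulus), ``score_distance``,
    ``score_angular`` and ``omitted``; ``summary`` holds the per-timepoint
    mean and 95% t-interval across cells, with omitted frames excluded.
    """

    cells: pd.DataFrame
    summary: pd.DataFrame


def polarity_timecourse(
    tracks: list[CellTrack],
    footprints: LabeledMaskStack,
    movie: Movie,
    channel: str,
    stim_frame: int = 0,
    omit_frames: set[int] | frozenset[int] = frozenset(),
    weighted_L: bool = False,
) -> PolarityTrace:
    """Score every tracked cell at every frame and summarize the population.

    ``footprints`` are the propagated biosensor regions whose labels follow
    each track's per-frame labels; the intensity is the dark-subtracted
    ``channel``. Frames in ``omit_frames`` (e.g. timepoints swamped by the
    uncaging UV flash) are flagged and excluded from the summary. The time
    axis is re-zeroed so that ``stim_frame`` is t = 0 s.
    """
    data = movie.corrected(channel)
    rows = []
    for tr in tracks:
        for f, lab in zip(tr.frames, tr.labels):
            fp = footprints.frame(f) == lab
            if not fp.any():
                continue
            intensity = data[f]
            try:
                sd = polarity_distance(fp, intensity, weighted_L=weighted_L)
                sa = polarity_angular(fp, intensity)
            except ValueError:
                continue
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": f,
                    "t_s": (f - stim_frame) * movie.frame_interval,
                    "score_distance": sd,
                    "score_angular": sa,
                    "omitted": f in omit_frames,
                }
            )
    cells = pd.DataFrame(rows)
    if cells.empty:
        return PolarityTrace(cells=cells, summary=pd.DataFrame())
    kept = cells[~cells["omitted"]]
    groups = []
    for (f, t_s), grp in kept.groupby(["frame", "t_s"]):
        entry = {"frame": f, "t_s": t_s, "n_cells": len(grp)}
        for col in ("score_distance", "score_angular"):
            vals = grp[col].to_numpy()
            m = float(np.mean(vals))
            entry[f"{col}_mean"] = m
            if len(vals) > 1:
                sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                tcrit = float(stats.t.ppf(0.975, len(vals) - 1))
                entry[f"{col}_ci_lo"] = m - tcrit * sem
                entry[f"{col}_ci_hi"] = m + tcrit * sem
            else:
                entry[f"{col}_ci_lo"] = np.nan
                entry[f"{col}_ci_hi"] = np.nan
        groups.append(entry)
    summary = pd.DataFrame(groups).sort_values("frame").reset_index(drop=True)
    return PolarityTrace(cells=cells, summary=summary)
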