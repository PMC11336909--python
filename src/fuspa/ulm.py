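"""Ultrasound localization microscopy: sub-pixel microbubble localization,
optimal-assignment tracking, and accumulation onto a super-resolution grid.

Sparse microbubbles act as point scatterers whose centers can be localized
far below the diffraction limit; linking localizations across frames with a
minimum-total-distance bipartite assignment (the Hungarian algorithm) yields
trajectories, and accumulating many trajectories onto a fine grid (default
10 um) builds density, vertical-direction, and mean-speed maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max

__all__ = [
    "Localization",
    "TrackSet",
    "ULMMaps",
    "localize_mbs",
    "localize_movie",
    "link_tracks",
    "accumulate_maps",
]


@dataclass(frozen=True)
class Localization:
    """One sub-pixel microbubble detection."""

    frame: int
    z: float
    x: float
    amplitude: float


@dataclass
class TrackSet:
    """Microbubble trajectories.

    Each track is an (n, 3) float array of (frame, z, x) with frame indices
    strictly increasing by 1 (no gap closing by default); positions are in
    continuous pixel units.
    """

    tracks: list = field(default_factory=list)
    frame_period_s: float = 1.4e-3
    pixel_pitch_mm: float = 0.1

    @property
    def n_localizations(self) -> int:
        return sum(len(t) for t in self.tracks)


@dataclass
class ULMMaps:
    """Accumulated super-resolution maps on a ``grid_pitch_mm`` grid.

    ``density`` counts localizations per bin; ``direction_coded`` is the
    density signed by each track's net depth displacement (+ descending,
    - ascending); ``mean_speed`` (mm/s) averages the track-step speeds
    touching each bin and is NaN where no step passed.
    """

    density: np.ndarray
    direction_coded: np.ndarray
    mean_speed: np.ndarray
    grid_pitch_mm: float


def _subpixel_refine(frame: np.ndarray, iz: int, ix: int, r: int = 2) -> tuple:
    """Sub-pixel refinement of an integer peak by an intensity-weighted
    log-quadratic surface fit over a (2r+1)^2 neighborhood.

    A Gaussian blob is an exact paraboloid in log-intensity, so the fit is
    exact in the noiseless case; squared-intensity weights keep noisy tail
    pixels from dominating the log. Non-positive pixels are excluded; if too
    few remain, or the fitted surface has no interior maximum along an axis,
    the integer position is kept for that axis. Offsets are clamped to
    +/-1 px.
    """
    nz, nx = frame.shape
    z0, z1 = max(iz - r, 0), min(iz + r + 1, nz)
    x0, x1 = max(ix - r, 0), min(ix + r + 1, nx)
    patch = frame[z0:z1, x0:x1].astype(float)
    zz, xx = np.meshgrid(
        np.arange(z0, z1) - iz, np.arange(x0, x1) - ix, indexing="ij"
    )
    ok = patch > 0
    if ok.sum() < 6:
        return float(iz), float(ix)
    w = patch[ok] ** 2
    y = np.log(patch[ok])
    a_mat = np.column_stack(
        [np.ones(ok.sum()), zz[ok], xx[ok], zz[ok] ** 2, xx[ok] ** 2]
    )
    aw = a_mat * w[:, None]
    try:
        coef = np.linalg.solve(aw.T @ a_mat, aw.T @ y)
    except np.linalg.LinAlgError:
        return float(iz), float(ix)
    _, b, c, d, e = coef
    dz = -b / (2 * d) if d < 0 else 0.0
    dx = -c / (2 * e) if e < 0 else 0.0
    return iz + float(np.clip(dz, -1, 1)), ix + float(np.clip(dx, -1, 1))


def localize_mbs(
    frame: np.ndarray,
    detection_threshold: float,
    min_distance: int = 3,
    frame_index: int = 0,
):
    """Detect and sub-pixel-localize microbubbles in one amplitude frame.

    Regional maxima above ``detection_threshold`` (absolute, on |IQ| or the
    envelope) separated by at least ``min_distance`` pixels are refined by
    separable quadratic interpolation. Returns a (possibly empty) list of
    :class:`Localization`.
    """
    frame = np.asarray(frame, dtype=float)
    peaks = peak_local_max(
        frame,
        min_distance=min_distance,
        threshold_abs=detection_threshold,
        exclude_border=False,
    )
    out = []
    for iz, ix in peaks:
        z, x = _subpixel_refine(frame, int(iz), int(ix))
        out.append(Localization(frame=frame_index, z=z, x=x, amplitude=frame[iz, ix]))
    return out


def localize_movie(frames, detection_threshold: float, min_distance: int = 3):
    """Per-frame localization of a (n_frames, z, x) movie."""
    return [
        localize_mbs(f, detection_threshold, min_distance, frame_index=i)
        for i, f in enumerate(frames)
    ]


def link_tracks(
    detections_per_frame,
    max_link_distance: float,
    min_track_length: int = 20,
    max_gap: int = 0,
    frame_period_s: float = 1.4e-3,
    pixel_pitch_mm: float = 0.1,
) -> TrackSet:
    """Link per-frame localizations into tracks by optimal bipartite matching.

    Frame-to-frame assignment minimizes total Euclidean distance
    (``scipy.optimize.linear_sum_assignment``); pairs farther than
    ``max_link_distance`` are rejected, unmatched detections open new tracks,
    and tracks shorter than ``min_track_length`` localizations are dropped.
    Gap closing is not performed (``max_gap`` must be 0).
    """
    if max_gap != 0:
        raise NotImplementedError("gap closing is not supported (max_gap must be 0)")
    active: list = []  # each: list of Localization
    finished: list = []
    for frame_idx, dets in enumerate(detections_per_frame):
        dets = list(dets)
        if active:
            last = np.array([[t[-1].z, t[-1].x] for t in active])
            if dets:
                cur = np.array([[d.z, d.x] for d in dets])
                cost = cdist(last, cur)
                # forbid links beyond the radius with a large finite cost
                big = max_link_distance * 1e6 + 1.0
                padded = np.where(cost <= max_link_distance, cost, big)
                rows, cols = linear_sum_assignment(padded)
                matched_tracks = set()
                matched_dets = set()
                for r, ccol in zip(rows, cols):
                    if padded[r, ccol] <= max_link_distance:
                        active[r].append(dets[ccol])
                        matched_tracks.add(r)
                        matched_dets.add(ccol)
                still_active = []
                for i, t in enumerate(active):
                    if i in matched_tracks:
                        still_active.append(t)
                    else:
                        finished.append(t)
                active = still_active
                for j, d in enumerate(dets):
                    if j not in matched_dets:
                        active.append([d])
            else:
                finished.extend(active)
                active = []
        else:
            active = [[d] for d in dets]
    finished.extend(active)

    tracks = []
    for t in finished:
        if len(t) >= min_track_length:
            tracks.append(
                np.array([[d.frame, d.z, d.x] for d in t], dtype=float)
            )
    return TrackSet(
        tracks=tracks, frame_period_s=frame_period_s, pixel_pitch_mm=pixel_pitch_mm
    )


def accumulate_maps(
    tracks: TrackSet,
    grid_pitch_mm: float = 0.01,
    fov_shape_px=None,
) -> ULMMaps:
    """Accumulate tracks onto the super-resolution grid.

    Every localization increments its bin in ``density`` (so the density sum
    equals the number of accumulated localizations). Each consecutive-frame
    step contributes its speed — displacement x pixel pitch x frame rate —
    to the bins of both endpoints; ``mean_speed`` is the per-bin average.
    ``direction_coded`` signs each track's counts by its net depth
    displacement (+ descending / downward).
    """
    if grid_pitch_mm <= 0:
        raise ValueError("grid_pitch_mm must be > 0")
    if not tracks.tracks:
        raise ValueError("track set is empty")
    ratio = tracks.pixel_pitch_mm / grid_pitch_mm
    if fov_shape_px is None:
        max_z = max(t[:, 1].max() for t in tracks.tracks)
        max_x = max(t[:, 2].max() for t in tracks.tracks)
        fov_shape_px = (int(np.ceil(max_z)) + 1, int(np.ceil(max_x)) + 1)
    gz = int(np.ceil(fov_shape_px[0] * ratio))
    gx = int(np.ceil(fov_shape_px[1] * ratio))
    density = np.zeros((gz, gx))
    signed = np.zeros((gz, gx))
    speed_sum = np.zeros((gz, gx))
    speed_count = np.zeros((gz, gx))
    frame_rate = 1.0 / tracks.frame_period_s

    def bin_of(z, x):
        bz = min(int(z * ratio), gz - 1)
        bx = min(int(x * ratio), gx - 1)
        return bz, bx

    for track in tracks.tracks:
        direction = 1.0 if track[-1, 1] - track[0, 1] >= 0 else -1.0
        bins = [bin_of(z, x) for _, z, x in track]
        for bz, bx in bins:
            density[bz, bx] += 1
            signed[bz, bx] += direction
        steps = np.diff(track[:, 1:], axis=0)
        step_speed = np.hypot(steps[:, 0], steps[:, 1]) * tracks.pixel_pitch_mm * frame_rate
        for i, sp in enumerate(step_speed):
            for bz, bx in (bins[i], bins[i + 1]):
                speed_sum[bz, bx] += sp
                speed_count[bz, bx] += 1
    mean_speed = np.full((gz, gx), np.nan)
    touched = speed_count > 0
    mean_speed[touched] = speed_sum[touched] / speed_count[touched]
    return ULMMaps(
        density=density,
        direction_coded=signed,
        mean_speed=mean_speed,
        grid_pitch_mm=grid_pitch_mm,
    )
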