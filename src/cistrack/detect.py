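"""Puncta detection, frame-to-frame track linking, and ERES contact calls.

Detection uses a multi-scale Laplacian-of-Gaussian (LoG) blob detector with
anisotropic voxels handled by working in physical (micrometre) units: filter
scales are specified in um and converted to per-axis voxel sigmas, and the
Laplacian is the physical one (per-axis second derivatives weighted by
1/voxel_size^2). The best-responding scale is converted to a PSF-corrected
object diameter by inverting the closed-form LoG response of a Gaussian
blob, which accounts both for the 3-D scale-space bias (the response of an
isotropic Gaussian blob of width sigma_b peaks at sigma = sqrt(2/3) sigma_b,
not sigma_b) and for the axial/lateral PSF anisotropy.

Linking is optimal bipartite assignment (Hungarian algorithm) on squared
displacement, with links beyond a gating distance forbidden and track ends
bridged across short detection gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.optimize import linear_sum_assignment, minimize_scalar

__all__ = [
    "Spot",
    "Track",
    "ContactEvent",
    "detect_spots",
    "link_tracks",
    "detect_contacts",
    "spots_table",
    "tracks_table",
    "contacts_table",
]

_FORBIDDEN = 1e18


@dataclass
class Spot:
    """A detected punctum in one 3D frame (coordinates in um)."""

    frame: int
    z_um: float
    y_um: float
    x_um: float
    intensity: float
    diameter_um: float
    response: float = 0.0
    channel: int = 0


@dataclass
class Track:
    """Temporal linkage of one punctum; gaps are interpolated on demand."""

    track_id: int
    spots: list[Spot] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots])

    @property
    def positions(self) -> np.ndarray:
        return np.array([[s.z_um, s.y_um, s.x_um] for s in self.spots])

    @property
    def birth_frame(self) -> int:
        return self.spots[0].frame

    @property
    def death_frame(self) -> int:
        return self.spots[-1].frame

    def __len__(self) -> int:
        return len(self.spots)

    def interpolated(self) -> tuple[np.ndarray, np.ndarray]:
        """(frames, positions) on every frame of the track's life span;
        positions across detection gaps are linearly interpolated."""
        frames = np.arange(self.birth_frame, self.death_frame + 1)
        have = self.frames
        pos = self.positions
        out = np.column_stack(
            [np.interp(frames, have, pos[:, a]) for a in range(3)]
        )
        return frames, out


@dataclass
class ContactEvent:
    """A maximal run of frames during which a track sits at an ERES."""

    track_id: int
    eres_id: int
    start_frame: int
    end_frame: int
    duration_s: float
    min_distance_um: float


# ---------------------------------------------------------------------------
# scale-space model: best-responding LoG scale for a Gaussian blob


def _blob_response(sigma: float, sb: tuple[float, float, float]) -> float:
    """Scale-normalized LoG center response to an anisotropic Gaussian blob.

    Blob has unit peak amplitude and per-axis sigma ``sb``; the filter is
    isotropic (in um) with width ``sigma``. Up to a constant this is
    sigma^2 * prod_a(sb_a / s_a) * sum_a(1 / s_a^2) with
    s_a^2 = sigma^2 + sb_a^2.
    """
    s2 = np.array([sigma**2 + b**2 for b in sb])
    return float(sigma**2 * np.prod([b / math.sqrt(x) for b, x in zip(sb, s2)]) * np.sum(1.0 / s2))


@lru_cache(maxsize=8)
def _diameter_lookup(psf_xy: float, psf_z: float) -> tuple[np.ndarray, np.ndarray]:
    """Monotone table mapping best-responding scale (um) -> object diameter.

    For each candidate diameter the effective blob widths are
    sqrt((d/4)^2 + psf^2) per axis; the predicted optimal scale is the
    argmax of the closed-form response. Inverting the table is the
    PSF-corrected size estimate (its isotropic no-PSF limit is the familiar
    quadrature subtraction sigma_obj^2 = sigma_meas^2 - sigma_psf^2).
    """
    diameters = np.linspace(0.0, 2.5, 251)
    scales = np.empty_like(diameters)
    for i, d in enumerate(diameters):
        s_obj = d / 4.0
        sb = (
            math.hypot(s_obj, psf_z),
            math.hypot(s_obj, psf_xy),
            math.hypot(s_obj, psf_xy),
        )
        res = minimize_scalar(
            lambda s: -_blob_response(s, sb),
            bounds=(0.05 * min(sb), 3.0 * max(sb)),
            method="bounded",
            options={"xatol": 1e-5},
        )
        scales[i] = res.x
    order = np.argsort(scales)
    return scales[order], diameters[order]


def scale_to_diameter(scale_um, psf_sigma_xy: float, psf_sigma_z: float):
    """PSF-corrected object diameter (um) from a best-responding LoG scale."""
    s, d = _diameter_lookup(round(psf_sigma_xy, 6), round(psf_sigma_z, 6))
    return np.interp(scale_um, s, d)


def _k_squared(shape: tuple[int, ...], voxel: tuple[float, float, float]) -> np.ndarray:
    """|k|^2 grid (rad^2/um^2) matching rfftn output layout."""
    kz = 2 * np.pi * np.fft.fftfreq(shape[0], d=voxel[0])
    ky = 2 * np.pi * np.fft.fftfreq(shape[1], d=voxel[1])
    kx = 2 * np.pi * np.fft.rfftfreq(shape[2], d=voxel[2])
    return (
        kz[:, None, None] ** 2 + ky[None, :, None] ** 2 + kx[None, None, :] ** 2
    )


def _physical_log(
    frame: np.ndarray,
    sigma_um: float,
    voxel: tuple[float, float, float],
    spectrum: np.ndarray | None = None,
    k2: np.ndarray | None = None,
) -> np.ndarray:
    """Scale-normalized negative LoG in physical units.

    Evaluated in the Fourier domain (multiplication by sigma^2 |k|^2
    exp(-sigma^2 |k|^2 / 2)), which keeps sub-voxel filter scales exact on
    anisotropic voxel grids where sampled spatial kernels are unreliable.
    Boundaries are periodic; callers should keep objects a few sigma from
    the border.
    """
    if spectrum is None:
        spectrum = np.fft.rfftn(np.asarray(frame, dtype=np.float64))
    if k2 is None:
        k2 = _k_squared(frame.shape, voxel)
    gain = (sigma_um**2 * k2) * np.exp(-0.5 * sigma_um**2 * k2)
    return np.fft.irfftn(spectrum * gain, s=frame.shape, axes=(0, 1, 2))


def _parabolic_offset(fm: float, f0: float, fp: float) -> float:
    denom = fm - 2.0 * f0 + fp
    if denom >= -1e-12:  # not a strict maximum
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def detect_spots(
    frame: np.ndarray,
    voxel_size: tuple[float, float, float] | None,
    min_diameter: float = 0.25,
    max_diameter: float = 0.9,
    threshold: float = 5.0,
    threshold_mode: str = "sd",
    psf_sigma_xy: float = 0.075,
    psf_sigma_z: float = 0.25,
    n_scales: int = 6,
    min_separation: float | None = None,
    channel: int = 0,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect punctate blobs in one 3D frame.

    Parameters
    ----------
    frame : (nz, ny, nx) array, camera counts.
    voxel_size : (z, y, x) voxel edge lengths in um. Required: anisotropy
        cannot be guessed from the array.
    min_diameter, max_diameter : um, the object size range scanned.
    threshold : detection threshold on spot peak intensity. With
        ``threshold_mode='sd'`` it is in robust standard deviations above
        the frame background (median / MAD estimate); with ``'absolute'``
        it is in raw counts.
    min_separation : um; candidates closer than this to a stronger one are
        suppressed (default: ``min_diameter``).

    Returns spots with sub-voxel centers (per-axis quadratic interpolation
    of the LoG response) and PSF-corrected diameter estimates from the
    best-responding scale (parabolic interpolation across scales).
    """
    if voxel_size is None:
        raise ValueError(
            "voxel_size (z, y, x in um) is required; refusing to assume isotropy"
        )
    frame = np.asarray(frame)
    if frame.ndim != 3:
        raise ValueError(f"expected a 3D frame, got shape {frame.shape}")
    if threshold <= 0 or min_diameter <= 0 or max_diameter <= min_diameter:
        raise ValueError("thresholds and diameter range must be positive and ordered")
    if min_separation is None:
        min_separation = min_diameter
    voxel = tuple(float(v) for v in voxel_size)

    # scale range bracketing the best-responding scales of the diameter range
    lut_s, lut_d = _diameter_lookup(round(psf_sigma_xy, 6), round(psf_sigma_z, 6))
    s_lo = 0.85 * float(np.interp(min_diameter, lut_d, lut_s))
    s_hi = 1.15 * float(np.interp(max_diameter, lut_d, lut_s))
    scales = np.geomspace(s_lo, s_hi, n_scales)

    spectrum = np.fft.rfftn(frame.astype(np.float64))
    k2 = _k_squared(frame.shape, voxel)
    resp = np.stack(
        [_physical_log(frame, s, voxel, spectrum=spectrum, k2=k2) for s in scales]
    )
    maxed = ndi.maximum_filter(resp, size=3, mode="nearest")
    cand = np.argwhere((resp >= maxed) & (resp > 0))

    bg = float(np.median(frame))
    noise_sd = 1.4826 * float(np.median(np.abs(frame - bg)))
    # floor at 0.1% of the dynamic range so a (near-)noiseless background
    # cannot drive the sd-based cut to zero
    noise_floor = max(1e-3 * (float(frame.max()) - bg), 1e-12)
    if threshold_mode == "sd":
        cut = bg + threshold * max(noise_sd, noise_floor)
    elif threshold_mode == "absolute":
        cut = threshold
    else:
        raise ValueError("threshold_mode must be 'sd' or 'absolute'")

    picks = []
    for si, z, y, x in cand:
        if frame[z, y, x] < cut:
            continue
        picks.append((float(resp[si, z, y, x]), int(si), int(z), int(y), int(x)))
    picks.sort(key=lambda p: (-p[0], p[1], p[2], p[3], p[4]))

    kept: list[Spot] = []
    kept_pos: list[np.ndarray] = []
    log_scales = np.log(scales)
    shape = frame.shape
    for r0, si, z, y, x in picks:
        # sub-voxel center from the response at the best scale
        center = np.array([z, y, x], dtype=float)
        layer = resp[si]
        for ax, idx in enumerate((z, y, x)):
            if 0 < idx < shape[ax] - 1:
                lo = tuple(np.array([z, y, x]) - np.eye(3, dtype=int)[ax])
                hi = tuple(np.array([z, y, x]) + np.eye(3, dtype=int)[ax])
                center[ax] += _parabolic_offset(layer[lo], layer[z, y, x], layer[hi])
        pos_um = center * np.array(voxel)
        if kept_pos and np.min(
            np.linalg.norm(np.array(kept_pos) - pos_um, axis=1)
        ) < min_separation:
            continue
        # sub-scale refinement: parabola in log(scale)
        log_s = log_scales[si]
        if 0 < si < len(scales) - 1:
            off = _parabolic_offset(resp[si - 1, z, y, x], r0, resp[si + 1, z, y, x])
            log_s = log_scales[si] + off * (log_scales[1] - log_scales[0])
        diameter = float(
            scale_to_diameter(math.exp(log_s), psf_sigma_xy, psf_sigma_z)
        )
        kept.append(
            Spot(
                frame=frame_index,
                z_um=float(pos_um[0]),
                y_um=float(pos_um[1]),
                x_um=float(pos_um[2]),
                intensity=float(frame[z, y, x]),
                diameter_um=diameter,
                response=r0,
                channel=channel,
            )
        )
        kept_pos.append(pos_um)
    return kept


def detect_spots_movie(
    stack: np.ndarray,
    voxel_size: tuple[float, float, float],
    channel: int | None = None,
    **kwargs,
) -> list[Spot]:
    """Run :func:`detect_spots` on every frame of a (t, c, z, y, x) stack.

    With ``channel=None`` the channels are summed before detection, so a
    cisterna stays detectable across its whole two-marker life span.
    """
    spots: list[Spot] = []
    for f in range(stack.shape[0]):
        frame = stack[f].sum(axis=0) if channel is None else stack[f, channel]
        spots.extend(
            detect_spots(
                frame,
                voxel_size,
                frame_index=f,
                channel=-1 if channel is None else channel,
                **kwargs,
            )
        )
    return spots


# ---------------------------------------------------------------------------
# linking


def link_tracks(
    spots: list[Spot],
    max_displacement: float = 0.5,
    max_gap: int = 2,
) -> list[Track]:
    """Link spots into tracks by optimal frame-to-frame assignment.

    At each frame, open tracks (last spot within ``max_gap + 1`` frames) and
    the frame's spots are matched by the Hungarian algorithm on squared
    distance; pairs farther than ``max_displacement`` (um) are forbidden.
    Unmatched spots seed new tracks. Fully deterministic: candidates are
    ordered by (last frame, track id) and spots by detection order.
    """
    if not spots:
        return []
    by_frame: dict[int, list[Spot]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)

    tracks: list[Track] = []
    open_ids: list[int] = []
    lo, hi = min(by_frame), max(by_frame)
    for f in range(lo, hi + 1):
        frame_spots = by_frame.get(f, [])
        open_ids = [
            i for i in open_ids if f - tracks[i].spots[-1].frame <= max_gap + 1
        ]
        if frame_spots and open_ids:
            last = np.array(
                [
                    [tracks[i].spots[-1].z_um, tracks[i].spots[-1].y_um, tracks[i].spots[-1].x_um]
                    for i in open_ids
                ]
            )
            new = np.array([[s.z_um, s.y_um, s.x_um] for s in frame_spots])
            d2 = ((last[:, None, :] - new[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_displacement**2, d2, _FORBIDDEN)
            rows, cols = linear_sum_assignment(cost)
            matched_spots = set()
            for r, c in zip(rows, cols):
                if cost[r, c] >= _FORBIDDEN:
                    continue
                tracks[open_ids[r]].spots.append(frame_spots[c])
                matched_spots.add(c)
        else:
            matched_spots = set()
        for c, s in enumerate(frame_spots):
            if c not in matched_spots:
                tracks.append(Track(track_id=len(tracks), spots=[s]))
                open_ids.append(len(tracks) - 1)
        # keep matched tracks open
        open_ids = sorted(set(open_ids))
    return tracks


# ---------------------------------------------------------------------------
# contacts


def detect_contacts(
    tracks: list[Track],
    eres_positions: np.ndarray,
    frame_interval: float | None,
    contact_distance: float = 0.35,
    min_frames: int = 2,
) -> list[ContactEvent]:
    """Find maximal runs of frames during which a track touches an ERES.

    A contact event is >= ``min_frames`` consecutive frames with
    track-to-ERES center distance <= ``contact_distance`` (um). The reported
    duration follows the (last - first) * frame_interval convention, so a
    single-frame dip has duration 0.
    """
    if frame_interval is None:
        raise ValueError("frame_interval (s) is required to report durations")
    eres_positions = np.atleast_2d(np.asarray(eres_positions, dtype=float))
    events: list[ContactEvent] = []
    for track in tracks:
        frames, pos = track.interpolated()
        for j, ep in enumerate(eres_positions):
            dist = np.linalg.norm(pos - ep[None, :], axis=1)
            close = dist <= contact_distance
            i = 0
            n = len(frames)
            while i < n:
                if not close[i]:
                    i += 1
                    continue
                j2 = i
                while j2 + 1 < n and close[j2 + 1]:
                    j2 += 1
                if j2 - i + 1 >= min_frames:
                    events.append(
                        ContactEvent(
                            track_id=track.track_id,
                            eres_id=j,
                            start_frame=int(frames[i]),
                            end_frame=int(frames[j2]),
                            duration_s=float((frames[j2] - frames[i]) * frame_interval),
                            min_distance_um=float(dist[i : j2 + 1].min()),
                        )
                    )
                i = j2 + 1
    return events


# ---------------------------------------------------------------------------
# tabular views


def spots_table(spots: list[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": s.frame,
                "channel": s.channel,
                "z_um": s.z_um,
                "y_um": s.y_um,
                "x_um": s.x_um,
                "intensity": s.intensity,
                "diameter_um": s.diameter_um,
                "response": s.response,
            }
            for s in spots
        ],
        columns=["frame", "channel", "z_um", "y_um", "x_um", "intensity", "diameter_um", "response"],
    )


def tracks_table(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for s in t.spots:
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": s.frame,
                    "z_um": s.z_um,
                    "y_um": s.y_um,
                    "x_um": s.x_um,
                    "intensity": s.intensity,
                    "diameter_um": s.diameter_um,
                }
            )
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "z_um", "y_um", "x_um", "intensity", "diameter_um"]
    )


def contacts_table(events: list[ContactEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": e.track_id,
                "eres_id": e.eres_id,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "duration_s": e.duration_s,
                "min_distance_um": e.min_distance_um,
            }
            for e in events
        ],
        columns=["track_id", "eres_id", "start_frame", "end_frame", "duration_s", "min_distance_um"],
    )
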