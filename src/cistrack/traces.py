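"""Per-cisterna fluorescence time courses and maturation statistics.

The measurement chain mirrors how maturation kinetics are quantified from
two-colour movies: the mean intensity F inside a small ROI following the
tracked cisterna is read out per channel per frame, normalized to its
maximum over the observation window (F/F_peak), the per-channel peak times
give the peak-to-peak duration delta = t_red - t_green of that cisterna,
and traces from many cisternae are averaged after shifting each pair so
that time zero is the midpoint between its green and red peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .detect import Track

__all__ = [
    "CisternaTrace",
    "PeakPair",
    "MaturationSummary",
    "extract_trace",
    "find_peak",
    "peak_to_peak",
    "align_and_average",
    "residency_interval",
    "summarize_maturation",
]


@dataclass
class CisternaTrace:
    """Two(-or-more)-channel intensity readout along one track.

    ``intensity`` has shape (n_frames, n_channels), background already
    subtracted according to the chosen policy. ``normalized`` rescales each
    channel by its maximum over the observed window (F/F_peak).
    """

    track_id: int
    times: np.ndarray  # seconds, constant spacing
    intensity: np.ndarray  # (n_frames, n_channels)
    roi_radius_um: float
    background: np.ndarray  # per-channel background estimate subtracted

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def normalized(self) -> np.ndarray:
        peak = self.intensity.max(axis=0)
        peak = np.where(peak > 0, peak, 1.0)
        return self.intensity / peak


@dataclass(frozen=True)
class PeakPair:
    """Green and red peak times of one cisterna and their difference."""

    t_green_peak: float
    t_red_peak: float

    @property
    def delta(self) -> float:
        """Peak-to-peak duration; positive when red peaks later."""
        return self.t_red_peak - self.t_green_peak

    @property
    def midpoint(self) -> float:
        """The alignment origin: midway between the two peaks."""
        return 0.5 * (self.t_green_peak + self.t_red_peak)


@dataclass
class MaturationSummary:
    """Aggregated peak-to-peak statistics and aligned average curves."""

    label: str
    n: int
    mean_delta_s: float
    sd_delta_s: float
    sem_delta_s: float
    grid_s: np.ndarray
    mean_curves: np.ndarray  # (n_grid, n_channels)
    sem_curves: np.ndarray
    coverage: np.ndarray  # traces contributing per grid point
    deltas_s: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": [self.label],
                "mean_delta_s": [self.mean_delta_s],
                "sd_delta_s": [self.sd_delta_s],
                "sem_delta_s": [self.sem_delta_s],
                "n_puncta": [self.n],
            }
        )


def extract_trace(
    track: Track,
    stack: np.ndarray,
    voxel_size: tuple[float, float, float],
    frame_interval: float,
    roi_radius_um: float = 0.35,
    background: str | float = "none",
) -> CisternaTrace:
    """Mean ROI intensity per channel along a track.

    The ROI is a sphere of ``roi_radius_um`` in physical units (hence an
    ellipsoid in voxel indices) centred on the track position; positions on
    frames with a detection gap are linearly interpolated. ROIs clipped by
    the image border are truncated with a warning.

    background: 'none' (raw ROI means), 'median' (subtract the per-frame,
    per-channel image median), or a constant in counts.
    """
    if roi_radius_um <= 0:
        raise ValueError("roi_radius_um must be > 0")
    n_frames, n_channels = stack.shape[:2]
    frames, pos = track.interpolated()
    if frames[0] < 0 or frames[-1] >= n_frames:
        raise ValueError("track extends outside the stack")
    voxel = np.asarray(voxel_size, dtype=float)
    shape = np.array(stack.shape[2:])
    half = np.ceil(roi_radius_um / voxel).astype(int)

    out = np.empty((len(frames), n_channels))
    bg = np.zeros(n_channels)
    warned = False
    for i, (f, center) in enumerate(zip(frames, pos)):
        c_vox = center / voxel
        lo = np.floor(c_vox - half).astype(int)
        hi = np.ceil(c_vox + half).astype(int) + 1
        if (lo < 0).any() or (hi > shape).any():
            if not warned:
                warnings.warn(
                    f"ROI of track {track.track_id} truncated at image border",
                    stacklevel=2,
                )
                warned = True
            lo = np.maximum(lo, 0)
            hi = np.minimum(hi, shape)
        grids = np.meshgrid(
            *[(np.arange(lo[a], hi[a]) * voxel[a] - center[a]) for a in range(3)],
            indexing="ij",
        )
        mask = sum(g**2 for g in grids) <= roi_radius_um**2
        if not mask.any():
            raise ValueError(f"empty ROI for track {track.track_id} at frame {f}")
        for c in range(n_channels):
            sub = stack[f, c, lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            val = float(sub[mask].mean())
            if background == "median":
                val -= float(np.median(stack[f, c]))
            out[i, c] = val
    if isinstance(background, (int, float)) and not isinstance(background, bool):
        out -= float(background)
        bg[:] = float(background)
    elif background not in ("none", "median"):
        raise ValueError("background must be 'none', 'median' or a constant")
    times = frames * frame_interval
    return CisternaTrace(
        track_id=track.track_id,
        times=times.astype(float),
        intensity=out,
        roi_radius_um=roi_radius_um,
        background=bg,
    )


def find_peak(
    values: np.ndarray, times: np.ndarray, smoothing_window: int = 3
) -> float:
    """Peak time of one channel: argmax after moving-average smoothing.

    Ties are broken toward the earliest time; no sub-frame interpolation is
    performed, so the result is always one of ``times``. A constant series
    has no unique peak and raises ``ValueError``.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 samples to locate a peak")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    smooth = ndi.uniform_filter1d(values, size=smoothing_window, mode="nearest")
    if np.ptp(smooth) == 0:
        raise ValueError("no unique peak: trace is constant after smoothing")
    return float(times[int(np.argmax(smooth))])


def peak_to_peak(
    trace: CisternaTrace,
    green: int = 0,
    red: int = 1,
    smoothing_window: int = 3,
) -> PeakPair:
    """Per-cisterna peak-to-peak pair from a two-channel trace."""
    t_g = find_peak(trace.intensity[:, green], trace.times, smoothing_window)
    t_r = find_peak(trace.intensity[:, red], trace.times, smoothing_window)
    return PeakPair(t_green_peak=t_g, t_red_peak=t_r)


def align_and_average(
    traces: list[CisternaTrace],
    pairs: list[PeakPair],
    grid_spacing: float | None = None,
    label: str = "green->red",
) -> MaturationSummary:
    """Midpoint-align traces and average their F/F_peak curves.

    Each trace's time axis is shifted by minus its pair midpoint (so the
    green and red peaks sit at -delta/2 and +delta/2), resampled by linear
    interpolation onto a common grid, and averaged per grid point over the
    traces whose observation window covers that point (no extrapolation).
    """
    if not traces:
        raise ValueError("no traces to average")
    if len(traces) != len(pairs):
        raise ValueError("traces and pairs must pair up")
    if grid_spacing is None:
        grid_spacing = float(traces[0].times[1] - traces[0].times[0])

    shifted = [tr.times - pp.midpoint for tr, pp in zip(traces, pairs)]
    lo = min(t[0] for t in shifted)
    hi = max(t[-1] for t in shifted)
    grid = np.arange(
        np.floor(lo / grid_spacing), np.ceil(hi / grid_spacing) + 1
    ) * grid_spacing

    n_channels = traces[0].n_channels
    resampled = np.full((len(traces), len(grid), n_channels), np.nan)
    for i, (tr, t_sh) in enumerate(zip(traces, shifted)):
        norm = tr.normalized
        inside = (grid >= t_sh[0] - 1e-9) & (grid <= t_sh[-1] + 1e-9)
        for c in range(n_channels):
            resampled[i, inside, c] = np.interp(grid[inside], t_sh, norm[:, c])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(resampled, axis=0)
        coverage = np.sum(~np.isnan(resampled[:, :, 0]), axis=0)
        sd = np.nanstd(resampled, axis=0, ddof=1)
    sem = sd / np.sqrt(np.maximum(coverage, 1))[:, None]

    deltas = np.array([pp.delta for pp in pairs])
    n = len(deltas)
    sd_delta = float(np.std(deltas, ddof=1)) if n > 1 else 0.0
    return MaturationSummary(
        label=label,
        n=n,
        mean_delta_s=float(deltas.mean()),
        sd_delta_s=sd_delta,
        sem_delta_s=sd_delta / np.sqrt(n) if n > 1 else 0.0,
        grid_s=grid,
        mean_curves=mean,
        sem_curves=sem,
        coverage=coverage,
        deltas_s=deltas,
    )


def residency_interval(
    grid_s: np.ndarray,
    curve: np.ndarray,
    threshold_fraction: float = 0.2,
) -> tuple[float, float]:
    """First and last times the averaged curve stays above a fraction of
    its peak, with linear interpolation at the crossings.

    With ``threshold_fraction=0`` this returns the full observed support.
    """
    grid_s = np.asarray(grid_s, dtype=float)
    curve = np.asarray(curve, dtype=float)
    ok = np.isfinite(curve)
    grid_s, curve = grid_s[ok], curve[ok]
    if curve.size == 0 or curve.max() <= 0:
        raise ValueError("curve has no positive values")
    thr = threshold_fraction * curve.max()
    above = curve >= thr
    if not above.any():
        raise ValueError("curve never reaches the residency threshold")
    first = int(np.argmax(above))
    last = len(curve) - 1 - int(np.argmax(above[::-1]))
    start = grid_s[first]
    if first > 0 and curve[first] > thr:
        start = np.interp(thr, [curve[first - 1], curve[first]], [grid_s[first - 1], grid_s[first]])
    end = grid_s[last]
    if last < len(curve) - 1 and curve[last] > thr:
        end = np.interp(
            thr, [curve[last + 1], curve[last]], [grid_s[last + 1], grid_s[last]]
        )
    return float(start), float(end)


def summarize_maturation(
    tracks: list[Track],
    stack: np.ndarray,
    voxel_size: tuple[float, float, float],
    frame_interval: float,
    roi_radius_um: float = 0.35,
    background: str | float = "none",
    smoothing_window: int = 3,
    min_track_frames: int = 5,
    edge_margin_frames: int = 1,
    min_contrast: float = 0.3,
    label: str = "green->red",
) -> tuple[MaturationSummary, list[CisternaTrace], list[PeakPair], list[str]]:
    """Tracks -> traces -> peak pairs -> summary, with exclusion logging.

    Tracks are excluded (with a reason string) when too short, when a
    channel has no unique peak or shows no real signal ((max - min) / min
    contrast below ``min_contrast``, i.e. the channel never rises above
    background within the track), or when a peak lands on the first/last
    observed frame (its true maximum may lie outside the window).
    """
    traces, pairs, log = [], [], []
    for track in tracks:
        if len(track) < min_track_frames:
            log.append(f"track {track.track_id}: excluded, only {len(track)} frames")
            continue
        trace = extract_trace(
            track, stack, voxel_size, frame_interval, roi_radius_um, background
        )
        smooth = ndi.uniform_filter1d(
            trace.intensity, size=smoothing_window, axis=0, mode="nearest"
        )
        floor = np.maximum(smooth.min(axis=0), 1e-9)
        contrast = (smooth.max(axis=0) - smooth.min(axis=0)) / floor
        if (contrast < min_contrast).any():
            log.append(
                f"track {track.track_id}: excluded, channel without signal "
                f"(contrast {contrast.min():.2f})"
            )
            continue
        try:
            pair = peak_to_peak(trace, smoothing_window=smoothing_window)
        except ValueError as err:
            log.append(f"track {track.track_id}: excluded, {err}")
            continue
        t0 = trace.times[0] + (edge_margin_frames - 1) * frame_interval
        t1 = trace.times[-1] - (edge_margin_frames - 1) * frame_interval
        if min(pair.t_green_peak, pair.t_red_peak) <= t0 or max(
            pair.t_green_peak, pair.t_red_peak
        ) >= t1:
            log.append(
                f"track {track.track_id}: excluded, peak at observation window edge"
            )
            continue
        traces.append(trace)
        pairs.append(pair)
        log.append(
            f"track {track.track_id}: delta = {pair.delta:+.1f} s "
            f"(green {pair.t_green_peak:.1f} s, red {pair.t_red_peak:.1f} s)"
        )
    if not traces:
        raise ValueError("no usable traces survived filtering")
    summary = align_and_average(traces, pairs, frame_interval, label=label)
    return summary, traces, pairs, log
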