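"""Ground-truthed synthetic 4D fluorescence movies of maturing cisternae.

This module renders multi-channel time-lapse 3D stacks that emulate
high-speed spinning-disk confocal (SCLIM-style) acquisitions of budding
yeast: mobile punctate cisternae ~0.5 um in diameter that live for a few
minutes, recruit fluorescent markers sequentially (each channel's intensity
follows a smooth unimodal pulse with a programmed peak time), and optionally
approach static ER exit sites (ERES) for transient seconds-scale contacts.

Every generated movie is paired with an exact ground-truth register (peak
times, channel-to-channel delays, per-frame centers, contact windows) so the
detection, tracking, trace and contact analyses can be scored against truth.

Units: lengths in micrometres, times in seconds, intensities in camera
counts. Axis order is t, c, z, y, x throughout; voxel centers sit at
index * voxel size.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionConfig",
    "MarkerKinetics",
    "SimCisterna",
    "SimERES",
    "GroundTruth",
    "PRESETS",
    "preset_config",
    "kinetic_profile",
    "generate_movie",
    "generate_coloc_phantom",
    "maturation_scene",
    "contact_scene",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Geometry, optics and camera model of one acquisition regime.

    Defaults mirror a 4D maturation movie: 21 optical slices 0.2 um apart
    acquired every 5 s, with ~0.18 um lateral resolution (Gaussian PSF,
    sigma = FWHM / 2.355) and an EM-CCD-like camera (Poisson shot noise on
    the photon signal, Gaussian read noise, constant offset).
    """

    nx: int = 64
    ny: int = 64
    nz: int = 21
    voxel_xy: float = 0.1
    voxel_z: float = 0.2
    n_frames: int = 40
    frame_interval: float = 5.0
    psf_sigma_xy: float = 0.075
    psf_sigma_z: float = 0.25
    camera_offset: float = 100.0
    read_noise_sd: float = 2.0
    photons_per_unit: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz", "n_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("voxel_xy", "voxel_z", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValueError("PSF sigmas must be > 0")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """(z, y, x) voxel edge lengths in micrometres."""
        return (self.voxel_z, self.voxel_xy, self.voxel_xy)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def fov_um(self) -> tuple[float, float, float]:
        """(z, y, x) physical extent spanned by voxel centers."""
        return (
            (self.nz - 1) * self.voxel_z,
            (self.ny - 1) * self.voxel_xy,
            (self.nx - 1) * self.voxel_xy,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionConfig":
        return cls(**json.loads(Path(path).read_text()))


#: The three acquisition regimes used throughout: a single-timepoint 3D
#: survey (41 slices), 4D maturation imaging (21 slices every 5 s) and fast
#: 4D contact imaging (9 slices 0.25 um apart every 1.1 s).
PRESETS: dict[str, dict] = {
    "survey": dict(nz=41, voxel_z=0.2, n_frames=1, frame_interval=5.0),
    "maturation": dict(nz=21, voxel_z=0.2, frame_interval=5.0),
    "contact": dict(nz=9, voxel_z=0.25, frame_interval=1.1),
}


def preset_config(name: str, **overrides) -> AcquisitionConfig:
    """Build an :class:`AcquisitionConfig` from a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return AcquisitionConfig(**kwargs)


@dataclass(frozen=True)
class MarkerKinetics:
    """Unimodal recruitment pulse of one marker on one cisterna.

    The pulse is an asymmetric Gaussian: amplitude * exp(-(t-peak)^2 /
    (2 rise_sigma^2)) before the peak and with decay_sigma after it, which
    reproduces the rise-and-fall of measured F/F_peak curves while keeping
    the true peak time available in closed form.

    zone_offset displaces this marker's sub-zone from the cisterna center
    (z, y, x, um), modelling intra-cisternal segregation of early and late
    marker zones; the displacement is ramped on and off around the
    cisterna's transition window by the renderer.
    """

    peak_time: float
    rise_sigma: float = 15.0
    decay_sigma: float = 20.0
    amplitude: float = 1.0
    zone_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rise_sigma <= 0 or self.decay_sigma <= 0:
            raise ValueError("rise_sigma and decay_sigma must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def kinetic_profile(t, k: MarkerKinetics):
    """Evaluate the marker pulse at time(s) ``t`` (seconds).

    Returns ``k.amplitude`` at ``t == k.peak_time``, falling off as a
    Gaussian with ``rise_sigma`` before the peak and ``decay_sigma`` after.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time passed to kinetic_profile")
    dt = t - k.peak_time
    sigma = np.where(dt < 0, k.rise_sigma, k.decay_sigma)
    out = k.amplitude * np.exp(-0.5 * (dt / sigma) ** 2)
    return out if out.ndim else float(out)


@dataclass
class SimCisterna:
    """One simulated cisterna: lifetime, per-frame center, marker pulses."""

    cisterna_id: int
    birth_time: float
    death_time: float
    trajectory: np.ndarray  # (n_frames, 3) z,y,x centers in um
    kinetics: tuple[MarkerKinetics, ...]  # one per channel
    diameter: float = 0.5

    def __post_init__(self) -> None:
        self.trajectory = np.asarray(self.trajectory, dtype=float)
        if self.death_time <= self.birth_time:
            raise ValueError("death_time must exceed birth_time")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")

    def zone_ramp(self, t: float) -> float:
        """Weight in [0, 1] applied to zone offsets at time ``t``.

        Rises linearly from 0 at the earliest marker peak to 1 at the
        midpoint of the peak span and back to 0 at the latest peak, so
        sub-zones segregate most strongly mid-transition.
        """
        peaks = [k.peak_time for k in self.kinetics]
        lo, hi = min(peaks), max(peaks)
        if hi - lo <= 0:
            return 0.0
        mid = 0.5 * (lo + hi)
        return float(np.clip(1.0 - abs(t - mid) / (0.5 * (hi - lo)), 0.0, 1.0))


@dataclass
class SimERES:
    """A static ER exit site with a schedule of cisterna contacts."""

    eres_id: int
    position: tuple[float, float, float]  # z,y,x um
    diameter: float = 0.5
    amplitude: float = 1.0
    channel: int = 1
    contact_schedule: list[tuple[int, float, float]] = field(default_factory=list)
    # entries: (partner cisterna id, start s, end s)


@dataclass
class GroundTruth:
    """Exact truth register for one simulated movie.

    ``cisternae``: one row per cisterna (birth/death, per-channel true peak
    times, ``delta_true_s`` = red peak - green peak).
    ``centers``: one row per cisterna per frame (true z,y,x um).
    ``contacts``: one row per scheduled ERES contact (start/end s).
    """

    cisternae: pd.DataFrame
    centers: pd.DataFrame
    contacts: pd.DataFrame

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.cisternae.to_csv(prefix.with_suffix(".cisternae.csv"), index=False)
        self.centers.to_csv(prefix.with_suffix(".centers.csv"), index=False)
        self.contacts.to_csv(prefix.with_suffix(".contacts.csv"), index=False)

    @classmethod
    def load(cls, prefix: str | Path) -> "GroundTruth":
        prefix = Path(prefix)
        return cls(
            cisternae=pd.read_csv(prefix.with_suffix(".cisternae.csv")),
            centers=pd.read_csv(prefix.with_suffix(".centers.csv")),
            contacts=pd.read_csv(prefix.with_suffix(".contacts.csv")),
        )


def _spot_sigmas(diameter: float, config: AcquisitionConfig) -> tuple[float, float, float]:
    """Effective per-axis Gaussian sigmas (um) of a rendered object.

    The object is approximated as a Gaussian of sigma = diameter / 4;
    convolution with the Gaussian PSF adds variances.
    """
    s_obj = diameter / 4.0
    sz = math.hypot(s_obj, config.psf_sigma_z)
    sxy = math.hypot(s_obj, config.psf_sigma_xy)
    return (sz, sxy, sxy)


def _add_gaussian_spot(
    photons: np.ndarray,
    center_um: np.ndarray,
    sigmas_um: tuple[float, float, float],
    amplitude: float,
    voxel: tuple[float, float, float],
) -> None:
    """Accumulate a peak-normalized 3D Gaussian into ``photons`` in place."""
    if amplitude <= 0:
        return
    shape = photons.shape
    lo, hi, grids = [], [], []
    for ax in range(3):
        c_vox = center_um[ax] / voxel[ax]
        half = 4.0 * sigmas_um[ax] / voxel[ax]
        a = max(0, int(math.floor(c_vox - half)))
        b = min(shape[ax], int(math.ceil(c_vox + half)) + 1)
        if a >= b:
            return
        lo.append(a)
        hi.append(b)
        idx = np.arange(a, b)
        grids.append(((idx * voxel[ax] - center_um[ax]) / sigmas_um[ax]) ** 2)
    gz, gy, gx = grids
    bump = amplitude * np.exp(
        -0.5 * (gz[:, None, None] + gy[None, :, None] + gx[None, None, :])
    )
    photons[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += bump


def _check_fov(cisternae: list[SimCisterna], config: AcquisitionConfig) -> None:
    margin = 2.0 * config.voxel_xy
    ext = config.fov_um
    for cis in cisternae:
        for ax in range(3):
            m = margin if ax else 2.0 * config.voxel_z
            if (cis.trajectory[:, ax] < m - 1e-9).any() or (
                cis.trajectory[:, ax] > ext[ax] - m + 1e-9
            ).any():
                raise ValueError(
                    f"cisterna {cis.cisterna_id} leaves the field of view "
                    f"(axis {'zyx'[ax]})"
                )


def generate_movie(
    config: AcquisitionConfig,
    cisternae: list[SimCisterna],
    eres: list[SimERES] | None = None,
    n_channels: int = 2,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a movie (t, c, z, y, x, float32 counts) and its ground truth.

    Each marker is rendered as a 3D Gaussian at the cisterna center plus its
    ramped zone offset; expected photon counts are Poisson-sampled, then
    Gaussian read noise and the constant camera offset are added. All
    randomness derives from ``config.seed``.
    """
    eres = eres or []
    _check_fov(cisternae, config)
    rng = np.random.default_rng(config.seed)
    voxel = config.voxel_size
    photons = np.zeros(
        (config.n_frames, n_channels, config.nz, config.ny, config.nx), dtype=np.float64
    )

    for f, t in enumerate(config.times):
        for cis in cisternae:
            if not (cis.birth_time <= t <= cis.death_time):
                continue
            ramp = cis.zone_ramp(t)
            sig = _spot_sigmas(cis.diameter, config)
            for c in range(n_channels):
                k = cis.kinetics[c]
                amp = config.photons_per_unit * kinetic_profile(t, k)
                center = cis.trajectory[f] + ramp * np.asarray(k.zone_offset)
                _add_gaussian_spot(photons[f, c], center, sig, amp, voxel)
        for site in eres:
            sig = _spot_sigmas(site.diameter, config)
            _add_gaussian_spot(
                photons[f, site.channel],
                np.asarray(site.position, dtype=float),
                sig,
                config.photons_per_unit * site.amplitude,
                voxel,
            )

    stack = rng.poisson(photons).astype(np.float32)
    if config.read_noise_sd > 0:
        stack += rng.normal(0.0, config.read_noise_sd, size=stack.shape).astype(
            np.float32
        )
    stack += np.float32(config.camera_offset)

    truth = _ground_truth(config, cisternae, eres, n_channels)
    return stack, truth


def _ground_truth(config, cisternae, eres, n_channels) -> GroundTruth:
    rows, centers = [], []
    for cis in cisternae:
        row = {
            "cisterna_id": cis.cisterna_id,
            "birth_s": cis.birth_time,
            "death_s": cis.death_time,
            "diameter_um": cis.diameter,
        }
        for c in range(n_channels):
            row[f"peak_s_ch{c}"] = cis.kinetics[c].peak_time
        if n_channels >= 2:
            row["delta_true_s"] = cis.kinetics[1].peak_time - cis.kinetics[0].peak_time
        rows.append(row)
        for f in range(config.n_frames):
            centers.append(
                {
                    "cisterna_id": cis.cisterna_id,
                    "frame": f,
                    "z_um": cis.trajectory[f, 0],
                    "y_um": cis.trajectory[f, 1],
                    "x_um": cis.trajectory[f, 2],
                }
            )
    contacts = [
        {
            "eres_id": site.eres_id,
            "cisterna_id": cid,
            "start_s": start,
            "end_s": end,
            "duration_s": end - start,
        }
        for site in eres
        for cid, start, end in site.contact_schedule
    ]
    return GroundTruth(
        cisternae=pd.DataFrame(rows),
        centers=pd.DataFrame(centers),
        contacts=pd.DataFrame(
            contacts, columns=["eres_id", "cisterna_id", "start_s", "end_s", "duration_s"]
        ),
    )


def _confined_walk(
    rng: np.random.Generator,
    home: np.ndarray,
    n_frames: int,
    step_sd: tuple[float, float, float] = (0.02, 0.03, 0.03),
    confine: tuple[float, float, float] = (0.15, 0.25, 0.25),
) -> np.ndarray:
    """Random walk reflected inside a box of half-widths ``confine`` (um)."""
    steps = rng.normal(0.0, step_sd, size=(n_frames, 3))
    pos = np.cumsum(steps, axis=0)
    conf = np.asarray(confine)
    # reflect into [-conf, conf] (triangle-wave folding)
    pos = np.abs((pos + conf) % (4 * conf) - 2 * conf) - conf
    return home[None, :] + pos


def _grid_homes(n: int, config: AcquisitionConfig, spacing: float, margin: float):
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    zc = (config.nz - 1) * config.voxel_z / 2.0
    homes = []
    for i in range(n):
        r, c = divmod(i, cols)
        homes.append(np.array([zc, margin + r * spacing, margin + c * spacing]))
    return homes, rows, cols


def maturation_scene(
    mean_delta: float,
    sd_delta: float,
    n_cisternae: int,
    seed: int = 0,
    base_config: AcquisitionConfig | None = None,
    rise_sigma: float = 15.0,
    decay_sigma: float = 20.0,
    zone_offset_um: float = 0.0,
    spacing: float = 1.6,
    deltas: np.ndarray | None = None,
) -> tuple[AcquisitionConfig, list[SimCisterna]]:
    """Two-channel maturation experiment with programmed green-to-red delays.

    Per-cisterna red-minus-green peak delays are drawn from
    N(mean_delta, sd_delta^2) (truncated at +-4 SD, a negligible mass);
    green peak phases are uniform within one frame interval so estimated
    delays are not locked to the frame grid. The field of view and movie
    length are sized so every cisterna and both of its peaks fit, with
    cisternae on a grid of confined random walks far enough apart that
    tracks stay unambiguous.

    ``deltas`` overrides the drawn per-cisterna delays with explicit values
    (still clipped to the +-4 SD envelope the movie is sized for) — used by
    the replicated recovery experiments for antithetic sampling.

    Pulse widths are broadened for cisternae whose two peaks are far apart
    (sigma >= |delta| / 3.5) so the cisterna never goes dark between its
    green and red phases — mirroring the selection of continuously
    trackable cisternae that the maturation statistic presumes.

    Returns a config (with nx/ny/n_frames set) and the cisterna list.
    """
    if n_cisternae < 1:
        raise ValueError("n_cisternae must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_config or preset_config("maturation")
    dt = base.frame_interval

    lo = min(0.0, mean_delta - 4.0 * sd_delta)
    hi = max(0.0, mean_delta + 4.0 * sd_delta)
    sigma_cap = max(rise_sigma, decay_sigma, max(abs(lo), abs(hi)) / 3.5)
    pre = 2.0 * sigma_cap - lo
    duration = pre + dt + hi + 2.0 * sigma_cap
    n_frames = int(math.ceil(duration / dt)) + 1

    margin = 0.9
    cols = math.ceil(math.sqrt(n_cisternae))
    rows = math.ceil(n_cisternae / cols)
    nx = int(round(((cols - 1) * spacing + 2 * margin) / base.voxel_xy)) + 1
    ny = int(round(((rows - 1) * spacing + 2 * margin) / base.voxel_xy)) + 1
    config = dataclasses.replace(
        base, nx=nx, ny=ny, n_frames=n_frames, seed=int(rng.integers(2**31))
    )

    homes, _, _ = _grid_homes(n_cisternae, config, spacing, margin)
    if deltas is not None and len(deltas) != n_cisternae:
        raise ValueError("deltas must have one value per cisterna")
    cisternae = []
    for i, home in enumerate(homes):
        raw = rng.normal(mean_delta, sd_delta) if deltas is None else deltas[i]
        delta = float(
            np.clip(raw, mean_delta - 4 * sd_delta, mean_delta + 4 * sd_delta)
        )
        t_green = pre + rng.uniform(0.0, dt)
        traj = _confined_walk(rng, home, n_frames)
        off = (
            np.array([0.0, 0.0, zone_offset_um]) if zone_offset_um else np.zeros(3)
        )
        rise_i = max(rise_sigma, abs(delta) / 3.5)
        decay_i = max(decay_sigma, abs(delta) / 3.5)
        kin = (
            MarkerKinetics(
                peak_time=t_green,
                rise_sigma=rise_i,
                decay_sigma=decay_i,
                amplitude=float(rng.uniform(0.8, 1.2)),
                zone_offset=tuple(-off / 2),
            ),
            MarkerKinetics(
                peak_time=t_green + delta,
                rise_sigma=rise_i,
                decay_sigma=decay_i,
                amplitude=float(rng.uniform(0.8, 1.2)),
                zone_offset=tuple(off / 2),
            ),
        )
        cisternae.append(
            SimCisterna(
                cisterna_id=i,
                birth_time=0.0,
                death_time=(n_frames - 1) * dt,
                trajectory=traj,
                kinetics=kin,
            )
        )
    return config, cisternae


def contact_scene(
    n_pairs: int = 3,
    seed: int = 0,
    contact_duration_range: tuple[float, float] = (2.0, 3.0),
    contact_distance: float = 0.15,
    roam_distance: float = 1.0,
    n_frames: int = 40,
) -> tuple[AcquisitionConfig, list[SimCisterna], list[SimERES]]:
    """Fast-imaging scene of cisternae transiently contacting static ERES.

    Each pair holds one static ERES (red channel) and one mobile cisterna
    (green channel) that roams ~``roam_distance`` away, dwells within
    ``contact_distance`` of the ERES for a scheduled 2-3 s window, then
    leaves again. Frame interval follows the fast 'contact' preset (1.1 s).
    """
    rng = np.random.default_rng(seed)
    base = preset_config("contact", n_frames=n_frames)
    dt = base.frame_interval
    spacing = 3.0
    margin = 1.2
    cols = math.ceil(math.sqrt(n_pairs))
    rows_n = math.ceil(n_pairs / cols)
    nx = int(round(((cols - 1) * spacing + 2 * margin) / base.voxel_xy)) + 1
    ny = int(round(((rows_n - 1) * spacing + 2 * margin) / base.voxel_xy)) + 1
    config = dataclasses.replace(
        base, nx=nx, ny=ny, seed=int(rng.integers(2**31))
    )
    homes, _, _ = _grid_homes(n_pairs, config, spacing, margin)

    duration = (n_frames - 1) * dt
    cisternae, sites = [], []
    for i, home in enumerate(homes):
        dwell = float(rng.uniform(*contact_duration_range))
        start = float(rng.uniform(0.25 * duration, 0.75 * duration - dwell))
        # snap the window to the frame grid so the programmed duration is
        # exactly what a frame-sampled detector can see
        start = round(start / dt) * dt
        dwell = round(dwell / dt) * dt
        end = start + dwell
        site = SimERES(
            eres_id=i,
            position=tuple(home),
            channel=1,
            contact_schedule=[(i, start, end)],
        )
        traj = np.empty((n_frames, 3))
        ang = rng.uniform(0, 2 * math.pi)
        for f in range(n_frames):
            t = f * dt
            in_contact = start - 1e-9 <= t <= end + 1e-9
            offset = contact_distance if in_contact else roam_distance
            if not in_contact:
                ang += rng.uniform(-0.5, 0.5)  # smooth orbit, linkable at 1.1 s
            traj[f] = home + np.array(
                [0.0, offset * math.sin(ang), offset * math.cos(ang)]
            )
        kin = (
            MarkerKinetics(peak_time=duration / 2, rise_sigma=1e4, decay_sigma=1e4),
            MarkerKinetics(peak_time=0.0, rise_sigma=1.0, decay_sigma=1.0, amplitude=0.0),
        )
        cisternae.append(
            SimCisterna(
                cisterna_id=i,
                birth_time=0.0,
                death_time=duration,
                trajectory=traj,
                kinetics=kin,
            )
        )
        sites.append(site)
    return config, cisternae, sites


def generate_coloc_phantom(
    config: AcquisitionConfig,
    rho_target: float,
    n_spots: int,
    seed: int = 0,
    noise: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Two-channel 3D phantom sharing a fraction ``rho_target`` of spots.

    ``round(rho_target * n_spots)`` spot positions (and amplitudes) are
    common to both channels; each channel additionally receives its own
    independent spots to bring its total to ``n_spots``. With ``noise=False``
    the returned stack is the noiseless photon image (so ``rho_target=1``
    gives exactly identical channels).

    Returns a (2, z, y, x) stack and a table of true spots
    (channel: 0, 1, or -1 for shared; z/y/x um; amplitude).
    """
    if not 0.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must be in [0, 1]")
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    rng = np.random.default_rng(seed)
    voxel = config.voxel_size
    ext = config.fov_um
    margin = (2 * config.voxel_z, 0.4, 0.4)

    def draw(n):
        return np.column_stack(
            [rng.uniform(margin[a], ext[a] - margin[a], size=n) for a in range(3)]
        )

    n_shared = int(round(rho_target * n_spots))
    n_unique = n_spots - n_shared
    sig = _spot_sigmas(0.5, config)
    photons = np.zeros((2, config.nz, config.ny, config.nx))
    records = []

    shared = draw(n_shared)
    amps = rng.uniform(0.5, 1.5, size=n_shared) * config.photons_per_unit
    for pos, amp in zip(shared, amps):
        for c in (0, 1):
            _add_gaussian_spot(photons[c], pos, sig, amp, voxel)
        records.append({"channel": -1, "z_um": pos[0], "y_um": pos[1], "x_um": pos[2], "amplitude": amp})
    for c in (0, 1):
        uniq = draw(n_unique)
        amps = rng.uniform(0.5, 1.5, size=n_unique) * config.photons_per_unit
        for pos, amp in zip(uniq, amps):
            _add_gaussian_spot(photons[c], pos, sig, amp, voxel)
            records.append({"channel": c, "z_um": pos[0], "y_um": pos[1], "x_um": pos[2], "amplitude": amp})

    if noise:
        stack = rng.poisson(photons).astype(np.float32)
        stack += rng.normal(0.0, config.read_noise_sd, size=stack.shape).astype(np.float32)
        stack += np.float32(config.camera_offset)
    else:
        stack = photons.astype(np.float32)
    return stack, pd.DataFrame(records, columns=["channel", "z_um", "y_um", "x_um", "amplitude"])
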