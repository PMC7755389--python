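"""Prescribed beat kinematics of the vaned choanocyte flagella.

Each flagellum is a thin sheet (flagellum + vane) beating in a vertical
plane.  The centerline carries a base-to-tip traveling sine wave whose
amplitude envelope saturates over a length scale delta:

    d(s, t) = a * (1 - exp(-(s/delta)^2)) * sin(2*pi*(s/lambda - f*t) + phi)

with s the arclength from the base.  The base case (a = 1 um, delta = 1 um,
lambda = 5 um, f = 30 Hz, vane width 0.7 um) reaches its ~1 um amplitude
within a few um of the base; the increased-amplitude beat (a = 5 um,
delta = 22 um) grows steadily to a 2 um peak at the tip.

The displacement is applied transverse to the collar axis as a function of
distance along the axis (the prescribed-motion convention of morphing-mesh
solvers): the flagellar tip stays at a fixed height and the centerline
length is constant over the beat period to well within 1% (the traveling
wave shifts where the steep portions sit without changing the integrated
arclength), so the sheet does not stretch in time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .geometry import ChamberGeometry

#: flagellum length (um) consistent with a 2 um tip amplitude for the
#: increased-amplitude beat (a=5, delta=22)
DEFAULT_FLAGELLUM_LENGTH = 15.7

PresenceMask = Literal["full", "unconfined-only", "confined-only"]


@dataclass(frozen=True)
class BeatKinematics:
    """Traveling-wave beat parameters shared by the 24 flagella."""

    wavelength: float = 5.0        # um
    amplitude: float = 1.0         # um
    envelope_scale: float = 1.0    # um (delta)
    frequency: float = 30.0        # Hz
    vane_width_confined: float = 0.7     # um, inside the collar
    vane_width_unconfined: float = 0.7   # um, above the collar
    flagellum_length: float = DEFAULT_FLAGELLUM_LENGTH
    #: optional (a, delta) of a second saturating envelope acting as a
    #: lower bound: the amplitude-modulated beat grows the waveform outside
    #: the collar while the confined amplitude keeps its base value
    envelope_floor: tuple[float, float] | None = None
    phase_offsets: tuple[float, ...] | None = None   # rad, per flagellum
    beat_plane_azimuths: tuple[float, ...] | None = None  # rad, per flagellum
    presence_mask: PresenceMask = "full"

    def __post_init__(self) -> None:
        for name in ("wavelength", "amplitude", "envelope_scale", "frequency",
                     "flagellum_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.vane_width_confined < 0 or self.vane_width_unconfined < 0:
            raise ValueError("vane widths must be >= 0")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def with_vane_width(self, confined: float, unconfined: float | None = None):
        return replace(
            self,
            vane_width_confined=confined,
            vane_width_unconfined=confined if unconfined is None else unconfined,
        )

    def increased_amplitude(
        self, a: float = 5.0, delta: float = 22.0
    ) -> "BeatKinematics":
        """Amplitude-modulated beat: the waveform grows toward the tip
        (peaking at 2 um for the defaults) while the amplitude inside the
        collar keeps its base value."""
        return replace(
            self,
            amplitude=a,
            envelope_scale=delta,
            envelope_floor=(self.amplitude, self.envelope_scale),
        )

    def randomized_phases(self, n: int, seed: int) -> "BeatKinematics":
        rng = np.random.default_rng(seed)
        return replace(self, phase_offsets=tuple(rng.uniform(0, 2 * np.pi, n)))

    def randomized_beat_planes(self, n: int, seed: int) -> "BeatKinematics":
        rng = np.random.default_rng(seed)
        return replace(self, beat_plane_azimuths=tuple(rng.uniform(0, np.pi, n)))


def envelope(s, k: BeatKinematics) -> np.ndarray:
    """Amplitude envelope (um) at arclength s.

    With an ``envelope_floor`` the envelope is the pointwise maximum of the
    two saturating profiles: the confined amplitude keeps its (floor) value
    while the waveform grows toward the tip.
    """
    s = np.asarray(s, dtype=float)
    env = k.amplitude * (1.0 - np.exp(-((s / k.envelope_scale) ** 2)))
    if k.envelope_floor is not None:
        a0, d0 = k.envelope_floor
        env = np.maximum(env, a0 * (1.0 - np.exp(-((s / d0) ** 2))))
    return env


def waveform(
    s, t: float, k: BeatKinematics, phase_offset: float = 0.0
) -> np.ndarray:
    """Transverse centerline displacement (um) at arclength s and time t."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > k.flagellum_length + 1e-12):
        raise ValueError("arclength outside [0, flagellum_length]")
    phase = 2.0 * np.pi * (s / k.wavelength - k.frequency * t) + phase_offset
    return envelope(s, k) * np.sin(phase)


def waveform_velocity(
    s, t: float, k: BeatKinematics, phase_offset: float = 0.0
) -> np.ndarray:
    """Analytic time derivative of :func:`waveform` at fixed arclength."""
    s = np.asarray(s, dtype=float)
    phase = 2.0 * np.pi * (s / k.wavelength - k.frequency * t) + phase_offset
    return -envelope(s, k) * 2.0 * np.pi * k.frequency * np.cos(phase)


@dataclass
class SheetState:
    """One flagellar sheet at one instant: centerline + vane extent."""

    points: np.ndarray       # (n, 3) centerline positions, um
    velocities: np.ndarray   # (n, 3) centerline velocities, um/s
    half_width: np.ndarray   # (n,) vane half-width at each arclength, um
    vane_dir: np.ndarray     # (3,) unit vector spanning the vane
    arclength: np.ndarray    # (n,) material arclength coordinate


def centerline_length(t: float, k: BeatKinematics, phase_offset: float = 0.0,
                      n: int = 2000) -> float:
    """Instantaneous arclength of the centerline (um)."""
    yy = np.linspace(0.0, k.flagellum_length, n)
    d = waveform(yy, t, k, phase_offset)
    dd = np.gradient(d, yy)
    ds = np.sqrt(1.0 + dd**2)
    return float(np.trapezoid(ds, yy))


def sheet_state(
    t: float,
    k: BeatKinematics,
    geom: ChamberGeometry,
    n_points: int | None = None,
    ds_target: float = 0.25,
) -> list[SheetState]:
    """All flagellar sheets at time t, positioned on their collar axes.

    The transverse displacement is applied at fixed height along the
    collar axis (prescribed motion), so the velocity is the exact analytic
    time derivative of the waveform.  The presence mask truncates the
    sheet to its unconfined (above the collar tip) or confined (inside the
    collar) portion.
    """
    centers = geom.collar_centers()
    nf = len(centers)
    if n_points is None:
        n_points = max(int(np.ceil(k.flagellum_length / ds_target)) + 1, 8)
    phases = k.phase_offsets or (0.0,) * nf
    azimuths = k.beat_plane_azimuths or (0.0,) * nf
    if len(phases) != nf or len(azimuths) != nf:
        raise ValueError("per-flagellum parameter length mismatch")

    sheets: list[SheetState] = []
    for (cx, cz), phi, theta in zip(centers, phases, azimuths):
        s = np.linspace(0.0, k.flagellum_length, n_points)
        y0 = s
        d0 = waveform(s, t, k, phi)
        vd = waveform_velocity(s, t, k, phi)

        e_beat = np.array([np.cos(theta), 0.0, np.sin(theta)])
        e_vane = np.array([-np.sin(theta), 0.0, np.cos(theta)])
        base = np.array([cx, 0.0, cz])
        pts = base + y0[:, None] * np.array([0.0, 1.0, 0.0]) + d0[:, None] * e_beat
        vel = vd[:, None] * e_beat

        half_w = np.where(
            y0 <= geom.collar_length,
            k.vane_width_confined / 2.0,
            k.vane_width_unconfined / 2.0,
        )

        if k.presence_mask == "unconfined-only":
            keep = y0 > geom.collar_length
        elif k.presence_mask == "confined-only":
            keep = y0 <= geom.collar_length
        else:
            keep = np.ones_like(y0, dtype=bool)

        sheets.append(
            SheetState(
                points=pts[keep],
                velocities=vel[keep],
                half_width=half_w[keep],
                vane_dir=e_vane,
                arclength=s[keep],
            )
        )
    return sheets


def sheet_point_cloud(
    sheets: Sequence[SheetState], dw: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten sheets into a point cloud sampling the vane surface.

    Lateral sample spacing is at most ``dw``; every lateral point inherits
    the centerline velocity at its arclength (the vane is rigid laterally).
    Returns (points (m,3), velocities (m,3), sheet id (m,)).
    """
    all_pts, all_vel, all_gid = [], [], []
    for gid, sh in enumerate(sheets):
        if len(sh.points) == 0:
            continue
        wmax = float(sh.half_width.max())
        n_lat = max(int(np.ceil(2 * wmax / dw)) + 1, 1)
        offsets = np.linspace(-1.0, 1.0, n_lat) if n_lat > 1 else np.array([0.0])
        for off in offsets:
            lateral = (off * sh.half_width)[:, None] * sh.vane_dir
            all_pts.append(sh.points + lateral)
            all_vel.append(sh.velocities)
            all_gid.append(np.full(len(sh.points), gid))
    if not all_pts:
        return np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0, dtype=int)
    return (
        np.concatenate(all_pts),
        np.concatenate(all_vel),
        np.concatenate(all_gid),
    )
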