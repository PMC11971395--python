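"""Synthetic data generators with known ground truth.

Four generators emulate the four input kinds the analysis pipelines
consume, so every stage is testable without microscope data:

* fluorescence cell images — a kinetoplast blob plus a flagellar signal
  that switches on along the traced path following a logistic ramp;
* beating flagellum waveform series — travelling sinusoidal tangent-angle
  waves integrated into planar shapes;
* axoneme EM cross-sections — a ninefold-symmetric density (doublets,
  outer dynein arms with controllable occupancy, central-pair density)
  under an elliptical tilt projection;
* swimming tracks — correlated random walks at fixed step speed.

Noise is additive Gaussian throughout.  Identical spec + seed gives
bit-identical output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .waveform import WaveformSeries

__all__ = [
    "SyntheticCellSpec",
    "SyntheticBeatSpec",
    "SyntheticAxonemeSpec",
    "AXONEME_GEOMETRY",
    "generate_cell_image",
    "generate_beat_series",
    "generate_axoneme_stack",
    "axoneme_template_centres",
    "oda_template_mask",
    "generate_tracks",
]


# ---------------------------------------------------------------------------
# fluorescence cell images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of a synthetic fluorescence cell image.

    The flagellar signal along the traced path follows a logistic ramp in
    arclength, centred at ``onset_distance`` (μm from the kinetoplast) with
    steepness ``onset_slope`` (per pixel), from ``background`` up to
    ``plateau`` (AU).  A Gaussian kinetoplast blob of peak
    ``kinetoplast_intensity`` sits at ``kinetoplast_xy``.
    """

    image_size: tuple[int, int] = (128, 128)  # (h, w) pixels
    pixel_size: float = 0.1  # μm / pixel
    kinetoplast_xy: tuple[float, float] = (30.0, 64.0)  # (x, y) pixels
    kinetoplast_intensity: float = 300.0  # AU
    path_points: tuple[tuple[float, float], ...] = ((30.0, 64.0), (120.0, 64.0))
    onset_distance: float = 2.0  # μm along path
    onset_slope: float = 1.5  # per pixel
    plateau: float = 3000.0  # AU
    background: float = 100.0  # AU
    noise_sd: float = 0.0  # AU
    seed: int = 0
    line_sd: float = 1.0  # px, width of the rendered flagellum line
    kinetoplast_sd: float = 2.0  # px

    def validate(self) -> None:
        if self.onset_distance < 0:
            raise ValueError("onset_distance must be >= 0")
        if not (self.plateau > self.background >= 0):
            raise ValueError("require plateau > background >= 0")
        pts = np.asarray(self.path_points, dtype=float)
        if pts.shape[0] < 2:
            raise ValueError("path needs at least 2 points")
        arclen_um = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() * self.pixel_size
        if arclen_um < self.onset_distance:
            raise ValueError(
                f"path length {arclen_um:.3f} μm shorter than onset_distance "
                f"{self.onset_distance:.3f} μm"
            )


def _densify_path(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ``step``-pixel arclength spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    s = np.arange(0.0, total + step / 2, step)
    s[-1] = min(s[-1], total)
    x = np.interp(s, arc, points[:, 0])
    y = np.interp(s, arc, points[:, 1])
    return s, np.column_stack([x, y])


def _stamp_max(canvas: np.ndarray, cx: float, cy: float, sd: float, amp: float) -> None:
    """Max-composite a Gaussian blob into the canvas (amp at centre)."""
    h, w = canvas.shape
    r = int(np.ceil(4 * sd))
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    blob = amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sd**2))
    np.maximum(canvas[y0:y1, x0:x1], blob, out=canvas[y0:y1, x0:x1])


def generate_cell_image(
    spec: SyntheticCellSpec,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render a synthetic cell image.

    Returns
    -------
    (image, trace, onset_distance)
        The image (float64 AU), the ground-truth flagellum trace in pixel
        coordinates (base first), and the ground-truth onset distance (μm).
    """
    spec.validate()
    h, w = spec.image_size
    signal = np.zeros((h, w))
    pts = np.asarray(spec.path_points, dtype=float)
    s_px, dense = _densify_path(pts, step=0.25)
    onset_px = spec.onset_distance / spec.pixel_size
    amp = (spec.plateau - spec.background) / (
        1.0 + np.exp(-np.clip(spec.onset_slope * (s_px - onset_px), -500, 500))
    )
    for (x, y), a in zip(dense, amp):
        if a > 1e-9:
            _stamp_max(signal, x, y, spec.line_sd, a)
    kx, ky = spec.kinetoplast_xy
    _stamp_max(signal, kx, ky, spec.kinetoplast_sd, spec.kinetoplast_intensity)
    image = spec.background + signal
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return image, pts, spec.onset_distance


# ---------------------------------------------------------------------------
# beating flagellum waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticBeatSpec:
    """Parameters of a synthetic travelling-wave beat.

    The tangent angle is theta(s, t) = a sin(2 pi f t + sign * 2 pi w s)
    with sign +1 for tip-to-base propagation (crests move from s=1 toward
    s=0, the wild-type direction) and -1 for base-to-tip.  Shapes are
    obtained by integrating the tangent angle along arclength at uniform
    steps (midpoint rule), base fixed at the origin, body axis = +x.
    Angular noise (sd in radians) is added to the tangent angle before
    integration, so the per-frame arclength is exactly the specified
    length regardless of noise.
    """

    frequency: float = 28.0  # Hz
    half_amplitude: float = 0.5  # radians (a); full range is 2a
    waves_per_flagellum: float = 1.5  # dimensionless (w)
    length: float = 20.0  # μm
    fps: float = 200.0
    duration: float = 0.5  # s
    direction: str = "tip_to_base"
    n_points: int = 50
    noise_sd: float = 0.0  # radians
    seed: int = 0

    def validate(self) -> None:
        if self.frequency >= self.fps / 2:
            raise ValueError("frequency must be below Nyquist (fps/2)")
        if self.waves_per_flagellum < 0:
            raise ValueError("waves_per_flagellum must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if round(self.duration * self.fps) < 2:
            raise ValueError("need at least 2 frames")
        if self.direction not in ("tip_to_base", "base_to_tip"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")


def generate_beat_series(
    spec: SyntheticBeatSpec,
) -> tuple[WaveformSeries, dict]:
    """Generate a waveform series with a pure travelling-wave beat.

    Returns the series and a ground-truth dict with keys ``frequency``,
    ``amplitude_range`` (= 2a), ``waves`` and ``direction``.
    """
    spec.validate()
    T = int(round(spec.duration * spec.fps))
    n = spec.n_points
    ds = spec.length / (n - 1)
    sign = 1.0 if spec.direction == "tip_to_base" else -1.0
    # tangent angles at segment midpoints (normalized arclength)
    s_mid = (np.arange(n - 1) + 0.5) / (n - 1)
    t = np.arange(T) / spec.fps
    phase = (
        2 * np.pi * spec.frequency * t[:, None]
        + sign * 2 * np.pi * spec.waves_per_flagellum * s_mid[None, :]
    )
    theta = spec.half_amplitude * np.sin(phase)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        theta = theta + rng.normal(0.0, spec.noise_sd, size=theta.shape)
    frames = np.zeros((T, n, 2))
    frames[:, 1:, 0] = np.cumsum(ds * np.cos(theta), axis=1)
    frames[:, 1:, 1] = np.cumsum(ds * np.sin(theta), axis=1)
    series = WaveformSeries(cell_id="synthetic", fps=spec.fps, frames=frames)
    truth = {
        "frequency": spec.frequency,
        "amplitude_range": 2 * spec.half_amplitude,
        "waves": spec.waves_per_flagellum,
        "direction": spec.direction,
    }
    return series, truth


# ---------------------------------------------------------------------------
# axoneme EM cross-sections
# ---------------------------------------------------------------------------

#: Geometry of the ninefold density template, in units of the ring radius
#: (radii) and degrees (angles).  Tests derive ODA masks from this block.
AXONEME_GEOMETRY = {
    "doublet_amplitude": 1.5,
    "oda_radius_factor": 1.25,     # ODA centre radius / ring radius
    "oda_angle_offset_deg": 10.0,  # ODA angular offset from its doublet
    "oda_amplitude": 1.0,
    "central_pair_radius_factor": 0.18,
    "central_pair_sd_factor": 0.06,  # radial sd of the central density / ring radius
    "central_pair_amplitude": 1.0,
}


@dataclass(frozen=True)
class SyntheticAxonemeSpec:
    """Parameters of a synthetic axoneme cross-section stack.

    The density template holds nine doublet blobs at 40° spacing on a ring,
    an outer-dynein-arm (ODA) blob outside each doublet scaled by the
    per-doublet ``oda_occupancy``, and (optionally) central-pair density
    rendered as a rotationally symmetric annulus so the uniform-occupancy
    template is exactly invariant under 40° rotation.  The projection model
    is an anisotropic scaling by ``axis_ratio`` (a tilted circular section
    images as an ellipse) followed by an in-plane rotation.
    """

    image_size: tuple[int, int] = (96, 96)
    ring_radius: float = 28.0  # px
    doublet_sd: float = 2.0  # px
    oda_occupancy: float | tuple[float, ...] = 1.0
    central_pair: bool = True
    axis_ratio: float = 1.0  # b/a in (0, 1]
    in_plane_rotation: float = 0.0  # degrees
    noise_sd: float = 0.0  # AU
    seed: int = 0

    def occupancy_vector(self) -> np.ndarray:
        occ = np.asarray(self.oda_occupancy, dtype=float)
        if occ.ndim == 0:
            occ = np.full(9, float(occ))
        if occ.shape != (9,):
            raise ValueError("oda_occupancy must be a scalar or 9-vector")
        return occ

    def validate(self) -> None:
        if not (0 < self.axis_ratio <= 1):
            raise ValueError("axis_ratio must be in (0, 1]")
        occ = self.occupancy_vector()
        if np.any(occ < 0) or np.any(occ > 1):
            raise ValueError("occupancy entries must lie in [0, 1]")
        if self.ring_radius <= 0 or self.doublet_sd <= 0:
            raise ValueError("ring_radius and doublet_sd must be positive")


def _template_density(
    spec: SyntheticAxonemeSpec, u: np.ndarray, v: np.ndarray, include: str = "all"
) -> np.ndarray:
    """Analytic template density at coordinates (u, v) relative to the centre.

    ``include`` selects components: 'all', 'oda' (ODA blobs only).
    """
    g = AXONEME_GEOMETRY
    R = spec.ring_radius
    occ = spec.occupancy_vector()
    dens = np.zeros_like(u, dtype=float)
    angles = np.deg2rad(40.0 * np.arange(9))
    if include in ("all",):
        for ang in angles:
            cx, cy = R * np.cos(ang), R * np.sin(ang)
            dens += g["doublet_amplitude"] * np.exp(
                -((u - cx) ** 2 + (v - cy) ** 2) / (2 * spec.doublet_sd**2)
            )
    oda_r = g["oda_radius_factor"] * R
    oda_off = np.deg2rad(g["oda_angle_offset_deg"])
    for k, ang in enumerate(angles):
        a = ang + oda_off
        cx, cy = oda_r * np.cos(a), oda_r * np.sin(a)
        dens += (
            occ[k]
            * g["oda_amplitude"]
            * np.exp(-((u - cx) ** 2 + (v - cy) ** 2) / (2 * spec.doublet_sd**2))
        )
    if include == "all" and spec.central_pair:
        r = np.hypot(u, v)
        cp_r = g["central_pair_radius_factor"] * R
        cp_sd = g["central_pair_sd_factor"] * R
        dens += g["central_pair_amplitude"] * np.exp(
            -((r - cp_r) ** 2) / (2 * cp_sd**2)
        )
    return dens


def _projection_matrix(spec: SyntheticAxonemeSpec) -> np.ndarray:
    """Forward map template frame -> image frame (about the image centre)."""
    phi = np.deg2rad(spec.in_plane_rotation)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    scale = np.diag([1.0, spec.axis_ratio])
    return rot @ scale


def axoneme_template_centres(spec: SyntheticAxonemeSpec) -> np.ndarray:
    """Ground-truth doublet centres (9, 2) in image pixel coordinates."""
    h, w = spec.image_size
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    angles = np.deg2rad(40.0 * np.arange(9))
    ring = spec.ring_radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return ring @ _projection_matrix(spec).T + c


def _render(spec: SyntheticAxonemeSpec, include: str = "all") -> np.ndarray:
    h, w = spec.image_size
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    p = np.stack([xx - c[0], yy - c[1]], axis=-1)
    inv = np.linalg.inv(_projection_matrix(spec))
    uv = p @ inv.T
    return _template_density(spec, uv[..., 0], uv[..., 1], include=include)


def generate_axoneme_stack(
    spec: SyntheticAxonemeSpec, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n`` cross-section images plus per-image doublet centres.

    All images of a stack share the geometric transform (tilt projection and
    in-plane rotation); noise is fresh per image.

    Returns
    -------
    (images, centres)
        ``images`` has shape (n, h, w); ``centres`` shape (n, 9, 2) in
        (x, y) pixel coordinates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    base = _render(spec)
    centres = axoneme_template_centres(spec)
    rng = np.random.default_rng(spec.seed)
    images = np.empty((n, *spec.image_size))
    for i in range(n):
        images[i] = base
        if spec.noise_sd > 0:
            images[i] = images[i] + rng.normal(0.0, spec.noise_sd, size=base.shape)
    return images, np.broadcast_to(centres, (n, 9, 2)).copy()


def oda_template_mask(spec: SyntheticAxonemeSpec, threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of pixels where full-occupancy ODA density exceeds
    ``threshold`` times the ODA blob amplitude; derived from the geometry
    block, independent of the spec's own occupancy."""
    full = dataclasses.replace(spec, oda_occupancy=1.0)
    dens = _render(full, include="oda")
    return dens > threshold * AXONEME_GEOMETRY["oda_amplitude"]


# ---------------------------------------------------------------------------
# swimming tracks
# ---------------------------------------------------------------------------

def generate_tracks(
    n: int,
    speed: float,
    turn_sd: float,
    fps: float = 5.0,
    duration: float = 25.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlated-random-walk swimming tracks at fixed step speed.

    Each step advances ``speed / fps`` μm along a heading that performs a
    Gaussian random walk with per-step sd ``turn_sd`` (radians);
    ``turn_sd = 0`` gives perfectly straight tracks.

    Returns a long DataFrame with columns ``track_id, t_s, x_um, y_um``.
    """
    if speed < 0:
        raise ValueError("speed must be >= 0")
    rng = np.random.default_rng(seed)
    steps = int(round(duration * fps))
    dt = 1.0 / fps
    records = []
    for i in range(n):
        heading = rng.uniform(0, 2 * np.pi) + np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, turn_sd, size=steps))]
        )
        step_len = speed * dt
        x = np.concatenate([[0.0], np.cumsum(step_len * np.cos(heading[:-1]))])
        y = np.concatenate([[0.0], np.cumsum(step_len * np.sin(heading[:-1]))])
        t = np.arange(steps + 1) * dt
        records.append(
            pd.DataFrame(
                {"track_id": f"track_{i:04d}", "t_s": t, "x_um": x, "y_um": y}
            )
        )
    return pd.concat(records, ignore_index=True)
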