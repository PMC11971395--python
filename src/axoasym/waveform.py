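"""Flagellar beat metrics from digitised waveform time series.

A planar flagellum shape is described by the tangent angle theta(s, t): the
angle the local tangent makes with the cell-body axis, as a function of
normalized arclength s (0 = base, 1 = tip) and time t.  All beat metrics —
angular amplitude, dominant frequency, waves per flagellum — are computed
from this field.  The module also provides the screening steps applied
before metric extraction (flagellum-length consistency, sinusoidality) and
a tally of manually assigned beat-type classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import uniform_filter1d

__all__ = [
    "BEAT_CLASSES",
    "WaveformSeries",
    "TangentAngleField",
    "BeatMetrics",
    "SegmentMetrics",
    "BeatClassTally",
    "screen_by_length_cv",
    "resample_frames",
    "smooth_spacetime",
    "compute_tangent_angles",
    "angular_amplitude",
    "beat_cycle_amplitude",
    "dominant_frequency",
    "waves_per_flagellum",
    "sinusoid_screen",
    "segment_metrics",
    "analyze_series",
    "beat_type_tally",
    "required_signal_speed",
]

#: Beat-type vocabulary used for manual waveform classification.
BEAT_CLASSES = (
    "tip_to_base_continuous",
    "tip_to_base_interrupted",
    "base_to_tip_asymmetric",
    "switch",
    "static_uncoordinated",
)


@dataclass
class WaveformSeries:
    """Digitised flagellar waveform video: per-frame ordered point coordinates.

    Parameters
    ----------
    cell_id : str
        Identifier of the cell the series was digitised from.
    fps : float
        Frame rate of the source video in frames per second.
    frames : ndarray, shape (T, N, 2)
        Planar point coordinates in micrometres; the first point of each
        frame is the flagellum base.
    """

    cell_id: str
    fps: float
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames.ndim != 3 or self.frames.shape[2] != 2:
            raise ValueError("frames must have shape (T, N, 2)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.frames.shape[1] < 2:
            raise ValueError("need at least 2 points per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_points(self) -> int:
        return self.frames.shape[1]

    @property
    def lengths(self) -> np.ndarray:
        """Measured flagellum arclength per frame (μm)."""
        seg = np.linalg.norm(np.diff(self.frames, axis=1), axis=2)
        return seg.sum(axis=1)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class TangentAngleField:
    """Tangent angle theta[s, t] on an arclength-by-time grid.

    ``theta`` has shape (N, T); ``s`` is the normalized arclength grid and
    ``t`` the time grid at 1/fps spacing.  Angles are in radians, measured
    relative to the cell-body axis.
    """

    theta: np.ndarray
    s: np.ndarray
    t: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("tangent angles must be finite everywhere")
        if np.any(np.diff(self.s) <= 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("s and t grids must be strictly increasing")

    def restrict(self, s_min: float, s_max: float) -> "TangentAngleField":
        """Sub-field on the arclength interval [s_min, s_max)."""
        keep = (self.s >= s_min) & (self.s < s_max)
        if keep.sum() < 3:
            raise ValueError(
                f"segment [{s_min}, {s_max}) has fewer than 3 arclength samples"
            )
        return TangentAngleField(self.theta[keep], self.s[keep], self.t, self.fps)


def screen_by_length_cv(series: WaveformSeries, cv_max: float = 0.05) -> bool:
    """Length-consistency screen: pass iff CV of per-frame length <= cv_max.

    The coefficient of variation of measured flagellum length over the video
    is a proxy for digitisation consistency; jittery tracing inflates it.
    """
    lengths = series.lengths
    mean = lengths.mean()
    if mean == 0:
        raise ValueError("mean flagellum length is zero")
    return float(lengths.std(ddof=0) / mean) <= cv_max


def resample_frames(series: WaveformSeries, n_points: int = 50) -> WaveformSeries:
    """Resample every frame to ``n_points`` equally spaced arclength points."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    out = np.empty((series.n_frames, n_points, 2))
    for k, frame in enumerate(series.frames):
        seg = np.linalg.norm(np.diff(frame, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        if total == 0:
            raise ValueError(f"frame {k} has zero arclength")
        target = np.linspace(0.0, total, n_points)
        out[k, :, 0] = np.interp(target, arc, frame[:, 0])
        out[k, :, 1] = np.interp(target, arc, frame[:, 1])
    return replace(series, frames=out)


def smooth_spacetime(
    series: WaveformSeries, smooth_s: float = 0.0, smooth_t: float = 0.0
) -> WaveformSeries:
    """Smoothing-spline denoising, first along arclength then along time.

    ``smooth_s`` and ``smooth_t`` are the spline residual budgets (the
    UnivariateSpline ``s`` parameter) per curve; 0 gives the interpolating
    limit, i.e. the identity on the sampled points.
    """
    T, N, _ = series.frames.shape
    order = 3
    if N <= order or T <= order:
        raise ValueError("too few points or frames for cubic smoothing splines")
    out = series.frames.copy()
    idx_s = np.arange(N, dtype=float)
    for k in range(T):
        for c in range(2):
            spl = UnivariateSpline(idx_s, out[k, :, c], k=order, s=smooth_s)
            out[k, :, c] = spl(idx_s)
    idx_t = np.arange(T, dtype=float)
    for i in range(N):
        for c in range(2):
            spl = UnivariateSpline(idx_t, out[:, i, c], k=order, s=smooth_t)
            out[:, i, c] = spl(idx_t)
    return replace(series, frames=out)


def _body_axis_angle(frames: np.ndarray) -> float:
    """Angle of the cell-body axis: base tangent of the time-averaged shape."""
    mean_shape = frames.mean(axis=0)
    v = mean_shape[1] - mean_shape[0]
    return float(np.arctan2(v[1], v[0]))


def compute_tangent_angles(
    series: WaveformSeries, body_axis: tuple[float, float] | None = None
) -> TangentAngleField:
    """Tangent-angle field of a (smoothed, resampled) waveform series.

    The tangent at each point is estimated by central differences (one-sided
    at the ends), its angle unwrapped along arclength, and the cell-body
    axis angle subtracted so a straight flagellum lying along the body axis
    has theta identically zero.  The body axis defaults to the base tangent
    of the time-averaged shape (so it co-rotates with the cell); pass an
    explicit ``body_axis`` vector to measure angles against a fixed
    laboratory direction instead.
    """
    frames = series.frames
    seg = np.linalg.norm(np.diff(frames, axis=1), axis=2)
    if np.any(seg < 1e-12):
        t_bad, i_bad = np.argwhere(seg < 1e-12)[0]
        raise ValueError(
            f"coincident consecutive points at frame {t_bad}, point {i_bad}"
        )
    if body_axis is None:
        axis_angle = _body_axis_angle(frames)
    else:
        axis_angle = float(np.arctan2(body_axis[1], body_axis[0]))
    T, N, _ = frames.shape
    theta = np.empty((N, T))
    for k in range(T):
        dx = np.gradient(frames[k, :, 0])
        dy = np.gradient(frames[k, :, 1])
        ang = np.unwrap(np.arctan2(dy, dx))
        theta[:, k] = ang - axis_angle
    # keep frames on the same 2*pi branch: base angle varies continuously
    for k in range(1, T):
        jump = np.round((theta[0, k] - theta[0, k - 1]) / (2 * np.pi))
        theta[:, k] -= 2 * np.pi * jump
    s = np.linspace(0.0, 1.0, N)
    return TangentAngleField(theta=theta, s=s, t=series.times, fps=series.fps)


def angular_amplitude(field: TangentAngleField) -> float:
    """Max over arclength of the tangent-angle range over the beat cycle."""
    ranges = field.theta.max(axis=1) - field.theta.min(axis=1)
    return float(ranges.max())


def _single_tone_fit(
    field: TangentAngleField, f_dom: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-s least-squares fit of theta[s, .] to a single tone at f_dom.

    Returns (beta, resid): beta rows are the sin, cos and constant
    coefficients per s; resid is the (T, N) residual matrix.
    """
    t = field.t
    design = np.column_stack(
        [np.sin(2 * np.pi * f_dom * t), np.cos(2 * np.pi * f_dom * t),
         np.ones_like(t)]
    )
    beta, *_ = np.linalg.lstsq(design, field.theta.T, rcond=None)
    resid = field.theta.T - design @ beta
    return beta, resid


def beat_cycle_amplitude(field: TangentAngleField, profile_window: int = 5) -> float:
    """Angular amplitude as the range over one beat cycle of the
    dominant-frequency reconstruction.

    For each arclength position the tangent angle is fitted to a single
    tone at the dominant frequency; the range over the cycle is twice the
    fitted amplitude.  The squared amplitude is corrected for its additive
    noise bias (4 sigma^2 / T, estimated from the fit residuals) and the
    amplitude profile smoothed over ``profile_window`` arclength samples —
    the physical amplitude profile is smooth, so this suppresses the
    upward bias of a max over noisy per-s estimates.  For a noiseless
    sinusoidal beat this equals the true range 2a regardless of how many
    frames sample each beat cycle, where the raw min-max range
    (:func:`angular_amplitude`) undershoots at coarse temporal sampling.
    """
    f_dom = dominant_frequency(field)
    if f_dom is None:
        raise ValueError("dominant frequency undefined for a static field")
    beta, resid = _single_tone_fit(field, f_dom)
    T = field.t.size
    sigma2 = (resid**2).sum(axis=0) / max(T - 3, 1)
    amp2 = np.clip(beta[0] ** 2 + beta[1] ** 2 - 4 * sigma2 / T, 0.0, None)
    if profile_window > 1:
        amp2 = uniform_filter1d(amp2, profile_window, mode="nearest")
    return float(2 * np.sqrt(amp2).max())


def _mean_power_spectrum(
    field: TangentAngleField, window: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-s detrended power spectra averaged along arclength."""
    detrended = field.theta - field.theta.mean(axis=1, keepdims=True)
    T = field.theta.shape[1]
    if window == "hann":
        detrended = detrended * np.hanning(T)[None, :]
    elif window is not None:
        raise ValueError(f"unknown window: {window!r}")
    coef = np.fft.rfft(detrended, axis=1)
    power = np.abs(coef) ** 2
    freqs = np.fft.rfftfreq(T, d=1.0 / field.fps)
    return freqs, power.mean(axis=0)


def dominant_frequency(
    field: TangentAngleField, window: str | None = None
) -> float | None:
    """Frequency maximizing the arclength-aggregated tangent-angle power spectrum.

    Returns None for a static (all-zero after detrending) field; such cells
    carry no beat and are excluded from frequency statistics.  Spectral
    resolution is fps/T.  Detrending is mean-removal only by default;
    ``window='hann'`` tapers the series against leakage for off-bin tones.
    """
    if field.theta.shape[1] < 4:
        raise ValueError("need at least 4 frames for a frequency estimate")
    detrended = field.theta - field.theta.mean(axis=1, keepdims=True)
    if np.allclose(detrended, 0.0):
        return None
    freqs, spectrum = _mean_power_spectrum(field, window=window)
    k = 1 + int(np.argmax(spectrum[1:]))  # exclude DC
    return float(freqs[k])


def _dominant_bin(field: TangentAngleField) -> int:
    f_dom = dominant_frequency(field)
    if f_dom is None:
        raise ValueError("dominant frequency undefined for a static field")
    freqs = np.fft.rfftfreq(field.theta.shape[1], d=1.0 / field.fps)
    return int(np.argmin(np.abs(freqs - f_dom)))


def waves_per_flagellum(field: TangentAngleField) -> tuple[float, bool]:
    """Waves on the flagellum: spatial phase progression at the dominant frequency.

    At the dominant frequency bin the complex Fourier coefficient is taken
    for every arclength position; the number of waves is the magnitude of
    the total unwrapped phase change across the field's s-range divided by
    2*pi.  A travelling wave with w wavelengths per unit s yields w over
    s in [0, 1]; a standing wave yields 0.

    Returns
    -------
    (waves, low_confidence)
        ``low_confidence`` is set when the coefficient magnitude is below
        the per-position noise floor (median magnitude over the other
        frequency bins) for more than half of the arclength positions.
    """
    k = _dominant_bin(field)
    detrended = field.theta - field.theta.mean(axis=1, keepdims=True)
    coef = np.fft.rfft(detrended, axis=1)
    c = coef[:, k]
    phase = np.unwrap(np.angle(c))
    waves = float(abs(phase[-1] - phase[0]) / (2 * np.pi))
    others = np.delete(np.abs(coef[:, 1:]), k - 1, axis=1)
    floor = np.median(others, axis=1)
    low_confidence = bool(np.mean(np.abs(c) <= floor) > 0.5)
    return waves, low_confidence


def sinusoid_screen(
    field: TangentAngleField, r2_min: float = 0.5
) -> tuple[bool, float]:
    """Sinusoidality screen: aggregate R² of per-s single-tone fits.

    For every arclength position, theta[s, .] is fitted by least squares to
    A(s) sin(2*pi*f_dom*t + phi(s)) + c(s); the aggregate R² is
    1 - sum(SS_res)/sum(SS_tot) pooled across s.  Waveforms far from a
    single-frequency sinusoid (the wild-type tip-to-base beat shape) fail.
    """
    f_dom = dominant_frequency(field)
    if f_dom is None:
        raise ValueError("dominant frequency undefined for a static field")
    _, resid = _single_tone_fit(field, f_dom)
    ss_res = float(np.sum(resid**2))
    centered = field.theta - field.theta.mean(axis=1, keepdims=True)
    ss_tot = float(np.sum(centered**2))
    if ss_tot == 0:
        return False, 0.0
    r2 = 1.0 - ss_res / ss_tot
    return r2 >= r2_min, r2


@dataclass
class SegmentMetrics:
    """Beat metrics for the proximal (s < 0.5) and distal (s >= 0.5) halves."""

    proximal_amplitude: float
    distal_amplitude: float
    proximal_frequency: float | None
    distal_frequency: float | None
    proximal_waves: float | None
    distal_waves: float | None


def segment_metrics(field: TangentAngleField) -> SegmentMetrics:
    """Amplitude, dominant frequency and waves per flagellum half."""
    prox = field.restrict(0.0, 0.5)
    dist = field.restrict(0.5, np.inf)
    values = {}
    for name, sub in (("proximal", prox), ("distal", dist)):
        values[name + "_amplitude"] = angular_amplitude(sub)
        f = dominant_frequency(sub)
        values[name + "_frequency"] = f
        values[name + "_waves"] = waves_per_flagellum(sub)[0] if f is not None else None
    return SegmentMetrics(**values)


@dataclass
class BeatMetrics:
    """Per-cell beat metrics with screening verdicts."""

    cell_id: str
    angular_amplitude: float | None
    dominant_frequency: float | None
    waves_per_flagellum: float | None
    waves_low_confidence: bool
    length_cv_passed: bool
    sinusoid_passed: bool
    sinusoid_r2: float | None
    segments: SegmentMetrics | None = None


def analyze_series(
    series: WaveformSeries,
    *,
    n_points: int = 50,
    smooth_s: float = 0.0,
    smooth_t: float = 0.0,
    cv_max: float = 0.05,
    r2_min: float = 0.5,
    with_segments: bool = False,
) -> BeatMetrics:
    """Full per-cell pipeline: screen, resample, smooth, extract metrics.

    Cells failing the length-CV screen receive no metrics; cells whose
    tangent-angle field is static receive no frequency or waves estimate.
    """
    if not screen_by_length_cv(series, cv_max=cv_max):
        return BeatMetrics(
            cell_id=series.cell_id,
            angular_amplitude=None,
            dominant_frequency=None,
            waves_per_flagellum=None,
            waves_low_confidence=False,
            length_cv_passed=False,
            sinusoid_passed=False,
            sinusoid_r2=None,
        )
    resampled = resample_frames(series, n_points=n_points)
    smoothed = smooth_spacetime(resampled, smooth_s=smooth_s, smooth_t=smooth_t)
    field = compute_tangent_angles(smoothed)
    f_dom = dominant_frequency(field)
    if f_dom is None:
        amplitude = angular_amplitude(field)
        return BeatMetrics(
            cell_id=series.cell_id,
            angular_amplitude=amplitude,
            dominant_frequency=None,
            waves_per_flagellum=None,
            waves_low_confidence=False,
            length_cv_passed=True,
            sinusoid_passed=False,
            sinusoid_r2=None,
        )
    amplitude = beat_cycle_amplitude(field)
    waves, low_conf = waves_per_flagellum(field)
    sin_ok, r2 = sinusoid_screen(field, r2_min=r2_min)
    segments = segment_metrics(field) if with_segments else None
    return BeatMetrics(
        cell_id=series.cell_id,
        angular_amplitude=amplitude,
        dominant_frequency=f_dom,
        waves_per_flagellum=waves,
        waves_low_confidence=low_conf,
        length_cv_passed=True,
        sinusoid_passed=sin_ok,
        sinusoid_r2=r2,
        segments=segments,
    )


@dataclass
class BeatClassTally:
    """Counts and proportions of manually assigned beat-type classes."""

    counts: dict[str, int]
    proportions: dict[str, float]
    n: int


def beat_type_tally(labels: Sequence[str]) -> BeatClassTally:
    """Tally beat-type class labels into counts and proportions.

    Labels must come from the five-class vocabulary in :data:`BEAT_CLASSES`.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    for lab in labels:
        if lab not in BEAT_CLASSES:
            raise ValueError(f"unknown beat class label: {lab!r}")
    counts = {c: 0 for c in BEAT_CLASSES}
    for lab in labels:
        counts[lab] += 1
    n = len(labels)
    proportions = {c: counts[c] / n for c in BEAT_CLASSES}
    return BeatClassTally(counts=counts, proportions=proportions, n=n)


def required_signal_speed(frequency: float, length: float) -> tuple[float, float]:
    """Kinematic requirement on a base-to-tip initiation signal.

    For successive tip-to-base waveforms at ``frequency`` (Hz), a signal
    from the flagellar base must traverse a flagellum of ``length`` (μm)
    within one beat period.

    Returns
    -------
    (period_ms, speed_um_per_s)
        The beat period in milliseconds and the required signal speed in
        μm/s (frequency × length).
    """
    if frequency <= 0 or length <= 0:
        raise ValueError("frequency and length must be positive")
    return 1000.0 / frequency, frequency * length
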