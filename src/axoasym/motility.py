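"""Swimming-track statistics: mean speed, mean velocity, directionality.

A track is a sequence of timestamped planar positions of one cell.  Mean
speed is path length over duration; mean velocity is net displacement
over duration; directionality is the ratio of displacement achieved to
distance travelled (1 = perfectly straight).  Irregular sampling is
supported — durations always come from the timestamps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

__all__ = [
    "Track",
    "TrackMetrics",
    "mean_speed",
    "mean_velocity",
    "directionality",
    "track_metrics",
    "compute_track_metrics",
    "normalize_to_reference",
    "compare_lines",
]


@dataclass
class Track:
    """Timestamped planar positions of one swimming cell."""

    track_id: str
    t: np.ndarray  # s
    x: np.ndarray  # μm
    y: np.ndarray  # μm

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if self.t.size < 2:
            raise ValueError("track needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def displacement(self) -> float:
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class TrackMetrics:
    mean_speed: float  # μm/s
    mean_velocity: float  # μm/s
    directionality: float | None  # displacement / path length, in [0, 1]


def mean_speed(track: Track) -> float:
    """Total path length divided by total duration (μm/s)."""
    if track.duration == 0:
        raise ValueError("zero track duration")
    return track.path_length / track.duration


def mean_velocity(track: Track) -> float:
    """Net displacement divided by total duration (μm/s)."""
    if track.duration == 0:
        raise ValueError("zero track duration")
    return track.displacement / track.duration


def directionality(track: Track) -> float | None:
    """Displacement achieved over distance travelled; None for a static track."""
    path = track.path_length
    if path == 0:
        return None
    return track.displacement / path


def track_metrics(track: Track) -> TrackMetrics:
    return TrackMetrics(
        mean_speed=mean_speed(track),
        mean_velocity=mean_velocity(track),
        directionality=directionality(track),
    )


def compute_track_metrics(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track metrics from a long table (track_id, t_s, x_um, y_um)."""
    required = {"track_id", "t_s", "x_um", "y_um"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"tracks table missing columns: {sorted(missing)}")
    rows = []
    for tid, grp in tracks.groupby("track_id", sort=True):
        tr = Track(str(tid), grp["t_s"].to_numpy(), grp["x_um"].to_numpy(),
                   grp["y_um"].to_numpy())
        m = track_metrics(tr)
        rows.append(
            {"track_id": tid, "mean_speed": m.mean_speed,
             "mean_velocity": m.mean_velocity,
             "directionality": m.directionality}
        )
    return pd.DataFrame(rows)


def normalize_to_reference(
    values: np.ndarray,
    replicates: np.ndarray,
    reference_values: np.ndarray,
    reference_replicates: np.ndarray | None = None,
) -> dict:
    """Per-replicate group means normalized to the reference-line mean.

    Each replicate's mean of ``values`` is divided by the overall reference
    mean (the mean of reference per-replicate means when replicate labels
    are given, else the pooled mean); the normalized ratio is reported as
    mean ± SD across replicates.
    """
    values = np.asarray(values, dtype=float)
    replicates = np.asarray(replicates)
    reference_values = np.asarray(reference_values, dtype=float)
    if values.size == 0 or reference_values.size == 0:
        raise ValueError("empty group or reference")
    if reference_replicates is not None:
        reference_replicates = np.asarray(reference_replicates)
        ref_mean = float(
            np.mean([reference_values[reference_replicates == r].mean()
                     for r in np.unique(reference_replicates)])
        )
    else:
        ref_mean = float(reference_values.mean())
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    rep_ratios = np.array(
        [values[replicates == r].mean() / ref_mean for r in np.unique(replicates)]
    )
    sd = float(rep_ratios.std(ddof=1)) if rep_ratios.size > 1 else np.nan
    return {
        "ratio_mean": float(rep_ratios.mean()),
        "ratio_sd": sd,
        "replicate_ratios": rep_ratios,
        "n_replicates": int(rep_ratios.size),
    }


def compare_lines(
    replicate_means_a: np.ndarray, replicate_means_b: np.ndarray
) -> dict:
    """Two-tailed Student's t-test on per-replicate means of two cell lines."""
    a = np.asarray(replicate_means_a, dtype=float)
    b = np.asarray(replicate_means_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per line")
    stat, p = ttest_ind(a, b, equal_var=True)
    return {"t": float(stat), "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}
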