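"""Kinetoplast-to-signal-onset distance via radial maxima and a sigmoid fit.

For each cell, the maximum pixel value within discs of increasing radius
around the kinetoplast centroid forms a monotone non-decreasing radial
profile.  Where the flagellar fluorescence starts, this profile steps up;
a four-parameter logistic is fitted and its midpoint, converted to μm,
is the per-cell onset-distance measurement.  Quality-control gates on the
fitted midpoint, slope, maximum and R² exclude unreliable cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RadialMaxProfile",
    "SigmoidFit",
    "QCResult",
    "radial_max_profile",
    "fit_onset_sigmoid",
    "qc_onset",
    "onset_distance",
    "measure_onset",
    "summarize_onsets",
]


@dataclass
class RadialMaxProfile:
    """Maximum pixel value within nested discs of increasing radius.

    Disc maxima are nested, so ``values`` is monotone non-decreasing by
    construction.  ``truncated`` flags that the largest disc ran past the
    image border and was restricted to in-bounds pixels.
    """

    radii: np.ndarray  # px
    values: np.ndarray  # AU
    truncated: bool = False


@dataclass
class SigmoidFit:
    """Four-parameter logistic fit v(r) = b + (M - b) / (1 + exp(-k (r - r50))).

    ``maximum`` is the upper asymptote M, ``slope`` the steepness k (per
    pixel, positive by parameterization), ``midpoint`` r50 in pixels.
    ``success`` is False when the optimizer failed or the profile was
    degenerate (zero total variance).
    """

    baseline: float
    maximum: float
    midpoint: float
    slope: float
    r_squared: float
    success: bool = True


@dataclass
class QCResult:
    """Quality-control verdict for one sigmoid fit."""

    passed: bool
    reasons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must match empty reasons")


def radial_max_profile(
    image: np.ndarray,
    centroid: tuple[float, float],
    r_max: float = 40.0,
    dr: float = 0.5,
    mode: str = "disc",
) -> RadialMaxProfile:
    """Radial maximum profile around a centroid.

    In the default ``disc`` mode the value at radius r is the maximum over
    all pixels whose centre lies within Euclidean distance r of
    ``centroid`` — nested discs, hence a monotone profile, the property
    the sigmoid model assumes.  ``annulus`` mode takes the maximum within
    each (r - dr, r] shell instead; it is not monotone and exists for
    diagnostics only.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cx, cy = centroid
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"centroid ({cx}, {cy}) outside the {w}x{h} image")
    if not (r_max >= dr > 0):
        raise ValueError("require r_max >= dr > 0")
    if mode not in ("disc", "annulus"):
        raise ValueError(f"unknown mode: {mode!r}")
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy).ravel()
    vals = image.ravel()
    order = np.argsort(dist, kind="stable")
    dist_sorted = dist[order]
    radii = dr * np.arange(1, int(np.floor(r_max / dr)) + 1)
    idx = np.searchsorted(dist_sorted, radii, side="right") - 1
    if mode == "disc":
        cummax = np.maximum.accumulate(vals[order])
        values = np.where(idx >= 0, cummax[np.clip(idx, 0, None)], vals[order[0]])
    else:
        sorted_vals = vals[order]
        lo = np.concatenate([[0], idx[:-1] + 1])
        values = np.array(
            [sorted_vals[a:b + 1].max() if b >= a else
             sorted_vals[max(a - 1, 0)]
             for a, b in zip(lo, idx)]
        )
    border = min(cx, cy, (w - 1) - cx, (h - 1) - cy)
    return RadialMaxProfile(
        radii=radii, values=values, truncated=bool(radii[-1] > border)
    )


def _logistic(r: np.ndarray, b: float, log_amp: float, r50: float, log_k: float):
    k = np.exp(log_k)
    amp = np.exp(log_amp)
    return b + amp / (1.0 + np.exp(-np.clip(k * (r - r50), -500, 500)))


def fit_onset_sigmoid(
    profile: RadialMaxProfile, fix_baseline: float | None = None
) -> SigmoidFit:
    """Nonlinear least-squares logistic fit to a radial-max profile.

    The amplitude (M - b) and slope are log-parameterized, enforcing
    M >= b and k > 0.  Initialization is derivative-free: b and M from the
    profile extremes, r50 from the half-maximum crossing, slope from the
    interquartile crossing width.  Degenerate (flat) profiles and optimizer
    failures return a fit flagged unsuccessful.  ``fix_baseline`` pins the
    baseline (e.g. 0 for a three-parameter fit) instead of estimating it.
    """
    r = np.asarray(profile.radii, dtype=float)
    v = np.asarray(profile.values, dtype=float)
    if r.size < 5:
        raise ValueError("need at least 5 profile samples")
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot == 0:
        return SigmoidFit(
            baseline=float(v[0]), maximum=float(v[0]), midpoint=np.nan,
            slope=np.nan, r_squared=np.nan, success=False,
        )
    b0, m0 = float(v.min()), float(v.max())
    amp0 = max(m0 - b0, 1e-12)

    def first_crossing(level: float) -> float:
        above = np.nonzero(v >= level)[0]
        return float(r[above[0]]) if above.size else float(r[-1])

    r50_0 = first_crossing(b0 + 0.5 * amp0)
    r25, r75 = first_crossing(b0 + 0.25 * amp0), first_crossing(b0 + 0.75 * amp0)
    k0 = 4.0 / (r75 - r25) if r75 > r25 else 1.0
    if fix_baseline is None:
        model = _logistic
        p0 = [b0, np.log(amp0), r50_0, np.log(k0)]
    else:
        def model(rr, log_amp, r50, log_k):
            return _logistic(rr, fix_baseline, log_amp, r50, log_k)

        amp0 = max(m0 - fix_baseline, 1e-12)
        p0 = [np.log(amp0), r50_0, np.log(k0)]
    try:
        popt, _ = curve_fit(model, r, v, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError):
        return SigmoidFit(
            baseline=np.nan, maximum=np.nan, midpoint=np.nan,
            slope=np.nan, r_squared=np.nan, success=False,
        )
    if fix_baseline is None:
        b, log_amp, r50, log_k = popt
    else:
        b = fix_baseline
        log_amp, r50, log_k = popt
    resid = v - model(r, *popt)
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot
    return SigmoidFit(
        baseline=float(b),
        maximum=float(b + np.exp(log_amp)),
        midpoint=float(r50),
        slope=float(np.exp(log_k)),
        r_squared=r_squared,
        success=True,
    )


def qc_onset(
    fit: SigmoidFit,
    r_max: float,
    slope_min: float = 0.7,
    max_min: float = 1000.0,
    r2_min: float = 0.95,
) -> QCResult:
    """Quality-control gates on a sigmoid fit (all strict inequalities).

    A measurement is accepted only if the fitted midpoint lies within the
    measured distance range (0, r_max), the slope is sharp (> 0.7 per px,
    tied to the point-spread-function scale), the sigmoid maximum is high
    (> 1000 AU, typical real-signal intensity) and R² > 0.95.
    """
    if not fit.success:
        return QCResult(passed=False, reasons=frozenset({"poor_fit"}))
    reasons = set()
    if not (0.0 < fit.midpoint < r_max):
        reasons.add("midpoint_out_of_range")
    if not (fit.slope > slope_min):
        reasons.add("slope_too_shallow")
    if not (fit.maximum > max_min):
        reasons.add("max_too_low")
    if not (fit.r_squared > r2_min):
        reasons.add("poor_fit")
    return QCResult(passed=not reasons, reasons=frozenset(reasons))


def onset_distance(fit: SigmoidFit, qc: QCResult, pixel_size: float) -> float:
    """Onset distance in μm: fitted midpoint times pixel size.

    Only QC-passing cells yield a measurement; failing cells are excluded
    from population statistics.
    """
    if not qc.passed:
        raise ValueError(f"QC failed ({sorted(qc.reasons)}); no measurement emitted")
    return fit.midpoint * pixel_size


def measure_onset(
    image: np.ndarray,
    centroid: tuple[float, float],
    pixel_size: float,
    r_max: float = 40.0,
    dr: float = 0.5,
    slope_min: float = 0.7,
    max_min: float = 1000.0,
    r2_min: float = 0.95,
) -> dict:
    """Full per-cell onset pipeline; returns a record dict.

    Keys: ``fit``, ``qc``, ``distance_um`` (None when QC fails).
    """
    profile = radial_max_profile(image, centroid, r_max=r_max, dr=dr)
    fit = fit_onset_sigmoid(profile)
    qc = qc_onset(fit, r_max=r_max, slope_min=slope_min, max_min=max_min,
                  r2_min=r2_min)
    distance = onset_distance(fit, qc, pixel_size) if qc.passed else None
    return {"profile": profile, "fit": fit, "qc": qc, "distance_um": distance}


def summarize_onsets(distances_um: list[float]) -> dict:
    """Mean, standard error and n of per-cell onset distances."""
    arr = np.asarray([d for d in distances_um if d is not None], dtype=float)
    if arr.size == 0:
        return {"mean_um": np.nan, "sem_um": np.nan, "n": 0}
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
    return {"mean_um": float(arr.mean()), "sem_um": sem, "n": int(arr.size)}
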