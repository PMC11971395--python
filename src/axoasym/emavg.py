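"""Ninefold rotational averaging of axoneme EM cross-sections.

Pipeline: the nine doublet A-tubule centres of each cross-section are
fitted to an ellipse; the section is perspective-corrected by the
anisotropic scaling that maps this ellipse to a circle (a tilted circular
section images as an ellipse, and this inverts that distortion model);
the corrected image is averaged over rotations by multiples of 40° about
the ring centre; rotational averages are mutually aligned (translation
plus in-plane rotation over [0°, 40°)) and group-averaged.  Group
differences are mapped per pixel with a two-sided Mann-Whitney U test and
multiple-comparison correction over the pixels of the axoneme mask.

Interpolation: rotations use cubic (prefiltered) splines, which are
near-variance-preserving on pixel noise; pure translations and the
perspective warp use bilinear interpolation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm, rankdata
from skimage.measure import EllipseModel

__all__ = [
    "EllipseFit",
    "RotationalAverage",
    "GroupAverage",
    "DifferenceMap",
    "fit_doublet_ellipse",
    "correct_perspective",
    "rotational_average_9fold",
    "align_rotational_averages",
    "group_average",
    "axoneme_mask",
    "mann_whitney_map",
    "difference_map",
    "process_cross_section",
]

_SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


@dataclass
class EllipseFit:
    """Geometric ellipse parameters: centre (x, y), semi-axes a >= b, orientation
    of the major axis in radians."""

    centre: tuple[float, float]
    a: float
    b: float
    orientation: float

    @property
    def axis_ratio(self) -> float:
        return self.b / self.a


@dataclass
class RotationalAverage:
    """A perspective-corrected, ninefold-averaged cross-section."""

    image: np.ndarray
    centre: tuple[float, float]  # ring centre (x, y) on this grid
    ring_radius: float  # px, mean centre-to-doublet distance after correction
    provenance: dict = field(default_factory=dict)


@dataclass
class GroupAverage:
    """Pixel-wise mean of an aligned stack; the stack is retained for
    per-pixel statistics."""

    mean: np.ndarray
    stack: np.ndarray  # (n, h, w)
    n: int


@dataclass
class DifferenceMap:
    """Parental-minus-mutant difference with per-pixel significance.

    Positive ``delta`` means electron density present in the parental line
    but lost in the mutant.  ``p_corrected`` is NaN outside the analysed
    mask; ``significant_mask`` is always a subset of ``mask``.
    """

    delta: np.ndarray
    p_map: np.ndarray
    p_corrected: np.ndarray
    significant_mask: np.ndarray
    mask: np.ndarray
    alpha: float
    correction: str


def fit_doublet_ellipse(centres: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse through the nine doublet centres."""
    centres = np.asarray(centres, dtype=float)
    if centres.shape != (9, 2):
        raise ValueError("expected exactly 9 doublet centres")
    centred = centres - centres.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise ValueError("doublet centres are collinear")
    try:
        model = EllipseModel.from_estimate(centres)
        if not model:
            raise ValueError("degenerate conic: ellipse fit failed")
        xc, yc = model.center
        a, b = model.axis_lengths
        theta = model.theta
    except AttributeError:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(centres):
            raise ValueError("degenerate conic: ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    if b <= 0:
        raise ValueError("degenerate conic: non-positive semi-axis")
    return EllipseFit(centre=(float(xc), float(yc)), a=float(a), b=float(b),
                      orientation=float(theta))


def _rot2(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def _affine_warp_xy(
    image: np.ndarray, matrix_xy: np.ndarray, centre_xy: np.ndarray,
    shift_xy: np.ndarray | None = None, order: int = 1,
) -> np.ndarray:
    """Warp so that output(p) = input(M (p - d - c) + c) in (x, y) coordinates."""
    d = np.zeros(2) if shift_xy is None else np.asarray(shift_xy, dtype=float)
    m_rc = _SWAP @ matrix_xy @ _SWAP
    c_rc = centre_xy[::-1]
    d_rc = d[::-1]
    offset = c_rc - m_rc @ (c_rc + d_rc)
    return ndimage.affine_transform(
        image, m_rc, offset=offset, order=order, mode="nearest",
        prefilter=order > 1,
    )


def correct_perspective(
    image: np.ndarray, ellipse: EllipseFit, centres: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Anisotropic scaling mapping the fitted ellipse to a circle of radius
    sqrt(a*b) (area-preserving), bilinear resampling.

    Returns the corrected image and, if given, the correspondingly
    transformed doublet centres.
    """
    r = np.sqrt(ellipse.a * ellipse.b)
    if ellipse.axis_ratio < 0.3:
        warnings.warn(
            f"extreme ellipse (b/a = {ellipse.axis_ratio:.2f}); "
            "perspective correction may be unreliable",
            stacklevel=2,
        )
    phi = ellipse.orientation
    c = np.asarray(ellipse.centre, dtype=float)
    # output -> input: stretch the unit circle back onto the ellipse
    m_in = _rot2(phi) @ np.diag([ellipse.a / r, ellipse.b / r]) @ _rot2(-phi)
    corrected = _affine_warp_xy(np.asarray(image, dtype=float), m_in, c, order=1)
    new_centres = None
    if centres is not None:
        m_fwd = _rot2(phi) @ np.diag([r / ellipse.a, r / ellipse.b]) @ _rot2(-phi)
        new_centres = (np.asarray(centres, dtype=float) - c) @ m_fwd.T + c
    return corrected, new_centres


def _rotate_about(
    image: np.ndarray, angle_deg: float, centre_xy: np.ndarray, order: int = 3
) -> np.ndarray:
    """Rotate image content by ``angle_deg`` about a sub-pixel centre."""
    m_in = _rot2(np.deg2rad(-angle_deg))  # output -> input rotates backwards
    return _affine_warp_xy(image, m_in, np.asarray(centre_xy, float), order=order)


def rotational_average_9fold(
    image: np.ndarray, centre: tuple[float, float]
) -> np.ndarray:
    """Pixel-wise mean of the image rotated by k*40° (k = 0..8) about ``centre``."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cx, cy = centre
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError("centre must lie inside the image")
    acc = image.copy()
    for k in range(1, 9):
        acc += _rotate_about(image, 40.0 * k, np.array([cx, cy]), order=3)
    return acc / 9.0


def process_cross_section(
    image: np.ndarray, centres: np.ndarray, source_id: str = ""
) -> RotationalAverage:
    """Ellipse fit, perspective correction and ninefold averaging for one image."""
    ellipse = fit_doublet_ellipse(centres)
    corrected, new_centres = correct_perspective(image, ellipse, centres)
    ring_radius = float(
        np.linalg.norm(new_centres - np.asarray(ellipse.centre), axis=1).mean()
    )
    averaged = rotational_average_9fold(corrected, ellipse.centre)
    return RotationalAverage(
        image=averaged,
        centre=ellipse.centre,
        ring_radius=ring_radius,
        provenance={
            "source_id": source_id,
            "ellipse": {"a": ellipse.a, "b": ellipse.b,
                        "orientation": ellipse.orientation},
        },
    )


def _xcorr_shift(ref: np.ndarray, img: np.ndarray) -> tuple[np.ndarray, float]:
    """Translation of ``img`` best matching ``ref`` by FFT cross-correlation,
    sub-pixel by quadratic interpolation of the correlation peak.

    Returns (shift_xy, normalized correlation at the peak).
    """
    a = ref - ref.mean()
    b = img - img.mean()
    corr = np.fft.irfft2(np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = np.array(peak, dtype=float)
    sub = np.zeros(2)
    for axis in range(2):
        idx = [peak[0], peak[1]]
        vals = []
        for step in (-1, 0, 1):
            idx[axis] = (peak[axis] + step) % corr.shape[axis]
            vals.append(corr[tuple(idx)])
        denom = vals[0] - 2 * vals[1] + vals[2]
        if denom < 0:
            sub[axis] = 0.5 * (vals[0] - vals[2]) / denom
    shift += sub
    # wrap to signed shifts
    for axis in range(2):
        if shift[axis] > corr.shape[axis] / 2:
            shift[axis] -= corr.shape[axis]
    norm_ab = np.sqrt((a**2).sum() * (b**2).sum())
    score = float(corr[peak] / norm_ab) if norm_ab > 0 else 0.0
    # corr peak at (dy, dx) means img displaced by -(dy, dx) relative to ref
    return np.array([shift[1], shift[0]]), score


def align_rotational_averages(
    averages: list[RotationalAverage] | np.ndarray,
    rotation: bool = True,
    n_iter: int = 3,
    coarse_step: float = 2.0,
    fine_step: float = 0.5,
    corr_threshold: float = 0.1,
) -> tuple[np.ndarray, list[dict], np.ndarray]:
    """Mutually align rotational averages to an iteratively refined mean.

    Each image is registered to the current mean reference by translation
    (cross-correlation peak, sub-pixel by quadratic interpolation) and, if
    ``rotation`` is enabled, an in-plane rotation searched over [0°, 40°) —
    the full search space under ninefold symmetry — coarsely at
    ``coarse_step`` then locally at ``fine_step``.  Images whose best
    normalized correlation falls below ``corr_threshold`` are flagged and
    excluded from the reference.

    Returns (aligned stack, per-image transforms, included mask).
    """
    if isinstance(averages, np.ndarray):
        stack = averages.astype(float)
        centre = np.array([(stack.shape[2] - 1) / 2.0, (stack.shape[1] - 1) / 2.0])
    else:
        stack = np.stack([ra.image for ra in averages]).astype(float)
        centre = np.mean([ra.centre for ra in averages], axis=0)
    n = stack.shape[0]
    if n == 1:
        return stack.copy(), [{"rotation_deg": 0.0, "shift_xy": (0.0, 0.0),
                               "score": 1.0}], np.array([True])
    aligned = stack.copy()
    transforms = [{"rotation_deg": 0.0, "shift_xy": (0.0, 0.0), "score": 1.0}
                  for _ in range(n)]
    included = np.ones(n, dtype=bool)
    for _ in range(n_iter):
        reference = aligned[included].mean(axis=0)
        for i in range(n):
            best = (0.0, np.zeros(2), -np.inf)  # angle, shift, score
            if rotation:
                coarse = np.arange(0.0, 40.0, coarse_step)
                best_angle = _best_rotation(reference, stack[i], centre, coarse)
                fine = best_angle + np.arange(-coarse_step, coarse_step + 1e-9,
                                              fine_step)
                angles = np.unique(np.mod(fine, 40.0))
            else:
                angles = np.array([0.0])
            for ang in angles:
                cand = (_rotate_about(stack[i], ang, centre, order=3)
                        if ang != 0.0 else stack[i])
                shift, score = _xcorr_shift(reference, cand)
                if score > best[2]:
                    best = (float(ang), shift, score)
            ang, shift, score = best
            transforms[i] = {"rotation_deg": ang, "shift_xy": tuple(shift),
                             "score": score}
            included[i] = score >= corr_threshold
            img = (_rotate_about(stack[i], ang, centre, order=3)
                   if ang != 0.0 else stack[i])
            aligned[i] = ndimage.shift(img, (shift[1], shift[0]), order=1,
                                       mode="nearest")
    return aligned, transforms, included


def _best_rotation(
    reference: np.ndarray, image: np.ndarray, centre: np.ndarray,
    angles: np.ndarray,
) -> float:
    best_ang, best_score = 0.0, -np.inf
    for ang in angles:
        cand = (_rotate_about(image, ang, centre, order=3)
                if ang != 0.0 else image)
        _, score = _xcorr_shift(reference, cand)
        if score > best_score:
            best_ang, best_score = float(ang), score
    return best_ang


def group_average(stack: np.ndarray) -> GroupAverage:
    """Pixel-wise mean of an aligned stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("need a non-empty (n, h, w) stack")
    return GroupAverage(mean=stack.mean(axis=0), stack=stack, n=stack.shape[0])


def axoneme_mask(
    shape: tuple[int, int], centre: tuple[float, float], ring_radius: float,
    factor: float = 1.4,
) -> np.ndarray:
    """Disc mask of radius factor × ring radius: the analysed cross-section."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(xx - centre[0], yy - centre[1]) <= factor * ring_radius


def mann_whitney_map(
    stack_a: np.ndarray, stack_b: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Per-pixel two-sided Mann-Whitney U p-values inside ``mask``.

    Normal approximation with tie and continuity corrections, vectorised
    over pixels; NaN outside the mask.  With group sizes n_a, n_b the
    smallest attainable two-sided p is bounded away from 0, so callers
    should check attainability against their corrected threshold.
    """
    na, nb = stack_a.shape[0], stack_b.shape[0]
    data = np.concatenate(
        [stack_a[:, mask], stack_b[:, mask]], axis=0
    )  # (na+nb, m)
    ranks = rankdata(data, axis=0)
    u1 = ranks[:na].sum(axis=0) - na * (na + 1) / 2
    n = na + nb
    mu = na * nb / 2.0
    # tie correction per pixel
    sorted_data = np.sort(data, axis=0)
    new_val = np.ones_like(sorted_data, dtype=bool)
    new_val[1:] = sorted_data[1:] != sorted_data[:-1]
    tie_sum = np.zeros(data.shape[1])
    for j in range(data.shape[1]):
        counts = np.diff(np.concatenate(
            [np.nonzero(new_val[:, j])[0], [n]]))
        tie_sum[j] = (counts**3 - counts).sum()
    sigma = np.sqrt(na * nb / 12.0 * ((n + 1) - tie_sum / (n * (n - 1))))
    u = np.maximum(u1, na * nb - u1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu - 0.5) / sigma
    p = np.where(sigma > 0, np.minimum(1.0, 2.0 * norm.sf(z)), 1.0)
    p_map = np.full(mask.shape, np.nan)
    p_map[mask] = p
    return p_map


def _min_attainable_p(na: int, nb: int) -> float:
    n = na + nb
    sigma = np.sqrt(na * nb * (n + 1) / 12.0)
    z = (na * nb - na * nb / 2.0 - 0.5) / sigma
    return float(min(1.0, 2.0 * norm.sf(z)))


def difference_map(
    parental: GroupAverage,
    mutant: GroupAverage,
    mask: np.ndarray,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> DifferenceMap:
    """Parental-minus-mutant difference map with per-pixel significance.

    ``delta`` = parental mean − mutant mean, so positive values mark
    electron density lost in the mutant.  Per-pixel two-sided Mann-Whitney
    U p-values inside the axoneme mask are corrected for the number of
    mask pixels (Bonferroni by default, Holm optionally) and thresholded
    at ``alpha``.
    """
    if parental.n < 4 or mutant.n < 4:
        raise ValueError("need at least 4 images per group")
    if parental.mean.shape != mutant.mean.shape:
        raise ValueError("groups must share a common grid")
    if correction not in ("bonferroni", "holm"):
        raise ValueError(f"unknown correction: {correction!r}")
    m = int(mask.sum())
    p_min = _min_attainable_p(parental.n, mutant.n)
    if p_min * m >= alpha:
        warnings.warn(
            f"group sizes too small: minimum attainable corrected p "
            f"{p_min * m:.3g} >= alpha {alpha}",
            stacklevel=2,
        )
    delta = parental.mean - mutant.mean
    p_map = mann_whitney_map(parental.stack, mutant.stack, mask)
    p_corrected = np.full(mask.shape, np.nan)
    pvals = p_map[mask]
    if correction == "bonferroni":
        p_corrected[mask] = np.minimum(1.0, pvals * m)
    else:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(pvals, method="holm")
        p_corrected[mask] = p_adj
    significant = np.zeros(mask.shape, dtype=bool)
    significant[mask] = p_corrected[mask] < alpha
    return DifferenceMap(
        delta=delta,
        p_map=p_map,
        p_corrected=p_corrected,
        significant_mask=significant,
        mask=mask,
        alpha=alpha,
        correction=correction,
    )
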