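"""Quantification of simulated patterns.

Metrics implemented here operationalize the qualitative readouts used to
interpret dot-stripe simulations: dot-maxima positions, the agreement of
the stripe pattern with the Voronoi tessellation predicted by those maxima,
the dominant spatial wavelength (radially averaged power spectrum), ridge
orientation (structure tensor), transverse-joint counting, a coarse
pattern-class label, and the clamp experiments that probe how the stripe
subsystem responds to imposed dot-subsystem values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import Voronoi
from skimage.measure import euler_number, label, regionprops
from skimage.morphology import skeletonize

from .geometry import DigitGeometry, DomainMasks, GridSpec, full_masks
from .kinetics import CouplingParams, StripeParams
from .models import FourSpeciesModel
from .solver import SolverConfig, simulate

PATTERN_CLASSES = ("dots", "stripes", "holes", "lattice", "none")

# documented analysis constants (the source procedures give no numeric values)
RIDGE_QUANTILE = 0.90       # top decile of the stripe field marks ridges
JOINT_SD_FACTOR = 1.0       # joint threshold: mean + 1 SD inside the digit
SKEW_THRESHOLD = 0.3        # |skewness| above which dots/holes are declared
ELONGATION_THRESHOLD = 2.5  # major/minor axis ratio marking stripe components
SPECTRUM_PEAK_RATIO = 8.0   # peak/median power required for a dominant scale
COHERENCE_THRESHOLD = 0.2   # structure-tensor anisotropy needed for orientation


class AnalysisError(ValueError):
    pass


@dataclass
class PatternMetrics:
    """Derived quantities of one snapshot."""

    dot_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    wavelength: float = float("nan")
    orientation_deg: float = float("nan")
    joint_count: int = 0
    voronoi_score: float = float("nan")
    pattern_class: str = "none"

    def as_dict(self) -> dict:
        return {
            "n_dots": int(len(self.dot_points)),
            "wavelength": self.wavelength,
            "orientation_deg": self.orientation_deg,
            "joint_count": self.joint_count,
            "voronoi_score": self.voronoi_score,
            "pattern_class": self.pattern_class,
        }


def find_dot_maxima(
    field_arr: np.ndarray,
    masks: DomainMasks,
    min_prominence: float = 0.1,
    neighborhood: int = 3,
) -> np.ndarray:
    """Local maxima of a field inside the domain, as (row, col) bin indices.

    A bin is a maximum if it attains the maximum of its 3x3 neighbourhood
    and stands at least ``min_prominence`` above the minimum of the
    surrounding ``neighborhood``-radius disk; plateau ties collapse to the
    plateau centroid.
    """
    if not np.all(np.isfinite(field_arr)):
        raise AnalysisError("field contains non-finite values")
    f = np.where(masks.omega, field_arr, -np.inf)
    is_max = (f == ndimage.maximum_filter(f, size=3)) & masks.omega
    r = neighborhood
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy**2 + xx**2) <= r**2
    local_min = ndimage.minimum_filter(
        np.where(masks.omega, field_arr, np.inf), footprint=disk
    )
    is_max &= (field_arr - local_min) >= min_prominence
    if not is_max.any():
        return np.empty((0, 2))
    labels, n = ndimage.label(is_max)
    centers = ndimage.center_of_mass(is_max, labels, range(1, n + 1))
    return np.array([(round(cy), round(cx)) for cy, cx in centers], dtype=float)


def _voronoi_segments(points_xy: np.ndarray, pad: float) -> np.ndarray:
    """Finite Voronoi edge segments, with infinite ridges clipped far away.

    Returns an array of shape (n_segments, 2, 2) of (x, y) endpoints.
    """
    vor = Voronoi(points_xy)
    center = points_xy.mean(axis=0)
    span = np.ptp(points_xy, axis=0).max() + pad
    segments = []
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 >= 0 and v2 >= 0:
            segments.append((vor.vertices[v1], vor.vertices[v2]))
            continue
        # semi-infinite ridge: extend from its finite vertex along the
        # outward normal of the generating pair
        finite = vor.vertices[v2 if v1 < 0 else v1]
        t = points_xy[p2] - points_xy[p1]
        t = t / np.linalg.norm(t)
        n = np.array([-t[1], t[0]])
        mid = points_xy[[p1, p2]].mean(axis=0)
        direction = np.sign(np.dot(mid - center, n)) * n
        if not direction.any():
            direction = n
        segments.append((finite, finite + direction * 4 * span))
    return np.asarray(segments)


def _point_segment_distance(pts: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Min distance from each point (n,2) to any segment (m,2,2)."""
    a, b = segs[:, 0], segs[:, 1]
    ab = b - a  # (m, 2)
    denom = (ab**2).sum(axis=1)  # (m,)
    ap = pts[:, None, :] - a[None, :, :]  # (n, m, 2)
    t = np.clip((ap * ab[None]).sum(axis=2) / np.maximum(denom, 1e-30), 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(pts[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def extract_ridges(field_arr: np.ndarray, masks: DomainMasks) -> np.ndarray:
    """Skeletonized top-decile bins of a stripe field, as a boolean mask."""
    inside = masks.omega
    vals = field_arr[inside]
    thr = np.quantile(vals, RIDGE_QUANTILE)
    ridge = inside & (field_arr >= thr)
    return skeletonize(ridge)


def voronoi_agreement(
    dot_points: np.ndarray,
    stripe_field: np.ndarray,
    masks: DomainMasks,
    wavelength: float,
    grid: GridSpec | None = None,
) -> float:
    """Distance of stripe ridges from the Voronoi diagram of the dots.

    Score = median distance from skeletonized ridge bins to the nearest
    Voronoi edge, normalized by the pattern wavelength; small scores mean
    the stripes trace the tessellation predicted by the dot positions.
    """
    dot_points = np.asarray(dot_points, float)
    if len(dot_points) < 3:
        raise AnalysisError("need at least 3 dot points for a Voronoi diagram")
    spread = np.linalg.norm(dot_points - dot_points.mean(axis=0), axis=1)
    # collinearity check via the singular values of the centred points
    sv = np.linalg.svd(dot_points - dot_points.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise AnalysisError("dot points are collinear; Voronoi diagram degenerate")
    if wavelength <= 0:
        raise AnalysisError("wavelength must be positive")
    h = grid.h if grid is not None else 1.0
    ridge = extract_ridges(stripe_field, masks)
    ry, rx = np.nonzero(ridge)
    if len(ry) == 0:
        raise AnalysisError("no ridge bins found in the stripe field")
    pts_xy = np.column_stack([rx, ry]).astype(float) * h
    dots_xy = dot_points[:, ::-1] * h  # (row, col) -> (x, y)
    segs = _voronoi_segments(dots_xy, pad=10 * wavelength)
    d = _point_segment_distance(pts_xy, segs)
    return float(np.median(d) / wavelength)


def estimate_wavelength(field_arr: np.ndarray, masks: DomainMasks, h: float = 1.0) -> float:
    """Dominant spatial period via the radially averaged power spectrum.

    The field is mean-subtracted and windowed to the domain; the peak of the
    angular average of |FFT|^2 gives the dominant wavenumber.  A flat
    spectrum (no scale standing above the background) raises an error.
    """
    inside = masks.omega
    f = np.where(inside, field_arr - field_arr[inside].mean(), 0.0)
    F = np.fft.fft2(f)
    power = np.abs(F) ** 2
    ny, nx = f.shape
    ky = np.fft.fftfreq(ny, d=h)
    kx = np.fft.fftfreq(nx, d=h)
    kmag = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    kmax = 0.5 / h  # Nyquist (cycles per length)
    dk = 1.0 / (max(nx, ny) * h)
    nbins = int(kmax / dk)
    bins = np.linspace(dk / 2, kmax, nbins + 1)
    idx = np.digitize(kmag.ravel(), bins)
    radial = np.zeros(nbins)
    for b in range(1, nbins + 1):
        sel = idx.ravel() == b
        if sel.any():
            radial[b - 1] = power.ravel()[sel].mean()
    valid = radial > 0
    if not valid.any():
        raise AnalysisError("no dominant scale: empty spectrum")
    centers = 0.5 * (bins[:-1] + bins[1:])
    peak_i = int(np.argmax(radial))
    peak, med = radial[peak_i], np.median(radial[valid])
    if med <= 0 or peak < SPECTRUM_PEAK_RATIO * med:
        raise AnalysisError("no dominant scale: spectrum is flat")
    return float(1.0 / centers[peak_i])


def dominant_orientation(
    field_arr: np.ndarray,
    masks: DomainMasks,
    sigma: float = 2.0,
    axis_deg: float = 0.0,
) -> float:
    """Dominant ridge orientation in degrees relative to the digit axis.

    Uses the gradient structure tensor averaged over the domain; returns an
    angle in [0, 90], where 90 means transverse stripes (perpendicular to
    the axis).  Raises if the field is isotropic (low tensor coherence).
    """
    f = ndimage.gaussian_filter(np.asarray(field_arr, float), sigma=1.0)
    fy, fx = np.gradient(f)
    w = masks.omega.astype(float)
    # erode so boundary gradients of the mask window do not dominate
    w = ndimage.binary_erosion(masks.omega, iterations=2).astype(float)
    if w.sum() == 0:
        w = masks.omega.astype(float)
    Jxx = float((fx * fx * w).sum())
    Jyy = float((fy * fy * w).sum())
    Jxy = float((fx * fy * w).sum())
    tr = Jxx + Jyy
    if tr <= 0:
        raise AnalysisError("no dominant orientation: zero gradient energy")
    lam_diff = np.hypot(Jxx - Jyy, 2 * Jxy)
    coherence = lam_diff / tr
    if coherence < COHERENCE_THRESHOLD:
        raise AnalysisError(
            f"no dominant orientation: coherence {coherence:.3f} below "
            f"{COHERENCE_THRESHOLD}"
        )
    grad_angle = 0.5 * np.degrees(np.arctan2(2 * Jxy, Jxx - Jyy))
    ridge_angle = grad_angle + 90.0  # ridges run perpendicular to the gradient
    rel = (ridge_angle - axis_deg) % 180.0
    if rel > 90.0:
        rel = 180.0 - rel
    return float(rel)


def count_transverse_joints(
    stripe_field: np.ndarray,
    masks: DomainMasks,
    grid: GridSpec | None = None,
    midline_row: float | None = None,
) -> int:
    """Number of stripe bands spanning the digit width across the midline.

    The stripe field is thresholded at mean + 1 SD inside the domain; a
    connected component counts as a joint if it has bins on both lateral
    sides of the digit midline.
    """
    inside = masks.omega
    if not inside.any():
        return 0
    vals = stripe_field[inside]
    thr = vals.mean() + JOINT_SD_FACTOR * vals.std()
    binary = inside & (stripe_field > thr)
    if not binary.any():
        return 0
    # one-step closing bridges single-bin pinches where a band crosses the
    # saddle of the dot field without splitting distinct bands
    binary = ndimage.binary_closing(binary, structure=np.ones((3, 3))) & inside
    if midline_row is None:
        rows = np.nonzero(inside.any(axis=1))[0]
        midline_row = 0.5 * (rows.min() + rows.max())
    labels = label(binary, connectivity=2)
    count = 0
    for i in range(1, labels.max() + 1):
        rows_i = np.nonzero(labels == i)[0]
        if rows_i.min() < midline_row and rows_i.max() > midline_row:
            count += 1
    return count


def _component_stats(mask: np.ndarray) -> tuple[int, float]:
    """(number of components, median major/minor axis ratio)."""
    lab = label(mask, connectivity=2)
    props = regionprops(lab)
    if not props:
        return 0, 0.0
    ratios = []
    for p in props:
        if p.area < 4:
            continue
        minor = max(p.axis_minor_length, 1.0)
        ratios.append(p.axis_major_length / minor)
    return len(props), float(np.median(ratios)) if ratios else 1.0


def classify_pattern(field_arr: np.ndarray, masks: DomainMasks) -> str:
    """Coarse pattern class: dots, holes, stripes, lattice or none.

    Decision rule on the standardized in-domain field: a connected positive
    network enclosing several cells is a lattice; strong positive (negative)
    skew with many compact positive (negative) components is dots (holes);
    elongated components are stripes.
    """
    inside = masks.omega
    vals = field_arr[inside]
    sd = vals.std()
    if sd == 0:
        return "none"
    z = np.where(inside, (field_arr - vals.mean()) / sd, 0.0)
    pos = inside & (z > 0.5)
    neg = inside & (z < -0.5)
    skew = float(stats.skew(vals))
    n_pos, elong_pos = _component_stats(pos)
    n_neg, elong_neg = _component_stats(neg)
    if n_pos == 0 and n_neg == 0:
        return "none"
    # a holes field and a lattice share their positive-phase topology
    # (connected network enclosing cells); strong negative skew separates
    # localized depressions (holes) from thin positive ridges (lattice)
    if skew <= -SKEW_THRESHOLD and n_neg >= 3 and elong_neg < ELONGATION_THRESHOLD:
        return "holes"
    if 1 <= n_pos <= 2 and pos.any():
        holes = n_pos - euler_number(pos, connectivity=2)
        if holes >= 3:
            return "lattice"
    if skew >= SKEW_THRESHOLD and n_pos >= 3 and elong_pos < ELONGATION_THRESHOLD:
        return "dots"
    if max(elong_pos, elong_neg) >= ELONGATION_THRESHOLD or n_pos >= 2:
        return "stripes"
    return "none"


def compute_metrics(
    field_dots: np.ndarray | None,
    field_stripes: np.ndarray,
    masks: DomainMasks,
    grid: GridSpec,
    min_prominence: float | None = None,
) -> PatternMetrics:
    """Convenience bundle of all metrics for one snapshot."""
    m = PatternMetrics()
    if min_prominence is None and field_dots is not None:
        vals = field_dots[masks.omega]
        min_prominence = 0.25 * max(vals.std(), 1e-12)
    if field_dots is not None:
        m.dot_points = find_dot_maxima(field_dots, masks, min_prominence)
    try:
        m.wavelength = estimate_wavelength(
            field_dots if field_dots is not None else field_stripes, masks, grid.h
        )
    except AnalysisError:
        pass
    try:
        m.orientation_deg = dominant_orientation(field_stripes, masks)
    except AnalysisError:
        pass
    m.joint_count = count_transverse_joints(field_stripes, masks, grid)
    m.pattern_class = classify_pattern(field_stripes, masks)
    if len(m.dot_points) >= 3 and np.isfinite(m.wavelength):
        try:
            m.voronoi_score = voronoi_agreement(
                m.dot_points, field_stripes, masks, m.wavelength, grid
            )
        except AnalysisError:
            pass
    return m


def joint_positions_profile(
    stripe_field: np.ndarray, masks: DomainMasks, prominence_factor: float = 0.25
) -> np.ndarray:
    """Along-axis joint positions from peaks of the width-averaged profile.

    More robust than component counting when band amplitudes vary (e.g.
    committed bands frozen below full amplitude and then stretched): a band
    only needs prominence, not a fixed global threshold.  Returns x bin
    coordinates of interior peaks, sorted.
    """
    from scipy.signal import find_peaks

    w = masks.omega
    occ = np.maximum(w.sum(axis=0), 1)
    prof = np.where(w, stripe_field, 0.0).sum(axis=0) / occ
    valid = w.any(axis=0)
    p = np.where(valid, prof, 0.0)
    sd = prof[valid].std()
    peaks, _ = find_peaks(p, prominence=prominence_factor * max(sd, 1e-12))
    return np.asarray(sorted(pk + 0.5 for pk in peaks if valid[pk]), float)


def mean_ridge_curvature(
    field_arr: np.ndarray, masks: DomainMasks, sigma: float = 2.0
) -> float:
    """Mean absolute level-set curvature along the field's ridge skeleton.

    Straight joint bands score low; the blobby, strongly curved bands of a
    dot-hole model score high.  Curvature of the iso-contours is
    kappa = (f_xx f_y^2 - 2 f_xy f_x f_y + f_yy f_x^2) / |grad f|^3,
    evaluated on skeletonized top-decile ridge bins.
    """
    f = ndimage.gaussian_filter(np.asarray(field_arr, float), sigma)
    fy, fx = np.gradient(f)
    fyy, _ = np.gradient(fy)
    fxy, fxx = np.gradient(fx)
    g2 = fx**2 + fy**2
    kappa = (fxx * fy**2 - 2 * fxy * fx * fy + fyy * fx**2) / np.maximum(g2, 1e-12) ** 1.5
    sel = extract_ridges(field_arr, masks) & (g2 > 1e-6)
    if not sel.any():
        raise AnalysisError("no ridge bins with usable gradient")
    return float(np.abs(kappa[sel]).mean())


# ---------------------------------------------------------------------------
# clamp experiments: drive (B, I) with imposed (A, S)


def clamp_uniform(
    A_val: float,
    S_val: float,
    stripe: StripeParams,
    coupling: CouplingParams,
    grid: GridSpec,
    config: SolverConfig,
    dot_params=None,
) -> float:
    """Final spatial SD of B when (A, S) are clamped uniform over the domain.

    Near-dot-centre values (A high, S low) should suppress stripe
    self-organization; far-from-dot values (A low, S high) should allow it.
    """
    from .kinetics import DotParams

    model = FourSpeciesModel(
        dot=dot_params or DotParams(),
        stripe=stripe,
        coupling=coupling,
        frozen={"A": float(A_val), "S": float(S_val)},
    )
    traj = simulate(model, grid, config)
    B = traj.final_fields["B"]
    return float(B.std())


def clamp_gradient(
    direction_deg: float,
    A_range: tuple[float, float],
    S_range: tuple[float, float],
    stripe: StripeParams,
    coupling: CouplingParams,
    grid: GridSpec,
    config: SolverConfig,
    dot_params=None,
) -> float:
    """Stripe orientation under a frozen linear (A, S) gradient.

    The gradient runs along ``direction_deg`` from (A high, S low) to
    (A low, S high); returns the dominant stripe orientation in degrees
    relative to the gradient direction (90 = perpendicular).
    """
    from .kinetics import DotParams

    X, Y = grid.meshgrid()
    th = np.radians(direction_deg)
    s = (X - X.min()) * np.cos(th) + (Y - Y.min()) * np.sin(th)
    s = (s - s.min()) / max(s.max() - s.min(), 1e-12)
    A_field = A_range[0] + (A_range[1] - A_range[0]) * s
    S_field = S_range[0] + (S_range[1] - S_range[0]) * s
    model = FourSpeciesModel(
        dot=dot_params or DotParams(),
        stripe=stripe,
        coupling=coupling,
        frozen={"A": A_field, "S": S_field},
    )
    traj = simulate(model, grid, config)
    B = traj.final_fields["B"]
    return dominant_orientation(B, full_masks(grid), axis_deg=direction_deg)
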