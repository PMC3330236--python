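"""Lumen wall kinematics: contour containers, circumferential length and strain.

The deformation signal extracted from time-resolved lumen cross sections is the
circumferential strain: the fractional change of the lumen perimeter L(i) on
frame i relative to a reference frame, eps(i) = (L(i) - L_ref) / L_ref
(engineering strain). The reference is the diastolic (minimum-pressure) frame
when a pressure trace is available, else the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "ContourSeries",
    "StrainSeries",
    "circumferential_length",
    "fourier_smooth_contour",
    "resample_closed_contour",
    "segment_lumen",
    "strain_series",
]


def _polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as an (n, 2) array."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_simple(vertices: np.ndarray) -> bool:
    # Shapely's is_simple handles the general case; the lazy import keeps the
    # geometry dependency out of purely tabular code paths.
    from shapely.geometry import LinearRing

    try:
        return LinearRing(vertices).is_simple
    except Exception:
        return False


@dataclass
class ContourSeries:
    """Ordered closed lumen contours, one per imaging frame.

    Parameters
    ----------
    timestamps : (n_frames,) array of acquisition times in seconds,
        strictly increasing.
    contours : list of (k, 2) arrays of vertex coordinates in mm, ordered
        along the boundary; the closing edge (last vertex back to the first)
        is implicit. Each contour must have at least 8 vertices, enclose
        positive area and be non-self-intersecting.
    """

    timestamps: np.ndarray
    contours: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.contours = [np.asarray(c, dtype=float) for c in self.contours]
        if self.timestamps.ndim != 1 or len(self.timestamps) < 2:
            raise ValidationError("timestamps: need at least 2 frames")
        if len(self.contours) != len(self.timestamps):
            raise ValidationError(
                "contours: length must match timestamps "
                f"({len(self.contours)} vs {len(self.timestamps)})"
            )
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps: must be strictly increasing")
        for i, c in enumerate(self.contours):
            if c.ndim != 2 or c.shape[1] != 2:
                raise ValidationError(f"contours[{i}]: expected an (n, 2) array")
            if len(c) < 8:
                raise ValidationError(f"contours[{i}]: need >= 8 vertices, got {len(c)}")
            if not np.all(np.isfinite(c)):
                raise ValidationError(f"contours[{i}]: non-finite coordinates")
            if abs(_polygon_area(c)) <= 0.0:
                raise ValidationError(f"contours[{i}]: zero enclosed area")
            if not _is_simple(c):
                raise ValidationError(f"contours[{i}]: self-intersecting contour")

    def __len__(self) -> int:
        return len(self.contours)


@dataclass
class StrainSeries:
    """Per-frame circumferential length and engineering strain.

    Fields are parallel arrays: ``timestamps`` (s), ``lengths`` (mm, the lumen
    perimeter L(i)) and ``strains`` (dimensionless, zero at the reference
    frame). ``reference_index`` records which frame defined L_ref.
    """

    timestamps: np.ndarray
    lengths: np.ndarray
    strains: np.ndarray
    reference_index: int = 0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.strains = np.asarray(self.strains, dtype=float)
        if not (len(self.timestamps) == len(self.lengths) == len(self.strains)):
            raise ValidationError("strain series: mismatched array lengths")
        if np.any(self.lengths <= 0):
            raise ValidationError("lengths: must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)


def circumferential_length(contour: np.ndarray) -> float:
    """Perimeter of a closed polygonal contour (mm).

    Sum of Euclidean edge lengths including the closing edge from the last
    vertex back to the first. Raises on fewer than 3 vertices.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2:
        raise ValidationError("contour: expected an (n, 2) array")
    if len(contour) < 3:
        raise ValidationError(f"contour: need >= 3 vertices, got {len(contour)}")
    edges = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.sum(np.hypot(edges[:, 0], edges[:, 1])))


def resample_closed_contour(contour: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed contour to ``n_points`` vertices at uniform arc length.

    The resampled vertices lie on the original polygonal boundary, starting at
    the original first vertex. Used to decouple perimeter estimates from the
    vertex density the boundary happened to be traced with.
    """
    contour = np.asarray(contour, dtype=float)
    if n_points < 3:
        raise ValidationError("n_points: need >= 3")
    closed = np.vstack([contour, contour[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValidationError("contour: zero total arc length")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def fourier_smooth_contour(
    contour: np.ndarray,
    n_harmonics: int = 10,
    n_points: int | None = None,
) -> np.ndarray:
    """Low-pass a closed contour by truncating its Fourier descriptors.

    The contour is resampled to ``n_points`` (default: at least 128) at
    uniform arc length, written as a complex boundary signal z(s) = x + iy,
    and reconstructed from its first ``n_harmonics`` positive and negative
    harmonics (plus the centroid term). Vertex-level tracing noise lives in
    the high harmonics and inflates the measured perimeter quadratically;
    truncation removes it while leaving smooth lumen shapes essentially
    untouched. Linear in the coordinates, so it commutes with scaling,
    rotation and translation.
    """
    contour = np.asarray(contour, dtype=float)
    if n_harmonics < 1:
        raise ValidationError("n_harmonics: need >= 1")
    if n_points is None:
        n_points = max(len(contour), 128)
    if n_points < 2 * n_harmonics + 1:
        raise ValidationError("n_points: need >= 2 * n_harmonics + 1")
    res = resample_closed_contour(contour, n_points)
    z = res[:, 0] + 1j * res[:, 1]
    spectrum = np.fft.fft(z)
    keep = np.zeros(n_points, dtype=bool)
    keep[: n_harmonics + 1] = True
    keep[-n_harmonics:] = True
    spectrum[~keep] = 0.0
    smooth = np.fft.ifft(spectrum)
    return np.column_stack([smooth.real, smooth.imag])


def strain_series(
    contours: ContourSeries,
    reference: str = "first-frame",
    pressure=None,
    resample: bool = True,
    smooth_harmonics: int | None = 10,
) -> StrainSeries:
    """Circumferential strain of every frame against a reference frame.

    Parameters
    ----------
    contours : ContourSeries
    reference : "first-frame" or "min-pressure-frame". The latter picks the
        frame whose (interpolated) pressure is smallest — the diastolic
        configuration — and requires ``pressure``.
    pressure : PressureTrace, required for the min-pressure reference.
    resample : resample every contour to a common uniform-arc-length vertex
        count (the maximum count over frames, at least 128) before measuring
        perimeters, so that frames traced with different vertex densities
        remain comparable.
    smooth_harmonics : truncate each contour's Fourier descriptors to this
        many harmonics before measuring the perimeter (None disables).
        Vertex-level tracing noise inflates a polygon's perimeter by a
        noise-dependent amount that fluctuates frame to frame and would leak
        into the strain; low-pass smoothing suppresses it. Lower values give
        stronger smoothing; shapes with genuine sharp features need this
        raised or disabled.
    """
    if reference not in ("first-frame", "min-pressure-frame"):
        raise ValidationError(f"reference: unknown selector '{reference}'")

    polys = contours.contours
    n = max(max(len(c) for c in polys), 128)
    if smooth_harmonics is not None:
        polys = [fourier_smooth_contour(c, smooth_harmonics, n) for c in polys]
    elif resample:
        polys = [resample_closed_contour(c, n) for c in polys]
    lengths = np.array([circumferential_length(c) for c in polys])

    if reference == "min-pressure-frame":
        if pressure is None:
            raise ValidationError("pressure: required for min-pressure-frame reference")
        p_at_frames = np.interp(contours.timestamps, pressure.timestamps, pressure.pressures)
        ref_idx = int(np.argmin(p_at_frames))
    else:
        ref_idx = 0

    l_ref = lengths[ref_idx]
    if l_ref <= 0:
        raise ValidationError("reference frame has zero circumferential length")
    strains = (lengths - l_ref) / l_ref
    return StrainSeries(
        timestamps=contours.timestamps,
        lengths=lengths,
        strains=strains,
        reference_index=ref_idx,
    )


def _segment_frame(
    image: np.ndarray,
    n_rays: int,
    step_px: float,
    grad_threshold: float,
    smooth_sigma: float,
) -> tuple[np.ndarray, int]:
    """Radial-ray boundary detection on one frame; returns (points_px, n_failed).

    Rays are cast from the intensity-weighted lumen centroid (pixels darker
    than the median weighted by their darkness); per ray the boundary is the
    sub-pixel location of the maximum outward intensity gradient, refined by
    a parabolic fit around the discrete maximum.
    """
    from scipy import ndimage

    img = ndimage.gaussian_filter(image.astype(float), smooth_sigma)
    weights = np.clip(np.median(img) - img, 0.0, None)
    total = weights.sum()
    if total <= 0:
        return np.empty((0, 2)), n_rays
    rows, cols = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    c_row = float((weights * rows).sum() / total)
    c_col = float((weights * cols).sum() / total)

    r_max = min(c_row, c_col, img.shape[0] - 1 - c_row, img.shape[1] - 1 - c_col)
    radii = np.arange(0.0, r_max, step_px)
    if len(radii) < 5:
        return np.empty((0, 2)), n_rays
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays

    points = np.full((n_rays, 2), np.nan)
    n_failed = 0
    for k, theta in enumerate(angles):
        # image rows grow downward; keep the ray sweep counter-clockwise in
        # the physical (y-up) plane by negating the row component
        ray_rows = c_row - radii * np.sin(theta)
        ray_cols = c_col + radii * np.cos(theta)
        profile = ndimage.map_coordinates(img, [ray_rows, ray_cols], order=1)
        grad = np.gradient(profile, step_px)
        j = int(np.argmax(grad))
        if grad[j] < grad_threshold:
            n_failed += 1
            continue
        # parabolic sub-pixel refinement of the gradient peak
        if 0 < j < len(grad) - 1:
            denom = grad[j - 1] - 2.0 * grad[j] + grad[j + 1]
            delta = 0.5 * (grad[j - 1] - grad[j + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        r_b = radii[j] + delta * step_px
        points[k] = (c_row - r_b * np.sin(theta), c_col + r_b * np.cos(theta))
    return points, n_failed


def segment_lumen(
    frames,
    n_rays: int = 64,
    step_px: float = 0.25,
    grad_rel_threshold: float = 0.05,
    smooth_sigma: float = 1.0,
    max_failed_fraction: float = 0.10,
) -> ContourSeries:
    """Extract the lumen boundary from B-mode-like frames by radial ray casting.

    Per frame, rays are cast from the intensity-weighted lumen centroid
    (the lumen is the dark region) and the boundary point on each ray is the
    sub-pixel maximum of the outward intensity gradient — the dark-to-bright
    transition at the inner wall edge. A ray with no gradient maximum above
    ``grad_rel_threshold`` of the frame's dynamic range (per pixel) counts as
    failed; more than ``max_failed_fraction`` failed rays raises
    SegmentationError carrying the frame index. Failed rays below that
    fraction are filled by periodic interpolation of the boundary radius
    from neighbouring rays.

    Returns contours in mm coordinates via the frame-stack manifest.
    """
    from .errors import SegmentationError

    if len(frames) == 0:
        raise ValidationError("frames: empty stack")
    if n_rays < 8:
        raise ValidationError("n_rays: need >= 8")

    contours = []
    for i, image in enumerate(frames.frames):
        dyn = float(image.max()) - float(image.min())
        threshold = grad_rel_threshold * dyn if dyn > 0 else np.inf
        pts_px, n_failed = _segment_frame(image, n_rays, step_px, threshold,
                                          smooth_sigma)
        if n_failed / n_rays >= max_failed_fraction or len(pts_px) == 0:
            raise SegmentationError(
                f"frame {i}: no boundary gradient on {n_failed}/{n_rays} rays",
                frame_index=i,
            )
        if n_failed:
            ok = ~np.isnan(pts_px[:, 0])
            idx = np.arange(n_rays)
            for col in (0, 1):
                pts_px[~ok, col] = np.interp(idx[~ok], idx[ok], pts_px[ok, col],
                                             period=n_rays)
        contours.append(frames.pixel_to_mm(pts_px[:, 0], pts_px[:, 1]))
    return ContourSeries(timestamps=frames.timestamps.copy(), contours=contours)
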