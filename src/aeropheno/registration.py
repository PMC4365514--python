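"""Fiducial-marker co-registration of the multi-sensor imagery.

Round dark metal plates on poles around the field are the fiducials.  They
are dark in the optical images (detected in the blue channel) and warm in
the thermal images (the plates heat above canopy and soil).  Detection is
quantile thresholding -> connected components -> shape filters (area from
the expected radius, circularity 4*pi*A/P^2, solidity), with sub-pixel
centres from an intensity-weighted centroid.  Cross-sensor correspondence is
refined by normalized cross-correlation (NCC), with the vegetation-camera
(B+NIR) marker regions as templates.  A projective transform (homography) is
fitted to the correspondences by normalized DLT followed by a geometric
least-squares refinement, and each sensor is warped into the common
area-of-interest (AoI) frame with bicubic interpolation.

Coordinate convention: 0-based (row, col), pixel centres at integer
coordinates.  Homographies act on homogeneous (row, col, 1) vectors and are
normalized to H[2, 2] = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize
from skimage import feature, measure, transform

from .errors import FitError, InvalidSpecError, RegistrationInfeasibleError, \
    UndefinedCorrelationError
from .image import SensorImage

__all__ = [
    "MarkerObservation",
    "RegistrationModel",
    "detect_markers",
    "refine_by_ncc",
    "fit_projective",
    "warp_to_aoi",
    "upscale_thermal",
    "match_to_reference",
]


@dataclass(frozen=True)
class MarkerObservation:
    """One detected fiducial: sub-pixel centre, radius and a quality score."""

    center: tuple[float, float]  # (row, col)
    radius: float
    score: float | None = None
    source_channel: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidSpecError("marker radius must be > 0")


@dataclass
class RegistrationModel:
    """Fitted projective map from sensor pixels into the AoI frame."""

    correspondences: list  # [( (r,c) source, (r,c) target ), ...]
    H: np.ndarray  # 3x3, acts on (row, col, 1), H[2,2] == 1
    rmse: float

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape != (3, 3):
            raise ValueError("H must be 3x3")
        if abs(np.linalg.det(self.H)) < 1e-12:
            raise FitError("homography is singular")
        self.H = self.H / self.H[2, 2]
        if len(self.correspondences) < 4:
            raise FitError("a registration model needs >= 4 correspondences")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")

    def transform(self, points_rc) -> np.ndarray:
        """Map (N, 2) source (row, col) points into the target frame."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.H.T
        return out[:, :2] / out[:, 2:3]

    def inverse_transform(self, points_rc) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ np.linalg.inv(self.H).T
        return out[:, :2] / out[:, 2:3]


def detection_channel(img: SensorImage, polarity: str) -> tuple[np.ndarray, str]:
    """Channel used for marker detection: blue if present, else thermal."""
    if "B" in img.channel_names:
        return img.channel("B"), "B"
    if "T" in img.channel_names:
        if polarity != "bright":
            raise InvalidSpecError(
                "thermal marker detection requires polarity='bright' "
                "(the metal plates emit warmer than plants and soil)"
            )
        return img.channel("T"), "T"
    return img.pixels[:, :, 0], img.channel_names[0]


def detect_markers(
    img: SensorImage,
    polarity: str = "dark",
    expected_radius_px: tuple[float, float] = (3.0, 30.0),
    max_markers: int = 12,
    channel: str | None = None,
    threshold_quantile: float = 0.02,
    min_circularity: float = 0.6,
    min_solidity: float = 0.8,
) -> list[MarkerObservation]:
    """Detect circular fiducials of the requested polarity.

    Thresholds the detection channel at ``threshold_quantile`` (the darkest /
    brightest tail), labels connected components and keeps blobs whose area
    is compatible with ``expected_radius_px``, whose circularity
    ``4*pi*A/P^2`` is at least ``min_circularity`` and whose solidity passes.
    Centres are intensity-weighted centroids (weights: contrast beyond the
    threshold), giving sub-pixel accuracy.

    Raises :class:`RegistrationInfeasibleError` carrying the partial list
    when fewer than four markers survive — the caller may then fall back to
    a manual-override marker file.
    """
    if polarity not in ("dark", "bright"):
        raise InvalidSpecError("polarity must be 'dark' or 'bright'")
    if channel is not None:
        data, ch_name = img.channel(channel), channel
    else:
        data, ch_name = detection_channel(img, polarity)
    work = np.where(np.isfinite(data), data, np.nanmedian(data))
    if polarity == "dark":
        work = -work
    # the fiducials are extreme against the scene: gate the quantile
    # threshold at the midpoint between background median and the far tail,
    # so smooth scene texture in the tail cannot flood the mask
    thr = max(
        np.quantile(work, 1.0 - threshold_quantile),
        0.5 * (np.median(work) + work.max()),
    )
    mask = work > thr
    r_min, r_max = expected_radius_px
    min_area = max(3.0, np.pi * r_min**2)
    max_area = np.pi * r_max**2

    # 4-connectivity: diagonal speckle does not merge into a marker blob
    labels = measure.label(mask, connectivity=1)
    max_contrast = work.max() - thr
    found = []
    for region in measure.regionprops(labels):
        if not (min_area <= region.area <= max_area):
            continue
        perim = region.perimeter
        circularity = 4.0 * np.pi * region.area / perim**2 if perim > 0 else 0.0
        if circularity < min_circularity or region.solidity < min_solidity:
            continue
        rr, cc = region.coords.T
        w = np.clip(work[rr, cc] - thr, 0, None)
        if w.sum() <= 0:
            w = np.ones_like(w)
        center = (float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum()))
        # score by contrast depth: the fiducials are the most extreme blobs
        score = float(np.clip(w.mean() / max_contrast, 0.0, 1.0)) \
            if max_contrast > 0 else 0.0
        found.append(
            MarkerObservation(
                center=center,
                radius=float(np.sqrt(region.area / np.pi)),
                score=score,
                source_channel=ch_name,
            )
        )
    found.sort(key=lambda m: (-(m.score or 0.0), m.center))
    found = found[:max_markers]
    if len(found) < 4:
        raise RegistrationInfeasibleError(
            f"only {len(found)} marker(s) detected (need >= 4); supply manual "
            f"marker centres to proceed",
            detections=found,
        )
    return found


def _window(arr: np.ndarray, center_rc, half: int) -> np.ndarray:
    r, c = int(round(center_rc[0])), int(round(center_rc[1]))
    if (
        r - half < 0
        or c - half < 0
        or r + half >= arr.shape[0]
        or c + half >= arr.shape[1]
    ):
        raise InvalidSpecError("window not fully inside image")
    return arr[r - half : r + half + 1, c - half : c + half + 1], (r, c)


def refine_by_ncc(
    template_img: SensorImage,
    search_img: SensorImage,
    marker: MarkerObservation,
    window_px: int,
    search_center: tuple[float, float] | None = None,
    slack_px: int | None = None,
    template_channel: str | None = None,
    search_channel: str | None = None,
) -> MarkerObservation:
    """Re-locate ``marker`` in ``search_img`` by normalized cross-correlation.

    A (2*window+1)^2 template around the marker in ``template_img`` is slid
    over a search region of the same size plus ``slack_px`` (default
    1.5 x the marker radius) around ``search_center`` (default: the marker's
    own coordinates) in ``search_img``.  Returns the marker with its centre
    at the NCC-maximizing offset and ``score`` set to the peak NCC in
    [-1, 1].  Ties are broken by the smallest offset magnitude, then
    row-major order.
    """
    if slack_px is None:
        slack_px = max(1, int(round(1.5 * marker.radius)))

    def _default_channel(im: SensorImage) -> np.ndarray:
        for name in ("B", "T"):
            if name in im.channel_names:
                return im.channel(name)
        return im.pixels[:, :, 0]

    t_data = (
        template_img.channel(template_channel)
        if template_channel
        else _default_channel(template_img)
    )
    s_data = (
        search_img.channel(search_channel)
        if search_channel
        else _default_channel(search_img)
    )
    templ, _ = _window(t_data, marker.center, window_px)
    if search_center is None:
        search_center = marker.center
    region, (r0, c0) = _window(s_data, search_center, window_px + slack_px)
    if templ.std() == 0:
        raise UndefinedCorrelationError("zero-variance template")
    if region.std() == 0:
        raise UndefinedCorrelationError("zero-variance search window")
    corr = feature.match_template(region, templ)  # (2*slack+1)^2 map
    peak = corr.max()
    tie = np.argwhere(corr >= peak - 1e-12)
    offsets = tie - slack_px  # offset of template centre from search centre
    order = np.lexsort((offsets[:, 1], offsets[:, 0],
                        (offsets**2).sum(axis=1)))
    dr, dc = offsets[order[0]]
    new_center = (r0 + float(dr), c0 + float(dc))
    return replace(marker, center=new_center, score=float(peak))


def _collinear(p, q, s, tol: float = 1e-8) -> bool:
    area = abs(
        (q[0] - p[0]) * (s[1] - p[1]) - (q[1] - p[1]) * (s[0] - p[0])
    )
    scale = max(1.0, abs(q[0] - p[0]), abs(q[1] - p[1]), abs(s[0] - p[0]),
                abs(s[1] - p[1]))
    return area < tol * scale**2


def fit_projective(correspondences) -> RegistrationModel:
    """Fit a homography to >= 4 (source, target) point pairs.

    Normalized DLT (via :class:`skimage.transform.ProjectiveTransform`)
    followed by a Levenberg-Marquardt refinement of the sum of squared
    target-plane residuals.  With exactly four non-degenerate pairs the fit
    interpolates exactly; degenerate configurations (any three collinear
    target or source points among four, or a rank-deficient system) raise
    :class:`FitError` naming the offending points.
    """
    pairs = [(np.asarray(s, float), np.asarray(t, float)) for s, t in correspondences]
    if len(pairs) < 4:
        raise FitError(f"need >= 4 correspondences, got {len(pairs)}")
    src = np.array([p[0] for p in pairs])
    dst = np.array([p[1] for p in pairs])
    if len(pairs) == 4:
        for pts, name in ((src, "source"), (dst, "target")):
            for i, j, k in (
                (0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3),
            ):
                if _collinear(pts[i], pts[j], pts[k]):
                    raise FitError(
                        f"degenerate configuration: {name} points "
                        f"{i}, {j}, {k} are collinear: "
                        f"{pts[i]}, {pts[j]}, {pts[k]}"
                    )
    else:
        # reject globally collinear clouds
        for pts, name in ((src, "source"), (dst, "target")):
            centered = pts - pts.mean(axis=0)
            if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(pts).max())) < 2:
                raise FitError(f"degenerate configuration: all {name} points collinear")

    # DLT is axis-agnostic: feed (row, col) directly.
    if hasattr(transform.ProjectiveTransform, "from_estimate"):
        tform = transform.ProjectiveTransform.from_estimate(src, dst)
        ok = bool(tform)
    else:  # older scikit-image
        tform = transform.ProjectiveTransform()
        ok = tform.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tform.params)):
        raise FitError("projective estimation failed (degenerate configuration)")
    H = tform.params / tform.params[2, 2]

    def residuals(h8):
        Hm = np.append(h8, 1.0).reshape(3, 3)
        hom = np.column_stack([src, np.ones(len(src))]) @ Hm.T
        proj = hom[:, :2] / hom[:, 2:3]
        return (proj - dst).ravel()

    if len(pairs) > 4:
        sol = optimize.least_squares(residuals, H.ravel()[:8], method="lm")
        H = np.append(sol.x, 1.0).reshape(3, 3)
    res = residuals(H.ravel()[:8]).reshape(-1, 2)
    rmse = float(np.sqrt((res**2).sum(axis=1).mean()))
    return RegistrationModel(
        correspondences=[(tuple(s), tuple(t)) for s, t in pairs], H=H, rmse=rmse
    )


def _rc_to_xy(H: np.ndarray) -> np.ndarray:
    """Convert a (row, col) homography to (x, y) = (col, row) convention."""
    P = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    return P @ H @ P


def warp_to_aoi(
    img: SensorImage, model: RegistrationModel, aoi_shape: tuple[int, int]
) -> SensorImage:
    """Warp a sensor image into the AoI frame with bicubic interpolation.

    Output pixels whose pre-image falls outside the source raster (or whose
    bicubic support touches the outside) are NaN and are excluded from all
    downstream statistics.
    """
    H = model.H
    if np.allclose(H, np.eye(3), atol=1e-12):
        h, w = aoi_shape
        src = img.pixels
        out = np.full((h, w, src.shape[2]), np.nan)
        hh, ww = min(h, src.shape[0]), min(w, src.shape[1])
        out[:hh, :ww] = src[:hh, :ww]
        return img.with_pixels(out)
    inv_xy = np.linalg.inv(_rc_to_xy(H))
    tform = transform.ProjectiveTransform(matrix=inv_xy)
    channels = []
    for c in range(img.pixels.shape[2]):
        warped = transform.warp(
            img.pixels[:, :, c],
            inverse_map=tform,
            output_shape=aoi_shape,
            order=3,
            mode="constant",
            cval=np.nan,
            preserve_range=True,
        )
        channels.append(warped)
    return img.with_pixels(np.stack(channels, axis=-1))


def upscale_thermal(img: SensorImage, target_shape: tuple[int, int]) -> SensorImage:
    """Upscale a thermal raster with temperature-preserving interpolation.

    Align-corners bilinear sampling: constants are reproduced exactly and a
    linear temperature ramp stays linear everywhere including the borders;
    the global mean is preserved to well within 0.1% for integer factors.
    Downscaling requests are rejected.
    """
    h_in, w_in = img.shape
    h_out, w_out = target_shape
    if h_out < h_in or w_out < w_in:
        raise InvalidSpecError(
            f"upscale_thermal cannot downscale ({img.shape} -> {target_shape})"
        )
    if (h_out, w_out) == (h_in, w_in):
        return img.with_pixels(img.pixels.copy())
    rows = np.linspace(0.0, h_in - 1.0, h_out) if h_out > 1 else np.zeros(1)
    cols = np.linspace(0.0, w_in - 1.0, w_out) if w_out > 1 else np.zeros(1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    channels = []
    for c in range(img.pixels.shape[2]):
        channels.append(
            ndimage.map_coordinates(
                img.pixels[:, :, c], [rr, cc], order=1, mode="nearest"
            )
        )
    return img.with_pixels(np.stack(channels, axis=-1))


def scale_factor_between(img: SensorImage, target_shape: tuple[int, int]) -> float:
    """Isotropic scale from an image's shape to a target shape (mean of axes)."""
    return float(
        ((target_shape[0] - 1) / max(1, img.shape[0] - 1)
         + (target_shape[1] - 1) / max(1, img.shape[1] - 1)) / 2.0
    )


def match_to_reference(
    detections: list[MarkerObservation],
    reference_points_rc,
    init_scale: float = 1.0,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Pair detections with known AoI-frame marker positions.

    The initial guess is a pure scale map (sensor ground-pixel ratio); the
    assignment minimizing total squared distance under that guess is solved
    exactly (Hungarian algorithm).  Returns (source, target) pairs for
    :func:`fit_projective`; unmatched detections are dropped.
    """
    from scipy.optimize import linear_sum_assignment

    ref = np.asarray(reference_points_rc, dtype=float)
    det = np.array([m.center for m in detections], dtype=float)
    cost = ((det[:, None, :] - init_scale * ref[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return [(tuple(det[i]), tuple(ref[j])) for i, j in zip(rows, cols)]
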