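"""Curved-ribbon extraction along the leading edge.

The leading edge (LE) of the closing embryo is a curved path.  To profile
fluorescence along it, a smooth spline is fitted through operator-traced
control points and re-parameterized by arc length, a band of fixed physical
half-width is resampled on the (s, t) frame — s the arc position along the
midline, t the signed offset along the local normal — and the straightened
band is collapsed to a 1-D mean-intensity profile I(s).  Samples that fall
outside the image are masked, never zero-filled, so border segments are not
biased toward zero.

Orientation convention: s increases anterior -> posterior (T1 at s = 0); the
midline control points must be supplied in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage
from skimage.filters import threshold_otsu

from .imagedata import ImagePlane

__all__ = [
    "ArcCurve",
    "Ribbon",
    "LineProfile",
    "fit_midline",
    "straighten",
    "project_profile",
    "suggest_boundaries",
]


@dataclass
class ArcCurve:
    """Arc-length-parameterized smooth curve through the LE midline.

    Maps arc position ``s`` in micrometres, ``s in [0, total_length]``, to
    pixel coordinates ``(x, y)`` and to the local unit tangent/normal.  The
    normal is the tangent rotated +90 deg (counter-clockwise in (x, y) with
    y pointing down rows).
    """

    tck: tuple
    pixel_size: float
    total_length: float
    _u_dense: np.ndarray = field(repr=False)
    _s_dense: np.ndarray = field(repr=False)
    control_points: np.ndarray = field(repr=False, default=None)
    smoothing: float = 0.0

    def _u_of_s(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        return np.interp(s, self._s_dense, self._u_dense)

    def evaluate(self, s) -> np.ndarray:
        """Pixel coordinates (x, y) at arc positions ``s`` (μm); shape (n, 2)."""
        u = self._u_of_s(s)
        x, y = interpolate.splev(u, self.tck)
        return np.stack([np.atleast_1d(x), np.atleast_1d(y)], axis=-1)

    def tangent(self, s) -> np.ndarray:
        """Unit tangent vectors at arc positions ``s``; shape (n, 2)."""
        u = self._u_of_s(s)
        dx, dy = interpolate.splev(u, self.tck, der=1)
        t = np.stack([np.atleast_1d(dx), np.atleast_1d(dy)], axis=-1)
        norm = np.linalg.norm(t, axis=-1, keepdims=True)
        return t / norm

    def normal(self, s) -> np.ndarray:
        """Unit normals (tangent rotated +90 deg); shape (n, 2)."""
        t = self.tangent(s)
        return np.stack([-t[..., 1], t[..., 0]], axis=-1)

    def max_curvature(self) -> float:
        """Maximum absolute curvature along the curve, per micrometre."""
        theta = np.unwrap(
            np.arctan2(*self.tangent(self._s_dense)[:, ::-1].T)
        )
        ds = np.diff(self._s_dense)
        ok = ds > 0
        return float(np.max(np.abs(np.diff(theta)[ok] / ds[ok])))


def fit_midline(
    points,
    smoothing: float = 0.0,
    pixel_size: float = 1.0,
    n_dense: int | None = None,
) -> ArcCurve:
    """Fit a smooth arc-length-parameterized curve through midline points.

    Parameters
    ----------
    points
        Ordered (x, y) pixel coordinates, anterior first; >= 2 distinct
        points required.
    smoothing
        ``scipy.interpolate.splprep`` smoothing factor; 0 interpolates.
    pixel_size
        μm per pixel; ``total_length`` and all arc positions are in μm.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    # drop consecutive duplicates, which splprep rejects
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("need >= 2 distinct midline points")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    k = min(3, len(pts) - 1)
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=smoothing, k=k)
    if n_dense is None:
        n_dense = max(2000, 50 * len(pts))
    u = np.linspace(0.0, 1.0, n_dense)
    x, y = interpolate.splev(u, tck)
    seg = np.hypot(np.diff(x), np.diff(y)) * pixel_size
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    if not total > 0:
        raise ValueError("degenerate midline (zero length)")
    return ArcCurve(
        tck=tck,
        pixel_size=pixel_size,
        total_length=total,
        _u_dense=u,
        _s_dense=s,
        control_points=pts,
        smoothing=smoothing,
    )


@dataclass
class Ribbon:
    """Straightened band R(s, t) around the midline.

    ``values[i, j]`` is the bilinear image sample at arc position ``s[i]``
    and normal offset ``t[j]`` (both μm); ``mask`` is True where the sample
    landed inside the image.
    """

    values: np.ndarray
    mask: np.ndarray
    s: np.ndarray
    t: np.ndarray
    pixel_size: float
    channel: str = "signal"

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.s), len(self.t)):
            raise ValueError("grid shape does not match the s/t axes")


@dataclass
class LineProfile:
    """1-D mean-intensity profile I(s) along the LE."""

    s: np.ndarray
    intensity: np.ndarray
    embryo_id: str = ""
    channel: str = "signal"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.shape != self.intensity.shape:
            raise ValueError("s and intensity must have equal length")


def straighten(
    image: ImagePlane,
    curve: ArcCurve,
    half_width: float = 5.0,
    step: float | None = None,
) -> Ribbon:
    """Resample the image on the curved (s, t) frame of the midline.

    ``half_width`` (μm) is the normal extent on each side; ``step`` (μm)
    defaults to one pixel and is used for both axes.  Values are bilinear
    interpolations of the image; out-of-image samples are masked.  A warning
    is emitted when ``half_width * max_curvature >= 1``, where the normal fan
    self-intersects and near-edge rows fold back on themselves.
    """
    if not half_width > 0:
        raise ValueError("half_width must be > 0")
    if step is None:
        step = image.pixel_size
    if not step > 0:
        raise ValueError("step must be > 0")

    kappa = curve.max_curvature()
    if half_width * kappa >= 1.0:
        warnings.warn(
            f"half_width ({half_width:g} um) times max curvature "
            f"({kappa:.3g} /um) >= 1: the ribbon self-intersects",
            stacklevel=2,
        )

    n_s = int(np.floor(curve.total_length / step + 0.5)) + 1
    s = np.arange(n_s) * step
    n_t = int(np.floor(half_width / step + 1e-9))
    t = np.arange(-n_t, n_t + 1) * step

    centers = curve.evaluate(s)          # (n_s, 2) pixel coords
    normals = curve.normal(s)            # (n_s, 2)
    offsets_px = t / image.pixel_size
    # coords[i, j] = centers[i] + offsets_px[j] * normals[i]
    xs = centers[:, None, 0] + offsets_px[None, :] * normals[:, None, 0]
    ys = centers[:, None, 1] + offsets_px[None, :] * normals[:, None, 1]
    # snap coordinates a few ulp off the pixel grid (arc-length re-param
    # round-off) so axis-aligned midlines reproduce pixel values exactly
    for arr in (xs, ys):
        near = np.abs(arr - np.round(arr)) < 1e-6
        arr[near] = np.round(arr[near])

    h, w = image.shape
    mask = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if not mask.any():
        raise ValueError("curve (and ribbon) lies entirely outside the image")
    values = ndimage.map_coordinates(
        image.pixels, [ys, xs], order=1, mode="nearest"
    )
    values[~mask] = np.nan
    return Ribbon(
        values=values,
        mask=mask,
        s=s,
        t=t,
        pixel_size=image.pixel_size,
        channel=image.channel,
    )


def project_profile(ribbon: Ribbon, embryo_id: str = "") -> LineProfile:
    """Collapse a ribbon to I(s): the mean over unmasked t at each s.

    Positions where every sample is masked get NaN; a fully masked ribbon is
    an error.
    """
    counts = ribbon.mask.sum(axis=1)
    if not counts.any():
        raise ValueError("ribbon is fully masked")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        intensity = np.nanmean(np.where(ribbon.mask, ribbon.values, np.nan), axis=1)
    intensity[counts == 0] = np.nan
    return LineProfile(
        s=ribbon.s, intensity=intensity, embryo_id=embryo_id, channel=ribbon.channel
    )


def suggest_boundaries(
    marker_profile: LineProfile, expected_segments: int = 10
) -> np.ndarray:
    """Suggest segment-boundary arc positions from a marker (En) profile.

    The posterior compartment of every segment expresses the marker as a
    stripe; the anterior onset of each stripe is detected as an up-crossing
    of Otsu's threshold on the profile.  Suggestions are advisory: the
    operator's annotation file always wins, and a count differing from
    ``expected_segments`` is flagged with a warning, not an error.
    """
    if expected_segments < 1:
        raise ValueError("expected_segments must be >= 1")
    i = marker_profile.intensity
    finite = np.isfinite(i)
    if not finite.any() or np.ptp(i[finite]) == 0:
        raise ValueError("no stripes detected: marker profile is flat")
    thr = threshold_otsu(i[finite])
    above = np.zeros_like(i, dtype=bool)
    above[finite] = i[finite] >= thr
    up = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    positions = marker_profile.s[up]
    if above[0]:
        warnings.warn(
            "marker already high at s = 0: degenerate leading stripe",
            stacklevel=2,
        )
        positions = np.concatenate([[marker_profile.s[0]], positions])
    if len(positions) == 0:
        raise ValueError("no stripes detected: no threshold up-crossing")
    if len(positions) != expected_segments:
        warnings.warn(
            f"detected {len(positions)} stripe onsets, expected "
            f"{expected_segments}; review the annotation",
            stacklevel=2,
        )
    return positions
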