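"""Quantification core: background correction, segment splitting, length
normalization, d_LE / d_NS / AP-ratio computation and multi-embryo pooling.

The pipeline mirrors the pre-treatment order used for LE mRNA profiles:

1. estimate the background as the median intensity over an amnioserosa ROI;
2. subtract it from the LE profile and clamp negatives to 0 (expression
   below background is reported as 0, before any binning);
3. split the profile into segments — at annotated boundaries ("anatomical"
   mode, labels T1..A7) or into ten equal-length segments ("equal-10" mode);
4. length-normalize each segment into 10 equal bins ("cells"): bins 1-7 are
   the anterior compartment, bins 8-10 the posterior (En) compartment, the
   parasegmental boundary sitting between bins 7 and 8.

d_LE is the mean signal of a whole segment, d_NS the 10-bin vector, and the
AP ratio the anterior-compartment mean over the posterior-compartment mean.
Pooling supports the two conventions used for reporting: per-segment
statistics over embryos (AP axis, n = embryos) and per-bin statistics over
all segments of all embryos (compartmental axis, n = segments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .imagedata import SEGMENT_MEAN, ImagePlane, ResultTable
from .ribbon import LineProfile

__all__ = [
    "SegmentProfile",
    "CompartmentStats",
    "PooledProfile",
    "estimate_background",
    "correct_background",
    "split_segments",
    "normalize_segment",
    "compartment_stats",
    "pool",
    "quantify_profile",
]

N_BINS = 10
ANTERIOR_BINS = slice(0, 7)   # bins 1-7
POSTERIOR_BINS = slice(7, 10)  # bins 8-10
EQUAL10_LABELS = tuple(f"S{i}" for i in range(1, 11))


@dataclass
class SegmentProfile:
    """One segment of the LE profile, raw and length-normalized.

    ``d_ns`` always has 10 entries; its plain mean equals ``d_le`` because
    the bins are equal-length by construction (linear resampling to a
    multiple of 10 samples).
    """

    label: str
    s_start: float
    s_end: float
    s: np.ndarray | None = None
    intensity: np.ndarray | None = None
    d_le: float | None = None
    d_ns: np.ndarray | None = None

    @property
    def length(self) -> float:
        return self.s_end - self.s_start

    @property
    def normalized(self) -> bool:
        return self.d_ns is not None


@dataclass
class CompartmentStats:
    """Anterior/posterior compartment means and their ratio for one segment."""

    anterior_mean: float
    posterior_mean: float
    ap_ratio: float  # NaN sentinel when posterior_mean == 0

    @property
    def defined(self) -> bool:
        return math.isfinite(self.ap_ratio)


@dataclass
class PooledProfile:
    """Pooled mean / s.d. / s.e.m. table over embryos or segments.

    ``data`` columns: segment, bin, mean, sd, sem, n.  ``bin`` is 1..10 for
    compartmental rows and ``"segment_mean"`` for AP-axis rows.  s.d. and
    s.e.m. are NaN (emitted as empty fields) when n = 1.
    """

    axis: str
    data: pd.DataFrame

    def to_result_table(self, embryo_id: str = "pooled") -> ResultTable:
        df = self.data.copy()
        df.insert(0, "embryo_id", embryo_id)
        df = df.rename(columns={"mean": "value"})
        return ResultTable(df[["embryo_id", "segment", "bin", "value", "sd", "sem", "n"]])


def estimate_background(image: ImagePlane, roi: np.ndarray, min_pixels: int = 25) -> float:
    """Median intensity over a polygonal ROI (amnioserosa), boundary-inclusive.

    The median is robust to stray bright specks inside the ROI.  Raises if
    the ROI covers fewer than ``min_pixels`` image pixels.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[1] != 2 or len(roi) < 3:
        raise ValueError("roi must be an (n >= 3, 2) polygon")
    poly = shapely.Polygon(roi)
    if poly.area <= 0:
        raise ValueError("degenerate ROI polygon")
    h, w = image.shape
    x0 = max(int(np.floor(roi[:, 0].min())), 0)
    x1 = min(int(np.ceil(roi[:, 0].max())), w - 1)
    y0 = max(int(np.floor(roi[:, 1].min())), 0)
    y1 = min(int(np.ceil(roi[:, 1].max())), h - 1)
    if x1 < x0 or y1 < y0:
        raise ValueError("ROI lies outside the image")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    n_in = int(inside.sum())
    if n_in < min_pixels:
        raise ValueError(f"ROI too small: {n_in} pixels inside (need >= {min_pixels})")
    vals = image.pixels[ys.ravel()[inside], xs.ravel()[inside]]
    return float(np.median(vals))


def correct_background(profile: LineProfile, background: float) -> LineProfile:
    """Subtract a background level and clamp negatives to zero.

    Expression below background is reported as 0 rather than a negative
    intensity.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    corrected = np.maximum(profile.intensity - background, 0.0)
    return LineProfile(
        s=profile.s,
        intensity=corrected,
        embryo_id=profile.embryo_id,
        channel=profile.channel,
    )


def split_segments(
    profile: LineProfile,
    boundaries: Sequence[tuple[float, str]] | None = None,
    mode: str = "anatomical",
) -> list[SegmentProfile]:
    """Split a profile into half-open segments [s_i, s_{i+1}).

    In anatomical mode ``boundaries`` are (arc position μm, label) pairs; a
    boundary's label names the segment starting at it, the last boundary
    closes the final segment.  In equal-10 mode the full profile extent is
    split into ten equal-length segments S1..S10.  A sample exactly on an
    internal boundary belongs to the posterior-adjacent (right-hand)
    segment.
    """
    total = float(profile.s[-1])
    if mode == "equal-10":
        edges = np.linspace(0.0, total, N_BINS + 1)
        labels = list(EQUAL10_LABELS)
    elif mode == "anatomical":
        if boundaries is None or len(boundaries) < 2:
            raise ValueError("anatomical mode needs >= 2 boundaries")
        edges = np.array([s for s, _ in boundaries], dtype=float)
        labels = [lab for _, lab in boundaries][:-1]
        # the last profile sample may sit up to one step short of the curve's
        # total length; tolerate boundaries within that spacing
        spacing = float(profile.s[1] - profile.s[0]) if len(profile.s) > 1 else 0.0
        if edges[0] < -1e-9 or edges[-1] > total + spacing + 1e-9:
            raise ValueError("boundary outside [0, total_length]")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out: list[SegmentProfile] = []
    for i, lab in enumerate(labels):
        lo, hi = edges[i], edges[i + 1]
        if i == len(labels) - 1:
            sel = (profile.s >= lo) & (profile.s <= hi)  # close the last segment
        else:
            sel = (profile.s >= lo) & (profile.s < hi)
        out.append(
            SegmentProfile(
                label=lab,
                s_start=float(lo),
                s_end=float(hi),
                s=profile.s[sel],
                intensity=profile.intensity[sel],
            )
        )
    return out


def normalize_segment(
    segment: SegmentProfile, n_bins: int = N_BINS, min_per_bin: int = 4
) -> SegmentProfile:
    """Length-normalize a segment into ``n_bins`` equal bins and fill d_LE/d_NS.

    The raw samples are linearly resampled onto ``n_bins * k`` points placed
    at the centres of equal sub-intervals (k >= ``min_per_bin``), so each bin
    averages exactly k points and the plain mean of the bin means equals the
    segment mean by construction.
    """
    if segment.s is None or len(segment.s) == 0:
        raise ValueError(f"empty segment {segment.label!r}")
    good = np.isfinite(segment.intensity)
    if not good.any():
        raise ValueError(f"segment {segment.label!r} has no finite samples")
    s, i = segment.s[good], segment.intensity[good]
    k = max(min_per_bin, int(np.ceil(len(s) / n_bins)))
    m = n_bins * k
    target = segment.s_start + (np.arange(m) + 0.5) * (segment.length / m)
    resampled = np.interp(target, s, i)  # edge-clamped outside the sample range
    d_ns = resampled.reshape(n_bins, k).mean(axis=1)
    d_le = float(d_ns.mean())
    return SegmentProfile(
        label=segment.label,
        s_start=segment.s_start,
        s_end=segment.s_end,
        s=segment.s,
        intensity=segment.intensity,
        d_le=d_le,
        d_ns=d_ns,
    )


def compartment_stats(segment: SegmentProfile) -> CompartmentStats:
    """Anterior (bins 1-7) and posterior (bins 8-10) means and the AP ratio.

    The ratio is the NaN sentinel when the posterior mean is 0.
    """
    if segment.d_ns is None:
        raise ValueError("segment not normalized: d_NS missing")
    a = float(np.mean(segment.d_ns[ANTERIOR_BINS]))
    p = float(np.mean(segment.d_ns[POSTERIOR_BINS]))
    ratio = a / p if p > 0 else float("nan")
    return CompartmentStats(anterior_mean=a, posterior_mean=p, ap_ratio=ratio)


def _pool_stats(values: np.ndarray) -> tuple[float, float, float, int]:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, float("nan"), float("nan"), n
    sd = float(np.std(values, ddof=1))
    return mean, sd, sd / math.sqrt(n), n


def pool(
    profiles: Mapping[str, Sequence[SegmentProfile]], axis: str = "AP"
) -> PooledProfile:
    """Pool normalized segment profiles across embryos.

    ``axis="AP"``: per-segment d_LE mean / s.d. / s.e.m. over embryos
    (n = contributing embryos; segment labels must agree across embryos).
    ``axis="compartmental"``: per-bin d_NS statistics over every segment of
    every embryo (n = pooled segments).
    """
    if not profiles:
        raise ValueError("no embryos to pool")
    for eid, segs in profiles.items():
        for seg in segs:
            if not seg.normalized:
                raise ValueError(f"segment {seg.label!r} of {eid!r} not normalized")

    if axis == "AP":
        label_sets = [tuple(s.label for s in segs) for segs in profiles.values()]
        if len(set(label_sets)) != 1:
            raise ValueError("segment labels differ across embryos")
        rows = []
        for j, label in enumerate(label_sets[0]):
            values = np.array([list(segs)[j].d_le for segs in profiles.values()])
            mean, sd, sem, n = _pool_stats(values)
            rows.append((label, SEGMENT_MEAN, mean, sd, sem, n))
    elif axis == "compartmental":
        all_dns = np.array(
            [seg.d_ns for segs in profiles.values() for seg in segs]
        )
        rows = []
        for b in range(N_BINS):
            mean, sd, sem, n = _pool_stats(all_dns[:, b])
            rows.append(("all", b + 1, mean, sd, sem, n))
    else:
        raise ValueError(f"unknown axis {axis!r}; use 'AP' or 'compartmental'")

    df = pd.DataFrame(rows, columns=["segment", "bin", "mean", "sd", "sem", "n"])
    return PooledProfile(axis=axis, data=df)


def quantify_profile(
    profile: LineProfile,
    background: float,
    boundaries: Sequence[tuple[float, str]] | None = None,
    mode: str = "anatomical",
) -> list[SegmentProfile]:
    """Convenience pipeline: correct -> split -> normalize every segment."""
    corrected = correct_background(profile, background)
    return [
        normalize_segment(seg)
        for seg in split_segments(corrected, boundaries=boundaries, mode=mode)
    ]
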