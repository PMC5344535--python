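"""Synthetic test fixtures with analytically known ground truth.

Two generators drive the whole test bed:

* :func:`make_embryo` paints a fluorescence image pair (signal + En-like
  marker) around a curved leading-edge midline.  Each of the ``n_segments``
  equal-arc-length segments carries a constant anterior amplitude ``a_i``
  over its anterior 70% and a posterior amplitude ``p_i`` over the
  remaining 30% — the 7-cell / 3-cell compartment structure of an embryonic
  segment — on top of a flat background, with seeded additive Gaussian
  noise clipped at 0.  The marker channel carries stripes over exactly the
  posterior compartments, so stripe onsets have an analytic truth.  The
  returned annotations hold the exact midline and boundaries, and the
  ground-truth table lists the expected background-corrected value of every
  (segment, bin).

* :func:`make_closure_series` emits dorsal-closure frames in which the two
  canthi advance at programmed zipping rates (nm/s, optionally functions of
  the closure stage) and the opening is a sine arch whose apex height
  shrinks proportionally to the remaining opening length.  The closed-form
  meeting point for constant rates is ``r_A / (r_A + r_P)`` of the initial
  extent from the anterior.

Both generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dynamics import ClosureFrame
from .imagedata import AnnotationSet, ImagePlane, SEGMENT_MEAN
from .ribbon import ArcCurve, fit_midline

__all__ = ["EmbryoSpec", "ClosureSpec", "make_embryo", "make_closure_series"]

#: Anatomical labels of the 10 LE segments, anterior to posterior.
SEGMENT_LABELS_10 = ("T1", "T2", "T3", "A1", "A2", "A3", "A4", "A5", "A6", "A7")


@dataclass
class EmbryoSpec:
    """Parameters of a synthetic embryo image.

    Defaults emulate a 40x confocal field scaled down for desk-size tests:
    a 512 px square at 0.5 μm/px, a sinusoidal LE midline of 20 μm
    amplitude, 10 segments with a 2:1 anterior:posterior amplitude step on
    a background of 10 a.u., and additive Gaussian noise of 0.1 a.u.
    (5% of the anterior signal).
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.5
    midline_shape: str = "sinusoid"  # "straight" | "arc" | "sinusoid"
    midline_amplitude_um: float = 20.0
    midline_periods: float = 1.0
    margin_px: float = 40.0
    n_segments: int = 10
    anterior_amp: float | Sequence[float] = 2.0
    posterior_amp: float | Sequence[float] = 1.0
    anterior_fraction: float = 0.7
    band_half_width_um: float = 6.0
    background: float = 10.0
    noise_sigma: float = 0.1
    marker_amp: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.anterior_fraction < 1:
            raise ValueError("anterior_fraction must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.anterior_amp = np.broadcast_to(
            np.asarray(self.anterior_amp, float), (self.n_segments,)
        ).copy()
        self.posterior_amp = np.broadcast_to(
            np.asarray(self.posterior_amp, float), (self.n_segments,)
        ).copy()
        if (self.anterior_amp < 0).any() or (self.posterior_amp < 0).any():
            raise ValueError("amplitudes must be >= 0")

    @property
    def segment_labels(self) -> tuple[str, ...]:
        if self.n_segments == 10:
            return SEGMENT_LABELS_10
        return tuple(f"S{i}" for i in range(1, self.n_segments + 1))


def _midline_control_points(spec: EmbryoSpec) -> np.ndarray:
    h, w = spec.shape
    x = np.linspace(spec.margin_px, w - 1 - spec.margin_px, 33)
    yc = (h - 1) / 2.0
    amp_px = spec.midline_amplitude_um / spec.pixel_size
    if spec.midline_shape == "straight":
        y = np.full_like(x, yc)
    elif spec.midline_shape == "sinusoid":
        u = (x - x[0]) / (x[-1] - x[0])
        y = yc + amp_px * np.sin(2.0 * np.pi * spec.midline_periods * u)
    elif spec.midline_shape == "arc":
        if amp_px <= 0:
            y = np.full_like(x, yc)
        else:
            half = (x[-1] - x[0]) / 2.0
            xc = (x[0] + x[-1]) / 2.0
            radius = (half**2 + amp_px**2) / (2.0 * amp_px)
            y = yc + radius - amp_px - np.sqrt(radius**2 - (x - xc) ** 2)
    else:
        raise ValueError(f"unknown midline_shape {spec.midline_shape!r}")
    return np.stack([x, y], axis=1)


def _segment_amplitudes(spec: EmbryoSpec, s: np.ndarray, total_length: float):
    """Per-sample signal and marker amplitudes from the arc position."""
    seg_len = total_length / spec.n_segments
    idx = np.minimum((s / seg_len).astype(int), spec.n_segments - 1)
    frac = s / seg_len - idx
    posterior = frac >= spec.anterior_fraction
    amp = np.where(
        posterior, spec.posterior_amp[idx], spec.anterior_amp[idx]
    )
    marker = np.where(posterior, spec.marker_amp, 0.0)
    return amp, marker


def make_embryo(
    spec: EmbryoSpec,
) -> tuple[ImagePlane, ImagePlane, AnnotationSet, pd.DataFrame]:
    """Render a synthetic embryo: signal image, marker image, annotations
    and the ground-truth (segment, bin) table.

    The painted band follows the same arc-length-parameterized spline the
    quantification pipeline fits from the returned midline control points,
    so painted compartment boundaries and annotated boundaries agree.
    """
    rng = np.random.default_rng(spec.seed)
    control = _midline_control_points(spec)
    curve: ArcCurve = fit_midline(control, smoothing=0.0, pixel_size=spec.pixel_size)
    total = curve.total_length

    # dense curve samples for nearest-point painting
    ds = 0.4 * spec.pixel_size
    s_dense = np.arange(0.0, total + ds / 2, ds)
    pos = curve.evaluate(s_dense)  # pixel coords (n, 2)
    tree = cKDTree(pos)

    h, w = spec.shape
    pad = spec.band_half_width_um / spec.pixel_size + 2.0
    x0 = max(int(pos[:, 0].min() - pad), 0)
    x1 = min(int(np.ceil(pos[:, 0].max() + pad)), w - 1)
    y0 = max(int(pos[:, 1].min() - pad), 0)
    y1 = min(int(np.ceil(pos[:, 1].max() + pad)), h - 1)
    if y0 <= 0 or y1 >= h - 1:
        raise ValueError("LE band exits the image; enlarge the image or margins")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    dist_px, idx = tree.query(np.stack([xs.ravel(), ys.ravel()], axis=1))
    in_band = dist_px * spec.pixel_size <= spec.band_half_width_um
    amp, marker_amp = _segment_amplitudes(spec, s_dense[idx], total)

    signal = np.full(spec.shape, spec.background, dtype=float)
    marker = np.zeros(spec.shape, dtype=float)
    flat_sig = np.zeros(xs.size)
    flat_sig[in_band] = amp[in_band]
    flat_mark = np.zeros(xs.size)
    flat_mark[in_band] = marker_amp[in_band]
    signal[ys.ravel(), xs.ravel()] += flat_sig
    marker[ys.ravel(), xs.ravel()] += flat_mark

    if spec.noise_sigma > 0:
        signal = signal + rng.normal(0.0, spec.noise_sigma, spec.shape)
        marker = marker + rng.normal(0.0, spec.noise_sigma, spec.shape)
    signal = np.clip(signal, 0.0, None)
    marker = np.clip(marker, 0.0, None)

    seg_len = total / spec.n_segments
    labels = spec.segment_labels
    boundaries = [(i * seg_len, labels[i]) for i in range(spec.n_segments)]
    boundaries.append((total, "end"))
    roi = np.array([[2.0, 2.0], [62.0, 2.0], [62.0, 62.0], [2.0, 62.0]])
    ann = AnnotationSet(
        pixel_size=spec.pixel_size,
        midline=control,
        boundaries=boundaries,
        background_roi=roi,
        mode="anatomical",
    )

    rows = []
    for i, lab in enumerate(labels):
        a, p = spec.anterior_amp[i], spec.posterior_amp[i]
        for b in range(1, 11):
            rows.append((lab, b, a if b <= 7 else p))
        rows.append((lab, SEGMENT_MEAN, spec.anterior_fraction * a + (1 - spec.anterior_fraction) * p))
    truth = pd.DataFrame(rows, columns=["segment", "bin", "value"])

    return (
        ImagePlane(signal, spec.pixel_size, channel="signal"),
        ImagePlane(marker, spec.pixel_size, channel="marker"),
        ann,
        truth,
    )


RateSpec = float | Callable[[float], float]


@dataclass
class ClosureSpec:
    """Parameters of a synthetic closure time series.

    Rates are in nm/s and may be callables of the closure stage (%DC) for
    stage-dependent zipping.  Defaults close a 250 μm opening of 60 μm
    initial apex height symmetrically in about 2.9 h, sampled every 5 min —
    the scale of a live-imaged dorsal closure.
    """

    initial_extent: float = 250.0
    initial_height: float = 60.0
    anterior_rate: RateSpec = 12.0
    posterior_rate: RateSpec = 12.0
    frame_interval: float = 300.0
    n_frames: int = 40
    n_contour_points: int = 65
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.initial_extent > 0:
            raise ValueError("initial_extent must be > 0")
        if not self.initial_height > 0:
            raise ValueError("initial_height must be > 0")
        for r in (self.anterior_rate, self.posterior_rate):
            if not callable(r) and r < 0:
                raise ValueError("rates must be >= 0")


def _rate(r: RateSpec, pct: float) -> float:
    return float(r(pct)) if callable(r) else float(r)


def _arch_frame(t: float, x_a: float, x_p: float, h: float, n: int) -> ClosureFrame:
    u = np.linspace(0.0, 1.0, n)
    x = x_a + u * (x_p - x_a)
    y = 0.5 * h * np.sin(np.pi * u)
    top = np.stack([x, y], axis=1)
    bottom = np.stack([x, -y], axis=1)
    return ClosureFrame(
        time=t,
        contour_top=top,
        contour_bottom=bottom,
        canthus_anterior=np.array([x_a, 0.0]),
        canthus_posterior=np.array([x_p, 0.0]),
    )


def make_closure_series(spec: ClosureSpec) -> tuple[list[ClosureFrame], dict]:
    """Simulate closure frames and their ground truth.

    The apex height is ``h0 * L(t) / L0`` and the opening is a sine arch,
    so the height at fractional station q is ``h(t) * sin(pi q)`` and, for
    constant rates, shrinks linearly in time with slope
    ``h0 (r_A + r_P) / L0 * sin(pi q)``.  Ground truth carries L(t),
    %DC(t), the meeting-point fraction and (for constant rates) the
    expected closure speed per default station.
    """
    L0 = spec.initial_extent
    h0 = spec.initial_height
    x_a, x_p = 0.0, L0
    t = 0.0
    n_sub = 20  # integration substeps per frame, for stage-dependent rates
    frames: list[ClosureFrame] = []
    times, lengths = [], []
    meeting = None
    for _ in range(spec.n_frames):
        L = max(x_p - x_a, 0.0)
        frames.append(_arch_frame(t, x_a, x_p, h0 * L / L0, spec.n_contour_points))
        times.append(t)
        lengths.append(L)
        if L <= 0:
            break
        dt = spec.frame_interval / n_sub
        for _ in range(n_sub):
            L = x_p - x_a
            if L <= 0:
                break
            pct = 100.0 * (L0 - L) / L0
            ra = _rate(spec.anterior_rate, pct) * 1e-3
            rp = _rate(spec.posterior_rate, pct) * 1e-3
            total_rate = ra + rp
            if total_rate <= 0:
                continue
            step = min(total_rate * dt, L)
            x_a += step * ra / total_rate
            x_p -= step * rp / total_rate
            if x_p - x_a <= 1e-12 and meeting is None:
                meeting = x_a / L0
        t += spec.frame_interval

    lengths_arr = np.array(lengths)
    pct_dc = 100.0 * (L0 - lengths_arr) / L0
    truth: dict = {
        "times": np.array(times),
        "L": lengths_arr,
        "pct_dc": pct_dc,
        "meeting_point_fraction": meeting,
        "initial_extent": L0,
        "initial_height": h0,
    }
    if not callable(spec.anterior_rate) and not callable(spec.posterior_rate):
        q = np.array([(i + 1) / 8 for i in range(7)])
        total_rate = spec.anterior_rate + spec.posterior_rate  # nm/s
        truth["expected_speed_nm_s"] = h0 / L0 * total_rate * np.sin(np.pi * q)
        truth["positions"] = q
        if meeting is None and total_rate > 0:
            truth["meeting_point_fraction"] = spec.anterior_rate / total_rate
    return frames, truth
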