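"""Dorsal-closure kinematics from annotated leading-edge contours.

Each time point carries the two opposing LE contours (top and bottom flank)
between the anterior and posterior canthi.  From these the module measures:

* ``L`` — length of the open LE projected on the AP (x) axis, i.e. the
  canthus-to-canthus distance;
* ``seam`` — already-fused LE, ``reference_extent - L``, where
  ``reference_extent`` is the LE extent at closure onset;
* ``%DC`` — closure stage, ``100 * seam / reference_extent``; by this
  convention 0 at onset and 100 at full closure, and it grows monotonically
  for a monotonically closing embryo;
* ``H(q)`` — dorsal opening height, the vertical distance between the two
  contours at fractional stations q of L (defaults: q = 1/8 .. 7/8, the 8
  subdomains corresponding approximately to the 8 segments of the opening);
* closure speeds — least-squares slopes of H(t) per station within %DC
  stage bins (default thirds, quartile preset available), positive =
  closing, in nm/s;
* final closure point, zipping-zone lengths and En-matched closure-delay
  distances.

All coordinates here are in micrometres; the annotation reader converts
from pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imagedata import AnnotationSet

__all__ = [
    "ClosureFrame",
    "ClosureMetrics",
    "frames_from_annotations",
    "frame_metrics",
    "closure_speeds",
    "final_closure_point",
    "zipping_zone_length",
    "closure_delay",
    "STAGE_THIRDS",
    "STAGE_QUARTILES",
]

#: Stage-bin edges on %DC: early/mid/late thirds.
STAGE_THIRDS = (0.0, 100.0 / 3.0, 200.0 / 3.0, 100.0)
#: Quartile preset: early / mid-early / mid-late / late.
STAGE_QUARTILES = (0.0, 25.0, 50.0, 75.0, 100.0)

#: Default H stations: 8 subdomains -> 7 interior eighths of L.
DEFAULT_POSITIONS = tuple((i + 1) / 8 for i in range(7))

CANTHUS_TOL = 0.5  # μm; contours must meet the canthi within this


@dataclass
class ClosureFrame:
    """One annotated time point of a closing dorsal opening (μm units)."""

    time: float
    contour_top: np.ndarray
    contour_bottom: np.ndarray
    canthus_anterior: np.ndarray
    canthus_posterior: np.ndarray
    zipping_marks: dict = field(default_factory=dict)  # side -> (contact, stable_junction)
    delay_marks: dict = field(default_factory=dict)    # segment -> (point, matched point)

    def __post_init__(self) -> None:
        self.contour_top = np.asarray(self.contour_top, dtype=float)
        self.contour_bottom = np.asarray(self.contour_bottom, dtype=float)
        self.canthus_anterior = np.asarray(self.canthus_anterior, dtype=float)
        self.canthus_posterior = np.asarray(self.canthus_posterior, dtype=float)
        for name in ("contour_top", "contour_bottom"):
            c = getattr(self, name)
            if c.ndim != 2 or c.shape[1] != 2 or len(c) < 2:
                raise ValueError(f"{name} must be an (n >= 2, 2) point list")
            ends = np.array([c[0], c[-1]])
            canthi = np.array([self.canthus_anterior, self.canthus_posterior])
            d = np.linalg.norm(ends - canthi, axis=1)
            if np.any(d > CANTHUS_TOL):
                raise ValueError(
                    f"{name} endpoints are {d.max():.2f} um from the canthi "
                    f"(> {CANTHUS_TOL} um tolerance)"
                )


@dataclass
class ClosureMetrics:
    """Per-frame closure metrics (μm; see module docstring)."""

    time: float
    L: float
    seam: float
    pct_dc: float
    positions: np.ndarray
    H: np.ndarray
    subdomain_edges: np.ndarray


def frames_from_annotations(ann: AnnotationSet) -> list[ClosureFrame]:
    """Build :class:`ClosureFrame` objects from an annotation dynamics block.

    Pixel coordinates in the file are converted to μm with the annotation's
    pixel size; frame times must be strictly increasing.
    """
    if not ann.dynamics:
        raise ValueError("annotation file has no dynamics block")
    ps = ann.pixel_size
    frames: list[ClosureFrame] = []
    for raw in ann.dynamics:
        zip_marks = {
            side: (np.asarray(m["contact"], float) * ps,
                   np.asarray(m["stable_junction"], float) * ps)
            for side, m in raw.get("zipping", {}).items()
        }
        delay_marks = {
            seg: (np.asarray(m["point"], float) * ps,
                  np.asarray(m["matched_point"], float) * ps)
            for seg, m in raw.get("delays", {}).items()
        }
        frames.append(
            ClosureFrame(
                time=float(raw["time_s"]),
                contour_top=np.asarray(raw["contour_top"], float) * ps,
                contour_bottom=np.asarray(raw["contour_bottom"], float) * ps,
                canthus_anterior=np.asarray(raw["canthus_anterior"], float) * ps,
                canthus_posterior=np.asarray(raw["canthus_posterior"], float) * ps,
                zipping_marks=zip_marks,
                delay_marks=delay_marks,
            )
        )
    times = [f.time for f in frames]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("frame times must be strictly increasing")
    return frames


def _contour_height(contour: np.ndarray, x: np.ndarray) -> np.ndarray:
    order = np.argsort(contour[:, 0])
    return np.interp(x, contour[order, 0], contour[order, 1])


def frame_metrics(
    frame: ClosureFrame,
    reference_extent: float,
    positions=DEFAULT_POSITIONS,
) -> ClosureMetrics:
    """Measure L, seam, %DC and the height profile H(q) for one frame.

    ``reference_extent`` is the LE extent at DC onset (frame 0's L); contours
    are treated as piecewise-linear and H is the vertical separation at the
    x-station ``x_anterior + q * L``.
    """
    if not reference_extent > 0:
        raise ValueError("reference_extent must be > 0")
    x_a = frame.canthus_anterior[0]
    x_p = frame.canthus_posterior[0]
    L = abs(x_p - x_a)
    if L > reference_extent + CANTHUS_TOL:
        raise ValueError(
            f"frame L ({L:.2f} um) exceeds the reference extent "
            f"({reference_extent:.2f} um): inconsistent annotation"
        )
    seam = max(reference_extent - L, 0.0)
    pct = 100.0 * seam / reference_extent
    q = np.asarray(positions, dtype=float)
    if L == 0:
        h = np.zeros_like(q)
    else:
        x = min(x_a, x_p) + q * L
        h = np.abs(
            _contour_height(frame.contour_top, x)
            - _contour_height(frame.contour_bottom, x)
        )
    edges = min(x_a, x_p) + np.linspace(0.0, 1.0, 9) * L
    return ClosureMetrics(
        time=frame.time,
        L=L,
        seam=seam,
        pct_dc=pct,
        positions=q,
        H=h,
        subdomain_edges=edges,
    )


def closure_speeds(
    frames: list[ClosureFrame],
    reference_extent: float | None = None,
    positions=DEFAULT_POSITIONS,
    stage_edges=STAGE_THIRDS,
) -> pd.DataFrame:
    """Stage-binned closure speeds (nm/s) per fractional position.

    The speed at a position within a %DC stage bin is minus the ordinary
    least-squares slope of H(t) over the frames falling in that bin
    (half-open bins; a frame sitting exactly on an edge joins the later
    bin); positive values mean the opening is closing.  Bins with fewer
    than two frames are reported empty (NaN).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if reference_extent is None:
        m0 = frame_metrics(frames[0], reference_extent=1.0, positions=positions)
        reference_extent = m0.L if m0.L > 0 else None
        if reference_extent is None:
            raise ValueError("cannot infer reference extent from a closed first frame")
    metrics = [frame_metrics(f, reference_extent, positions) for f in frames]
    pct = np.array([m.pct_dc for m in metrics])
    t = np.array([m.time for m in metrics])
    H = np.array([m.H for m in metrics])  # (n_frames, n_positions)
    edges = np.asarray(stage_edges, dtype=float)
    # half-open [e_i, e_{i+1}); a frame at 100% joins the last bin
    bin_idx = np.clip(np.searchsorted(edges, pct, side="right") - 1, 0, len(edges) - 2)
    rows = []
    q = np.asarray(positions, dtype=float)
    for b in range(len(edges) - 1):
        sel = bin_idx == b
        for j, pos in enumerate(q):
            if sel.sum() >= 2:
                slope = np.polyfit(t[sel], H[sel, j], 1)[0]
                speed = -slope * 1e3  # μm/s -> nm/s, positive = closing
            else:
                speed = np.nan
            rows.append(
                {
                    "stage_bin": f"[{edges[b]:g},{edges[b + 1]:g})",
                    "pct_dc_lo": edges[b],
                    "pct_dc_hi": edges[b + 1],
                    "position": pos,
                    "speed_nm_s": speed,
                    "n_frames": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def final_closure_point(
    frames: list[ClosureFrame],
    eps: float = 1.0,
    n_stations: int = 201,
) -> float | None:
    """Fraction of the onset-frame L where the opening closes last.

    Fixed x-stations spanning the onset opening are tracked through time;
    a station is open while its H exceeds ``eps`` (1 μm default, sub-pixel
    at the relevant magnifications) and closed once it leaves the open
    canthus-to-canthus interval.  The result is the mean open-station
    position at the last frame with any open station, as a fraction of the
    onset L (0 = anterior).  Returns ``None`` when the series never closes.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    f0 = frames[0]
    x_a0 = min(f0.canthus_anterior[0], f0.canthus_posterior[0])
    x_p0 = max(f0.canthus_anterior[0], f0.canthus_posterior[0])
    L0 = x_p0 - x_a0
    if not L0 > 0:
        raise ValueError("onset frame already closed")
    fractions = np.linspace(0.0, 1.0, n_stations)
    stations = x_a0 + fractions * L0

    def open_mask(frame: ClosureFrame) -> np.ndarray:
        lo = min(frame.canthus_anterior[0], frame.canthus_posterior[0])
        hi = max(frame.canthus_anterior[0], frame.canthus_posterior[0])
        inside = (stations >= lo) & (stations <= hi)
        h = np.zeros_like(stations)
        if hi > lo:
            h[inside] = np.abs(
                _contour_height(frame.contour_top, stations[inside])
                - _contour_height(frame.contour_bottom, stations[inside])
            )
        return inside & (h > eps)

    masks = [open_mask(f) for f in frames]
    if masks[-1].any():
        return None  # not closed
    last_open = None
    for m in reversed(masks):
        if m.any():
            last_open = m
            break
    if last_open is None:
        raise ValueError("series starts closed (H <= eps everywhere at onset)")
    return float(fractions[last_open].mean())


def zipping_zone_length(frame: ClosureFrame, side: str) -> float:
    """Zipping-zone length on one side (μm): distance from the point where
    the opposing LEs come into close contact to the first stable junction."""
    if side not in ("anterior", "posterior"):
        raise ValueError("side must be 'anterior' or 'posterior'")
    if side not in frame.zipping_marks:
        raise ValueError(f"no zipping marks annotated for the {side} side")
    contact, stable = frame.zipping_marks[side]
    return float(np.hypot(*(np.asarray(stable) - np.asarray(contact))))


def closure_delay(frame: ClosureFrame, segment: str) -> float:
    """Closure-delay distance (μm) between matched En compartments of one
    segment across the two flanks, measured when the opposing end of the
    embryo has just closed."""
    if segment not in frame.delay_marks:
        raise ValueError(f"no matched delay marks annotated for segment {segment!r}")
    a, b = frame.delay_marks[segment]
    return float(np.hypot(*(np.asarray(b) - np.asarray(a))))
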