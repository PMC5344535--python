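"""Image, annotation and result-table I/O.

All spatial quantities follow one convention: pixel coordinates are 0-based
with ``x`` = column and ``y`` = row; arc lengths and physical distances are in
micrometres, converted through the annotation file's ``pixel_size_um``.
Microscope TIFF metadata is deliberately ignored — the annotation file is the
single authority for the pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImagePlane",
    "AnnotationSet",
    "ResultTable",
    "read_image",
    "read_annotations",
    "write_annotations",
    "write_results",
    "read_results",
]

#: Column order of the results CSV dialect.
RESULT_COLUMNS = ("embryo_id", "segment", "bin", "value", "sd", "sem", "n")

#: Sentinel value for the ``bin`` column of per-segment (d_LE) rows.
SEGMENT_MEAN = "segment_mean"


@dataclass
class ImagePlane:
    """A single 2-D fluorescence intensity plane.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities in arbitrary fluorescence
        units; typically a maximum-intensity projection of a confocal stack.
    pixel_size
        Isotropic pixel size in micrometres per pixel.
    channel
        Free-form channel label, e.g. ``"mRNA"`` or ``"En"``.
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str = "signal"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("image must have at least 2 rows and 2 columns")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AnnotationSet:
    """Operator-supplied annotations for one embryo image.

    The midline traces the leading edge anterior -> posterior (T1 first), in
    pixel coordinates.  Segment boundaries are arc-length positions along
    that midline, in micrometres from its anterior end.  ``background_roi``
    is a polygon over the amnioserosa used for background estimation.  In
    ``"equal-10"`` mode boundaries may be omitted: the profile is split into
    ten equal-length segments downstream.
    """

    pixel_size: float
    midline: np.ndarray
    boundaries: list[tuple[float, str]] = field(default_factory=list)
    background_roi: np.ndarray | None = None
    mode: str = "anatomical"
    dynamics: list[dict] | None = None

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.mode not in ("anatomical", "equal-10"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.midline = np.asarray(self.midline, dtype=float)
        if self.midline.ndim != 2 or self.midline.shape[1] != 2 or len(self.midline) < 2:
            raise ValueError("midline needs >= 2 (x, y) control points")
        self.boundaries = [(float(s), str(lab)) for s, lab in self.boundaries]
        positions = [s for s, _ in self.boundaries]
        if any(b - a <= 0 for a, b in zip(positions, positions[1:])):
            raise ValueError("non-increasing boundaries")
        labels = [lab for _, lab in self.boundaries]
        if len(set(labels)) != len(labels):
            raise ValueError("boundary labels must be unique")
        if self.mode == "anatomical" and len(self.boundaries) < 2 and self.dynamics is None:
            # Anatomical splitting needs at least one interval; tolerated when
            # the file only carries a dynamics block.
            if self.boundaries:
                raise ValueError("anatomical mode needs >= 2 boundaries")
        if self.background_roi is not None:
            self.background_roi = np.asarray(self.background_roi, dtype=float)
            if self.background_roi.ndim != 2 or self.background_roi.shape[1] != 2:
                raise ValueError("background_roi must be an (n, 2) polygon")
            if abs(_polygon_area(self.background_roi)) <= 0:
                raise ValueError("degenerate background ROI (area = 0)")

    @property
    def boundary_positions(self) -> np.ndarray:
        return np.array([s for s, _ in self.boundaries], dtype=float)

    @property
    def boundary_labels(self) -> list[str]:
        return [lab for _, lab in self.boundaries]


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def read_image(
    path: str | Path,
    channel: str = "signal",
    projection: str = "max",
    pixel_size: float = 1.0,
) -> ImagePlane:
    """Read a single- or multi-page TIFF into an :class:`ImagePlane`.

    Z-stacks are reduced by per-pixel maximum-intensity projection when
    ``projection="max"``; ``projection="none"`` requires a single plane.
    ``pixel_size`` must come from the annotation file — TIFF metadata is not
    consulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = np.asarray(tifffile.imread(path), dtype=float)
    if projection == "max":
        if data.ndim == 3:
            data = data.max(axis=0)
    elif projection == "none":
        if data.ndim == 3 and data.shape[0] == 1:
            data = data[0]
    else:
        raise ValueError(f"unknown projection {projection!r}; use 'max' or 'none'")
    if data.ndim != 2:
        raise ValueError(f"expected a 2-D result, got shape {data.shape}")
    return ImagePlane(pixels=data, pixel_size=pixel_size, channel=channel)


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read the JSON annotation dialect (see module docstring of this package).

    Boundary positions are stored in micrometres in the file and validated
    against the :class:`AnnotationSet` invariants on load.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    try:
        pixel_size = float(raw["pixel_size_um"])
        midline = raw["midline"]
    except KeyError as exc:  # pragma: no cover - message detail
        raise ValueError(f"annotation file missing required key: {exc}") from exc
    boundaries = [(float(b["s_um"]), str(b["label"])) for b in raw.get("boundaries", [])]
    roi = raw.get("background_roi")
    return AnnotationSet(
        pixel_size=pixel_size,
        midline=midline,
        boundaries=boundaries,
        background_roi=None if roi is None else np.asarray(roi, dtype=float),
        mode=raw.get("mode", "anatomical"),
        dynamics=raw.get("dynamics"),
    )


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` back to the JSON dialect."""
    payload: dict = {
        "pixel_size_um": ann.pixel_size,
        "mode": ann.mode,
        "midline": ann.midline.tolist(),
        "boundaries": [{"s_um": s, "label": lab} for s, lab in ann.boundaries],
    }
    if ann.background_roi is not None:
        payload["background_roi"] = ann.background_roi.tolist()
    if ann.dynamics is not None:
        payload["dynamics"] = ann.dynamics
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


@dataclass
class ResultTable:
    """Quantification results keyed by (embryo, segment, bin).

    ``bin`` is 1..10 for per-cell (d_NS) rows or :data:`SEGMENT_MEAN` for
    per-segment (d_LE) rows.  Dispersion columns are empty (NaN) when n = 1,
    never 0.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in RESULT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")
        df = df.loc[:, list(RESULT_COLUMNS)].reset_index(drop=True)
        if len(df):
            if (df["value"] < 0).any():
                raise ValueError("result values must be >= 0 (post-clamp)")
            has_sd = df["sd"].notna()
            if (df.loc[has_sd, "n"] < 1).any():
                raise ValueError("n must be >= 1 wherever dispersion is reported")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResultTable):
            return NotImplemented
        return self.data.equals(other.data)


def write_results(table: ResultTable, path: str | Path) -> None:
    """Write a :class:`ResultTable` as CSV with the fixed column order.

    Floats are emitted at 17 significant digits so that a read-back
    round-trips bit-exactly; empty dispersion fields stay empty.
    """
    table.data.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> ResultTable:
    """Read a results CSV written by :func:`write_results`."""
    df = pd.read_csv(
        path,
        dtype={"embryo_id": str, "segment": str, "bin": str},
        keep_default_na=True,
        float_precision="round_trip",
    )
    if df.empty and list(df.columns) == list(RESULT_COLUMNS):
        df = df.astype({"value": float, "sd": float, "sem": float, "n": float})
    if len(df):
        df["n"] = df["n"].astype(int)
    return ResultTable(df)


def make_result_rows(
    embryo_id: str,
    segment: str,
    values: Sequence[float],
    sds: Sequence[float] | None = None,
    sems: Sequence[float] | None = None,
    ns: Sequence[int] | None = None,
    bins: Sequence[object] | None = None,
) -> pd.DataFrame:
    """Helper building result-table rows with consistent columns."""
    k = len(values)
    if bins is None:
        bins = list(range(1, k + 1))
    return pd.DataFrame(
        {
            "embryo_id": [embryo_id] * k,
            "segment": [segment] * k,
            "bin": list(bins),
            "value": list(values),
            "sd": list(sds) if sds is not None else [np.nan] * k,
            "sem": list(sems) if sems is not None else [np.nan] * k,
            "n": list(ns) if ns is not None else [1] * k,
        }
    )
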