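"""Cine loops, polygon ROIs, and time–intensity curve (TIC) extraction.

A contrast-enhanced ultrasound acquisition is represented as a
:class:`CineLoop`: a T x H x W stack of grayscale frames on the 8-bit video
scale with per-frame timestamps and (optionally) the time of the
microbubble destruction pulse.  Regions of interest are labelled polygons
in continuous image coordinates; the mean intensity inside an ROI per frame
is the time–intensity curve from which enhancement statistics are computed.

Coordinate convention (fixed and documented): 0-based, row-major pixels;
pixel (row i, col j) spans the square [j, j+1) x [i, i+1) so its center is
(j + 0.5, i + 0.5).  A pixel belongs to an ROI iff its center is inside the
polygon under the even–odd rule; centers exactly on an edge are resolved by
the half-open crossing convention implemented in :func:`rasterize_roi`,
which is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    ConfigurationError,
    EmptyRoiError,
    InvalidParameterError,
    InvalidWindowError,
)

__all__ = [
    "CineLoop",
    "RoiPolygon",
    "TimeIntensityCurve",
    "rasterize_roi",
    "extract_tic",
    "smooth_tic",
    "estimate_background",
    "save_cine",
    "load_cine",
    "save_rois",
    "load_rois",
    "save_tics",
    "load_tics",
]

ROI_LABELS = ("lumen", "adventitia", "plaque", "background")


@dataclass
class CineLoop:
    """A timed stack of grayscale frames.

    ``frames`` has shape (T, H, W) with intensities in [0, 255];
    ``timestamps`` is strictly increasing, one entry per frame;
    ``destruction_time`` is the destruction-pulse time in seconds, or None
    when the acquisition carries no pulse marker.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    destruction_time: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ConfigurationError("frames must be a T x H x W array")
        T = self.frames.shape[0]
        if T < 1:
            raise ConfigurationError("cine loop needs at least one frame")
        if self.timestamps.shape != (T,):
            raise ConfigurationError("timestamps must match frame count")
        if T > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise ConfigurationError("intensities must lie in [0, 255]")
        if self.destruction_time is not None:
            lo, hi = self.timestamps[0], self.timestamps[-1]
            if not (lo <= self.destruction_time <= hi):
                raise ConfigurationError(
                    "destruction_time outside the acquisition interval"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class RoiPolygon:
    """A labelled simple polygon in continuous (x, y) image coordinates."""

    label: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", verts)
        if self.label not in ROI_LABELS:
            raise InvalidParameterError(
                f"label must be one of {ROI_LABELS}, got {self.label!r}"
            )
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise InvalidParameterError("polygon needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(verts)):
            raise InvalidParameterError("polygon vertices must be finite")
        if not _ShapelyPolygon(verts).is_valid:
            raise InvalidParameterError(
                f"ROI {self.label!r} polygon is not simple"
            )


@dataclass
class TimeIntensityCurve:
    """Mean video-intensity of one ROI per frame."""

    times: np.ndarray
    intensities: np.ndarray
    roi_label: str
    n_pixels: int
    smoothing: str = "none"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise InvalidParameterError("times/intensities must be equal-length 1-D")
        if self.n_pixels < 1:
            raise InvalidParameterError("n_pixels must be >= 1")
        if self.intensities.size and (
            self.intensities.min() < 0 or self.intensities.max() > 255
        ):
            raise InvalidParameterError("TIC intensities must lie in [0, 255]")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "mean_intensity": self.intensities,
                "roi_label": self.roi_label,
                "n_pixels": self.n_pixels,
                "smoothing": self.smoothing,
            }
        )


def _pixel_centers(image_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = image_shape
    px = np.arange(w, dtype=float)[None, :] + 0.5  # x = j + 0.5
    py = np.arange(h, dtype=float)[:, None] + 0.5  # y = i + 0.5
    return np.broadcast_to(px, (h, w)), np.broadcast_to(py, (h, w))


def _even_odd_inside(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even–odd (crossing-number) point-in-polygon test, vectorized.

    An edge from (x1, y1) to (x2, y2) is counted when the test point's y lies
    in the half-open span [min, max) of the edge's y's — specifically when
    ``(y1 <= y) != (y2 <= y)`` — and the point is strictly left of the
    edge/ray intersection.  This half-open rule makes boundary points resolve
    deterministically and shared edges between adjacent polygons partition
    cleanly.
    """
    inside = np.zeros(px.shape, dtype=bool)
    x1 = verts[:, 0]
    y1 = verts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    for k in range(verts.shape[0]):
        crosses = (y1[k] <= py) != (y2[k] <= py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1[k] + (py - y1[k]) * (x2[k] - x1[k]) / (y2[k] - y1[k])
        inside ^= crosses & (px < x_int)
    return inside


def rasterize_roi(roi: RoiPolygon, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon ROI to a boolean H x W mask.

    Pixel (i, j) is in the mask iff its center (j + 0.5, i + 0.5) is inside
    the polygon under the even–odd rule (see :func:`_even_odd_inside` for the
    edge convention).  Raises :class:`EmptyRoiError` naming the label when no
    pixel center falls inside.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h < 1 or w < 1:
        raise InvalidParameterError("image_shape must be positive")
    px, py = _pixel_centers((h, w))
    mask = _even_odd_inside(px, py, roi.vertices)
    if not mask.any():
        raise EmptyRoiError(roi.label)
    return mask


def extract_tic(cine: CineLoop, roi: RoiPolygon) -> TimeIntensityCurve:
    """Mean video-intensity inside ``roi`` for each frame of ``cine``."""
    mask = rasterize_roi(roi, cine.image_shape)
    flat = cine.frames.reshape(cine.n_frames, -1)
    means = flat[:, mask.ravel()].mean(axis=1)
    return TimeIntensityCurve(
        times=cine.timestamps.copy(),
        intensities=means,
        roi_label=roi.label,
        n_pixels=int(mask.sum()),
        smoothing="none",
    )


def smooth_tic(tic: TimeIntensityCurve, window: int) -> TimeIntensityCurve:
    """Centered moving average with edge truncation.

    ``window`` must be odd and within [1, len(tic)].  At the boundaries the
    window is truncated to the frames that exist, so the output length equals
    the input length; ``window=1`` is the identity.  The smoothing choice is
    recorded in the returned curve's metadata.
    """
    n = len(tic)
    if window % 2 == 0 or window < 1 or window > n:
        raise InvalidParameterError(
            f"window must be odd and in [1, {n}], got {window}"
        )
    if window == 1:
        return replace(tic, smoothing="none")
    kernel = np.ones(window)
    sums = np.convolve(tic.intensities, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return replace(
        tic,
        intensities=sums / counts,
        smoothing=f"moving_average({window})",
    )


def estimate_background(
    tic: TimeIntensityCurve,
    reference_window: tuple[float, float] | None = None,
    destruction_time: float | None = None,
) -> float:
    """Background video-intensity of a TIC.

    With an explicit ``reference_window`` (start, end), returns the mean
    intensity over frames whose timestamp falls in the half-open interval
    [start, end).  Otherwise the default reference is every frame strictly
    before ``destruction_time``; when no destruction time is known the onset
    of enhancement is detected as the first frame exceeding the curve minimum
    by 10% of the curve's dynamic range, and pre-onset frames are used (the
    first frame alone when enhancement starts immediately).

    Raises :class:`InvalidWindowError` when the window contains no frames.
    """
    t = tic.times
    y = tic.intensities
    if reference_window is not None:
        start, end = reference_window
        sel = (t >= start) & (t < end)
        if not sel.any():
            raise InvalidWindowError(
                f"reference window [{start}, {end}) contains no frames"
            )
        return float(y[sel].mean())
    if destruction_time is not None:
        sel = t < destruction_time
        if not sel.any():
            raise InvalidWindowError(
                "no frames precede the destruction pulse; pass an explicit window"
            )
        return float(y[sel].mean())
    # no timing metadata: detect first-enhancement onset
    lo, hi = y.min(), y.max()
    if hi == lo:
        return float(y.mean())
    onset = int(np.argmax(y > lo + 0.1 * (hi - lo)))
    if onset == 0:
        return float(y[0])
    return float(y[:onset].mean())


# ---------------------------------------------------------------------------
# I/O: multi-frame grayscale TIFF + JSON sidecar, ROI JSON, TIC CSV
# ---------------------------------------------------------------------------

def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def save_cine(cine: CineLoop, tiff_path: str | Path) -> Path:
    """Write a cine loop as multi-frame float32 TIFF plus a JSON sidecar.

    The sidecar holds timestamps and the destruction time; returns the
    sidecar path.
    """
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, cine.frames.astype(np.float32))
    meta = {
        "timestamps": cine.timestamps.tolist(),
        "destruction_time": cine.destruction_time,
    }
    sidecar = _sidecar_path(tiff_path)
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_cine(tiff_path: str | Path) -> CineLoop:
    tiff_path = Path(tiff_path)
    frames = np.asarray(tifffile.imread(tiff_path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar_path(tiff_path).read_text())
    return CineLoop(
        frames=frames,
        timestamps=np.asarray(meta["timestamps"], dtype=float),
        destruction_time=meta.get("destruction_time"),
    )


def save_rois(rois: list[RoiPolygon], path: str | Path) -> None:
    payload = [
        {"label": r.label, "vertices": r.vertices.tolist()} for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_rois(path: str | Path) -> list[RoiPolygon]:
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, dict):  # allow {"rois": [...]} wrapping
        payload = payload["rois"]
    return [RoiPolygon(p["label"], np.asarray(p["vertices"])) for p in payload]


def save_tics(tics: list[TimeIntensityCurve], path: str | Path) -> None:
    pd.concat([t.to_frame() for t in tics], ignore_index=True).to_csv(
        path, index=False
    )


def load_tics(path: str | Path) -> list[TimeIntensityCurve]:
    df = pd.read_csv(path)
    out = []
    for (label, smoothing, n_pix), grp in df.groupby(
        ["roi_label", "smoothing", "n_pixels"], sort=False
    ):
        out.append(
            TimeIntensityCurve(
                times=grp["time_s"].to_numpy(),
                intensities=grp["mean_intensity"].to_numpy(),
                roi_label=str(label),
                n_pixels=int(n_pix),
                smoothing=str(smoothing),
            )
        )
    return out
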