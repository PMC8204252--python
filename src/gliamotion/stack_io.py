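"""Reading and writing of time-lapse stacks, calibration metadata and result tables.

Conventions used throughout the package: pixel indices are 0-based,
``(row, col) == (y, x)``, and masks are half-open grids of pixel centers.
Axis order of raw stacks is ``T, Z, Y, X`` (time, depth, row, column).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile


class StackIOError(RuntimeError):
    """Raised for unreadable files, ambiguous axes or missing calibration."""


@dataclass(frozen=True)
class Calibration:
    """Acquisition geometry of a two-photon recording.

    Parameters
    ----------
    pixel_size_um
        Lateral sampling, µm per pixel (x and y assumed equal).
    z_step_um
        Axial step between consecutive planes, µm.
    frame_interval_s
        Seconds between the starts of consecutive stacks.
    field_um
        Optional ``(x_extent, y_extent)`` of the field of view in µm; when
        given it must agree with ``pixel_size_um × pixel count`` within 1 %.
    """

    pixel_size_um: float
    z_step_um: float = 1.0
    frame_interval_s: float = 60.0
    field_um: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "z_step_um", "frame_interval_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.field_um is not None:
            fx, fy = self.field_um
            if fx <= 0 or fy <= 0:
                raise ValueError("field_um extents must be strictly positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def check_field(self, shape_yx: Tuple[int, int]) -> None:
        """Verify that field_um matches the pixel grid within 1 %."""
        if self.field_um is None:
            return
        fx, fy = self.field_um
        ny, nx = shape_yx
        for extent, n, axis in ((fx, nx, "x"), (fy, ny, "y")):
            expected = self.pixel_size_um * n
            if abs(extent - expected) > 0.01 * expected:
                raise ValueError(
                    f"field_um[{axis}]={extent} inconsistent with "
                    f"{n} px × {self.pixel_size_um} µm/px = {expected:.3f} µm"
                )


@dataclass
class TimeLapseStack:
    """Raw 4D intensity data (T × Z × Y × X) plus calibration.

    ``plane_replicates`` records how many consecutively stored images were
    acquired per nominal z-plane (averaged by :func:`average_plane_replicates`).
    """

    data: np.ndarray
    calibration: Calibration
    plane_replicates: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be T×Z×Y×X, got ndim={self.data.ndim}")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.plane_replicates < 1:
            raise ValueError("plane_replicates must be ≥ 1")
        self.calibration.check_field(self.data.shape[2:])

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]


@dataclass
class ProjectionSeries:
    """Registered 2D+T intensity series for one cell.

    ``registration_offsets[t]`` is the (dy, dx) translation in pixels that was
    applied to frame ``t`` to bring it into frame-0 coordinates; the first
    entry is always ``(0, 0)``.
    """

    frames: np.ndarray
    calibration: Calibration
    registration_offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×Y×X, got ndim={self.frames.ndim}")
        if self.registration_offsets is None:
            self.registration_offsets = np.zeros((self.frames.shape[0], 2))
        self.registration_offsets = np.asarray(self.registration_offsets, dtype=float)
        if self.registration_offsets.shape != (self.frames.shape[0], 2):
            raise ValueError("registration_offsets must have shape (T, 2)")
        if not np.allclose(self.registration_offsets[0], 0.0):
            raise ValueError("offsets[0] must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# TIFF input / output
# ---------------------------------------------------------------------------

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _parse_ome_calibration(ome_xml: str) -> dict:
    """Extract pixel size / z-step / frame interval from OME-XML, all in µm / s."""
    out: dict = {}
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return out
    pixels = root.find(f".//{_OME_NS}Pixels")
    if pixels is None:  # fall back to namespace-agnostic search
        pixels = next((e for e in root.iter() if e.tag.endswith("Pixels")), None)
    if pixels is None:
        return out
    if pixels.get("PhysicalSizeX"):
        out["pixel_size_um"] = float(pixels.get("PhysicalSizeX"))
    if pixels.get("PhysicalSizeZ"):
        out["z_step_um"] = float(pixels.get("PhysicalSizeZ"))
    if pixels.get("TimeIncrement"):
        out["frame_interval_s"] = float(pixels.get("TimeIncrement"))
    return out


def read_timelapse(
    path: str | Path,
    calibration_override: Optional[Calibration] = None,
    axis_order: Optional[str] = None,
    plane_replicates: int = 1,
) -> TimeLapseStack:
    """Read a TIFF / OME-TIFF time-lapse into a :class:`TimeLapseStack`.

    Axis metadata embedded in the file (OME or ImageJ) is trusted when
    present; otherwise an explicit ``axis_order`` string such as ``"TZYX"``
    or ``"ZTYX"`` must be supplied — silent axis guessing is refused because
    it corrupts every downstream number.  Calibration comes from embedded
    OME metadata and is overridden field-by-field by ``calibration_override``.

    Raises
    ------
    StackIOError
        If the file is unreadable, the axis order cannot be resolved, or no
        pixel size is available from metadata or override.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            file_axes = series.axes
            ome_xml = tif.ome_metadata
    except (tifffile.TiffFileError, OSError, ValueError, IndexError) as exc:
        raise StackIOError(f"unreadable file: {path}: {exc}") from exc

    axes = axis_order if axis_order is not None else file_axes
    axes = axes.upper().replace("S", "C")
    if sorted(set(axes)) == sorted(axes) and set(axes) <= set("TZYXC") and len(axes) == data.ndim:
        pass
    else:
        raise StackIOError(
            f"ambiguous axis order {axes!r} for data of shape {data.shape}; "
            "supply axis_order explicitly"
        )
    if "C" in axes:
        data = np.take(data, 0, axis=axes.index("C"))
        axes = axes.replace("C", "")
    # insert singleton T / Z axes when absent, then transpose to TZYX
    for ax in "TZ":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    if set(axes) != set("TZYX"):
        raise StackIOError(f"cannot resolve axes {axes!r} to T,Z,Y,X")
    data = np.transpose(data, [axes.index(a) for a in "TZYX"])

    meta = _parse_ome_calibration(ome_xml) if ome_xml else {}
    if calibration_override is not None:
        cal = calibration_override
    elif "pixel_size_um" in meta:
        cal = Calibration(**meta)
    else:
        raise StackIOError(
            f"no calibration in {path} and no calibration_override supplied"
        )
    return TimeLapseStack(data=data, calibration=cal, plane_replicates=plane_replicates)


def write_timelapse(stack: TimeLapseStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with embedded calibration metadata."""
    cal = stack.calibration
    tifffile.imwrite(
        Path(path),
        stack.data,
        ome=True,
        metadata={
            "axes": "TZYX",
            "PhysicalSizeX": cal.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": cal.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": cal.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": cal.frame_interval_s,
            "TimeIncrementUnit": "s",
        },
    )


def write_mask_series(masks: np.ndarray, path: str | Path) -> None:
    """Write a boolean T×Y×X mask series as a multi-page uint8 TIFF (0/255)."""
    tifffile.imwrite(
        Path(path), (np.asarray(masks, bool) * np.uint8(255)), photometric="minisblack"
    )


def average_plane_replicates(stack: TimeLapseStack) -> TimeLapseStack:
    """Average consecutively stored replicate images of each z-plane.

    With ``plane_replicates = r`` the Z axis shrinks by a factor ``r`` and
    each output plane is the arithmetic mean of its ``r`` replicates.
    """
    r = stack.plane_replicates
    if r == 1:
        return stack
    t, z, y, x = stack.data.shape
    if z % r != 0:
        raise ValueError(f"Z={z} not divisible by plane_replicates={r}")
    averaged = stack.data.reshape(t, z // r, r, y, x).mean(axis=2)
    return TimeLapseStack(data=averaged, calibration=stack.calibration, plane_replicates=1)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


@dataclass
class CellRecord:
    """One analyzed cell: identity, dynamics readouts and Sholl profile."""

    cell_id: str
    dynamics: object  # DynamicsResult
    sholl: Optional[object] = None  # ShollProfile
    group: str = ""
    slice_age_min: Optional[float] = None


def results_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Tidy per-cell table of the scalar readouts (one row per cell)."""
    rows = []
    for rec in records:
        d = rec.dynamics
        rows.append(
            {
                "cell_id": rec.cell_id,
                "group": rec.group,
                "n_frames": len(d.area_series_px),
                "motility_index": d.motility_index,
                "surveillance_index_px": d.surveillance_index_px,
                "surveillance_index_um2": d.surveillance_index_um2,
                "mean_area_px": float(np.mean(d.area_series_px)),
                "mean_area_um2": d.mean_area_um2,
                "slice_age_min": rec.slice_age_min,
            }
        )
    return pd.DataFrame(rows)


def transitions_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Long per-transition table (one row per cell per frame transition)."""
    rows = []
    for rec in records:
        for tr in rec.dynamics.transitions:
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "t": tr.t,
                    "retraction_px": tr.retraction_px,
                    "extension_px": tr.extension_px,
                    "retraction_rel": tr.retraction_rel,
                    "extension_rel": tr.extension_rel,
                    "motility_t": tr.motility_t,
                }
            )
    return pd.DataFrame(rows)


def sholl_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Long-format Sholl table: cell_id, radius_um, intersections."""
    rows = []
    for rec in records:
        if rec.sholl is None:
            continue
        for r, n in zip(rec.sholl.radii_um, rec.sholl.intersections):
            rows.append({"cell_id": rec.cell_id, "radius_um": float(r), "intersections": int(n)})
    return pd.DataFrame(rows)


def write_results(records: Sequence[CellRecord], out_dir: str | Path) -> dict:
    """Write per-cell results, per-transition and Sholl CSVs to ``out_dir``.

    Returns a dict of the written paths.  Floats are written with 6 decimals
    so that a write → parse round-trip reproduces values to that precision.
    """
    records = list(records)
    if not records:
        raise ValueError("empty result collection")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out_dir / "results.csv",
        "transitions": out_dir / "transitions.csv",
        "sholl": out_dir / "sholl.csv",
    }
    results_frame(records).to_csv(paths["results"], index=False, float_format="%.6f")
    transitions_frame(records).to_csv(paths["transitions"], index=False, float_format="%.6f")
    sholl_frame(records).to_csv(paths["sholl"], index=False, float_format="%.6f")
    return paths
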