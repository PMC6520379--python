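"""Reading, writing and ROI sampling of cardiac-gated phase-contrast series.

Two on-disk representations are supported:

* ``fixture`` — a portable single-file plain-text container: a magic line,
  a JSON header carrying every scalar field of :class:`PhaseSeries`, then
  the frames as whitespace-separated signed integers (T*H rows of W values).
* ``dicom`` — a directory of single-frame explicit-VR little-endian DICOM
  files, one per cardiac phase, ordered by TriggerTime (ties broken by
  InstanceNumber).  Velocity encoding and grey full scale travel in
  ImageComments as a small JSON payload; RR interval in NominalInterval.

Coordinate convention: (row, col), 0-based, pixel centers at integer
coordinates; physical distances use the per-axis pixel spacing in mm.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dicom
from .errors import GeometryError, MetadataError, RangeError, StructuralError

SEGMENTS = ("C2", "C3", "C4", "C5", "C6", "C7")
ROI_LABELS = ("cord", "static_tissue", "csf")

_FIXTURE_MAGIC = "#cordmotion-phase-series v1"

#: Cord ROI area in mm^2 used throughout (ellipse, pi*a*b).
CORD_ROI_AREA_MM2 = 30.52
#: Default cord ROI semi-axis along rows (anterior-posterior), mm.  The
#: aspect ratio is a free choice; the area is what is fixed.
DEFAULT_SEMI_AXIS_ROW_MM = 2.7


@dataclass(frozen=True)
class EllipseROI:
    """Ellipsoid region of interest, axis-aligned, placed in pixel coordinates.

    Semi-axes are physical (mm); the pixel-inclusion test therefore respects
    anisotropic pixel spacing.
    """

    center: tuple[float, float]          # (row, col), pixels
    semi_axis_row: float                 # mm
    semi_axis_col: float                 # mm
    label: str = "cord"

    def __post_init__(self):
        if self.semi_axis_row <= 0 or self.semi_axis_col <= 0:
            raise ValueError("ROI semi-axes must be positive")
        if self.label not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}")

    @property
    def area_mm2(self) -> float:
        """Ellipse area pi*a*b in mm^2."""
        return math.pi * self.semi_axis_row * self.semi_axis_col

    def shifted(self, d_row: float, d_col: float) -> "EllipseROI":
        return EllipseROI((self.center[0] + d_row, self.center[1] + d_col),
                          self.semi_axis_row, self.semi_axis_col, self.label)


def default_cord_roi(center: tuple[float, float],
                     semi_axis_row: float = DEFAULT_SEMI_AXIS_ROW_MM) -> EllipseROI:
    """Cord ROI with the standard 30.52 mm^2 area, mid-centred at `center`."""
    semi_axis_col = CORD_ROI_AREA_MM2 / (math.pi * semi_axis_row)
    return EllipseROI(center, semi_axis_row, semi_axis_col, "cord")


@dataclass
class PhaseSeries:
    """One cardiac-gated phase image stack for one segment/subject/scan."""

    subject_id: str
    scan_id: str
    segment: str
    frames: np.ndarray                   # (T, H, W) signed integers
    venc: float = 2.0                    # cm/s
    grey_full_scale: int = 4096
    rr_interval: float = 1000.0          # ms
    pixel_spacing: tuple[float, float] = (0.5, 0.5)  # mm (row, col)
    saturated: bool = field(init=False, default=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if not np.issubdtype(self.frames.dtype, np.integer):
            if not np.all(self.frames == np.round(self.frames)):
                raise StructuralError("frames must hold integer grey values")
            self.frames = self.frames.astype(np.int32)
        if self.frames.ndim != 3:
            raise StructuralError(f"frames must be (T, H, W); got shape {self.frames.shape}")
        if self.segment not in SEGMENTS:
            raise MetadataError(f"unknown segment {self.segment!r}; expected one of {SEGMENTS}")
        if self.n_timepoints < 2:
            raise StructuralError("a phase series needs at least 2 timepoints")
        if self.venc <= 0:
            raise MetadataError("venc must be positive")
        if self.rr_interval <= 0:
            raise MetadataError("rr_interval must be positive")
        if any(s <= 0 for s in self.pixel_spacing):
            raise MetadataError("pixel spacings must be positive")
        amax = int(np.abs(self.frames).max()) if self.frames.size else 0
        if amax > self.grey_full_scale:
            raise RangeError(
                f"grey value magnitude {amax} exceeds full scale {self.grey_full_scale}")
        self.saturated = amax == self.grey_full_scale

    @property
    def n_timepoints(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __eq__(self, other):
        if not isinstance(other, PhaseSeries):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.scan_id == other.scan_id
            and self.segment == other.segment
            and self.venc == other.venc
            and self.grey_full_scale == other.grey_full_scale
            and self.rr_interval == other.rr_interval
            and self.pixel_spacing == other.pixel_spacing
            and self.frames.shape == other.frames.shape
            and bool(np.all(self.frames == other.frames))
        )


# ---------------------------------------------------------------------------
# fixture format
# ---------------------------------------------------------------------------

def _write_fixture(series: PhaseSeries, path: Path) -> Path:
    header = {
        "subject_id": series.subject_id,
        "scan_id": series.scan_id,
        "segment": series.segment,
        "n_timepoints": series.n_timepoints,
        "height": series.frames.shape[1],
        "width": series.frames.shape[2],
        "venc": series.venc,
        "grey_full_scale": series.grey_full_scale,
        "rr_interval": series.rr_interval,
        "pixel_spacing": list(series.pixel_spacing),
    }
    t, h, w = series.frames.shape
    with open(path, "w") as fh:
        fh.write(_FIXTURE_MAGIC + "\n")
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, series.frames.reshape(t * h, w), fmt="%d")
    return path


def _read_fixture(path: Path) -> PhaseSeries:
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _FIXTURE_MAGIC:
            raise StructuralError(f"{path}: not a phase-series fixture (bad magic line)")
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise StructuralError(f"{path}: unparseable fixture header") from exc
        for key in ("subject_id", "scan_id", "segment", "n_timepoints", "height",
                    "width", "venc", "grey_full_scale", "rr_interval", "pixel_spacing"):
            if key not in header:
                raise MetadataError(f"{path}: fixture header missing field {key!r}")
        data = np.loadtxt(fh, dtype=np.int32, ndmin=2)
    t, h, w = header["n_timepoints"], header["height"], header["width"]
    if data.shape != (t * h, w):
        raise StructuralError(
            f"{path}: header advertises {t} frames of {h}x{w} "
            f"but data block has shape {data.shape}")
    return PhaseSeries(
        subject_id=header["subject_id"],
        scan_id=header["scan_id"],
        segment=header["segment"],
        frames=data.reshape(t, h, w),
        venc=float(header["venc"]),
        grey_full_scale=int(header["grey_full_scale"]),
        rr_interval=float(header["rr_interval"]),
        pixel_spacing=tuple(float(s) for s in header["pixel_spacing"]),
    )


# ---------------------------------------------------------------------------
# DICOM format (directory of single-frame files)
# ---------------------------------------------------------------------------

def _write_dicom_dir(series: PhaseSeries, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    t = series.n_timepoints
    h, w = series.shape
    comments = json.dumps({
        "venc": series.venc,
        "grey_full_scale": series.grey_full_scale,
        "segment": series.segment,
        "scan_id": series.scan_id,
        "rr_interval": series.rr_interval,   # full precision; NominalInterval is integer ms
    })
    frames16 = series.frames.astype("<i2")
    for i in range(t):
        trigger = i * series.rr_interval / t
        elements = [
            (_dicom.SERIES_DESCRIPTION, "LO", f"PC cord motion {series.segment}"),
            (_dicom.MODALITY, "CS", "MR"),
            (_dicom.PATIENT_ID, "LO", series.subject_id),
            (_dicom.SEQUENCE_NAME, "SH", f"pc_venc{series.venc:g}cms"),
            (_dicom.TRIGGER_TIME, "DS", f"{trigger:.6f}"),
            (_dicom.NOMINAL_INTERVAL, "IS", str(int(round(series.rr_interval)))),
            (_dicom.INSTANCE_NUMBER, "IS", str(i + 1)),
            (_dicom.IMAGE_COMMENTS, "LT", comments),
            (_dicom.SAMPLES_PER_PIXEL, "US", 1),
            (_dicom.PHOTOMETRIC, "CS", "MONOCHROME2"),
            (_dicom.ROWS, "US", h),
            (_dicom.COLUMNS, "US", w),
            (_dicom.PIXEL_SPACING, "DS",
             f"{series.pixel_spacing[0]:.6f}\\{series.pixel_spacing[1]:.6f}"),
            (_dicom.BITS_ALLOCATED, "US", 16),
            (_dicom.BITS_STORED, "US", 16),
            (_dicom.HIGH_BIT, "US", 15),
            (_dicom.PIXEL_REPRESENTATION, "US", 1),
            (_dicom.RESCALE_INTERCEPT, "DS", "0"),
            (_dicom.RESCALE_SLOPE, "DS", "1"),
            (_dicom.PIXEL_DATA, "OW", frames16[i].tobytes()),
        ]
        key = f"{series.subject_id}/{series.scan_id}/{series.segment}".encode()
        suffix = f"{zlib.crc32(key)}.{i + 1}"
        _dicom.write_dicom(path / f"frame_{i:03d}.dcm", elements, suffix)
    return path


def _read_dicom_frame(fp: Path):
    ds = _dicom.read_dicom(fp)
    h = _dicom.get_us(ds, _dicom.ROWS, "Rows", fp)
    w = _dicom.get_us(ds, _dicom.COLUMNS, "Columns", fp)
    rep = _dicom.get_us(ds, _dicom.PIXEL_REPRESENTATION, "PixelRepresentation", fp)
    if _dicom.PIXEL_DATA not in ds:
        raise MetadataError(f"missing required DICOM field PixelData in {fp}")
    dtype = "<i2" if rep == 1 else "<u2"
    pixels = np.frombuffer(ds[_dicom.PIXEL_DATA][1], dtype=dtype)
    if pixels.size < h * w:
        raise StructuralError(f"{fp}: pixel data shorter than Rows x Columns")
    frame = pixels[:h * w].reshape(h, w).astype(np.int32)
    slope = float(_dicom.get_str(ds, _dicom.RESCALE_SLOPE, "RescaleSlope", fp)) \
        if _dicom.RESCALE_SLOPE in ds else 1.0
    intercept = float(_dicom.get_str(ds, _dicom.RESCALE_INTERCEPT, "RescaleIntercept", fp)) \
        if _dicom.RESCALE_INTERCEPT in ds else 0.0
    if (slope, intercept) != (1.0, 0.0):
        frame = np.round(frame * slope + intercept).astype(np.int32)
    trigger = _dicom.get_float(ds, _dicom.TRIGGER_TIME, "TriggerTime", fp)
    instance = int(_dicom.get_str(ds, _dicom.INSTANCE_NUMBER, "InstanceNumber", fp)) \
        if _dicom.INSTANCE_NUMBER in ds else 0
    rr = _dicom.get_float(ds, _dicom.NOMINAL_INTERVAL, "NominalInterval (RR)", fp)
    try:
        comments = json.loads(_dicom.get_str(ds, _dicom.IMAGE_COMMENTS, "ImageComments", fp))
        venc = float(comments["venc"])
        full_scale = int(comments["grey_full_scale"])
        segment = comments["segment"]
        scan_id = str(comments["scan_id"])
        rr = float(comments.get("rr_interval", rr))
    except (json.JSONDecodeError, KeyError) as exc:
        raise MetadataError(
            f"{fp}: ImageComments does not carry venc/grey_full_scale metadata") from exc
    spacing = tuple(float(x) for x in
                    _dicom.get_str(ds, _dicom.PIXEL_SPACING, "PixelSpacing", fp).split("\\"))
    subject = _dicom.get_str(ds, _dicom.PATIENT_ID, "PatientID", fp)
    return trigger, instance, frame, dict(
        subject_id=subject, scan_id=scan_id, segment=segment, venc=venc,
        grey_full_scale=full_scale, rr_interval=rr, pixel_spacing=spacing)


def _read_dicom_dir(path: Path) -> PhaseSeries:
    files = sorted(Path(path).glob("*.dcm"))
    if not files:
        raise StructuralError(f"{path}: no .dcm files found")
    records = [_read_dicom_frame(fp) for fp in files]
    records.sort(key=lambda r: (r[0], r[1]))
    meta = records[0][3]
    for _, _, _, m in records[1:]:
        if m != meta:
            raise StructuralError(f"{path}: inconsistent metadata across frames")
    frames = np.stack([r[2] for r in records])
    return PhaseSeries(frames=frames, **meta)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_phase_series(series: PhaseSeries, path, format: str = "fixture") -> Path:
    """Write `series` to `path`; returns the path written.

    ``fixture`` writes one text file; ``dicom`` writes a directory of
    per-frame files.  ``read_phase_series(write_phase_series(s)) == s``.
    """
    path = Path(path)
    if format == "fixture":
        return _write_fixture(series, path)
    if format == "dicom":
        return _write_dicom_dir(series, path)
    raise ValueError(f"unknown format {format!r}")


def read_phase_series(path, format: str = "fixture") -> PhaseSeries:
    """Read a phase series; frames come back ordered by cardiac phase."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fixture":
        return _read_fixture(path)
    if format == "dicom":
        return _read_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}")


def ellipse_pixel_mask(shape: tuple[int, int], roi: EllipseROI,
                       pixel_spacing: tuple[float, float]) -> np.ndarray:
    """Boolean (H, W) mask: pixel centers inside the ellipse, mm metric.

    A pixel (r, c) is inside iff
    ``((r-cr)*sr/a)**2 + ((c-cc)*sc/b)**2 <= 1``
    with spacings (sr, sc) in mm/px and semi-axes (a, b) in mm.
    """
    h, w = shape
    sr, sc = pixel_spacing
    cr, cc = roi.center
    rows = (np.arange(h)[:, None] - cr) * sr / roi.semi_axis_row
    cols = (np.arange(w)[None, :] - cc) * sc / roi.semi_axis_col
    return rows ** 2 + cols ** 2 <= 1.0


def roi_mean_greyvalues(series: PhaseSeries, roi: EllipseROI) -> np.ndarray:
    """Mean grey value inside the ROI at each timepoint (length-T array)."""
    h, w = series.shape
    sr, sc = series.pixel_spacing
    half_r = roi.semi_axis_row / sr
    half_c = roi.semi_axis_col / sc
    if (roi.center[0] - half_r < 0 or roi.center[0] + half_r > h - 1
            or roi.center[1] - half_c < 0 or roi.center[1] + half_c > w - 1):
        raise GeometryError(
            f"ROI centred at {roi.center} with extent ±({half_r:.2f}, {half_c:.2f}) px "
            f"exceeds the {h}x{w} image grid")
    mask = ellipse_pixel_mask((h, w), roi, series.pixel_spacing)
    if not mask.any():
        raise GeometryError("ROI covers zero pixel centers")
    return series.frames[:, mask].mean(axis=1)


def read_roi_file(path) -> list[EllipseROI]:
    """Parse a plain-text ROI config: one ROI per line,
    ``label center_row center_col semi_axis_row_mm semi_axis_col_mm``.
    Blank lines and ``#`` comments are ignored.
    """
    rois = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise StructuralError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        label, cr, cc, a, b = parts
        rois.append(EllipseROI((float(cr), float(cc)), float(a), float(b), label))
    return rois


def write_roi_file(rois: list[EllipseROI], path) -> Path:
    lines = ["# label center_row center_col semi_axis_row_mm semi_axis_col_mm"]
    for roi in rois:
        lines.append(f"{roi.label} {roi.center[0]:g} {roi.center[1]:g} "
                     f"{roi.semi_axis_row:.6f} {roi.semi_axis_col:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
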