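"""Grey-value → velocity conversion, phase-drift correction, motion readouts.

The processing chain for one segment:

1. average grey values inside the cord ROI per timepoint,
2. map to velocity: ``v_i = grey_i / grey_full_scale * venc`` (cm/s,
   positive = cranial),
3. subtract the waveform mean (zero-net-motion assumption) to remove the
   scanner phase-drift offset,
4. reduce to four readouts: amplitude, max cranial velocity, max caudal
   velocity, displacement (rectified rectangle-rule AUC with step RR/T).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import RangeError, StateError
from .phase_image_io import EllipseROI, PhaseSeries, roi_mean_greyvalues

READOUT_NAMES = ("amplitude", "max_cranial", "max_caudal", "displacement")


@dataclass(frozen=True)
class VelocityWaveform:
    """Velocity samples over one cardiac cycle.

    `values` are in cm/s (positive = cranial), `rr_interval` in seconds.
    `drift_estimate` is the constant removed by drift correction (0 while
    uncorrected).  `saturated` flags series whose grey values touched full
    scale, for downstream QC.
    """

    values: np.ndarray
    rr_interval: float           # s
    corrected: bool = False
    drift_estimate: float = 0.0
    saturated: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("waveform needs at least 2 samples")
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be positive")
        if self.corrected:
            m = float(np.mean(self.values))
            scale = max(1.0, float(np.max(np.abs(self.values))))
            if abs(m) > 1e-12 * scale:
                raise ValueError(f"corrected waveform has nonzero mean {m!r}")

    @property
    def n_timepoints(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class MotionReadouts:
    """The four per-segment motion parameters."""

    amplitude: float      # cm/s, peak-to-peak
    max_cranial: float    # cm/s, >= 0 for physiological waveforms
    max_caudal: float     # cm/s, signed (negative = caudal)
    displacement: float   # cm, rectified AUC

    def as_dict(self) -> dict[str, float]:
        return {
            "amplitude": self.amplitude,
            "max_cranial": self.max_cranial,
            "max_caudal": self.max_caudal,
            "displacement": self.displacement,
        }


def grey_to_velocity(grey_means, venc: float, grey_full_scale: int = 4096,
                     rr_interval: float = 1.0) -> VelocityWaveform:
    """Linear grey→velocity map: ``v = g / grey_full_scale * venc``.

    `rr_interval` is in seconds.  Raises :class:`RangeError` if any mean
    grey value exceeds the encodable range (aliasing/saturation upstream).
    """
    grey = np.asarray(grey_means, dtype=float)
    if venc <= 0:
        raise ValueError("venc must be positive")
    amax = float(np.max(np.abs(grey))) if grey.size else 0.0
    if amax > grey_full_scale:
        raise RangeError(
            f"grey mean magnitude {amax} exceeds full scale {grey_full_scale}")
    values = grey / grey_full_scale * venc
    return VelocityWaveform(values=values, rr_interval=rr_interval,
                            corrected=False, drift_estimate=0.0,
                            saturated=amax == grey_full_scale)


def correct_phase_drift(w: VelocityWaveform) -> VelocityWaveform:
    """Remove the phase-drift offset by subtracting the waveform mean.

    Net cord motion over a cardiac cycle is assumed zero, so the waveform
    mean estimates the constant drift.  Double correction is refused.
    """
    if w.corrected:
        raise StateError("waveform is already drift-corrected")
    drift = float(np.mean(w.values))
    return replace(w, values=w.values - drift, corrected=True, drift_estimate=drift)


def compute_readouts(w: VelocityWaveform) -> MotionReadouts:
    """Reduce a corrected waveform to the four motion readouts.

    Displacement is the rectified rectangle-rule integral
    ``sum_i |v_i| * (rr / T)`` — RR in seconds, result in cm.
    """
    if not w.corrected:
        raise StateError("readouts are defined on drift-corrected waveforms; "
                         "call correct_phase_drift first (or use raw_readouts)")
    return _readouts(w)


def raw_readouts(w: VelocityWaveform) -> MotionReadouts:
    """Readouts of an uncorrected waveform (for drift-sensitivity analyses)."""
    return _readouts(w)


def _readouts(w: VelocityWaveform) -> MotionReadouts:
    values = w.values
    max_cranial = float(np.max(values))
    max_caudal = float(np.min(values))
    step = w.rr_interval / w.n_timepoints
    displacement = float(np.sum(np.abs(values)) * step)
    return MotionReadouts(
        amplitude=max_cranial - max_caudal,
        max_cranial=max_cranial,
        max_caudal=max_caudal,
        displacement=displacement,
    )


def waveform_from_series(series: PhaseSeries, roi: EllipseROI) -> VelocityWaveform:
    """ROI-average a series and convert to an uncorrected velocity waveform."""
    grey = roi_mean_greyvalues(series, roi)
    w = grey_to_velocity(grey, venc=series.venc,
                         grey_full_scale=series.grey_full_scale,
                         rr_interval=series.rr_interval / 1000.0)
    if series.saturated:
        w = replace(w, saturated=True)
    return w


def process_series(series: PhaseSeries, roi: EllipseROI
                   ) -> tuple[VelocityWaveform, MotionReadouts]:
    """Full chain: ROI mean → velocity → drift correction → readouts."""
    corrected = correct_phase_drift(waveform_from_series(series, roi))
    return corrected, compute_readouts(corrected)


def quantify_series_set(series_list, rois, include_raw: bool = True) -> pd.DataFrame:
    """Quantify a collection of series into a long readouts table.

    `rois` is either a single cord ROI (one rater ``R1``) or a mapping
    ``rater_id -> EllipseROI``.  Each series contributes one row per rater
    with drift-corrected readouts and, if `include_raw` is set, a second
    row with raw (uncorrected) readouts flagged ``corrected=False``.
    """
    if isinstance(rois, EllipseROI):
        rois = {"R1": rois}
    rows = []
    for series in series_list:
        for rater_id, roi in rois.items():
            raw = waveform_from_series(series, roi)
            corrected = correct_phase_drift(raw)
            base = {
                "subject_id": series.subject_id,
                "scan_id": series.scan_id,
                "segment": series.segment,
                "rater_id": rater_id,
                "drift_estimate": corrected.drift_estimate,
                "rr_interval": series.rr_interval,
            }
            rows.append(base | {"corrected": True}
                        | compute_readouts(corrected).as_dict())
            if include_raw:
                rows.append(base | {"corrected": False, "drift_estimate": 0.0}
                            | raw_readouts(raw).as_dict())
    return pd.DataFrame(rows)
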