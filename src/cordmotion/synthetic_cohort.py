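"""Synthetic cardiac-gated phase-contrast cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a biphasic pulse-synchronous motion template (quiet first half of
the cycle, then a caudal followed by a cranial lobe), per-subject peak
velocities drawn from per-segment normal distributions, a positive
phase-drift offset injected into every pixel, integer grey-value
quantization at the venc full scale, and optional per-pixel Gaussian noise.

Every stochastic quantity is a pure function of the config seed, and each
generated series is returned together with its ground truth (true peaks,
true drift, exact displacement of the unquantized waveform), so parameter
recovery by the measurement pipeline is an exact, testable contract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, SaturationError
from .phase_image_io import (SEGMENTS, EllipseROI, PhaseSeries, default_cord_roi,
                             ellipse_pixel_mask, write_phase_series)

# lobe-width search window (cycle fractions) for displacement matching
W_MIN = 0.015
W_MAX = 0.2


# ---------------------------------------------------------------------------
# motion template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionTemplate:
    """Parametric biphasic waveform shape on a T-point cardiac-cycle grid.

    Phases are cycle fractions in [0, 1); the sample grid is t_i = i/T.
    The first `quiescent_fraction` of the cycle is exactly zero; the active
    remainder holds a negative (caudal) then a positive (cranial)
    raised-cosine lobe, each peak snapped to its nearest grid sample.
    `lobe_width` sets the lobe half-support (scaled by 2.2); widths beyond
    the room between quiescence, the inter-lobe midpoint and the cycle end
    flatten the lobe top instead of widening it.
    """

    n_timepoints: int = 20
    quiescent_fraction: float = 0.5
    caudal_peak_phase: float = 0.65
    cranial_peak_phase: float = 0.85
    lobe_width: float = 0.08

    def __post_init__(self):
        if self.n_timepoints < 4:
            raise ConfigurationError("template needs at least 4 timepoints")
        if not (0 < self.quiescent_fraction < self.caudal_peak_phase
                < self.cranial_peak_phase < 1):
            raise ConfigurationError(
                "require 0 < quiescent_fraction < caudal_peak_phase "
                "< cranial_peak_phase < 1")
        if self.lobe_width <= 0:
            raise ConfigurationError("lobe_width must be positive")
        if self.caudal_index == self.cranial_index:
            raise ConfigurationError("peak phases collide on the sample grid")
        if self.grid[self.caudal_index] < self.quiescent_fraction:
            raise ConfigurationError("caudal peak snaps into the quiescent half")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.n_timepoints) / self.n_timepoints

    @property
    def caudal_index(self) -> int:
        return int(np.argmin(np.abs(self.grid - self.caudal_peak_phase)))

    @property
    def cranial_index(self) -> int:
        return int(np.argmin(np.abs(self.grid - self.cranial_peak_phase)))


def evaluate_template(template: MotionTemplate, max_cranial: float,
                      max_caudal: float) -> np.ndarray:
    """Zero-mean velocity sequence whose gridded extrema equal the requested
    peaks exactly.

    Two compact-support lobes live on the active (post-quiescent) part of
    the cycle; each basis lobe is mean-compensated inside the active window, so
    the returned sequence is exactly zero during the quiescent first part
    and has exactly zero mean — injected drift is then the unique waveform
    mean, making drift recovery well-posed.
    """
    if not (max_cranial > 0 > max_caudal):
        raise ConfigurationError("require max_cranial > 0 > max_caudal")
    t = template.grid
    active = t >= template.quiescent_fraction
    n_active = int(active.sum())
    if n_active < 3:
        raise ConfigurationError("active window must contain at least 3 samples")
    i_ca, i_cr = template.caudal_index, template.cranial_index

    half = 2.2 * template.lobe_width      # raised-cosine half-support
    mid = 0.5 * (t[i_ca] + t[i_cr])       # lobes stay on their own side

    def lobe(center_idx: int, sign: float, h: float,
             room_left: float, room_right: float) -> np.ndarray:
        # compact-support raised cosine, sides clipped so the lobes never
        # overlap each other, the quiescent half, or the cycle end; no
        # cross-talk means the peak-matching solve is diagonally dominant.
        # width beyond the available room flattens the top instead (keeps
        # the area growing while the support is pinned)
        p = t[center_idx]
        left = min(h, room_left)
        right = min(h, room_right)
        flatten = min(1.0, (room_left + room_right) / (2.0 * h))
        exponent = max(0.3, flatten)
        dt = t - p
        bump = np.zeros_like(t)
        rise = (dt >= -left) & (dt < 0)
        fall = (dt >= 0) & (dt <= right)
        bump[rise] = (0.5 * (1.0 + np.cos(np.pi * dt[rise] / left))) ** exponent
        bump[fall] = (0.5 * (1.0 + np.cos(np.pi * dt[fall] / right))) ** exponent
        bump = np.where(active, bump, 0.0) * sign
        bump[active] -= bump[active].mean()   # zero-mean, quiescent part untouched
        return bump

    # zero mean forces the lobe areas to roughly cancel; the shallower lobe
    # is widened by the amplitude ratio so the flat compensation pedestal
    # stays small and cannot out-rank the smaller peak
    ratio = -max_caudal / max_cranial
    h_ca = half if ratio >= 1.0 else half * min(1.0 / ratio, 8.0)
    h_cr = half * min(ratio, 8.0) if ratio >= 1.0 else half
    u = lobe(i_ca, -1.0, h_ca, t[i_ca] - template.quiescent_fraction,
             mid - t[i_ca])
    v = lobe(i_cr, +1.0, h_cr, t[i_cr] - mid, 1.0 - t[i_cr])
    design = np.array([[u[i_ca], v[i_ca]], [u[i_cr], v[i_cr]]])
    try:
        alpha, beta = np.linalg.solve(design, [max_caudal, max_cranial])
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("degenerate lobe configuration") from exc
    if alpha <= 0 or beta <= 0:
        raise ConfigurationError(
            "lobe coefficients lost their sign (peaks too asymmetric)")
    values = alpha * u + beta * v
    if int(np.argmin(values)) != i_ca or int(np.argmax(values)) != i_cr:
        raise ConfigurationError(
            "template extrema not attained at the requested peak phases "
            "(lobes overlap too strongly)")
    return values


def exact_displacement(values: np.ndarray, rr_seconds: float) -> float:
    """Rectified rectangle-rule AUC of an exact velocity sequence, in cm."""
    return float(np.sum(np.abs(values)) * rr_seconds / len(values))


def solve_lobe_width(template: MotionTemplate, max_cranial: float,
                     max_caudal: float, rr_seconds: float,
                     target_displacement: float,
                     w_min: float = W_MIN, w_max: float = W_MAX):
    """Lobe width making the exact-waveform displacement hit the target.

    Returns the width, or None if the target is outside the achievable
    range on [w_min, w_max] (caller may redraw or clamp).
    """
    def disp(width: float) -> float:
        tpl = dataclasses.replace(template, lobe_width=width)
        return exact_displacement(evaluate_template(tpl, max_cranial, max_caudal),
                                  rr_seconds)

    # wide lobes can merge and break the gridded-extrema contract; back the
    # upper bracket off until the template is well formed
    w_hi = w_max
    while w_hi > w_min:
        try:
            hi = disp(w_hi) - target_displacement
            break
        except ConfigurationError:
            w_hi *= 0.9
    else:
        return None
    try:
        lo = disp(w_min) - target_displacement
    except ConfigurationError:
        return None
    if lo == 0.0:
        return w_min
    if hi == 0.0:
        return w_hi
    if np.sign(lo) == np.sign(hi):
        return None
    return float(brentq(lambda w: disp(w) - target_displacement, w_min, w_hi,
                        xtol=1e-14, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentMotionDistribution:
    """Per-segment normal distributions of the true motion parameters."""

    max_cranial: tuple[float, float]          # (mean, sd), cm/s, mean > 0
    max_caudal: tuple[float, float]           # (mean, sd), cm/s, mean < 0
    displacement: tuple[float, float] | None = None   # (mean, sd), cm

    def __post_init__(self):
        if self.max_cranial[0] <= 0:
            raise ConfigurationError("max_cranial mean must be positive")
        if self.max_caudal[0] >= 0:
            raise ConfigurationError("max_caudal mean must be negative")
        for pair in (self.max_cranial, self.max_caudal, self.displacement or (0, 0)):
            if pair[1] < 0:
                raise ConfigurationError("standard deviations must be >= 0")


#: Nominal per-segment motion parameter distributions for a healthy cohort
#: (group mean, SD): max cranial velocity (cm/s), max caudal velocity (cm/s),
#: displacement (cm).
DEFAULT_SEGMENT_DISTRIBUTIONS: dict[str, SegmentMotionDistribution] = {
    "C2": SegmentMotionDistribution((0.115, 0.041), (-0.182, 0.060), (0.036, 0.009)),
    "C3": SegmentMotionDistribution((0.132, 0.042), (-0.204, 0.072), (0.042, 0.011)),
    "C4": SegmentMotionDistribution((0.161, 0.052), (-0.226, 0.096), (0.048, 0.013)),
    "C5": SegmentMotionDistribution((0.186, 0.078), (-0.259, 0.094), (0.054, 0.016)),
    "C6": SegmentMotionDistribution((0.161, 0.050), (-0.197, 0.061), (0.049, 0.010)),
    "C7": SegmentMotionDistribution((0.168, 0.053), (-0.169, 0.055), (0.051, 0.015)),
}


def _default_distributions():
    return dict(DEFAULT_SEGMENT_DISTRIBUTIONS)


def _default_roi():
    return default_cord_roi((15.5, 15.5))


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to synthesize a cohort, seed included."""

    seed: int
    n_subjects: int = 18
    segments: tuple[str, ...] = SEGMENTS
    distributions: dict[str, SegmentMotionDistribution] = field(
        default_factory=_default_distributions)
    match_displacement: bool = True
    drift: tuple[float, float] = (0.25, 0.025)        # cm/s (mean, sd)
    pixel_noise_sd: float = 0.0                       # grey-value units
    rr_distribution: tuple[float, float] = (1000.0, 80.0)  # ms (mean, sd)
    venc: float = 2.0
    grey_full_scale: int = 4096
    image_size: tuple[int, int] = (32, 32)
    pixel_spacing: tuple[float, float] = (0.5, 0.5)
    roi: EllipseROI = field(default_factory=_default_roi)
    template: MotionTemplate = field(default_factory=MotionTemplate)
    n_scans: int = 1
    retest_scale_sd: float = 0.05     # between-scan fractional perturbation of true values
    n_excluded_stenosis: int = 0      # trailing subjects flagged for exclusion
    n_missing_bp: int = 0             # subjects with missing blood pressure
    disp_amplitude_corr: float = 0.8  # correlation of displacement draw with amplitude
    motion_scale_sd: float = 0.0      # subject-level latent motion scale SD
    anatomy_motion_coupling: float = 0.5

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_scans not in (1, 2):
            raise ConfigurationError("n_scans must be 1 or 2")
        unknown = set(self.segments) - set(SEGMENTS)
        if unknown:
            raise ConfigurationError(f"unknown segments: {sorted(unknown)}")
        missing = set(self.segments) - set(self.distributions)
        if missing:
            raise ConfigurationError(f"no distribution for segments: {sorted(missing)}")
        if self.n_excluded_stenosis >= self.n_subjects:
            raise ConfigurationError("cannot flag every subject for exclusion")


@dataclass
class CohortData:
    """In-memory result of cohort synthesis."""

    series: list[PhaseSeries]
    ground_truth: pd.DataFrame      # one row per subject x scan x segment
    subjects: pd.DataFrame          # subject-level covariates + exclusion flags
    anatomy: pd.DataFrame           # subject x segment anatomical measures


# ---------------------------------------------------------------------------
# series synthesis
# ---------------------------------------------------------------------------

def _encode_frames(values: np.ndarray, drift: float, config: CohortConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Build the T-frame grey-value stack for exact velocities + drift."""
    venc, fs = config.venc, config.grey_full_scale
    if np.max(np.abs(values + drift)) > venc:
        raise SaturationError(
            "velocity plus drift exceeds venc; reduce signal or drift in config")
    h, w = config.image_size
    mask = ellipse_pixel_mask((h, w), config.roi, config.pixel_spacing)
    grey_bg = int(round(drift / venc * fs))
    grey_in = np.round((values + drift) / venc * fs).astype(np.int64)
    frames = np.full((len(values), h, w), grey_bg, dtype=np.int64)
    frames[:, mask] = grey_in[:, None]
    if config.pixel_noise_sd > 0:
        noise = np.round(rng.normal(0.0, config.pixel_noise_sd, frames.shape))
        frames = frames + noise.astype(np.int64)
    if np.max(np.abs(frames)) > fs:
        raise SaturationError("noisy grey values exceed the full scale")
    return frames.astype(np.int32)


# admissibility window for drawn peak pairs: near-zero or wildly asymmetric
# peaks make the two-lobe template degenerate (the mean-compensation baseline
# would out-rank a peak), so such draws are rejected and redrawn
MIN_PEAK = 0.02
MAX_PEAK_RATIO = 3.0


def _draw_peaks(rng, dist: SegmentMotionDistribution, max_tries=200
                ) -> tuple[float, float]:
    """Draw (max_cranial, max_caudal); the caudal draw is never altered,
    the cranial draw is clamped into the feasible asymmetry band (clamping
    rather than pair-rejection keeps the caudal distribution unbiased)."""
    ca = _draw_truncated(rng, *dist.max_caudal, lambda x: x < -MIN_PEAK,
                         max_tries)
    cr = _draw_truncated(rng, *dist.max_cranial, lambda x: x > MIN_PEAK,
                         max_tries)
    cr = float(np.clip(cr, -ca / MAX_PEAK_RATIO, -ca * MAX_PEAK_RATIO))
    return cr, ca


def _draw_displacement(rng, dist: SegmentMotionDistribution, max_cranial: float,
                       max_caudal: float, corr: float, max_tries=200) -> float:
    """Displacement draw correlated with the drawn amplitude.

    Gaussian copula: the marginal stays Normal(mean, sd) while subjects with
    larger drawn amplitude get larger displacement targets, which keeps the
    targets inside the waveform-feasible range (real readouts co-vary the
    same way).
    """
    amp_mean = dist.max_cranial[0] - dist.max_caudal[0]
    amp_sd = float(np.hypot(dist.max_cranial[1], dist.max_caudal[1]))
    z_amp = 0.0 if amp_sd == 0 else \
        ((max_cranial - max_caudal) - amp_mean) / amp_sd
    mean_d, sd_d = dist.displacement
    for _ in range(max_tries):
        z = corr * z_amp + np.sqrt(1.0 - corr ** 2) * rng.standard_normal()
        d = float(mean_d + sd_d * z)
        if d > 1e-4:
            return d
    raise ConfigurationError("could not draw a positive displacement target")


def _draw_truncated(rng, mean, sd, ok, max_tries=200):
    for _ in range(max_tries):
        x = float(rng.normal(mean, sd))
        if ok(x):
            return x
    raise ConfigurationError(
        f"could not draw an admissible value from N({mean}, {sd})")


def _build_series(config: CohortConfig, subject_id: str, scan_id: str,
                  segment: str, max_cranial: float, max_caudal: float,
                  lobe_width: float, rr_ms: float, drift: float,
                  rng: np.random.Generator) -> tuple[PhaseSeries, dict]:
    values = None
    for _ in range(12):   # back the width off if this peak pair needs narrower lobes
        template = dataclasses.replace(config.template, lobe_width=lobe_width)
        try:
            values = evaluate_template(template, max_cranial, max_caudal)
            break
        except ConfigurationError:
            lobe_width *= 0.8
    if values is None:
        raise ConfigurationError(
            f"no feasible lobe width for peaks ({max_cranial}, {max_caudal})")
    frames = _encode_frames(values, drift, config, rng)
    series = PhaseSeries(
        subject_id=subject_id, scan_id=scan_id, segment=segment,
        frames=frames, venc=config.venc, grey_full_scale=config.grey_full_scale,
        rr_interval=rr_ms, pixel_spacing=config.pixel_spacing)
    truth = {
        "subject_id": subject_id, "scan_id": scan_id, "segment": segment,
        "rr_interval": rr_ms, "drift": drift,
        "max_cranial": max_cranial, "max_caudal": max_caudal,
        "amplitude": max_cranial - max_caudal,
        "displacement": exact_displacement(values, rr_ms / 1000.0),
        "lobe_width": lobe_width,
    }
    return series, truth


def synthesize_series(config: CohortConfig, subject_id: str, segment: str,
                      rng: np.random.Generator, scan_id: str = "scan1"
                      ) -> tuple[PhaseSeries, dict]:
    """Draw one subject-segment series and its ground truth from the config."""
    dist = config.distributions[segment]
    max_cranial, max_caudal = _draw_peaks(rng, dist)
    rr_ms = _draw_truncated(rng, *config.rr_distribution, lambda x: x > 100.0)
    drift = float(rng.normal(*config.drift))
    lobe_width = config.template.lobe_width
    if config.match_displacement and dist.displacement is not None:
        lobe_width = _draw_matching_width(config, dist, max_cranial, max_caudal,
                                          rr_ms, rng)
    return _build_series(config, subject_id, scan_id, segment, max_cranial,
                         max_caudal, lobe_width, rr_ms, drift, rng)


def _nearest_feasible_width(template, max_cranial, max_caudal, rr_seconds,
                            target) -> float:
    """Clamp an unreachable displacement target to the closest window edge."""
    tpl = dataclasses.replace(template, lobe_width=W_MIN)
    d_min = exact_displacement(evaluate_template(tpl, max_cranial, max_caudal),
                               rr_seconds)
    if target <= d_min:
        return W_MIN
    w_hi = W_MAX
    while w_hi > W_MIN:
        try:
            tpl = dataclasses.replace(template, lobe_width=w_hi)
            evaluate_template(tpl, max_cranial, max_caudal)
            return w_hi
        except ConfigurationError:
            w_hi *= 0.9
    return W_MIN


def _draw_matching_width(config, dist, max_cranial, max_caudal, rr_ms, rng,
                         max_tries=200):
    """Draw a displacement target and solve the lobe width achieving it."""
    for _ in range(max_tries):
        target = _draw_displacement(rng, dist, max_cranial, max_caudal,
                                    config.disp_amplitude_corr)
        width = solve_lobe_width(config.template, max_cranial, max_caudal,
                                 rr_ms / 1000.0, target)
        if width is not None:
            return width
    raise ConfigurationError(
        "displacement distribution incompatible with the peak distribution "
        "(no admissible lobe width found)")


# ---------------------------------------------------------------------------
# cohort synthesis
# ---------------------------------------------------------------------------

def _subject_covariates(config: CohortConfig, i: int, rng, motion_scale: float,
                        rr_ms: float) -> dict:
    sex = "m" if i % 2 == 0 else "f"
    coupling = config.anatomy_motion_coupling
    body_size = float(rng.normal(172.0, 9.0) - coupling * 20.0 * (motion_scale - 1.0))
    return {
        "subject_id": f"S{i + 1:02d}",
        "sex": sex,
        "age": float(rng.normal(62.2, 6.5)),
        "body_size": body_size,
        "body_weight": float(rng.normal(75.0, 12.0)),
        "sys_before": float(rng.normal(129.7, 13.7)),
        "dia_before": float(rng.normal(80.0, 7.3)),
        "sys_after": float(rng.normal(122.7, 10.5)),
        "dia_after": float(rng.normal(77.0, 7.7)),
        "rr_interval": rr_ms,
        "excluded": False,
        "exclusion_reason": "",
    }


_ANATOMY_MEANS = {        # per-segment canal/cord geometry anchors (cm, cm^2)
    "C2": (1.29, 1.58, 2.27, 3.20, 0.83),
    "C3": (1.25, 1.52, 2.22, 3.00, 0.78),
    "C4": (1.21, 1.46, 2.17, 2.80, 0.74),
    "C5": (1.17, 1.40, 2.12, 2.60, 0.69),
    "C6": (1.14, 1.35, 2.07, 2.40, 0.62),
    "C7": (1.11, 1.29, 2.03, 2.21, 0.56),
}


def _segment_anatomy(config: CohortConfig, subject_id: str, segment: str,
                     rng, motion_scale: float) -> dict:
    ap_sag, ap_ax, rl_ax, canal_csa, cord_csa = _ANATOMY_MEANS[segment]
    shrink = 1.0 - config.anatomy_motion_coupling * 0.1 * (motion_scale - 1.0)
    canal = canal_csa * shrink * float(rng.normal(1.0, 0.03))
    cord = cord_csa * float(rng.normal(1.0, 0.03))
    return {
        "subject_id": subject_id, "segment": segment,
        "canal_ap_sagittal": ap_sag * shrink * float(rng.normal(1.0, 0.02)),
        "canal_ap_axial": ap_ax * shrink * float(rng.normal(1.0, 0.02)),
        "canal_rl_axial": rl_ax * shrink * float(rng.normal(1.0, 0.02)),
        "canal_csa": canal,
        "cord_csa": cord,
        "csf_area": max(canal - cord, 0.1),
    }


def synthesize_cohort(config: CohortConfig, out_dir: str | Path | None = None
                      ) -> CohortData:
    """Generate the full cohort: series, ground truth, covariates, anatomy.

    With `out_dir` set, fixture-format series plus ``ground_truth.csv``,
    ``subjects.csv`` and ``anatomy.csv`` are written there.  The entire
    output is a pure function of the config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    series_list: list[PhaseSeries] = []
    truth_rows, subject_rows, anatomy_rows = [], [], []
    scan_ids = [f"scan{k + 1}" for k in range(config.n_scans)]

    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        motion_scale = 1.0
        if config.motion_scale_sd > 0:
            motion_scale = _draw_truncated(rng, 1.0, config.motion_scale_sd,
                                           lambda x: x > 0.2)
        # subject-level true motion parameters, shared across scans
        base: dict[str, tuple[float, float, float | None]] = {}
        for segment in config.segments:
            dist = config.distributions[segment]
            cr, ca = _draw_peaks(rng, dist)
            disp = None
            if config.match_displacement and dist.displacement is not None:
                disp = _draw_displacement(rng, dist, cr, ca,
                                          config.disp_amplitude_corr)
            base[segment] = (cr * motion_scale, ca * motion_scale,
                             None if disp is None else disp * motion_scale)

        rr_scan1 = None
        for scan_id in scan_ids:
            rr_ms = _draw_truncated(rng, *config.rr_distribution, lambda x: x > 100.0)
            rr_scan1 = rr_scan1 if rr_scan1 is not None else rr_ms
            scan_scale = 1.0
            if scan_id != "scan1" and config.retest_scale_sd > 0:
                scan_scale = _draw_truncated(rng, 1.0, config.retest_scale_sd,
                                             lambda x: x > 0.2)
            for segment in config.segments:
                cr, ca, disp = base[segment]
                cr, ca = cr * scan_scale, ca * scan_scale
                drift = float(rng.normal(*config.drift))
                width = config.template.lobe_width
                if disp is not None:
                    width = solve_lobe_width(config.template, cr, ca,
                                             rr_ms / 1000.0, disp * scan_scale)
                    if width is None:   # unreachable target: clamp to window edge
                        width = _nearest_feasible_width(
                            config.template, cr, ca, rr_ms / 1000.0,
                            disp * scan_scale)
                series, truth = _build_series(config, subject_id, scan_id, segment,
                                              cr, ca, width, rr_ms, drift, rng)
                series_list.append(series)
                truth_rows.append(truth)

        subject_rows.append(_subject_covariates(config, i, rng, motion_scale, rr_scan1))
        for segment in config.segments:
            anatomy_rows.append(_segment_anatomy(config, subject_id, segment,
                                                 rng, motion_scale))

    subjects = pd.DataFrame(subject_rows)
    # trailing subjects carry the stenosis flag; deterministic and config-driven
    if config.n_excluded_stenosis:
        idx = subjects.index[-config.n_excluded_stenosis:]
        subjects.loc[idx, "excluded"] = True
        subjects.loc[idx, "exclusion_reason"] = "incidental stenosis"
    if config.n_missing_bp:
        bp_cols = ["sys_before", "dia_before", "sys_after", "dia_after"]
        miss = rng.choice(config.n_subjects, size=config.n_missing_bp, replace=False)
        subjects.loc[sorted(miss), bp_cols] = np.nan

    data = CohortData(series=series_list,
                      ground_truth=pd.DataFrame(truth_rows),
                      subjects=subjects,
                      anatomy=pd.DataFrame(anatomy_rows))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in data.series:
            name = f"{s.subject_id}_{s.scan_id}_{s.segment}.pcs"
            write_phase_series(s, out_dir / name, "fixture")
        data.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
        data.subjects.to_csv(out_dir / "subjects.csv", index=False)
        data.anatomy.to_csv(out_dir / "anatomy.csv", index=False)
    return data
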