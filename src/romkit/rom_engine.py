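"""From endpoint trajectories to a cleaned movement-angle series and a ROM.

The movement angle at frame *t* is the angle between the segment's unit
vector at *t* and at the start of the trial:

    v_t = (P1_t - P2_t) / ||P1_t - P2_t||
    alpha_t = arccos(v_t . v_0)          (degrees, in [0, 180])

The ROM is the maximum of alpha over the trial, after masking anomalous
frames.  Anomalies (tracking glitches that would otherwise masquerade as
the maximum) are found by an additive decomposition of the angle series
into trend + seasonal + residual; frames whose residual lies more than
``sd_multiplier`` standard deviations from the residual mean are masked.
The trend itself is never used as the angle estimate — decomposition can
distort the apex — only its residuals feed the anomaly mask, and the
maximum is taken over the original angles.

No smoothing is applied anywhere: ROM extraction needs a single point of
the trajectory, and filtering a slow, low-frequency movement risks
attenuating exactly that point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .registry import MovementSpec
from .trajectory_io import (
    DEFAULT_VISIBILITY_THRESHOLD,
    TrialTrajectory,
    filter_visibility,
    resolve_endpoint,
)

logger = logging.getLogger(__name__)


@dataclass
class DecompositionConfig:
    """Tuning for the additive decomposition and anomaly mask.

    ``period``: seasonal period in frames; defaults to the trial's nominal
    fps (about one second of movement) so the trend tracks the slow
    deliberate excursion while glitches land in the residual.
    ``trend_window``: centered moving-average window, default = period.
    ``sd_multiplier``: residual z-score threshold for the anomaly mask.
    ``peak_tolerance`` / ``trough_depth``: the multi-peak flag fires when a
    second local maximum lies within ``peak_tolerance`` of the global
    maximum and is separated from it by a trough deeper than
    ``trough_depth`` of the global maximum — a machine stand-in for manual
    review of ambiguous trials (an artifact policy, not a measurement).
    """

    period: Optional[int] = None
    sd_multiplier: float = 3.0
    trend_window: Optional[int] = None
    peak_tolerance: float = 0.05
    trough_depth: float = 0.10

    def __post_init__(self) -> None:
        if self.period is not None and self.period < 2:
            raise ValueError("period must be >= 2 frames")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")

    def resolved_period(self, fps: float) -> int:
        if self.period is not None:
            return int(self.period)
        return max(2, int(round(fps)) or 2)


@dataclass
class AngleSeries:
    """Per-frame movement angle with decomposition and anomaly mask."""

    t: np.ndarray
    alpha: np.ndarray          # degrees
    v0: np.ndarray             # reference unit vector
    trend: np.ndarray | None = None
    seasonal: np.ndarray | None = None
    residual: np.ndarray | None = None
    anomaly_mask: np.ndarray | None = None   # True = excluded frame

    def __len__(self) -> int:
        return len(self.alpha)


@dataclass
class ROMResult:
    """One extracted range-of-motion angle with quality flags."""

    movement: str = ""
    subject: str = ""
    device: str = ""
    trial: int = 0
    rom: float = float("nan")
    n_anomalies: int = 0
    multi_peak_flag: bool = False
    usable: bool = True
    n_frames: int = 0
    notes: str = ""


# ---------------------------------------------------------------------------
# vector algebra
# ---------------------------------------------------------------------------

def segment_vectors(
    p1: np.ndarray, p2: np.ndarray, *, atol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise unit vectors of the segment P1 - P2.

    Returns ``(v, keep)`` where ``keep`` marks frames with a non-degenerate
    segment (norm > atol); degenerate frames are dropped from ``v`` with a
    logged warning.  Each returned vector has unit norm to 1e-9.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if p1.shape != p2.shape:
        raise ValueError("endpoint series must be frame-aligned")
    diff = p1 - p2
    norms = np.linalg.norm(diff, axis=-1)
    keep = norms > atol
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d frame(s) with coincident endpoints", dropped)
    v = diff[keep] / norms[keep, None]
    return v, keep


def movement_angles(
    t: np.ndarray,
    vectors: np.ndarray,
    reference: str = "first_frame",
    n_reference: int = 5,
) -> AngleSeries:
    """Angle (degrees) of each frame's segment vector to the reference.

    ``reference="first_frame"`` uses v_0 = the first retained frame, so
    alpha_0 = 0 by construction.  ``"mean_first_n"`` averages the first
    ``n_reference`` frames (renormalized) — useful when a noisy first
    frame would bias every subsequent angle.
    """
    vectors = np.asarray(vectors, float)
    if len(vectors) < 2:
        raise ValueError("need at least 2 frames to compute movement angles")
    if reference == "first_frame":
        v0 = vectors[0]
    elif reference == "mean_first_n":
        v0 = vectors[: max(1, n_reference)].mean(axis=0)
        norm = np.linalg.norm(v0)
        if norm == 0:
            raise ValueError("reference frames average to the zero vector")
        v0 = v0 / norm
    else:
        raise ValueError(f"unknown reference {reference!r}")
    cosines = np.clip(vectors @ v0, -1.0, 1.0)
    # atan2(||v x v0||, v . v0) evaluates arccos(v . v0) in a numerically
    # stable way: plain arccos loses ~sqrt(eps) precision near 0 and 180 deg
    sines = np.linalg.norm(np.cross(vectors, v0), axis=-1)
    alpha = np.degrees(np.arctan2(sines, cosines))
    return AngleSeries(t=np.asarray(t, float), alpha=alpha, v0=v0)


# ---------------------------------------------------------------------------
# decomposition and anomaly detection
# ---------------------------------------------------------------------------

def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with nearest-valid-value edge extension.

    Even windows use the classical half-weight kernel of length
    ``window + 1`` so the average stays centered.
    """
    n = len(x)
    window = int(window)
    if window <= 1 or n < 2:
        return x.astype(float).copy()
    if window % 2 == 1:
        kernel = np.full(window, 1.0 / window)
    else:
        kernel = np.r_[0.5, np.ones(window - 1), 0.5] / window
    if len(kernel) > n:  # window longer than series: global mean
        return np.full(n, float(np.mean(x)))
    valid = np.convolve(x, kernel, mode="valid")
    half = (len(kernel) - 1) // 2
    out = np.empty(n)
    out[half : half + len(valid)] = valid
    out[:half] = valid[0]
    out[half + len(valid):] = valid[-1]
    return out


def decompose_additive(
    alpha: np.ndarray, cfg: DecompositionConfig, fps: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive decomposition alpha = trend + seasonal + residual.

    Trend: centered moving average (window ``trend_window``, default the
    period), edges extended with the nearest interior value.  Seasonal:
    mean of the detrended series per phase (frame index mod period),
    re-centered to zero mean.  The three components reconstruct alpha
    exactly on every frame.

    Series shorter than two periods cannot support a seasonal estimate:
    the seasonal component is zero and the residual is the deviation from
    the moving-average trend alone (logged).
    """
    alpha = np.asarray(alpha, float)
    n = len(alpha)
    period = cfg.resolved_period(fps)
    window = int(cfg.trend_window) if cfg.trend_window is not None else period
    trend = _centered_moving_average(alpha, window)
    if n < 2 * period:
        logger.warning(
            "series of %d frames < 2 periods (%d); seasonal component skipped",
            n, period,
        )
        seasonal = np.zeros(n)
        return trend, seasonal, alpha - trend
    detrended = alpha - trend
    phases = np.arange(n) % period
    # phase means use only the interior frames where the centered moving
    # average is exact; the edge-extended trend would otherwise leak a
    # spurious seasonal signal out of trending series
    half = window // 2
    interior = np.zeros(n, bool)
    interior[half : n - half] = True
    phase_means = np.array(
        [
            detrended[(phases == p) & interior].mean()
            if ((phases == p) & interior).any()
            else 0.0
            for p in range(period)
        ]
    )
    phase_means -= phase_means.mean()
    seasonal = phase_means[phases]
    residual = alpha - trend - seasonal
    return trend, seasonal, residual


def detect_anomalies(residual: np.ndarray, sd_multiplier: float = 3.0) -> np.ndarray:
    """Flag frames whose residual is > ``sd_multiplier`` SDs from the mean.

    Mean and SD are computed over all residuals of the trial.  A
    zero-variance residual series yields an empty mask.
    """
    residual = np.asarray(residual, float)
    if not np.all(np.isfinite(residual)):
        raise ValueError("residuals must be finite")
    sd = residual.std()
    if sd == 0:
        return np.zeros(len(residual), bool)
    return np.abs(residual - residual.mean()) > sd_multiplier * sd


# ---------------------------------------------------------------------------
# ROM extraction
# ---------------------------------------------------------------------------

def extract_rom(
    angles: AngleSeries,
    cfg: DecompositionConfig | None = None,
    **keys,
) -> ROMResult:
    """Global maximum of the angle series over non-anomalous frames.

    The multi-peak flag fires when at least two local maxima lie within
    ``peak_tolerance`` (fraction) of the global maximum and are separated
    by a trough deeper than ``trough_depth`` of it — trials a human
    operator would re-inspect.  ``keys`` fill the identifying fields of
    the result (movement, subject, device, trial).
    """
    cfg = cfg or DecompositionConfig()
    mask = (
        angles.anomaly_mask
        if angles.anomaly_mask is not None
        else np.zeros(len(angles), bool)
    )
    ok = ~mask
    n_anom = int(mask.sum())
    if not ok.any():
        return ROMResult(
            usable=False, n_anomalies=n_anom, n_frames=len(angles),
            notes="no usable frames", **keys,
        )
    clean = angles.alpha[ok]
    gmax = float(clean.max())
    multi = _multi_peak(clean, gmax, cfg)
    return ROMResult(
        rom=gmax,
        n_anomalies=n_anom,
        multi_peak_flag=multi,
        usable=True,
        n_frames=len(angles),
        **keys,
    )


def _multi_peak(clean: np.ndarray, gmax: float, cfg: DecompositionConfig) -> bool:
    if gmax <= 0 or len(clean) < 3:
        return False
    peaks, _ = find_peaks(clean)
    # the global maximum may sit on the series boundary
    for edge in (0, len(clean) - 1):
        if clean[edge] >= gmax and edge not in peaks:
            peaks = np.sort(np.append(peaks, edge))
    high = peaks[clean[peaks] >= (1 - cfg.peak_tolerance) * gmax]
    if len(high) < 2:
        return False
    for a, b in zip(high[:-1], high[1:]):
        trough = clean[a : b + 1].min()
        if gmax - trough > cfg.trough_depth * gmax:
            return True
    return False


# ---------------------------------------------------------------------------
# end-to-end composition
# ---------------------------------------------------------------------------

def compute_angle_series(
    traj: TrialTrajectory,
    spec: MovementSpec,
    cfg: DecompositionConfig | None = None,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    reference: str = "first_frame",
) -> AngleSeries | None:
    """Run the per-trial pipeline up to the decorated angle series.

    Returns None when fewer than two usable frames survive filtering.
    """
    cfg = cfg or DecompositionConfig()
    if traj.device == "pose33" and "visibility" in traj.df.columns:
        traj = filter_visibility(traj, visibility_threshold)
    ep1, ep2 = spec.endpoint_pair(traj.device)
    t1, p1 = resolve_endpoint(traj, ep1)
    t2, p2 = resolve_endpoint(traj, ep2)
    # align the two endpoint series on their common frames
    common, i1, i2 = np.intersect1d(t1, t2, return_indices=True)
    if len(common) < 2:
        return None
    v, keep = segment_vectors(p1[i1], p2[i2])
    t = common[keep]
    if len(v) < 2:
        return None
    series = movement_angles(t, v, reference=reference)
    trend, seasonal, residual = decompose_additive(series.alpha, cfg, fps=traj.fps)
    series.trend, series.seasonal, series.residual = trend, seasonal, residual
    series.anomaly_mask = detect_anomalies(residual, cfg.sd_multiplier)
    return series


def compute_trial_rom(
    traj: TrialTrajectory,
    spec: MovementSpec,
    cfg: DecompositionConfig | None = None,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    reference: str = "first_frame",
) -> ROMResult:
    """Full per-trial pipeline: filter, resolve, angles, clean, extract.

    Degenerate trials (all relevant landmarks filtered away, coincident
    endpoints everywhere, ...) yield ``usable=False`` rather than raising.
    """
    keys = dict(
        movement=spec.label, subject=traj.subject,
        device=traj.device, trial=traj.trial,
    )
    try:
        series = compute_angle_series(
            traj, spec, cfg, visibility_threshold, reference
        )
    except Exception as exc:  # degenerate trials must not crash a batch
        logger.warning("%s: trial unusable: %s", keys, exc)
        return ROMResult(usable=False, notes=str(exc), **keys)
    if series is None:
        logger.warning("%s: fewer than 2 usable frames", keys)
        return ROMResult(usable=False, notes="fewer than 2 usable frames", **keys)
    return extract_rom(series, cfg, **keys)
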