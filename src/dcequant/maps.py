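"""Semi-quantitative maps, quality-control masks and tumor histogram summaries.

Covers the signal enhancement ratio SER = (S9 - S2)/(S26 - S2), masking of
unenhanced voxels, plausibility filtering of fitted k_io values, the
time-summed EES concentration map (a surrogate for water-exchange
sensitivity of each voxel's data), and per-lesion mean/median/iqr summaries
of parametric maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SERMap",
    "LesionStats",
    "TumorSummary",
    "mask_unenhanced",
    "compute_ser",
    "filter_kio",
    "sum_cao_map",
    "summarize_metric",
]

KIO_FILTER_RANGE = (0.1, 20.0)  # s^-1, biologically meaningful / achievable
SER_FRAMES = (2, 9, 26)         # 1-based baseline / early / delayed frames
ENHANCEMENT_THRESHOLD = 0.3     # fractional peak enhancement over baseline


@dataclass(frozen=True)
class SERMap:
    """Per-voxel signal enhancement ratio with a validity mask."""

    ser: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class LesionStats:
    lesion_id: int
    n_voxels: int
    mean: float
    median: float
    iqr: float


@dataclass(frozen=True)
class TumorSummary:
    """Per-lesion and patient-level histogram summary of one metric.

    ``mean``/``median``/``iqr`` are the patient-level values: for a single
    lesion they equal that lesion's statistics, for multiple lesions the
    unweighted mean of per-lesion values. ``iqr`` is the width
    (75th - 25th percentile) of the voxel-value histogram.
    """

    metric: str
    lesions: tuple[LesionStats, ...]
    mean: float
    median: float
    iqr: float
    kio_fraction: float | None = None


def mask_unenhanced(dce, roi_mask, threshold: float = ENHANCEMENT_THRESHOLD,
                    baseline_frames=(0, 1), injection_frame: int = 3):
    """Quality-control mask excluding unenhanced voxels within the ROI.

    A voxel is retained iff
    (peak post-injection signal - baseline) / baseline >= threshold,
    with baseline the mean over pre-injection frames.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    dce = np.asarray(dce, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    base = dce[..., list(baseline_frames)].mean(axis=-1)
    peak = dce[..., injection_frame - 1:].max(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        enh = np.where(base > 0, (peak - base) / base, 0.0)
    return roi & (enh >= threshold)


def compute_ser(dce, enhancing_mask, early_frame: int = SER_FRAMES[1],
                baseline_frame: int = SER_FRAMES[0],
                late_frame: int = SER_FRAMES[2]) -> SERMap:
    """Signal enhancement ratio (S_early - S_base)/(S_late - S_base).

    Frame arguments are 1-based (defaults 2/9/26 on the 15 s grid,
    i.e. ~110 s and ~380 s after injection). Voxels whose late-phase
    enhancement denominator is below a machine-epsilon-scaled guard are
    flagged invalid instead of producing infinities.
    """
    dce = np.asarray(dce, dtype=float)
    mask = np.asarray(enhancing_mask, dtype=bool)
    n_frames = dce.shape[-1]
    for f in (baseline_frame, early_frame, late_frame):
        if not 1 <= f <= n_frames:
            raise ValueError(f"frame {f} outside dynamic series of {n_frames}")
    s_base = dce[..., baseline_frame - 1]
    s_early = dce[..., early_frame - 1]
    s_late = dce[..., late_frame - 1]
    denom = s_late - s_base
    guard = np.finfo(float).eps * np.maximum(np.abs(s_late), np.abs(s_base)) * 100
    ok = mask & (np.abs(denom) > np.maximum(guard, np.finfo(float).tiny))
    ser = np.zeros_like(denom)
    ser[ok] = (s_early[ok] - s_base[ok]) / denom[ok]
    return SERMap(ser=ser, valid=ok)


def ser_frames_for_grid(frame_interval: float, injection_frame: int = 3,
                        early_delay: float = 90.0, late_delay: float = 345.0):
    """Map the nominal early/late post-injection delays to nearest frames.

    Returns 1-based (baseline, early, late) frame indices for an arbitrary
    frame spacing. The default delays place the early frame ~1.5 min and the
    delayed frame ~6 min after injection, measured at frame starts, which on
    the 15 s grid reproduces the canonical frames (2, 9, 26).
    """
    t_inj = (injection_frame - 1) * frame_interval
    early = int(round((t_inj + early_delay) / frame_interval)) + 1
    late = int(round((t_inj + late_delay) / frame_interval)) + 1
    return injection_frame - 1, early, late


def filter_kio(kio_map, lo: float = KIO_FILTER_RANGE[0],
               hi: float = KIO_FILTER_RANGE[1], roi_mask=None):
    """Plausibility filter for fitted k_io values.

    Voxels are retained iff lo < k_io < hi (strict: values at or beyond the
    endpoints correspond to implausibly slow exchange or to effectively
    fast-exchange-limit behavior). The fraction is taken over ``roi_mask``
    when given (the enhancing-ROI voxel count), else over all voxels.

    Returns
    -------
    (retained_mask, kio_fraction)
    """
    kio = np.asarray(kio_map, dtype=float)
    retained = (kio > lo) & (kio < hi)
    if roi_mask is not None:
        roi = np.asarray(roi_mask, dtype=bool)
        retained = retained & roi
        denom = int(roi.sum())
    else:
        denom = kio.size
    fraction = float(retained.sum()) / denom if denom else 0.0
    return retained, fraction


def sum_cao_map(ct_map_t, ve_map, frame_interval: float | None = None):
    """Time-summed EES concentration Sigma[CA_o] per voxel.

    [CA_o](t) = C_t(t)/v_e; the default integrates with the frame spacing
    (units mM.s, grid-independent); pass ``frame_interval=None``-> plain
    frame sum (units mM) reproducing a literal summation over frames.
    """
    ct = np.asarray(ct_map_t, dtype=float)
    ve = np.asarray(ve_map, dtype=float)
    if np.any(ve <= 0):
        raise ValueError("ve must be > 0 on evaluated voxels")
    cao_sum = (ct / ve[..., None]).sum(axis=-1)
    if frame_interval is not None:
        cao_sum = cao_sum * frame_interval
    return cao_sum


def _quantile(values, p):
    """Linear interpolation of order statistics at position 1 + p(n-1)."""
    return float(np.quantile(values, p, method="linear"))


def summarize_metric(metric_map, lesion_masks, metric: str = "",
                     valid=None, kio_fraction: float | None = None) -> TumorSummary:
    """Histogram summary (mean/median/iqr) of a voxel metric per lesion.

    Parameters
    ----------
    metric_map : ndarray
        Voxel metric values on the grid.
    lesion_masks : boolean array or sequence of boolean arrays
        One mask per lesion. The patient-level value is the unweighted mean
        of per-lesion values when several lesions are present.
    valid : boolean array, optional
        Additional per-voxel validity restriction (e.g. fit convergence).
    """
    metric_map = np.asarray(metric_map, dtype=float)
    if isinstance(lesion_masks, np.ndarray) and lesion_masks.dtype == bool \
            and lesion_masks.shape == metric_map.shape:
        lesion_masks = [lesion_masks]
    stats = []
    for lesion_id, mask in enumerate(lesion_masks):
        mask = np.asarray(mask, dtype=bool)
        if valid is not None:
            mask = mask & np.asarray(valid, dtype=bool)
        vals = metric_map[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"lesion {lesion_id}: no valid voxels")
        stats.append(LesionStats(
            lesion_id=lesion_id, n_voxels=int(vals.size),
            mean=float(vals.mean()), median=_quantile(vals, 0.5),
            iqr=_quantile(vals, 0.75) - _quantile(vals, 0.25)))
    return TumorSummary(
        metric=metric, lesions=tuple(stats),
        mean=float(np.mean([s.mean for s in stats])),
        median=float(np.mean([s.median for s in stats])),
        iqr=float(np.mean([s.iqr for s in stats])),
        kio_fraction=kio_fraction)
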