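"""B1-corrected variable-flip-angle (VFA) R1 mapping.

The spoiled gradient-recalled echo (SPGR) steady-state signal

    S(alpha) = S0 * (1 - E) * sin(alpha) / (1 - cos(alpha) * E),
    E = exp(-TR * R1)

is fitted voxel-by-voxel over (R1, S0) against signals acquired at several
nominal flip angles. A B1 ratio map (actual/prescribed flip angle; 1.0 means
perfect calibration) replaces each nominal angle with the angle actually
delivered. Per-angle vendor intensity scaling factors are divided out before
fitting. Fitting is seeded by the standard DESPOT1 linearization
(S/sin(alpha) vs S/tan(alpha)) and refined by bounded nonlinear least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .protocol import AcquisitionProtocol

__all__ = [
    "VFASeries",
    "B1RatioMap",
    "R1Map",
    "spgr_signal",
    "spgr_inverse",
    "apply_scale_correction",
    "fit_vfa_r1",
]

R1_BOUNDS = (1e-6, 20.0)  # s^-1; fitted R1 constrained to this interval


def spgr_signal(s0, r1, alpha_deg, tr):
    """SPGR steady-state signal.

    Parameters
    ----------
    s0 : array-like
        Equilibrium signal scale (fully-relaxed 90-degree signal).
    r1 : array-like
        Longitudinal relaxation rate, s^-1. r1 = 0 yields zero signal
        (no recovery between excitations).
    alpha_deg : array-like
        Flip angle in degrees, in (0, 90].
    tr : float
        Repetition time, seconds.

    Broadcasting applies across all array arguments.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    alpha_deg = np.asarray(alpha_deg, dtype=float)
    if np.any(alpha_deg <= 0) or np.any(alpha_deg > 90):
        raise ValueError("flip angle must lie in (0, 90] degrees")
    a = np.deg2rad(alpha_deg)
    e = np.exp(-tr * np.asarray(r1, dtype=float))
    return np.asarray(s0, dtype=float) * (1.0 - e) * np.sin(a) / (1.0 - np.cos(a) * e)


def spgr_inverse(signal, s0, alpha_deg, tr, r1_clip=(1e-4, 50.0)):
    """Invert the SPGR equation for R1 given the signal scale ``s0``.

    Noisy signals that leave the physically attainable range are clipped to
    ``r1_clip`` rather than raising, since the inversion is used framewise on
    measured dynamic data.
    """
    a = np.deg2rad(float(alpha_deg))
    y = np.asarray(signal, dtype=float) / float(s0)
    sin_a, cos_a = np.sin(a), np.cos(a)
    denom = sin_a - y * cos_a
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (sin_a - y) / denom
    lo = np.exp(-tr * r1_clip[1])
    hi = np.exp(-tr * r1_clip[0])
    e = np.clip(np.nan_to_num(e, nan=hi), lo, hi)
    return -np.log(e) / tr


@dataclass(frozen=True)
class VFASeries:
    """Signals at each flip angle plus per-angle intensity scale factors.

    ``signals`` has the flip-angle axis last: shape (..., n_angles).
    """

    signals: np.ndarray
    angles: tuple[float, ...]
    scale_factors: tuple[float, ...] | None = None

    def __post_init__(self):
        signals = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "signals", signals)
        if signals.shape[-1] != len(self.angles):
            raise ValueError("need one signal volume per flip angle")
        if self.scale_factors is not None:
            if len(self.scale_factors) != len(self.angles):
                raise ValueError("need one scale factor per flip angle")
            if any(f <= 0 for f in self.scale_factors):
                raise ValueError("scale factors must be positive")


@dataclass(frozen=True)
class B1RatioMap:
    """Per-voxel multiplicative deviation of actual from prescribed flip angle."""

    ratio: np.ndarray

    def __post_init__(self):
        ratio = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "ratio", ratio)
        if np.any(ratio <= 0):
            raise ValueError("B1 ratio must be positive everywhere")


@dataclass(frozen=True)
class R1Map:
    """Fitted R1 (s^-1), signal scale, RMS residual and validity per voxel."""

    r1: np.ndarray
    s0: np.ndarray
    residual: np.ndarray
    valid: np.ndarray


def apply_scale_correction(vfa: VFASeries) -> VFASeries:
    """Divide out per-angle vendor intensity scaling factors.

    Unit factors leave the data unchanged. After correction the stored
    factors are reset to one so the operation is idempotent.
    """
    if vfa.scale_factors is None:
        raise ValueError("scale_factors missing; nothing to correct")
    factors = np.asarray(vfa.scale_factors, dtype=float)
    corrected = vfa.signals / factors
    return replace(vfa, signals=corrected,
                   scale_factors=tuple(1.0 for _ in vfa.angles))


def _despot_init(signals, angles_rad, tr):
    """Linearized SPGR (DESPOT1) estimate of (R1, S0) per voxel.

    signals: (n_vox, n_angles); angles_rad: (n_vox, n_angles).
    """
    y = signals / np.sin(angles_rad)
    x = signals / np.tan(angles_rad)
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    var = ((x - xm) ** 2).sum(axis=1)
    cov = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var > 0, cov / var, np.nan)
    slope = np.clip(np.nan_to_num(slope, nan=0.5), 1e-9, 1 - 1e-12)
    r1 = np.clip(-np.log(slope) / tr, *R1_BOUNDS)
    intercept = ym[:, 0] - slope * xm[:, 0]
    s0 = np.maximum(intercept / (1.0 - slope), 1e-12)
    return r1, s0


def fit_vfa_r1(vfa: VFASeries, b1: B1RatioMap,
               protocol: AcquisitionProtocol, mask=None,
               refine: bool = True) -> R1Map:
    """Voxelwise nonlinear (R1, S0) fit of the SPGR equation to VFA data.

    Each voxel's nominal flip angles are multiplied by its B1 ratio before
    fitting. Voxels with all-zero or non-finite signals, or for which the
    optimizer fails, are flagged invalid (never silently dropped).

    Parameters
    ----------
    vfa : VFASeries
        Scale-corrected signals; if scale factors differ from one they are
        applied first.
    b1 : B1RatioMap
        Ratio map broadcastable to the voxel grid of ``vfa``.
    mask : ndarray of bool, optional
        Restrict fitting to these voxels (others marked invalid).
    refine : bool
        If False, return the linearized DESPOT1 estimate only.
    """
    if vfa.scale_factors is not None and any(f != 1.0 for f in vfa.scale_factors):
        vfa = apply_scale_correction(vfa)
    grid_shape = vfa.signals.shape[:-1]
    n_angles = len(vfa.angles)
    if n_angles < 2:
        raise ValueError("need at least two flip angles")
    signals = vfa.signals.reshape(-1, n_angles)
    ratio = np.broadcast_to(np.asarray(b1.ratio, dtype=float), grid_shape).reshape(-1)
    n_vox = signals.shape[0]
    fit_idx = np.arange(n_vox)
    if mask is not None:
        fit_idx = fit_idx[np.asarray(mask, dtype=bool).reshape(-1)]

    nominal = np.deg2rad(np.asarray(vfa.angles, dtype=float))
    angles_rad = ratio[:, None] * nominal[None, :]

    r1 = np.zeros(n_vox)
    s0 = np.zeros(n_vox)
    residual = np.full(n_vox, np.inf)
    valid = np.zeros(n_vox, dtype=bool)

    sig_fit = signals[fit_idx]
    ang_fit = angles_rad[fit_idx]
    finite = np.isfinite(sig_fit).all(axis=1) & (np.abs(sig_fit).sum(axis=1) > 0)
    r1_init, s0_init = _despot_init(np.where(finite[:, None], sig_fit, 1.0), ang_fit,
                                    protocol.tr_vfa)
    tr = protocol.tr_vfa

    for j, i in enumerate(fit_idx):
        if not finite[j]:
            continue
        sig = sig_fit[j]
        sin_a = np.sin(ang_fit[j])
        cos_a = np.cos(ang_fit[j])

        def resid(p):
            e = np.exp(-tr * p[0])
            return p[1] * (1 - e) * sin_a / (1 - cos_a * e) - sig

        try:
            sol = least_squares(
                resid, x0=[r1_init[j], s0_init[j]],
                bounds=([R1_BOUNDS[0], 0.0], [R1_BOUNDS[1], np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200,
            ) if refine else None
        except ValueError:
            continue
        if refine:
            if not sol.success:
                continue
            r1[i], s0[i] = sol.x
            residual[i] = float(np.sqrt(np.mean(sol.fun**2)))
        else:
            r1[i], s0[i] = r1_init[j], s0_init[j]
            residual[i] = float(np.sqrt(np.mean(resid([r1[i], s0[i]]) ** 2)))
        valid[i] = np.isfinite(residual[i]) and r1[i] > 0

    return R1Map(
        r1=r1.reshape(grid_shape),
        s0=s0.reshape(grid_shape),
        residual=residual.reshape(grid_shape),
        valid=valid.reshape(grid_shape),
    )
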