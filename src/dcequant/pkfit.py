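"""Inverse pharmacokinetic modeling of dynamic signal curves.

``fit_tm`` fits the Tofts model (Ktrans, ve) and ``fit_ssm`` the
shutter-speed model (Ktrans, ve, k_io) by bounded nonlinear least squares on
the composed forward model Kety -> R1(t) -> SPGR signal, with the signal
scale calibrated on the pre-injection baseline frames. ``estimate_bat``
aligns the arterial input to a tissue curve by minimizing the residual of
the linearized Tofts system over a bolus-arrival-time shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .aif import AIFCurve
from .kinetics import (calibrate_s0, concentration_from_signal, fxl_r1,
                       fxr_r1, kety_concentration, signal_from_r1)
from .protocol import AcquisitionProtocol

__all__ = ["PKFitResult", "fit_tm", "fit_ssm", "roi_average_curve",
           "estimate_bat"]

KTRANS_BOUNDS = (0.0, 5.0)      # min^-1
VE_BOUNDS = (1e-3, 1.0)
KIO_BOUNDS = (1e-3, 1000.0)     # s^-1; generous ceiling so fits rarely stop
                                # at the fast-exchange boundary prematurely

#: Fixed SSM start list (ktrans min^-1, ve, kio s^-1); deterministic
#: multi-start mitigates the local minima of the exchange model.
SSM_STARTS = ((0.05, 0.2, 1.0), (0.3, 0.4, 3.0), (1.0, 0.6, 10.0))
TM_START = (0.1, 0.3)

def _at_bound(ktrans, ve, kio=None):
    """True when a fitted parameter sits essentially on a search bound.

    Lower bounds are compared multiplicatively (k_io and ve spans are
    log-scaled), upper bounds within 1%. A Ktrans of ~0 is a meaningful
    interior answer (no transfer), not a boundary stop.
    """
    hit = ktrans >= 0.99 * KTRANS_BOUNDS[1]
    hit = hit or ve <= 1.05 * VE_BOUNDS[0] or ve >= 0.999 * VE_BOUNDS[1]
    if kio is not None:
        hit = hit or kio <= 1.05 * KIO_BOUNDS[0] or kio >= 0.99 * KIO_BOUNDS[1]
    return bool(hit)


@dataclass(frozen=True)
class PKFitResult:
    """Fitted pharmacokinetic parameters for one voxel or ROI curve.

    ``kep`` is derived as ktrans/ve exactly. ``kio`` is None for the Tofts
    model. ``at_bound`` flags convergence onto a parameter bound (within 1%
    of the bound range), which for k_io signals water-exchange insensitivity.
    """

    ktrans: float
    ve: float
    s0: float
    bat: float
    rss: float
    converged: bool
    kio: float | None = None
    at_bound: bool = False

    @property
    def kep(self) -> float:
        return self.ktrans / self.ve


def _prepare(voxel_curve, aif, protocol, bat):
    curve = np.asarray(voxel_curve, dtype=float)
    if curve.shape != (protocol.n_frames,):
        raise ValueError("curve length must equal protocol.n_frames")
    if len(protocol.baseline_frames) < 2:
        raise ValueError("need at least 2 pre-injection frames")
    aif_sh = aif.shifted(bat) if bat != 0.0 else aif
    return curve, aif_sh, protocol.frame_times


def fit_tm(voxel_curve, r10, aif: AIFCurve, protocol: AcquisitionProtocol,
           bat: float = 0.0) -> PKFitResult:
    """Tofts-model (FXL) fit of (Ktrans, ve) to one dynamic signal curve.

    Parameters
    ----------
    voxel_curve : (n_frames,) array
        Measured signal.
    r10 : float
        Pre-contrast R1, s^-1 (fixed literature value or VFA-measured).
    bat : float
        Additional bolus arrival delay applied to the AIF, seconds.
    """
    curve, aif_sh, times = _prepare(voxel_curve, aif, protocol, bat)
    s0 = float(calibrate_s0(curve, r10, protocol))
    rel = protocol.relaxivity_r1

    def resid(p):
        ct = kety_concentration(p[0], p[1], aif_sh, times)
        return signal_from_r1(fxl_r1(ct, r10, rel), s0, protocol) - curve

    sol = least_squares(resid, x0=TM_START,
                        bounds=([KTRANS_BOUNDS[0], VE_BOUNDS[0]],
                                [KTRANS_BOUNDS[1], VE_BOUNDS[1]]),
                        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400)
    ktrans, ve = sol.x
    return PKFitResult(ktrans=float(ktrans), ve=float(ve), s0=s0, bat=bat,
                       rss=float(np.sum(sol.fun**2)), converged=bool(sol.success),
                       kio=None, at_bound=_at_bound(ktrans, ve))


def fit_ssm(voxel_curve, r10, aif: AIFCurve, protocol: AcquisitionProtocol,
            bat: float = 0.0) -> PKFitResult:
    """Shutter-speed-model (FXR) fit of (Ktrans, ve, k_io).

    Pre-contrast intra- and extracellular R1 are both set to ``r10`` (no
    compartmental difference before contrast), so the fixed-R1,0 convention
    remains well defined. Three fixed starts are run and the lowest residual
    kept; ``at_bound`` is set when any parameter lands within 1% of a bound.
    """
    curve, aif_sh, times = _prepare(voxel_curve, aif, protocol, bat)
    s0 = float(calibrate_s0(curve, r10, protocol))
    rel = protocol.relaxivity_r1

    def resid(p):
        ct = kety_concentration(p[0], p[1], aif_sh, times)
        r1_t = fxr_r1(ct, p[1], p[2], r10, r10, rel)
        return signal_from_r1(r1_t, s0, protocol) - curve

    lo = [KTRANS_BOUNDS[0], VE_BOUNDS[0], KIO_BOUNDS[0]]
    hi = [KTRANS_BOUNDS[1], VE_BOUNDS[1], KIO_BOUNDS[1]]
    best = None
    for start in SSM_STARTS:
        sol = least_squares(resid, x0=start, bounds=(lo, hi),
                            x_scale=[0.1, 0.1, 1.0],
                            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=600)
        if best is None or np.sum(sol.fun**2) < np.sum(best.fun**2) - 1e-30:
            best = sol
    ktrans, ve, kio = best.x
    return PKFitResult(ktrans=float(ktrans), ve=float(ve), s0=s0, bat=bat,
                       rss=float(np.sum(best.fun**2)),
                       converged=bool(best.success),
                       kio=float(kio), at_bound=_at_bound(ktrans, ve, kio))


def roi_average_curve(dce, roi_mask):
    """Framewise arithmetic mean signal over all masked voxels.

    ``dce`` has the frame axis last (..., n_frames); multi-slice ROIs are
    concatenated implicitly since the mean runs over every masked voxel.
    """
    dce = np.asarray(dce, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != dce.shape[:-1]:
        raise ValueError("mask shape must match the voxel grid of dce")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return dce[mask].mean(axis=0)


def _linearized_tm_rss(ct, cum_cp, times):
    """Residual of the linearized Tofts system by linear least squares.

    Solves C_t(t) = Ktrans * int C_p - kep * int C_t for (Ktrans, kep) on
    concentration data; returns the residual sum of squares.
    """
    dt = np.diff(times)
    cum_ct = np.concatenate([[0.0], np.cumsum(0.5 * (ct[1:] + ct[:-1]) * dt)])
    design = np.column_stack([cum_cp, -cum_ct])
    coef, *_ = np.linalg.lstsq(design, ct, rcond=None)
    r = design @ coef - ct
    return float(r @ r)


def estimate_bat(voxel_curve, aif: AIFCurve, protocol: AcquisitionProtocol,
                 r10: float, enhancement_threshold: float = 0.3,
                 grid_lo_frames: float = -2.0, grid_hi_frames: float = 6.0,
                 grid_step_frames: float = 0.25) -> float:
    """Bolus arrival time of a tissue curve relative to the AIF, seconds.

    The curve is converted to concentration (fixed-R1,0 SPGR inversion), and
    for each candidate AIF shift on a coarse grid (default -2 to +6 frame
    intervals in quarter-frame steps) the linearized Tofts system is solved
    by linear least squares; the best candidate is refined by a bounded
    derivative-free line search confined to +/- one coarse step.

    Raises
    ------
    ValueError
        "BAT undefined" when the curve does not enhance above
        ``enhancement_threshold`` (fractional peak enhancement over baseline).
    """
    curve = np.asarray(voxel_curve, dtype=float)
    times = protocol.frame_times
    base_idx = list(protocol.baseline_frames)
    base = curve[base_idx].mean()
    post = curve[protocol.injection_frame - 1:]
    if base <= 0 or (post.max() - base) / base < enhancement_threshold:
        raise ValueError("BAT undefined: curve does not enhance")

    ct = concentration_from_signal(curve, r10, protocol)
    dt_frame = protocol.frame_interval
    step = grid_step_frames * dt_frame
    candidates = np.arange(grid_lo_frames * dt_frame,
                           grid_hi_frames * dt_frame + 0.5 * step, step)

    from scipy.integrate import cumulative_trapezoid

    # integrate the AIF on its own (fine) grid: the bolus peak is far
    # sharper than the frame spacing
    cum_cp_fine = cumulative_trapezoid(aif.cp, aif.times, initial=0.0)

    def rss_at(delta):
        cum_cp = np.interp(times - delta, aif.times, cum_cp_fine, left=0.0)
        return _linearized_tm_rss(ct, cum_cp, times)

    rss = np.array([rss_at(d) for d in candidates])
    best = int(np.argmin(rss))
    lo = candidates[max(best - 1, 0)]
    hi = candidates[min(best + 1, len(candidates) - 1)]
    if hi > lo:
        sol = minimize_scalar(rss_at, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-3})
        if sol.fun <= rss[best]:
            return float(sol.x)
    return float(candidates[best])
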