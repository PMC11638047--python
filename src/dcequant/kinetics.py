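"""Forward pharmacokinetic signal models.

Concentration kinetics follow the Kety/Tofts rate law

    C_t(t) = Ktrans * int_0^t C_p(tau) exp(-kep (t - tau)) dtau,
    kep = Ktrans / ve,

evaluated by exact convolution of a piecewise-linear AIF with the
exponential kernel. Two longitudinal relaxation models convert tissue
concentration to R1(t):

* FXL (fast-exchange limit, Tofts model): R1(t) = R1_0 + r1 * C_t(t) —
  water exchange is fast enough that the tissue relaxes mono-exponentially
  at the population-average rate.
* FXR (fast-exchange regime, shutter-speed model): transcytolemmal water
  exchange at finite rate k_io makes relaxation bi-exponential; the observed
  rate is taken as the smaller eigenvalue of the two-site exchange matrix.

The SPGR readout then maps R1(t) to signal at the dynamic flip angle/TR.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .aif import AIFCurve
from .protocol import AcquisitionProtocol
from .relaxometry import spgr_signal, spgr_inverse

__all__ = [
    "kety_concentration",
    "fxl_r1",
    "fxr_r1",
    "signal_from_r1",
    "calibrate_s0",
    "concentration_from_signal",
]


def _phi1(x):
    """(1 - exp(-x)) / x, series-stabilized near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-5
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x / 2.0 + x * x / 6.0, -np.expm1(-safe) / safe)
    return out


def _phi2(x):
    """(1 - phi1(x)) / x, series-stabilized near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    out = np.where(small, 0.5 - x / 6.0 + x * x / 24.0, (1.0 - _phi1(safe)) / safe)
    return out


def _exp_conv_uniform(cp, dt, kep):
    """y_k = int_0^{t_k} cp(tau) exp(-kep (t_k - tau)) dtau on a uniform grid.

    Exact for piecewise-linear ``cp``. kep is a scalar (per-voxel callers
    loop). Uses the one-pole recursion y_{k+1} = E y_k + I_k implemented with
    scipy.signal.lfilter for speed.
    """
    x = kep * dt
    e = np.exp(-x)
    a = cp[:-1]
    b = np.diff(cp) / dt
    seg = dt * (a * _phi1(x) + b * dt * _phi2(x))
    y = np.empty_like(cp)
    y[0] = 0.0
    y[1:] = lfilter([1.0], [1.0, -e], seg)
    return y


def kety_concentration(ktrans, ve, aif: AIFCurve, times, dt: float = 1.0):
    """Tissue concentration C_t(t) in mM under the Kety/Tofts rate law.

    Parameters
    ----------
    ktrans : float or (n,) array
        Volume transfer constant, min^-1 (>= 0).
    ve : float or (n,) array
        EES volume fraction in (0, 1].
    aif : AIFCurve
        Plasma input; resampled internally to a uniform grid of spacing
        ``dt`` seconds, on which the convolution is exact for the
        piecewise-linear interpolant.
    times : array-like
        Output sample times, seconds.

    Returns
    -------
    ndarray
        Shape (n_times,) for scalar inputs, else (n, n_times).
    """
    ktrans = np.asarray(ktrans, dtype=float)
    ve = np.asarray(ve, dtype=float)
    if np.any(ktrans < 0):
        raise ValueError("ktrans must be >= 0")
    if np.any(ve <= 0) or np.any(ve > 1):
        raise ValueError("ve must lie in (0, 1]")
    times = np.asarray(times, dtype=float)
    scalar = ktrans.ndim == 0 and ve.ndim == 0
    ktrans_v, ve_v = np.broadcast_arrays(np.atleast_1d(ktrans), np.atleast_1d(ve))

    t_end = max(times.max(), aif.times.max())
    grid = np.arange(0.0, t_end + dt, dt)
    cp = aif.resampled(grid)

    kep_s = (ktrans_v / ve_v) / 60.0  # s^-1
    out = np.zeros((ktrans_v.size, times.size))
    for i in range(ktrans_v.size):
        if ktrans_v[i] == 0.0:
            continue
        y = _exp_conv_uniform(cp, dt, kep_s[i])
        out[i] = (ktrans_v[i] / 60.0) * np.interp(times, grid, y)
    return out[0] if scalar else out


def fxl_r1(ct, r10, relaxivity):
    """Fast-exchange-limit R1(t) = R1_0 + r1 * C_t(t)."""
    if np.any(np.asarray(r10) <= 0):
        raise ValueError("r10 must be > 0")
    return np.asarray(r10) + relaxivity * np.asarray(ct, dtype=float)


def fxr_r1(ct, ve, kio, r1i, r1o0, relaxivity):
    """Fast-exchange-regime (shutter-speed) R1(t).

    The longitudinal magnetization of the intra-/extracellular two-site
    exchange system relaxes bi-exponentially; in the FXR the observed
    (slowly relaxing) component carries rate

        R1 = (R1i + kio + R1o + koi)/2
             - sqrt((R1i + kio - R1o - koi)^2 + 4 kio koi)/2

    with R1o(t) = R1o_0 + r1 * C_t(t)/ve, water populations p_o = ve,
    p_i = 1 - ve, and detailed balance koi = kio * p_i / p_o.

    Parameters
    ----------
    ct : array-like
        Tissue concentration C_t(t), mM.
    ve : float or array
        EES volume fraction in (0, 1].
    kio : float or array
        Cellular water efflux rate, s^-1, > 0.
    r1i, r1o0 : float or array
        Pre-contrast intracellular and extracellular R1, s^-1.
    relaxivity : float
        CA relaxivity, mM^-1 s^-1 (acts on the EES concentration C_t/ve).
    """
    ve = np.asarray(ve, dtype=float)
    kio = np.asarray(kio, dtype=float)
    if np.any(kio <= 0):
        raise ValueError("kio must be > 0")
    if np.any(ve <= 0) or np.any(ve > 1):
        raise ValueError("ve must lie in (0, 1]")
    ct = np.asarray(ct, dtype=float)
    r1o = np.asarray(r1o0, dtype=float) + relaxivity * ct / ve
    koi = kio * (1.0 - ve) / ve
    s = np.asarray(r1i, dtype=float) + kio + r1o + koi
    d = np.asarray(r1i, dtype=float) + kio - r1o - koi
    return 0.5 * s - 0.5 * np.sqrt(d * d + 4.0 * kio * koi)


def signal_from_r1(r1_t, s0, protocol: AcquisitionProtocol):
    """Framewise SPGR signal at the dynamic flip angle and TR."""
    return spgr_signal(s0, r1_t, protocol.fa_dce, protocol.tr_dce)


def calibrate_s0(measured_curve, r10, protocol: AcquisitionProtocol,
                 baseline_frames=None):
    """Signal scale S0 such that modeled pre-injection frames match data.

    The mean of the measured pre-injection frames is divided by the unit-S0
    SPGR signal at R1_0, so that by construction the mean modeled baseline
    equals the mean measured baseline.
    """
    measured_curve = np.asarray(measured_curve, dtype=float)
    idx = list(protocol.baseline_frames if baseline_frames is None else baseline_frames)
    if len(idx) < 1:
        raise ValueError("need at least one baseline frame")
    base = measured_curve[..., idx].mean(axis=-1)
    unit = spgr_signal(1.0, r10, protocol.fa_dce, protocol.tr_dce)
    return base / unit


def concentration_from_signal(signal_curve, r10, protocol: AcquisitionProtocol,
                              baseline_frames=None):
    """Convert a dynamic signal curve to C_t(t) via SPGR inversion.

    Uses a fixed pre-contrast R1_0 (the fixed-R1,0-first convention): S0 is
    calibrated on the baseline frames, the SPGR equation is inverted
    framewise for R1(t), and C_t = (R1 - R1_0)/r1 under the FXL assumption.
    """
    s0 = calibrate_s0(signal_curve, r10, protocol, baseline_frames)
    r1_t = spgr_inverse(signal_curve, s0, protocol.fa_dce, protocol.tr_dce)
    return (r1_t - r10) / protocol.relaxivity_r1
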