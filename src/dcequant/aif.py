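"""Population arterial input function (AIF).

A directly measured patient AIF is rarely available in breast DCE-MRI; a
population-averaged plasma concentration curve C_p(t) is used instead. Here
the parametric form of Parker et al. (MRM 2006) serves as the population
curve: a pair of Gaussians describing the first- and second-pass bolus peaks
plus a sigmoid-modulated exponential washout tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AIFCurve", "population_aif", "PARKER_PARAMS"]

#: Parker population parameters. Amplitudes in mM.min (Gaussians) and mM
#: (tail); centers/widths in minutes; rates in 1/min.
PARKER_PARAMS: dict[str, float] = {
    "a1": 0.809,
    "a2": 0.330,
    "t1": 0.17046,
    "t2": 0.365,
    "sigma1": 0.0563,
    "sigma2": 0.132,
    "alpha": 1.050,
    "beta": 0.1685,
    "s": 38.078,
    "tau": 0.483,
}


@dataclass(frozen=True)
class AIFCurve:
    """Sampled plasma concentration curve.

    Attributes
    ----------
    times : ndarray
        Sample times, seconds, strictly increasing.
    cp : ndarray
        Plasma contrast concentration, mM; zero before ``bat_shift``.
    bat_shift : float
        Bolus onset time in seconds; cp(t) = 0 for t < bat_shift.
    """

    times: np.ndarray
    cp: np.ndarray
    bat_shift: float = 0.0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        cp = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "cp", cp)
        if times.ndim != 1 or times.shape != cp.shape:
            raise ValueError("times and cp must be matching 1-D arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(cp < -1e-12):
            raise ValueError("cp must be non-negative")

    def shifted(self, delta: float) -> "AIFCurve":
        """Return the same curve with bolus onset delayed by ``delta`` s."""
        cp = np.interp(self.times - delta, self.times, self.cp, left=0.0)
        return AIFCurve(self.times, cp, bat_shift=self.bat_shift + delta)

    def resampled(self, times) -> np.ndarray:
        """cp interpolated at arbitrary times (0 before support)."""
        return np.interp(np.asarray(times, dtype=float), self.times, self.cp,
                         left=0.0)


def parker_cp(t_minutes, params: dict[str, float] | None = None) -> np.ndarray:
    """Evaluate the Parker functional form at times given in minutes."""
    p = dict(PARKER_PARAMS)
    if params:
        p.update(params)
    t = np.asarray(t_minutes, dtype=float)
    gauss = np.zeros_like(t)
    for a, mu, sig in ((p["a1"], p["t1"], p["sigma1"]),
                       (p["a2"], p["t2"], p["sigma2"])):
        gauss = gauss + a / (sig * np.sqrt(2 * np.pi)) * np.exp(
            -((t - mu) ** 2) / (2 * sig**2))
    tail = p["alpha"] * np.exp(-p["beta"] * t) / (1 + np.exp(-p["s"] * (t - p["tau"])))
    return gauss + tail


def population_aif(times, params: dict[str, float] | None = None,
                   bat_shift: float = 0.0) -> AIFCurve:
    """Build the population AIF sampled at ``times`` (seconds).

    The curve is zero before ``bat_shift`` (bolus onset); the parametric
    form is evaluated on the elapsed time since onset.

    Parameters
    ----------
    times : array-like
        Non-negative, strictly increasing sample times in seconds.
    params : dict, optional
        Overrides for the Parker parameters (see ``PARKER_PARAMS``).
    bat_shift : float
        Bolus onset in seconds.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D array")
    t_rel_min = (times - bat_shift) / 60.0
    cp = np.where(t_rel_min >= 0, parker_cp(np.maximum(t_rel_min, 0.0), params), 0.0)
    cp = np.maximum(cp, 0.0)
    return AIFCurve(times, cp, bat_shift=bat_shift)
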