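"""Acquisition protocol metadata shared by all signal equations.

Default values correspond to a 3T spoiled-gradient-echo breast protocol:
variable-flip-angle (VFA) R1 mapping at 3/9/15 degrees and a dynamic series
of 32 frames at 15 s temporal resolution, 10 degree flip angle, contrast
injection starting at the third frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, flip-angle and relaxivity context for SPGR signal modeling.

    Parameters
    ----------
    tr_vfa : float
        Repetition time of the VFA scan, seconds.
    vfa_angles : tuple of float
        Nominal VFA flip angles, degrees.
    tr_dce, fa_dce : float
        Repetition time (s) and flip angle (degrees) of the dynamic scan.
    frame_interval : float
        Dynamic frame spacing, seconds.
    n_frames : int
        Number of dynamic frames.
    injection_frame : int
        1-based index of the frame at whose *start* the contrast agent is
        injected; frames before it are pre-contrast baseline.
    relaxivity_r1 : float
        Contrast-agent longitudinal relaxivity, mM^-1 s^-1.
    """

    tr_vfa: float = 0.0056
    vfa_angles: tuple[float, ...] = (3.0, 9.0, 15.0)
    tr_dce: float = 0.0056
    fa_dce: float = 10.0
    frame_interval: float = 15.0
    n_frames: int = 32
    injection_frame: int = 3
    relaxivity_r1: float = 4.0

    def __post_init__(self) -> None:
        for name in ("tr_vfa", "tr_dce", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.vfa_angles:
            raise ValueError("vfa_angles must be non-empty")
        for a in (*self.vfa_angles, self.fa_dce):
            if not 0 < a < 90:
                raise ValueError(f"flip angles must lie in (0, 90) degrees, got {a}")
        if self.n_frames < 3:
            raise ValueError("need at least 3 dynamic frames")
        if self.injection_frame < 2:
            raise ValueError("injection_frame must be >= 2 (need a baseline frame)")
        if self.injection_frame > self.n_frames:
            raise ValueError("injection_frame beyond the dynamic series")
        if self.relaxivity_r1 <= 0:
            raise ValueError("relaxivity_r1 must be > 0")

    @property
    def frame_times(self):
        """Start time of each frame in seconds (frame 1 at t = 0)."""
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval

    @property
    def injection_time(self) -> float:
        """Injection time in seconds (start of ``injection_frame``)."""
        return (self.injection_frame - 1) * self.frame_interval

    @property
    def baseline_frames(self):
        """0-based indices of pre-injection frames."""
        return tuple(range(self.injection_frame - 1))
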