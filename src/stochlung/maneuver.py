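"""Through-device inhalation maneuvers and flow-profile reconstruction.

A recorded maneuver consists of four summary numbers: the inspired
volume through the device (IVC_d, L), the peak inspiratory flow (PIF_d,
L/s), the inhalation time (t_in, s) and the breath-hold time (t_bh, s).
The spirometer's raw flow trace is not available, so the simulator
reconstructs a smooth inspiratory flow profile Q(t) that reproduces all
three flow summaries exactly, appends the breath-hold (Q = 0) and a
mirrored passive exhalation of equal volume.

Two profile families cover all feasible maneuvers:

* *trapezoid* — when IVC_d/PIF_d >= t_in/2, a symmetric trapezoid with
  ramp time ``t_in − IVC_d/PIF_d`` and a plateau at PIF_d;
* *spike* — for peaky breaths (IVC_d/PIF_d < t_in/2), a linear rise
  over 0.1·t_in to PIF_d followed by an exponential decay whose time
  constant is solved so the inhaled volume equals IVC_d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SubjectLungFunction",
    "Maneuver",
    "FlowProfile",
    "InfeasibleManeuverError",
    "build_flow_profile",
    "lung_volume_trajectory",
    "geometry_scale_factor",
]

GROUPS = ("Control", "S-COPD", "AE-COPD")
DEVICES = ("Foster_pMDI", "Trimbow_pMDI", "Spiriva_Respimat")

#: slack on the ivc_d <= pif_d * t_in feasibility bound, absorbing
#: rounding in recorded inputs
FEASIBILITY_SLACK = 0.01


class InfeasibleManeuverError(ValueError):
    """Raised when the recorded summaries admit no valid flow profile."""


@dataclass(frozen=True)
class SubjectLungFunction:
    """Static lung volumes and spirometry of one subject (liters, L/s)."""

    rv: float
    tlc: float
    frc: float
    ivc_spiro: float = float("nan")
    pif_spiro: float = float("nan")
    group: str = "Control"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.rv < self.frc < self.tlc):
            raise ValueError(
                f"require 0 < rv < frc < tlc, got rv={self.rv}, "
                f"frc={self.frc}, tlc={self.tlc}")
        if np.isfinite(self.ivc_spiro) and self.ivc_spiro > self.tlc - self.rv + 0.1:
            raise ValueError("spirometric IVC exceeds TLC - RV")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class Maneuver:
    """One through-device inhalation record."""

    ivc_d: float  # L
    pif_d: float  # L/s
    t_in: float  # s
    t_bh: float  # s
    device: str = "Foster_pMDI"
    repetition: int = 1

    def __post_init__(self) -> None:
        if min(self.ivc_d, self.pif_d, self.t_in) <= 0:
            raise ValueError("ivc_d, pif_d and t_in must be positive")
        if self.t_bh < 0:
            raise ValueError("t_bh must be nonnegative")
        bound = self.pif_d * self.t_in
        if self.ivc_d > bound * (1.0 + FEASIBILITY_SLACK):
            raise InfeasibleManeuverError(
                f"infeasible maneuver: ivc_d={self.ivc_d:.3f} L exceeds "
                f"pif_d*t_in={bound:.3f} L (volume cannot be inhaled at "
                f"or below the recorded peak flow)")
        if self.device not in DEVICES:
            raise ValueError(f"unknown device {self.device!r}")
        if self.repetition not in (1, 2):
            raise ValueError("repetition must be 1 or 2")


@dataclass(frozen=True)
class FlowProfile:
    """Piecewise inspiratory flow profile with breath-hold and exhalation.

    ``flow(t)`` is >= 0 during inhalation, exactly 0 during breath-hold,
    and negative (mirrored trapezoid) during exhalation.
    ``inhaled_volume(t)`` is the running integral of the inspiratory
    phase only.
    """

    ivc_d: float
    pif_d: float
    t_in: float
    t_bh: float
    t_ex: float
    shape: str  # "trapezoid" | "spike"
    t_ramp: float = 0.0  # trapezoid ramp
    t_rise: float = 0.0  # spike rise
    tau: float = 0.0  # spike decay constant
    breakpoints: tuple = field(default=())

    @property
    def t_end_inhalation(self) -> float:
        return self.t_in

    @property
    def t_end_breath_hold(self) -> float:
        return self.t_in + self.t_bh

    @property
    def duration(self) -> float:
        return self.t_in + self.t_bh + self.t_ex

    # -- inspiratory phase -------------------------------------------------
    def _inspiratory_flow(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.shape == "trapezoid":
            r = self.t_ramp
            if r <= 0:
                q = np.full_like(t, self.pif_d)
            else:
                q = np.where(
                    t < r, self.pif_d * t / r,
                    np.where(t <= self.t_in - r, self.pif_d,
                             self.pif_d * (self.t_in - t) / r))
        else:  # spike
            q = np.where(
                t < self.t_rise, self.pif_d * t / np.maximum(self.t_rise, 1e-300),
                self.pif_d * np.exp(-(t - self.t_rise) / self.tau))
        return np.clip(q, 0.0, None)

    def inhaled_volume(self, t) -> np.ndarray:
        """Cumulative inhaled volume (L) at time t, analytic."""
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, 0.0, self.t_in)
        if self.shape == "trapezoid":
            r = self.t_ramp
            if r <= 0:
                v = self.pif_d * tc
            else:
                v_ramp = 0.5 * self.pif_d * np.minimum(tc, r) ** 2 / r
                v_plat = self.pif_d * np.clip(tc - r, 0.0, self.t_in - 2 * r)
                td = np.clip(tc - (self.t_in - r), 0.0, r)
                v_down = self.pif_d * td - 0.5 * self.pif_d * td**2 / r
                v = v_ramp + v_plat + v_down
        else:
            v_rise = 0.5 * self.pif_d * np.minimum(tc, self.t_rise) ** 2 / self.t_rise
            te = np.clip(tc - self.t_rise, 0.0, None)
            v_dec = self.pif_d * self.tau * (1.0 - np.exp(-te / self.tau))
            v = v_rise + v_dec
        return v if v.shape else float(v)

    def flow(self, t) -> np.ndarray:
        """Signed flow (L/s): + inhalation, 0 breath-hold, − exhalation."""
        scalar = np.isscalar(t) or np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        q = np.zeros_like(t)
        inh = (t >= 0) & (t <= self.t_in)
        q[inh] = self._inspiratory_flow(t[inh])
        ex = (t > self.t_end_breath_hold) & (t <= self.duration)
        if np.any(ex) and self.t_ex > 0:
            # mirrored trapezoid of equal volume
            te = t[ex] - self.t_end_breath_hold
            pif_ex = self.ivc_d / self.t_ex / (1.0 - _mirror_ramp(self.t_ex) / self.t_ex)
            r = _mirror_ramp(self.t_ex)
            qe = np.where(te < r, pif_ex * te / r,
                          np.where(te <= self.t_ex - r, pif_ex,
                                   pif_ex * (self.t_ex - te) / r))
            q[ex] = -np.clip(qe, 0.0, None)
        return float(q[0]) if scalar else q

    def exhaled_volume(self, t_since_exhalation_start) -> np.ndarray:
        """Cumulative exhaled volume (L); mirrored trapezoid, total ivc_d."""
        te = np.clip(np.asarray(t_since_exhalation_start, dtype=float), 0.0, self.t_ex)
        r = _mirror_ramp(self.t_ex)
        pif_ex = self.ivc_d / (self.t_ex - r)
        v_ramp = 0.5 * pif_ex * np.minimum(te, r) ** 2 / r
        v_plat = pif_ex * np.clip(te - r, 0.0, self.t_ex - 2 * r)
        td = np.clip(te - (self.t_ex - r), 0.0, r)
        v_down = pif_ex * td - 0.5 * pif_ex * td**2 / r
        v = v_ramp + v_plat + v_down
        return v if v.shape else float(v)


def _mirror_ramp(t_ex: float) -> float:
    # fixed 25% ramps for the passive exhalation mirror
    return 0.25 * t_ex


def build_flow_profile(m: Maneuver, exhalation_multiplier: float = 1.0) -> FlowProfile:
    """Reconstruct a flow profile reproducing (pif_d, ivc_d, t_in) exactly.

    Raises :class:`InfeasibleManeuverError` for ivc_d > pif_d*t_in
    (beyond 1 % slack).  The spike branch solves the decay constant by a
    bracketed 1-D root find to 1e-9 L on the inhaled volume.
    """
    pif, t_in = m.pif_d, m.t_in
    # records inside the 1 % feasibility slack are clamped to a rectangle
    ivc = min(m.ivc_d, pif * t_in)
    t_ex = t_in * exhalation_multiplier
    ratio = ivc / pif
    if ratio >= t_in / 2.0:
        t_ramp = t_in - ratio
        prof = FlowProfile(ivc_d=ivc, pif_d=pif, t_in=t_in, t_bh=m.t_bh,
                           t_ex=t_ex, shape="trapezoid", t_ramp=t_ramp)
        bps = ((0.0, 0.0), (t_ramp, pif), (t_in - t_ramp, pif), (t_in, 0.0))
    else:
        t_rise = 0.1 * t_in
        v_rise = 0.5 * pif * t_rise
        if ivc <= v_rise:
            # extremely peaky record: shrink the rise so a decay exists
            t_rise = ivc / pif
            v_rise = 0.5 * pif * t_rise

        def volume_err(tau: float) -> float:
            return (v_rise + pif * tau * (1.0 - np.exp(-(t_in - t_rise) / tau))
                    - ivc)

        lo, hi = 1e-9, 1e6
        tau = brentq(volume_err, lo, hi, xtol=1e-12, rtol=8.9e-16)
        prof = FlowProfile(ivc_d=ivc, pif_d=pif, t_in=t_in, t_bh=m.t_bh,
                           t_ex=t_ex, shape="spike", t_rise=t_rise, tau=tau)
        bps = ((0.0, 0.0), (t_rise, pif), (t_in, float(pif * np.exp(-(t_in - t_rise) / tau))))
    object.__setattr__(prof, "breakpoints", bps)
    assert abs(prof.inhaled_volume(t_in) - ivc) < 1e-6, "volume closure failed"
    return prof


def lung_volume_trajectory(profile: FlowProfile, lungs: SubjectLungFunction):
    """Return V(t): lung volume starting from RV (deep exhalation first).

    V is nondecreasing during inhalation, constant during breath-hold,
    and retraces during exhalation.  Warns (not fatal) if the record is
    internally inconsistent (rv + ivc_d exceeding TLC by > 0.1 L).
    """
    if lungs.rv + profile.ivc_d > lungs.tlc + 0.1:
        warnings.warn(
            f"inconsistent subject record: rv + ivc_d = "
            f"{lungs.rv + profile.ivc_d:.2f} L exceeds TLC = {lungs.tlc:.2f} L",
            stacklevel=2)

    def volume(t):
        scalar = np.isscalar(t) or np.ndim(t) == 0
        ta = np.atleast_1d(np.asarray(t, dtype=float))
        v = lungs.rv + np.asarray(
            profile.inhaled_volume(np.clip(ta, 0.0, profile.t_in)))
        ex = ta > profile.t_end_breath_hold
        if np.any(ex):
            v = np.where(ex, lungs.rv + profile.ivc_d
                         - profile.exhaled_volume(ta - profile.t_end_breath_hold), v)
        return float(v[0]) if scalar else v

    return volume


def geometry_scale_factor(v_l: float, v_ref_l: float = 4.8) -> float:
    """Isotropic airway rescaling factor (V/V_ref)^(1/3).

    Applied multiplicatively to airway lengths and diameters so the
    whole-lung volume tracks the instantaneous inflation state.
    """
    if v_l <= 0 or v_ref_l <= 0:
        raise ValueError("volumes must be positive")
    return float((v_l / v_ref_l) ** (1.0 / 3.0))
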