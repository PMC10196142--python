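"""Single-airway and extrathoracic deposition probabilities.

Closed-form deposition probabilities for the three mechanisms acting on
inhaled particles in the lung — inertial impaction at bifurcations,
gravitational settling, and Brownian diffusion — plus an empirical
single-compartment mouth–throat (extrathoracic) model.  All functions
are vectorized over numpy arrays and return probabilities in [0, 1].

Conventions
-----------
Particle diameters are *aerodynamic* diameters in µm (unit-density
convention: ``rho_p = 1 g/cm³`` unless stated otherwise).  Airway
dimensions are in cm, velocities in m/s, times in s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicsConstants",
    "ParticleTransportProperties",
    "cunningham",
    "settling_velocity",
    "diffusion_coefficient",
    "stokes_number",
    "p_impaction",
    "p_sedimentation",
    "p_diffusion",
    "p_alveolar",
    "combine_mechanisms",
    "extrathoracic_efficiency",
]


@dataclass(frozen=True)
class PhysicsConstants:
    """Gas and environment constants (body conditions by default)."""

    viscosity_air: float = 1.81e-5  # Pa s
    mean_free_path_um: float = 0.066  # µm, air at body conditions
    gravity: float = 9.81  # m/s²
    boltzmann: float = 1.380649e-23  # J/K
    temperature: float = 310.0  # K

    def __post_init__(self) -> None:
        for name in ("viscosity_air", "mean_free_path_um", "gravity",
                     "boltzmann", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONSTANTS = PhysicsConstants()


def cunningham(d_p_um, constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Cunningham slip correction factor.

    Cc = 1 + (λ/d)·(2.514 + 0.8·exp(−0.55·d/λ)) with λ the mean free
    path of air.  Approaches 1 for large particles.
    """
    d = np.asarray(d_p_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("particle diameter must be positive")
    lam = constants.mean_free_path_um
    return 1.0 + (lam / d) * (2.514 + 0.8 * np.exp(-0.55 * d / lam))


def settling_velocity(d_p_um, rho_p: float = 1.0, cc=None,
                      constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Terminal settling velocity (m/s), Stokes regime with slip.

    v_s = ρ_p g d² Cc / (18 µ).  With aerodynamic diameters use the
    default unit density.
    """
    d = np.asarray(d_p_um, dtype=float)
    if np.any(d < 0) or rho_p <= 0:
        raise ValueError("need d_p >= 0 and rho_p > 0")
    if cc is None:
        cc = np.where(d > 0, cunningham(np.where(d > 0, d, 1.0), constants), 1.0)
    d_m = d * 1e-6
    rho_si = rho_p * 1000.0
    return rho_si * constants.gravity * d_m**2 * cc / (18.0 * constants.viscosity_air)


def diffusion_coefficient(d_p_um, cc=None,
                          constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Brownian diffusion coefficient (m²/s), Stokes–Einstein with slip."""
    d = np.asarray(d_p_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("particle diameter must be positive")
    if cc is None:
        cc = cunningham(d, constants)
    d_m = d * 1e-6
    return (constants.boltzmann * constants.temperature * cc
            / (3.0 * np.pi * constants.viscosity_air * d_m))


def stokes_number(d_p_um, u_ms, d_airway_cm, rho_p: float = 1.0, cc=None,
                  constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Stokes number St = ρ_p d² Cc U / (18 µ D) of a tube flow.

    ``u_ms`` is the mean airflow speed in the parent airway (m/s) and
    ``d_airway_cm`` the parent diameter.
    """
    d = np.asarray(d_p_um, dtype=float)
    if cc is None:
        cc = cunningham(d, constants)
    d_m = d * 1e-6
    rho_si = rho_p * 1000.0
    return (rho_si * d_m**2 * cc * np.asarray(u_ms, dtype=float)
            / (18.0 * constants.viscosity_air * np.asarray(d_airway_cm, dtype=float) * 1e-2))


def p_impaction(st, branching_angle_deg):
    """Inertial impaction probability at a bifurcation (Yeh–Schum form).

    With x = θ_rad·St:  p = 1 − (2/π)·arccos(x) − (1/π)·sin(2·arccos(x))
    for x < 1, saturating at 1 otherwise.  p(St=0) = 0.
    """
    st = np.asarray(st, dtype=float)
    theta = np.deg2rad(np.asarray(branching_angle_deg, dtype=float))
    if np.any(st < 0) or np.any(theta < 0):
        raise ValueError("Stokes number and branching angle must be nonnegative")
    x = np.clip(theta * st, 0.0, 1.0)
    acos = np.arccos(x)
    p = 1.0 - (2.0 / np.pi) * acos - (1.0 / np.pi) * np.sin(2.0 * acos)
    return np.clip(np.where(theta * st >= 1.0, 1.0, p), 0.0, 1.0)


def p_sedimentation(v_s_ms, cos_gravity, t_res_s, d_airway_cm):
    """Gravitational settling probability in a tube.

    p = 1 − exp(−4 v_s |cos φ| t / (π D)) with D the tube diameter
    converted to meters and φ the angle between tube axis and gravity
    (only the component across the tube matters, hence |cos|).
    """
    t = np.asarray(t_res_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("residence time must be nonnegative")
    arg = (4.0 * np.asarray(v_s_ms, dtype=float) * np.abs(np.asarray(cos_gravity, dtype=float)) * t
           / (np.pi * np.asarray(d_airway_cm, dtype=float) * 1e-2))
    return 1.0 - np.exp(-arg)


def p_diffusion(d_diff_m2s, t_res_s, r_airway_m, k_geo: float = 5.784):
    """Brownian deposition probability in a tube.

    First-Fourier-mode cylinder form p = 1 − exp(−k D t / R²) with
    k = 5.784 by default.
    """
    t = np.asarray(t_res_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("residence time must be nonnegative")
    arg = k_geo * np.asarray(d_diff_m2s, dtype=float) * t / np.asarray(r_airway_m, dtype=float) ** 2
    return 1.0 - np.exp(-arg)


def p_alveolar(v_s_ms, d_diff_m2s, t_res_s, r_alv_cm: float = 0.014,
               k_geo: float = 5.784):
    """Deposition probability inside an alveolated space during a pause.

    Settling over the alveolar radius combined (independently) with the
    diffusive term: p = 1 − exp(−v_s t / r_alv) ⊕ 1 − exp(−k D t / r²).
    """
    r_m = r_alv_cm * 1e-2
    p_s = 1.0 - np.exp(-np.asarray(v_s_ms, dtype=float) * np.asarray(t_res_s, dtype=float) / r_m)
    p_d = p_diffusion(d_diff_m2s, t_res_s, r_m, k_geo)
    return combine_mechanisms(0.0, p_s, p_d)


def combine_mechanisms(p_i, p_s, p_d):
    """Combine independent mechanism probabilities:
    p = 1 − (1−p_i)(1−p_s)(1−p_d), clipped to [0, 1]."""
    p = 1.0 - (1.0 - np.asarray(p_i)) * (1.0 - np.asarray(p_s)) * (1.0 - np.asarray(p_d))
    return np.clip(p, 0.0, 1.0)


def extrathoracic_efficiency(d_p_um, q_lpm, a: float = 1.1e-4, b: float = 1.4,
                             v_et_ml: float = 50.0, r_et_cm: float = 1.0,
                             constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Mouth–throat collection efficiency, single-compartment empirical model.

    Impaction parameterized by d²Q (µm²·L/min):
    ``η_imp = 1 − exp(−a·(d²Q)^b)``, monotone increasing in d²Q, plus a
    small-particle diffusive term ``η_diff = 1 − exp(−9·sqrt(D·t_ET)/R_ET)``
    with residence time t_ET = V_ET/Q.  The two combine independently.

    ``a`` is the empirical impaction coefficient; device presets may
    override it to absorb spray-momentum and mouthpiece effects.
    """
    d = np.asarray(d_p_um, dtype=float)
    q = np.asarray(q_lpm, dtype=float)
    if np.any(d < 0) or np.any(q < 0):
        raise ValueError("diameter and flow must be nonnegative")
    eta_imp = 1.0 - np.exp(-a * np.power(d**2 * q, b))
    # diffusive term; guard zero flow / zero diameter
    q_safe = np.maximum(q, 1e-12)
    d_safe = np.maximum(d, 1e-6)
    t_et = (v_et_ml * 1e-3) / (q_safe / 60.0)  # L / (L/s) = s
    d_diff = diffusion_coefficient(d_safe, constants=constants)
    eta_diff = 1.0 - np.exp(-9.0 * np.sqrt(d_diff * t_et) / (r_et_cm * 1e-2))
    return combine_mechanisms(eta_imp, eta_diff, 0.0)


@dataclass(frozen=True)
class ParticleTransportProperties:
    """Transport properties of a single particle (scalar convenience type).

    The Monte Carlo engine works on arrays internally; this type backs
    the scalar API and tests.
    """

    d_p: float  # aerodynamic diameter, µm
    rho_p: float  # g/cm³
    cc: float
    v_s: float  # m/s
    d_diff: float  # m²/s

    @classmethod
    def from_diameter(cls, d_p_um: float, rho_p: float = 1.0,
                      constants: PhysicsConstants = DEFAULT_CONSTANTS
                      ) -> "ParticleTransportProperties":
        cc = float(cunningham(d_p_um, constants))
        return cls(
            d_p=float(d_p_um),
            rho_p=float(rho_p),
            cc=cc,
            v_s=float(settling_velocity(d_p_um, rho_p, cc, constants)),
            d_diff=float(diffusion_coefficient(d_p_um, cc, constants)),
        )

    def __post_init__(self) -> None:
        if self.cc < 1.0:
            raise ValueError("slip factor cannot be below 1")
        if self.v_s < 0 or self.d_diff <= 0:
            raise ValueError("invalid transport properties")

    def stokes(self, u_ms: float, d_airway_cm: float,
               constants: PhysicsConstants = DEFAULT_CONSTANTS) -> float:
        return float(stokes_number(self.d_p, u_ms, d_airway_cm,
                                   self.rho_p, self.cc, constants))
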