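"""Monte Carlo particle tracking through inhalation, breath-hold and exhalation.

Each tracked particle receives: a random aerodynamic diameter from the
device's lognormal distribution, a random entry time inside the
emission window, a mouth–throat Bernoulli trial, and — if it survives —
a freshly sampled stochastic airway path.  Transport follows the
volumetric-front abstraction: the particle rides the local flow front,
and its penetration depth is limited by the volume of air inhaled
behind its entry time.  Crossing each airway costs inhaled volume
``v_seg / F`` where ``v_seg`` is the (lung-volume-scaled) tube volume
and ``F`` the cumulative flow fraction of the path, so residence times
follow directly from the reconstructed flow profile.  Deposition is a
per-segment Bernoulli trial combining impaction, settling and
diffusion; the breath-hold applies settling + diffusion (alveolar
closed forms inside the acinus) in the halting segment; exhalation
retraces the path with a mirrored flow profile and the same mechanism
set.  Particles exiting generation 0 count as exhaled.

Everything is vectorized over particles; randomness comes from a
counter-based (Philox) generator with a fixed draw order, so a run is
reproducible for a given seed independent of batching.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physics
from .aerosol import AerosolSpec, device_preset, sample_diameters
from .airways import (AcinarTable, MorphometryTable, default_acinus,
                      default_morphometry, sample_path_arrays)
from .maneuver import (FlowProfile, Maneuver, SubjectLungFunction,
                       build_flow_profile, geometry_scale_factor)
from .physics import PhysicsConstants, DEFAULT_CONSTANTS

logger = logging.getLogger(__name__)

__all__ = ["EngineConfig", "DepositionResult", "simulate_deposition",
           "mean_of_two", "run_cohort", "single_tube_harness", "row_seed"]


@dataclass(frozen=True)
class EngineConfig:
    """Tunable engine parameters (all per-run configurable)."""

    n_particles: int = 100_000
    v_ref_l: float = 4.8  # morphometric reference lung volume
    exhalation_multiplier: float = 1.0  # t_ex = multiplier * t_in
    r_alv_cm: float = 0.014  # alveolar radius for pause deposition
    et_a: float = 1.1e-4  # mouth–throat impaction coefficient (default)
    et_b: float = 1.4
    et_v_ml: float = 50.0
    et_r_cm: float = 1.0
    n_time_grid: int = 1024
    morphometry: MorphometryTable = field(default_factory=default_morphometry)
    acinus: AcinarTable = field(default_factory=default_acinus)
    constants: PhysicsConstants = DEFAULT_CONSTANTS


DEFAULT_ENGINE = None  # lazily built; default_morphometry reads a file


def _default_engine() -> EngineConfig:
    global DEFAULT_ENGINE
    if DEFAULT_ENGINE is None:
        DEFAULT_ENGINE = EngineConfig()
    return DEFAULT_ENGINE


@dataclass(frozen=True)
class DepositionResult:
    """Deposition tallies of one simulated maneuver, % of tracked dose."""

    pd_pct: float
    etd_pct: float
    exhaled_pct: float
    se_pd: float
    se_etd: float
    per_generation: np.ndarray  # % by generation; conducting 0..17, acinar after
    n_particles: int
    seed: int

    def __post_init__(self) -> None:
        total = self.pd_pct + self.etd_pct + self.exhaled_pct
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"tallies sum to {total}, not 100")
        if min(self.pd_pct, self.etd_pct, self.exhaled_pct) < 0:
            raise ValueError("negative deposition fraction")


def _se_pct(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n) * 100.0)


def _transit_probability(d_cm, cos_grav, branch_deg, t_res, v_s, d_diff,
                         st_parent, active):
    """Combined per-segment deposition probability during a flow phase.

    ``st_parent`` is the Stokes number evaluated with the parent tube's
    speed and diameter; ``active`` masks segments actually traversed.
    """
    p_i = physics.p_impaction(st_parent, branch_deg)
    p_s = physics.p_sedimentation(v_s, cos_grav, t_res, d_cm)
    p_d = physics.p_diffusion(d_diff, t_res, d_cm / 2.0 * 1e-2)
    return np.where(active, physics.combine_mechanisms(p_i, p_s, p_d), 0.0)


def simulate_deposition(lungs: SubjectLungFunction, m: Maneuver,
                        spec: AerosolSpec, n_particles: int | None = None,
                        seed: int = 0, config: EngineConfig | None = None
                        ) -> DepositionResult:
    """Track ``n_particles`` particles through one inhalation maneuver."""
    cfg = config or _default_engine()
    n = int(n_particles or cfg.n_particles)
    if n < 1:
        raise ValueError("n_particles must be >= 1")
    profile = build_flow_profile(m, cfg.exhalation_multiplier)
    rng = np.random.Generator(np.random.Philox(key=int(seed) & 0x7FFFFFFF))
    const = cfg.constants

    # --- particle properties and mouth–throat stage ----------------------
    d_um = sample_diameters(spec, n, rng)
    cc = physics.cunningham(d_um, const)
    v_s = physics.settling_velocity(d_um, spec.density, cc, const)
    d_diff = physics.diffusion_coefficient(d_um, cc, const)

    w0, w1 = spec.emission_window
    w1 = min(w1, m.t_in)  # emission cannot outlast the inhalation
    w0 = min(w0, 0.99 * w1)
    t_e = rng.uniform(w0, w1, n)
    q_entry = np.maximum(profile.flow(t_e), 0.0)  # L/s
    eta = physics.extrathoracic_efficiency(
        d_um, q_entry * 60.0, a=(spec.et_coeff or cfg.et_a), b=cfg.et_b,
        v_et_ml=cfg.et_v_ml, r_et_cm=cfg.et_r_cm, constants=const)
    in_throat = rng.uniform(size=n) < eta

    # --- stochastic paths and volumetric bookkeeping ----------------------
    paths = sample_path_arrays(cfg.morphometry, cfg.acinus, n, rng)
    scale = geometry_scale_factor(lungs.rv + profile.ivc_d / 2.0, cfg.v_ref_l)
    length = paths["length_cm"] * scale
    diam = paths["diameter_cm"] * scale
    valid = paths["valid"]
    n_cond_max = cfg.morphometry.n_generations
    n_acin = cfg.acinus.n_generations
    s_max = n_cond_max + n_acin
    seg_idx = np.arange(s_max)[None, :]
    rows = np.arange(n)

    v_seg_l = np.pi / 4.0 * diam**2 * length / 1000.0  # cm³ -> L
    f_cum = np.cumprod(paths["flow_fraction"], axis=1)
    cost = np.where(valid, v_seg_l / f_cum, 0.0)
    c_end = np.cumsum(cost, axis=1)  # inhaled-volume coordinate of segment ends

    # inhaled-volume time grid (monotone) for front-crossing inversion
    t_grid = np.linspace(0.0, m.t_in, cfg.n_time_grid)
    v_grid = np.asarray(profile.inhaled_volume(t_grid), dtype=float)
    ivc_tot = float(v_grid[-1])
    v_entry = np.asarray(profile.inhaled_volume(t_e), dtype=float)

    targets = v_entry[:, None] + c_end
    t_end = np.interp(targets.ravel(), v_grid, t_grid).reshape(n, s_max)
    t_start = np.concatenate([t_e[:, None], t_end[:, :-1]], axis=1)
    t_res = np.maximum(t_end - t_start, 0.0)

    crossed = (targets <= ivc_tot - 1e-12) & valid
    not_crossed = (~crossed) & valid
    any_halt = not_crossed.any(axis=1)
    n_valid = paths["n_conducting"] + n_acin
    halt = np.where(any_halt, not_crossed.argmax(axis=1), n_valid - 1)

    # mean total flow while the particle crosses each segment
    prev_targets = np.concatenate([v_entry[:, None], targets[:, :-1]], axis=1)
    dv = np.clip(np.minimum(targets, ivc_tot) - np.minimum(prev_targets, ivc_tot), 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_tot = np.where(t_res > 0, dv / np.maximum(t_res, 1e-300), 0.0)
    q_loc = q_tot * f_cum  # L/s through the single tube
    area_cm2 = np.pi / 4.0 * diam**2
    u_ms = q_loc * 1000.0 / area_cm2 / 100.0  # cm³/s / cm² -> m/s
    u_parent = np.concatenate([np.zeros((n, 1)), u_ms[:, :-1]], axis=1)
    d_parent = np.concatenate([diam[:, :1], diam[:, :-1]], axis=1)

    in_path = valid & (seg_idx <= halt[:, None]) & (t_res > 0)
    st = physics.stokes_number(d_um[:, None], u_parent, d_parent,
                               spec.density, cc[:, None], const)
    p_inh = _transit_probability(diam, paths["cos_gravity"], paths["branch_deg"],
                                 t_res, v_s[:, None], d_diff[:, None],
                                 st, in_path)
    u_draw = rng.uniform(size=(n, s_max))
    hit_inh = u_draw < p_inh
    any_inh = hit_inh.any(axis=1)
    seg_inh = hit_inh.argmax(axis=1)

    # --- breath-hold in the halting segment -------------------------------
    d_h = diam[rows, halt]
    cos_h = paths["cos_gravity"][rows, halt]
    acin_h = paths["is_acinar"][rows, halt]
    p_tube = physics.combine_mechanisms(
        0.0,
        physics.p_sedimentation(v_s, cos_h, m.t_bh, d_h),
        physics.p_diffusion(d_diff, m.t_bh, d_h / 2.0 * 1e-2))
    p_alv = physics.p_alveolar(v_s, d_diff, m.t_bh, cfg.r_alv_cm)
    p_bh = np.where(acin_h, p_alv, p_tube)
    hit_bh = rng.uniform(size=n) < p_bh

    # --- exhalation: retrace the path with a mirrored profile -------------
    penetration = np.minimum(ivc_tot - v_entry, c_end[rows, halt])
    t_grid_ex = np.linspace(0.0, profile.t_ex, cfg.n_time_grid)
    v_grid_ex = np.asarray(profile.exhaled_volume(t_grid_ex), dtype=float)
    c_start = c_end - cost
    enter_v = np.clip(penetration[:, None] - c_end, 0.0, None)
    exit_v = np.clip(penetration[:, None] - c_start, 0.0, None)
    t_enter = np.interp(enter_v.ravel(), v_grid_ex, t_grid_ex).reshape(n, s_max)
    t_exit = np.interp(exit_v.ravel(), v_grid_ex, t_grid_ex).reshape(n, s_max)
    t_res_ex = np.maximum(t_exit - t_enter, 0.0)
    dv_ex = np.clip(np.minimum(exit_v, v_grid_ex[-1]) - np.minimum(enter_v, v_grid_ex[-1]),
                    0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_tot_ex = np.where(t_res_ex > 0, dv_ex / np.maximum(t_res_ex, 1e-300), 0.0)
    u_ms_ex = q_tot_ex * f_cum * 1000.0 / area_cm2 / 100.0
    # on the way out the "parent" of the bend is the deeper tube
    u_parent_ex = np.concatenate([u_ms_ex[:, 1:], np.zeros((n, 1))], axis=1)
    d_parent_ex = np.concatenate([diam[:, 1:], diam[:, -1:]], axis=1)
    active_ex = valid & (seg_idx <= halt[:, None]) & (t_res_ex > 0)
    st_ex = physics.stokes_number(d_um[:, None], u_parent_ex, d_parent_ex,
                                  spec.density, cc[:, None], const)
    p_ex = _transit_probability(diam, paths["cos_gravity"], paths["branch_deg"],
                                t_res_ex, v_s[:, None], d_diff[:, None],
                                st_ex, active_ex)
    u_draw_ex = rng.uniform(size=(n, s_max))
    hit_ex = u_draw_ex < p_ex
    any_ex = hit_ex.any(axis=1)
    # retracing runs from the deepest segment outward: deepest hit wins
    seg_ex = s_max - 1 - hit_ex[:, ::-1].argmax(axis=1)

    # --- resolve particle fates ------------------------------------------
    # priority: throat > inhalation transit > breath-hold > exhalation
    lung_seg = np.where(any_inh, seg_inh,
                        np.where(hit_bh, halt,
                                 np.where(any_ex, seg_ex, -1)))
    in_lung = (~in_throat) & (lung_seg >= 0)
    exhaled = (~in_throat) & (lung_seg < 0)

    n_et = int(in_throat.sum())
    n_lung = int(in_lung.sum())
    n_out = int(exhaled.sum())
    assert n_et + n_lung + n_out == n

    # per-generation tally: conducting segments keep their generation
    # number; acinar segments are binned after the deepest conducting row
    gen_label = np.where(paths["is_acinar"],
                         n_cond_max + (seg_idx - paths["n_conducting"][:, None]),
                         seg_idx)
    per_gen = np.zeros(s_max)
    if n_lung:
        labels = gen_label[rows, lung_seg][in_lung]
        per_gen = np.bincount(labels, minlength=s_max) / n * 100.0

    pd_pct = n_lung / n * 100.0
    etd_pct = n_et / n * 100.0
    exhaled_pct = n_out / n * 100.0
    logger.debug("conservation check: %.12f", pd_pct + etd_pct + exhaled_pct)
    return DepositionResult(
        pd_pct=pd_pct, etd_pct=etd_pct, exhaled_pct=exhaled_pct,
        se_pd=_se_pct(n_lung / n, n), se_etd=_se_pct(n_et / n, n),
        per_generation=per_gen, n_particles=n, seed=int(seed))


def mean_of_two(first: DepositionResult, second: DepositionResult
                ) -> tuple[float, float]:
    """Mean PD and ETD of the two repeated maneuvers (the study's unit
    of analysis)."""
    return ((first.pd_pct + second.pd_pct) / 2.0,
            (first.etd_pct + second.etd_pct) / 2.0)


def row_seed(master_seed: int, subject_id: str, device: str,
             repetition: int | None) -> int:
    """Stable per-row engine seed: crc32 of the row identity, mixed with
    the master seed.  Passing ``repetition=None`` makes both repetitions
    share a seed (used for degenerate repeatability checks)."""
    tag = f"{subject_id}|{device}|{repetition if repetition is not None else 0}"
    return (zlib.crc32(tag.encode()) ^ (int(master_seed) * 0x9E3779B1)) & 0x7FFFFFFF


REQUIRED_COLUMNS = ["subject_id", "group", "device", "repetition",
                    "ivc_d_l", "pif_d_lps", "t_in_s", "t_bh_s",
                    "rv_l", "tlc_l", "frc_l"]


def run_cohort(records: pd.DataFrame, seed: int = 0,
               n_particles: int | None = None,
               config: EngineConfig | None = None,
               aerosols: dict[str, AerosolSpec] | None = None,
               repetition_seed: bool = True) -> pd.DataFrame:
    """Simulate every maneuver row of a cohort table.

    ``records`` uses the maneuver CSV dialect (one row per subject x
    device x repetition).  Returns a long-format table with deposition
    fractions and Monte Carlo standard errors.  Rows with missing values
    are reported and skipped; the run continues.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks columns: {missing}")
    cfg = config or _default_engine()
    out = []
    for _, row in records.iterrows():
        if row[REQUIRED_COLUMNS].isna().any():
            logger.warning("skipping incomplete maneuver row for subject %s "
                           "device %s rep %s", row.get("subject_id"),
                           row.get("device"), row.get("repetition"))
            continue
        lungs = SubjectLungFunction(rv=row["rv_l"], tlc=row["tlc_l"],
                                    frc=row["frc_l"], group=row["group"],
                                    subject_id=str(row["subject_id"]))
        man = Maneuver(ivc_d=row["ivc_d_l"], pif_d=row["pif_d_lps"],
                       t_in=row["t_in_s"], t_bh=row["t_bh_s"],
                       device=row["device"], repetition=int(row["repetition"]))
        spec = (aerosols or {}).get(row["device"]) or device_preset(row["device"])
        rseed = row_seed(seed, str(row["subject_id"]), row["device"],
                         int(row["repetition"]) if repetition_seed else None)
        res = simulate_deposition(lungs, man, spec, n_particles, rseed, cfg)
        out.append({
            "subject_id": row["subject_id"], "group": row["group"],
            "device": row["device"], "repetition": int(row["repetition"]),
            "pd_pct": res.pd_pct, "etd_pct": res.etd_pct,
            "exhaled_pct": res.exhaled_pct,
            "se_pd": res.se_pd, "se_etd": res.se_etd,
        })
    return pd.DataFrame(out)


def single_tube_harness(d_airway_cm: float, length_cm: float,
                        branch_deg: float, cos_gravity: float,
                        d_p_um: float, flow_lps: float,
                        n_particles: int = 100_000, seed: int = 0,
                        constants: PhysicsConstants = DEFAULT_CONSTANTS
                        ) -> tuple[float, float, float]:
    """Monte Carlo deposition in one straight tube at constant flow.

    Returns ``(mc_fraction, mc_se, closed_form)`` where the closed form
    is the combined impaction/settling/diffusion probability for the
    same residence time.  Used to validate the Bernoulli machinery
    against the analytic single-airway model.
    """
    cc = float(physics.cunningham(d_p_um, constants))
    v_s = float(physics.settling_velocity(d_p_um, 1.0, cc, constants))
    d_diff = float(physics.diffusion_coefficient(d_p_um, cc, constants))
    vol_l = np.pi / 4.0 * d_airway_cm**2 * length_cm / 1000.0
    t_res = vol_l / flow_lps
    u_ms = flow_lps * 1000.0 / (np.pi / 4.0 * d_airway_cm**2) / 100.0
    st = float(physics.stokes_number(d_p_um, u_ms, d_airway_cm, 1.0, cc, constants))
    p = float(_transit_probability(
        np.array(d_airway_cm), np.array(cos_gravity), np.array(branch_deg),
        np.array(t_res), v_s, d_diff, np.array(st), np.array(True)))
    rng = np.random.Generator(np.random.Philox(key=int(seed) & 0x7FFFFFFF))
    hits = rng.uniform(size=n_particles) < p
    frac = float(hits.mean())
    return frac, _se_pct(frac, n_particles) / 100.0, p
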