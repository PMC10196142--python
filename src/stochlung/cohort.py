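"""Synthetic study cohort emulating the published group-level summaries.

No subject-level data were published, only group means ± SEM of the
through-device maneuver parameters and lung function per group.  The
generator draws subject-level values so that the *group* statistics are
recovered: each parameter is truncated-normal around the published
group/device mean with SD = SEM·√n (the implied between-subject SD),
subjects carry a latent severity factor inducing the physiological
correlation between hyperinflation (RV) and through-device inspired
volume, and the second repetition of each maneuver is the first times
mean-one lognormal noise with a configurable intra-subject CV.

The repetition CV is the one quantity with no published anchor: the
default 0.08 puts synthetic Bland–Altman coefficients of repeatability
in the single-digit percentage-point range of the published grid, and
it is deliberately the most prominent knob in the config.

Feasibility (ivc_d <= pif_d·t_in) is repaired by redrawing only t_in,
never the volume or flow, so the published IVC_d and PIF_d means are
recovered exactly in large samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import study
from .engine import EngineConfig, run_cohort
from .repeatability import rank_summary, repeatability_table

logger = logging.getLogger(__name__)

__all__ = ["CohortConfig", "generate_cohort", "end_to_end_fixture"]

#: physiologic floors for the truncated-normal subject draws
FLOORS = {"ivc_d": 0.5, "pif_d": 0.3, "t_in": 0.5, "t_bh": 0.5,
          "rv_pct": 30.0, "tlc_pct": 50.0, "tgv_pct": 40.0}


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(study.GROUP_SIZES))
    maneuver_stats: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in study.MANEUVER_STATS.items()})
    lung_stats: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in study.LUNG_FUNCTION_STATS.items()})
    reference_volumes: dict = field(
        default_factory=lambda: dict(study.REFERENCE_VOLUMES))
    #: published per-group sample sizes; the between-subject SD implied
    #: by a published SEM is SEM·√(reference n), independent of how many
    #: synthetic subjects are generated
    reference_sizes: dict[str, int] = field(
        default_factory=lambda: dict(study.GROUP_SIZES))
    intra_subject_cv: float = 0.08
    latent_corr: float = 0.6  # severity factor loading on RV / IVC_d / PIF_d
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g} needs n >= 2")
        if self.intra_subject_cv < 0:
            raise ValueError("intra-subject CV must be nonnegative")
        if not (0.0 <= self.latent_corr < 1.0):
            raise ValueError("latent correlation must lie in [0, 1)")
        for (group, dev), stats in self.maneuver_stats.items():
            n = self.reference_sizes.get(group, 2)
            for name, (mean, sem) in stats.items():
                if mean <= 0:
                    raise ValueError(f"{group}/{dev}/{name}: nonpositive mean")
                sd = sem * np.sqrt(n)
                floor = FLOORS.get(name, 0.0)
                if floor > mean + 4.0 * sd:
                    raise ValueError(
                        f"{group}/{dev}/{name}: floor {floor} above mean+4SD")


def _mean_preserving_loc(mean: float, sd: float, floor: float) -> float:
    """Location of a floor-truncated normal whose mean equals ``mean``.

    Truncation pulls the mean up by sd*phi(a)/(1-Phi(a)); a fixed-point
    correction keeps the published group mean exactly recoverable.
    """
    loc = mean
    for _ in range(4):
        a = (floor - loc) / sd
        shift = sd * sps.norm.pdf(a) / max(sps.norm.sf(a), 1e-300)
        loc = mean - shift
    return loc


def _truncated_normal(mean, sd, floor, z, rng) -> np.ndarray:
    """Truncated-normal draw built from a provided standard-normal array.

    ``z`` carries the latent-factor structure; draws below the floor are
    replaced by exact truncated-normal resamples (rare by construction).
    The location is adjusted so the *mean* of the truncated draw equals
    the published target.
    """
    if sd <= 0:
        return np.full_like(np.asarray(z, float), mean)
    loc = _mean_preserving_loc(mean, sd, floor)
    x = loc + sd * z
    bad = x < floor
    if np.any(bad):
        a = (floor - loc) / sd
        x[bad] = sps.truncnorm.rvs(a, np.inf, loc=loc, scale=sd,
                                   size=int(bad.sum()), random_state=rng)
    return np.maximum(x, floor)


def generate_cohort(cfg: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Maneuver CSV rows: 2 repetitions x 3 device products x n subjects.

    Foster and Trimbow share each subject's physical pMDI maneuver (one
    placebo pMDI was used for both products); Respimat has its own.
    Deterministic for a fixed seed.
    """
    rng = np.random.Generator(np.random.Philox(
        key=(int(seed if seed is not None else cfg.seed)) & 0x7FFFFFFF))
    rows = []
    sigma_rep = np.sqrt(np.log1p(cfg.intra_subject_cv**2))
    rho = cfg.latent_corr
    for group, n in cfg.group_sizes.items():
        severity = rng.standard_normal(n)  # higher = worse

        def corr_z(loading: float) -> np.ndarray:
            eps = rng.standard_normal(n)
            return loading * severity + np.sqrt(1.0 - loading**2) * eps

        lf = cfg.lung_stats[group]
        sqn = np.sqrt(cfg.reference_sizes.get(group, n))
        rv_pct = _truncated_normal(lf["rv_pct"][0], lf["rv_pct"][1] * sqn,
                                   FLOORS["rv_pct"], corr_z(rho), rng)
        tlc_pct = _truncated_normal(lf["tlc_pct"][0], lf["tlc_pct"][1] * sqn,
                                    FLOORS["tlc_pct"], corr_z(rho / 2.0), rng)
        tgv_pct = _truncated_normal(lf["tgv_pct"][0], lf["tgv_pct"][1] * sqn,
                                    FLOORS["tgv_pct"], corr_z(rho), rng)
        rv = rv_pct / 100.0 * cfg.reference_volumes["rv"]
        tlc = tlc_pct / 100.0 * cfg.reference_volumes["tlc"]
        frc = tgv_pct / 100.0 * cfg.reference_volumes["frc"]
        # enforce rv < frc < tlc subject-wise (clamp, rare at defaults)
        frc = np.clip(frc, rv * 1.05, None)
        tlc = np.clip(tlc, frc * 1.05, None)

        for device_class in ("pMDI", "Respimat"):
            stats = cfg.maneuver_stats[(group, device_class)]
            draws = {}
            loads = {"ivc_d": -rho, "pif_d": -rho, "t_in": 0.0, "t_bh": 0.0}
            for name, (mean, sem) in stats.items():
                draws[name] = _truncated_normal(mean, sem * sqn, FLOORS[name],
                                                corr_z(loads[name]), rng)
            rep1 = {k: v.copy() for k, v in draws.items()}
            _repair_feasibility(rep1, rng)
            noise = {k: np.exp(sigma_rep * rng.standard_normal(n)
                               - 0.5 * sigma_rep**2)
                     for k in draws}  # mean-one lognormal
            rep2 = {k: rep1[k] * noise[k] for k in draws}
            # with zero CV rep2 equals the already-feasible rep1 and no
            # further repair draws are consumed
            if sigma_rep > 0:
                _repair_feasibility(rep2, rng)

            devices = (["Foster_pMDI", "Trimbow_pMDI"] if device_class == "pMDI"
                       else ["Spiriva_Respimat"])
            for i in range(n):
                sid = f"{group}-{i + 1:03d}"
                for rep_idx, vals in ((1, rep1), (2, rep2)):
                    for device in devices:
                        rows.append({
                            "subject_id": sid, "group": group,
                            "device": device, "repetition": rep_idx,
                            "ivc_d_l": vals["ivc_d"][i],
                            "pif_d_lps": vals["pif_d"][i],
                            "t_in_s": vals["t_in"][i],
                            "t_bh_s": vals["t_bh"][i],
                            "rv_l": rv[i], "tlc_l": tlc[i], "frc_l": frc[i],
                        })
    return pd.DataFrame(rows)


def _repair_feasibility(vals: dict[str, np.ndarray],
                        rng: np.random.Generator, max_tries: int = 100) -> None:
    """Redraw t_in where ivc_d > pif_d*t_in; clamp after max_tries."""
    mean_t, sd_t = vals["t_in"].mean(), max(vals["t_in"].std(), 1e-6)
    need = vals["ivc_d"] / vals["pif_d"]
    bad = vals["t_in"] < need
    tries = 0
    while np.any(bad) and tries < max_tries:
        k = int(bad.sum())
        vals["t_in"][bad] = np.maximum(
            mean_t + sd_t * rng.standard_normal(k), FLOORS["t_in"])
        bad = vals["t_in"] < need
        tries += 1
    if np.any(bad):
        logger.info("clamping t_in for %d infeasible synthetic maneuvers",
                    int(bad.sum()))
        vals["t_in"][bad] = need[bad] * 1.02


def end_to_end_fixture(cfg: CohortConfig | None = None,
                       n_particles: int = 2000, seed: int = 0,
                       engine_config: EngineConfig | None = None,
                       repetition_seed: bool = True) -> dict:
    """Run the whole pipeline on a (typically small) synthetic cohort.

    Returns the maneuver table, the per-maneuver deposition table, the
    repeatability grid and the device rank counts; asserts the schema
    contracts between stages.
    """
    cfg = cfg or CohortConfig()
    maneuvers = generate_cohort(cfg, seed)
    deposition = run_cohort(maneuvers, seed=seed, n_particles=n_particles,
                            config=engine_config,
                            repetition_seed=repetition_seed)
    expected_rows = sum(3 * 2 * n for n in cfg.group_sizes.values())
    assert len(deposition) == expected_rows, "pipeline dropped maneuver rows"
    table = repeatability_table(deposition)
    wide = deposition.pivot_table(index=["group", "subject_id", "device"],
                                  columns="repetition", values="pd_pct")
    diffs = (wide[1] - wide[2]).abs().rename("abs_diff").reset_index()
    ranks = rank_summary(diffs)
    return {"maneuvers": maneuvers, "deposition": deposition,
            "repeatability": table, "ranks": ranks}
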