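"""Stochastic conducting-airway paths and the acinar region.

The lung is not stored as a full bifurcating tree.  Instead, one random
*path* from the trachea (generation 0) down to a terminal bronchiole is
drawn per tracked particle, with airway lengths and diameters sampled
lognormally around per-generation baseline means (a classic symmetric
adult morphometry at a 4,800 mL reference volume, shipped as a CSV),
daughter diameters correlated with the sampled parent, random branching
and gravity angles, and an asymmetric flow split at every bifurcation
proportional to daughter diameter squared.  Beyond the terminal
bronchiole an eight-generation acinar region follows, with the
alveolated wall fraction ramping up to 1.

The conducting path depth (terminal generation) is itself random,
uniform over 12–17 by default, mimicking the variable path lengths of
an asymmetric tree.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AirwaySegment",
    "AcinarSegment",
    "MorphometryTable",
    "AcinarTable",
    "default_morphometry",
    "default_acinus",
    "sample_conducting_path",
    "sample_acinus",
    "assign_flow_split",
    "sample_path_arrays",
]


@dataclass(frozen=True)
class AirwaySegment:
    """One conducting airway tube along a sampled path."""

    generation: int
    length: float  # cm
    diameter: float  # cm
    branching_angle: float  # degrees, [0, 90]
    gravity_angle: float  # degrees, [0, 180], axis vs gravity vector
    flow_fraction: float = 1.0  # share of parent flow entering this tube

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("length and diameter must be positive")
        if not (0.0 <= self.branching_angle <= 90.0):
            raise ValueError("branching angle outside [0, 90] degrees")
        if not (0.0 <= self.gravity_angle <= 180.0):
            raise ValueError("gravity angle outside [0, 180] degrees")
        if not (0.0 < self.flow_fraction <= 1.0):
            raise ValueError("flow fraction outside (0, 1]")

    def scaled(self, factor: float) -> "AirwaySegment":
        """Isotropically rescaled copy (lung-volume scaling)."""
        return replace(self, length=self.length * factor,
                       diameter=self.diameter * factor)


@dataclass(frozen=True)
class AcinarSegment:
    """One acinar duct generation (partially alveolated)."""

    generation: int  # acinar generation index, 0-based
    length: float  # cm
    diameter: float  # cm
    alveolar_fraction: float  # wall fraction covered by alveoli, [0, 1]
    cumulative_volume_share: float  # share of acinar volume up to here

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("length and diameter must be positive")
        if not (0.0 <= self.alveolar_fraction <= 1.0):
            raise ValueError("alveolar fraction outside [0, 1]")


@dataclass(frozen=True)
class MorphometryTable:
    """Per-generation baseline airway dimensions at reference volume.

    The means are the centers of the lognormal sampling distributions;
    ``cv_*`` are their coefficients of variation.
    """

    mean_length_cm: np.ndarray
    mean_diameter_cm: np.ndarray
    cv_length: np.ndarray
    cv_diameter: np.ndarray
    parent_daughter_corr: float = 0.5
    terminal_generation_range: tuple[int, int] = (12, 17)
    branching_angle_range: tuple[float, float] = (15.0, 60.0)
    reference_volume_l: float = 4.8

    def __post_init__(self) -> None:
        n = len(self.mean_length_cm)
        for name in ("mean_diameter_cm", "cv_length", "cv_diameter"):
            if len(getattr(self, name)) != n:
                raise ValueError("morphometry columns have unequal lengths")
        if np.any(self.mean_length_cm <= 0) or np.any(self.mean_diameter_cm <= 0):
            raise ValueError("baseline dimensions must be positive")
        if np.any(self.cv_length < 0) or np.any(self.cv_diameter < 0):
            raise ValueError("CVs must be nonnegative")
        if np.any(np.diff(self.mean_diameter_cm) >= 0):
            raise ValueError("baseline diameters must decrease with generation")
        lo, hi = self.terminal_generation_range
        if not (0 < lo <= hi < n):
            raise ValueError("terminal generation range outside table")
        if not (-1.0 <= self.parent_daughter_corr <= 1.0):
            raise ValueError("correlation outside [-1, 1]")

    @property
    def n_generations(self) -> int:
        return len(self.mean_length_cm)

    @classmethod
    def from_csv(cls, path, **overrides) -> "MorphometryTable":
        df = pd.read_csv(path).sort_values("generation")
        return cls(
            mean_length_cm=df["mean_length_cm"].to_numpy(float),
            mean_diameter_cm=df["mean_diameter_cm"].to_numpy(float),
            cv_length=df["cv_length"].to_numpy(float),
            cv_diameter=df["cv_diameter"].to_numpy(float),
            **overrides,
        )


def default_morphometry(**overrides) -> MorphometryTable:
    """Packaged baseline morphometry (adult, 4,800 mL reference)."""
    ref = importlib.resources.files("stochlung.data") / "morphometry_weibel.csv"
    with importlib.resources.as_file(ref) as path:
        return MorphometryTable.from_csv(path, **overrides)


@dataclass(frozen=True)
class AcinarTable:
    """Baseline acinar duct dimensions and alveolation ramp."""

    length_cm: np.ndarray = field(default_factory=lambda: np.array(
        [0.130, 0.120, 0.110, 0.100, 0.090, 0.085, 0.080, 0.075]))
    diameter_cm: np.ndarray = field(default_factory=lambda: np.array(
        [0.050, 0.045, 0.040, 0.037, 0.034, 0.031, 0.029, 0.027]))
    alveolar_fraction: np.ndarray = field(default_factory=lambda: np.linspace(0.2, 1.0, 8))
    cv: float = 0.0  # acinar dimensions treated as deterministic by default
    path_length_bounds_cm: tuple[float, float] = (0.5, 1.2)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.alveolar_fraction) < 0):
            raise ValueError("alveolar fraction must be nondecreasing")
        total = float(self.length_cm.sum())
        lo, hi = self.path_length_bounds_cm
        if not (lo <= total <= hi):
            raise ValueError(f"acinar path length {total:.2f} cm outside [{lo}, {hi}]")

    @property
    def n_generations(self) -> int:
        return len(self.length_cm)


def default_acinus() -> AcinarTable:
    return AcinarTable()


def assign_flow_split(d1_cm: float, d2_cm: float) -> tuple[float, float]:
    """Flow fractions of two daughters, proportional to diameter squared."""
    a1, a2 = d1_cm**2, d2_cm**2
    total = a1 + a2
    return a1 / total, a2 / total


def _lognormal_params(mean: np.ndarray, cv: np.ndarray):
    """(mu, sigma) of a lognormal with given arithmetic mean and CV."""
    sigma2 = np.log1p(np.asarray(cv, float) ** 2)
    mu = np.log(np.asarray(mean, float)) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


def sample_path_arrays(table: MorphometryTable, acinus: AcinarTable,
                       n_paths: int, rng: np.random.Generator) -> dict:
    """Vectorized sampling of ``n_paths`` airway paths.

    Returns a dict of float arrays of shape (n_paths, S) where
    S = table.n_generations + acinus.n_generations; segments beyond a
    path's terminal depth are masked out by ``valid``:

    ``length_cm, diameter_cm, branch_deg, cos_gravity, flow_fraction,
    is_acinar, alveolar_fraction, valid, n_conducting``.

    The per-segment draw order is fixed, so results are reproducible for
    a given generator state regardless of caller batching.
    """
    n_cond_max = table.n_generations
    n_acin = acinus.n_generations
    s_max = n_cond_max + n_acin
    lo, hi = table.terminal_generation_range
    n_conducting = rng.integers(lo, hi + 1, size=n_paths) + 1  # segments 0..G_term

    mu_l, sig_l = _lognormal_params(table.mean_length_cm, table.cv_length)
    mu_d, sig_d = _lognormal_params(table.mean_diameter_cm, table.cv_diameter)
    rho = table.parent_daughter_corr

    length = np.empty((n_paths, s_max))
    diam = np.empty((n_paths, s_max))
    branch = np.zeros((n_paths, s_max))
    cosg = np.empty((n_paths, s_max))
    ffrac = np.ones((n_paths, s_max))

    z_parent = rng.standard_normal(n_paths)  # trachea diameter z-score
    diam[:, 0] = np.exp(mu_d[0] + sig_d[0] * z_parent)
    length[:, 0] = np.exp(mu_l[0] + sig_l[0] * rng.standard_normal(n_paths))
    cosg[:, 0] = rng.uniform(-1.0, 1.0, n_paths)

    b_lo, b_hi = table.branching_angle_range
    for g in range(1, n_cond_max):
        length[:, g] = np.exp(mu_l[g] + sig_l[g] * rng.standard_normal(n_paths))
        # followed daughter and its sibling, both correlated with the
        # sampled parent; the followed tube keeps the table marginals and
        # receives the d²-rule share of the parent flow
        eps = rng.standard_normal((n_paths, 2))
        z_d = rho * z_parent[:, None] + np.sqrt(1.0 - rho**2) * eps
        d_pair = np.exp(mu_d[g] + sig_d[g] * z_d)
        diam[:, g] = d_pair[:, 0]
        ffrac[:, g] = d_pair[:, 0] ** 2 / (d_pair[:, 0] ** 2 + d_pair[:, 1] ** 2)
        z_parent = z_d[:, 0]
        branch[:, g] = rng.uniform(b_lo, b_hi, n_paths)
        cosg[:, g] = rng.uniform(-1.0, 1.0, n_paths)

    # acinar block: deterministic dims (cv 0 default), symmetric splits
    for j in range(n_acin):
        s = n_cond_max + j
        if acinus.cv > 0:
            mu, sig = _lognormal_params(acinus.length_cm[j], acinus.cv)
            length[:, s] = np.exp(mu + sig * rng.standard_normal(n_paths))
            mu, sig = _lognormal_params(acinus.diameter_cm[j], acinus.cv)
            diam[:, s] = np.exp(mu + sig * rng.standard_normal(n_paths))
        else:
            length[:, s] = acinus.length_cm[j]
            diam[:, s] = acinus.diameter_cm[j]
        branch[:, s] = 45.0
        cosg[:, s] = rng.uniform(-1.0, 1.0, n_paths)
        ffrac[:, s] = 0.5

    # compact each path: acinar segments start right after the terminal
    # bronchiole, i.e. at per-path index n_conducting
    seg_idx = np.arange(s_max)[None, :]
    nc = n_conducting[:, None]
    is_acinar = (seg_idx >= nc) & (seg_idx < nc + n_acin)
    valid = seg_idx < nc + n_acin
    # shift the acinar block left into the slots right after the terminal
    acin_src = n_cond_max + (seg_idx - nc)  # source column for acinar slots
    acin_src = np.clip(acin_src, 0, s_max - 1)
    rows = np.arange(n_paths)[:, None]

    def compact(a: np.ndarray) -> np.ndarray:
        return np.where(is_acinar, a[rows, acin_src], a)

    alv = np.zeros((n_paths, s_max))
    alv_table = np.concatenate([np.zeros(n_cond_max), acinus.alveolar_fraction])
    alv = np.where(is_acinar, alv_table[np.clip(acin_src, 0, s_max - 1)], 0.0)

    return {
        "length_cm": compact(length),
        "diameter_cm": compact(diam),
        "branch_deg": compact(branch),
        "cos_gravity": compact(cosg),
        "flow_fraction": compact(ffrac),
        "is_acinar": is_acinar,
        "alveolar_fraction": alv,
        "valid": valid,
        "n_conducting": n_conducting,
    }


def sample_conducting_path(table: MorphometryTable, rng_seed) -> list[AirwaySegment]:
    """One stochastic path from the trachea to a terminal bronchiole.

    Deterministic for a fixed seed (or a passed-in Generator).
    """
    rng = _as_rng(rng_seed)
    arrays = sample_path_arrays(table, AcinarTable(), 1, rng)
    nc = int(arrays["n_conducting"][0])
    segs = []
    for g in range(nc):
        segs.append(AirwaySegment(
            generation=g,
            length=float(arrays["length_cm"][0, g]),
            diameter=float(arrays["diameter_cm"][0, g]),
            branching_angle=float(arrays["branch_deg"][0, g]),
            gravity_angle=float(np.degrees(np.arccos(arrays["cos_gravity"][0, g]))),
            flow_fraction=float(arrays["flow_fraction"][0, g]),
        ))
    return segs


def sample_acinus(rng_seed, acinus: AcinarTable | None = None) -> list[AcinarSegment]:
    """Acinar generations appended after the terminal bronchiole."""
    acinus = acinus or AcinarTable()
    rng = _as_rng(rng_seed)
    lengths = np.array(acinus.length_cm, float)
    diams = np.array(acinus.diameter_cm, float)
    if acinus.cv > 0:
        mu, sig = _lognormal_params(lengths, acinus.cv)
        lengths = np.exp(mu + sig * rng.standard_normal(len(lengths)))
        mu, sig = _lognormal_params(diams, acinus.cv)
        diams = np.exp(mu + sig * rng.standard_normal(len(diams)))
    vols = np.pi / 4.0 * diams**2 * lengths * (1.0 + acinus.alveolar_fraction)
    share = np.cumsum(vols) / vols.sum()
    return [
        AcinarSegment(generation=j, length=float(lengths[j]),
                      diameter=float(diams[j]),
                      alveolar_fraction=float(acinus.alveolar_fraction[j]),
                      cumulative_volume_share=float(share[j]))
        for j in range(acinus.n_generations)
    ]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.Generator(np.random.Philox(key=int(rng_seed)))
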