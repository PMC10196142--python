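"""Bland–Altman repeatability, bias tests, device ranking, group tests.

The study's statistical layer works on pairs of deposition values
computed from the two repeated inhalation maneuvers of each subject.
For a difference vector d_i = first_i − second_i:

* bias = mean(d), SD of differences with the n−1 denominator,
* 95 % limits of agreement LoA = bias ± 1.96·sd_d,
* coefficient of repeatability CR = 1.96·RMS(d) = 1.96·sqrt(Σd²/n)
  — algebraically identical to 1.96·sqrt(bias² + sd²·(n−1)/n), the only
  definition consistent with published repeatability tables of this
  kind (lower CR = better repeatability),
* a two-sided one-sample t test of the bias against zero.

Devices are ranked per subject by |d| (rank 1 = most repeatable), and
groups are compared by ANOVA + Bonferroni or Kruskal–Wallis + Dunn,
selected by per-group Shapiro normality at α = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "BlandAltmanResult", "bland_altman", "cr_from_summary", "sd_from_loa",
    "bias_t_test", "rank_devices", "rank_summary", "GroupComparison",
    "group_compare", "repeatability_table",
]

DEVICE_ORDER = ("Foster_pMDI", "Trimbow_pMDI", "Spiriva_Respimat")


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float
    sd_d: float  # SD of differences, n−1 denominator
    loa_low: float
    loa_high: float
    cr: float
    t_stat: float
    p_value: float
    loa_multiplier: float = 1.96

    def __post_init__(self) -> None:
        width = self.loa_high - self.loa_low
        if abs(width - 2.0 * self.loa_multiplier * self.sd_d) > 1e-9 * max(1.0, width):
            raise ValueError("LoA width inconsistent with sd_d")


def bland_altman(first, second, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman analysis of two repeated measurement vectors."""
    f = np.asarray(first, dtype=float)
    s = np.asarray(second, dtype=float)
    if f.shape != s.shape or f.ndim != 1:
        raise ValueError("first and second must be equal-length 1-D vectors")
    n = len(f)
    if n < 2:
        raise ValueError("need at least two paired measurements")
    if np.any(np.isnan(f)) or np.any(np.isnan(s)):
        raise ValueError("missing values are not allowed")
    d = f - s
    bias = float(d.mean())
    sd_d = float(d.std(ddof=1))
    cr = float(loa_multiplier * np.sqrt(np.mean(d**2)))
    t_stat, p = bias_t_test(bias, sd_d, n)
    return BlandAltmanResult(
        n=n, bias=bias, sd_d=sd_d,
        loa_low=bias - loa_multiplier * sd_d,
        loa_high=bias + loa_multiplier * sd_d,
        cr=cr, t_stat=t_stat, p_value=p, loa_multiplier=loa_multiplier)


def cr_from_summary(bias: float, sd_d: float, n: int,
                    loa_multiplier: float = 1.96) -> float:
    """CR from summary statistics: k·sqrt(bias² + sd²·(n−1)/n).

    Independent algebraic route to the same quantity as
    ``loa_multiplier * RMS(d)``; used to reconstruct CR from published
    (bias, LoA, n) rows.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(loa_multiplier * np.sqrt(bias**2 + sd_d**2 * (n - 1) / n))


def sd_from_loa(loa_low: float, loa_high: float,
                loa_multiplier: float = 1.96) -> float:
    """SD of differences reconstructed from the printed LoA half-width."""
    return (loa_high - loa_low) / 2.0 / loa_multiplier


def bias_t_test(bias: float, sd_d: float, n: int) -> tuple[float, float]:
    """Two-sided one-sample t test of the bias against 0, df = n−1."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd_d == 0.0:
        return (0.0, 1.0) if bias == 0.0 else (np.inf * np.sign(bias), 0.0)
    t = bias / (sd_d / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def rank_devices(abs_diffs: dict[str, float],
                 order: tuple[str, ...] = DEVICE_ORDER) -> dict[str, int]:
    """Rank one subject's devices by |d|; rank 1 = smallest difference.

    Ties are broken by the fixed device order and logged.
    """
    if set(abs_diffs) != set(order) or len(order) != 3:
        raise ValueError(f"need exactly the three devices {order}")
    keyed = sorted(order, key=lambda dev: (abs_diffs[dev], order.index(dev)))
    vals = [abs_diffs[d] for d in order]
    if len(set(vals)) < len(vals):
        logger.info("tie among device differences %s broken by device order", abs_diffs)
    return {dev: r + 1 for r, dev in enumerate(keyed)}


def rank_summary(per_subject: pd.DataFrame,
                 value_col: str = "abs_diff") -> pd.DataFrame:
    """Per-group counts of each rank per device.

    ``per_subject`` needs columns subject_id, group, device and the
    absolute-difference column; every subject must have all three
    devices.
    """
    rows = []
    for (group, sid), sub in per_subject.groupby(["group", "subject_id"]):
        diffs = dict(zip(sub["device"], sub[value_col]))
        for dev, r in rank_devices(diffs).items():
            rows.append({"group": group, "subject_id": sid,
                         "device": dev, "rank": r})
    ranks = pd.DataFrame(rows)
    counts = (ranks.groupby(["group", "device", "rank"]).size()
              .rename("count").reset_index())
    return counts


@dataclass(frozen=True)
class GroupComparison:
    method: str  # "anova" or "kruskal"
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float]  # adjusted p per comparison
    normality_p: dict[str, float] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()


def group_compare(values_by_group: dict[str, np.ndarray],
                  method: str = "auto", alpha: float = 0.05
                  ) -> GroupComparison:
    """Omnibus + post-hoc comparison across groups.

    ``auto`` picks ANOVA + Bonferroni-adjusted pairwise t tests when all
    groups pass Shapiro normality at ``alpha``, otherwise
    Kruskal–Wallis + Dunn's test.  Groups with n < 3 force the
    nonparametric branch (with a warning).
    """
    if method not in ("auto", "anova", "kruskal"):
        raise ValueError("method must be auto, anova or kruskal")
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    warn: list[str] = []
    normality: dict[str, float] = {}
    small = [g for g, s in zip(names, samples) if len(s) < 3]
    if method == "auto":
        if small:
            warn.append(f"groups with n<3 ({small}); forcing nonparametric tests")
            method = "kruskal"
        else:
            for g, s in zip(names, samples):
                # Shapiro is degenerate on constant samples; call those
                # non-normal rather than erroring
                if np.ptp(s) == 0:
                    normality[g] = 0.0
                else:
                    normality[g] = float(sps.shapiro(s).pvalue)
            method = "anova" if all(p > alpha for p in normality.values()) else "kruskal"
    elif small:
        warn.append(f"groups with n<3 ({small}); forcing nonparametric tests")
        method = "kruskal"

    m = len(names) * (len(names) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    if method == "anova":
        if np.ptp(np.concatenate(samples)) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.f_oneway(*samples)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if np.ptp(np.concatenate([samples[i], samples[j]])) == 0:
                    praw = 1.0
                else:
                    praw = float(sps.ttest_ind(samples[i], samples[j]).pvalue)
                pairwise[(names[i], names[j])] = min(1.0, praw * m)
    else:
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            stat, p = 0.0, 1.0
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    pairwise[(names[i], names[j])] = 1.0
        else:
            stat, p = sps.kruskal(*samples)
            pairwise = _dunn_test(names, samples, m)
    return GroupComparison(method=method, statistic=float(stat),
                           p_value=float(p), pairwise=pairwise,
                           normality_p=normality, warnings=tuple(warn))


def _dunn_test(names, samples, m) -> dict[tuple[str, str], float]:
    """Dunn's post-hoc z tests on pooled ranks, tie-corrected,
    Bonferroni-adjusted over the m comparisons."""
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_tot = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start:start + len(s)].mean())
        start += len(s)
    out = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_term * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            praw = 2.0 * sps.norm.sf(abs(z))
            out[(names[i], names[j])] = min(1.0, float(praw) * m)
    return out


def repeatability_table(deposition: pd.DataFrame,
                        loa_multiplier: float = 1.96) -> pd.DataFrame:
    """Bland–Altman summary per group x site x device.

    ``deposition`` is the engine's long-format table (one row per
    subject x device x repetition with pd_pct/etd_pct).  Output mirrors
    a published repeatability grid: n, bias, p, LoA, CR for the lung
    and extrathoracic site of every device within every group.
    """
    rows = []
    wide = deposition.pivot_table(
        index=["group", "subject_id", "device"], columns="repetition",
        values=["pd_pct", "etd_pct"])
    for (group, device), sub in wide.groupby(level=["group", "device"]):
        for site, col in (("lung", "pd_pct"), ("et", "etd_pct")):
            first = sub[(col, 1)].to_numpy()
            second = sub[(col, 2)].to_numpy()
            ba = bland_altman(first, second, loa_multiplier)
            rows.append({"group": group, "site": site, "device": device,
                         "n": ba.n, "bias": ba.bias, "p": ba.p_value,
                         "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                         "cr": ba.cr})
    return pd.DataFrame(rows)
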