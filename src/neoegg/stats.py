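"""Cohort-level statistics.

Two analyses mirror the study design:

* one-way ANOVA across the three feeding phases (pre / during / post)
  within a GA group, band and feature, followed by Tukey's HSD post-hoc
  test for the three phase pairs;
* ordinary least-squares regression of a feature on gestational age
  (weeks), reporting slope, intercept, r² and the two-sided p-value of
  the slope.

The significance level is 0.05 throughout; no correction is applied
beyond Tukey's (a Benjamini–Hochberg option exists but defaults off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatResult", "CohortTable", "anova_across_phases",
           "regress_on_ga", "null_calibration", "benjamini_hochberg"]

ALPHA = 0.05

PHASES = ("pre", "during", "post")

#: Tidy per-subject feature table columns.
COHORT_COLUMNS = ("subject_id", "ga_weeks", "ga_group", "phase", "band",
                  "feature", "value")

CohortTable = pd.DataFrame


@dataclass
class StatResult:
    """One test outcome: ANOVA cell, Tukey pair, or regression."""

    kind: str                  # anova | tukey_pair | regression
    label: str                 # e.g. "early/normo/mPSD" or "pre-during"
    statistic: float           # F, or Tukey's q-derived statistic, or slope
    p_value: float
    n: int
    r_squared: float | None = None
    slope: float | None = None
    intercept: float | None = None
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _cell(table: CohortTable, **filters) -> CohortTable:
    out = table
    for col, val in filters.items():
        out = out[out[col] == val]
    return out


def anova_across_phases(table: CohortTable, ga_group: str, band: str,
                        feature: str) -> tuple[StatResult, list[StatResult]]:
    """One-way ANOVA of a feature across phases within one GA group/band,
    with Tukey HSD pairwise comparisons.

    Returns the ANOVA result and the list of phase-pair results.
    """
    cell = _cell(table, ga_group=ga_group, band=band, feature=feature)
    groups = [cell[cell["phase"] == ph]["value"].to_numpy(dtype=float)
              for ph in PHASES]
    present = [(ph, g) for ph, g in zip(PHASES, groups) if len(g) > 0]
    if len(present) < 2 or any(len(g) < 2 for _, g in present):
        raise ValueError(
            f"insufficient data for ANOVA in cell "
            f"({ga_group}, {band}, {feature}): need >= 2 phases with >= 2 "
            "observations each")
    names = [ph for ph, _ in present]
    data = [g for _, g in present]

    f_stat, p = sps.f_oneway(*data)
    n_total = sum(len(g) for g in data)
    anova = StatResult("anova", f"{ga_group}/{band}/{feature}",
                       float(f_stat), float(p), n_total)

    tukey = sps.tukey_hsd(*data)
    pairs: list[StatResult] = []
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            pairs.append(StatResult(
                "tukey_pair",
                f"{ga_group}/{band}/{feature}:{names[i]}-{names[j]}",
                float(tukey.statistic[i, j]), float(tukey.pvalue[i, j]),
                len(data[i]) + len(data[j])))
    return anova, pairs


def regress_on_ga(table: CohortTable, phase: str, band: str,
                  feature: str) -> StatResult:
    """OLS of a feature on gestational age for one phase and band."""
    cell = _cell(table, phase=phase, band=band, feature=feature)
    ga = cell["ga_weeks"].to_numpy(dtype=float)
    y = cell["value"].to_numpy(dtype=float)
    if len(np.unique(ga)) < 3:
        raise ValueError(
            f"regression in cell ({phase}, {band}, {feature}) needs >= 3 "
            "subjects with distinct gestational ages")
    if np.ptp(ga) == 0:
        raise ValueError("gestational age is constant; cannot regress")
    res = sps.linregress(ga, y)
    return StatResult("regression", f"{phase}/{band}/{feature}",
                      float(res.slope), float(res.pvalue), len(ga),
                      r_squared=float(res.rvalue ** 2),
                      slope=float(res.slope), intercept=float(res.intercept))


def null_calibration(ga: np.ndarray, y: np.ndarray, reps: int = 1000,
                     seed: int = 0, alpha: float = ALPHA) -> float:
    """Type-I error of the GA regression under the null.

    Permutes the GA labels ``reps`` times and returns the fraction of
    permutations whose slope p-value falls below ``alpha``; for a
    well-calibrated test this is ≈ alpha.
    """
    ga = np.asarray(ga, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(ga)
        if np.ptp(perm) == 0:
            continue
        res = sps.linregress(perm, y)
        hits += res.pvalue < alpha
    return hits / reps


def benjamini_hochberg(results: list[StatResult]) -> np.ndarray:
    """BH-adjusted p-values (optional; the default reporting applies none)."""
    from statsmodels.stats.multitest import multipletests
    p = np.array([r.p_value for r in results])
    return multipletests(p, method="fdr_bh")[1]
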