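"""Reliability, variability and dimorphism statistics for repeated osteometric data.

Covers the standard intra-observer toolkit for two-repeat measurement designs:

* TEM — absolute technical error of measurement, sqrt(sum d_i^2 / 2n) over n
  duplicate pairs (mm);
* rTEM — TEM as a percentage of the grand mean of all 2n observations;
* R — coefficient of reliability, 1 - TEM^2/SD^2, the fraction of the
  between-subject variance not attributable to measurement error;
* CV — coefficient of variation, 100*SD/mean;
* SDI — sexual dimorphism index, 100*(male mean - female mean)/male mean;
* one-way ANOVA for sex and inter-population comparisons;
* a grouped summariser producing the per (measurement, group, sex) table of
  mean/SD/min/max/n with CV, SDI and the between-sex ANOVA appended.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "RepeatPair",
    "ReliabilityResult",
    "AnovaResult",
    "tem",
    "rtem",
    "reliability_r",
    "reliability_report",
    "cv",
    "sdi",
    "one_way_anova",
    "summarize",
    "dimorphism_table",
]

MEASUREMENTS = ("ab_mm", "bc_mm", "ac_mm")


@dataclass(frozen=True)
class RepeatPair:
    """Duplicate measurements of one specimen for one variable (mm)."""

    first_mm: float
    second_mm: float

    def __post_init__(self) -> None:
        if not (self.first_mm > 0 and self.second_mm > 0):
            raise ValueError("repeat measurements must be positive")


@dataclass(frozen=True)
class ReliabilityResult:
    tem_mm: float
    rtem_pct: float
    r_coeff: float


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int


def tem(pairs: Sequence[RepeatPair]) -> float:
    """Technical error of measurement for a two-repeat design.

    tem = sqrt( sum_i (first_i - second_i)^2 / (2 n) ).
    """
    if len(pairs) == 0:
        raise ValueError("tem requires at least one repeat pair")
    d = np.array([p.first_mm - p.second_mm for p in pairs])
    return float(np.sqrt(np.sum(d**2) / (2 * len(d))))


def rtem(tem_mm: float, grand_mean_mm: float) -> float:
    """Relative TEM (%): 100*tem/grand mean of all 2n observations."""
    if grand_mean_mm <= 0:
        raise ValueError("grand mean must be positive")
    return 100.0 * tem_mm / grand_mean_mm


def reliability_r(tem_mm: float, total_sd_mm: float) -> float:
    """Coefficient of reliability R = 1 - TEM^2 / SD^2.

    SD is the between-subject standard deviation of the variable; R <= 1,
    and can go negative when measurement error exceeds true variation.
    """
    if total_sd_mm <= 0:
        raise ValueError("total SD must be positive")
    return 1.0 - (tem_mm / total_sd_mm) ** 2


def reliability_report(pairs: Sequence[RepeatPair], total_sd_mm: float | None = None) -> ReliabilityResult:
    """TEM, rTEM and R for one variable's duplicate pairs.

    If ``total_sd_mm`` is not given, the sample SD of the 2n observations is
    used (small-subsample estimate of the between-subject SD).
    """
    t = tem(pairs)
    obs = np.array([[p.first_mm, p.second_mm] for p in pairs]).ravel()
    grand_mean = float(obs.mean())
    sd = float(np.std(obs, ddof=1)) if total_sd_mm is None else total_sd_mm
    return ReliabilityResult(tem_mm=t, rtem_pct=rtem(t, grand_mean), r_coeff=reliability_r(t, sd))


def cv(mean_mm: float, sd_mm: float) -> float:
    """Coefficient of variation (%): 100*SD/mean."""
    if mean_mm <= 0:
        raise ValueError("mean must be positive")
    return 100.0 * sd_mm / mean_mm


def sdi(mean_male_mm: float, mean_female_mm: float) -> float:
    """Sexual dimorphism index (%): 100*(M - F)/M.

    Positive when males are larger; 0 under identical means.
    """
    if mean_male_mm <= 0:
        raise ValueError("male mean must be positive")
    return 100.0 * (mean_male_mm - mean_female_mm) / mean_male_mm


def one_way_anova(groups: Iterable[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one_way_anova requires at least two groups")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    n_total = sum(len(g) for g in arrays)
    k = len(arrays)
    within_ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    means = [g.mean() for g in arrays]
    if within_ss == 0 and max(means) == min(means):
        raise ValueError("zero within-group variance with equal means: F undefined")
    f_stat, p_value = _sps.f_oneway(*arrays)
    return AnovaResult(
        f_stat=float(f_stat), p_value=float(p_value),
        df_between=k - 1, df_within=n_total - k,
    )


def summarize(
    table: pd.DataFrame,
    measurements: Sequence[str] = MEASUREMENTS,
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Per (measurement, group, sex) summary rows: mean, sd, min, max, n.

    ``table`` must carry ``group`` and ``sex`` label columns plus the
    measurement columns.  When ``include_pooled`` the groups-pooled cells are
    appended under group "Pooled".  Ordering is deterministic (measurement,
    then group alphabetical with Pooled last, then sex F before M).  A cell
    with a single observation gets sd = NaN; empty cells are absent from the
    output and reported via the ``n`` column of present cells only.
    """
    frames = [table]
    if include_pooled:
        frames.append(table.assign(group="Pooled"))
    stacked = pd.concat(frames, ignore_index=True)

    rows = []
    group_order = sorted(g for g in stacked["group"].unique() if g != "Pooled")
    if include_pooled:
        group_order.append("Pooled")
    for meas in measurements:
        for group in group_order:
            for sex in ("F", "M"):
                cell = stacked.loc[(stacked["group"] == group) & (stacked["sex"] == sex), meas]
                if cell.empty:
                    continue
                rows.append({
                    "measurement": meas, "group": group, "sex": sex,
                    "mean": float(cell.mean()),
                    "sd": float(cell.std(ddof=1)) if len(cell) > 1 else float("nan"),
                    "min": float(cell.min()), "max": float(cell.max()),
                    "n": int(len(cell)),
                })
    return pd.DataFrame(rows)


def dimorphism_table(table: pd.DataFrame, measurements: Sequence[str] = MEASUREMENTS) -> pd.DataFrame:
    """Summary statistics with CV, SDI and the between-sex ANOVA appended.

    One row per (measurement, group, sex) cell; CV per cell, SDI and the
    male-vs-female one-way ANOVA (F, p on df=1) repeated on both sex rows of
    each (measurement, group) pair.  Mirrors the layout of a standard
    dimorphism report.
    """
    summary = summarize(table, measurements=measurements)
    summary["cv"] = [cv(m, s) for m, s in zip(summary["mean"], summary["sd"])]

    sdi_col, f_col, p_col = [], [], []
    pooled = pd.concat([table, table.assign(group="Pooled")], ignore_index=True)
    for _, row in summary.iterrows():
        cell = pooled[pooled["group"] == row["group"]]
        male = cell.loc[cell["sex"] == "M", row["measurement"]]
        female = cell.loc[cell["sex"] == "F", row["measurement"]]
        if len(male) >= 2 and len(female) >= 2:
            sdi_col.append(sdi(float(male.mean()), float(female.mean())))
            res = one_way_anova([male.to_numpy(), female.to_numpy()])
            f_col.append(res.f_stat)
            p_col.append(res.p_value)
        else:
            sdi_col.append(float("nan"))
            f_col.append(float("nan"))
            p_col.append(float("nan"))
    summary["sdi"] = sdi_col
    summary["F"] = f_col
    summary["p"] = [round(p, 4) if np.isfinite(p) else p for p in p_col]
    return summary
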