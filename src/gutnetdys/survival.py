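"""Kaplan–Meier survival, log-rank comparisons and per-bee feeding rates.

All estimators operate on aggregated per-cage per-day ledgers rather than
per-subject duration vectors: the cage experiment records daily death and
censoring counts, and the product-limit estimator and log-rank statistic
have exact forms on day-grouped data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import validate_feeding_ledger, validate_survival_ledger

logger = logging.getLogger("gutnetdys.survival")

__all__ = [
    "SurvivalCurve",
    "kaplan_meier",
    "median_survival",
    "logrank",
    "feeding_rate",
    "feeding_comparisons",
]


@dataclass
class SurvivalCurve:
    group: str
    times: np.ndarray      # event/censoring days, ascending
    s_hat: np.ndarray      # S(t) just after each day
    n_risk: np.ndarray     # at risk at the start of each day
    n_events: np.ndarray   # deaths during each day

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "day": self.times,
                "s_hat": self.s_hat,
                "n_risk": self.n_risk,
                "n_events": self.n_events,
            }
        )

    def at(self, day: float) -> float:
        """S(day): the step function value at (just after) ``day``."""
        idx = np.searchsorted(self.times, day, side="right") - 1
        return 1.0 if idx < 0 else float(self.s_hat[idx])


def _aggregate_group(ledger: pd.DataFrame, group) -> pd.DataFrame:
    sub = ledger[ledger["group"] == group]
    if sub.empty:
        raise ValueError(f"no survival ledger rows for group {group!r}")
    agg = (
        sub.groupby("day")[["n_at_risk", "deaths", "censored"]]
        .sum()
        .sort_index()
        .reset_index()
    )
    if (agg["deaths"] > agg["n_at_risk"]).any():
        raise ValueError(f"group {group!r}: deaths exceed the risk set")
    return agg


def kaplan_meier(ledger: pd.DataFrame, group) -> SurvivalCurve:
    """Product-limit estimate S(t) = Π_{d_i ≤ t} (1 − deaths_i / n_risk_i).

    Deaths and censoring are pooled across the group's cages per day;
    censored bees (weekly samplings) leave the risk set at the end of their
    day.  S is a right-continuous step function with S(0⁻) = 1.
    """
    ledger = validate_survival_ledger(ledger)
    agg = _aggregate_group(ledger, group)
    days = agg["day"].to_numpy()
    n_risk = agg["n_at_risk"].to_numpy(dtype=float)
    deaths = agg["deaths"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where(n_risk > 0, 1.0 - deaths / n_risk, 1.0)
    s_hat = np.cumprod(factors)
    return SurvivalCurve(
        group=str(group),
        times=days,
        s_hat=s_hat,
        n_risk=n_risk.astype(int),
        n_events=deaths.astype(int),
    )


def median_survival(curve: SurvivalCurve) -> float | None:
    """Smallest event day with S(t) ≤ 0.5, or None when S never gets there."""
    below = np.nonzero(curve.s_hat <= 0.5)[0]
    if below.size == 0:
        return None
    return float(curve.times[below[0]])


def logrank(ledger: pd.DataFrame, group_a, group_b) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two groups.

    Standard observed-minus-expected statistic over the pooled event days,
    with the hypergeometric variance term; censoring removes bees from the
    risk set after their day.
    """
    ledger = validate_survival_ledger(ledger)
    a = _aggregate_group(ledger, group_a).set_index("day")
    b = _aggregate_group(ledger, group_b).set_index("day")
    days = sorted(set(a.index) | set(b.index))

    o_minus_e = 0.0
    var = 0.0
    for day in days:
        n1 = float(a.loc[day, "n_at_risk"]) if day in a.index else 0.0
        n2 = float(b.loc[day, "n_at_risk"]) if day in b.index else 0.0
        d1 = float(a.loc[day, "deaths"]) if day in a.index else 0.0
        d2 = float(b.loc[day, "deaths"]) if day in b.index else 0.0
        n = n1 + n2
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def feeding_rate(ledger: pd.DataFrame) -> pd.DataFrame:
    """Per-bee daily syrup consumption.

    per_bee = syrup_consumed / mean(alive at t−1, alive at t) for each cage
    and day; rows whose mean alive count is zero are skipped with a warning.
    """
    ledger = validate_feeding_ledger(ledger)
    mean_alive = (ledger["alive_prev"] + ledger["alive_now"]) / 2.0
    skipped = int((mean_alive == 0).sum())
    if skipped:
        logger.warning("feeding_rate: skipped %d cage-day(s) with no living bees",
                       skipped)
    out = ledger.loc[mean_alive > 0, ["group", "cage", "day"]].copy()
    out["per_bee_consumption"] = (
        ledger.loc[mean_alive > 0, "syrup_consumed"] / mean_alive[mean_alive > 0]
    )
    return out.reset_index(drop=True)


def feeding_comparisons(
    rates: pd.DataFrame,
    control_group,
    paired_by_day: bool = False,
) -> pd.DataFrame:
    """Each group vs control on per-bee consumption.

    Default: two-sided Wilcoxon rank-sum over all cage-day values.  With
    ``paired_by_day``, cages are averaged within group per day and a
    Wilcoxon signed-rank test is run over the paired daily means.
    """
    ctrl = rates[rates["group"] == control_group]
    if ctrl.empty:
        raise ValueError(f"no feeding rows for control group {control_group!r}")
    rows = []
    for group, sub in rates.groupby("group"):
        if group == control_group:
            continue
        if paired_by_day:
            ga = sub.groupby("day")["per_bee_consumption"].mean()
            gc = ctrl.groupby("day")["per_bee_consumption"].mean()
            days = sorted(set(ga.index) & set(gc.index))
            diffs = ga.loc[days].to_numpy() - gc.loc[days].to_numpy()
            if np.allclose(diffs, 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(diffs)
            test = "wilcoxon_signed_rank"
        else:
            stat, p = stats.ranksums(
                sub["per_bee_consumption"], ctrl["per_bee_consumption"]
            )
            test = "wilcoxon_rank_sum"
        rows.append(
            {
                "group": group,
                "control": control_group,
                "test": test,
                "statistic": float(stat),
                "p": float(p),
                "median_group": float(sub["per_bee_consumption"].median()),
                "median_control": float(ctrl["per_bee_consumption"].median()),
            }
        )
    return pd.DataFrame(rows)


def feeding_daily_kw(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-day Kruskal–Wallis across all groups' cage values."""
    rows = []
    for day, sub in rates.groupby("day"):
        groups = [g["per_bee_consumption"].to_numpy()
                  for _, g in sub.groupby("group")]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            continue
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        rows.append({"day": day, "kw_H": float(h), "kw_p": float(p)})
    return pd.DataFrame(rows)
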