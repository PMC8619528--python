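"""Per-condition differential activity of ASVs versus the unexposed control.

A deliberately simple, fully specified statistic: counts are normalised by
median-of-ratios size factors within the two-arm subset, the effect size is
a pseudocounted log2 ratio of normalised means, significance comes from a
two-sided Wilcoxon rank-sum test per ASV with Benjamini–Hochberg adjustment
across the subset.  This trades the negative-binomial machinery of dedicated
DE engines for exact reproducibility and transparent assumptions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ActivityTable, condition_samples

logger = logging.getLogger("gutnetdys.differential")

__all__ = ["size_factors", "diff_activity"]

#: Pseudocount added to normalised means before taking the log2 ratio.
PSEUDOCOUNT = 0.5


def size_factors(table: ActivityTable, fallback: bool = True) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    factor_j = median over taxa of count_ij / geometric-mean_i(count_i·),
    medians taken over taxa with all-positive counts, then normalised so the
    factors themselves have geometric mean 1.

    When no taxon is positive in every sample, the ``fallback`` computes
    geometric means over positive entries only (zeros skipped), the common
    "poscounts" convention; with ``fallback=False`` that situation is an
    error.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValueError("size factors need at least two samples")
    all_positive = (counts > 0).all(axis=0)
    if all_positive.any():
        sub = counts[:, all_positive]
        geo = np.exp(np.log(sub).mean(axis=0))
        ratios = sub / geo
    elif fallback:
        logger.warning(
            "size_factors: no taxon positive in all samples; "
            "using positive-entry geometric means (poscounts)"
        )
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        geo = np.exp(np.nanmean(logc, axis=0))
        keep = np.isfinite(geo) & (geo > 0)
        if not keep.any():
            raise ValueError("size factors undefined: table has no positive counts")
        with np.errstate(invalid="ignore"):
            ratios = np.where(counts[:, keep] > 0,
                              counts[:, keep] / geo[keep], np.nan)
    else:
        raise ValueError(
            "no taxon with all-positive counts and poscounts fallback disabled"
        )
    factors = np.nanmedian(ratios, axis=1)
    if (~np.isfinite(factors) | (factors <= 0)).any():
        raise ValueError("degenerate size factors; check the activity table")
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return pd.Series(factors, index=table.sample_ids, name="size_factor")


def diff_activity(
    table: ActivityTable,
    meta: pd.DataFrame,
    section: str,
    dose_ppb: float,
    control_dose_ppb: float = 0.0,
    alpha: float = 0.05,
    min_per_arm: int = 3,
) -> pd.DataFrame:
    """Differential ASV activity for one gut section, dose vs control.

    Returns one row per ASV present in at least one arm:
    ``asv_id, section, dose_ppb, base_mean, log2fc, p_raw, p_adj, direction,
    significant``.  log2fc = log2((mean_exposed + c)/(mean_control + c)) on
    size-factor-normalised counts with pseudocount c = 0.5; p from the
    two-sided Wilcoxon rank-sum test; BH across all retained ASVs;
    significance flagged at adjusted p < ``alpha``.
    """
    exposed_ids = condition_samples(meta, section, dose_ppb)
    control_ids = condition_samples(meta, section, control_dose_ppb)
    exposed_ids = [s for s in exposed_ids if s in table.counts.index]
    control_ids = [s for s in control_ids if s in table.counts.index]
    if len(exposed_ids) < min_per_arm or len(control_ids) < min_per_arm:
        raise ValueError(
            f"condition ({section}, {dose_ppb:g} ppb vs {control_dose_ppb:g}): "
            f"needs ≥{min_per_arm} samples per arm, has "
            f"{len(exposed_ids)} exposed / {len(control_ids)} control"
        )
    subset = table.subset(control_ids + exposed_ids)
    factors = size_factors(subset)
    norm = subset.counts.div(factors, axis=0)

    present = (norm.sum(axis=0) > 0).to_numpy()
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("diff_activity: %d ASV(s) absent in both arms suppressed",
                    n_dropped)
    norm = norm.loc[:, present]

    ctrl = norm.loc[control_ids].to_numpy()
    expo = norm.loc[exposed_ids].to_numpy()
    mean_c = ctrl.mean(axis=0)
    mean_e = expo.mean(axis=0)
    log2fc = np.log2((mean_e + PSEUDOCOUNT) / (mean_c + PSEUDOCOUNT))

    p_raw = np.empty(norm.shape[1])
    for k in range(norm.shape[1]):
        if np.all(expo[:, k] == expo[0, k]) and np.all(ctrl[:, k] == ctrl[0, k]) \
                and expo[0, k] == ctrl[0, k]:
            p_raw[k] = 1.0  # identical constant arms: no evidence either way
        else:
            p_raw[k] = stats.ranksums(expo[:, k], ctrl[:, k]).pvalue
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "asv_id": norm.columns,
            "section": section,
            "dose_ppb": float(dose_ppb),
            "base_mean": (mean_c + mean_e) / 2.0,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["significant"] = out["p_adj"] < alpha
    return out


def diff_all_conditions(
    table: ActivityTable, meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Run diff_activity for every section × nonzero dose cell."""
    frames = []
    sections = sorted(meta["gut_section"].unique())
    doses = sorted(d for d in meta["dose_ppb"].unique() if d > 0)
    for section in sections:
        for dose in doses:
            frames.append(diff_activity(table, meta, section, dose, alpha=alpha))
    return pd.concat(frames, ignore_index=True)
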