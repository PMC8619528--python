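"""Alpha diversity and the nonparametric group-comparison chain.

Per-sample richness (bias-corrected Chao1) and Shannon diversity (nats) are
computed on raw ASV counts, without rarefaction; sample depths are reported
alongside so comparability can be judged.  Group comparisons follow
Kruskal–Wallis → Dunn's post hoc → Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as skbio_alpha
from statsmodels.stats.multitest import multipletests

from .types import ActivityTable

logger = logging.getLogger("gutnetdys.diversity")

__all__ = ["chao1", "shannon", "alpha_diversity", "kw_dunn"]


def chao1(counts: Sequence[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1·(F1−1) / (2·(F2+1)).

    F1 and F2 are the singleton and doubleton counts.  Defined on raw
    integer counts only (undefined on normalised data); an all-zero sample
    has richness 0.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("chao1 requires non-negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("chao1 is undefined on non-integer (normalised) counts")
    arr = np.round(arr).astype(int)
    if arr.sum() == 0:
        return 0.0
    return float(skbio_alpha.chao1(arr, bias_corrected=True))


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity H = −Σ p_i ln p_i, in nats."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("shannon requires non-negative counts")
    if arr.sum() == 0:
        raise ValueError("shannon is undefined for a zero-sum sample")
    return float(skbio_alpha.shannon(arr, base=np.e))


def alpha_diversity(table: ActivityTable) -> pd.DataFrame:
    """Per-sample observed taxa, Chao1, Shannon and sequencing depth."""
    rows = []
    for sid in table.sample_ids:
        counts = table.counts.loc[sid].to_numpy()
        rows.append(
            {
                "sample_id": sid,
                "observed": int((counts > 0).sum()),
                "chao1": chao1(counts),
                "shannon": shannon(counts),
                "depth": float(counts.sum()),
            }
        )
    return pd.DataFrame(rows)


def kw_dunn(groups: Mapping[str, Sequence[float]]) -> tuple[float, float, pd.DataFrame]:
    """Kruskal–Wallis omnibus test plus Dunn's pairwise post hoc with BH.

    Parameters
    ----------
    groups
        Mapping of group label → values.  At least two groups with at least
        two values each.

    Returns
    -------
    (H, p_kw, pairwise)
        Tie-corrected Kruskal–Wallis H and p, and a DataFrame with one row
        per unordered pair: ``comparison, dunn_z, p_raw, p_bh``.  Dunn's z
        uses pooled mean ranks with the standard tie correction; BH is
        applied across the pairwise family.
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(labels) < 2:
        raise ValueError("kw_dunn needs at least two groups")
    for g, arr in zip(labels, data):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than two values")

    pooled = np.concatenate(data)
    if np.all(pooled == pooled[0]):
        h_stat, p_kw = 0.0, 1.0
    else:
        h_stat, p_kw = stats.kruskal(*data)

    # Dunn's test on pooled ranks
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for g, arr in zip(labels, data):
        mean_ranks[g] = ranks[start : start + arr.size].mean()
        sizes[g] = arr.size
        start += arr.size
    # tie correction: sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            se = np.sqrt(var_factor * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
            if se == 0.0:  # every pooled value tied
                z = 0.0
            else:
                z = (mean_ranks[ga] - mean_ranks[gb]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"comparison": f"{ga} vs {gb}", "dunn_z": z, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_bh"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]
    return float(h_stat), float(p_kw), pairwise


def diversity_comparisons(
    diversity: pd.DataFrame,
    meta: pd.DataFrame,
    metric: str = "shannon",
    stratify_section: bool = False,
) -> pd.DataFrame:
    """Compare a diversity metric across doses, pooled or per gut section."""
    merged = diversity.merge(meta, on="sample_id")
    out = []
    strata = merged.groupby("gut_section") if stratify_section else [("all", merged)]
    for section, sub in strata:
        groups = {
            f"{dose:g} ppb": grp[metric].to_numpy()
            for dose, grp in sub.groupby("dose_ppb")
        }
        h_stat, p_kw, pairwise = kw_dunn(groups)
        pairwise = pairwise.assign(section=section, metric=metric,
                                   kw_H=h_stat, kw_p=p_kw)
        out.append(pairwise)
    return pd.concat(out, ignore_index=True)
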