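"""Genus-level co-abundance network inference per experimental condition.

For each (gut section, dose) condition subset: ASV activities are summed to
the genus level, genera present in fewer than 8 of the 10 condition samples
are dropped, Spearman rank correlations are computed between all retained
genus pairs on per-sample relative activity, and the pair family is screened
with both a Benjamini–Hochberg FDR and a Bonferroni correction.  An edge is
kept when |rho| ≥ 0.4 AND the BH-adjusted p < 0.05 AND the
Bonferroni-adjusted p < 0.05 — the dual correction is redundant (Bonferroni
dominates) but is enforced deliberately; ``bonferroni=False`` relaxes to
FDR-only.  Edge sign follows the sign of rho.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ActivityTable, Lineage, condition_samples

logger = logging.getLogger("gutnetdys.conetwork")

__all__ = [
    "CorrelationScreen",
    "TaxonNetwork",
    "aggregate_genus",
    "occurrence_filter",
    "spearman_screen",
    "build_network",
    "run_all_conditions",
    "RHO_THRESHOLD",
    "EDGE_ALPHA",
]

#: Absolute Spearman rho an edge must reach.
RHO_THRESHOLD = 0.4
#: Significance level applied to both adjusted p-value clauses.
EDGE_ALPHA = 0.05
#: Occurrence rule: a genus must be present in strictly more than this
#: fraction of a condition's samples (8 of 10 at the design size).
OCCURRENCE_FRACTION = 0.7


@dataclass
class CorrelationScreen:
    """Upper-triangle Spearman screen for one condition subset.

    ``pairs`` has one row per unordered genus pair with columns
    ``a, b, rho, p_raw, p_bh, p_bonf``; pairs involving a genus that is
    constant across the subset are excluded from the testing family.
    """

    section: str
    dose_ppb: float
    genus_ids: list[str]
    n_samples: int
    pairs: pd.DataFrame
    n_family: int = 0


@dataclass
class TaxonNetwork:
    """Genus co-abundance graph for one condition.

    Nodes carry ``total_activity`` (summed relative activity over the
    subset), ``occurrence`` (samples present) and ``taxon_class``
    (core / noncore / low_activity); edges carry ``rho``, ``sign`` and the
    three p-values.
    """

    section: str
    dose_ppb: float
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_pos_edges(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "+")

    @property
    def n_neg_edges(self) -> int:
        return sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "-")


def genus_label(lineage: Lineage) -> str:
    """Genus-level aggregation label for one ASV lineage.

    ASVs assigned to genus (or deeper) aggregate under the genus name; ASVs
    resolved only to a shallower rank fall into an
    ``unassigned_<rank>_<name>`` bucket; fully unassigned ASVs pool under
    ``unassigned``.
    """
    if lineage.genus:
        return lineage.genus
    rank = lineage.assigned_rank
    if rank is None:
        return "unassigned"
    return f"unassigned_{rank}_{lineage.name_at(rank)}"


def aggregate_genus(
    table: ActivityTable, lineages: dict[str, Lineage]
) -> ActivityTable:
    """Sum ASV activities to the genus level.

    Columns of the result are ordered by descending total activity, ties
    broken lexicographically, so output order is deterministic.
    """
    missing = [t for t in table.taxon_ids if t not in lineages]
    if missing:
        raise KeyError(f"ASVs without a lineage (use the unassigned sentinel): "
                       f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    labels = {asv: genus_label(lineages[asv]) for asv in table.taxon_ids}
    grouped = table.counts.T.groupby(
        table.counts.columns.map(labels)
    ).sum().T
    totals = grouped.sum(axis=0)
    order = sorted(grouped.columns, key=lambda g: (-totals[g], g))
    return ActivityTable(grouped[order])


def occurrence_filter(
    table: ActivityTable,
    min_fraction: float = OCCURRENCE_FRACTION,
    min_samples: int = 4,
) -> list[str]:
    """Genera present (count > 0) in strictly more than ``min_fraction`` of
    the subset's samples — at the design size of 10, that is ≥ 8 of 10.
    """
    n = table.n_samples
    if n < min_samples:
        raise ValueError(
            f"condition subset has {n} samples; correlations need ≥ {min_samples}"
        )
    occurrence = (table.counts > 0).sum(axis=0)
    kept = [g for g in table.taxon_ids if occurrence[g] > min_fraction * n]
    logger.info(
        "occurrence_filter: kept %d of %d genera (present in > %g of %d samples)",
        len(kept), table.n_taxa, min_fraction * n, n,
    )
    return kept


def spearman_screen(
    table: ActivityTable,
    section: str = "",
    dose_ppb: float = float("nan"),
    use_relative: bool = True,
) -> CorrelationScreen:
    """Spearman correlation screen over all genus pairs of a subset.

    rho uses average-rank tie handling; two-sided p from the t
    approximation t = rho·√((n−2)/(1−rho²)) with n−2 df (p = 0 at |rho| = 1).
    BH and Bonferroni are applied across the family of non-degenerate
    upper-triangle pairs; pairs touching a genus constant across the subset
    are excluded from the family (logged).

    Spearman is rank-based, so using per-sample relative activity
    (``use_relative``, default) differs from raw counts only when sequencing
    depths differ between samples.
    """
    n, g = table.n_samples, table.n_taxa
    if n < 4:
        raise ValueError("spearman_screen needs at least 4 samples")
    if g < 2:
        raise ValueError("spearman_screen needs at least 2 genera")
    data = table.relative().counts if use_relative else table.counts
    mat = data.to_numpy(dtype=float)
    genus_ids = table.taxon_ids

    constant = [genus_ids[j] for j in range(g) if np.all(mat[:, j] == mat[0, j])]
    if constant:
        logger.warning(
            "spearman_screen: %d constant genus(era) excluded from the "
            "testing family: %s", len(constant), constant,
        )

    rows = []
    for i, j in itertools.combinations(range(g), 2):
        a, b = genus_ids[i], genus_ids[j]
        if a in constant or b in constant:
            rows.append({"a": a, "b": b, "rho": np.nan, "p_raw": np.nan})
            continue
        rho, p = stats.spearmanr(mat[:, i], mat[:, j])
        if abs(rho) >= 1.0 - 1e-12:  # degenerate: perfectly (anti)monotone
            rho, p = math.copysign(1.0, rho), 0.0
        rows.append({"a": a, "b": b, "rho": float(rho), "p_raw": float(p)})
    pairs = pd.DataFrame(rows, columns=["a", "b", "rho", "p_raw"])

    tested = pairs["p_raw"].notna()
    m = int(tested.sum())
    pairs["p_bh"] = np.nan
    pairs["p_bonf"] = np.nan
    if m:
        praw = pairs.loc[tested, "p_raw"].to_numpy()
        pairs.loc[tested, "p_bh"] = multipletests(praw, method="fdr_bh")[1]
        pairs.loc[tested, "p_bonf"] = np.minimum(1.0, praw * m)
    return CorrelationScreen(
        section=section, dose_ppb=dose_ppb, genus_ids=genus_ids,
        n_samples=n, pairs=pairs, n_family=m,
    )


def build_network(
    screen: CorrelationScreen,
    table: ActivityTable,
    classes: dict[str, str] | None = None,
    rho_threshold: float = RHO_THRESHOLD,
    alpha: float = EDGE_ALPHA,
    bonferroni: bool = True,
) -> TaxonNetwork:
    """Apply the edge rule to a correlation screen.

    An edge requires |rho| ≥ ``rho_threshold`` and BH-adjusted p < ``alpha``
    and (with ``bonferroni``, the default) Bonferroni-adjusted p < ``alpha``.
    Retained genera that gain no edge stay in the network as degree-0 nodes.
    """
    net = TaxonNetwork(section=screen.section, dose_ppb=screen.dose_ppb)
    rel = table.relative().counts
    classes = classes or {}
    for genus in screen.genus_ids:
        net.graph.add_node(
            genus,
            total_activity=float(rel[genus].sum()),
            occurrence=int((table.counts[genus] > 0).sum()),
            taxon_class=classes.get(genus, "noncore"),
        )
    kept = 0
    for row in screen.pairs.itertuples(index=False):
        if not np.isfinite(row.rho):
            continue
        ok = abs(row.rho) >= rho_threshold and row.p_bh < alpha
        if bonferroni:
            ok = ok and row.p_bonf < alpha
        if ok:
            net.graph.add_edge(
                row.a, row.b,
                rho=float(row.rho),
                sign="+" if row.rho > 0 else "-",
                p_raw=float(row.p_raw),
                p_fdr=float(row.p_bh),
                p_bonf=float(row.p_bonf),
            )
            kept += 1
    logger.info(
        "build_network(%s, %g ppb): %d node(s), %d edge(s) of %d tested pairs",
        screen.section, screen.dose_ppb, net.n_nodes, kept, screen.n_family,
    )
    return net


def condition_network(
    genus_table: ActivityTable,
    meta: pd.DataFrame,
    section: str,
    dose_ppb: float,
    classes: dict[str, str] | None = None,
    bonferroni: bool = True,
) -> TaxonNetwork:
    """Occurrence-filter, screen and build one condition's network."""
    ids = [s for s in condition_samples(meta, section, dose_ppb)
           if s in genus_table.counts.index]
    if not ids:
        raise ValueError(f"no samples for condition ({section}, {dose_ppb:g} ppb)")
    subset = genus_table.subset(ids)
    retained = occurrence_filter(subset)
    if len(retained) < 2:
        logger.warning(
            "condition (%s, %g ppb): fewer than 2 genera pass the occurrence "
            "filter; emitting an edgeless network", section, dose_ppb,
        )
        net = TaxonNetwork(section=section, dose_ppb=dose_ppb)
        rel = subset.relative().counts
        for genus in retained:
            net.graph.add_node(
                genus,
                total_activity=float(rel[genus].sum()),
                occurrence=int((subset.counts[genus] > 0).sum()),
                taxon_class=(classes or {}).get(genus, "noncore"),
            )
        return net
    filtered = ActivityTable(subset.counts[retained])
    screen = spearman_screen(filtered, section=section, dose_ppb=dose_ppb)
    return build_network(screen, filtered, classes=classes, bonferroni=bonferroni)


def run_all_conditions(
    genus_table: ActivityTable,
    meta: pd.DataFrame,
    classes_by_condition: dict[tuple[str, float], dict[str, str]] | None = None,
    bonferroni: bool = True,
) -> tuple[dict[tuple[str, float], TaxonNetwork], pd.DataFrame]:
    """Build the full grid of condition networks (12 for the study design).

    Returns the networks keyed by (section, dose) plus a summary table of
    node and signed-edge counts per condition.
    """
    sections = [s for s in ("midgut", "ileum", "rectum")
                if s in set(meta["gut_section"])]
    doses = sorted(meta["dose_ppb"].unique())
    missing = [
        (s, d) for s in sections for d in doses
        if not condition_samples(meta, s, d)
    ]
    if missing:
        raise ValueError(f"design cells without samples: {missing}")

    networks: dict[tuple[str, float], TaxonNetwork] = {}
    rows = []
    for section in sections:
        for dose in doses:
            classes = (classes_by_condition or {}).get((section, dose))
            net = condition_network(
                genus_table, meta, section, dose,
                classes=classes, bonferroni=bonferroni,
            )
            networks[(section, dose)] = net
            rows.append(
                {
                    "section": section,
                    "dose_ppb": dose,
                    "nodes": net.n_nodes,
                    "pos_edges": net.n_pos_edges,
                    "neg_edges": net.n_neg_edges,
                }
            )
    return networks, pd.DataFrame(rows)
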