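"""Dysbiosis signatures: exposed-vs-control network and activity shifts.

A signature compares one exposed condition's genus network with the control
network of the same gut section: node and signed-edge tallies, per-genus
gained and lost correlation partners, the direction of each genus's summed
relative activity change (with a ±10% stability band), a core / noncore /
low-activity classification, and keystone flags for jointly high-degree,
high-neighborhood-connectivity nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .conetwork import TaxonNetwork
from .types import ActivityTable, condition_samples

logger = logging.getLogger("gutnetdys.dysbiosis")

__all__ = [
    "DEFAULT_CORE_GENERA",
    "classify_taxa",
    "DysbiosisSignature",
    "signature",
    "keystone_flags",
]

#: Genera treated as core members of the healthy honeybee gut microbiota.
DEFAULT_CORE_GENERA = (
    "Lactobacillus",
    "Bifidobacterium",
    "Gilliamella",
    "Snodgrassella",
    "Frischella",
)

#: Low-activity rule: < 0.01% of the condition subset's total activity ...
LOW_ACTIVITY_FRACTION = 1e-4
#: ... present in fewer than this fraction of the subset's samples
#: (fewer than 3 of 10 at the design size).
LOW_OCCURRENCE_FRACTION = 0.3

#: Relative-activity change within ±10% counts as stable.
STABILITY_BAND = 0.10


def classify_taxa(
    genus_table: ActivityTable,
    core_genera: tuple[str, ...] = DEFAULT_CORE_GENERA,
) -> dict[str, str]:
    """Classify each genus of a condition subset as core, noncore or
    low_activity.

    low_activity requires BOTH a very low share of the subset's total
    activity (< 0.01%) AND presence in fewer than 3 of 10 samples (scaled as
    occurrence < 0.3·N); core membership is a configurable genus list and
    takes precedence; everything else is noncore.
    """
    counts = genus_table.counts
    total = counts.to_numpy().sum()
    n = genus_table.n_samples
    out: dict[str, str] = {}
    for genus in genus_table.taxon_ids:
        if genus in core_genera:
            out[genus] = "core"
            continue
        share = counts[genus].sum() / total if total > 0 else 0.0
        occurrence = int((counts[genus] > 0).sum())
        if share < LOW_ACTIVITY_FRACTION and occurrence < LOW_OCCURRENCE_FRACTION * n:
            out[genus] = "low_activity"
        else:
            out[genus] = "noncore"
    return out


@dataclass
class DysbiosisSignature:
    section: str
    dose_ppb: float
    nodes_control: int
    nodes_exposed: int
    pos_edges_control: int
    pos_edges_exposed: int
    neg_edges_control: int
    neg_edges_exposed: int
    #: per-genus rows: genus, activity_direction, partners_gained,
    #: partners_lost, taxon_class, keystone
    per_genus: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary_row(self) -> dict:
        return {
            "section": self.section,
            "dose_ppb": self.dose_ppb,
            "nodes_control": self.nodes_control,
            "nodes_exposed": self.nodes_exposed,
            "pos_edges_control": self.pos_edges_control,
            "pos_edges_exposed": self.pos_edges_exposed,
            "neg_edges_control": self.neg_edges_control,
            "neg_edges_exposed": self.neg_edges_exposed,
        }


def _activity_share(table: ActivityTable, meta, section, dose) -> pd.Series:
    ids = [s for s in condition_samples(meta, section, dose)
           if s in table.counts.index]
    rel = table.subset(ids).relative().counts
    return rel.sum(axis=0) / len(ids)


def signature(
    control_net: TaxonNetwork,
    exposed_net: TaxonNetwork,
    genus_table: ActivityTable,
    meta: pd.DataFrame,
    classes: dict[str, str] | None = None,
    keystone: dict[str, bool] | None = None,
    stability_band: float = STABILITY_BAND,
) -> DysbiosisSignature:
    """Extract the exposed-vs-control dysbiosis signature for one section.

    Per genus (union of both networks' nodes): correlation partners gained
    (neighbors in the exposed network only) and lost (control only), and the
    direction of the change in mean relative activity — ``up`` / ``down``
    outside the ±``stability_band``, ``stable`` within it.
    """
    if control_net.section != exposed_net.section:
        raise ValueError(
            f"section mismatch: control {control_net.section!r} vs "
            f"exposed {exposed_net.section!r}"
        )
    section = control_net.section
    share_control = _activity_share(genus_table, meta, section,
                                    control_net.dose_ppb)
    share_exposed = _activity_share(genus_table, meta, section,
                                    exposed_net.dose_ppb)

    genera = sorted(set(control_net.graph.nodes) | set(exposed_net.graph.nodes))
    rows = []
    for genus in genera:
        nb_c = set(control_net.graph.neighbors(genus)) \
            if genus in control_net.graph else set()
        nb_e = set(exposed_net.graph.neighbors(genus)) \
            if genus in exposed_net.graph else set()
        a0 = float(share_control.get(genus, 0.0))
        a1 = float(share_exposed.get(genus, 0.0))
        if a0 == 0.0:
            direction = "up" if a1 > 0 else "stable"
        else:
            change = (a1 - a0) / a0
            if change > stability_band:
                direction = "up"
            elif change < -stability_band:
                direction = "down"
            else:
                direction = "stable"
        rows.append(
            {
                "genus": genus,
                "activity_direction": direction,
                "partners_gained": ",".join(sorted(nb_e - nb_c)),
                "partners_lost": ",".join(sorted(nb_c - nb_e)),
                "n_partners_gained": len(nb_e - nb_c),
                "n_partners_lost": len(nb_c - nb_e),
                "taxon_class": (classes or {}).get(genus, "noncore"),
                "keystone": bool((keystone or {}).get(genus, False)),
            }
        )
    return DysbiosisSignature(
        section=section,
        dose_ppb=exposed_net.dose_ppb,
        nodes_control=control_net.n_nodes,
        nodes_exposed=exposed_net.n_nodes,
        pos_edges_control=control_net.n_pos_edges,
        pos_edges_exposed=exposed_net.n_pos_edges,
        neg_edges_control=control_net.n_neg_edges,
        neg_edges_exposed=exposed_net.n_neg_edges,
        per_genus=pd.DataFrame(rows),
    )


def keystone_flags(
    topo: pd.DataFrame, quantile: float = 0.75
) -> dict[str, bool]:
    """Flag keystone genera: degree AND neighborhood connectivity both in
    the top quartile (configurable) of the network's nonzero-degree nodes.
    """
    connected = topo[topo["degree"] > 0]
    if connected.empty:
        return {g: False for g in topo["genus"]}
    dg_cut = connected["degree"].quantile(quantile)
    nc_cut = connected["neighborhood_connectivity"].quantile(quantile)
    flags = {}
    for row in topo.itertuples(index=False):
        flags[row.genus] = bool(
            row.degree > 0
            and row.degree >= dg_cut
            and row.neighborhood_connectivity >= nc_cut
        )
    return flags
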