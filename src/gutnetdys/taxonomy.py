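"""Taxonomic assignment of ASVs from BLAST tabular hits.

The assignment rule mirrors common practice for 16S amplicons against the
NCBI 16S Microbial database: a best hit above the identity threshold (98%
by default) is taken at face value; otherwise the lineages of the top 50
hits (ranked by bitscore) are reconciled by lowest common ancestor, in the
spirit of MEGAN's naive LCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .types import Lineage, RANKS

logger = logging.getLogger("gutnetdys.taxonomy")

__all__ = ["BlastHit", "lca", "assign_taxon", "assign_all", "read_blast_hits"]

#: Columns of BLAST tabular output (-outfmt 6) plus staxids as column 13.
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "staxids",
)


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_taxid: str
    percent_identity: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )


def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Lowest common ancestor of a set of lineages.

    Walks superkingdom → species and keeps the deepest rank at which all
    inputs agree; disagreement already at superkingdom yields the unassigned
    sentinel.  Unassigned inputs are ignored (they constrain nothing); an
    empty list is an error.
    """
    if len(lineages) == 0:
        raise ValueError("lca of an empty lineage list is undefined")
    informative = [lin for lin in lineages if not lin.is_unassigned]
    if not informative:
        return Lineage.unassigned()
    depth = 0
    for i in range(len(RANKS)):
        names = {lin.names[i] for lin in informative}
        if len(names) == 1 and names != {""}:
            depth = i + 1
        else:
            break
    return informative[0].truncate(depth)


def assign_taxon(
    hits: Sequence[BlastHit],
    lineage_lookup: Mapping[str, Lineage],
    identity_threshold: float = 98.0,
    top_n: int = 50,
) -> Lineage:
    """Assign a lineage to one query from its BLAST hits.

    If the best hit's identity is strictly above ``identity_threshold`` the
    hit's full lineage is returned; otherwise the LCA of the top ``top_n``
    hits by bitscore.  Hits whose taxid is missing from the lookup are
    dropped with a warning; no usable hits yield the unassigned sentinel.
    """
    ranked = sorted(
        enumerate(hits), key=lambda ih: (-ih[1].bitscore, ih[0])
    )
    usable: list[BlastHit] = []
    for _, hit in ranked:
        if hit.subject_taxid in lineage_lookup:
            usable.append(hit)
        else:
            logger.warning(
                "query %s: taxid %s missing from lineage lookup; hit dropped",
                hit.query_id, hit.subject_taxid,
            )
    if not usable:
        logger.info("query %s: no usable hits, left unassigned",
                    hits[0].query_id if hits else "<empty>")
        return Lineage.unassigned()
    best = usable[0]
    if best.percent_identity > identity_threshold:
        return lineage_lookup[best.subject_taxid]
    top = usable[: min(top_n, len(usable))]
    return lca([lineage_lookup[h.subject_taxid] for h in top])


def assign_all(
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    lineage_lookup: Mapping[str, Lineage],
    identity_threshold: float = 98.0,
    top_n: int = 50,
) -> dict[str, Lineage]:
    return {
        q: assign_taxon(h, lineage_lookup, identity_threshold, top_n)
        for q, h in hits_by_query.items()
    }


def read_blast_hits(path: str | Path) -> dict[str, list[BlastHit]]:
    """Parse BLAST -outfmt 6 (with staxids as the 13th column), grouped by
    query in input order."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS,
                     dtype={"qseqid": str, "staxids": str})
    out: dict[str, list[BlastHit]] = {}
    for _, row in df.iterrows():
        # multi-taxid subjects ("taxid1;taxid2") keep the first taxid
        taxid = str(row["staxids"]).split(";")[0]
        out.setdefault(row["qseqid"], []).append(
            BlastHit(
                query_id=row["qseqid"],
                subject_taxid=taxid,
                percent_identity=float(row["pident"]),
                bitscore=float(row["bitscore"]),
            )
        )
    return out
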