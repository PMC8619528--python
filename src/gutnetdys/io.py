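"""Readers and writers for the pipeline's on-disk formats.

Tabular inputs are TSV (UTF-8, header row); activity tables may also arrive
as dense BIOM-style JSON.  Networks are exported in three Cytoscape-friendly
dialects: SIF, GraphML and an edge TSV that round-trips the signed edge set
exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    ActivityTable,
    Lineage,
    RANKS,
    ValidationError,
    validate_feeding_ledger,
    validate_metadata,
    validate_survival_ledger,
)

logger = logging.getLogger("gutnetdys.io")

#: Fixed float formatting for every TSV the pipeline writes (6 significant
#: digits) so re-runs produce byte-identical artifacts across platforms.
FLOAT_FORMAT = "%.6g"

EDGE_TSV_COLUMNS = ("source", "target", "rho", "p_raw", "p_fdr", "p_bonf", "sign")


# ---------------------------------------------------------------------------
# activity tables
# ---------------------------------------------------------------------------

def read_activity_table(
    path: str | Path,
    format: str = "tsv",
    known_samples: Iterable[str] | None = None,
    require_integer: bool = True,
) -> ActivityTable:
    """Read a samples × taxa activity table.

    TSV dialect: first column = sample id, remaining columns = taxon ids,
    header row present.  Orientation is fixed as samples-in-rows; the
    transpose is auto-detected only when the column ids match a known sample
    list (``known_samples``) — silent transposition is the classic microbiome
    pipeline bug, so anything else is an error.

    Samples whose row sums to zero are dropped with a logged warning.
    Negative or non-integer entries (for raw tables) are hard errors naming
    the offending cell.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "biom_json":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown activity table format: {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if known_samples is not None:
        known = set(map(str, known_samples))
        rows_match = len(set(df.index) & known) > 0
        cols_match = len(set(df.columns) & known) > 0
        if cols_match and not rows_match:
            logger.warning("activity table %s appears transposed; fixing", path.name)
            df = df.T

    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError(f"{path.name}: non-numeric entries in activity table")
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ValidationError(
            f"{path.name}: negative count {vals[i, j]} at sample "
            f"{df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    if require_integer and not np.allclose(vals, np.round(vals)):
        i, j = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise ValidationError(
            f"{path.name}: non-integer count {vals[i, j]} at sample "
            f"{df.index[i]!r}, taxon {df.columns[j]!r}"
        )

    zero = vals.sum(axis=1) == 0
    if zero.any():
        dropped = df.index[zero].tolist()
        logger.warning(
            "read_activity_table: dropped %d all-zero sample(s): %s",
            len(dropped),
            dropped,
        )
        df = df.loc[~zero]
    return ActivityTable(df)


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Dense BIOM-style JSON: observations are taxa (rows), columns samples."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    data = np.asarray(doc["data"], dtype=float)
    if doc.get("matrix_type", "dense") != "dense":
        raise ValidationError(f"{path.name}: only dense BIOM JSON is supported")
    if data.shape != (len(taxa), len(samples)):
        raise ValidationError(
            f"{path.name}: BIOM data shape {data.shape} inconsistent with "
            f"{len(taxa)} observations × {len(samples)} samples"
        )
    # BIOM stores observations × samples; our convention is samples × taxa.
    return pd.DataFrame(data.T, index=samples, columns=taxa)


def write_activity_table(table: ActivityTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id",
                        float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# metadata and ledgers
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


def read_survival_ledger(path: str | Path) -> pd.DataFrame:
    return validate_survival_ledger(pd.read_csv(path, sep="\t"))


def read_feeding_ledger(path: str | Path) -> pd.DataFrame:
    return validate_feeding_ledger(pd.read_csv(path, sep="\t"))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with the pipeline's fixed float format."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# lineages
# ---------------------------------------------------------------------------

def read_lineage_table(path: str | Path,
                       id_column: str | None = None) -> dict[str, Lineage]:
    """Read an id→lineage lookup TSV: an identifier column (``taxid`` or
    ``asv_id``, auto-detected unless given) plus the seven rank columns."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if id_column is None:
        candidates = [c for c in ("taxid", "asv_id") if c in df.columns]
        if not candidates:
            raise ValidationError(
                "lineage table needs a 'taxid' or 'asv_id' column"
            )
        id_column = candidates[0]
    elif id_column not in df.columns:
        raise ValidationError(f"lineage table has no {id_column!r} column")
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValidationError(f"lineage table missing rank columns: {missing}")
    out: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        out[str(row[id_column])] = Lineage.from_ranks(
            {r: row[r] for r in RANKS}
        )
    return out


def write_lineage_table(lineages: dict[str, Lineage], path: str | Path,
                        id_column: str = "taxid") -> None:
    rows = [{id_column: k, **lin.as_dict()} for k, lin in lineages.items()]
    pd.DataFrame(rows, columns=[id_column, *RANKS]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(network, path: str | Path, format: str = "edge_tsv") -> None:
    """Export a genus co-abundance network.

    SIF dialect: ``source<TAB>pp|pn<TAB>target`` (pp = positive, pn =
    negative correlation); isolated nodes appear as bare single-column lines.
    GraphML carries node attributes (activity, class) and edge attributes
    (rho, sign).  edge_tsv round-trips the signed edge set exactly via
    :func:`read_edge_tsv`.
    """
    path = Path(path)
    g = network.graph
    if format == "sif":
        with open(path, "w") as fh:
            covered: set[str] = set()
            for a, b, attrs in sorted(g.edges(data=True)):
                rel = "pp" if attrs["sign"] == "+" else "pn"
                fh.write(f"{a}\t{rel}\t{b}\n")
                covered.update((a, b))
            for node in sorted(set(g.nodes) - covered):
                fh.write(f"{node}\n")
    elif format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        rows = [
            {
                "source": a,
                "target": b,
                "rho": attrs["rho"],
                "p_raw": attrs["p_raw"],
                "p_fdr": attrs["p_fdr"],
                "p_bonf": attrs["p_bonf"],
                "sign": attrs["sign"],
            }
            for a, b, attrs in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(
            path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_edge_tsv(path: str | Path) -> set[tuple[str, str, str]]:
    """Recover the signed edge set ``{(source, target, sign), ...}`` with the
    endpoints of each edge in sorted order."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    edges = set()
    for _, row in df.iterrows():
        a, b = sorted((row["source"], row["target"]))
        edges.add((a, b, row["sign"]))
    return edges
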