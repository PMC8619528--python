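"""End-to-end orchestration with a deterministic run manifest.

``run_pipeline`` executes the stage chain
simulate (or load) → genus aggregation → diversity → differential activity
→ condition networks → topology → dysbiosis signatures → survival/feeding,
writes every artifact as TSV / SIF / GraphML with fixed float formatting,
and records a manifest (config hash, seed, per-file SHA-256 digests, filter
tallies) so re-runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as gio
from .conetwork import aggregate_genus, run_all_conditions
from .differential import diff_all_conditions
from .diversity import alpha_diversity, diversity_comparisons
from .dysbiosis import classify_taxa, keystone_flags, signature
from .survival import (
    feeding_comparisons,
    feeding_rate,
    kaplan_meier,
    logrank,
    median_survival,
)
from .synthetic import SynthConfig, generate_all
from .taxonomy import assign_all, read_blast_hits
from .topology import compare_condition_grid, topology_table
from .types import condition_samples

logger = logging.getLogger("gutnetdys.pipeline")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _load_inputs(config: dict) -> dict:
    if config.get("simulate", False):
        synth = SynthConfig(seed=int(config.get("seed", 0)),
                            **config.get("synthetic", {}))
        return generate_all(synth)
    counts = gio.read_activity_table(config["counts"])
    meta = gio.read_metadata(config["meta"])
    data: dict = {"meta": meta, "activity": counts}
    if "lineages" in config and "blast_hits" in config:
        lookup = gio.read_lineage_table(config["lineages"])
        hits = read_blast_hits(config["blast_hits"])
        data["lineages"] = assign_all(hits, lookup)
    elif "asv_lineages" in config:
        data["lineages"] = gio.read_lineage_table(config["asv_lineages"])
    else:
        raise ValueError(
            "config must provide either blast_hits+lineages or asv_lineages"
        )
    if "survival" in config:
        data["survival"] = gio.read_survival_ledger(config["survival"])
    if "feeding" in config:
        data["feeding"] = gio.read_feeding_ledger(config["feeding"])
    return data


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run every stage and write the artifact directory.

    ``config`` either sets ``simulate: true`` (with ``seed`` and optional
    ``synthetic`` overrides) or names real input files (``counts``, ``meta``,
    taxonomy inputs, optional ``survival`` / ``feeding`` ledgers).
    """
    out = Path(out_dir)
    nets_dir = out / "nets"
    nets_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": int(config.get("seed", 0)),
        "filters": {},
        "files": {},
    }

    data = _load_inputs(config)
    meta, table = data["meta"], data["activity"]
    missing = sorted(
        {(s, d) for s in meta["gut_section"].unique()
         for d in meta["dose_ppb"].unique()
         if not condition_samples(meta, s, d)}
    )
    if missing:
        raise ValueError(f"design cells without samples: {missing}")

    gio.write_table(meta, out / "meta.tsv")
    gio.write_activity_table(table, out / "activity_asv.tsv")
    gio.write_lineage_table(data["lineages"], out / "lineages.tsv", id_column="asv_id")

    # --- genus aggregation ---------------------------------------------
    genus_table = aggregate_genus(table, data["lineages"])
    gio.write_activity_table(genus_table, out / "activity_genus.tsv")
    manifest["filters"]["asvs"] = table.n_taxa
    manifest["filters"]["genera"] = genus_table.n_taxa

    # --- diversity ------------------------------------------------------
    div = alpha_diversity(table)
    gio.write_table(div, out / "diversity.tsv")
    gio.write_table(diversity_comparisons(div, meta),
                    out / "diversity_comparisons.tsv")

    # --- differential activity ------------------------------------------
    diff = diff_all_conditions(table, meta)
    gio.write_table(diff, out / "differential.tsv")
    manifest["filters"]["differential_significant"] = int(diff["significant"].sum())

    # --- condition networks ---------------------------------------------
    classes_by_condition = {
        (s, d): classify_taxa(genus_table.subset(condition_samples(meta, s, d)))
        for s in meta["gut_section"].unique()
        for d in meta["dose_ppb"].unique()
    }
    networks, summary = run_all_conditions(
        genus_table, meta, classes_by_condition=classes_by_condition
    )
    gio.write_table(summary, out / "network_summary.tsv")
    for (section, dose), net in networks.items():
        stem = f"{section}_{dose:g}ppb"
        gio.write_network(net, nets_dir / f"{stem}.edges.tsv", "edge_tsv")
        gio.write_network(net, nets_dir / f"{stem}.sif", "sif")
        gio.write_network(net, nets_dir / f"{stem}.graphml", "graphml")

    # --- topology ---------------------------------------------------------
    topo = pd.concat(
        [topology_table(net) for net in networks.values()], ignore_index=True
    )
    gio.write_table(topo, out / "topology.tsv")
    gio.write_table(compare_condition_grid(topo), out / "topology_comparisons.tsv")

    # --- dysbiosis signatures ---------------------------------------------
    sig_rows, per_genus = [], []
    doses = sorted(meta["dose_ppb"].unique())
    control = doses[0]
    for section in meta["gut_section"].unique():
        control_net = networks[(section, control)]
        for dose in doses[1:]:
            exposed_net = networks[(section, dose)]
            flags = keystone_flags(
                topo[(topo["section"] == section) & (topo["dose_ppb"] == dose)]
            )
            sig = signature(
                control_net, exposed_net, genus_table, meta,
                classes=classes_by_condition[(section, dose)], keystone=flags,
            )
            sig_rows.append(sig.summary_row())
            per_genus.append(
                sig.per_genus.assign(section=section, dose_ppb=dose)
            )
    gio.write_table(pd.DataFrame(sig_rows), out / "signatures.tsv")
    gio.write_table(pd.concat(per_genus, ignore_index=True),
                    out / "signature_genus.tsv")

    # --- survival & feeding -----------------------------------------------
    if "survival" in data:
        ledger = data["survival"]
        gio.write_table(ledger, out / "survival_ledger.tsv")
        groups = sorted(ledger["group"].unique())
        curves = [kaplan_meier(ledger, g) for g in groups]
        gio.write_table(pd.concat([c.as_frame() for c in curves],
                                  ignore_index=True), out / "km.tsv")
        med = []
        for c in curves:
            m = median_survival(c)
            med.append({"group": c.group,
                        "median_day": m if m is not None else float("nan")})
        gio.write_table(pd.DataFrame(med), out / "km_medians.tsv")
        lr = []
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                chi2, p = logrank(ledger, ga, gb)
                lr.append({"group_a": ga, "group_b": gb, "chi2": chi2, "p": p})
        gio.write_table(pd.DataFrame(lr), out / "logrank.tsv")
    if "feeding" in data:
        rates = feeding_rate(data["feeding"])
        gio.write_table(rates, out / "feeding_rates.tsv")
        control_group = sorted(
            rates["group"].unique(), key=lambda g: float(g.split()[0])
        )[0]
        gio.write_table(feeding_comparisons(rates, control_group),
                        out / "feeding_comparisons.tsv")

    # --- manifest ---------------------------------------------------------
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d artifact(s) in %s",
                len(manifest["files"]), out)
    return out
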