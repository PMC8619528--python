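"""Assign taxonomy to ASVs from BLAST tabular hits.

Rule: a best hit above 98% identity is taken at face value (full lineage);
anything weaker falls back to the lowest common ancestor of the top 50
hits by bitscore — ambiguous ASVs land at the deepest rank their hits
agree on.
"""

from gutnetdys import BlastHit, Lineage, assign_taxon
from gutnetdys.types import RANKS


def lineage(*names):
    return Lineage(tuple(names) + ("",) * (len(RANKS) - len(names)))


lookup = {
    "1": lineage("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                 "Orbales", "Orbaceae", "Gilliamella", "Gilliamella apicola"),
    "2": lineage("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                 "Lactobacillaceae", "Lactobacillus", "Lactobacillus apis"),
    "3": lineage("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                 "Lactobacillaceae", "Lactobacillus", "Lactobacillus kimbladii"),
}

# strong hit: species-level assignment
strong = [BlastHit("asv1", "1", percent_identity=99.1, bitscore=450.0)]
print("asv1 (99.1% id):", assign_taxon(strong, lookup).name_at("species"))

# two sub-threshold congeneric hits: LCA stops at the genus
weak = [
    BlastHit("asv2", "2", percent_identity=95.0, bitscore=400.0),
    BlastHit("asv2", "3", percent_identity=94.0, bitscore=390.0),
]
result = assign_taxon(weak, lookup)
print("asv2 (95%/94% id): assigned at", result.assigned_rank,
      "->", result.genus)

# no hits at all: the unassigned sentinel
print("asv3 (no hits): unassigned =", assign_taxon([], lookup).is_unassigned)
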