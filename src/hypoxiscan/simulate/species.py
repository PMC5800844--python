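"""Species tree and clade labels for the comparative analyses.

The default tree spans the opisthokont sampling used for pathway
presence–absence profiling: bilaterians, a cnidarian, a placozoan, two
ctenophores, all four sponge classes, a choanoflagellate and Capsaspora as
non-metazoan outgroups.  Branch lengths are in arbitrary time units and the
tree is ultrametric; the topology shown here places sponges as sister to
the remaining animals, but downstream classification never depends on that
choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["SpeciesTree", "default_species_tree", "DEFAULT_CLADES"]

_DEFAULT_NEWICK = (
    "((((((tethya:0.3,amphimedon:0.3):0.2,aphrocallistes:0.5):0.3,"
    "(sycon:0.6,oscarella:0.6):0.2):0.2,"
    "((mnemiopsis:0.3,euplokamis:0.3):0.6,"
    "((((human:0.15,mouse:0.15):0.35,dmel:0.5):0.15,nematostella:0.65):0.05,"
    "trichoplax:0.7):0.2):0.1):0.2,monosiga:1.2):0.2,capsaspora:1.4);"
)

DEFAULT_CLADES: dict[str, str] = {
    "human": "Bilateria",
    "mouse": "Bilateria",
    "dmel": "Bilateria",
    "nematostella": "Cnidaria",
    "trichoplax": "Placozoa",
    "mnemiopsis": "Ctenophora",
    "euplokamis": "Ctenophora",
    "tethya": "Demospongiae",
    "amphimedon": "Demospongiae",
    "aphrocallistes": "Hexactinellida",
    "sycon": "Calcarea",
    "oscarella": "Homoscleromorpha",
    "monosiga": "Choanoflagellata",
    "capsaspora": "Capsaspora",
}

#: Clades outside Metazoa, used for the secondary-loss rule.
DEFAULT_OUTGROUP_CLADES = ("Choanoflagellata", "Capsaspora")


@dataclass
class SpeciesTree:
    """Rooted, binary species tree with one clade label per species."""

    tree: dendropy.Tree
    clades: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("species tree leaf labels must be unique")
        missing = [s for s in labels if s not in self.clades]
        if missing:
            raise ValueError(f"species without clade label: {missing}")
        for node in self.tree.preorder_node_iter():
            n = len(node.child_nodes())
            if n not in (0, 2):
                raise ValueError("species tree must be binary")

    @property
    def species(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def clade_members(self, clade: str) -> list[str]:
        return [s for s, c in self.clades.items() if c == clade]


def default_species_tree() -> SpeciesTree:
    tree = dendropy.Tree.get(data=_DEFAULT_NEWICK, schema="newick")
    return SpeciesTree(tree=tree, clades=dict(DEFAULT_CLADES))
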