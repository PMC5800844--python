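"""Gene-tree orthology classification and presence–absence profiling.

Given a gene tree whose leaves are labelled ``<species>|<gene_id>``, internal
nodes are first labelled as speciation or duplication events by the
species-overlap rule: a node is a duplication if and only if the species
sets of its child subtrees intersect.  Genes are then classified against a
reference protein of characterised function (e.g. human HIF1A) per target
species:

* ortholog_1to1 / ortholog_1tomany — the target species carries one / several
  genes related to the reference purely through speciation nodes, and the
  reference is the single co-ortholog on its side;
* homolog — the relation passes through duplications (usually many-to-many),
  or the target species has family members but none orthologous to the
  reference;
* absent — the species has no gene in the tree at all.

Per-clade verdicts aggregate over member species, an 'M' flag marks clades
with multiple lineage-specific duplications, and absences are upgraded to
secondary losses when non-metazoan outgroups retain the component.

The species-overlap rule needs no species-tree topology, so classification
is agnostic about the contested branching order of sponges and ctenophores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

__all__ = [
    "OrthologyCall",
    "read_newick",
    "write_newick",
    "leaf_species",
    "root_tree",
    "collapse_low_support",
    "label_events_species_overlap",
    "classify_relation",
    "classify_clade",
    "flag_lineage_duplications",
    "call_secondary_loss",
    "build_matrix",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "VERDICTS",
]

VERDICTS = (
    "ortholog_1to1",
    "ortholog_1tomany",
    "homolog",
    "absent",
    "secondary_loss",
)

#: aggregation preference when a clade has several member species
_VERDICT_RANK = {
    "ortholog_1to1": 0,
    "ortholog_1tomany": 1,
    "homolog": 2,
    "absent": 3,
}


@dataclass(frozen=True)
class OrthologyCall:
    component: str
    clade: str
    verdict: str
    lineage_dup_flag: bool = False

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def leaf_species(label: str) -> str:
    """Species part of a ``<species>|<gene_id>`` leaf label."""
    return label.split("|", 1)[0]


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; internal node labels are support values.

    Numeric internal labels (bootstrap-style, 0–100) are stored on
    ``node.support``; branch lengths are preserved.
    """
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    # treat the parsed topology as rooted so downstream operations (MRCA,
    # rerooting) never collapse the basal bifurcation
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("gene tree leaf labels must be unique")
    for node in tree.preorder_internal_node_iter():
        support = None
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None and not (0.0 <= support <= 100.0):
            raise ValueError(f"support value {support} outside [0, 100]")
        node.support = support
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return out.getvalue().strip()


def root_tree(
    tree: dendropy.Tree, outgroup_species: Sequence[str] = ()
) -> dendropy.Tree:
    """Root on the configured outgroup species if present, else midpoint."""
    og_leaves = [
        leaf
        for leaf in tree.leaf_node_iter()
        if leaf_species(leaf.taxon.label) in set(outgroup_species)
    ]
    if og_leaves:
        if len(og_leaves) == 1:
            node = og_leaves[0]
        else:
            node = tree.mrca(taxa=[l.taxon for l in og_leaves])
        if node is not tree.seed_node:
            tree.reroot_at_edge(node.edge, update_bipartitions=False)
    elif len(tree.seed_node.child_nodes()) > 2:
        # basal polytomy = unrooted input; fall back to midpoint rooting
        tree.encode_bipartitions()
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def collapse_low_support(tree: dendropy.Tree, min_support: float) -> dendropy.Tree:
    """Collapse internal edges with support below ``min_support`` to polytomies."""
    to_collapse = [
        node
        for node in tree.preorder_internal_node_iter(exclude_seed_node=True)
        if getattr(node, "support", None) is not None
        and node.support < min_support
    ]
    for node in to_collapse:
        node.edge.collapse()
    return tree


def _leafset(node) -> frozenset:
    return node._hx_leafset


def _index_tree(tree: dendropy.Tree) -> None:
    """Attach descendant-leaf sets to every node (postorder)."""
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._hx_leafset = frozenset([node.taxon.label])
        else:
            node._hx_leafset = frozenset().union(
                *(c._hx_leafset for c in node.child_nodes())
            )


def label_events_species_overlap(
    tree: dendropy.Tree, species_map: Mapping[str, str]
) -> dendropy.Tree:
    """Label internal nodes speciation/duplication by species overlap.

    A node is a duplication iff any two of its child subtrees share a
    species (for polytomies, children are considered pairwise).  Every
    leaf's species must appear in ``species_map``.
    """
    for leaf in tree.leaf_node_iter():
        sp = leaf_species(leaf.taxon.label)
        if sp not in species_map:
            raise ValueError(
                f"leaf {leaf.taxon.label!r}: species {sp!r} not in species map"
            )
    _index_tree(tree)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.event = None
            continue
        child_species = [
            {leaf_species(l) for l in c._hx_leafset} for c in node.child_nodes()
        ]
        dup = False
        for i in range(len(child_species)):
            for j in range(i + 1, len(child_species)):
                if child_species[i] & child_species[j]:
                    dup = True
        node.event = "duplication" if dup else "speciation"
    return tree


def _require_events(tree: dendropy.Tree) -> None:
    for node in tree.preorder_internal_node_iter():
        if getattr(node, "event", None) not in ("speciation", "duplication"):
            raise ValueError(
                "tree is not event-labelled; run label_events_species_overlap first"
            )


def _lca_events_from(tree: dendropy.Tree, leaf_label: str) -> dict[str, str]:
    """Event label at LCA(leaf, x) for every other leaf x.

    Walks root-ward from the leaf: leaves first joined at ancestor A have
    their LCA with the focal leaf at A.
    """
    focal = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == leaf_label:
            focal = leaf
            break
    if focal is None:
        raise ValueError(f"leaf {leaf_label!r} not found in tree")
    events: dict[str, str] = {}
    seen = {leaf_label}
    node = focal.parent_node
    while node is not None:
        for other in node._hx_leafset - seen:
            events[other] = node.event
        seen |= node._hx_leafset
        node = node.parent_node
    return events


def classify_relation(
    tree: dendropy.Tree, reference_leaf: str, target_species: str
) -> str:
    """Verdict for one reference gene against one target species.

    Let O be the target-species leaves whose LCA with the reference is a
    speciation node, and R the reference-species leaves that are
    speciation-related to any member of O.  |O|=1 and |R|=1 gives
    ortholog_1to1; |O|>1 and |R|=1 gives ortholog_1tomany; |R|>1 (or O
    empty while the species is present) gives homolog; a species absent
    from the tree entirely is absent.
    """
    _require_events(tree)
    ref_species = leaf_species(reference_leaf)
    all_leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    target_leaves = [l for l in all_leaves if leaf_species(l) == target_species]
    if not target_leaves:
        return "absent"
    ev_ref = _lca_events_from(tree, reference_leaf)
    O = [t for t in target_leaves if ev_ref.get(t) == "speciation"]
    if target_species == ref_species:
        # the reference gene is trivially its own ortholog
        O.append(reference_leaf)
    if not O:
        return "homolog"
    ref_leaves = [l for l in all_leaves if leaf_species(l) == ref_species]
    R = set()
    for t in O:
        ev_t = _lca_events_from(tree, t)
        R.update(r for r in ref_leaves if ev_t.get(r) == "speciation")
    R.add(reference_leaf)
    if len(O) == 1 and len(R) == 1:
        return "ortholog_1to1"
    if len(O) > 1 and len(R) == 1:
        return "ortholog_1tomany"
    return "homolog"


def classify_clade(
    tree: dendropy.Tree,
    reference_leaf: str,
    clade_species: Sequence[str],
) -> str:
    """Aggregate per-species verdicts over a clade.

    The clade verdict is the best verdict among member species, ordered
    1to1 > 1tomany > homolog > absent, i.e. presence in any member species
    counts as presence for the clade.
    """
    verdicts = [
        classify_relation(tree, reference_leaf, sp) for sp in clade_species
    ]
    if not verdicts:
        raise ValueError("clade has no member species")
    return min(verdicts, key=lambda v: _VERDICT_RANK[v])


def flag_lineage_duplications(
    tree: dendropy.Tree,
    species_map: Mapping[str, str],
    clade: str,
) -> bool:
    """True iff ≥2 duplication nodes have all descendants inside the clade."""
    _require_events(tree)
    members = {s for s, c in species_map.items() if c == clade}
    count = 0
    for node in tree.preorder_internal_node_iter():
        if node.event != "duplication":
            continue
        species = {leaf_species(l) for l in _leafset(node)}
        if species and species <= members:
            count += 1
    return count >= 2


def call_secondary_loss(
    component: str,
    clade: str,
    matrix_context: Mapping[tuple[str, str], str],
    outgroup_clades: Sequence[str],
) -> str:
    """Upgrade an absence to secondary loss if outgroups retain the component.

    ``matrix_context`` maps (component, clade) to the already-computed
    verdicts, including those of the configured non-metazoan outgroup
    clades (e.g. Choanoflagellata, Capsaspora).
    """
    if not outgroup_clades:
        raise ValueError("no outgroup clades configured")
    verdict = matrix_context[(component, clade)]
    if verdict != "absent":
        return verdict
    for og in outgroup_clades:
        if matrix_context.get((component, og), "absent") != "absent":
            return "secondary_loss"
    return "absent"


def build_matrix(
    calls: Iterable[OrthologyCall],
    component_order: Optional[Sequence[str]] = None,
    clade_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Assemble the presence–absence matrix (components × clades).

    Cells hold the verdict code with an ``+M`` suffix when the clade shows
    multiple lineage-specific duplications.  Every (component, clade) pair
    must be covered exactly once.
    """
    calls = list(calls)
    components = list(
        component_order
        if component_order is not None
        else dict.fromkeys(c.component for c in calls)
    )
    clades = list(
        clade_order
        if clade_order is not None
        else dict.fromkeys(c.clade for c in calls)
    )
    cell: dict[tuple[str, str], str] = {}
    for c in calls:
        value = c.verdict + ("+M" if c.lineage_dup_flag else "")
        cell[(c.component, c.clade)] = value
    gaps = [
        (comp, clade)
        for comp in components
        for clade in clades
        if (comp, clade) not in cell
    ]
    if gaps:
        raise ValueError(f"missing (component, clade) calls: {gaps}")
    data = {
        clade: [cell[(comp, clade)] for comp in components] for clade in clades
    }
    return pd.DataFrame(data, index=pd.Index(components, name="component"))


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="component")
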