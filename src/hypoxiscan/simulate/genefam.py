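"""Gene-family simulation by a duplication–loss birth–death process.

Gene families are simulated gene-tree-first: a single ancestral gene enters
the species-tree root and, along every species-tree branch, each gene
lineage independently experiences duplications and losses at constant rates
(events per unit branch length).  Surviving lineages split at every
speciation node.  Because every event is recorded, the true orthology
relation of any gene pair (speciation vs duplication at their divergence)
is known exactly, which makes the simulator an oracle for the gene-tree
classification stage.  No sequence evolution is modelled here; sequences
are only needed by the motif/homology generators.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Optional

from hypoxiscan.simulate.species import SpeciesTree

__all__ = [
    "GeneNode",
    "FamilyTruth",
    "simulate_gene_family",
    "true_pairwise_relations",
    "true_verdict",
    "truth_events_by_leafset",
    "patristic_distances",
]


class GeneNode:
    """Node of a simulated gene tree.

    ``event`` is ``"speciation"`` or ``"duplication"`` for internal nodes
    and ``"leaf"`` for extant genes; ``length`` is the branch length above
    the node in species-tree time units.
    """

    __slots__ = ("children", "length", "event", "species", "name")

    def __init__(
        self,
        event: str,
        length: float = 0.0,
        children: Optional[list["GeneNode"]] = None,
        species: Optional[str] = None,
        name: Optional[str] = None,
    ) -> None:
        self.event = event
        self.length = length
        self.children = children if children is not None else []
        self.species = species
        self.name = name

    def iter_nodes(self) -> Iterator["GeneNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list["GeneNode"]:
        return [n for n in self.iter_nodes() if n.event == "leaf"]

    def to_newick(self) -> str:
        def fmt(node: GeneNode, is_root: bool) -> str:
            if node.event == "leaf":
                body = node.name
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if is_root:
                return body
            return f"{body}:{node.length:.6f}"

        return fmt(self, True) + ";"


@dataclass
class FamilyTruth:
    """Recorded truth for one simulated gene family."""

    root: Optional[GeneNode]
    newick: str
    copy_number: dict[str, int]
    n_duplications: int
    n_losses: int
    dup_rate: float
    loss_rate: float
    seed: int
    #: cross-species pairwise relation, keyed (gene_a, gene_b) in both
    #: orders; values: "1:1", "1:many", "many:1", "many:many", "paralog"
    relations: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def extinct(self) -> bool:
        return self.root is None

    def genes(self) -> list[str]:
        if self.root is None:
            return []
        return [leaf.name for leaf in self.root.leaves()]


def _evolve_on_edge(
    sp_node,
    t_remain: float,
    dup_rate: float,
    loss_rate: float,
    rng: random.Random,
    counters: dict[str, int],
) -> Optional[GeneNode]:
    """Evolve one gene lineage along (the rest of) a species-tree edge.

    Returns the surviving gene subtree with ``length`` measured from the
    entry point on the edge, or None if every descendant lineage is lost.
    Pass-through nodes (one surviving child) are collapsed, accumulating
    branch length, so the returned tree contains only observable nodes.
    """
    total = dup_rate + loss_rate
    wait = rng.expovariate(total) if total > 0 else float("inf")
    if wait < t_remain:
        if rng.random() < (dup_rate / total if total > 0 else 0.0):
            counters["dup"] += 1
            left = _evolve_on_edge(
                sp_node, t_remain - wait, dup_rate, loss_rate, rng, counters
            )
            right = _evolve_on_edge(
                sp_node, t_remain - wait, dup_rate, loss_rate, rng, counters
            )
            surviving = [c for c in (left, right) if c is not None]
            if len(surviving) == 2:
                return GeneNode("duplication", length=wait, children=surviving)
            if len(surviving) == 1:
                child = surviving[0]
                child.length += wait
                return child
            return None
        counters["loss"] += 1
        return None
    # reached the bottom of the edge without an event
    if sp_node.is_leaf():
        return GeneNode("leaf", length=t_remain, species=sp_node.taxon.label)
    children = []
    for sp_child in sp_node.child_nodes():
        sub = _evolve_on_edge(
            sp_child, sp_child.edge.length, dup_rate, loss_rate, rng, counters
        )
        if sub is not None:
            children.append(sub)
    if len(children) == 2:
        return GeneNode("speciation", length=t_remain, children=children)
    if len(children) == 1:
        child = children[0]
        child.length += t_remain
        return child
    return None


def simulate_gene_family(
    species_tree: SpeciesTree,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    family_id: Optional[str] = None,
) -> FamilyTruth:
    """Simulate one gene family along the species tree.

    Complete extinction of the family is a valid outcome, reported via
    ``FamilyTruth.extinct`` rather than an exception.  With both rates
    zero the gene tree is topologically identical to the species tree and
    every between-species relation is 1:1.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("duplication and loss rates must be >= 0")
    rng = random.Random(seed)
    counters = {"dup": 0, "loss": 0}
    root = _evolve_on_edge(
        species_tree.tree.seed_node, 0.0, dup_rate, loss_rate, rng, counters
    )

    copy_number = {s: 0 for s in species_tree.species}
    if family_id is None:
        family_id = f"f{seed}"
    if root is not None:
        # deterministic naming "<species>|<family>g<k>" in traversal order;
        # the family tag keeps gene ids unique across simulated families
        per_species: dict[str, int] = {}
        for leaf in _ordered_leaves(root):
            k = per_species.get(leaf.species, 0) + 1
            per_species[leaf.species] = k
            leaf.name = f"{leaf.species}|{family_id}g{k}"
            copy_number[leaf.species] += 1
        # a single surviving gene is a leaf-only "tree"
        newick = root.to_newick()
    else:
        newick = ""

    truth = FamilyTruth(
        root=root,
        newick=newick,
        copy_number=copy_number,
        n_duplications=counters["dup"],
        n_losses=counters["loss"],
        dup_rate=dup_rate,
        loss_rate=loss_rate,
        seed=seed,
    )
    truth.relations = true_pairwise_relations(truth)
    return truth


def _ordered_leaves(root: GeneNode) -> list[GeneNode]:
    out: list[GeneNode] = []

    def walk(node: GeneNode) -> None:
        if node.event == "leaf":
            out.append(node)
        for c in node.children:
            walk(c)

    walk(root)
    return out


def _leafsets(root: GeneNode) -> dict[int, frozenset]:
    """Map id(node) -> frozenset of descendant leaf names."""
    sets: dict[int, frozenset] = {}

    def walk(node: GeneNode) -> frozenset:
        if node.event == "leaf":
            s = frozenset([node.name])
        else:
            s = frozenset().union(*(walk(c) for c in node.children))
        sets[id(node)] = s
        return s

    walk(root)
    return sets


def truth_events_by_leafset(truth: FamilyTruth) -> dict[frozenset, str]:
    """Map each internal node's descendant-leaf set to its true event label.

    The leaf set identifies a node uniquely in any tree with the same
    topology, so this is the bridge between the simulator's truth and an
    independently parsed/annotated copy of the same tree.
    """
    if truth.root is None:
        return {}
    sets = _leafsets(truth.root)
    return {
        sets[id(n)]: n.event
        for n in truth.root.iter_nodes()
        if n.event in ("speciation", "duplication")
    }


def _lca_events(root: GeneNode) -> dict[frozenset, str]:
    """Event label at the LCA of every leaf pair, by replaying the tree."""
    events: dict[frozenset, str] = {}

    def walk(node: GeneNode) -> list[str]:
        if node.event == "leaf":
            return [node.name]
        child_leaf_lists = [walk(c) for c in node.children]
        for i in range(len(child_leaf_lists)):
            for j in range(i + 1, len(child_leaf_lists)):
                for a in child_leaf_lists[i]:
                    for b in child_leaf_lists[j]:
                        events[frozenset((a, b))] = node.event
        return [x for lst in child_leaf_lists for x in lst]

    walk(root)
    return events


def _species_of(gene: str) -> str:
    return gene.split("|", 1)[0]


def true_pairwise_relations(truth: FamilyTruth) -> dict[tuple[str, str], str]:
    """Cross-species pairwise relations derived from the event history.

    A pair whose gene-tree LCA is a speciation node is an ortholog pair;
    the 1:1 / 1:many / many:many refinement counts co-orthologs on each
    side.  Pairs diverging at a duplication are recorded as "paralog".
    """
    if truth.root is None:
        return {}
    events = _lca_events(truth.root)
    genes = truth.genes()
    # orthologs of g in species s
    orth: dict[str, dict[str, list[str]]] = {g: {} for g in genes}
    for a in genes:
        for b in genes:
            if a >= b or _species_of(a) == _species_of(b):
                continue
            if events[frozenset((a, b))] == "speciation":
                orth[a].setdefault(_species_of(b), []).append(b)
                orth[b].setdefault(_species_of(a), []).append(a)
    rel: dict[tuple[str, str], str] = {}
    for a in genes:
        for b in genes:
            if a >= b or _species_of(a) == _species_of(b):
                continue
            if events[frozenset((a, b))] != "speciation":
                rel[(a, b)] = rel[(b, a)] = "paralog"
                continue
            n_in_b = len(orth[a].get(_species_of(b), []))
            n_in_a = len(orth[b].get(_species_of(a), []))
            if n_in_b == 1 and n_in_a == 1:
                rel[(a, b)] = rel[(b, a)] = "1:1"
            elif n_in_b > 1 and n_in_a == 1:
                rel[(a, b)] = "1:many"
                rel[(b, a)] = "many:1"
            elif n_in_b == 1 and n_in_a > 1:
                rel[(a, b)] = "many:1"
                rel[(b, a)] = "1:many"
            else:
                rel[(a, b)] = rel[(b, a)] = "many:many"
    return rel


def true_verdict(truth: FamilyTruth, reference_leaf: str, target_species: str) -> str:
    """Replay the event history to get the expected per-species verdict.

    Mirrors the classification contract: O = target-species genes
    orthologous to the reference; R = reference-species co-orthologs of O.
    """
    genes = truth.genes()
    if reference_leaf not in genes:
        raise ValueError(f"reference leaf {reference_leaf!r} not in family")
    target_genes = [g for g in genes if _species_of(g) == target_species]
    if not target_genes:
        return "absent"
    events = _lca_events(truth.root)
    ref_species = _species_of(reference_leaf)
    O = [
        t
        for t in target_genes
        if events[frozenset((reference_leaf, t))] == "speciation"
    ]
    if not O:
        return "homolog"
    R = {
        r
        for r in genes
        if _species_of(r) == ref_species
        and any(events[frozenset((r, t))] == "speciation" for t in O)
    }
    if len(O) == 1 and len(R) == 1:
        return "ortholog_1to1"
    if len(O) > 1 and len(R) == 1:
        return "ortholog_1tomany"
    return "homolog"


def patristic_distances(truth: FamilyTruth) -> dict[frozenset, float]:
    """Leaf-to-leaf path distances on the simulated gene tree."""
    if truth.root is None:
        return {}
    depth: dict[str, float] = {}
    lca_depth: dict[frozenset, float] = {}

    def walk(node: GeneNode, d: float) -> list[tuple[str, float]]:
        here = d + node.length
        if node.event == "leaf":
            depth[node.name] = here
            return [(node.name, here)]
        lists = [walk(c, here) for c in node.children]
        for i in range(len(lists)):
            for j in range(i + 1, len(lists)):
                for a, _ in lists[i]:
                    for b, _ in lists[j]:
                        lca_depth[frozenset((a, b))] = here
        return [x for lst in lists for x in lst]

    walk(truth.root, 0.0)
    return {
        pair: depth[tuple(pair)[0]] + depth[tuple(pair)[1]] - 2 * d
        for pair, d in lca_depth.items()
    }
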