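"""Scan gene trees for topologies compatible with lateral gene transfer.

A rooted gene tree supports an LGT event when some internal node A
splits into a *receiver clade* — only plant-parasitic nematode leaves,
at least one of them from M. incognita or M. hapla — and a *donor
clade* containing no eumetazoan leaf, while the rest of the tree (the
*external clade*) contains no plant-parasitic nematode.  That node A is
the minimal phylogenetic support.  Support is upgraded (A+B) when
node B, the parent of A, joins this pair to an external clade that
itself contains at least one non-metazoan leaf: under vertical descent
node B would separate clean metazoan and non-metazoan sides, so a mixed
external clade marks B as a duplication-like node and strengthens the
transfer reading.

Post-transfer duplication is read off the receiver subtree with the
species-overlap rule: a node whose child clades share a species is a
duplication node.  Duplications *before* the split of the two
root-knot nematodes show as a duplication node with both species on
both sides; duplications *after* the split show as duplication nodes
heading single-species clades.  Because roughly half the M. incognita
genome is present in two copies, at least three M. incognita leaves
(but only two M. hapla leaves) are required to call a duplication.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .taxonomy import EUMETAZOA_TAXID, TaxonomyTree

FOCAL_SPECIES = ("Minc", "Mhap")


class LeafResolutionError(ValueError):
    """A leaf label could not be resolved to a taxid."""


@dataclass(frozen=True)
class GeneLeaf:
    label: str
    protein_id: str
    species: str
    taxid: int


@dataclass
class GeneTree:
    """A rooted gene tree whose leaves carry species tags and taxids.

    Leaf labels follow the ``species|protein_id`` convention; the
    species tag is resolved to a taxid through ``species_taxids``.
    """

    tree_id: str
    tree: dendropy.Tree
    leaves: dict[str, GeneLeaf]

    @classmethod
    def from_newick(
        cls,
        newick: str,
        tree_id: str,
        species_taxids: Mapping[str, int],
    ) -> "GeneTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        leaves: dict[str, GeneLeaf] = {}
        for taxon in tree.taxon_namespace:
            label = taxon.label
            if "|" in label:
                species, protein_id = label.split("|", 1)
            else:
                species, protein_id = label, label
            if species not in species_taxids:
                raise LeafResolutionError(
                    f"tree {tree_id}: leaf {label!r}: species tag "
                    f"{species!r} has no taxid mapping")
            leaves[label] = GeneLeaf(label, protein_id, species,
                                     species_taxids[species])
        return cls(tree_id=tree_id, tree=tree, leaves=leaves)

    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass
class LgtCall:
    """One matched transfer pattern at a node A of a gene tree."""

    tree_id: str
    node_id: int
    receiver_leaves: frozenset[str]
    donor_leaves: frozenset[str]
    external_leaves: frozenset[str]
    support: str  # "A" | "A_plus_B"
    n_minc: int
    n_mhap: int
    #: child subtrees of node A making up the receiver clade, for
    #: duplication analysis (dendropy nodes; not serialized)
    receiver_children: tuple = field(default=(), repr=False, compare=False)

    def __post_init__(self):
        if self.receiver_leaves & self.donor_leaves:
            raise ValueError("receiver and donor clades overlap")


@dataclass(frozen=True)
class DuplicationReport:
    tree_id: str
    duplicated: bool
    before_split: bool
    after_split: bool
    both_species_present: bool
    n_minc: int = 0
    n_mhap: int = 0


@dataclass
class ScanConfig:
    metazoa_taxid: int = EUMETAZOA_TAXID
    focal_species: tuple[str, ...] = FOCAL_SPECIES
    min_leaves: int = 3
    minc_dup_min: int = 3  # genome-duplication correction for M. incognita
    mhap_dup_min: int = 2


def _leaf_flags(gt: GeneTree, tax: TaxonomyTree, cfg: ScanConfig):
    """Per-leaf (is_ppn, is_metazoan, is_focal) lookups."""
    flags = {}
    for label, leaf in gt.leaves.items():
        if leaf.taxid not in tax:
            raise LeafResolutionError(
                f"tree {gt.tree_id}: leaf {label!r}: taxid {leaf.taxid} "
                f"not in taxonomy")
        flags[label] = (
            tax.is_ppn(leaf.taxid),
            tax.is_descendant(leaf.taxid, cfg.metazoa_taxid),
            leaf.species in cfg.focal_species,
        )
    return flags


def _clade_labels(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def match_lgt_pattern(
    gt: GeneTree,
    tax: TaxonomyTree,
    cfg: ScanConfig | None = None,
) -> list[LgtCall]:
    """All node-A matches of the transfer pattern in one gene tree.

    At a multifurcating node the children are classified individually;
    the node matches when at least one child clade is receiver-valid,
    at least one is donor-valid, and none is invalid (mixed).  Every
    matching node is reported; per-tree summaries keep the best grade.
    """
    cfg = cfg or ScanConfig()
    if gt.n_leaves() < cfg.min_leaves:
        return []
    flags = _leaf_flags(gt, tax, cfg)
    all_labels = frozenset(gt.leaves)

    def receiver_valid(labels: frozenset[str]) -> bool:
        return (all(flags[l][0] for l in labels)
                and any(flags[l][2] for l in labels))

    def donor_valid(labels: frozenset[str]) -> bool:
        return not any(flags[l][1] for l in labels)

    calls: list[LgtCall] = []
    for node_id, node in enumerate(gt.tree.preorder_node_iter()):
        children = node.child_nodes()
        if len(children) < 2:
            continue
        recv_children, donor_children, ok = [], [], True
        for child in children:
            labels = _clade_labels(child)
            if receiver_valid(labels):
                recv_children.append(child)
            elif donor_valid(labels):
                donor_children.append(child)
            else:
                ok = False
                break
        if not ok or not recv_children or not donor_children:
            continue
        receiver = frozenset().union(*(_clade_labels(c) for c in recv_children))
        donor = frozenset().union(*(_clade_labels(c) for c in donor_children))
        external = all_labels - receiver - donor
        if any(flags[l][0] for l in external):
            continue  # plant-parasitic nematodes may not sit outside A
        has_parent = node.parent_node is not None
        external_has_non_metazoan = any(not flags[l][1] for l in external)
        support = ("A_plus_B" if has_parent and external_has_non_metazoan
                   else "A")
        species = [gt.leaves[l].species for l in receiver]
        calls.append(LgtCall(
            tree_id=gt.tree_id,
            node_id=node_id,
            receiver_leaves=receiver,
            donor_leaves=donor,
            external_leaves=external,
            support=support,
            n_minc=sum(1 for s in species if s == "Minc"),
            n_mhap=sum(1 for s in species if s == "Mhap"),
            receiver_children=tuple(recv_children),
        ))
    return calls


def classify_support(call: LgtCall) -> str:
    """Support grade of a call: minimal ("A") or strong ("A_plus_B")."""
    return call.support


def best_call(calls: Sequence[LgtCall]) -> LgtCall | None:
    """Deterministic best call of a tree: strongest support, then the
    largest receiver clade, then lowest node id."""
    if not calls:
        return None
    return min(calls, key=lambda c: (c.support != "A_plus_B",
                                     -len(c.receiver_leaves), c.node_id))


def calls_by_tree(calls: Iterable[LgtCall]) -> dict[str, LgtCall]:
    grouped: dict[str, list[LgtCall]] = defaultdict(list)
    for c in calls:
        grouped[c.tree_id].append(c)
    return {tid: best_call(cs) for tid, cs in grouped.items()}


def _species_of_clade(node, leaves: Mapping[str, GeneLeaf]) -> set[str]:
    return {leaves[lf.taxon.label].species for lf in node.leaf_iter()}


def infer_duplication_nodes(receiver_children: Sequence,
                            leaves: Mapping[str, GeneLeaf]) -> set[int]:
    """Species-overlap duplication nodes inside a receiver subtree.

    A node is a duplication node when the species sets of at least two
    of its child clades intersect.  Returns ids of duplication nodes
    (python ``id`` of the dendropy node; the virtual root joining
    multiple receiver children has id -1).
    """
    dup: set[int] = set()

    def visit(node) -> set[str]:
        children = node.child_nodes()
        if not children:
            return {leaves[node.taxon.label].species}
        child_sets = [visit(c) for c in children]
        if _any_overlap(child_sets):
            dup.add(id(node))
        return set().union(*child_sets)

    child_sets = [visit(c) for c in receiver_children]
    if len(receiver_children) > 1 and _any_overlap(child_sets):
        dup.add(-1)
    return dup


def _any_overlap(sets: Sequence[set[str]]) -> bool:
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                return True
    return False


def classify_duplication_timing(
    call: LgtCall,
    leaves: Mapping[str, GeneLeaf],
    cfg: ScanConfig | None = None,
) -> DuplicationReport:
    """Timing of post-transfer duplications in a receiver clade.

    duplicated: at least ``mhap_dup_min`` M. hapla or ``minc_dup_min``
    M. incognita leaves (the asymmetry corrects for the duplicated
    genome structure of M. incognita).  before_split: some node has at
    least two child clades each containing both species — the
    duplication predates the speciation node.  after_split: some node
    heads a single-species clade large enough to clear the same
    per-species thresholds.
    """
    cfg = cfg or ScanConfig()
    both = call.n_minc >= 1 and call.n_mhap >= 1
    duplicated = call.n_mhap >= cfg.mhap_dup_min or call.n_minc >= cfg.minc_dup_min

    before = False
    after = False
    if duplicated:
        focal = set(cfg.focal_species)

        def visit(node) -> tuple[set[str], int, int]:
            nonlocal before, after
            children = node.child_nodes()
            if not children:
                sp = leaves[node.taxon.label].species
                return {sp}, int(sp == "Minc"), int(sp == "Mhap")
            stats = [visit(c) for c in children]
            n_with_both = sum(1 for s, _, _ in stats if focal <= s)
            if n_with_both >= 2:
                before = True
            species = set().union(*(s for s, _, _ in stats))
            n_minc = sum(m for _, m, _ in stats)
            n_mhap = sum(h for _, _, h in stats)
            _check_after(species, n_minc, n_mhap)
            return species, n_minc, n_mhap

        def _check_after(species: set[str], n_minc: int, n_mhap: int):
            nonlocal after
            if species == {"Minc"} and n_minc >= cfg.minc_dup_min:
                after = True
            elif species == {"Mhap"} and n_mhap >= cfg.mhap_dup_min:
                after = True

        stats = [visit(c) for c in call.receiver_children]
        if len(call.receiver_children) > 1:
            if sum(1 for s, _, _ in stats if focal <= s) >= 2:
                before = True
            species = set().union(*(s for s, _, _ in stats))
            _check_after(species, sum(m for _, m, _ in stats),
                         sum(h for _, _, h in stats))

    return DuplicationReport(
        tree_id=call.tree_id,
        duplicated=duplicated,
        before_split=before,
        after_split=after,
        both_species_present=both,
        n_minc=call.n_minc,
        n_mhap=call.n_mhap,
    )


def summarize_donor_taxa(
    calls: Sequence[LgtCall],
    leaf_maps: Mapping[str, Mapping[str, GeneLeaf]],
    tax: TaxonomyTree,
) -> dict[str, dict[str, int]]:
    """Per-division donor summary over trees.

    For each taxonomic division, the number of trees whose (best-call)
    donor clade contains at least one species of that division, and the
    number whose donor clade contains only that division.  A mixed
    donor clade contributes to several "at least one" rows and to no
    "only" row.
    """
    per_tree = calls_by_tree(calls)
    summary: dict[str, dict[str, int]] = defaultdict(
        lambda: {"at_least_one": 0, "only": 0})
    for tree_id, call in sorted(per_tree.items()):
        leaves = leaf_maps[tree_id]
        divisions = {tax.classify_division(leaves[l].taxid)
                     for l in call.donor_leaves}
        for d in divisions:
            summary[d]["at_least_one"] += 1
            if len(divisions) == 1:
                summary[d]["only"] += 1
    return dict(summary)


def scan_newick_file(
    path,
    species_taxids: Mapping[str, int],
    tax: TaxonomyTree,
    cfg: ScanConfig | None = None,
) -> tuple[list[LgtCall], dict[str, GeneTree]]:
    """Scan every tree in a Newick file (one tree per line).

    Lines may carry an optional ``tree_id<TAB>newick`` prefix;
    otherwise trees are numbered ``tree_0001``...
    """
    calls: list[LgtCall] = []
    trees: dict[str, GeneTree] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if "\t" in line:
                tree_id, newick = line.split("\t", 1)
            else:
                tree_id, newick = f"tree_{i:04d}", line
            gt = GeneTree.from_newick(newick, tree_id, species_taxids)
            trees[tree_id] = gt
            calls.extend(match_lgt_pattern(gt, tax, cfg))
    return calls, trees
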