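"""Taxonomy tree with the lineage queries the LGT filters depend on.

The pipeline reasons about BLAST subjects and gene-tree leaves through
three questions: is this taxon a metazoan (descendant of Eumetazoa,
taxid 6072)?  Is it a plant-parasitic nematode (PPN: Tylenchida 6300,
Triplonchida 211184 or Dorylaimina 211225), and therefore exempt from
the metazoan-hit count?  And which broad taxonomic division does it
belong to (Bacteria, Fungi, Protist, Plant, Archaea, Metazoa, Other)?

The tree is NCBI-like: integer taxids, parent links, one root.  It is
loaded from a plain tab-separated table (taxid, parent_taxid, name,
rank[, division]) rather than from the NCBI dump; users with the real
dump convert it to the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

#: Default taxids whose descendants count as plant-parasitic nematodes.
PPN_TAXIDS = frozenset({6300, 211184, 211225})

#: Eumetazoa; "metazoan" throughout the pipeline means descendant of this node.
EUMETAZOA_TAXID = 6072

#: Division anchors: the nearest anchor on the lineage decides the label.
#: Eukaryotes with no more specific anchor fall back to Protist (a
#: deliberately non-monophyletic catch-all); everything else falls back
#: to Other.
DEFAULT_DIVISION_ANCHORS: dict[int, str] = {
    2: "Bacteria",
    2157: "Archaea",
    4751: "Fungi",
    33090: "Plant",
    33208: "Metazoa",
    6072: "Metazoa",
}

EUKARYOTA_TAXID = 2759

DIVISIONS = ("Bacteria", "Fungi", "Protist", "Plant", "Archaea", "Metazoa", "Other")


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy table (cycle, orphan, duplicate)."""


class UnknownTaxidError(KeyError):
    """A query referenced a taxid absent from the tree."""

    def __init__(self, taxid: int):
        super().__init__(taxid)
        self.taxid = taxid

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown taxid: {self.taxid}"


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    name: str
    rank: str = ""
    division: str | None = None


@dataclass
class TaxonomyTree:
    """Rooted taxonomy over integer IDs with cached lineage lookups."""

    nodes: dict[int, TaxonNode]
    root: int
    ppn_taxids: frozenset[int] = PPN_TAXIDS
    division_anchors: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_DIVISION_ANCHORS)
    )
    _lineage_cache: dict[int, tuple[int, ...]] = field(
        default_factory=dict, repr=False
    )

    @classmethod
    def from_nodes(
        cls,
        nodes: Iterable[TaxonNode],
        ppn_taxids: Iterable[int] = PPN_TAXIDS,
        division_anchors: Mapping[int, str] | None = None,
    ) -> "TaxonomyTree":
        table: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in table:
                raise TaxonomyError(f"duplicate taxid: {node.taxid}")
            table[node.taxid] = node
        roots = [n.taxid for n in table.values() if n.parent_taxid == n.taxid]
        orphans = sorted(
            n.taxid
            for n in table.values()
            if n.parent_taxid != n.taxid and n.parent_taxid not in table
        )
        if orphans:
            raise TaxonomyError(f"orphan nodes with absent parents: {orphans}")
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {sorted(roots)}")
        tree = cls(
            nodes=table,
            root=roots[0],
            ppn_taxids=frozenset(ppn_taxids),
            division_anchors=dict(division_anchors or DEFAULT_DIVISION_ANCHORS),
        )
        tree._check_acyclic()
        return tree

    def _check_acyclic(self) -> None:
        for taxid in self.nodes:
            seen = set()
            cur = taxid
            while cur != self.root:
                if cur in seen:
                    raise TaxonomyError(f"cycle in parent links at taxid {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_taxid

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        return self._node(taxid).name

    def _node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def lineage(self, taxid: int) -> tuple[int, ...]:
        """Path from ``taxid`` up to and including the root."""
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        path = [taxid]
        cur = self._node(taxid)
        while cur.taxid != self.root:
            cur = self._node(cur.parent_taxid)
            path.append(cur.taxid)
        result = tuple(path)
        self._lineage_cache[taxid] = result
        return result

    def is_descendant(self, taxid: int, ancestor_taxid: int) -> bool:
        """True iff ``ancestor_taxid`` lies on the taxid→root path.

        A taxon is a descendant of itself (NCBI lineage convention), so
        clade constraints phrased as "descendant of T" include T.
        """
        self._node(ancestor_taxid)  # raise on unknown ancestor
        return ancestor_taxid in self.lineage(taxid)

    def is_ppn(self, taxid: int) -> bool:
        """True iff the taxon lies in a plant-parasitic nematode lineage."""
        lineage = self.lineage(taxid)
        return any(t in self.ppn_taxids for t in lineage)

    def is_metazoan(self, taxid: int, metazoa_taxid: int = EUMETAZOA_TAXID) -> bool:
        return self.is_descendant(taxid, metazoa_taxid) if metazoa_taxid in self.nodes \
            else False

    def classify_division(self, taxid: int) -> str:
        """Broad division label via the nearest anchor on the lineage.

        Eukaryotes that reach no more specific anchor are labelled
        Protist (the conventional catch-all for mostly unicellular
        eukaryotes, explicitly not monophyletic).  Non-eukaryotes with
        no anchor (viruses, unclassified) are Other, never Protist.
        """
        for t in self.lineage(taxid):
            label = self.division_anchors.get(t)
            if label is not None:
                return label
            if t == EUKARYOTA_TAXID:
                return "Protist"
        return "Other"

    def leaves(self) -> list[int]:
        parents = {n.parent_taxid for n in self.nodes.values() if n.parent_taxid != n.taxid}
        return sorted(t for t in self.nodes if t not in parents)

    def to_table(self, path: str | Path) -> None:
        """Write the tab-separated nodes table this tree loads from."""
        with open(path, "w") as fh:
            fh.write("taxid\tparent_taxid\tname\trank\tdivision\n")
            for taxid in sorted(self.nodes):
                n = self.nodes[taxid]
                fh.write(
                    f"{n.taxid}\t{n.parent_taxid}\t{n.name}\t{n.rank}\t"
                    f"{n.division or ''}\n"
                )


def load_taxonomy(
    path: str | Path,
    ppn_taxids: Iterable[int] = PPN_TAXIDS,
    division_anchors: Mapping[int, str] | None = None,
) -> TaxonomyTree:
    """Load a taxonomy from a tab-separated nodes table.

    Columns: taxid, parent_taxid, name, optional rank, optional
    division.  A header line starting with ``taxid`` is skipped.  The
    root is the row whose parent equals its own taxid.
    """
    nodes: list[TaxonNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "taxid":
                continue
            try:
                taxid = int(parts[0])
                parent = int(parts[1])
            except (IndexError, ValueError) as exc:
                raise TaxonomyError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            name = parts[2] if len(parts) > 2 else str(taxid)
            rank = parts[3] if len(parts) > 3 else ""
            division = parts[4] if len(parts) > 4 and parts[4] else None
            nodes.append(TaxonNode(taxid, parent, name, rank, division))
    return TaxonomyTree.from_nodes(nodes, ppn_taxids=ppn_taxids,
                                   division_anchors=division_anchors)
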