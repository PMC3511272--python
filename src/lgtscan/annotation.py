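"""Functional profiling through Pfam domains and GO-slim projection.

Proteins receive GO terms by union over their Pfam domains (pfam2go),
terms are projected onto a slim vocabulary through the ontology DAG,
and term distributions are compared descriptively between the LGT set
and the whole proteome.  Percentages are always over proteins with at
least one term in the namespace under comparison, never over the whole
proteome.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass(frozen=True)
class DomainAssignment:
    protein_id: str
    domain_id: str
    score: float | None = None


class GoDag:
    """is_a DAG over GO terms with per-term namespace.

    ``part_of`` edges, when present in the input, are treated as is_a
    when ``part_of_as_isa`` is set (the default), which matches how
    slim projection tools walk the graph.
    """

    def __init__(self, edges: Iterable[tuple[str, str]],
                 namespace: Mapping[str, str],
                 part_of_edges: Iterable[tuple[str, str]] = (),
                 part_of_as_isa: bool = True):
        g = nx.DiGraph()
        g.add_nodes_from(namespace)
        for child, parent in edges:
            g.add_edge(child, parent)
        if part_of_as_isa:
            for child, parent in part_of_edges:
                g.add_edge(child, parent)
        unknown = [n for n in g.nodes if n not in namespace]
        if unknown:
            raise ValueError(f"edge endpoints without namespace: {sorted(unknown)[:5]}")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO graph contains a cycle")
        self.graph = g
        self.namespace = dict(namespace)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term``, including itself."""
        return nx.descendants(self.graph, term) | {term}

    @classmethod
    def from_table(cls, path: str | Path, **kw) -> "GoDag":
        """Load from a tabular DAG: term <TAB> parent <TAB> namespace.

        A row with an empty parent declares a root term.
        """
        edges, ns = [], {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("term\t"):
                    continue
                term, parent, namespace = line.split("\t")[:3]
                ns[term] = namespace
                if parent:
                    ns.setdefault(parent, namespace)
                    edges.append((term, parent))
        return cls(edges, ns, **kw)


def load_pfam2go(path: str | Path) -> dict[str, set[str]]:
    """Parse a pfam2go flat file into domain -> GO term set.

    Lines look like ``Pfam:PF00001 7tm_1 > GO:G protein ... ; GO:0004930``;
    comment lines start with ``!``.
    """
    mapping: dict[str, set[str]] = defaultdict(set)
    pat = re.compile(r"^Pfam:(PF\d+)\S*\s.*?;\s*(GO:\d+)\s*$")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("!"):
                continue
            m = pat.match(line)
            if m:
                mapping[m.group(1)].add(m.group(2))
    return dict(mapping)


def load_domain_assignments(path: str | Path) -> list[DomainAssignment]:
    """Pfam assignment TSV: protein_id <TAB> domain_id [<TAB> score]."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            parts = line.split("\t")
            score = float(parts[2]) if len(parts) > 2 and parts[2] else None
            out.append(DomainAssignment(parts[0], parts[1], score))
    return out


def pfam_to_go(
    assignments: Sequence[DomainAssignment],
    pfam2go: Mapping[str, set[str]],
) -> tuple[dict[str, set[str]], int]:
    """Protein -> GO set by union over its domains.

    Returns the mapping and the number of proteins whose domains all
    lacked a GO mapping (they get an empty set).
    """
    result: dict[str, set[str]] = defaultdict(set)
    for a in assignments:
        result[a.protein_id] |= pfam2go.get(a.domain_id, set())
    unmapped = sum(1 for terms in result.values() if not terms)
    return dict(result), unmapped


def map_to_slim(
    terms: Iterable[str],
    dag: GoDag,
    slim: set[str],
    mode: str = "most_specific",
) -> tuple[set[str], set[str]]:
    """Project GO terms onto a slim vocabulary.

    ``most_specific`` (default): each term maps to its slim ancestors
    that have no other slim term both below them and above the input
    term; a term already in the slim maps to itself.  ``all``: every
    slim ancestor is kept.  Returns (slim terms, unmappable inputs).
    """
    mapped: set[str] = set()
    unmappable: set[str] = set()
    for term in terms:
        if term not in dag:
            unmappable.add(term)
            continue
        slim_anc = dag.ancestors(term) & slim
        if mode == "all" or not slim_anc:
            mapped |= slim_anc
            continue
        for s in slim_anc:
            # keep s unless a different slim ancestor of the term lies
            # strictly below s
            if not any(s in dag.ancestors(other)
                       for other in slim_anc if other != s):
                mapped.add(s)
    return mapped, unmappable


def slim_annotate(
    protein_terms: Mapping[str, set[str]],
    dag: GoDag,
    slim: set[str],
    mode: str = "most_specific",
) -> dict[str, set[str]]:
    return {pid: map_to_slim(terms, dag, slim, mode)[0]
            for pid, terms in protein_terms.items()}


def compare_go_distributions(
    set_a: Mapping[str, set[str]],
    set_b: Mapping[str, set[str]],
    dag: GoDag,
    top_k: int = 10,
) -> pd.DataFrame:
    """Per-term percentage comparison between two annotated protein sets.

    For each namespace, a protein counts once per term it carries; the
    denominator is the number of proteins of the set annotated in that
    namespace.  Output columns: namespace, term, pct_a, pct_b,
    abs_diff, top (rank among the ``top_k`` most different terms of its
    namespace, 0 if outside).
    """
    rows = []
    for ns in NAMESPACES:
        def ns_annot(pset):
            out = {}
            for pid, terms in pset.items():
                in_ns = {t for t in terms if dag.namespace.get(t) == ns}
                if in_ns:
                    out[pid] = in_ns
            return out

        a_ns, b_ns = ns_annot(set_a), ns_annot(set_b)
        if not a_ns and not b_ns:
            continue
        terms = set().union(*a_ns.values(), *b_ns.values(), set())
        for term in sorted(terms):
            pct_a = (100.0 * sum(1 for t in a_ns.values() if term in t)
                     / len(a_ns)) if a_ns else 0.0
            pct_b = (100.0 * sum(1 for t in b_ns.values() if term in t)
                     / len(b_ns)) if b_ns else 0.0
            rows.append((ns, term, pct_a, pct_b, abs(pct_a - pct_b)))
    df = pd.DataFrame(rows, columns=["namespace", "term", "pct_a", "pct_b",
                                     "abs_diff"])
    df["top"] = 0
    for ns in df["namespace"].unique():
        idx = (df[df["namespace"] == ns]
               .sort_values(["abs_diff", "term"], ascending=[False, True])
               .head(top_k).index)
        df.loc[idx, "top"] = range(1, len(idx) + 1)
    return df.sort_values(["namespace", "abs_diff"],
                          ascending=[True, False]).reset_index(drop=True)
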