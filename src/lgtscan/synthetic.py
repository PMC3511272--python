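"""Seeded generator of a miniature, fully consistent LGT study.

Everything the pipeline consumes is emulated with known ground truth:
a taxonomy with the 16-metazoan-species backbone plus non-metazoan
donor lineages, focal proteomes with planted exact duplicates and
contaminants, OrthoMCL-style groups consistent with planted copy
numbers (including 2:1 decoys), BLAST hit tables whose subject
taxonomies reflect donor divisions, Newick gene trees realizing planted
transfer topologies and duplication timings, genome annotation with
planted gene clusters and TE enrichment around LGT genes, CDS with
controlled GC, Pfam/GO fixtures with one planted enriched term, and
mobile-element hit tables.

Trees are emitted directly as topologies: the pipeline under test is
the decision logic downstream of tree inference, so no sequence
evolution is simulated.  BLAST tables are likewise synthesized from the
planted truth, not computed by alignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io as lio
from .context import GeneFeature, TeFeature
from .homology import BlastHit, OrthoGroup, ProteinRecord
from .taxonomy import TaxonNode, TaxonomyTree

AA = "ACDEFGHIKLMNPQRSTVWY"

#: species tag -> taxid for every leaf species the generator can emit.
SPECIES_TAXIDS: dict[str, int] = {
    # focal root-knot nematodes (Tylenchida)
    "Minc": 6306, "Mhap": 6305,
    # other metazoans
    "Cele": 6239, "Cbri": 6238, "Ppac": 54126, "Bmal": 6279,
    "Dmel": 7227, "Bmor": 7091, "Tcas": 7070,
    "Hsap": 9606, "Mmus": 10090, "Bflo": 7739, "Cint": 7719, "Spur": 7668,
    "Nvec": 45351, "Tadh": 10228,
    # bacteria
    "Ecoli": 562, "Bsub": 1423, "Rsol": 305, "Xcam": 339, "Smel": 382,
    # fungi
    "Afum": 746128, "Mgri": 148305,
    # protists
    "Pinf": 4787, "Ddis": 44689, "Tgon": 5811,
    # plants
    "Atha": 3702, "Osat": 4530,
    # archaea
    "Mjan": 2190,
}

DIVISION_SPECIES: dict[str, tuple[str, ...]] = {
    "Bacteria": ("Ecoli", "Bsub", "Rsol", "Xcam", "Smel"),
    "Fungi": ("Afum", "Mgri"),
    "Protist": ("Pinf", "Ddis", "Tgon"),
    "Plant": ("Atha", "Osat"),
    "Archaea": ("Mjan",),
}

METAZOAN_EXTERNALS = ("Hsap", "Mmus", "Dmel", "Cele", "Nvec")
OTHER_METAZOANS = ("Cele", "Cbri", "Ppac", "Bmal", "Dmel", "Bmor", "Tcas",
                   "Hsap", "Mmus", "Bflo", "Cint", "Spur", "Nvec", "Tadh")
#: eumetazoans only: Placozoa sits outside Eumetazoa, so a focal gene
#: with a Trichoplax sister would legitimately match the transfer
#: pattern — vertical-descent topologies must avoid it.
EUMETAZOAN_SIBLINGS = ("Cele", "Cbri", "Ppac", "Bmal", "Dmel", "Bmor",
                       "Tcas", "Hsap", "Mmus", "Bflo", "Cint", "Spur", "Nvec")


def build_default_taxonomy() -> TaxonomyTree:
    """The fixed taxonomy every synthetic bundle shares."""
    internal = [
        (1, 1, "root", "no rank"),
        (131567, 1, "cellular organisms", "no rank"),
        (2, 131567, "Bacteria", "superkingdom"),
        (2157, 131567, "Archaea", "superkingdom"),
        (2759, 131567, "Eukaryota", "superkingdom"),
        (4751, 2759, "Fungi", "kingdom"),
        (33090, 2759, "Viridiplantae", "kingdom"),
        (33634, 2759, "Stramenopiles", "clade"),
        (554915, 2759, "Amoebozoa", "clade"),
        (33630, 2759, "Alveolata", "clade"),
        (33208, 2759, "Metazoa", "kingdom"),
        (6072, 33208, "Eumetazoa", "clade"),
        (33213, 6072, "Bilateria", "clade"),
        (6073, 6072, "Cnidaria", "phylum"),
        (10226, 33208, "Placozoa", "phylum"),
        (6231, 33213, "Nematoda", "phylum"),
        (6300, 6231, "Tylenchida", "order"),
        (211184, 6231, "Triplonchida", "order"),
        (211225, 6231, "Dorylaimina", "suborder"),
        (6656, 33213, "Arthropoda", "phylum"),
        (7711, 33213, "Chordata", "phylum"),
    ]
    parent_of_species = {
        "Minc": 6300, "Mhap": 6300,
        "Cele": 6231, "Cbri": 6231, "Ppac": 6231, "Bmal": 6231,
        "Dmel": 6656, "Bmor": 6656, "Tcas": 6656,
        "Hsap": 7711, "Mmus": 7711, "Bflo": 7711, "Cint": 7711, "Spur": 33213,
        "Nvec": 6073, "Tadh": 10226,
        "Ecoli": 2, "Bsub": 2, "Rsol": 2, "Xcam": 2, "Smel": 2,
        "Afum": 4751, "Mgri": 4751,
        "Pinf": 33634, "Ddis": 554915, "Tgon": 33630,
        "Atha": 33090, "Osat": 33090,
        "Mjan": 2157,
    }
    nodes = [TaxonNode(t, p, name, rank) for t, p, name, rank in internal]
    nodes += [TaxonNode(SPECIES_TAXIDS[sp], parent, sp, "species")
              for sp, parent in parent_of_species.items()]
    return TaxonomyTree.from_nodes(nodes)


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic miniature.

    The duplication probabilities default to the observed cohort rates
    of the published survey (83% duplicated, 79% of those before the
    speciation split, 72% of those continuing after it), the donor mix
    to the published per-division tree counts renormalized, and the
    contamination/identity regimes to values that keep planted signal
    classes unambiguous: clean transfers never exceed 40% BLAST
    identity, planted contaminants never fall below 95%.
    """

    seed: int = 0
    n_vertical_genes: int = 200
    n_lgt_genes: int = 50
    n_contaminants: int = 10
    n_decoy_2to1: int = 5
    n_exact_duplicates: int = 5
    donor_mix: dict[str, float] = field(default_factory=lambda: {
        "Bacteria": 0.51, "Protist": 0.26, "Fungi": 0.13,
        "Plant": 0.08, "Archaea": 0.02})
    p_both_species: float = 0.65
    p_duplicated: float = 0.83
    p_before_given_dup: float = 0.79
    p_after_given_before: float = 0.72
    p_strong_support: float = 0.7
    p_mixed_donor: float = 0.25
    frac_vertical_restricted: float = 0.3
    te_lambda: float = 1.0
    te_enrichment: float = 2.0
    n_clusters: int = 3
    cluster_size: int = 4
    gc_content: float = 0.36
    min_protein_len: int = 80
    max_protein_len: int = 600
    go_enrich_lgt: float = 0.4
    go_enrich_other: float = 0.05
    frac_lgt_mobile: float = 0.3

    def validate(self) -> None:
        probs = [self.p_both_species, self.p_duplicated,
                 self.p_before_given_dup, self.p_after_given_before,
                 self.p_strong_support, self.p_mixed_donor, self.gc_content]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if self.n_clusters * self.cluster_size > max(self.n_lgt_genes, 1) * 4:
            raise ValueError("cluster spec exceeds available LGT gene copies")
        if abs(sum(self.donor_mix.values()) - 1.0) > 1e-6:
            raise ValueError("donor mix must sum to 1")


@dataclass
class GeneTruth:
    gene_id: str
    is_lgt: bool
    is_contaminant: bool = False
    donor_division: str | None = None
    n_copies_minc: int = 0
    n_copies_mhap: int = 0
    duplication_timing: str = "none"  # none | before | after | both
    both_species: bool = False
    support: str | None = None  # planted tree support grade
    in_cluster: bool = False
    te_enriched: bool = False
    in_group: bool = False
    representative: str = ""


@dataclass
class Bundle:
    """In-memory synthetic study; ``write`` emits the text files."""

    config: GeneratorConfig
    taxonomy: TaxonomyTree
    species_taxids: dict[str, int]
    proteins: list[ProteinRecord]
    groups: list[OrthoGroup]
    blast: dict[str, list[BlastHit]]
    trees: dict[str, str]  # tree_id -> newick
    genes: list[GeneFeature]
    tes: list[TeFeature]
    scaffold_lengths: dict[str, int]
    cds: dict[str, str]
    domains: list[tuple[str, str]]  # (protein_id, pfam_id)
    pfam2go: dict[str, set[str]]
    go_edges: list[tuple[str, str]]
    go_namespace: dict[str, str]
    go_slim: set[str]
    mobile_hits: list
    truth: dict[str, GeneTruth]
    representatives: dict[str, str]  # gene_id -> representative protein id

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.taxonomy.to_table(outdir / "taxonomy.tsv")
        lio.write_proteome(self.proteins, outdir / "proteome.faa")
        lio.write_groups(self.groups, outdir / "groups.txt")
        lio.write_blast_table(self.blast, outdir / "blast.tsv")
        with open(outdir / "trees.nwk", "w") as fh:
            for tree_id in sorted(self.trees):
                fh.write(f"{tree_id}\t{self.trees[tree_id]}\n")
        lio.write_gff3(self.genes, self.tes, self.scaffold_lengths,
                       outdir / "genome.gff3")
        lio.write_fasta(self.cds, outdir / "cds.fna")
        with open(outdir / "domains.tsv", "w") as fh:
            fh.write("protein_id\tdomain_id\n")
            for pid, dom in self.domains:
                fh.write(f"{pid}\t{dom}\n")
        with open(outdir / "pfam2go.txt", "w") as fh:
            fh.write("!version: synthetic\n")
            for dom in sorted(self.pfam2go):
                for go in sorted(self.pfam2go[dom]):
                    fh.write(f"Pfam:{dom} {dom.lower()} > GO:synthetic ; {go}\n")
        with open(outdir / "go_dag.tsv", "w") as fh:
            fh.write("term\tparent\tnamespace\n")
            parents = {}
            for child, parent in self.go_edges:
                parents.setdefault(child, []).append(parent)
            for term in sorted(self.go_namespace):
                plist = parents.get(term, [""])
                for p in plist:
                    fh.write(f"{term}\t{p}\t{self.go_namespace[term]}\n")
        with open(outdir / "go_slim.txt", "w") as fh:
            for t in sorted(self.go_slim):
                fh.write(t + "\n")
        lio.write_mobile_hits(self.mobile_hits, outdir / "mobile_hits.tsv")
        with open(outdir / "species_taxids.tsv", "w") as fh:
            fh.write("species\ttaxid\n")
            for sp in sorted(self.species_taxids):
                fh.write(f"{sp}\t{self.species_taxids[sp]}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({gid: asdict(t) for gid, t in sorted(self.truth.items())},
                      fh, indent=1, sort_keys=True)
        return outdir


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    bases = rng.choice(["A", "C", "G", "T"], size=3 * n_codons,
                       p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(bases)


def _sample_timing(rng: np.random.Generator, cfg: GeneratorConfig,
                   force_both: bool = False) -> tuple[bool, str]:
    """(both_species, timing in {none, before, after, both})."""
    both = force_both or rng.random() < cfg.p_both_species
    if not both:
        return False, "none"
    if rng.random() >= cfg.p_duplicated:
        return True, "none"
    if rng.random() < cfg.p_before_given_dup:
        if rng.random() < cfg.p_after_given_before:
            return True, "both"
        return True, "before"
    return True, "after"


def _receiver_topology(rng: np.random.Generator, gene_id: str,
                       both: bool, timing: str) -> tuple[str, int, int]:
    """Newick receiver clade realizing a planted duplication timing.

    Returns (newick fragment, n_minc, n_mhap).  Thresholds are the
    analysis ones: a duplication needs >= 2 M. hapla or >= 3
    M. incognita copies.
    """
    def m(sp, i):  # leaf label
        return f"{sp}|{sp}{gene_id}_c{i}"

    if not both:
        sp = "Minc" if rng.random() < 0.7 else "Mhap"
        n = 1 if rng.random() < 0.8 else 2
        if n == 1:
            nwk = m(sp, 1)
        else:
            nwk = f"({m(sp, 1)},{m(sp, 2)})"
        # keep single-species clades below the duplication thresholds
        if sp == "Mhap":
            nwk, n = m(sp, 1), 1
        return nwk, (n if sp == "Minc" else 0), (n if sp == "Mhap" else 0)

    if timing == "none":
        return f"({m('Minc', 1)},{m('Mhap', 1)})", 1, 1
    if timing == "before":
        return (f"(({m('Minc', 1)},{m('Mhap', 1)}),"
                f"({m('Minc', 2)},{m('Mhap', 2)}))"), 2, 2
    if timing == "both":
        return (f"((({m('Mhap', 1)},{m('Mhap', 2)}),{m('Minc', 1)}),"
                f"({m('Minc', 2)},{m('Mhap', 3)}))"), 2, 3
    # after-only: duplication inside a single-species clade, no
    # both-species duplication node above it
    if rng.random() < 0.5:
        return (f"(({m('Mhap', 1)},{m('Mhap', 2)}),{m('Minc', 1)})"), 1, 2
    return (f"((({m('Minc', 1)},{m('Minc', 2)}),{m('Minc', 3)}),"
            f"{m('Mhap', 1)})"), 3, 1


def _donor_clade(rng: np.random.Generator, division: str,
                 mixed: bool) -> tuple[str, list[str]]:
    species = [rng.choice(DIVISION_SPECIES[division])]
    if mixed:
        other_div = rng.choice([d for d in DIVISION_SPECIES if d != division])
        species.append(rng.choice(DIVISION_SPECIES[other_div]))
    elif rng.random() < 0.5:
        pool = [s for s in DIVISION_SPECIES[division] if s not in species]
        if pool:
            species.append(rng.choice(pool))
    leaves = [f"{sp}|{sp}_d{i}" for i, sp in enumerate(species, 1)]
    nwk = leaves[0] if len(leaves) == 1 else "(" + ",".join(leaves) + ")"
    return nwk, species


def build_lgt_tree(rng: np.random.Generator, gene_id: str, division: str,
                   receiver_nwk: str, strong: bool, mixed_donor: bool,
                   ) -> tuple[str, str]:
    """Full rooted Newick for a planted transfer; returns (newick, support)."""
    donor_nwk, _ = _donor_clade(rng, division, mixed_donor)
    ext1 = f"{rng.choice(METAZOAN_EXTERNALS)}|e1"
    if strong:
        non_met = rng.choice([s for div in DIVISION_SPECIES.values()
                              for s in div])
        ext2 = f"{non_met}|e2"
        support = "A_plus_B"
    else:
        ext2 = f"{rng.choice(METAZOAN_EXTERNALS)}|e2"
        support = "A"
    nwk = f"(({receiver_nwk},{donor_nwk}),({ext1},{ext2}));"
    return nwk, support


def build_vertical_tree(rng: np.random.Generator, gene_id: str) -> str:
    """A vertical-descent topology: the focal gene nests inside
    metazoans, so no transfer pattern may match."""
    sibling = rng.choice(EUMETAZOAN_SIBLINGS)
    outs = rng.choice(METAZOAN_EXTERNALS, size=2, replace=False)
    return (f"((Minc|Minc{gene_id}_c1,{sibling}|{sibling}_v1),"
            f"({outs[0]}|v2,{outs[1]}|v3));")


def _make_blast_hits(rng: np.random.Generator, query_id: str, qlen: int,
                     profile: str, division: str | None,
                     tax_ids: Mapping[str, int]) -> list[BlastHit]:
    """Synthesize a hit list realizing a planted profile.

    ``lgt``: >=80% of the informative top 10 non-metazoan, identities
    <= 40%.  ``contaminant``: near-identical full-length non-metazoan
    hits.  ``vertical``: metazoan-dominated.  ``no_hit``: nothing
    passes the e-value/coverage filters.
    """
    hits: list[BlastHit] = []
    evalue = 1e-60

    def add(species: str, ident: float, cov: float, ev: float | None = None):
        nonlocal evalue
        if ev is None:
            evalue *= 10 ** rng.uniform(0.5, 2.0)
            ev = min(evalue, 9e-3)
        hits.append(BlastHit(
            query_id=query_id, subject_id=f"{species}_s{len(hits)}",
            subject_taxid=tax_ids[species],
            percent_identity=round(float(ident), 1),
            align_length_on_query=max(1, int(cov * qlen)),
            evalue=float(ev), bitscore=round(500.0 - 10 * len(hits), 1),
            rank=len(hits) + 1))

    if profile == "no_hit":
        add("Hsap", 35.0, 0.1, 0.5)  # fails both coverage and e-value
        return hits
    if profile == "contaminant":
        sp_pool = DIVISION_SPECIES["Bacteria"]
        for _ in range(5):
            add(rng.choice(sp_pool), rng.uniform(95.5, 99.5),
                rng.uniform(0.9, 1.0))
        for _ in range(3):
            add(rng.choice(METAZOAN_EXTERNALS), rng.uniform(30, 50),
                rng.uniform(0.4, 0.8))
        return hits
    if profile == "lgt":
        # a couple of plant-parasitic-nematode hits rank first and must
        # not occupy vote slots
        add("Mhap", rng.uniform(60, 80), rng.uniform(0.7, 1.0))
        n_non_met = int(rng.integers(8, 11))
        sp_pool = DIVISION_SPECIES[division]
        for _ in range(n_non_met):
            add(rng.choice(sp_pool), rng.uniform(25, 40),
                rng.uniform(0.4, 0.9))
        for _ in range(10 - n_non_met):
            add(rng.choice(METAZOAN_EXTERNALS), rng.uniform(25, 38),
                rng.uniform(0.35, 0.7))
        add("Hsap", 30.0, 0.1, 0.5)  # junk below thresholds
        return hits
    # vertical: metazoan-dominated
    n_met = int(rng.integers(7, 11))
    for _ in range(n_met):
        add(rng.choice(METAZOAN_EXTERNALS), rng.uniform(35, 70),
            rng.uniform(0.5, 1.0))
    for _ in range(10 - n_met):
        add(rng.choice(DIVISION_SPECIES["Bacteria"]), rng.uniform(25, 35),
            rng.uniform(0.4, 0.7))
    return hits


GO_NAMESPACE = {
    "GO:0008150": "biological_process",   # root BP
    "GO:0008152": "biological_process",   # metabolic process
    "GO:0005975": "biological_process",   # carbohydrate metabolic process
    "GO:0019538": "biological_process",   # protein metabolic process
    "GO:0006508": "biological_process",   # proteolysis
    "GO:0044042": "biological_process",   # glucan metabolic process
    "GO:0003674": "molecular_function",   # root MF
    "GO:0003824": "molecular_function",   # catalytic activity
    "GO:0016787": "molecular_function",   # hydrolase activity
    "GO:0008233": "molecular_function",   # peptidase activity
    "GO:0016301": "molecular_function",   # kinase activity
    "GO:0005488": "molecular_function",   # binding
}

GO_EDGES = [
    ("GO:0008152", "GO:0008150"),
    ("GO:0005975", "GO:0008152"),
    ("GO:0019538", "GO:0008152"),
    ("GO:0006508", "GO:0019538"),
    ("GO:0044042", "GO:0005975"),
    ("GO:0003824", "GO:0003674"),
    ("GO:0016787", "GO:0003824"),
    ("GO:0008233", "GO:0016787"),
    ("GO:0016301", "GO:0003824"),
    ("GO:0005488", "GO:0003674"),
]

GO_SLIM = {"GO:0008150", "GO:0005975", "GO:0019538", "GO:0003674",
           "GO:0003824", "GO:0016787", "GO:0005488"}

PFAM2GO = {
    "PF00001": {"GO:0005975"},                 # glycoside hydrolase-like
    "PF00002": {"GO:0006508", "GO:0008233"},   # peptidase-like
    "PF00003": {"GO:0016301"},                 # kinase-like
    "PF00004": {"GO:0005488"},                 # binder
    "PF00005": {"GO:0044042", "GO:0016787"},   # glucanase-like
    "PF00006": set(),                          # domain with no GO mapping
}


def generate(config: GeneratorConfig | None = None) -> Bundle:
    """Build a complete synthetic study bundle from a seeded config."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tax = build_default_taxonomy()

    proteins: list[ProteinRecord] = []
    groups: list[OrthoGroup] = []
    blast: dict[str, list[BlastHit]] = {}
    trees: dict[str, str] = {}
    truth: dict[str, GeneTruth] = {}
    representatives: dict[str, str] = {}
    cds: dict[str, str] = {}
    domains: list[tuple[str, str]] = []
    mobile_hits = []
    minc_gene_copies: dict[str, list[str]] = {}  # gene_id -> Minc copy ids

    def new_protein(pid: str, species: str, length: int | None = None,
                    sequence: str | None = None) -> ProteinRecord:
        if sequence is None:
            length = length or int(rng.integers(cfg.min_protein_len,
                                                cfg.max_protein_len))
            sequence = _random_protein(rng, length)
        rec = ProteinRecord(pid, species, len(sequence), sequence)
        proteins.append(rec)
        return rec

    divisions = sorted(cfg.donor_mix)
    div_p = np.array([cfg.donor_mix[d] for d in divisions])
    div_p = div_p / div_p.sum()

    # ---- LGT genes -----------------------------------------------------
    for i in range(1, cfg.n_lgt_genes + 1):
        gid = f"L{i:04d}"
        division = str(rng.choice(divisions, p=div_p))
        both, timing = _sample_timing(rng, cfg)
        recv_nwk, n_minc, n_mhap = _receiver_topology(rng, gid, both, timing)
        strong = rng.random() < cfg.p_strong_support
        mixed = rng.random() < cfg.p_mixed_donor
        nwk, support = build_lgt_tree(rng, gid, division, recv_nwk, strong,
                                      mixed)
        trees[gid] = nwk

        copy_ids = ([f"Minc{gid}_c{j}" for j in range(1, n_minc + 1)]
                    + [f"Mhap{gid}_c{j}" for j in range(1, n_mhap + 1)])
        members = []
        rep_len = int(rng.integers(cfg.max_protein_len,
                                   cfg.max_protein_len + 100))
        for k, cid in enumerate(copy_ids):
            sp = "Minc" if cid.startswith("Minc") else "Mhap"
            length = rep_len if k == 0 and sp == "Minc" else None
            members.append(new_protein(cid, sp, length))
        rep = members[0] if members[0].species == "Minc" else \
            max((m for m in members), key=lambda p: (p.species == "Minc",
                                                     p.length))
        representatives[gid] = rep.protein_id
        in_group = len(members) >= 2
        if in_group:
            groups.append(OrthoGroup(f"G_{gid}", tuple(members)))
        blast[rep.protein_id] = _make_blast_hits(
            rng, rep.protein_id, rep.length, "lgt", division, SPECIES_TAXIDS)
        minc_gene_copies[gid] = [m.protein_id for m in members
                                 if m.species == "Minc"]
        truth[gid] = GeneTruth(
            gene_id=gid, is_lgt=True, donor_division=division,
            n_copies_minc=n_minc, n_copies_mhap=n_mhap,
            duplication_timing=timing, both_species=both, support=support,
            in_group=in_group, te_enriched=True)

        if rng.random() < cfg.frac_lgt_mobile:
            from .mobile import MobileHit
            strict_ok = rng.random() < 0.5
            etype = str(rng.choice(["plasmid", "prophage", "virus"],
                                   p=[0.8, 0.13, 0.07]))
            if strict_ok:
                mobile_hits.append(MobileHit(
                    rep.protein_id, f"mge_{gid}", etype,
                    float(rng.uniform(31, 60)), float(rng.uniform(0.55, 0.95)),
                    float(rng.uniform(0.55, 0.95)),
                    float(10 ** rng.uniform(-40, -5))))
            else:
                mobile_hits.append(MobileHit(
                    rep.protein_id, f"mge_{gid}", etype,
                    float(rng.uniform(20, 28)), float(rng.uniform(0.2, 0.45)),
                    float(rng.uniform(0.2, 0.45)),
                    float(10 ** rng.uniform(-8, -4))))

    # ---- contaminants --------------------------------------------------
    for i in range(1, cfg.n_contaminants + 1):
        gid = f"C{i:04d}"
        rec = new_protein(f"Minc{gid}_c1", "Minc")
        representatives[gid] = rec.protein_id
        blast[rec.protein_id] = _make_blast_hits(
            rng, rec.protein_id, rec.length, "contaminant", None,
            SPECIES_TAXIDS)
        minc_gene_copies[gid] = [rec.protein_id]
        truth[gid] = GeneTruth(gene_id=gid, is_lgt=False, is_contaminant=True,
                               n_copies_minc=1)

    # ---- vertical genes ------------------------------------------------
    n_restricted = int(round(cfg.frac_vertical_restricted
                             * cfg.n_vertical_genes))
    for i in range(1, cfg.n_vertical_genes + 1):
        gid = f"V{i:04d}"
        rec = new_protein(f"Minc{gid}_c1", "Minc")
        minc_gene_copies[gid] = [rec.protein_id]
        restricted = i <= n_restricted
        truth[gid] = GeneTruth(gene_id=gid, is_lgt=False, n_copies_minc=1,
                               in_group=not restricted)
        if restricted:
            # root-knot-restricted singleton: survives the group filter,
            # must be rejected by the BLAST vote (or return nothing)
            representatives[gid] = rec.protein_id
            profile = "no_hit" if rng.random() < 0.1 else "vertical"
            blast[rec.protein_id] = _make_blast_hits(
                rng, rec.protein_id, rec.length, profile, None,
                SPECIES_TAXIDS)
            trees[gid] = build_vertical_tree(rng, gid)
        else:
            # clusters with another metazoan: discarded at stage 1
            other = str(rng.choice(OTHER_METAZOANS))
            partner = new_protein(f"{other}{gid}_h1", other)
            groups.append(OrthoGroup(f"G_{gid}", (rec, partner)))

    # ---- 2:1 decoy groups ----------------------------------------------
    for i in range(1, cfg.n_decoy_2to1 + 1):
        gid = f"D{i:04d}"
        a = new_protein(f"Minc{gid}_c1", "Minc")
        b = new_protein(f"Minc{gid}_c2", "Minc")
        c = new_protein(f"Mhap{gid}_c1", "Mhap")
        groups.append(OrthoGroup(f"G_{gid}", (a, b, c)))
        representatives[gid] = max((a, b), key=lambda p: p.length).protein_id
        blast[representatives[gid]] = _make_blast_hits(
            rng, representatives[gid], a.length, "vertical", None,
            SPECIES_TAXIDS)
        minc_gene_copies[gid] = [a.protein_id, b.protein_id]
        truth[gid] = GeneTruth(gene_id=gid, is_lgt=False, n_copies_minc=2,
                               n_copies_mhap=1, in_group=True)

    # ---- planted exact duplicates --------------------------------------
    originals = [p for p in proteins if p.species == "Minc"]
    for i in range(cfg.n_exact_duplicates):
        src = originals[int(rng.integers(len(originals)))]
        new_protein(f"{src.protein_id}_dup", "Minc", sequence=src.sequence)

    # ---- genome layout -------------------------------------------------
    genes, tes, scaffold_lengths = _layout_genome(rng, cfg, truth,
                                                  minc_gene_copies)

    # ---- CDS ------------------------------------------------------------
    for g in genes:
        n_codons = int(rng.integers(100, 300))
        cds[g.gene_id] = _random_cds(rng, n_codons, cfg.gc_content)

    # ---- domains --------------------------------------------------------
    dom_pool = sorted(PFAM2GO)
    for gid, t in sorted(truth.items()):
        pid = representatives.get(gid)
        if pid is None:
            pid = minc_gene_copies[gid][0]
        p_enriched = cfg.go_enrich_lgt if t.is_lgt else cfg.go_enrich_other
        if rng.random() < p_enriched:
            domains.append((pid, "PF00001"))
        elif rng.random() < 0.5:
            domains.append((pid, str(rng.choice(dom_pool[1:]))))

    for gid, rep_id in representatives.items():
        truth[gid].representative = rep_id

    return Bundle(
        config=cfg, taxonomy=tax, species_taxids=dict(SPECIES_TAXIDS),
        proteins=proteins, groups=groups, blast=blast, trees=trees,
        genes=genes, tes=tes, scaffold_lengths=scaffold_lengths, cds=cds,
        domains=domains, pfam2go={k: set(v) for k, v in PFAM2GO.items()},
        go_edges=list(GO_EDGES), go_namespace=dict(GO_NAMESPACE),
        go_slim=set(GO_SLIM), mobile_hits=mobile_hits, truth=truth,
        representatives=representatives)


def _layout_genome(rng, cfg, truth, minc_gene_copies):
    """Place M. incognita gene copies on scaffolds and sprinkle TEs.

    The first ``n_clusters`` scaffolds carry planted clusters of LGT
    copies spaced well under the 50 kb rule; all remaining genes are
    spaced 60 kb apart so no accidental cluster can form.  TEs are
    drawn per gene: Poisson(lambda) for ordinary genes,
    Poisson(lambda x enrichment) for LGT genes, placed uniformly within
    2 kb of the gene boundaries.
    """
    genes: list[GeneFeature] = []
    tes: list[TeFeature] = []
    scaffold_lengths: dict[str, int] = {}

    lgt_copy_ids = [cid for gid, t in sorted(truth.items()) if t.is_lgt
                    for cid in minc_gene_copies[gid]]
    other_copy_ids = [cid for gid, t in sorted(truth.items()) if not t.is_lgt
                      for cid in minc_gene_copies[gid]]
    lgt_set = set(lgt_copy_ids)

    clustered: list[str] = []
    idx = 0
    for c in range(cfg.n_clusters):
        take = lgt_copy_ids[idx: idx + cfg.cluster_size]
        idx += cfg.cluster_size
        if len(take) < 3:
            break
        clustered.extend(take)
        scaffold = f"scf_cluster_{c + 1}"
        pos = 10_000
        for cid in take:
            glen = int(rng.integers(1000, 3000))
            genes.append(GeneFeature(cid, scaffold, pos, pos + glen - 1,
                                     "+", True))
            pos += glen + int(rng.integers(5_000, 40_000))
        scaffold_lengths[scaffold] = pos + 10_000
        for gid, t in truth.items():
            if t.is_lgt and set(minc_gene_copies[gid]) & set(take):
                t.in_cluster = True

    remaining = ([cid for cid in lgt_copy_ids if cid not in clustered]
                 + other_copy_ids)
    per_scaffold = 10
    for s in range(0, len(remaining), per_scaffold):
        scaffold = f"scf_{s // per_scaffold + 1:03d}"
        pos = 10_000
        for cid in remaining[s: s + per_scaffold]:
            glen = int(rng.integers(1000, 3000))
            genes.append(GeneFeature(cid, scaffold, pos, pos + glen - 1,
                                     "+", cid in lgt_set))
            pos += glen + 60_000
        scaffold_lengths[scaffold] = pos + 10_000

    for g in genes:
        lam = cfg.te_lambda * (cfg.te_enrichment if g.is_lgt else 1.0)
        for k in range(rng.poisson(lam)):
            te_len = int(rng.integers(100, 500))
            offset = int(rng.integers(1, 2000))
            if rng.random() < 0.5:
                start = g.end + offset
            else:
                start = g.start - offset - te_len + 1
            start = max(1, start)
            tes.append(TeFeature(f"te_{g.gene_id}_{k}", g.scaffold_id,
                                 start, start + te_len - 1))
    return genes, tes, scaffold_lengths


def generate_duplication_trees(
    n_trees: int,
    seed: int,
    p_duplicated: float = 0.83,
    p_before_given_dup: float = 0.79,
    p_after_given_before: float = 0.72,
) -> tuple[dict[str, str], dict[str, str]]:
    """Trees of a both-species transfer cohort with planted timings.

    Returns (tree_id -> newick, tree_id -> planted timing).  Used to
    check that the timing classifier recovers the planted duplication
    rates at cohort scale.
    """
    cfg = GeneratorConfig(seed=seed, p_duplicated=p_duplicated,
                          p_before_given_dup=p_before_given_dup,
                          p_after_given_before=p_after_given_before)
    rng = np.random.default_rng(seed)
    trees: dict[str, str] = {}
    timings: dict[str, str] = {}
    for i in range(1, n_trees + 1):
        gid = f"T{i:05d}"
        _, timing = _sample_timing(rng, cfg, force_both=True)
        recv, _, _ = _receiver_topology(rng, gid, True, timing)
        division = str(rng.choice(sorted(DIVISION_SPECIES)))
        nwk, _ = build_lgt_tree(rng, gid, division, recv,
                                strong=bool(rng.random() < 0.7),
                                mixed_donor=False)
        trees[gid] = nwk
        timings[gid] = timing
    return trees, timings


def random_gene_trees(
    n_trees: int,
    n_leaves: int,
    species_pool: tuple[str, ...],
    seed: int,
) -> dict[str, str]:
    """Uniform random rooted binary topologies over random species draws.

    Leaves are labelled ``species|species_tNNN_i``; topologies are built
    by random sequential joining.  Used for oracle-equivalence checks
    of the pattern matcher, where no structure should be assumed.
    """
    rng = np.random.default_rng(seed)
    trees: dict[str, str] = {}
    for t in range(1, n_trees + 1):
        species = rng.choice(species_pool, size=n_leaves)
        nodes = [f"{sp}|{sp}_t{t:03d}_{i}" for i, sp in enumerate(species)]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            nodes.append(f"({a},{b})")
        trees[f"rt{t:04d}"] = nodes[0] + ";"
    return trees


def generate_te_layout(
    seed: int,
    n_per_class: int = 200,
    te_lambda: float = 1.0,
    enrichment: float = 2.0,
) -> tuple[list[GeneFeature], list[TeFeature], dict[str, int]]:
    """Coordinate-only genome: n LGT-class and n ordinary genes with
    Poisson TE counts (enriched around the LGT class).  Cheap enough to
    replicate for power checks."""
    cfg = GeneratorConfig(seed=seed, te_lambda=te_lambda,
                          te_enrichment=enrichment, n_clusters=0)
    rng = np.random.default_rng(seed)
    truth = {}
    copies = {}
    for i in range(n_per_class):
        truth[f"L{i:04d}"] = GeneTruth(f"L{i:04d}", True, te_enriched=True)
        copies[f"L{i:04d}"] = [f"MincL{i:04d}_c1"]
    for i in range(n_per_class):
        truth[f"V{i:04d}"] = GeneTruth(f"V{i:04d}", False)
        copies[f"V{i:04d}"] = [f"MincV{i:04d}_c1"]
    return _layout_genome(rng, cfg, truth, copies)
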