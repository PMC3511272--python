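"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA goes through Biopython.  Ortholog groups use the OrthoMCL line
format (``group_id: species|protein_id ...``).  BLAST hits are tabular
outfmt-6-like with a trailing subject-taxid column; the column order is
configurable.  Genome annotation is GFF3 (1-based inclusive) with
``##sequence-region`` pragmas carrying scaffold lengths.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .context import GeneFeature, TeFeature
from .homology import BlastHit, OrthoGroup, ProteinRecord, VoteDecision
from .mobile import MobileHit


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = path, lineno


# --- FASTA ---------------------------------------------------------------

def _split_tag(label: str) -> tuple[str, str]:
    if "|" in label:
        species, pid = label.split("|", 1)
        return species, pid
    return "", label


def read_proteome(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA whose IDs are ``species|protein_id``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species, pid = _split_tag(rec.id)
        seq = str(rec.seq)
        out.append(ProteinRecord(pid, species, len(seq), seq))
    return out


def write_proteome(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence or ""),
                  id=(f"{p.species}|{p.protein_id}" if p.species
                      else p.protein_id),
                  description="")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --- OrthoMCL groups -----------------------------------------------------

def read_groups(
    path: str | Path,
    protein_index: Mapping[str, ProteinRecord] | None = None,
) -> list[OrthoGroup]:
    """OrthoMCL group file: ``group_id: species|protein_id ...``.

    When a protein index (id -> record) is supplied, members reuse the
    indexed records (with lengths and sequences); otherwise stub
    records of length 1 are built from the species-tagged IDs.
    """
    groups = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(path, lineno, "missing 'group_id:' prefix")
            group_id, rest = line.split(":", 1)
            members = []
            for token in rest.split():
                species, pid = _split_tag(token)
                if protein_index and pid in protein_index:
                    members.append(protein_index[pid])
                else:
                    members.append(ProteinRecord(pid, species, 1))
            if not members:
                raise ParseError(path, lineno, f"group {group_id} is empty")
            groups.append(OrthoGroup(group_id.strip(), tuple(members)))
    return groups


def write_groups(groups: Iterable[OrthoGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in groups:
            members = " ".join(f"{m.species}|{m.protein_id}" for m in g.members)
            fh.write(f"{g.group_id}: {members}\n")


# --- BLAST tabular -------------------------------------------------------

#: outfmt-6 columns plus a trailing subject taxid.
DEFAULT_BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "staxid",
)

REQUIRED_BLAST_COLUMNS = ("qseqid", "sseqid", "pident", "length", "evalue",
                          "staxid")


def read_blast_table(
    path: str | Path,
    columns: Sequence[str] = DEFAULT_BLAST_COLUMNS,
) -> dict[str, list[BlastHit]]:
    """Parse a tabular BLAST file into per-query hit lists.

    Hits keep file order per query; ranks are assigned 1..n in that
    order (ascending e-value is the convention of the producing tool).
    """
    missing = [c for c in REQUIRED_BLAST_COLUMNS if c not in columns]
    if missing:
        raise ValueError(f"BLAST column spec lacks required columns: {missing}")
    idx = {c: i for i, c in enumerate(columns)}
    hits: dict[str, list[BlastHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < len(columns):
                raise ParseError(path, lineno,
                                 f"expected {len(columns)} columns, got {len(parts)}")
            try:
                query = parts[idx["qseqid"]]
                hit = BlastHit(
                    query_id=query,
                    subject_id=parts[idx["sseqid"]],
                    subject_taxid=int(parts[idx["staxid"]]),
                    percent_identity=float(parts[idx["pident"]]),
                    align_length_on_query=int(parts[idx["length"]]),
                    evalue=float(parts[idx["evalue"]]),
                    bitscore=(float(parts[idx["bitscore"]])
                              if "bitscore" in idx else None),
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            bucket = hits.setdefault(query, [])
            bucket.append(BlastHit(**{**hit.__dict__, "rank": len(bucket) + 1}))
    return hits


def write_blast_table(
    hits: Mapping[str, Sequence[BlastHit]],
    path: str | Path,
    columns: Sequence[str] = DEFAULT_BLAST_COLUMNS,
) -> None:
    with open(path, "w") as fh:
        for query in hits:
            for h in hits[query]:
                row = {
                    "qseqid": h.query_id, "sseqid": h.subject_id,
                    "pident": f"{h.percent_identity:.1f}",
                    "length": h.align_length_on_query,
                    "mismatch": 0, "gapopen": 0, "qstart": 1,
                    "qend": h.align_length_on_query, "sstart": 1,
                    "send": h.align_length_on_query,
                    "evalue": f"{h.evalue:.2e}",
                    "bitscore": f"{h.bitscore:.1f}" if h.bitscore else "0.0",
                    "staxid": h.subject_taxid,
                }
                fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def write_decision_log(decisions: Iterable[VoteDecision], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tstatus\tvote_fraction\tn_considered\treason\n")
        for d in decisions:
            frac = f"{d.vote_fraction:.3f}" if d.vote_fraction is not None else "NA"
            fh.write(f"{d.query_id}\t{d.status}\t{frac}\t{d.n_considered}\t"
                     f"{d.reason}\n")


# --- GFF3 ----------------------------------------------------------------

def read_gff3(
    path: str | Path,
    gene_types: frozenset[str] = frozenset({"gene"}),
    te_types: frozenset[str] = frozenset({"transposable_element", "repeat_region"}),
) -> tuple[list[GeneFeature], list[TeFeature], dict[str, int]]:
    """Genes, TEs and scaffold lengths from a GFF3 file.

    Feature identity comes from the ``ID=`` attribute; scaffold lengths
    from ``##sequence-region`` pragmas.  Which feature types count as
    genes or TEs is configurable.
    """
    genes: list[GeneFeature] = []
    tes: list[TeFeature] = []
    scaffold_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                scaffold_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(path, lineno, "GFF3 rows need 9 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            fid = attr.get("ID", f"{ftype}_{lineno}")
            if ftype in gene_types:
                genes.append(GeneFeature(fid, seqid, int(start), int(end),
                                         strand))
            elif ftype in te_types:
                tes.append(TeFeature(fid, seqid, int(start), int(end)))
    return genes, tes, scaffold_lengths


def write_gff3(
    genes: Sequence[GeneFeature],
    tes: Sequence[TeFeature],
    scaffold_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold in sorted(scaffold_lengths):
            fh.write(f"##sequence-region {scaffold} 1 "
                     f"{scaffold_lengths[scaffold]}\n")
        features = (
            [("gene", g.gene_id, g.scaffold_id, g.start, g.end, g.strand,
              f"ID={g.gene_id}" + (";lgt=1" if g.is_lgt else ""))
             for g in genes]
            + [("transposable_element", t.te_id, t.scaffold_id, t.start,
                t.end, "+", f"ID={t.te_id}") for t in tes]
        )
        for ftype, fid, scaffold, start, end, strand, attrs in sorted(
                features, key=lambda f: (f[2], f[3], f[1])):
            fh.write(f"{scaffold}\tlgtscan\t{ftype}\t{start}\t{end}\t.\t"
                     f"{strand}\t.\t{attrs}\n")


def mark_lgt_genes(genes: Sequence[GeneFeature],
                   lgt_ids: set[str]) -> list[GeneFeature]:
    return [GeneFeature(g.gene_id, g.scaffold_id, g.start, g.end, g.strand,
                        is_lgt=g.gene_id in lgt_ids) for g in genes]


# --- mobile-element hits -------------------------------------------------

def read_mobile_hits(path: str | Path) -> list[MobileHit]:
    """TSV: query_id, subject_id, element_type, pident, qcov, scov, evalue."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query_id\t"):
                continue
            parts = line.split("\t")
            try:
                out.append(MobileHit(parts[0], parts[1], parts[2],
                                     float(parts[3]), float(parts[4]),
                                     float(parts[5]), float(parts[6])))
            except (IndexError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_mobile_hits(hits: Iterable[MobileHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\telement_type\tpident\tqcov\tscov\t"
                 "evalue\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.element_type}\t"
                     f"{h.percent_identity:.1f}\t{h.qcov:.3f}\t{h.scov:.3f}\t"
                     f"{h.evalue:.2e}\n")


# --- published worked-example counts ------------------------------------

def load_published_counts() -> dict:
    """Counts of the original root-knot nematode survey, shipped with the
    package as worked-example inputs for the enumeration operations."""
    with resources.files("lgtscan.data").joinpath(
            "published_counts.json").open() as fh:
        return json.load(fh)
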