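"""Homology-based candidate filtering for lateral gene transfer.

Stages one and two of the pipeline: redundancy removal in the input
proteomes, selection of ortholog groups restricted to the focal
root-knot nematodes (any group that also contains another metazoan
species is evidence of vertical descent and is discarded), choice of a
single representative per group, the non-metazoan BLAST vote that marks
candidates for lateral acquisition, the contamination filter, and the
OrthoMCL-based in-paralog counts used to quantify lineage-specific
duplication.

The vote: after discarding hits failing the e-value and query-coverage
thresholds, and skipping hits to the focal species themselves or to
other plant-parasitic nematode lineages (those do not count as metazoan
evidence — a transfer that predates the split of plant-parasitic
lineages would otherwise be masked), a query is a candidate when at
least half of its ten best remaining hits are non-metazoan.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .taxonomy import EUMETAZOA_TAXID, TaxonomyTree

DEFAULT_FOCAL_SPECIES = ("Minc", "Mhap")


@dataclass(frozen=True)
class ProteinRecord:
    """A species-tagged protein sequence."""

    protein_id: str
    species: str
    length: int
    sequence: str | None = None

    def __post_init__(self):
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.protein_id}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass(frozen=True)
class OrthoGroup:
    """A named ortholog cluster of species-tagged protein IDs."""

    group_id: str
    members: tuple[ProteinRecord, ...]

    def __post_init__(self):
        ids = [m.protein_id for m in self.members]
        if not ids:
            raise ValueError(f"group {self.group_id} has no members")
        if len(set(ids)) != len(ids):
            raise ValueError(f"group {self.group_id} has duplicate member IDs")

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for m in self.members:
            counts[m.species] += 1
        return dict(counts)


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    subject_taxid: int
    percent_identity: float
    align_length_on_query: int
    evalue: float
    bitscore: float | None = None
    rank: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"{self.query_id}->{self.subject_id}: identity "
                f"{self.percent_identity} outside [0, 100]"
            )


@dataclass
class VoteConfig:
    """Thresholds of the BLAST filter; defaults are the published ones."""

    evalue_max: float = 0.01
    qcov_min: float = 0.30
    top_n: int = 10
    vote_min: float = 0.50
    metazoa_taxid: int = EUMETAZOA_TAXID
    #: If True (default), self/PPN hits are removed before the top-N
    #: window is taken, so the vote runs over N informative hits.
    skip_before_window: bool = True


@dataclass
class VoteDecision:
    query_id: str
    status: str  # candidate | not_candidate | no_hit
    vote_fraction: float | None
    n_considered: int
    reason: str

    @property
    def is_candidate(self) -> bool:
        return self.status == "candidate"


@dataclass
class CandidateSet:
    """Disjoint outcome classes of the BLAST stage."""

    candidate_ids: set[str] = field(default_factory=set)
    contaminants: set[str] = field(default_factory=set)
    no_hit_ids: set[str] = field(default_factory=set)

    def __post_init__(self):
        if (self.candidate_ids & self.contaminants
                or self.candidate_ids & self.no_hit_ids
                or self.contaminants & self.no_hit_ids):
            raise ValueError("candidate/contaminant/no-hit sets must be disjoint")


@dataclass(frozen=True)
class GroupParalogy:
    group_id: str
    n_minc: int
    n_mhap: int
    classification: str  # unclustered-singleton | not-duplicated |
    #                      discarded-2:1 | species-specific-duplication


@dataclass
class InparalogSummary:
    per_group: list[GroupParalogy]
    class_counts: dict[str, int]
    lgt_class_counts: dict[str, int]
    n_lgt_genes_in_groups: int
    n_lgt_genes_duplicated: int
    pct_lgt_duplicated: float
    n_groups: int
    n_groups_duplicated: int
    pct_groups_duplicated: float


def dedup_exact(proteins: Sequence[ProteinRecord]) -> tuple[
        list[ProteinRecord], dict[str, str]]:
    """Collapse clusters of 100%-identical sequences to one survivor.

    The survivor is the longest member (all members of an identical
    cluster necessarily tie), with lexicographically smallest ID on
    ties.  Returns the survivors in input order and a map from each
    redundant ID to its survivor's ID.
    """
    by_seq: dict[str, list[ProteinRecord]] = defaultdict(list)
    for p in proteins:
        if p.sequence is None:
            raise ValueError(f"protein {p.protein_id} has no sequence")
        by_seq[p.sequence].append(p)

    survivor_of: dict[str, str] = {}
    survivors: set[str] = set()
    for cluster in by_seq.values():
        keeper = min(cluster, key=lambda p: (-p.length, p.protein_id))
        survivors.add(keeper.protein_id)
        for p in cluster:
            if p.protein_id != keeper.protein_id:
                survivor_of[p.protein_id] = keeper.protein_id
    kept = [p for p in proteins if p.protein_id in survivors]
    return kept, survivor_of


def select_restricted_groups(
    groups: Sequence[OrthoGroup],
    focal_species: Iterable[str] = DEFAULT_FOCAL_SPECIES,
    ppn_ok: Iterable[str] = (),
    known_species: Iterable[str] | None = None,
) -> tuple[list[OrthoGroup], list[OrthoGroup]]:
    """Split groups into focal-restricted and discarded.

    A group survives only if every member belongs to the focal species
    or to an allowed plant-parasitic nematode species; clustering with
    any other metazoan is taken as evidence of vertical descent.
    Returns (restricted, discarded).
    """
    allowed = set(focal_species) | set(ppn_ok)
    known = set(known_species) if known_species is not None else None
    restricted: list[OrthoGroup] = []
    discarded: list[OrthoGroup] = []
    for g in groups:
        if known is not None:
            unknown = sorted({m.species for m in g.members} - known)
            if unknown:
                raise ValueError(
                    f"group {g.group_id}: unknown species tags {unknown}")
        if all(m.species in allowed for m in g.members):
            restricted.append(g)
        else:
            discarded.append(g)
    return restricted, discarded


def find_singletons(
    proteins: Sequence[ProteinRecord],
    groups: Sequence[OrthoGroup],
    focal_species: Iterable[str] = DEFAULT_FOCAL_SPECIES,
) -> list[ProteinRecord]:
    """Focal proteins that were not clustered into any group."""
    grouped = {m.protein_id for g in groups for m in g.members}
    focal = set(focal_species)
    return [p for p in proteins
            if p.species in focal and p.protein_id not in grouped]


def choose_representative(
    group: OrthoGroup,
    primary_species: str = "Minc",
    secondary_species: str = "Mhap",
) -> ProteinRecord:
    """Longest primary-species member; else longest secondary.

    Ties broken by lexicographically smallest protein ID.
    """
    for species in (primary_species, secondary_species):
        pool = [m for m in group.members if m.species == species]
        if pool:
            return min(pool, key=lambda p: (-p.length, p.protein_id))
    raise ValueError(
        f"group {group.group_id} contains neither {primary_species} nor "
        f"{secondary_species}")


def _sorted_hits(hits: Sequence[BlastHit]) -> list[BlastHit]:
    if all(h.rank is not None for h in hits) and hits:
        return sorted(hits, key=lambda h: h.rank)
    return sorted(
        hits,
        key=lambda h: (h.evalue,
                       -(h.bitscore if h.bitscore is not None else 0.0),
                       h.subject_id),
    )


def vote_non_metazoan(
    query: ProteinRecord,
    hits: Sequence[BlastHit],
    tree: TaxonomyTree,
    cfg: VoteConfig | None = None,
    self_taxids: frozenset[int] | None = None,
    species_taxids: Mapping[str, int] | None = None,
) -> VoteDecision:
    """Classify a query by the taxonomy of its best BLAST hits.

    Hits failing the e-value or query-coverage thresholds are dropped;
    hits to the focal species themselves (``self_taxids``, or the taxid
    of the query's own species via ``species_taxids``) and to
    plant-parasitic nematode lineages are skipped without occupying a
    slot.  The query is a candidate when the non-metazoan fraction of
    the surviving top-N hits reaches ``vote_min`` (inclusive).  With no
    surviving hits the query is unclassifiable (``no_hit``).
    """
    cfg = cfg or VoteConfig()
    skip_taxids = set(self_taxids or ())
    if species_taxids:
        for sp in DEFAULT_FOCAL_SPECIES:
            if sp in species_taxids:
                skip_taxids.add(species_taxids[sp])

    surviving: list[BlastHit] = []
    for h in _sorted_hits(hits):
        if h.evalue > cfg.evalue_max:
            continue
        if h.align_length_on_query < cfg.qcov_min * query.length:
            continue
        if cfg.skip_before_window and (
                h.subject_taxid in skip_taxids or tree.is_ppn(h.subject_taxid)):
            continue
        surviving.append(h)

    if not cfg.skip_before_window:
        surviving = surviving[: cfg.top_n]
        surviving = [h for h in surviving
                     if h.subject_taxid not in skip_taxids
                     and not tree.is_ppn(h.subject_taxid)]
    else:
        surviving = surviving[: cfg.top_n]

    if not surviving:
        return VoteDecision(query.protein_id, "no_hit", None, 0,
                            "no informative hit passed the filters")

    n_non_metazoan = sum(
        1 for h in surviving
        if not tree.is_descendant(h.subject_taxid, cfg.metazoa_taxid))
    fraction = n_non_metazoan / len(surviving)
    if fraction >= cfg.vote_min:
        return VoteDecision(query.protein_id, "candidate", fraction,
                            len(surviving),
                            f"{n_non_metazoan}/{len(surviving)} non-metazoan")
    return VoteDecision(query.protein_id, "not_candidate", fraction,
                        len(surviving),
                        f"{n_non_metazoan}/{len(surviving)} non-metazoan")


def flag_contaminants(
    query: ProteinRecord,
    hits: Sequence[BlastHit],
    tree: TaxonomyTree,
    identity_min: float = 80.0,
    qcov_min: float = 0.5,
    metazoa_taxid: int = EUMETAZOA_TAXID,
) -> bool:
    """True iff some non-metazoan hit looks like raw contamination.

    The thresholds are strict: identity must exceed ``identity_min``
    and the alignment must cover more than ``qcov_min`` of the query.
    A real transfer has had time to diverge; a near-identical
    full-length match to a non-metazoan sequence is more parsimoniously
    a contaminating contig.
    """
    for h in hits:
        if tree.is_descendant(h.subject_taxid, metazoa_taxid):
            continue
        if (h.percent_identity > identity_min
                and h.align_length_on_query > qcov_min * query.length):
            return True
    return False


def classify_group_paralogy(group: OrthoGroup,
                            minc: str = "Minc", mhap: str = "Mhap") -> GroupParalogy:
    counts = group.species_counts()
    n_minc = counts.get(minc, 0)
    n_mhap = counts.get(mhap, 0)
    if len(group.members) == 1:
        cls = "unclustered-singleton"
    elif n_minc >= 3 or n_mhap >= 2:
        cls = "species-specific-duplication"
    elif n_minc == 2 and n_mhap == 1:
        # Half the M. incognita genome is present in two copies; a
        # 2:1 group is indistinguishable from that structure and is
        # not counted as a true duplication.
        cls = "discarded-2:1"
    else:
        cls = "not-duplicated"
    return GroupParalogy(group.group_id, n_minc, n_mhap, cls)


def count_inparalog_groups(
    groups: Sequence[OrthoGroup],
    lgt_ids: set[str],
) -> InparalogSummary:
    """Per-group duplication classes, overall and for the LGT subset.

    A group shows lineage-specific (post-speciation) duplication when
    it holds at least three M. incognita or at least two M. hapla
    copies; 2:1 groups are discarded as a genome-structure artifact.
    The LGT tally counts focal genes (group members) in LGT-containing
    groups, mirroring the published per-gene proportions.
    """
    per_group = [classify_group_paralogy(g) for g in groups]
    class_counts: dict[str, int] = defaultdict(int)
    lgt_class_counts: dict[str, int] = defaultdict(int)
    n_lgt_in_groups = 0
    n_lgt_duplicated = 0
    for g, gp in zip(groups, per_group):
        class_counts[gp.classification] += 1
        has_lgt = any(m.protein_id in lgt_ids for m in g.members)
        if has_lgt:
            lgt_class_counts[gp.classification] += 1
            n_members = len(g.members)
            n_lgt_in_groups += n_members
            if gp.classification == "species-specific-duplication":
                n_lgt_duplicated += n_members
    n_groups = len(groups)
    n_groups_dup = class_counts.get("species-specific-duplication", 0)
    return InparalogSummary(
        per_group=per_group,
        class_counts=dict(class_counts),
        lgt_class_counts=dict(lgt_class_counts),
        n_lgt_genes_in_groups=n_lgt_in_groups,
        n_lgt_genes_duplicated=n_lgt_duplicated,
        pct_lgt_duplicated=(100.0 * n_lgt_duplicated / n_lgt_in_groups
                            if n_lgt_in_groups else 0.0),
        n_groups=n_groups,
        n_groups_duplicated=n_groups_dup,
        pct_groups_duplicated=(100.0 * n_groups_dup / n_groups
                               if n_groups else 0.0),
    )
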