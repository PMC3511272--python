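"""Headline tallies of the LGT survey.

Two enumerations of laterally acquired genes in the M. incognita
genome: one from ortholog groups plus the BLAST vote (singletons plus
every in-paralogous copy in LGT-containing groups), one from the trees
with phylogenetic support (summing M. incognita leaves over acceptor
subtrees).  Plus the duplication-cohort percentages computed from the
per-tree duplication reports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .treescan import DuplicationReport


@dataclass(frozen=True)
class CopyRow:
    copies: int | str  # exact count, or ">8"-style overflow bucket
    n_groups: int
    n_genes: int

    def validate(self) -> None:
        if self.n_groups < 0 or self.n_genes < 0:
            raise ValueError("negative counts in copy distribution row")
        if isinstance(self.copies, int):
            if self.n_genes != self.copies * self.n_groups:
                raise ValueError(
                    f"row copies={self.copies}: n_genes {self.n_genes} != "
                    f"{self.copies} x {self.n_groups} groups")


@dataclass
class CopyDistribution:
    """Copies-per-group histogram with unclustered singletons aside.

    Published tables merge singletons into the 1-copy display row;
    here they are stored separately so the exact-bucket consistency
    rule (n_genes == copies x n_groups) always holds, and the report
    renderer merges them for display.
    """

    rows: list[CopyRow] = field(default_factory=list)
    singletons: int = 0

    def __post_init__(self):
        for row in self.rows:
            row.validate()
        if self.singletons < 0:
            raise ValueError("negative singleton count")

    @classmethod
    def from_group_sizes(cls, sizes: Iterable[int], singletons: int = 0,
                         overflow_at: int = 8) -> "CopyDistribution":
        hist = Counter(sizes)
        rows = []
        over_groups = over_genes = 0
        for size in sorted(hist):
            if size <= overflow_at:
                rows.append(CopyRow(size, hist[size], size * hist[size]))
            else:
                over_groups += hist[size]
                over_genes += size * hist[size]
        if over_groups:
            rows.append(CopyRow(f">{overflow_at}", over_groups, over_genes))
        return cls(rows=rows, singletons=singletons)

    def n_groups(self) -> int:
        return sum(r.n_groups for r in self.rows)


def total_lgt_genes(dist: CopyDistribution) -> int:
    """Singletons plus every gene copy across the grouped rows."""
    return dist.singletons + sum(r.n_genes for r in dist.rows)


def total_phylo_supported(dist: CopyDistribution) -> int:
    """Total genes over a distribution of per-tree acceptor-leaf counts."""
    return dist.singletons + sum(r.n_genes for r in dist.rows)


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_of_proteome(n: int, proteome_size: int) -> float:
    """Percentage of the proteome, rounded half-up to 2 decimals."""
    if proteome_size <= 0:
        raise ValueError("proteome size must be positive")
    return round_half_up(100.0 * n / proteome_size, 2)


@dataclass
class CohortStats:
    n_both_species: int
    n_duplicated: int
    n_before: int
    n_after_given_before: int
    pct_duplicated: int
    pct_before: int
    pct_after_given_before: int


def cohort_percentages(n_both: int, n_dup: int, n_before: int,
                       n_after_given_before: int) -> CohortStats:
    def pct(a: int, b: int) -> int:
        return int(round_half_up(100.0 * a / b)) if b else 0

    return CohortStats(
        n_both_species=n_both,
        n_duplicated=n_dup,
        n_before=n_before,
        n_after_given_before=n_after_given_before,
        pct_duplicated=pct(n_dup, n_both),
        pct_before=pct(n_before, n_dup),
        pct_after_given_before=pct(n_after_given_before, n_before),
    )


def duplication_cohort_stats(reports: Sequence[DuplicationReport]) -> CohortStats:
    """Cohort percentages over trees containing both focal species.

    Of the trees holding both M. incognita and M. hapla genes (acquired
    at latest in their common ancestor): how many duplicated at all,
    how many of those duplicated before the speciation split, and how
    many of the before-split cases continued duplicating after it.
    Percentages printed as integers (half-up), as in the study.
    """
    both = [r for r in reports if r.both_species_present]
    dup = [r for r in both if r.duplicated]
    before = [r for r in dup if r.before_split]
    after_given_before = [r for r in before if r.after_split]
    return cohort_percentages(len(both), len(dup), len(before),
                              len(after_given_before))


def render_copy_table(dist: CopyDistribution) -> str:
    """Markdown-ish report merging singletons into the 1-copy row."""
    lines = ["copies\tn_groups\tn_genes"]
    for row in dist.rows:
        genes = row.n_genes
        note = ""
        if row.copies == 1 and dist.singletons:
            genes += dist.singletons
            note = f"  # incl. {dist.singletons} unclustered singletons"
        lines.append(f"{row.copies}\t{row.n_groups}\t{genes}{note}")
    if dist.singletons and not any(r.copies == 1 for r in dist.rows):
        lines.append(f"1\t0\t{dist.singletons}  # unclustered singletons")
    lines.append(f"Total\t{dist.n_groups()}\t{total_lgt_genes(dist)}")
    return "\n".join(lines)
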