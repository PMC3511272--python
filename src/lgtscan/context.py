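"""Genomic-context analytics around candidate LGT genes.

Clusters of laterally acquired genes on scaffolds, transposable-element
density in flanking windows with a chi-square comparison against the
rest of the gene set, relative scaffold-end positions, GC content and
codon-usage tables.  All coordinates are GFF3-style 1-based inclusive.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats

TE_WINDOWS = (200, 500, 1000, 2000)


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    is_lgt: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class TeFeature:
    te_id: str
    scaffold_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.te_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class GenomicCluster:
    scaffold_id: str
    gene_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def detect_lgt_clusters(
    genes: Sequence[GeneFeature],
    max_gap: int = 50_000,
    min_size: int = 3,
) -> list[GenomicCluster]:
    """Single-linkage chains of LGT genes along each scaffold.

    The gap between consecutive LGT genes is the number of bases
    between them (next.start − prev.end − 1, clamped at 0 for
    overlapping models); a chain extends while the gap stays strictly
    below ``max_gap``.  Chains of at least ``min_size`` genes are
    reported.  Output is independent of input order.
    """
    lgt = sorted((g for g in genes if g.is_lgt),
                 key=lambda g: (g.scaffold_id, g.start, g.end, g.gene_id))
    clusters: list[GenomicCluster] = []
    chain: list[GeneFeature] = []

    def flush():
        if len(chain) >= min_size:
            clusters.append(GenomicCluster(chain[0].scaffold_id,
                                           tuple(g.gene_id for g in chain)))

    for g in lgt:
        if chain and g.scaffold_id == chain[-1].scaffold_id:
            gap = max(0, g.start - chain[-1].end - 1)
            if gap < max_gap:
                chain.append(g)
                continue
        flush()
        chain = [g]
    flush()
    return clusters


def _flank_intervals(gene: GeneFeature, window: int,
                     scaffold_len: int | None) -> list[tuple[int, int]]:
    upstream = (gene.start - window, gene.start - 1)
    downstream = (gene.end + 1, gene.end + window)
    out = []
    for lo, hi in (upstream, downstream):
        lo = max(1, lo)
        if scaffold_len is not None:
            hi = min(scaffold_len, hi)
        if lo <= hi:
            out.append((lo, hi))
    return out


def count_te_in_windows(
    gene: GeneFeature,
    tes: Sequence[TeFeature],
    window: int,
    scaffold_len: int | None = None,
) -> int:
    """Number of TEs overlapping the two flanks of a gene.

    A TE counts when it overlaps either flank by at least one base;
    a TE spanning both flanks counts once.  Flanks are clipped at
    scaffold bounds.
    """
    flanks = _flank_intervals(gene, window, scaffold_len)
    n = 0
    for te in tes:
        if te.scaffold_id != gene.scaffold_id:
            continue
        if any(te.start <= hi and te.end >= lo for lo, hi in flanks):
            n += 1
    return n


def te_window_counts(
    genes: Sequence[GeneFeature],
    tes: Sequence[TeFeature],
    windows: Iterable[int] = TE_WINDOWS,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Long-form table: gene_id, is_lgt, window, n_te."""
    by_scaffold: dict[str, list[TeFeature]] = defaultdict(list)
    for te in tes:
        by_scaffold[te.scaffold_id].append(te)
    rows = []
    for g in genes:
        slen = (scaffold_lengths or {}).get(g.scaffold_id)
        local = by_scaffold.get(g.scaffold_id, ())
        for w in windows:
            rows.append((g.gene_id, g.is_lgt, w,
                         count_te_in_windows(g, local, w, slen)))
    return pd.DataFrame(rows, columns=["gene_id", "is_lgt", "window", "n_te"])


@dataclass
class TeDensityResult:
    window: int
    mean_lgt: float
    se_lgt: float
    mean_other: float
    se_other: float
    statistic: float
    df: int
    p_value: float
    low_expected: bool


def _mean_se(counts: Sequence[int]) -> tuple[float, float]:
    arr = np.asarray(counts, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return float(arr.mean()), se


def compare_te_density(
    lgt_counts: Sequence[int],
    other_counts: Sequence[int],
    window: int = 0,
) -> TeDensityResult:
    """Chi-square (1 df) comparison of TE presence near two gene classes.

    The 2x2 table is gene class x {>=1 TE in window, 0 TE}, Pearson
    chi-square without continuity correction.  Means and standard
    errors of the raw counts are reported alongside, matching the shape
    of the published density table.
    """
    if not lgt_counts or not other_counts:
        raise ValueError("both count lists must be non-empty")
    table = np.array([
        [sum(1 for c in lgt_counts if c > 0), sum(1 for c in lgt_counts if c == 0)],
        [sum(1 for c in other_counts if c > 0), sum(1 for c in other_counts if c == 0)],
    ], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        # One outcome column entirely absent: no association testable.
        statistic, p, low = 0.0, 1.0, True
    else:
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        statistic, low = float(chi2), bool((expected < 1).any())
        p = float(p)
    mean_lgt, se_lgt = _mean_se(lgt_counts)
    mean_other, se_other = _mean_se(other_counts)
    return TeDensityResult(window, mean_lgt, se_lgt, mean_other, se_other,
                           statistic, 1, p, low)


def te_density_report(
    counts: pd.DataFrame,
    windows: Iterable[int] = TE_WINDOWS,
) -> list[TeDensityResult]:
    """One density comparison per window from a ``te_window_counts`` table."""
    out = []
    for w in windows:
        sub = counts[counts["window"] == w]
        out.append(compare_te_density(
            sub.loc[sub["is_lgt"], "n_te"].tolist(),
            sub.loc[~sub["is_lgt"], "n_te"].tolist(),
            window=w,
        ))
    return out


def scaffold_end_positions(
    genes: Sequence[GeneFeature],
    scaffold_lengths: Mapping[str, int],
) -> dict[str, float]:
    """Relative distance of each gene's midpoint to the nearer scaffold
    end, in [0, 0.5]; 0 means at a tip, 0.5 means centered."""
    out = {}
    for g in genes:
        length = scaffold_lengths[g.scaffold_id]
        mid = (g.start + g.end) / 2
        out[g.gene_id] = min(mid - 1, length - mid) / length
    return out


def compare_end_positions(
    lgt_positions: Sequence[float],
    other_positions: Sequence[float],
    n_bins: int = 5,
) -> tuple[float, int, float]:
    """Chi-square on binned relative positions of the two gene classes."""
    bins = np.linspace(0, 0.5, n_bins + 1)
    h_lgt, _ = np.histogram(lgt_positions, bins=bins)
    h_other, _ = np.histogram(other_positions, bins=bins)
    table = np.vstack([h_lgt, h_other]).astype(float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def gc_content(cds: str) -> float:
    """GC percentage of a nucleotide sequence; N bases are excluded
    from the denominator."""
    seq = cds.upper()
    counts = Counter(seq)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom


_CODON_TABLE = unambiguous_dna_by_id[1]  # standard genetic code


def _codon_to_aa() -> dict[str, str]:
    mapping = dict(_CODON_TABLE.forward_table)
    for stop in _CODON_TABLE.stop_codons:
        mapping[stop] = "*"
    return mapping


CODON_AA = _codon_to_aa()
ALL_CODONS = tuple(sorted(CODON_AA))


def codon_usage_table(cds_set: Iterable[str]) -> pd.DataFrame:
    """Codon usage over a set of CDS (64 rows).

    Columns: codon, aa, occurrence, fraction (among synonymous codons
    of the same amino acid; stops form a 21st class), frequency (among
    all codons).  CDS lengths not divisible by 3 are trimmed; codons
    containing non-ACGT characters are skipped and tallied in the
    frame's ``attrs['skipped']``.
    """
    occurrence: Counter[str] = Counter()
    skipped = 0
    for cds in cds_set:
        seq = cds.upper()
        usable = len(seq) - len(seq) % 3
        for i in range(0, usable, 3):
            codon = seq[i:i + 3]
            if codon in CODON_AA:
                occurrence[codon] += 1
            else:
                skipped += 1
    total = sum(occurrence.values())
    aa_totals: Counter[str] = Counter()
    for codon, n in occurrence.items():
        aa_totals[CODON_AA[codon]] += n
    rows = []
    for codon in ALL_CODONS:
        aa = CODON_AA[codon]
        occ = occurrence.get(codon, 0)
        fraction = occ / aa_totals[aa] if aa_totals[aa] else 0.0
        frequency = occ / total if total else 0.0
        rows.append((codon, aa, occ, fraction, frequency))
    df = pd.DataFrame(rows, columns=["codon", "aa", "occurrence",
                                     "fraction", "frequency"])
    df.attrs["skipped"] = skipped
    return df


@dataclass
class CodonComparison:
    per_codon: pd.DataFrame  # codon, aa, fraction_diff, frequency_diff
    per_aa_mean: dict[str, float]
    global_mean: float
    flagged_aa_fraction: list[str]  # classes with a codon fraction diff > 0.05
    flagged_aa_frequency: list[str]


def compare_codon_usage(table_a: pd.DataFrame,
                        table_b: pd.DataFrame,
                        flag_threshold: float = 0.05) -> CodonComparison:
    """Absolute codon-usage differences between two tables.

    The headline number is the mean, over amino-acid classes, of the
    mean absolute difference of synonymous-codon fractions in that
    class.  Classes where any codon differs by more than
    ``flag_threshold`` are flagged, on both the fraction and the
    overall-frequency scale (the two readings of "differ in
    frequency").
    """
    a = table_a.set_index("codon")
    b = table_b.set_index("codon")
    rows = []
    for codon in ALL_CODONS:
        rows.append((codon, CODON_AA[codon],
                     abs(a.loc[codon, "fraction"] - b.loc[codon, "fraction"]),
                     abs(a.loc[codon, "frequency"] - b.loc[codon, "frequency"])))
    per_codon = pd.DataFrame(rows, columns=["codon", "aa", "fraction_diff",
                                            "frequency_diff"])
    per_aa = per_codon.groupby("aa")["fraction_diff"].mean().to_dict()
    global_mean = float(np.mean(list(per_aa.values())))
    flag_frac = sorted(per_codon.loc[per_codon["fraction_diff"] > flag_threshold,
                                     "aa"].unique())
    flag_freq = sorted(per_codon.loc[per_codon["frequency_diff"] > flag_threshold,
                                     "aa"].unique())
    return CodonComparison(per_codon, per_aa, global_mean,
                           list(flag_frac), list(flag_freq))
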