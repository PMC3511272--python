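# Methods

## Scope and model

`lgtscan` implements the decision logic of a genome-wide survey for
lateral gene transfer (LGT) of non-metazoan origin into root-knot
nematodes. It deliberately consumes the outputs of the heavy upstream
tools rather than re-running them: OrthoMCL clustering arrives as a
group file, BLAST as tabular hits with subject taxids, tree inference
as Newick gene trees, Pfam scanning as a domain table, TE annotation as
GFF3. The contribution of the package is everything downstream of
those artifacts — the filters, the topology pattern, the duplication
and genomic-context statistics — plus a generator that emulates all the
upstream artifacts with known truth so the logic is testable without
any external database.

## Taxonomy

The taxonomy is an NCBI-like tree over integer taxids loaded from a
tab-separated table. Three predicates drive the pipeline:

- `is_descendant(x, a)` — reflexive ancestor test (a taxon descends
  from itself, matching NCBI lineage conventions, so "descendant of T"
  clade constraints include T).
- `is_ppn(x)` — membership in the plant-parasitic nematode lineages
  Tylenchida (6300), Triplonchida (211184) or Dorylaimina (211225);
  configurable. These taxa are metazoans but are exempted from
  metazoan-hit counting, since a transfer predating the radiation of
  plant-parasitic lineages would otherwise mask itself.
- `classify_division(x)` — nearest division anchor on the lineage
  (Bacteria 2, Archaea 2157, Fungi 4751, Viridiplantae 33090,
  Metazoa 33208/Eumetazoa 6072). Eukaryotes reaching no more specific
  anchor become **Protist**, an explicitly non-monophyletic catch-all;
  taxa with no anchor at all (viruses, unclassified) become **Other**,
  never Protist.

"Metazoan" in the filters means *descendant of Eumetazoa (6072)*.
This follows the tree-pattern definition of the donor clade; note it
leaves Placozoa outside, so a placozoan is formally an admissible donor
leaf (see Limitations).

## Homology filters

- **Redundancy removal** collapses clusters of byte-identical
  sequences to one survivor (longest, then lexicographically smallest
  ID). Substring containment is deliberately not collapsed: only the
  100%-identical-cluster behavior is specified for the original
  survey, and containment removal could delete genuinely distinct
  gene models.
- **Group restriction** keeps groups whose members all belong to the
  focal (or allowed plant-parasitic) species. Representative choice:
  longest *M. incognita* member, else longest *M. hapla* member, ties
  by ID.
- **The vote** (`vote_non_metazoan`) filters hits by e-value ≤ 0.01
  (inclusive — cut-offs are conventionally inclusive in BLAST) and
  query coverage ≥ 30%, skips self/plant-parasitic-nematode subjects
  *before* taking the top-10 window (so the vote runs over ten
  informative hits when available; the alternative take-window-first
  mode is available via `VoteConfig.skip_before_window=False`), and
  calls a candidate at a non-metazoan fraction ≥ 0.5 (inclusive).
  Queries with fewer than ten surviving hits are voted over the
  survivors; queries with none are reported `no_hit` and leave the
  analysis. The vote is monotone: adding a non-metazoan hit can never
  un-make a candidate (property-tested).
- **Contamination screen**: any non-metazoan hit with identity
  strictly > 80% on strictly > 50% of the query length marks the query
  as a probable contaminating contig — a genuine transfer has had time
  to diverge. Contaminants, candidates and no-hit queries form
  disjoint classes by construction.
- **In-paralog counting**: a restricted group shows lineage-specific
  duplication when it carries ≥ 3 *M. incognita* or ≥ 2 *M. hapla*
  members. Groups with exactly two *M. incognita* and one *M. hapla*
  copies are discarded as indistinguishable from the two-copy genome
  structure of *M. incognita*; 2:0 groups simply fail the ≥ 3
  criterion and count as not-duplicated (the original survey does not
  state their treatment).

## Tree scan

Trees are consumed rooted as read (an optional midpoint rooting
pre-step is out of scope of the pattern itself; tree inference and
bootstraps are upstream). For every internal node the children are
classified: a child clade is *receiver-valid* when all its leaves are
plant-parasitic nematodes and at least one is focal, *donor-valid*
when it contains no eumetazoan leaf. A node matches when it has at
least one receiver-valid and one donor-valid child and no mixed child
(the multifurcation rule; with two children this reduces to the plain
bipartition test). The complement of the node must contain no
plant-parasitic nematode leaf. Support is upgraded from A to A+B when
the node has a parent and the external clade contains at least one
non-eumetazoan leaf — the literal reading of the published criterion;
the species-overlap duplication rule is used only inside receiver
subtrees. All matching nodes are reported; per-tree statistics use the
best call (strongest support, then largest receiver clade, then lowest
node id — a deterministic tie-break).

Duplication timing inside a receiver clade uses the species-overlap
rule (a node whose child clades share a species is a duplication
node):

- *duplicated*: ≥ 2 *M. hapla* or ≥ 3 *M. incognita* leaves (the
  asymmetric thresholds correct for the duplicated *M. incognita*
  genome);
- *before the split*: some node has ≥ 2 child clades each containing
  both species;
- *after the split*: some node heads a single-species clade clearing
  the same per-species thresholds.

Donor summaries count trees (not calls) with at least one donor leaf
of a division, and trees whose donor clade is pure in that division.

## Genomic context

Coordinates are GFF3 1-based inclusive throughout.

- **Clusters**: single-linkage chains of LGT genes per scaffold, gap
  = next.start − prev.end − 1 clamped at 0, chain extends while gap
  < 50,000 (strict, matching "distant of less than 50 kb"), reported
  at size ≥ 3. Output is invariant under input order.
- **TE windows**: a TE counts for a gene/window when it overlaps
  either flank `[start−w, start−1]`, `[end+1, end+w]` by ≥ 1 bp
  (clipped at scaffold bounds); a TE spanning both flanks counts once.
  Counts are monotone in window size.
- **Chi-square**: the published table reports X² with 1 df but not its
  construction; only a 2×2 yields df = 1, so the test is gene class ×
  {≥ 1 TE in window, 0 TE}, Pearson without continuity correction,
  alongside means ± standard error of the raw counts. Results on a
  real genome therefore depend on this reconstruction choice, which is
  why the original table's statistics are not treated as reproducible
  targets; the synthetic checks assert direction and power instead.
- **Scaffold ends**: relative position = distance of the gene midpoint
  to the nearer scaffold end divided by scaffold length (0 = tip,
  0.5 = center), compared between classes by chi-square on binned
  positions.
- **GC**: 100·(G+C)/(A+C+G+T), N excluded from the denominator; empty
  or all-N input is an error.
- **Codon usage**: 64-row table of occurrence, fraction (among
  synonymous codons of one amino acid, stops as a 21st class; sums to
  1 per class by construction) and frequency (among all codons). CDS
  lengths not divisible by 3 are trimmed with the remainder dropped;
  codons containing non-ACGT characters are skipped and tallied.
  Table comparison reports per-codon absolute differences on both the
  fraction and the frequency scale (the published "differ by more than
  5%" is ambiguous between the two, so both are flagged), per-class
  means, and a global mean over amino-acid classes.

## Functional profiling

GO terms are assigned per protein as the union over its Pfam domains
(pfam2go), then projected to a slim vocabulary through the is_a DAG
(part_of edges, when present, are treated as is_a by default). The
default projection keeps only the *most specific* slim ancestors of a
term (a slim term with no other slim term between it and the input); a
term already in the slim maps to itself, making the projection
idempotent on slim sets. An "all slim ancestors" mode is provided,
since the exact bucket semantics of the historical map2slim script are
not verifiable case by case. Distribution comparisons are descriptive:
per namespace, the percentage of *annotated* proteins (≥ 1 term in
that namespace — never the whole proteome) carrying each term, the
absolute difference, and the top-k most deviant terms. No significance
test is attached, matching the descriptive nature of the original
comparison.

## Mobile elements

Two screen stages against a plasmid/prophage/virus protein set: loose
(e-value < 0.001) and strict (additionally identity ≥ 30%, ≥ 50% query
and ≥ 50% subject coverage). The strict pass is a subset of the loose
pass by construction. Each passing query is typed by its lowest-e-value
hit (ties by subject ID) — the original survey reports one element type
per protein without stating its rule, so the best-hit rule is the
package's choice, with all hits retained in the detail output.

## Enumeration

Copy-number distributions store unclustered singletons separately from
the grouped rows so the consistency rule n_genes = copies × n_groups
always validates; the renderer merges singletons into the 1-copy row
for display, as published tables do. Percentages round half-up: two
decimals for proteome proportions, integers for cohort percentages.
The cohort statistics run over trees containing both nematode species:
fraction duplicated, fraction of duplicated that started before the
species split, and fraction of before-split cases that continued after
it.

## Synthetic data

The generator emits a complete miniature study from one seed
(`numpy.random.default_rng`), byte-identical across runs. Defaults are
the study conditions: 50 planted transfers, 200 vertical-descent genes,
10 contaminants, 5 decoy 2:1 groups, 5 planted exact duplicates;
duplication probabilities 0.83 (duplicated), 0.79 (before-split given
duplicated), 0.72 (continued after, given before); donor division mix
0.51/0.26/0.13/0.08/0.02 for bacteria/protists/fungi/plants/archaea
(the published per-division tree counts 72/51/21/19/4 of 141,
renormalized); 65% of transfers present in both species; TE counts
Poisson(1.0) per ordinary gene and doubled around LGT genes, placed
uniformly within 2 kb of gene boundaries; CDS GC 0.36.

Signal classes are kept deliberately unambiguous: clean transfers
receive BLAST identities ≤ 40% (never tripping the > 80% contamination
rule), contaminants ≥ 95% identity at near-full length, vertical genes
either cluster with another metazoan (removed at stage 1) or carry
metazoan-dominated hit profiles (rejected by the vote) and
vertical-descent tree topologies. Planted clusters sit on dedicated
scaffolds with gaps well under 50 kb; all other genes are spaced 60 kb
apart so no accidental cluster can form.

What the generator does **not** emulate: sequence evolution (trees are
emitted directly as topologies; BLAST tables are synthesized from the
truth, not computed by alignment), alignment noise, fragmented gene
models, incomplete taxon sampling, or contamination that is partially
diverged. Passing the end-to-end recovery checks therefore
demonstrates that the decision logic is faithful to its rules under
clean signal, not that the rules themselves are robust on noisy real
genomes — the original survey's tree-construction failures (119 of 609
candidates) have no synthetic counterpart.

Two scaled-down helpers support the statistical checks cheaply:
`generate_duplication_trees` (both-species cohort trees with planted
timings) and `generate_te_layout` (coordinate-only genome, no sequence
emission), which is what makes a 100-replicate power study affordable.
Problem sizes used by the shipped analyses: 500 trees × 10 seeds for
timing recovery, 200 genes per class × 100 replicates for TE power.

## Pipeline and interfaces

Stages exchange plain TSV/JSON artifacts with documented headers (no
database), are pure functions of their inputs, and log in/out counts.
Re-running a configuration reproduces every artifact byte for byte, so
a deleted stage output is restored by re-running — reproducibility is
the package's resume mechanism, chosen over mtime-based stage skipping
to avoid silently stale artifacts. The same stages are exposed as
library functions, as `analysis/` driver scripts, and as click
subcommands; configuration is one YAML file that round-trips through
`PipelineConfig`.

## Numerical and degenerate-input choices

- All ties (equal e-values, equal lengths, equal support) break
  lexicographically by ID for reproducibility.
- Hit ranking: file order per query when ranks are given, else
  ascending e-value, then descending bitscore, then subject ID.
- Trees with fewer than 3 leaves are not scanned (no-scan, not an
  error); unresolvable leaf taxids are errors naming the leaf.
- Chi-square with an entirely absent outcome column returns
  statistic 0, p = 1 with a low-expected-count flag rather than
  failing.
- Percentage rounding is decimal half-up (not banker's), via
  `decimal.Decimal`.

## Known limitations

- The placozoan gap: "metazoan" means Eumetazoa descent, so
  non-eumetazoan metazoans are admissible donors under the literal
  pattern; the generator avoids them in vertical topologies and the
  taxonomy module exposes Metazoa (33208) as an alternative anchor.
- The 2×2 chi-square construction and the map2slim bucket semantics
  are reconstructions of under-specified published procedures; both
  have documented alternatives behind flags.
- Whole-genome in-paralog proportions printed in the original survey
  round one value inconsistently (2,137/7,647 prints as 27.94 where
  exact arithmetic gives 27.9456 → 27.95); the package reports the
  arithmetically exact value.
- Donor summaries type one best call per tree; trees with several
  distinct valid transfer nodes contribute only their best call.
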