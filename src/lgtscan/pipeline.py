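"""End-to-end orchestration of the LGT detection pipeline.

Three main detection stages — ortholog-group restriction, the
non-metazoan BLAST vote with contamination screening, and the
gene-tree topology scan — followed by the characterization stages:
duplication analysis, genomic context, functional profiling,
mobile-element screening and the headline enumeration.  Every stage
persists a plain TSV/JSON artifact and logs its in/out counts.  Stages
are deterministic functions of their inputs, so re-running a pipeline
over the same inputs reproduces every artifact byte for byte; a deleted
stage output is restored simply by re-running.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as lio
from .annotation import (GoDag, compare_go_distributions,
                         load_domain_assignments, load_pfam2go, pfam_to_go,
                         slim_annotate)
from .context import (codon_usage_table, compare_codon_usage,
                      compare_end_positions, detect_lgt_clusters, gc_content,
                      scaffold_end_positions, te_density_report,
                      te_window_counts)
from .enumeration import (CopyDistribution, duplication_cohort_stats,
                          percent_of_proteome, total_lgt_genes,
                          total_phylo_supported)
from .homology import (CandidateSet, VoteConfig, choose_representative,
                       count_inparalog_groups, dedup_exact, find_singletons,
                       flag_contaminants, select_restricted_groups,
                       vote_non_metazoan)
from .mobile import MobileScreenConfig, classify_element_types, screen_mobile_hits
from .taxonomy import EUMETAZOA_TAXID, PPN_TAXIDS, load_taxonomy
from .treescan import (calls_by_tree, classify_duplication_timing,
                       scan_newick_file, summarize_donor_taxa)

log = logging.getLogger("lgtscan")


@dataclass
class PipelineConfig:
    """Input paths and thresholds; defaults are the published values."""

    input_dir: str = "."
    output_dir: str = "lgtscan_out"
    taxonomy: str = "taxonomy.tsv"
    proteome: str = "proteome.faa"
    groups: str = "groups.txt"
    blast: str = "blast.tsv"
    trees: str = "trees.nwk"
    gff: str = "genome.gff3"
    cds: str = "cds.fna"
    domains: str = "domains.tsv"
    pfam2go: str = "pfam2go.txt"
    go_dag: str = "go_dag.tsv"
    go_slim: str = "go_slim.txt"
    mobile_hits: str = "mobile_hits.tsv"
    species_taxids: str = "species_taxids.tsv"

    evalue_max: float = 0.01
    qcov_min: float = 0.30
    top_n: int = 10
    vote_min: float = 0.50
    contamination_identity: float = 80.0
    contamination_qcov: float = 0.5
    cluster_gap: int = 50_000
    cluster_min_size: int = 3
    te_windows: tuple[int, ...] = (200, 500, 1000, 2000)
    mobile_evalue: float = 0.001
    mobile_identity: float = 30.0
    mobile_qcov: float = 0.5
    mobile_scov: float = 0.5
    ppn_taxids: tuple[int, ...] = tuple(sorted(PPN_TAXIDS))
    eumetazoa_taxid: int = EUMETAZOA_TAXID
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.vote_min <= 1 and 0 <= self.qcov_min <= 1):
            raise ValueError("fractional thresholds must lie in [0, 1]")
        if self.evalue_max < 0 or self.cluster_gap <= 0 or self.top_n < 1:
            raise ValueError("thresholds out of range")

    def path(self, name: str) -> Path:
        return Path(self.input_dir) / getattr(self, name)

    def out(self, filename: str) -> Path:
        return Path(self.output_dir) / filename

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["te_windows"] = list(self.te_windows)
        d["ppn_taxids"] = list(self.ppn_taxids)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["te_windows"] = tuple(d.get("te_windows", (200, 500, 1000, 2000)))
        d["ppn_taxids"] = tuple(d.get("ppn_taxids", tuple(sorted(PPN_TAXIDS))))
        return cls(**d)


def _read_species_taxids(path: Path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("species\t"):
                continue
            sp, taxid = line.split("\t")
            out[sp] = int(taxid)
    return out


class Pipeline:
    """Stage runner over a config; stages write under ``output_dir``."""

    def __init__(self, config: PipelineConfig, force: bool = False):
        config.validate()
        for name in ("taxonomy", "proteome", "groups"):
            if not config.path(name).exists():
                raise FileNotFoundError(
                    f"missing required input '{name}': {config.path(name)}")
        self.cfg = config
        self.force = force
        Path(config.output_dir).mkdir(parents=True, exist_ok=True)
        self.tax = load_taxonomy(config.path("taxonomy"),
                                 ppn_taxids=config.ppn_taxids)
        self.species_taxids = _read_species_taxids(
            config.path("species_taxids"))
        self.counts: dict[str, int] = {}

    # --- stage 1: ortholog restriction --------------------------------
    def filter_ortho(self):
        cfg = self.cfg
        proteins = lio.read_proteome(cfg.path("proteome"))
        kept, redundant = dedup_exact(proteins)
        index = {p.protein_id: p for p in kept}
        groups = lio.read_groups(cfg.path("groups"), protein_index=index)
        restricted, discarded = select_restricted_groups(groups)
        singletons = find_singletons(kept, groups)
        reps = [choose_representative(g) for g in restricted]
        queries = {p.protein_id: p for p in reps + singletons}
        self.counts.update(
            n_proteins=len(proteins), n_nonredundant=len(kept),
            n_groups=len(groups), n_restricted_groups=len(restricted),
            n_discarded_groups=len(discarded), n_singletons=len(singletons),
            n_queries=len(queries))
        log.info("stage 1: %d proteins -> %d non-redundant; %d/%d groups "
                 "restricted; %d queries", len(proteins), len(kept),
                 len(restricted), len(groups), len(queries))
        with open(cfg.out("queries.tsv"), "w") as fh:
            fh.write("protein_id\tspecies\tlength\torigin\n")
            rep_ids = {p.protein_id for p in reps}
            for pid in sorted(queries):
                p = queries[pid]
                origin = "group-representative" if pid in rep_ids else "singleton"
                fh.write(f"{pid}\t{p.species}\t{p.length}\t{origin}\n")
        self._proteins, self._queries = kept, queries
        self._groups, self._restricted = groups, restricted
        return queries

    # --- stage 2: BLAST vote + contamination ---------------------------
    def filter_blast(self):
        cfg = self.cfg
        hits_by_query = lio.read_blast_table(cfg.path("blast"))
        vote_cfg = VoteConfig(evalue_max=cfg.evalue_max, qcov_min=cfg.qcov_min,
                              top_n=cfg.top_n, vote_min=cfg.vote_min,
                              metazoa_taxid=cfg.eumetazoa_taxid)
        focal_taxids = frozenset(
            self.species_taxids[sp] for sp in ("Minc", "Mhap")
            if sp in self.species_taxids)
        decisions, candidates, contaminants, no_hit = [], set(), set(), set()
        for pid in sorted(self._queries):
            query = self._queries[pid]
            hits = hits_by_query.get(pid, [])
            d = vote_non_metazoan(query, hits, self.tax, vote_cfg,
                                  self_taxids=focal_taxids)
            decisions.append(d)
            if d.status == "no_hit":
                no_hit.add(pid)
            elif d.is_candidate:
                if flag_contaminants(query, hits, self.tax,
                                     cfg.contamination_identity,
                                     cfg.contamination_qcov,
                                     cfg.eumetazoa_taxid):
                    contaminants.add(pid)
                else:
                    candidates.add(pid)
        lio.write_decision_log(decisions, cfg.out("blast_decisions.tsv"))
        for name, ids in (("candidates.txt", candidates),
                          ("contaminants.txt", contaminants),
                          ("no_hit.txt", no_hit)):
            with open(cfg.out(name), "w") as fh:
                fh.write("\n".join(sorted(ids)) + ("\n" if ids else ""))
        self.candidate_set = CandidateSet(candidates, contaminants, no_hit)
        self.counts.update(n_candidates=len(candidates),
                           n_contaminants=len(contaminants),
                           n_no_hit=len(no_hit))
        log.info("stage 2: %d candidates, %d contaminants, %d without "
                 "informative hits", len(candidates), len(contaminants),
                 len(no_hit))
        return self.candidate_set

    # --- stage 3: tree scan --------------------------------------------
    def scan_trees(self):
        cfg = self.cfg
        calls, trees = scan_newick_file(cfg.path("trees"), self.species_taxids,
                                        self.tax)
        cand = self.candidate_set.candidate_ids
        calls = [c for c in calls
                 if {trees[c.tree_id].leaves[l].protein_id
                     for l in c.receiver_leaves} & cand]
        per_tree = calls_by_tree(calls)
        reports = {tid: classify_duplication_timing(call,
                                                    trees[tid].leaves)
                   for tid, call in per_tree.items()}
        leaf_maps = {tid: trees[tid].leaves for tid in per_tree}
        donors = summarize_donor_taxa(list(per_tree.values()), leaf_maps,
                                      self.tax)
        with open(cfg.out("lgt_calls.tsv"), "w") as fh:
            fh.write("tree_id\tsupport\tn_minc\tn_mhap\tduplicated\t"
                     "before_split\tafter_split\tboth_species\t"
                     "donor_divisions\n")
            for tid in sorted(per_tree):
                call, rep = per_tree[tid], reports[tid]
                divisions = sorted({self.tax.classify_division(
                    trees[tid].leaves[l].taxid) for l in call.donor_leaves})
                fh.write(f"{tid}\t{call.support}\t{call.n_minc}\t"
                         f"{call.n_mhap}\t{rep.duplicated}\t"
                         f"{rep.before_split}\t{rep.after_split}\t"
                         f"{rep.both_species_present}\t"
                         f"{','.join(divisions)}\n")
        with open(cfg.out("donor_summary.json"), "w") as fh:
            json.dump(donors, fh, indent=1, sort_keys=True)
        self.calls, self.trees, self.reports = per_tree, trees, reports
        self.counts.update(n_trees_scanned=len(trees),
                           n_trees_with_call=len(per_tree))
        log.info("stage 3: %d/%d trees support a transfer", len(per_tree),
                 len(trees))
        return per_tree

    # --- characterization ----------------------------------------------
    def lgt_gene_ids(self) -> set[str]:
        """All focal gene copies implicated in LGT: candidates plus the
        in-paralogs sharing their restricted groups."""
        lgt = set(self.candidate_set.candidate_ids)
        for g in self._restricted:
            if {m.protein_id for m in g.members} & lgt:
                lgt |= {m.protein_id for m in g.members}
        return lgt

    def context_stage(self):
        cfg = self.cfg
        genes, tes, scaffold_lengths = lio.read_gff3(cfg.path("gff"))
        lgt_ids = self.lgt_gene_ids()
        genes = lio.mark_lgt_genes(genes, lgt_ids)
        clusters = detect_lgt_clusters(genes, cfg.cluster_gap,
                                       cfg.cluster_min_size)
        counts = te_window_counts(genes, tes, cfg.te_windows, scaffold_lengths)
        te_stats = te_density_report(counts, cfg.te_windows)
        positions = scaffold_end_positions(genes, scaffold_lengths)
        lgt_pos = [positions[g.gene_id] for g in genes if g.is_lgt]
        other_pos = [positions[g.gene_id] for g in genes if not g.is_lgt]
        end_chi2, end_df, end_p = compare_end_positions(lgt_pos, other_pos)

        cds = lio.read_cds_fasta(cfg.path("cds"))
        lgt_cds = [s for gid, s in cds.items() if gid in lgt_ids]
        other_cds = [s for gid, s in cds.items() if gid not in lgt_ids]
        gc_lgt = (sum(gc_content(s) for s in lgt_cds) / len(lgt_cds)
                  if lgt_cds else float("nan"))
        gc_other = (sum(gc_content(s) for s in other_cds) / len(other_cds)
                    if other_cds else float("nan"))
        cmp_codon = compare_codon_usage(codon_usage_table(lgt_cds),
                                        codon_usage_table(other_cds))

        with open(cfg.out("clusters.tsv"), "w") as fh:
            fh.write("scaffold\tsize\tgene_ids\n")
            for c in clusters:
                fh.write(f"{c.scaffold_id}\t{c.size}\t{','.join(c.gene_ids)}\n")
        with open(cfg.out("te_density.tsv"), "w") as fh:
            fh.write("window\tclass\tmean\tse\tchi2\tdf\tp\n")
            for r in te_stats:
                fh.write(f"{r.window}\tLGT\t{r.mean_lgt:.3f}\t{r.se_lgt:.3f}\t"
                         f"{r.statistic:.3f}\t{r.df}\t{r.p_value:.4g}\n")
                fh.write(f"{r.window}\tOther\t{r.mean_other:.3f}\t"
                         f"{r.se_other:.3f}\t\t\t\n")
        summary = {
            "n_lgt_gene_copies": len([g for g in genes if g.is_lgt]),
            "n_clusters": len(clusters),
            "n_clustered_genes": sum(c.size for c in clusters),
            "scaffold_end_chi2": end_chi2, "scaffold_end_df": end_df,
            "scaffold_end_p": end_p,
            "gc_lgt": gc_lgt, "gc_other": gc_other,
            "codon_mean_abs_fraction_diff": cmp_codon.global_mean,
            "codon_flagged_aa": cmp_codon.flagged_aa_fraction,
        }
        with open(cfg.out("context_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        self.context_summary = summary
        self.clusters, self.te_stats = clusters, te_stats
        self._genes = genes
        return summary

    def annotate_stage(self):
        cfg = self.cfg
        assignments = load_domain_assignments(cfg.path("domains"))
        pfam2go = load_pfam2go(cfg.path("pfam2go"))
        dag = GoDag.from_table(cfg.path("go_dag"))
        slim = {l.strip() for l in open(cfg.path("go_slim")) if l.strip()}
        protein_terms, _ = pfam_to_go(assignments, pfam2go)
        slim_terms = slim_annotate(protein_terms, dag, slim)
        lgt_ids = self.lgt_gene_ids()
        lgt_set = {p: t for p, t in slim_terms.items() if p in lgt_ids}
        all_set = slim_terms
        table = compare_go_distributions(lgt_set, all_set, dag)
        table.to_csv(cfg.out("go_comparison.tsv"), sep="\t", index=False)
        self.go_table = table
        return table

    def mobile_stage(self):
        cfg = self.cfg
        hits = lio.read_mobile_hits(cfg.path("mobile_hits"))
        mcfg = MobileScreenConfig(cfg.mobile_evalue, cfg.mobile_identity,
                                  cfg.mobile_qcov, cfg.mobile_scov)
        loose, loose_best = screen_mobile_hits(hits, "loose", mcfg)
        strict, strict_best = screen_mobile_hits(hits, "strict", mcfg)
        counts, pct = classify_element_types(loose_best)
        result = {"n_loose_queries": len(loose_best),
                  "n_strict_queries": len(strict_best),
                  "element_counts": counts, "element_pct": pct}
        with open(cfg.out("mobile_summary.json"), "w") as fh:
            json.dump(result, fh, indent=1, sort_keys=True)
        self.mobile_summary = result
        return result

    def summarize(self):
        cfg = self.cfg
        cand = self.candidate_set.candidate_ids
        minc_singleton_cands = [
            pid for pid in cand
            if self._queries[pid].species == "Minc"
            and not any(pid in {m.protein_id for m in g.members}
                        for g in self._restricted)]
        sizes = []
        for g in self._restricted:
            if {m.protein_id for m in g.members} & cand:
                n_minc = sum(1 for m in g.members if m.species == "Minc")
                if n_minc:
                    sizes.append(n_minc)
        dist = CopyDistribution.from_group_sizes(
            sizes, singletons=len(minc_singleton_cands))
        phylo_dist = CopyDistribution.from_group_sizes(
            [c.n_minc for c in self.calls.values() if c.n_minc > 0])
        n_minc_proteome = sum(1 for p in self._proteins
                              if p.species == "Minc")
        reports = list(self.reports.values())
        cohort = duplication_cohort_stats(reports)
        inpar = count_inparalog_groups(self._restricted, cand)
        summary = {
            "counts": self.counts,
            "total_lgt_genes": total_lgt_genes(dist),
            "total_phylo_supported": total_phylo_supported(phylo_dist),
            "pct_of_minc_proteome": percent_of_proteome(
                total_lgt_genes(dist), n_minc_proteome) if n_minc_proteome
                else None,
            "duplication_cohort": dataclasses.asdict(cohort),
            "inparalog_pct_lgt": inpar.pct_lgt_duplicated,
            "inparalog_pct_genome": inpar.pct_groups_duplicated,
        }
        with open(cfg.out("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        self.summary = summary
        return summary

    def evaluate_truth(self, truth_path: str | Path | None = None):
        """Sensitivity/specificity appendix against a planted truth file."""
        path = Path(truth_path or Path(self.cfg.input_dir) / "truth.json")
        if not path.exists():
            return None
        truth = json.loads(path.read_text())
        cand = self.candidate_set.candidate_ids
        called_proteins = set()
        for tid, call in self.calls.items():
            called_proteins |= {self.trees[tid].leaves[l].protein_id
                                for l in call.receiver_leaves}
        tp = fn = fp = 0
        contaminant_hit = contaminant_total = 0
        fp_ids = []
        for gid, t in truth.items():
            rep = t.get("representative", "")
            if t["is_lgt"]:
                if rep in cand and rep in called_proteins:
                    tp += 1
                else:
                    fn += 1
            elif t["is_contaminant"]:
                contaminant_total += 1
                if rep in self.candidate_set.contaminants:
                    contaminant_hit += 1
            else:
                if rep and (rep in cand or rep in called_proteins):
                    fp += 1
                    fp_ids.append(gid)
        n_lgt = tp + fn
        result = {
            "n_planted_lgt": n_lgt, "n_recovered": tp,
            "sensitivity_pct": 100.0 * tp / n_lgt if n_lgt else None,
            "n_false_positives": fp, "false_positive_ids": fp_ids,
            "n_planted_contaminants": contaminant_total,
            "n_flagged_contaminants": contaminant_hit,
            "contaminant_recall_pct": (100.0 * contaminant_hit
                                       / contaminant_total
                                       if contaminant_total else None),
        }
        with open(self.cfg.out("truth_eval.json"), "w") as fh:
            json.dump(result, fh, indent=1, sort_keys=True)
        self.truth_eval = result
        return result

    def run_all(self):
        self.filter_ortho()
        self.filter_blast()
        self.scan_trees()
        if self.cfg.path("gff").exists():
            self.context_stage()
        if self.cfg.path("domains").exists():
            self.annotate_stage()
        if self.cfg.path("mobile_hits").exists():
            self.mobile_stage()
        self.summarize()
        self.evaluate_truth()
        return self.summary


def run_pipeline(config: PipelineConfig, force: bool = True) -> dict:
    """Run every stage; returns the summary dictionary."""
    return Pipeline(config, force=force).run_all()
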