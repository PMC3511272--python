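"""Scaffold clusters, TE windows, chi-square, GC and codon usage."""

import numpy as np
import pytest

from lgtscan.context import (GeneFeature, TeFeature, codon_usage_table,
                             compare_codon_usage, compare_te_density,
                             count_te_in_windows, detect_lgt_clusters,
                             gc_content, scaffold_end_positions,
                             te_window_counts)


def gene(gid, start, end, scaffold="s1", lgt=True):
    return GeneFeature(gid, scaffold, start, end, "+", lgt)


def te(tid, start, end, scaffold="s1"):
    return TeFeature(tid, scaffold, start, end)


class TestClusters:
    def test_three_genes_within_gap_form_one_cluster(self):
        genes = [gene("a", 1, 1000), gene("b", 20000, 21000),
                 gene("c", 60000, 61000)]
        clusters = detect_lgt_clusters(genes)
        assert len(clusters) == 1
        assert clusters[0].gene_ids == ("a", "b", "c")

    def test_two_genes_never_cluster(self):
        genes = [gene("a", 1, 1000), gene("b", 11000, 12000)]
        assert detect_lgt_clusters(genes) == []

    def test_gap_threshold_is_strict(self):
        # gap of exactly 50,000 bases breaks the chain
        genes = [gene("a", 1, 1000), gene("b", 51001, 52000),
                 gene("c", 52100, 53000)]
        assert detect_lgt_clusters(genes) == []
        genes2 = [gene("a", 1, 1000), gene("b", 51000, 52000),
                  gene("c", 52100, 53000)]
        assert len(detect_lgt_clusters(genes2)) == 1

    def test_shuffle_invariance_and_oracle(self):
        rng = np.random.default_rng(2)
        genes = []
        for i in range(200):
            scaffold = f"s{int(rng.integers(1, 5))}"
            start = int(rng.integers(1, 500_000))
            genes.append(gene(f"g{i:03d}", start,
                              start + int(rng.integers(500, 3000)),
                              scaffold, bool(rng.random() < 0.6)))
        base = detect_lgt_clusters(genes)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert detect_lgt_clusters(shuffled) == base
        # oracle: quadratic chaining per scaffold
        expected = []
        for scaffold in sorted({g.scaffold_id for g in genes}):
            sub = sorted([g for g in genes
                          if g.scaffold_id == scaffold and g.is_lgt],
                         key=lambda g: (g.start, g.end, g.gene_id))
            chain = []
            for g in sub:
                if chain and max(0, g.start - chain[-1].end - 1) < 50_000:
                    chain.append(g)
                else:
                    if len(chain) >= 3:
                        expected.append(tuple(x.gene_id for x in chain))
                    chain = [g]
            if len(chain) >= 3:
                expected.append(tuple(x.gene_id for x in chain))
        assert [c.gene_ids for c in base] == expected
        assert sum(c.size for c in base) <= sum(g.is_lgt for g in genes)


class TestTeWindows:
    def test_no_te_nearby_counts_zero(self):
        g = gene("g", 10_000, 12_000)
        for w in (200, 500, 1000, 2000):
            assert count_te_in_windows(g, [te("t", 50_000, 50_100)], w) == 0

    def test_te_in_downstream_flank(self):
        g = gene("g", 10_000, 12_000)
        assert count_te_in_windows(g, [te("t", 12_010, 12_050)], 200) == 1

    def test_te_spanning_both_flanks_counts_once(self):
        g = gene("g", 1000, 1100)
        assert count_te_in_windows(g, [te("t", 500, 2000)], 500) == 1

    def test_monotone_in_window_size(self):
        rng = np.random.default_rng(4)
        g = gene("g", 50_000, 53_000)
        tes = [te(f"t{i}", int(p), int(p) + 200)
               for i, p in enumerate(rng.integers(40_000, 60_000, size=30))]
        counts = [count_te_in_windows(g, tes, w)
                  for w in (200, 500, 1000, 2000)]
        assert counts == sorted(counts)

    def test_matches_naive_overlap_oracle(self):
        rng = np.random.default_rng(8)
        genes = [gene(f"g{i}", int(s), int(s) + 1000)
                 for i, s in enumerate(rng.integers(5_000, 200_000, size=30))]
        tes = [te(f"t{i}", int(s), int(s) + int(rng.integers(50, 400)))
               for i, s in enumerate(rng.integers(1, 210_000, size=80))]
        for g in genes:
            for w in (200, 500, 1000, 2000):
                flanks = [(max(1, g.start - w), g.start - 1),
                          (g.end + 1, g.end + w)]
                expected = sum(
                    1 for t in tes
                    if any(t.start <= hi and t.end >= lo for lo, hi in flanks))
                assert count_te_in_windows(g, tes, w) == expected


class TestTeDensity:
    def test_identical_distributions_give_null_result(self):
        r = compare_te_density([0, 1, 2, 0, 1], [0, 1, 2, 0, 1])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_mean_and_se_closed_form(self):
        r = compare_te_density([0, 1, 2], [0, 1, 2])
        assert r.mean_lgt == pytest.approx(1.0)
        assert r.se_lgt == pytest.approx(0.577, abs=1e-3)

    def test_planted_enrichment_is_detected_with_power(self):
        from lgtscan.synthetic import generate_te_layout
        n_sig = 0
        n_rep = 30
        for seed in range(n_rep):
            genes, tes, lengths = generate_te_layout(seed, n_per_class=200)
            counts = te_window_counts(genes, tes, [2000], lengths)
            sub = counts[counts["window"] == 2000]
            r = compare_te_density(sub.loc[sub["is_lgt"], "n_te"].tolist(),
                                   sub.loc[~sub["is_lgt"], "n_te"].tolist())
            assert r.mean_lgt > r.mean_other
            n_sig += r.p_value < 0.05
        assert n_sig >= 0.9 * n_rep


class TestEndPositions:
    def test_centered_gene_is_half(self):
        pos = scaffold_end_positions([gene("g", 49_500, 50_500)],
                                     {"s1": 100_000})
        assert pos["g"] == pytest.approx(0.5, abs=0.01)

    def test_gene_at_start_is_near_zero(self):
        pos = scaffold_end_positions([gene("g", 1, 100)], {"s1": 100_000})
        assert pos["g"] == pytest.approx(0.0, abs=0.01)


class TestGc:
    def test_simple_values(self):
        assert gc_content("ATGC") == pytest.approx(50.0)
        assert gc_content("GGCC") == pytest.approx(100.0)

    def test_n_excluded_from_denominator(self):
        assert gc_content("GGNN") == pytest.approx(100.0)

    def test_empty_or_all_n_is_an_error(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            gc_content("NNN")

    def test_matches_letter_count_oracle(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGTN"), size=10_000))
        gc = sum(seq.count(b) for b in "GC")
        denom = sum(seq.count(b) for b in "ACGT")
        assert gc_content(seq) == pytest.approx(100.0 * gc / denom)


class TestCodonUsage:
    def test_single_codon_cds(self):
        t = codon_usage_table(["ATGATG"]).set_index("codon")
        assert t.loc["ATG", "occurrence"] == 2
        assert t.loc["ATG", "fraction"] == 1.0
        assert t.loc["ATG", "frequency"] == 1.0

    def test_fractions_sum_to_one_per_amino_acid(self):
        rng = np.random.default_rng(12)
        cds = ["".join(rng.choice(list("ACGT"), size=3 * 200))
               for _ in range(20)]
        t = codon_usage_table(cds)
        sums = t.groupby("aa")["fraction"].sum()
        present = t.groupby("aa")["occurrence"].sum()
        for aa, s in sums.items():
            if present[aa] > 0:
                assert s == pytest.approx(1.0, abs=1e-9)
        assert t["frequency"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_trailing_remainder_trimmed_and_n_skipped(self):
        t = codon_usage_table(["ATGNNNATGCC"])  # 3 full codons, 2 trailing
        assert t.set_index("codon").loc["ATG", "occurrence"] == 2
        assert t.attrs["skipped"] == 1

    def test_self_comparison_is_zero(self):
        t = codon_usage_table(["ATGGCGTAA", "CCTTGGAAA"])
        cmp = compare_codon_usage(t, t)
        assert cmp.global_mean == 0.0
        assert (cmp.per_codon["fraction_diff"] == 0).all()

    def test_two_codon_toy_difference(self):
        # Lys codons AAA/AAG: 3:2 vs 1:1 -> fraction diff 0.1 each
        ta = codon_usage_table(["AAAAAAAAAAAGAAG"])
        tb = codon_usage_table(["AAAAAG"])
        cmp = compare_codon_usage(ta, tb)
        d = cmp.per_codon.set_index("codon")
        assert d.loc["AAA", "fraction_diff"] == pytest.approx(0.1)
        assert cmp.per_aa_mean["K"] == pytest.approx(0.1)
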