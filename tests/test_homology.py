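"""Redundancy removal, group restriction, the BLAST vote and in-paralogs."""

import numpy as np
import pytest

from lgtscan.homology import (BlastHit, OrthoGroup, ProteinRecord, VoteConfig,
                              choose_representative, classify_group_paralogy,
                              count_inparalog_groups, dedup_exact,
                              find_singletons, flag_contaminants,
                              select_restricted_groups, vote_non_metazoan)


def prot(pid, species="Minc", length=100, seq=None):
    if seq is None:
        seq = "A" * length
    return ProteinRecord(pid, species, len(seq), seq)


def hit(taxid, pident=35.0, length=80, evalue=1e-20, rank=None, query="q"):
    return BlastHit(query, f"s{taxid}_{rank}", taxid, pident, length, evalue,
                    rank=rank)


class TestDedup:
    def test_identical_pair_keeps_lexicographically_first(self):
        a, b = prot("B", seq="MKV"), prot("A", seq="MKV")
        kept, redirect = dedup_exact([a, b])
        assert [p.protein_id for p in kept] == ["A"]
        assert redirect == {"B": "A"}

    def test_all_distinct_is_identity(self):
        ps = [prot("A", seq="MKV"), prot("B", seq="MKW")]
        kept, redirect = dedup_exact(ps)
        assert kept == ps and redirect == {}

    def test_missing_sequence_is_an_error(self):
        with pytest.raises(ValueError, match="X1"):
            dedup_exact([ProteinRecord("X1", "Minc", 5)])

    def test_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("MKVW"), size=6)) for _ in range(40)]
        ps = [prot(f"p{i:02d}", seq=rng.choice(seqs)) for i in range(60)]
        kept, redirect = dedup_exact(ps)
        # oracle: group by explicit all-pairs string equality
        survivors = set()
        for p in ps:
            cluster = [q for q in ps if q.sequence == p.sequence]
            best = min(cluster, key=lambda q: (-q.length, q.protein_id))
            survivors.add(best.protein_id)
        assert {p.protein_id for p in kept} == survivors
        assert all(redirect[r] in survivors for r in redirect)


class TestRestriction:
    def test_focal_only_group_is_retained(self):
        g = OrthoGroup("g1", (prot("a"), prot("b"), prot("c", "Mhap")))
        kept, _ = select_restricted_groups([g])
        assert kept == [g]

    def test_group_with_other_metazoan_is_discarded(self):
        g = OrthoGroup("g2", (prot("a"), prot("x", "Cele")))
        kept, dropped = select_restricted_groups([g])
        assert kept == [] and dropped == [g]

    def test_unknown_species_tag_is_an_error(self):
        g = OrthoGroup("g3", (prot("a"), prot("y", "Zzz")))
        with pytest.raises(ValueError, match="Zzz"):
            select_restricted_groups([g], known_species={"Minc", "Mhap"})

    def test_matches_membership_scan_oracle(self, small_bundle):
        kept, _ = select_restricted_groups(small_bundle.groups)
        expected = [g for g in small_bundle.groups
                    if all(m.species in ("Minc", "Mhap") for m in g.members)]
        assert kept == expected

    def test_singletons_are_focal_and_ungrouped(self):
        ps = [prot("a"), prot("b"), prot("x", "Cele")]
        groups = [OrthoGroup("g", (ps[0],))]
        lone = find_singletons(ps, groups)
        assert [p.protein_id for p in lone] == ["b"]


class TestRepresentative:
    def test_minc_preferred_over_longer_mhap(self):
        g = OrthoGroup("g", (prot("A", "Minc", seq="M" * 300),
                             prot("B", "Minc", seq="M" * 200),
                             prot("C", "Mhap", seq="M" * 400)))
        assert choose_representative(g).protein_id == "A"

    def test_mhap_fallback(self):
        g = OrthoGroup("g", (prot("C", "Mhap", seq="M" * 400),))
        assert choose_representative(g).protein_id == "C"

    def test_equal_length_tie_lexicographic(self):
        g = OrthoGroup("g", (prot("B", "Minc"), prot("A", "Minc")))
        assert choose_representative(g).protein_id == "A"

    def test_no_focal_member_is_an_error(self):
        g = OrthoGroup("g", (prot("x", "Cele"),))
        with pytest.raises(ValueError):
            choose_representative(g)


BACT = 562   # E. coli
HUMAN = 9606
MHAP = 6305


class TestVote:
    def test_half_non_metazoan_is_inclusive(self, tax):
        q = prot("q", length=100)
        hits = [hit(BACT, rank=i + 1) for i in range(5)] + \
               [hit(HUMAN, rank=i + 6) for i in range(5)]
        d = vote_non_metazoan(q, hits, tax)
        assert d.is_candidate and d.vote_fraction == pytest.approx(0.5)

    def test_ppn_hits_do_not_occupy_slots(self, tax):
        q = prot("q", length=100)
        hits = ([hit(MHAP, rank=1), hit(MHAP, rank=2)]
                + [hit(BACT, rank=r) for r in range(3, 7)]
                + [hit(HUMAN, rank=r) for r in range(7, 13)])
        d = vote_non_metazoan(q, hits, tax)
        assert not d.is_candidate
        assert d.vote_fraction == pytest.approx(0.4)
        assert d.n_considered == 10

    def test_few_hits_vote_over_survivors(self, tax):
        q = prot("q", length=100)
        hits = [hit(746128, rank=r) for r in (1, 2, 3)]  # fungal
        d = vote_non_metazoan(q, hits, tax)
        assert d.is_candidate and d.vote_fraction == 1.0

    def test_no_surviving_hits_is_no_hit_status(self, tax):
        q = prot("q", length=100)
        d = vote_non_metazoan(q, [hit(BACT, evalue=0.5, rank=1)], tax)
        assert d.status == "no_hit"
        assert vote_non_metazoan(q, [], tax).status == "no_hit"

    def test_coverage_filter_uses_query_length(self, tax):
        q = prot("q", length=300)
        d = vote_non_metazoan(q, [hit(BACT, length=80, rank=1)], tax)
        assert d.status == "no_hit"  # 80 < 0.3 * 300

    def test_adding_non_metazoan_hit_never_unmakes_candidate(self, tax):
        rng = np.random.default_rng(11)
        q = prot("q", length=100)
        for _ in range(30):
            n = int(rng.integers(1, 12))
            taxa = rng.choice([BACT, HUMAN, 4751], size=n)
            hits = [hit(int(t), rank=i + 1) for i, t in enumerate(taxa)]
            before = vote_non_metazoan(q, hits, tax)
            extra = hit(BACT, evalue=1e-50)
            hits2 = [extra] + [BlastHit(**{**h.__dict__, "rank": h.rank + 1})
                               for h in hits]
            hits2[0] = BlastHit(**{**extra.__dict__, "rank": 1})
            after = vote_non_metazoan(q, hits2, tax)
            if before.is_candidate:
                assert after.is_candidate


class TestContamination:
    def test_strong_full_length_bacterial_hit_flags(self, tax):
        q = prot("q", length=100)
        assert flag_contaminants(q, [hit(BACT, pident=85, length=60)], tax)

    def test_short_alignment_does_not_flag(self, tax):
        q = prot("q", length=100)
        assert not flag_contaminants(q, [hit(BACT, pident=85, length=40)], tax)

    def test_thresholds_are_strict(self, tax):
        q = prot("q", length=100)
        assert not flag_contaminants(q, [hit(BACT, pident=80.0, length=90)], tax)
        assert not flag_contaminants(q, [hit(BACT, pident=90.0, length=50)], tax)

    def test_metazoan_hit_never_flags(self, tax):
        q = prot("q", length=100)
        assert not flag_contaminants(q, [hit(HUMAN, pident=99, length=100)], tax)


class TestInparalogs:
    def group(self, n_minc, n_mhap, gid="g"):
        members = tuple(prot(f"{gid}_i{i}") for i in range(n_minc)) + \
            tuple(prot(f"{gid}_h{i}", "Mhap") for i in range(n_mhap))
        return OrthoGroup(gid, members)

    @pytest.mark.parametrize("n_minc,n_mhap,expected", [
        (2, 1, "discarded-2:1"),
        (3, 0, "species-specific-duplication"),
        (0, 2, "species-specific-duplication"),
        (1, 1, "not-duplicated"),
        (2, 0, "not-duplicated"),
        (1, 0, "unclustered-singleton"),
    ])
    def test_classification(self, n_minc, n_mhap, expected):
        assert classify_group_paralogy(
            self.group(n_minc, n_mhap)).classification == expected

    def test_summary_counts_lgt_genes(self):
        groups = [self.group(3, 0, "a"), self.group(2, 1, "b"),
                  self.group(1, 1, "c")]
        lgt = {"a_i0", "b_i0"}
        s = count_inparalog_groups(groups, lgt)
        assert s.n_groups == 3
        assert s.n_groups_duplicated == 1
        assert s.lgt_class_counts["species-specific-duplication"] == 1
        assert s.n_lgt_genes_in_groups == 6  # 3 in group a + 3 in group b
        assert s.n_lgt_genes_duplicated == 3
        assert s.pct_lgt_duplicated == pytest.approx(50.0)
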