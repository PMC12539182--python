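import math
import random

import pytest

from obpcur.consolidate import (DEFAULT_GROUPING, GroupingParams,
                                cluster_candidates, select_representative)
from obpcur.homology import HomologyHit, align_local, best_hit
from obpcur.seqio import SequenceRecord
from obpcur.synthetic import generate_scaffold, mutate_to_identity


def stub_hit(q, s, subject=None):
    return HomologyHit(query_id=q, subject_id=subject, identity_pct=0,
                       coverage_pct=0, raw_score=0, bit_score=0, evalue=math.inf,
                       no_hit=subject is None)


def pair_hit(a, b):
    return align_local(a.seq, b.seq, query_id=a.id, subject_id=b.id)


def make_family(seed, n_genes=5, n_variants=3, variant_identity=96.0):
    """Planted genes with high-identity variants; inter-gene identity is
    far below the grouping threshold."""
    rng = random.Random(seed)
    records, truth = [], {}
    for g in range(n_genes):
        base = generate_scaffold("Classical", rng=rng)
        for v in range(n_variants):
            seq = base if v == 0 else mutate_to_identity(
                base, variant_identity, rng=rng)
            rid = f"g{g}v{v}"
            records.append(SequenceRecord(rid, seq, source="genbank",
                                          complete_orf=True))
            truth[rid] = g
    return records, truth


class TestClustering:
    def test_identical_cross_assembly_pair_merges(self):
        seq = generate_scaffold("Classical", seed=1)
        a = SequenceRecord("a", seq, source="genomeA", complete_orf=True)
        b = SequenceRecord("b", seq, source="genomeB", complete_orf=True)
        hits = [pair_hit(a, b)]
        best = {"a": stub_hit("a", None, "R"), "b": stub_hit("b", None, "R")}
        groups = cluster_candidates([a, b], hits, best)
        assert len(groups) == 1
        assert groups[0].member_ids == ("a", "b")
        assert groups[0].representative_id == "a"  # genomeA priority

    def test_planted_five_genes_three_variants_recovered(self):
        records, truth = make_family(seed=0)
        hits = [pair_hit(a, b) for i, a in enumerate(records)
                for b in records[i + 1:]]
        best = {r.id: stub_hit(r.id, None, "R") for r in records}
        groups = cluster_candidates(records, hits, best)
        assert len(groups) == 5
        assert sorted(len(g.member_ids) for g in groups) == [3] * 5
        for g in groups:
            assert len({truth[m] for m in g.member_ids}) == 1

    def test_same_gene_split_by_different_best_hits(self):
        seq = generate_scaffold("Classical", seed=2)
        par = mutate_to_identity(seq, 92.0, seed=2)
        a = SequenceRecord("a", seq, complete_orf=True)
        b = SequenceRecord("b", par, complete_orf=True)
        hits = [pair_hit(a, b)]
        assert hits[0].identity_nongap_pct >= 90.0
        best = {"a": stub_hit("a", None, "R1"), "b": stub_hit("b", None, "R2")}
        assert len(cluster_candidates([a, b], hits, best)) == 2
        loose = GroupingParams(require_same_best_hit=False)
        assert len(cluster_candidates([a, b], hits, best, loose)) == 1

    def test_partition_property(self):
        records, _ = make_family(seed=3, n_genes=4)
        hits = [pair_hit(a, b) for i, a in enumerate(records)
                for b in records[i + 1:]]
        best = {r.id: stub_hit(r.id, None, "R") for r in records}
        groups = cluster_candidates(records, hits, best)
        seen = [m for g in groups for m in g.member_ids]
        assert sorted(seen) == sorted(r.id for r in records)

    def test_raising_identity_threshold_only_splits(self):
        records, _ = make_family(seed=4, n_genes=3, variant_identity=93.0)
        hits = [pair_hit(a, b) for i, a in enumerate(records)
                for b in records[i + 1:]]
        best = {r.id: stub_hit(r.id, None, "R") for r in records}
        loose = cluster_candidates(records, hits, best,
                                   GroupingParams(min_identity=85))
        strict = cluster_candidates(records, hits, best,
                                    GroupingParams(min_identity=95))
        loose_sets = [set(g.member_ids) for g in loose]
        for g in strict:
            assert any(set(g.member_ids) <= s for s in loose_sets)

    def test_unknown_record_in_hits_errors(self):
        a = SequenceRecord("a", generate_scaffold("Classical", seed=5))
        hits = [stub_hit("a", None, None)]
        ghost = HomologyHit(query_id="a", subject_id="ghost", identity_pct=99,
                            coverage_pct=99, raw_score=10, bit_score=10,
                            evalue=0.0)
        with pytest.raises(ValueError, match="ghost"):
            cluster_candidates([a], [ghost], {"a": stub_hit("a", None, "R")})

    def test_missing_best_hit_errors(self):
        a = SequenceRecord("a", generate_scaffold("Classical", seed=6))
        with pytest.raises(ValueError, match="best-hit"):
            cluster_candidates([a], [], {})


class TestRepresentative:
    def recs(self, spec):
        return {rid: SequenceRecord(rid, "M" * n, source=src, complete_orf=c)
                for rid, n, c, src in spec}

    def test_complete_beats_longer_incomplete(self):
        records = self.recs([("a", 147, True, "genbank"),
                             ("b", 160, False, "genbank")])
        assert select_representative(["a", "b"], records) == "a"

    def test_longer_wins_among_complete(self):
        records = self.recs([("a", 147, True, "genbank"),
                             ("b", 151, True, "genbank")])
        assert select_representative(["a", "b"], records) == "b"

    def test_source_priority_then_lexicographic(self):
        records = self.recs([("b", 150, True, "transcriptome"),
                             ("a", 150, True, "genomeB")])
        assert select_representative(["a", "b"], records) == "a"
        records = self.recs([("b", 150, True, "genbank"),
                             ("a", 150, True, "genbank")])
        assert select_representative(["a", "b"], records) == "a"


class TestSubentries:
    def test_isoform_split_emits_one_entry_per_form(self, default_dataset):
        """Planted isoforms (internal indel >= 15) surface as isoform
        sub-entries of one group, not separate groups."""
        from obpcur import homology
        from obpcur.pipeline import ALL_VS_ALL_SCREEN, classify_candidates
        ds = default_dataset
        iso_genes = set(ds.truth.loc[ds.truth.variant_kind == "isoform",
                                     "gene_id"])
        assert iso_genes, "expected at least one planted isoform at seed 42"
        kept, subfam, _ = classify_candidates(ds.candidates)
        best = {r.id: best_hit(r, ds.references) for r in kept}
        pair = homology.all_vs_all_hits(kept, screen_score_per_residue=ALL_VS_ALL_SCREEN)
        groups = cluster_candidates(kept, pair, best, subfamilies=subfam)
        truth_gene = ds.truth.set_index("record_id").gene_id.to_dict()
        for g in groups:
            gene = truth_gene[g.representative_id]
            kinds = [k for _, k in g.subentries]
            if gene in iso_genes:
                assert kinds.count("isoform") == 1
            else:
                assert "isoform" not in kinds
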