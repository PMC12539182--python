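import math
import random

import pytest

from obpcur.consolidate import GeneGroup
from obpcur.homology import HomologyHit
from obpcur.nomenclature import (assign_names, format_name, normalize_base,
                                 parse_name)
from obpcur.phylo import read_newick
from obpcur.seqio import SequenceRecord, load_repertoire_table


def hit(subject, bit, query="q"):
    return HomologyHit(query_id=query, subject_id=subject, identity_pct=50,
                       coverage_pct=90, raw_score=bit, bit_score=bit,
                       evalue=1e-30)


NO_HIT = HomologyHit(query_id="q", subject_id=None, identity_pct=0,
                     coverage_pct=0, raw_score=0, bit_score=0,
                     evalue=math.inf, no_hit=True)


def group(gid, rep, subject, bit, members=None, subentries=None):
    members = tuple(sorted(members or [rep]))
    return GeneGroup(group_id=gid, member_ids=members, representative_id=rep,
                     best_hit=hit(subject, bit) if subject else NO_HIT,
                     subfamily="Classical",
                     subentries=subentries or ((rep, "primary"),))


def ref(base):
    return SequenceRecord(f"Dmel{base}", "M" * 100, source="reference",
                          description=f"OBP{base}")


class TestParse:
    def test_parses_every_packaged_name_and_round_trips(self):
        for e in load_repertoire_table():
            p = parse_name(e.name)
            rebuilt = format_name(p.prefix, p.base, p.suffix_kind,
                                  p.suffix_value, p.copy_letter)
            assert rebuilt == e.name

    @pytest.mark.parametrize("name,base,kind,value,letter", [
        ("CcapOBP99c-like4a", "99c", "like_numbered", 4, "a"),
        ("CcapOBP44a-isoform2", "44a", "isoform", 2, None),
        ("CcapOBPlush", "lush", "none", None, None),
        ("CcapOBP56h1", "56h", "numeric_copy", 1, None),
        ("CcapOBP83cd", "83cd", "none", None, None),
        ("CcapOBP19a-like", "19a", "like", None, None),
        ("CcapOBP-novel2", "", "novel", 2, None),
    ])
    def test_component_decomposition(self, name, base, kind, value, letter):
        p = parse_name(name)
        assert (p.base, p.suffix_kind, p.suffix_value, p.copy_letter) == \
               (base, kind, value, letter)

    @pytest.mark.parametrize("bad", ["CcapOBP", "Ccap19a", "OBP19a",
                                     "CcapOBP19a-like1-isoform2",
                                     "CcapOBP19a-unknown"])
    def test_unparseable_names_error(self, bad):
        with pytest.raises(ValueError, match="parse"):
            parse_name(bad)

    def test_normalize_base_strips_isoform_qualifier(self):
        assert normalize_base("OBP19d isoform A") == "19d"
        assert normalize_base("OBP56h") == "56h"


class TestAssign:
    def refs(self):
        return [ref("19a"), ref("19b"), ref("56h"), ref("99c")]

    def tree(self, newick):
        return read_newick(newick)

    def test_one_to_one_ortholog_gets_plain_base(self):
        groups = [group("G001", "r1", "Dmel19a", 200.0)]
        tree = self.tree("((r1:0.1,Dmel19a:0.1):1,(Dmel19b:1,"
                         "(Dmel56h:1,Dmel99c:1):1):1);")
        (a,) = assign_names(groups, tree, self.refs())
        assert a.final_name == "CcapOBP19a"
        assert a.suffix_kind == "none"

    def test_second_claimant_becomes_like(self):
        groups = [group("G001", "r1", "Dmel19a", 200.0),
                  group("G002", "r2", "Dmel19a", 120.0)]
        tree = self.tree("(((r1:0.1,Dmel19a:0.1):1,r2:2):1,(Dmel19b:1,"
                         "(Dmel56h:1,Dmel99c:1):1):1);")
        names = {a.group_id: a.final_name
                 for a in assign_names(groups, tree, self.refs())}
        assert names == {"G001": "CcapOBP19a", "G002": "CcapOBP19a-like"}

    def test_near_equal_agreeing_duplicates_get_numeric_copies(self):
        groups = [group("G001", "r1", "Dmel56h", 150.0),
                  group("G002", "r2", "Dmel56h", 145.0)]
        tree = self.tree("(((r1:0.1,r2:0.1):0.2,Dmel56h:0.1):1,"
                         "(Dmel19a:1,(Dmel19b:1,Dmel99c:1):1):1);")
        names = sorted(a.final_name
                       for a in assign_names(groups, tree, self.refs()))
        assert names == ["CcapOBP56h1", "CcapOBP56h2"]

    def test_expansion_pattern_with_letter_copies(self):
        """Winner + five like-subgroups, two of them with tandem copies."""
        groups = [group("G000", "w", "Dmel99c", 300.0)]
        for i in range(5):
            sub = None
            if i in (0, 3):
                sub = ((f"s{i}", "primary"), (f"s{i}b", "copy"))
            groups.append(group(f"G{i + 1:03d}", f"s{i}", "Dmel99c",
                                200.0 - 10 * i,
                                members=[f"s{i}", f"s{i}b"] if sub else None,
                                subentries=sub))
        leaves = ",".join(f"s{i}:2" for i in range(5))
        tree = self.tree(f"(((w:0.1,Dmel99c:0.1):1,({leaves}):1):1,"
                         "(Dmel19a:1,(Dmel19b:1,Dmel56h:1):1):1);")
        names = sorted(a.final_name
                       for a in assign_names(groups, tree, self.refs()))
        assert names == ["CcapOBP99c", "CcapOBP99c-like1a", "CcapOBP99c-like1b",
                         "CcapOBP99c-like2", "CcapOBP99c-like3",
                         "CcapOBP99c-like4a", "CcapOBP99c-like4b",
                         "CcapOBP99c-like5"]

    def test_isoform_subentries_numbered(self):
        groups = [group("G001", "r1", "Dmel19a", 200.0,
                        members=["r1", "r2"],
                        subentries=(("r1", "primary"), ("r2", "isoform")))]
        tree = self.tree("((r1:0.1,Dmel19a:0.1):1,(Dmel19b:1,"
                         "(Dmel56h:1,Dmel99c:1):1):1);")
        names = sorted(a.final_name
                       for a in assign_names(groups, tree, self.refs()))
        assert names == ["CcapOBP19a-isoform1", "CcapOBP19a-isoform2"]

    def test_no_hit_group_flagged_novel(self):
        groups = [group("G001", "r1", None, 0.0)]
        (a,) = assign_names(groups, None, self.refs())
        assert a.final_name == "CcapOBP-novel1"
        assert a.rule == "no_reference_hit"

    def test_names_unique_and_permutation_invariant(self):
        groups = [group("G001", "r1", "Dmel19a", 200.0),
                  group("G002", "r2", "Dmel19a", 120.0),
                  group("G003", "r3", "Dmel19b", 90.0),
                  group("G004", "r4", None, 0.0)]
        tree = self.tree("((((r1:0.1,Dmel19a:0.1):1,r2:2):1,(r3:1,Dmel19b:1):1)"
                         ":1,((Dmel56h:1,Dmel99c:1):1,r4:4):1);")
        rng = random.Random(0)
        baseline = assign_names(groups, tree, self.refs())
        assert len({a.final_name for a in baseline}) == len(baseline)
        for _ in range(3):
            shuffled = groups[:]
            rng.shuffle(shuffled)
            assert assign_names(shuffled, tree, self.refs()) == baseline
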