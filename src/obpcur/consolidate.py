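"""Redundancy consolidation: group candidate records into genes and pick
representatives.

Multi-source mining (two genome assemblies, GenBank, a transcriptome)
yields several records per gene — alleles, cross-assembly duplicates,
isoforms, fragments.  Records are joined by single-linkage over explicit
thresholds (gap-excluded identity and mutual coverage, optionally an
identical best reference hit) and each connected component becomes one
gene group.  The representative is the most complete, then longest, then
highest-priority-source member.

Within a group two kinds of sub-entries are distinguished:

* isoforms — members whose alignment to the representative shows an
  internal indel of at least ``isoform_min_indel`` residues;
* copies — sub-clusters at the higher ``copy_min_identity`` threshold,
  standing in for tandem duplicates that external curation (for example
  chromosomal locations) keeps as separate entries of one gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx

from .homology import HomologyHit
from .seqio import SequenceRecord


@dataclass(frozen=True)
class GroupingParams:
    min_identity: float = 90.0   # gap-excluded %, same-gene edge threshold
    min_coverage: float = 80.0   # mutual coverage %
    require_same_best_hit: bool = True
    source_priority: tuple[str, ...] = ("genbank", "genomeA", "genomeB",
                                        "transcriptome")
    isoform_min_indel: int = 15  # residues of internal indel marking an isoform
    copy_min_identity: float = 94.0  # sub-cluster threshold for tandem copies

    def __post_init__(self):
        for v in (self.min_identity, self.min_coverage, self.copy_min_identity):
            if not 0 < v <= 100:
                raise ValueError("thresholds must lie in (0, 100]")


DEFAULT_GROUPING = GroupingParams()


@dataclass(frozen=True)
class GeneGroup:
    group_id: str
    member_ids: tuple[str, ...]          # sorted
    representative_id: str
    best_hit: Optional[HomologyHit]
    subfamily: str
    #: (member_id, kind) with kind in {"primary", "isoform", "copy"};
    #: the entries a report should emit for this gene
    subentries: tuple[tuple[str, str], ...] = ()


def _mutual_coverage(hit: HomologyHit, records: Mapping[str, SequenceRecord]) -> float:
    scov = 100.0 * (hit.s_end - hit.s_start + 1) / len(records[hit.subject_id].seq)
    return min(hit.coverage_pct, scov)


def _is_edge(hit: HomologyHit, records, best_hits, params: GroupingParams) -> bool:
    if hit.no_hit:
        return False
    if hit.identity_nongap_pct < params.min_identity:
        return False
    if _mutual_coverage(hit, records) < params.min_coverage:
        return False
    if params.require_same_best_hit:
        a = best_hits[hit.query_id].subject_id
        b = best_hits[hit.subject_id].subject_id
        if a != b:
            return False
    return True


def select_representative(member_ids: Sequence[str],
                          records: Mapping[str, SequenceRecord],
                          params: GroupingParams = DEFAULT_GROUPING) -> str:
    """Rank members by (complete ORF, length, source priority, id)."""
    prio = {s: i for i, s in enumerate(params.source_priority)}

    def key(mid: str):
        r = records[mid]
        return (not r.complete_orf, -len(r.seq),
                prio.get(r.source, len(prio)), mid)

    return min(member_ids, key=key)


def _consensus_subfamily(member_ids, subfamilies, representative_id) -> str:
    if not subfamilies:
        return "Unclassified"
    votes: dict[str, int] = {}
    for m in member_ids:
        s = subfamilies.get(m, "Unclassified")
        votes[s] = votes.get(s, 0) + 1
    top = max(votes.values())
    winners = sorted(s for s, v in votes.items() if v == top)
    rep_s = subfamilies.get(representative_id, "Unclassified")
    return rep_s if rep_s in winners else winners[0]


def _subentries(member_ids, rep, pair_hits, params) -> tuple[tuple[str, str], ...]:
    """Classify group members into primary / isoform / copy sub-entries.

    Splice forms are the connected components of the "no large internal
    indel between us" relation; when several forms coexist, each non-
    representative form contributes one isoform sub-entry.  Otherwise the
    members are sub-clustered at the copy threshold and each extra
    sub-cluster contributes one tandem-copy sub-entry.
    """
    entries: list[tuple[str, str]] = [(rep, "primary")]

    same_form = nx.Graph()
    same_form.add_nodes_from(member_ids)
    for i, a in enumerate(member_ids):
        for b in member_ids[i + 1:]:
            h = pair_hits.get(frozenset((a, b)))
            if h is not None and h.max_internal_gap < params.isoform_min_indel:
                same_form.add_edge(a, b)
    forms = sorted((sorted(c) for c in nx.connected_components(same_form)),
                   key=lambda c: c[0])
    if len(forms) > 1:
        for c in forms:
            if rep not in c:
                entries.append((min(c), "isoform"))
        return tuple(entries)

    copies = nx.Graph()
    copies.add_nodes_from(member_ids)
    for i, a in enumerate(member_ids):
        for b in member_ids[i + 1:]:
            h = pair_hits.get(frozenset((a, b)))
            if h is not None and h.identity_nongap_pct >= params.copy_min_identity:
                copies.add_edge(a, b)
    clusters = sorted((sorted(c) for c in nx.connected_components(copies)),
                      key=lambda c: c[0])
    if len(clusters) > 1:
        for c in clusters:
            if rep not in c:
                entries.append((min(c), "copy"))
    return tuple(entries)


def cluster_candidates(records: Sequence[SequenceRecord],
                       hits: Sequence[HomologyHit],
                       best_hits: Mapping[str, HomologyHit],
                       params: GroupingParams = DEFAULT_GROUPING,
                       subfamilies: Optional[Mapping[str, str]] = None,
                       ) -> list[GeneGroup]:
    """Partition candidates into gene groups (connected components of the
    same-gene graph), sorted by representative id."""
    rec_map = {r.id: r for r in records}
    for h in hits:
        for rid in (h.query_id, h.subject_id):
            if rid is not None and rid not in rec_map:
                raise ValueError(f"hit references unknown record {rid!r}")
    for rid in rec_map:
        if rid not in best_hits:
            raise ValueError(f"record {rid!r} has no best-hit entry")

    graph = nx.Graph()
    graph.add_nodes_from(rec_map)
    pair_hits: dict[frozenset, HomologyHit] = {}
    for h in hits:
        if h.no_hit:
            continue
        key = frozenset((h.query_id, h.subject_id))
        prev = pair_hits.get(key)
        if prev is None or h.raw_score > prev.raw_score:
            pair_hits[key] = h
        if _is_edge(h, rec_map, best_hits, params):
            graph.add_edge(h.query_id, h.subject_id)

    groups = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        rep = select_representative(members, rec_map, params)
        groups.append(GeneGroup(
            group_id="",  # assigned after sorting
            member_ids=members,
            representative_id=rep,
            best_hit=best_hits.get(rep),
            subfamily=_consensus_subfamily(members, subfamilies or {}, rep),
            subentries=_subentries(members, rep, pair_hits, params),
        ))
    groups.sort(key=lambda g: g.representative_id)
    return [GeneGroup(group_id=f"G{i + 1:03d}", member_ids=g.member_ids,
                      representative_id=g.representative_id, best_hit=g.best_hit,
                      subfamily=g.subfamily, subentries=g.subentries)
            for i, g in enumerate(groups)]
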