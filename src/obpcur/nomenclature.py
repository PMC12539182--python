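"""Standardized ortholog-anchored naming of consolidated gene groups.

Names follow the pattern ``<prefix>OBP<base><suffix>`` (for example
``CcapOBP19a``, ``CcapOBP56h1``, ``CcapOBP99c-like4a``,
``CcapOBP44a-isoform2``, ``CcapOBPlush``) where the base is the reference
ortholog's name:

* suffix **none** — the 1-to-1 ortholog of the reference gene, operationally
  the group whose best hit and nearest tree reference agree on the base and
  whose bit score is highest among such groups;
* **-like** / **-like1..N** — further groups claiming the same base without
  a 1-to-1 relationship, numbered by descending bit score when several;
* **numeric copies** ``B1, B2`` — species-specific duplications: two or
  more groups that all agree on the base with near-equal scores;
* **letter copies** ``a, b`` — tandem-duplicate sub-entries within a group;
* **-isoformN** — isoform sub-entries within a group.

Groups without any accepted reference hit are named
``<prefix>OBP-novel<N>`` and flagged for review.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from skbio import TreeNode

from .consolidate import GeneGroup
from .phylo import nearest_reference
from .seqio import SequenceRecord

SUFFIX_KINDS = ("none", "like", "like_numbered", "numeric_copy",
                "letter_copy", "isoform", "novel")

_NAME_RE = re.compile(
    r"""^(?P<prefix>[A-Z][A-Za-z]*?)OBP
        (?:
            -novel(?P<novel>\d+)
          | (?:(?P<wordbase>[a-z]+)|(?P<base>\d+[a-z]+?))
            (?:(?P<copy>\d+)(?P<copyletter>[a-z])?)?
            (?:(?P<like>-like)(?P<likenum>\d+)?(?P<likeletter>[a-z])?)?
            (?:-isoform(?P<iso>\d+))?
        )$""",
    re.VERBOSE,
)

_ISOFORM_DESC_RE = re.compile(r"\s+isoform\s+\S+$", re.IGNORECASE)


@dataclass(frozen=True)
class NameAssignment:
    group_id: str
    prefix: str
    base: str
    suffix_kind: str
    suffix_value: Optional[int] = None   # like number / copy number / isoform number
    copy_letter: Optional[str] = None    # letter copy within a like subgroup
    final_name: str = ""
    rule: str = ""                        # which naming rule fired
    evidence: str = ""                    # best hit / tree agreement summary
    member_id: Optional[str] = None       # record the entry points at


def normalize_base(description: str) -> str:
    """Reduce a reference description like ``OBP19d isoform A`` to ``19d``."""
    base = _ISOFORM_DESC_RE.sub("", description.strip())
    if base.upper().startswith("OBP"):
        base = base[3:]
    return base.strip()


def format_name(prefix: str, base: str, suffix_kind: str = "none",
                suffix_value: Optional[int] = None,
                copy_letter: Optional[str] = None) -> str:
    if suffix_kind == "novel":
        return f"{prefix}OBP-novel{suffix_value}"
    name = f"{prefix}OBP{base}"
    if suffix_kind == "numeric_copy":
        name += str(suffix_value)
        if copy_letter:
            name += copy_letter
    elif suffix_kind == "like":
        name += "-like"
        if copy_letter:
            name += copy_letter
    elif suffix_kind == "like_numbered":
        name += f"-like{suffix_value}"
        if copy_letter:
            name += copy_letter
    elif suffix_kind == "isoform":
        name += f"-isoform{suffix_value}"
    elif suffix_kind != "none":
        raise ValueError(f"unknown suffix kind {suffix_kind!r}")
    return name


def parse_name(name: str) -> NameAssignment:
    """Decompose a standardized name into its components (lossless:
    ``format_name`` of the parts reproduces the input)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse OBP name {name!r}")
    d = m.groupdict()
    prefix = d["prefix"]
    if d["novel"]:
        return NameAssignment(group_id="", prefix=prefix, base="",
                              suffix_kind="novel", suffix_value=int(d["novel"]),
                              final_name=name)
    base = d["wordbase"] or d["base"]
    if d["iso"]:
        kind, value, letter = "isoform", int(d["iso"]), None
        if d["copy"] or d["like"]:
            raise ValueError(f"cannot parse OBP name {name!r}: "
                             f"isoform combined with other suffixes")
    elif d["like"]:
        kind = "like_numbered" if d["likenum"] else "like"
        value = int(d["likenum"]) if d["likenum"] else None
        letter = d["likeletter"]
    elif d["copy"]:
        kind, value, letter = "numeric_copy", int(d["copy"]), d["copyletter"]
    else:
        kind, value, letter = "none", None, None
    return NameAssignment(group_id="", prefix=prefix, base=base,
                          suffix_kind=kind, suffix_value=value,
                          copy_letter=letter, final_name=name)


def _claim(group: GeneGroup, refs_by_id: Mapping[str, SequenceRecord]) -> Optional[str]:
    """Base name claimed by a group via its best reference hit."""
    if group.best_hit is None or group.best_hit.no_hit:
        return None
    ref = refs_by_id.get(group.best_hit.subject_id)
    if ref is None:
        return None
    return normalize_base(ref.description or ref.id)


def assign_names(groups: Sequence[GeneGroup], tree: Optional[TreeNode],
                 refs: Sequence[SequenceRecord], prefix: str = "Ccap",
                 near_equal_frac: float = 0.10,
                 tree_label: Mapping[str, str] | None = None,
                 ) -> list[NameAssignment]:
    """Assign a unique standardized name to every emitted entry of every
    group.  Deterministic under input permutation (groups are processed in
    group-id order, claims resolved by descending bit score then group id).

    ``tree_label`` maps record/reference ids to tree leaf labels when the
    tree uses decorated labels; identity is assumed otherwise.
    """
    refs_by_id = {r.id: r for r in refs}
    label = dict(tree_label) if tree_label else {}
    groups = sorted(groups, key=lambda g: g.group_id)

    claims: dict[str, list[tuple[GeneGroup, float, bool]]] = {}
    novel: list[GeneGroup] = []
    for g in groups:
        base = _claim(g, refs_by_id)
        if base is None:
            novel.append(g)
            continue
        agree = False
        if tree is not None:
            try:
                nearest = nearest_reference(
                    tree, label.get(g.representative_id, g.representative_id),
                    [label.get(r.id, r.id) for r in refs])
                back = {label.get(r.id, r.id): r.id for r in refs}
                nearest_base = normalize_base(
                    refs_by_id[back[nearest]].description or back[nearest])
                agree = nearest_base == base
            except ValueError:
                agree = False
        claims.setdefault(base, []).append((g, g.best_hit.bit_score, agree))

    assignments: list[NameAssignment] = []

    def emit(group: GeneGroup, kind: str, value=None, rule="", evidence=""):
        """Expand a group's naming decision over its sub-entries."""
        subs = group.subentries or ((group.representative_id, "primary"),)
        isoforms = [m for m, k in subs if k == "isoform"]
        copies = [m for m, k in subs if k == "copy"]
        primary = next(m for m, k in subs if k == "primary")
        base = _claim(group, refs_by_id) or ""
        if isoforms:
            # all emitted entries of an isoform-bearing gene are numbered
            for i, member in enumerate(sorted([primary] + isoforms), start=1):
                assignments.append(NameAssignment(
                    group_id=group.group_id, prefix=prefix, base=base,
                    suffix_kind="isoform", suffix_value=i,
                    final_name=format_name(prefix, base, "isoform", i),
                    rule=rule + "+isoform_split", evidence=evidence,
                    member_id=member))
            return
        if copies:
            # letter copies on like names, numeric promotion on plain bases
            members = sorted([primary] + copies)
            for i, member in enumerate(members):
                if kind in ("like", "like_numbered"):
                    nm = format_name(prefix, base, kind, value,
                                     copy_letter=chr(ord("a") + i))
                    assignments.append(NameAssignment(
                        group_id=group.group_id, prefix=prefix, base=base,
                        suffix_kind=kind, suffix_value=value,
                        copy_letter=chr(ord("a") + i), final_name=nm,
                        rule=rule + "+copy_split", evidence=evidence,
                        member_id=member))
                elif kind == "numeric_copy":
                    # letters nested under an already-numbered duplication
                    nm = format_name(prefix, base, "numeric_copy", value,
                                     copy_letter=chr(ord("a") + i))
                    assignments.append(NameAssignment(
                        group_id=group.group_id, prefix=prefix, base=base,
                        suffix_kind="numeric_copy", suffix_value=value,
                        copy_letter=chr(ord("a") + i), final_name=nm,
                        rule=rule + "+copy_split", evidence=evidence,
                        member_id=member))
                else:
                    nm = format_name(prefix, base, "numeric_copy", i + 1)
                    assignments.append(NameAssignment(
                        group_id=group.group_id, prefix=prefix, base=base,
                        suffix_kind="numeric_copy", suffix_value=i + 1,
                        final_name=nm, rule=rule + "+copy_split",
                        evidence=evidence, member_id=member))
            return
        assignments.append(NameAssignment(
            group_id=group.group_id, prefix=prefix, base=base,
            suffix_kind=kind, suffix_value=value,
            final_name=format_name(prefix, base, kind, value),
            rule=rule, evidence=evidence, member_id=primary))

    for base in sorted(claims):
        claimants = sorted(claims[base], key=lambda t: (-t[1], t[0].group_id))
        agreeing = [t for t in claimants if t[2]]
        like_pool: list[tuple[GeneGroup, float, bool]] = []
        if agreeing:
            top_bit = agreeing[0][1]
            dup = [t for t in agreeing if t[1] >= (1 - near_equal_frac) * top_bit]
            if len(dup) >= 2:
                for i, (g, bit, _) in enumerate(dup, start=1):
                    emit(g, "numeric_copy", i, rule="species_duplication",
                         evidence=f"best_hit={base} nearest={base} bit={bit:.1f}")
                like_pool = [t for t in claimants if t not in dup]
            else:
                g, bit, _ = agreeing[0]
                emit(g, "none", rule="one_to_one_ortholog",
                     evidence=f"best_hit={base} nearest={base} bit={bit:.1f}")
                like_pool = [t for t in claimants if t[0] is not g]
        else:
            like_pool = claimants
        if len(like_pool) == 1:
            g, bit, agree = like_pool[0]
            emit(g, "like", rule="no_one_to_one",
                 evidence=f"best_hit={base} agree={agree} bit={bit:.1f}")
        else:
            for i, (g, bit, agree) in enumerate(like_pool, start=1):
                emit(g, "like_numbered", i, rule="like_expansion",
                     evidence=f"best_hit={base} agree={agree} bit={bit:.1f}")

    for i, g in enumerate(sorted(novel, key=lambda g: g.group_id), start=1):
        assignments.append(NameAssignment(
            group_id=g.group_id, prefix=prefix, base="", suffix_kind="novel",
            suffix_value=i, final_name=format_name(prefix, "", "novel", i),
            rule="no_reference_hit", evidence="flagged_for_review",
            member_id=g.representative_id))

    names = [a.final_name for a in assignments]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise RuntimeError(f"duplicate names assigned: {dupes}")
    assignments.sort(key=lambda a: (a.group_id, a.final_name))
    return assignments
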