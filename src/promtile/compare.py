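"""Gene-set comparison across conditions and against expression data.

Bound-gene sets from two ChIP conditions (e.g. control vs hormone-treated)
are compared by plain set arithmetic — the union is the candidate
direct-target list — and the candidate list is cross-referenced against an
expression study's platform and regulation calls (epithelium / non-epithelium
compartments), reporting percentages with explicit denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATEGORY_EP = "EP"
CATEGORY_NONEP = "NonEP"
CATEGORY_BOTH = "both"
CATEGORY_UNREGULATED = "unregulated"
CATEGORY_ABSENT = "absent"


@dataclass(frozen=True)
class GeneSet:
    """A labelled, deduplicated set of gene identifiers."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("GeneSet label must be nonempty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapReport:
    """Sizes of all regions of a two-set Venn diagram."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    n_a_only: int
    n_b_only: int
    union_members: frozenset[str] = field(repr=False, default=frozenset())

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_intersection": self.n_intersection,
            "n_union": self.n_union,
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
        }


def compare_conditions(set_a: GeneSet, set_b: GeneSet) -> OverlapReport:
    """Venn arithmetic between two bound-gene sets.

    The union is the candidate target-gene list: e.g. 78 control-bound and
    253 treated-bound genes sharing 53 members form a union of 278
    candidates (inclusion–exclusion).
    """
    inter = set_a.members & set_b.members
    union = set_a.members | set_b.members
    return OverlapReport(
        label_a=set_a.label,
        label_b=set_b.label,
        n_a=len(set_a),
        n_b=len(set_b),
        n_intersection=len(inter),
        n_union=len(union),
        n_a_only=len(set_a.members - set_b.members),
        n_b_only=len(set_b.members - set_a.members),
        union_members=frozenset(union),
    )


def overlap_expression(
    target_set: GeneSet, expression_table: pd.DataFrame
) -> tuple[pd.Series, dict]:
    """Cross-reference candidate targets with an expression study.

    ``expression_table`` has columns gene_id, regulated_EP, regulated_NonEP
    and lists only genes present on the expression platform. Each target
    gene is categorized as EP / NonEP / both (regulated in one or both
    intestinal compartments), "unregulated" (on the platform but not
    regulated) or "absent" (not on the platform). Percentages are rounded
    to the nearest integer with their denominators stated: presence is a
    fraction of all targets, regulation a fraction of the present ones.
    """
    if expression_table["gene_id"].duplicated().any():
        dups = expression_table.loc[
            expression_table["gene_id"].duplicated(), "gene_id"
        ].tolist()
        raise ValueError(f"duplicate gene ids in expression table: {dups[:10]}")

    table = expression_table.set_index("gene_id")
    categories = {}
    for gene in sorted(target_set.members):
        if gene not in table.index:
            categories[gene] = CATEGORY_ABSENT
            continue
        ep = bool(table.at[gene, "regulated_EP"])
        nonep = bool(table.at[gene, "regulated_NonEP"])
        if ep and nonep:
            categories[gene] = CATEGORY_BOTH
        elif ep:
            categories[gene] = CATEGORY_EP
        elif nonep:
            categories[gene] = CATEGORY_NONEP
        else:
            categories[gene] = CATEGORY_UNREGULATED
    cat = pd.Series(categories, dtype=object, name="category")

    n_targets = len(target_set)
    n_present = int((cat != CATEGORY_ABSENT).sum())
    n_ep = int((cat == CATEGORY_EP).sum())
    n_nonep = int((cat == CATEGORY_NONEP).sum())
    n_both = int((cat == CATEGORY_BOTH).sum())
    n_regulated = n_ep + n_nonep + n_both
    summary = {
        "n_targets": n_targets,
        "n_present": n_present,
        "pct_present": round(100 * n_present / n_targets) if n_targets else 0,
        "frac_present": n_present / n_targets if n_targets else 0.0,
        "n_regulated": n_regulated,
        "pct_regulated_of_present": round(100 * n_regulated / n_present) if n_present else 0,
        "frac_regulated_of_present": n_regulated / n_present if n_present else 0.0,
        "n_EP_only": n_ep,
        "n_NonEP_only": n_nonep,
        "n_both": n_both,
    }
    return cat, summary


def match_gene_names(
    set_a: set[str], set_b: set[str], alias_map: dict[str, str] | None = None
) -> dict:
    """Case-insensitive gene-name matching through an optional alias map.

    Gene naming differs between platforms, so apparent non-overlap can be a
    nomenclature artifact; this step makes the losses explicit. Names are
    canonicalized through ``alias_map`` (synonym -> canonical id, matched
    case-insensitively) then compared case-folded. Returns matched pairs and
    the unmatched ids on each side.
    """
    alias_map = {k.casefold(): v for k, v in (alias_map or {}).items()}

    def canon(name: str) -> str:
        return alias_map.get(name.casefold(), name).casefold()

    canon_a: dict[str, list[str]] = {}
    for name in set_a:
        canon_a.setdefault(canon(name), []).append(name)
    matched, unmatched_b = [], []
    hit_keys = set()
    for name in set_b:
        key = canon(name)
        if key in canon_a:
            hit_keys.add(key)
            for orig in canon_a[key]:
                matched.append((orig, name))
        else:
            unmatched_b.append(name)
    unmatched_a = [n for k, names in canon_a.items() if k not in hit_keys for n in names]
    return {
        "matched": sorted(matched),
        "unmatched_a": sorted(unmatched_a),
        "unmatched_b": sorted(unmatched_b),
    }
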