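"""Condition-set Venn arithmetic and expression cross-referencing.

Reproduces the worked arithmetic of a two-condition TR-binding study:
78 genes bound in the control intestine and 253 in the hormone-treated one,
53 shared, giving 278 candidate direct targets; 95 of those present on an
expression platform (34%), 38 of the 95 regulated during metamorphosis
(40%), split 13 epithelium-only / 14 non-epithelium-only / 11 both.
"""

import pandas as pd

from promtile import GeneSet, compare_conditions, overlap_expression

shared = {f"shared{i}" for i in range(53)}
control = GeneSet("control", frozenset(shared | {f"ctl{i}" for i in range(25)}))
treated = GeneSet("t3", frozenset(shared | {f"t3_{i}" for i in range(200)}))

report = compare_conditions(control, treated)
print(f"control-bound: {report.n_a}, treated-bound: {report.n_b}, "
      f"shared: {report.n_intersection}, candidate targets (union): {report.n_union}")

# expression platform covers 95 of the 278 candidates; 13 + 14 + 11 = 38 regulated
targets = GeneSet("targets", report.union_members)
members = sorted(targets.members)
rows = []
for i, gene in enumerate(members[:95]):
    rows.append({
        "gene_id": gene,
        "regulated_EP": i < 13 or 27 <= i < 38,
        "regulated_NonEP": 13 <= i < 38,
    })
categories, summary = overlap_expression(targets, pd.DataFrame(rows))

print(f"on expression platform: {summary['n_present']}/{summary['n_targets']} "
      f"({summary['pct_present']}%)")
print(f"regulated during metamorphosis: {summary['n_regulated']}/{summary['n_present']} "
      f"({summary['pct_regulated_of_present']}%)")
print(f"compartments: EP-only {summary['n_EP_only']}, Non-EP-only {summary['n_NonEP_only']}, "
      f"both {summary['n_both']}")
# Percentages are rounded to integers with their denominators stated, because
# presence is a fraction of all targets while regulation is a fraction of the
# platform-present subset.
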