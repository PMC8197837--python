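"""Induce intelligible if-then rules and score them with covering/error + FET.

Each rule reads ``if((feature op threshold)...)then class`` with covering C
(fraction of its own class matched) and error r (fraction of the other
class matched); Fisher's exact test gates each rule at alpha = 0.05.
"""

import vitalgan as vg

cohort = vg.generate_cohort(43, seed=7)

print("greedy (sequential covering over quartile bins):")
greedy = vg.filter_rules_fet(vg.induce_rules_greedy(cohort, q_bins=4), cohort)
for rule in greedy:
    print("  " + vg.format_rule(rule))

print("tree (Gini decision tree converted to leaf-path rules):")
tree = vg.filter_rules_fet(vg.induce_rules_tree(cohort, max_depth=2), cohort)
for rule in tree:
    print("  " + vg.format_rule(rule))

acc, f1 = vg.evaluate_ruleset(greedy, cohort)
print(f"greedy ruleset on the cohort: accuracy={acc:.2f}  F1={f1:.2f}")

# Printed-style rules parse back losslessly:
rule = vg.parse_rule("if((FEV1<2.23))then low")
C, r = vg.covering_error(rule, cohort)
print(f"parsed rule '{vg.format_rule(rule, annotate=False)}': "
      f"C={C:.0%} r={r:.0%} p={vg.fet_rule_pvalue(rule, cohort):.3g}")
# Both inducers should agree that low FEV1 marks the low-PEF class; the FET
# p-value says how unlikely that premise/class association is by chance.
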