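"""Replay the structural evolution of the rubric: 9 criteria -> 7.

Starting from the nine-criterion intermediate set, remove the redundant
impact-of-uncertainty criterion (proportional renormalization) and merge
expertise with methodology (additive pooling).  The resulting *structure*
matches the final instrument; the final *weights* are the published
constants, not derived — the comparison below shows both.
"""

from rwemcda import (
    default_criterion_set,
    merge_criteria,
    remove_criterion,
    table1_criterion_set,
)

v1 = table1_criterion_set()
print(f"{v1.version_tag}: {len(v1.criteria)} criteria, equal weights "
      f"{v1.weights['benefit']:.2f} each")

pruned = remove_criterion(v1, "impact_of_uncertainty")
derived = merge_criteria(
    pruned,
    ("expertise", "methodology"),
    "expertise_and_methodology",
    "Expertise and methodology",
)
final = default_criterion_set()

print(f"\nafter remove + merge: {len(derived.criteria)} criteria, "
      f"sum {sum(derived.weights.values()):.6f}")
print("criterion                    derived   published")
for cid in final.ids():
    print(f"  {cid:<26} {derived.weights[cid]:7.2f}   {final.weights[cid]:7.2f}")
print("Structural edits conserve the 100 total; the published weights came"
      " from stakeholder elicitation, so they differ from the mechanical"
      " renormalization and are shipped verbatim.")
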