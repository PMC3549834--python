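"""Why plain Dempster combination can mislead, and what the alternatives do.

Two hypothetical bond-determination methods for the trypsin inhibitor
1G6X each back a different set of disulfide bonds with high confidence,
agreeing only on one bond they both consider near-impossible (belief
0.01).  Dempster's rule normalises the massive conflict away and hands
that shared long-shot everything; Yager and Campos instead move the
conflicting mass into the environment (ignorance).
"""

from ssfuse import bond_scores, combine_campos, combine_dempster, combine_yager
from ssfuse.fixtures import example1_evidence
from ssfuse.hypothesis import MassFunction

evidence = example1_evidence()
masses = [
    MassFunction.from_singleton_scores({e.bond: e.belief for e in evidence[m]})
    for m in ("M1", "M2")
]

for name, rule in (
    ("Dempster", combine_dempster),
    ("Yager", combine_yager),
    ("Campos", combine_campos),
):
    result = rule(masses)
    scores = bond_scores(result)
    top = max(scores, key=scores.get) if scores else None
    print(f"{name:9s} conflict={result.conflict_mass:.4f} "
          f"environment={result.fused.environment_mass:.4f} "
          f"top bond={top} score={scores.get(top, 0.0):.4f}")

print()
print("Both methods gave C14-C31 belief 0.01, yet Dempster fuses it to 1.0:")
print("the conflict between everything else was normalised out.  Yager and")
print("Campos leave most mass as ignorance instead of endorsing the long shot.")
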