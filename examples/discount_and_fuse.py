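"""Reliability discounting feeding the Shafer discount-and-average rule.

Sources are de-rated from their own data before averaging: MS evidence by
precursor size and matched-abundance significance, SVM evidence by its
own confidence, CSP evidence by profile divergence and match ambiguity.
"""

from ssfuse import fuse_evidence
from ssfuse.discounting import discount_csp, discount_ms, discount_svm
from ssfuse.fixtures import table4_evidence

# weights from typical evidence metadata
w_ms = discount_ms(precursor_mass=3200.0, pp2=30.0)     # light ion, weak abundance
w_svm = discount_svm(belief=0.96)                        # confident prediction
w_csp = discount_csp(divergence=15.0, n_best_matches=1)  # distant, ambiguous match

print("derived reliability weights:")
for w in (w_ms, w_svm, w_csp):
    print(f"  {w.method:4s} alpha = {w.alpha:.3f}")

evidence = table4_evidence()  # ordered MS, SVM, CSP
weights = {"MS": w_ms.alpha, "SVM": w_svm.alpha, "CSP": w_csp.alpha}
out = fuse_evidence(
    evidence, rule="shafer", weights=[weights[s.method] for s in evidence]
)
print("\nShafer fusion with discounting:")
for b, score in sorted(out.scores.items(), key=lambda kv: -kv[1]):
    print(f"  {b}: fused belief {score:.3f}")
print(f"  environment (ignorance): {out.result.fused.environment_mass:.3f}")

from ssfuse import global_topology

topology = global_topology(out.scores)
print("  maximum-weight matching:", ", ".join(str(b) for b in topology))
print()
print("Discounting shrinks each source toward ignorance in proportion to")
print("its unreliability before the average; the matching step then selects")
print("the mutually consistent bond set with the highest total belief.")
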