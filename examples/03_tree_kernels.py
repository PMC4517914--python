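"""Convolution tree kernel and the composite kernel.

Builds the dependency-path feature trees for two L-scope candidates of
the worked example and shows how the tree kernel, polynomial kernel and
their gamma-mix compare the instances.
"""
from hedgescope import (KernelParams, composite, dependency_feature_tree,
                        poly_kernel, tree_kernel)
from hedgescope.featurize import featurize_candidate
from hedgescope.fixtures_synth import sentence1_fixture

sent = sentence1_fixture().sentence
tree = sent.deptree

for cand in (13, 16):
    ft = dependency_feature_tree(tree, 10, cand)
    print(f"dependency path cue->candidate {cand}: {ft.to_bracketed()}")

a = featurize_candidate(sent, 10, 13, "L", "dep_lexical")
b = featurize_candidate(sent, 10, 16, "L", "dep_lexical")

kt = tree_kernel(a.dep_ft, b.dep_ft, lam=0.4)
kp = poly_kernel(a.lexical, b.lexical, d=2)
print(f"raw tree kernel (lambda=0.4): {kt:.4f}   "
      f"(weighted count of common subtree fragments)")
print(f"raw polynomial kernel (d=2):  {kp:.1f}   "
      f"((shared features + 1)^2)")

for gamma in (0.0, 0.3, 1.0):
    p = KernelParams(gamma_mix=gamma, mode="dep_lexical")
    print(f"composite kernel, gamma={gamma}: {composite(a, b, p):.4f}")
print()
print("gamma=0 is the normalized polynomial kernel alone, gamma=1 the")
print("normalized tree kernel alone; intermediate gamma blends lexical")
print("and structured-syntactic similarity.")
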