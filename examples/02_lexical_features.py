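"""Lexical featurization of one (cue, candidate) pair.

Reproduces the published feature table for candidate "regulation"
(token 16) and cue "potentially" (token 10): 8 window templates at
offsets -3..3 plus the token distance, 57 named binary features.
"""
from hedgescope import lexical_features
from hedgescope.fixtures_synth import sentence1_fixture

sent = sentence1_fixture().sentence
vec = lexical_features(sent, cue_anchor=10, cand=16)
feats = dict(item.split("=", 1) for item in vec.items)

for template in ("CandidateToken", "CandidatePos", "HedgeToken",
                 "HedgeStem"):
    row = [feats[f"{template}({i})"] for i in range(-3, 4)]
    print(f"{template:15s}", " ".join(f"{v:>12s}" for v in row))
print("Distance       ", feats["Distance"])
print()
print(f"{len(vec.items)} named features; out-of-range window positions"
      " carry the value 'null'.  These vectors feed the degree-2"
      " polynomial kernel (dot product = shared-feature count).")
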