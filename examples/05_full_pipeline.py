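"""End-to-end run on a seeded synthetic corpus.

Generates 100 annotated sentences, trains the F- and L-scope kernel SVMs
with dependency-based candidate selection, predicts scopes and scores
them, then contrasts the instance balance with the all-tokens baseline.
Takes ~15 s.
"""
from hedgescope import KernelParams, SynthParams, synthetic_corpus
from hedgescope.pipeline import (RunConfig, build_side_instances,
                                 predict_pipeline, train_pipeline)

corpus = synthetic_corpus(SynthParams(n_sentences=100, seed=11))
config = RunConfig(method="dcbs", mode="phrase_dep_lexical",
                   kernel=KernelParams(gamma_mix=0.3), C=1.0, seed=11)

model = train_pipeline(corpus, config)
for side, stats in model.train_stats.items():
    print(f"{side}-scope training instances: {stats.positives} positives, "
          f"{stats.negatives} negatives (ratio {stats.ratio})")
for side in ("F", "L"):
    ttb = build_side_instances(corpus, side, "ttb", config.mode).stats()
    print(f"{side}-scope all-tokens baseline ratio: {ttb.ratio}")

report = predict_pipeline(model, corpus).report
print(f"tag-level F1: F-scope {report.tag['F'].f1:.3f}, "
      f"L-scope {report.tag['L'].f1:.3f}")
print(f"sentence-level exact-match F1 (in-sample): "
      f"{report.sentence.f1:.3f}")
print()
print("Dependency-based selection cuts the negative:positive ratio to")
print("roughly a third of the baseline's while keeping every gold")
print("boundary reachable on noise-free parses.")
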