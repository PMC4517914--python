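"""End-to-end orchestration: ingest -> candidates -> features -> SVMs ->
postprocessing -> evaluation.

The library-level entry points work on lists of annotated
:class:`~hedgescope.types.Sentence` objects:

* :func:`build_side_instances` - candidate selection + featurization for
  one side under one method (dcbs or ttb);
* :func:`train_pipeline` - trains the F and L classifiers and returns a
  :class:`PipelineModel` with instance statistics;
* :func:`predict_pipeline` - classifies candidates, resolves one scope
  per cue, and (when gold scopes are present) produces tag-level and
  sentence-level reports.

File-based wrappers (:func:`run_train`, :func:`run_predict`,
:func:`load_corpus`) read the corpus formats and write a manifest with a
config hash so reruns are verifiably identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from . import corpus_io
from .dcbs import (CandidateSet, LabeledCandidate, label_candidates,
                   select_candidates, ttb_candidates)
from .errors import AlignmentError, ConfigError
from .evaluate import PRF, InstanceStats, instance_stats, sentence_level, tag_level
from .featurize import CandidateInstance, Mode, featurize_candidate
from .kernels import KernelParams
from .postprocess import BoundaryHits, resolve
from .scope_model import ScopeClassifier, predict, train
from .types import ScopeSpan, Sentence

log = logging.getLogger("hedgescope")

Method = Literal["dcbs", "ttb"]
SIDES = ("F", "L")


@dataclass
class RunConfig:
    """A reproducible pipeline run description."""

    method: Method = "dcbs"
    mode: Mode = "phrase_dep_lexical"
    kernel: KernelParams = field(default_factory=KernelParams)
    C: float = 1.0
    seed: int = 0
    trim_final_punct: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("dcbs", "ttb"):
            raise ConfigError(f"unknown method {self.method!r}")
        self.kernel.mode = self.mode

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kp = d.get("kernel", {})
        return cls(method=d.get("method", "dcbs"),
                   mode=d.get("mode", "phrase_dep_lexical"),
                   kernel=KernelParams(**{**kp, "mode":
                                          d.get("mode", "phrase_dep_lexical")}),
                   C=float(d.get("C", 1.0)), seed=int(d.get("seed", 0)),
                   trim_final_punct=bool(d.get("trim_final_punct", False)))


def candidates_for(s: Sentence, cue_anchor: int, side: str,
                   method: Method) -> CandidateSet:
    if method == "ttb":
        return ttb_candidates(s.n, cue_anchor, side)
    if s.deptree is None:
        raise ConfigError(
            f"method dcbs needs dependency trees (sentence {s.sent_id!r})")
    return select_candidates(s.deptree, cue_anchor, side,
                             punct_mask=s.punct_mask())


@dataclass
class SideInstances:
    """Labeled featurized instances for one side, with drop accounting."""

    side: str
    instances: list[CandidateInstance]
    dropped: int
    per_cue: list[tuple[Sentence, int, list[LabeledCandidate]]]

    def stats(self) -> InstanceStats:
        return instance_stats([self.per_cue_labels(i)
                               for i in range(len(self.per_cue))],
                              dropped=self.dropped)

    def per_cue_labels(self, i: int) -> list[LabeledCandidate]:
        return self.per_cue[i][2]


def build_side_instances(sentences: Sequence[Sentence], side: str,
                         method: Method, mode: Mode,
                         labeled: bool = True) -> SideInstances:
    """Select, label and featurize candidates for every cue in the corpus."""
    instances: list[CandidateInstance] = []
    dropped = 0
    per_cue: list[tuple[Sentence, int, list[LabeledCandidate]]] = []
    for s in sentences:
        for cue in s.cues:
            cands = candidates_for(s, cue.anchor, side, method)
            gold = s.scopes.get(cue.anchor)
            if labeled:
                if gold is None:
                    raise ConfigError(
                        f"sentence {s.sent_id!r} lacks a gold scope for "
                        f"cue {cue.anchor}")
                labs, was_dropped = label_candidates(cands, gold)
                dropped += int(was_dropped)
            else:
                labs = [LabeledCandidate(i, -1) for i in cands.candidates]
            per_cue.append((s, cue.anchor, labs))
            for lab in labs:
                instances.append(featurize_candidate(
                    s, cue.anchor, lab.index, side, mode,
                    label=lab.label if labeled else None))
    return SideInstances(side=side, instances=instances, dropped=dropped,
                         per_cue=per_cue)


@dataclass
class PipelineModel:
    """The trained F and L classifiers plus training statistics."""

    config: RunConfig
    classifiers: dict[str, ScopeClassifier]
    train_stats: dict[str, InstanceStats]

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "config_digest": self.config.digest(),
            "train_stats": {
                side: dataclasses.asdict(st) | {"ratio": st.ratio}
                for side, st in self.train_stats.items()
            },
        }


def train_pipeline(sentences: Sequence[Sentence],
                   config: RunConfig) -> PipelineModel:
    """Train both boundary classifiers on an annotated corpus."""
    classifiers: dict[str, ScopeClassifier] = {}
    stats: dict[str, InstanceStats] = {}
    for side in SIDES:
        side_inst = build_side_instances(
            sentences, side, config.method, config.mode)
        stats[side] = side_inst.stats()
        log.info("side %s: %d instances (%s, dropped %d)", side,
                 len(side_inst.instances), stats[side].ratio,
                 side_inst.dropped)
        classifiers[side] = train(side_inst.instances, config.kernel,
                                  C=config.C, side=side)
    return PipelineModel(config=config, classifiers=classifiers,
                         train_stats=stats)


@dataclass
class EvalReport:
    """Per-side tag-level scores plus sentence-level exact-match scores."""

    tag: dict[str, PRF]
    sentence: PRF
    dropped: dict[str, int]

    def to_dict(self) -> dict:
        def prf(p: PRF) -> dict:
            return {"precision": p.precision, "recall": p.recall,
                    "f1": p.f1, "tp": p.tp, "fp": p.fp, "fn": p.fn}
        return {"tag_level": {s: prf(p) for s, p in self.tag.items()},
                "sentence_level": prf(self.sentence),
                "dropped": dict(self.dropped)}


@dataclass
class PipelinePredictions:
    predictions: list[corpus_io.Prediction]
    report: Optional[EvalReport]


def predict_pipeline(model: PipelineModel,
                     sentences: Sequence[Sentence]) -> PipelinePredictions:
    """Classify candidates, resolve one scope per cue, optionally score."""
    config = model.config
    has_gold = all(cue.anchor in s.scopes
                   for s in sentences for cue in s.cues)
    hits_by_cue: dict[tuple[str, int], dict[str, list[int]]] = {}
    tag_pairs: dict[str, list[tuple[int, int]]] = {s: [] for s in SIDES}
    dropped: dict[str, int] = {}

    for side in SIDES:
        side_inst = build_side_instances(
            sentences, side, config.method, config.mode, labeled=has_gold)
        dropped[side] = side_inst.dropped
        preds = predict(model.classifiers[side], side_inst.instances)
        k = 0
        for s, anchor, labs in side_inst.per_cue:
            cue_hits = hits_by_cue.setdefault(
                (s.sent_id, anchor), {"F": [], "L": []})
            for lab in labs:
                score, plabel = preds[k]
                k += 1
                if plabel == 1:
                    cue_hits[side].append(lab.index)
                if has_gold:
                    tag_pairs[side].append((lab.label, plabel))

    predictions: list[corpus_io.Prediction] = []
    gold_spans: list[ScopeSpan] = []
    pred_spans: list[ScopeSpan] = []
    for s in sentences:
        for c_i, cue in enumerate(s.cues):
            hits = hits_by_cue.get((s.sent_id, cue.anchor), {"F": [], "L": []})
            span = resolve(
                BoundaryHits(tuple(sorted(hits["F"])),
                             tuple(sorted(hits["L"]))),
                cue, s, trim_final_punct=config.trim_final_punct)
            predictions.append((s.sent_id, f"c{c_i}", span))
            if has_gold:
                gold_spans.append(s.scopes[cue.anchor])
                pred_spans.append(span)

    report = None
    if has_gold:
        report = EvalReport(
            tag={side: tag_level(tag_pairs[side], dropped=dropped[side])
                 for side in SIDES},
            sentence=sentence_level(gold_spans, pred_spans),
            dropped=dropped)
    return PipelinePredictions(predictions=predictions, report=report)


# ---------------------------------------------------------------------------
# File-based corpus assembly

def load_corpus(inline_path: Optional[Path] = None,
                conllx_path: Optional[Path] = None,
                tagger_path: Optional[Path] = None,
                ptb_path: Optional[Path] = None) -> list[Sentence]:
    """Assemble Sentences from parallel annotation files.

    The inline file (one tagged sentence per line) provides tokens, cues
    and gold scopes; CoNLL-X, tagger TSV and bracketed-tree files are
    merged in by sentence position and must align token-for-token.
    """
    if inline_path is None:
        raise ConfigError("an inline-annotated sentence file is required")
    sentences: list[Sentence] = []
    with open(inline_path) as fh:
        for i, line in enumerate(fh):
            if line.strip():
                sentences.append(corpus_io.parse_inline(line.strip(),
                                                        sent_id=f"s{i}"))

    def check_len(kind: str, count: int) -> None:
        if count != len(sentences):
            raise AlignmentError(
                f"{kind} file has {count} sentences, inline file has "
                f"{len(sentences)}")

    if tagger_path is not None:
        blocks = corpus_io.read_tagger_tsv(open(tagger_path).read())
        check_len("tagger", len(blocks))
        for s, rows in zip(sentences, blocks):
            corpus_io.apply_tagger_rows(s, rows)
    if conllx_path is not None:
        trees = corpus_io.read_conllx(open(conllx_path).read())
        check_len("CoNLL-X", len(trees))
        for s, tree in zip(sentences, trees):
            corpus_io.attach_conllx(s, tree)
    if ptb_path is not None:
        trees_p = corpus_io.read_ptb(open(ptb_path).read())
        check_len("phrase-tree", len(trees_p))
        for s, pt in zip(sentences, trees_p):
            pt.check_alignment(s.tokens)
            s.phrasetree = pt
    return sentences


def run_train(sentences: Sequence[Sentence], config: RunConfig,
              out_dir: Path) -> PipelineModel:
    """Train, then write model files and a manifest under ``out_dir``."""
    from .scope_model import save_model
    model = train_pipeline(sentences, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for side, clf in model.classifiers.items():
        with open(out_dir / f"model_{side}.pkl", "wb") as fh:
            save_model(fh, clf)
    (out_dir / "manifest.json").write_text(
        json.dumps(model.manifest(), indent=2, sort_keys=True) + "\n")
    return model


def run_predict(model: PipelineModel, sentences: Sequence[Sentence],
                out_dir: Path) -> PipelinePredictions:
    """Predict, then write the prediction TSV and optional report JSON."""
    result = predict_pipeline(model, sentences)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "predictions.tsv", "w") as fh:
        corpus_io.write_predictions(fh, result.predictions)
    if result.report is not None:
        (out_dir / "report.json").write_text(
            json.dumps(result.report.to_dict(), indent=2, sort_keys=True)
            + "\n")
    return result
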