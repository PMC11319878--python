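"""Precision / recall / F1 scoring for entity extraction.

A true positive is an exact match of character span and ``group::attribute``
label between a predicted and a gold mention (strict matching, no partial
credit).  Macro scores are the unweighted means over the labels present in
the gold annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ontology import AnnotatedCriterion


class EvaluationError(ValueError):
    """Predicted and gold annotations do not refer to the same criteria."""


@dataclass
class LabelScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    per_label: dict[str, LabelScore] = field(default_factory=dict)
    gold_labels: list[str] = field(default_factory=list)

    def _macro(self, attr: str) -> float:
        labs = self.gold_labels
        if not labs:
            return 0.0
        return sum(getattr(self.per_label[lab], attr) for lab in labs) / len(labs)

    @property
    def macro_precision(self) -> float:
        return self._macro("precision")

    @property
    def macro_recall(self) -> float:
        return self._macro("recall")

    @property
    def macro_f1(self) -> float:
        return self._macro("f1")

    def summary(self) -> str:
        lines = [f"{'label':40s} {'P':>6s} {'R':>6s} {'F1':>6s} {'TP':>4s} {'FP':>4s} {'FN':>4s}"]
        for lab in sorted(self.per_label):
            s = self.per_label[lab]
            lines.append(
                f"{lab:40s} {s.precision:6.3f} {s.recall:6.3f} {s.f1:6.3f} "
                f"{s.tp:4d} {s.fp:4d} {s.fn:4d}"
            )
        lines.append(
            f"{'macro (over gold labels)':40s} {self.macro_precision:6.3f} "
            f"{self.macro_recall:6.3f} {self.macro_f1:6.3f}"
        )
        return "\n".join(lines)


def _mention_keys(criterion: AnnotatedCriterion) -> set[tuple[int, int, str]]:
    return {(m.start, m.end, m.label) for m in criterion.mentions}


def evaluate(
    predicted: list[AnnotatedCriterion], gold: list[AnnotatedCriterion]
) -> EvalReport:
    """Score predicted against gold annotations over the same criteria set.

    Criteria are aligned positionally and must agree on ``trial_id``.
    """
    if len(predicted) != len(gold):
        raise EvaluationError(
            f"{len(predicted)} predicted criteria vs {len(gold)} gold"
        )
    report = EvalReport()

    def score(lab: str) -> LabelScore:
        return report.per_label.setdefault(lab, LabelScore())

    gold_labels: set[str] = set()
    for p, g in zip(predicted, gold):
        if p.trial_id != g.trial_id:
            raise EvaluationError(
                f"criterion id mismatch: {p.trial_id!r} vs {g.trial_id!r}"
            )
        pk = _mention_keys(p)
        gk = _mention_keys(g)
        gold_labels.update(lab for _, _, lab in gk)
        for key in pk & gk:
            score(key[2]).tp += 1
        for key in pk - gk:
            score(key[2]).fp += 1
        for key in gk - pk:
            score(key[2]).fn += 1
    report.gold_labels = sorted(gold_labels)
    return report


def evaluate_corpus(model, gold: list[AnnotatedCriterion]) -> EvalReport:
    """Run a tagger over a gold corpus and score its mentions."""
    from .ontology import AnnotatedCriterion as AC

    predicted = []
    for g in gold:
        _, mentions = model.predict_criterion(g)
        predicted.append(AC(g.trial_id, g.section, g.text, mentions, []))
    return evaluate(predicted, gold)
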