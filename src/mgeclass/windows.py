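"""Group routing, non-overlapping window scanning, and score aggregation.

Sequences up to 1,200 bp go straight to the model of their length group.
Longer sequences are cut into contiguous non-overlapping windows of
1,200 bp (the final window keeps whatever remains), each window is
scored by the model for its own length, and the sequence score is the
window-length-weighted average. A 2,500 bp sequence therefore yields
windows [0,1200), [1200,2400), [2400,2500) routed to models C, C, A
with weights 1200/2500, 1200/2500, 100/2500.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fragments import CLASSES, DnaFragment, ScoreTriple
from .model import GroupModel

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 1200
MIN_FRAGMENT_LENGTH = 100  # whole sequences below this are skipped


@dataclass
class Window:
    start: int  # 0-based, half-open
    end: int
    group: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowPlan:
    total_length: int
    windows: list[Window]

    @property
    def weights(self) -> list[float]:
        return [w.length / self.total_length for w in self.windows]


@dataclass
class Prediction:
    id: str
    length: int
    scores: ScoreTriple
    label: str
    threshold: float


def select_group_for_length(length: int) -> str:
    """Model group for a fragment/window length.

    Boundaries are closed on the upper end of the lower group; windows
    shorter than 100 bp are routed to group A.
    """
    if length < 1:
        raise ValueError(f"length must be positive, got {length}")
    if length <= 400:
        return "A"
    if length <= 800:
        return "B"
    if length <= 1200:
        return "C"
    raise ValueError(
        f"length {length} exceeds {WINDOW_LENGTH}; split into windows first")


def plan_windows(length: int) -> WindowPlan:
    """Contiguous non-overlapping windows of 1,200 bp covering [0, length)."""
    if length < 1:
        raise ValueError(f"length must be positive, got {length}")
    windows = []
    for start in range(0, length, WINDOW_LENGTH):
        end = min(start + WINDOW_LENGTH, length)
        windows.append(Window(start, end, select_group_for_length(end - start)))
    return WindowPlan(total_length=length, windows=windows)


def label_with_threshold(scores: ScoreTriple, threshold: float = 0.0) -> str:
    """Argmax class, prefixed "uncertain " when the top score falls below
    the threshold. Threshold 0 never yields an uncertain label."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    cls = scores.argmax_class()
    if scores.max_score() < threshold:
        return f"uncertain {cls}"
    return cls


def aggregate_scores(window_scores: list[ScoreTriple],
                     weights: list[float]) -> ScoreTriple:
    arr = np.array([s.as_tuple() for s in window_scores], dtype=np.float64)
    agg = np.asarray(weights, dtype=np.float64) @ arr
    return ScoreTriple(*map(float, agg))


def predict_sequence(models: dict[str, GroupModel], fragment: DnaFragment,
                     threshold: float = 0.0) -> Prediction | None:
    """Score one fragment end to end; returns None (with a logged warning)
    for whole fragments shorter than 100 bp."""
    preds = predict_many(models, [fragment], threshold=threshold)
    return preds[0] if preds else None


def predict_many(models: dict[str, GroupModel], fragments: list[DnaFragment],
                 threshold: float = 0.0, batch_size: int = 256
                 ) -> list[Prediction]:
    """Score fragments, batching all windows of a group together.

    Fragments shorter than 100 bp are skipped with a warning; output
    order follows input order of the retained fragments.
    """
    plans: list[tuple[DnaFragment, WindowPlan]] = []
    by_group: dict[str, list[str]] = {"A": [], "B": [], "C": []}
    slots: list[list[tuple[str, int]]] = []  # per fragment: (group, pos)
    for frag in fragments:
        if len(frag) < MIN_FRAGMENT_LENGTH:
            logger.warning(
                "skipping %s: length %d < minimum %d",
                frag.id, len(frag), MIN_FRAGMENT_LENGTH)
            continue
        plan = plan_windows(len(frag))
        refs = []
        for win in plan.windows:
            refs.append((win.group, len(by_group[win.group])))
            by_group[win.group].append(frag.seq[win.start:win.end])
        plans.append((frag, plan))
        slots.append(refs)

    scored: dict[str, np.ndarray] = {}
    for group, seqs in by_group.items():
        if not seqs:
            continue
        if group not in models:
            raise ValueError(f"no model supplied for required group {group}")
        scored[group] = models[group].predict_proba(seqs, batch_size=batch_size)

    out = []
    for (frag, plan), refs in zip(plans, slots):
        window_scores = [ScoreTriple(*map(float, scored[g][pos]))
                         for g, pos in refs]
        agg = aggregate_scores(window_scores, plan.weights)
        out.append(Prediction(id=frag.id, length=len(frag), scores=agg,
                              label=label_with_threshold(agg, threshold),
                              threshold=threshold))
    return out
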