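"""Human-in-the-loop active learning for atom-to-atom mapping.

One iteration = sample -> label -> update template library -> train ->
predict the whole pool -> classify confidence.  The first iteration samples
uniformly at random; later iterations sample one reaction per uncertain
template, most popular template first (wrapping around when templates run
out before ``k``).  From the second iteration the training set is augmented
with confident predictions (up to ``per_template`` per verified template,
split 9:1 into train/validation); human-labeled reactions always stay in
the training set.

The labeling oracle is a callable ``record -> AtomMapping``; templates
extracted from oracle labels enter the library as human-verified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .mapping import AtomMapping, DecodeError, decode_greedy
from .model import AtomMapper
from .reaction_io import ReactionRecord
from .templates import (
    NullReactionError,
    TemplateLibrary,
    classify_confidence,
    extract_elrt,
    update_library,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LabelingOracle",
    "GroundTruthOracle",
    "Prediction",
    "LoopState",
    "random_sample",
    "active_sample",
    "augment_training_set",
    "run_iteration",
    "run_loop",
]


class LabelingOracle(Protocol):
    def __call__(self, record: ReactionRecord) -> AtomMapping: ...


class GroundTruthOracle:
    """Oracle backed by known gold mappings (the synthetic generator's)."""

    def __init__(self, gold: dict[str, AtomMapping]):
        self._gold = dict(gold)

    def __call__(self, record: ReactionRecord) -> AtomMapping:
        return self._gold[record.reaction_id]


@dataclass
class Prediction:
    mapping: Optional[AtomMapping]
    template_pattern: Optional[str]
    confident: bool


@dataclass
class LoopState:
    """Accumulated state across iterations.

    ``labeled`` only grows; the library's verified-entry count is
    non-decreasing; ``stats_history`` records per-iteration
    ``(iteration, n_labeled, template_count, coverage)``.
    """

    pool: list[ReactionRecord]
    iteration: int = 0
    labeled: list[tuple[ReactionRecord, AtomMapping]] = field(default_factory=list)
    labeled_ids: set[str] = field(default_factory=set)
    library: TemplateLibrary = field(default_factory=TemplateLibrary)
    model: Optional[AtomMapper] = None
    predictions: dict[str, Prediction] = field(default_factory=dict)
    stats_history: list[dict] = field(default_factory=list)

    def coverage(self) -> float:
        verified = self.library.verified_patterns()
        n_conf = sum(
            1
            for p in self.predictions.values()
            if p.template_pattern is not None and p.template_pattern in verified
        )
        return n_conf / len(self.pool) if self.pool else 0.0


def random_sample(
    pool: Sequence[ReactionRecord], k: int, seed: int
) -> list[ReactionRecord]:
    """Uniform sample without replacement, deterministic given ``seed``."""
    if k > len(pool):
        raise ValueError(f"cannot sample {k} from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[int(i)] for i in idx]


def active_sample(
    uncertain: Sequence[tuple[ReactionRecord, str]],
    k: int,
    seed: int = 0,
) -> list[ReactionRecord]:
    """One reaction per uncertain template, most-populated template first.

    Templates are ranked by reaction count (descending, ties by pattern
    string); if the unique templates are exhausted before ``k`` reactions,
    further passes take a second (third, ...) reaction per template in the
    same rank order.  Within a template, reactions are drawn in a
    seed-deterministic shuffled order of their ids.
    """
    by_template: dict[str, list[ReactionRecord]] = {}
    for record, pattern in uncertain:
        by_template.setdefault(pattern, []).append(record)
    if not by_template:
        return []
    rng = np.random.default_rng(seed)
    ranked = sorted(by_template, key=lambda p: (-len(by_template[p]), p))
    queues = {}
    for pattern in ranked:
        records = sorted(by_template[pattern], key=lambda r: r.reaction_id)
        order = rng.permutation(len(records))
        queues[pattern] = [records[int(i)] for i in order]
    sampled: list[ReactionRecord] = []
    depth = 0
    while len(sampled) < k:
        took_any = False
        for pattern in ranked:
            if len(sampled) >= k:
                break
            queue = queues[pattern]
            if depth < len(queue):
                sampled.append(queue[depth])
                took_any = True
        if not took_any:
            break  # every template exhausted
        depth += 1
    return sampled


def augment_training_set(
    predictions: Sequence[tuple[ReactionRecord, Prediction]],
    library: TemplateLibrary,
    labeled: Sequence[tuple[ReactionRecord, AtomMapping]],
    per_template: int = 100,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[
    list[tuple[ReactionRecord, AtomMapping]],
    list[tuple[ReactionRecord, AtomMapping]],
]:
    """Semi-supervised augmentation with confident predictions.

    Up to ``per_template`` confident reactions per verified template are
    sampled and split 9:1 into train/validation; the human-labeled pairs
    are always kept in the training set and never displaced by the split.
    """
    rng = np.random.default_rng(seed)
    labeled_ids = {r.reaction_id for r, _ in labeled}
    verified = library.verified_patterns()
    by_template: dict[str, list[tuple[ReactionRecord, AtomMapping]]] = {}
    for record, pred in predictions:
        if record.reaction_id in labeled_ids:
            continue
        if not pred.confident or pred.mapping is None:
            continue
        if pred.template_pattern in verified:
            by_template.setdefault(pred.template_pattern, []).append(
                (record, pred.mapping)
            )
    augmented: list[tuple[ReactionRecord, AtomMapping]] = []
    for pattern in sorted(by_template):
        group = sorted(by_template[pattern], key=lambda x: x[0].reaction_id)
        if len(group) > per_template:
            idx = rng.choice(len(group), size=per_template, replace=False)
            group = [group[int(i)] for i in sorted(idx)]
        augmented.extend(group)
    order = rng.permutation(len(augmented))
    n_train = int(round(train_fraction * len(augmented)))
    train = list(labeled) + [augmented[int(i)] for i in order[:n_train]]
    val = [augmented[int(i)] for i in order[n_train:]]
    return train, val


def _predict_pool(
    model: AtomMapper,
    pool: Sequence[ReactionRecord],
    library: TemplateLibrary,
) -> dict[str, Prediction]:
    predictions: dict[str, Prediction] = {}
    for record in pool:
        try:
            P = model.predict_proba([record])[0]
            mapping = decode_greedy(
                P, enforce_element_match=model.enforce_element_match
            )
        except (DecodeError, ValueError) as exc:
            logger.warning("prediction failed for %s: %s", record.reaction_id, exc)
            predictions[record.reaction_id] = Prediction(None, None, False)
            continue
        try:
            template = extract_elrt(record, mapping)
            pattern = template.canonical_pattern
            confident = classify_confidence(template, library) == "confident"
        except (NullReactionError, ValueError) as exc:
            logger.debug("template extraction failed for %s: %s",
                         record.reaction_id, exc)
            pattern, confident = None, False
        predictions[record.reaction_id] = Prediction(mapping, pattern, confident)
    return predictions


def run_iteration(
    state: LoopState,
    oracle: LabelingOracle,
    k: int,
    seed: int = 0,
    model_factory: Optional[Callable[[int], AtomMapper]] = None,
    per_template: int = 100,
    labeler: str = "oracle",
) -> LoopState:
    """Execute one full active-learning iteration, mutating ``state``.

    Iteration 1 samples at random; later iterations sample from uncertain
    predictions by template popularity.  Each iteration trains a fresh
    model (the factory receives a derived seed), re-predicts the pool, and
    appends coverage statistics.
    """
    n = state.iteration + 1
    iter_seed = seed + 1000 * n
    unlabeled = [r for r in state.pool if r.reaction_id not in state.labeled_ids]
    if n == 1 or not state.predictions:
        batch = random_sample(unlabeled, min(k, len(unlabeled)), iter_seed)
    else:
        uncertain = [
            (r, state.predictions[r.reaction_id].template_pattern)
            for r in unlabeled
            if r.reaction_id in state.predictions
            and not state.predictions[r.reaction_id].confident
            and state.predictions[r.reaction_id].template_pattern is not None
        ]
        batch = active_sample(uncertain, min(k, len(uncertain)), iter_seed)
        if len(batch) < k and len(unlabeled) > len(batch):
            # top up with random unlabeled reactions (e.g. decode failures)
            batch_ids = {r.reaction_id for r in batch}
            rest = [r for r in unlabeled if r.reaction_id not in batch_ids]
            extra = random_sample(
                rest, min(k - len(batch), len(rest)), iter_seed + 1
            )
            batch.extend(extra)

    new_templates = []
    for record in batch:
        mapping = oracle(record)
        if not mapping.is_total_over(record.n_product_atoms):
            logger.warning(
                "oracle label for %s rejected (not total); record re-queued",
                record.reaction_id,
            )
            continue
        state.labeled.append((record, mapping))
        state.labeled_ids.add(record.reaction_id)
        try:
            new_templates.append((extract_elrt(record, mapping), True))
        except NullReactionError:
            logger.warning("label for %s implies a null reaction",
                           record.reaction_id)
    update_library(state.library, new_templates, iteration=n, labeler=labeler)

    if n >= 2 and state.predictions:
        pred_pairs = [
            (r, state.predictions[r.reaction_id])
            for r in state.pool
            if r.reaction_id in state.predictions
        ]
        train, val = augment_training_set(
            pred_pairs, state.library, state.labeled,
            per_template=per_template, seed=iter_seed,
        )
    else:
        train, val = list(state.labeled), []

    factory = model_factory or (lambda s: AtomMapper(random_state=s))
    model = factory(iter_seed)
    records = [r for r, _ in train]
    mappings = [m for _, m in train]
    validation = ([r for r, _ in val], [m for _, m in val]) if val else None
    model.fit(records, mappings, validation=validation)
    state.model = model
    state.predictions = _predict_pool(model, state.pool, state.library)
    state.iteration = n
    state.stats_history.append(
        {
            "iteration": n,
            "n_labeled": len(state.labeled),
            "template_count": len(state.library.verified_patterns()),
            "coverage": state.coverage(),
        }
    )
    return state


def run_loop(
    pool: Sequence[ReactionRecord],
    oracle: LabelingOracle,
    k: int,
    iterations: int,
    seed: int = 0,
    model_factory: Optional[Callable[[int], AtomMapper]] = None,
    per_template: int = 100,
    coverage_target: Optional[float] = None,
) -> LoopState:
    """Run up to ``iterations`` active-learning iterations.

    Stops early when ``coverage_target`` (fraction of the pool with a
    verified predicted template) is reached.
    """
    state = LoopState(pool=list(pool))
    for _ in range(iterations):
        run_iteration(
            state, oracle, k, seed=seed,
            model_factory=model_factory, per_template=per_template,
        )
        logger.info(
            "iteration %d: %d labeled, %d verified templates, coverage %.3f",
            state.iteration, len(state.labeled),
            len(state.library.verified_patterns()), state.coverage(),
        )
        if coverage_target is not None and state.coverage() >= coverage_target:
            break
    return state
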