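"""Campaign engine: vote-based batch proposal and the iteration loop.

Each iteration: the ensemble votes a batch of unseen conditions, the batch is
observed (via a yield oracle or a human-supplied record file), failures prune
the ensemble, a new generation of members is trained on the target reactions
collected so far, and the generations are concatenated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .ensemble import (
    Ensemble,
    LabeledSet,
    ModelConfig,
    ReactionRecord,
    combine,
    label_records,
    predict_improvement,
    prune_failed,
    train_forest_batch,
)
from .reagent_space import (
    Condition,
    FeaturizationSchema,
    ReagentCatalog,
    build_schema,
    enumerate_space,
    featurize_all,
)

logger = logging.getLogger("atlkit")

#: oracle signature: condition -> assay yield percent (may raise to mark failure)
YieldOracle = Callable[[Condition], float]


@dataclass
class CampaignConfig:
    """Knobs of a closed-loop or human-in-the-loop campaign."""

    batch_size: int = 6
    votes_per_model: int | None = None  # default: batch_size
    n_iterations: int = 3
    model: ModelConfig = field(default_factory=ModelConfig)
    threshold_percent: float = 0.0
    fixed: dict[str, str] | None = None
    seed: int = 0
    allow_repeats: bool = False
    ratchet_threshold: bool = False
    train_window: str = "cumulative"  # or "latest_batch"
    prune_scope: str = "batch"  # or "cumulative"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.n_iterations < 0:
            raise ValueError("batch_size >= 1 and n_iterations >= 0 required")
        if self.votes_per_model is not None and self.votes_per_model < 1:
            raise ValueError("votes_per_model must be >= 1")
        if self.train_window not in ("cumulative", "latest_batch"):
            raise ValueError(f"unknown train_window {self.train_window!r}")
        if self.prune_scope not in ("batch", "cumulative"):
            raise ValueError(f"unknown prune_scope {self.prune_scope!r}")

    @property
    def n_votes(self) -> int:
        return self.votes_per_model or self.batch_size


@dataclass
class VoteTally:
    """Vote counts per candidate condition, with voting-member provenance."""

    counts: dict[Condition, int]
    generations: list[int]
    warning: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def vote_select(
    ensemble: Ensemble,
    candidates: Sequence[Condition],
    schema: FeaturizationSchema,
    catalog: ReagentCatalog,
    n_votes: int,
    batch_size: int,
    exclude: frozenset[Condition] | set[Condition] = frozenset(),
    feature_matrix: np.ndarray | None = None,
) -> tuple[list[Condition], VoteTally]:
    """Query-by-vote batch selection.

    Every member awards one vote to each of its top ``n_votes`` candidates by
    predicted improvement probability (ties inside a member broken by
    enumeration order).  The batch is the ``batch_size`` most-voted
    candidates; tally ties are broken by mean predicted probability across
    members, then by enumeration order.  ``exclude`` removes already-evaluated
    conditions before voting.
    """
    keep = [i for i, c in enumerate(candidates) if c not in exclude]
    if not keep:
        raise ValueError("no candidates remain after exclusion")
    if feature_matrix is None:
        feature_matrix = featurize_all(candidates, schema.substrate_pair, schema, catalog)
    X = feature_matrix[keep]
    pool = [candidates[i] for i in keep]

    # (n_members, n_pool) probabilities
    P = predict_improvement(ensemble, X)
    n_votes = min(n_votes, len(pool))

    votes = np.zeros(len(pool), dtype=int)
    # stable: highest prob first, ties by pool (enumeration) order
    order = np.argsort(-P, axis=1, kind="stable")
    for m in range(P.shape[0]):
        votes[order[m, :n_votes]] += 1

    mean_p = P.mean(axis=0)
    rank = np.lexsort((np.arange(len(pool)), -mean_p, -votes))

    warning = None
    if len(pool) < batch_size:
        warning = f"only {len(pool)} candidates remain (< batch_size {batch_size})"
        logger.warning(warning)
    batch = [pool[i] for i in rank[:batch_size]]
    tally = VoteTally(
        counts={pool[i]: int(votes[i]) for i in np.argsort(-votes, kind="stable") if votes[i] > 0},
        generations=ensemble.generations,
        warning=warning,
    )
    return batch, tally


def stopping_hint(n_varied_reagent_classes: int) -> int:
    """Rule-of-thumb iteration count: one less than the number of varied classes."""
    if n_varied_reagent_classes < 2:
        raise ValueError("need at least 2 varied reagent classes")
    return n_varied_reagent_classes - 1


@dataclass
class CampaignState:
    """Mutable state threaded through iterations of a campaign."""

    catalog: ReagentCatalog
    schema: FeaturizationSchema
    substrate_pair: tuple[str, str]
    config: CampaignConfig
    ensemble: Ensemble
    candidates: list[Condition]
    feature_matrix: np.ndarray
    threshold: float
    history: list[ReactionRecord] = field(default_factory=list)
    proposed: set[Condition] = field(default_factory=set)
    best_so_far: float = 0.0
    iteration: int = 0
    exhausted: bool = False


@dataclass
class CampaignTrace:
    """Per-iteration log plus a terminal summary; JSON-line serializable."""

    entries: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _observe(
    batch: Sequence[Condition],
    oracle: YieldOracle,
    state: CampaignState,
) -> tuple[list[ReactionRecord], list[Condition]]:
    records, missing = [], []
    for c in batch:
        try:
            y = float(oracle(c))
        except Exception:  # oracle failure -> excluded from labeling
            missing.append(c)
            continue
        records.append(
            ReactionRecord(
                substrate_pair=state.substrate_pair,
                condition=c,
                yield_percent=y,
                domain="target",
                iteration=state.iteration,
            )
        )
    return records, missing


def run_iteration(state: CampaignState, oracle: YieldOracle) -> dict:
    """One full cycle: propose -> observe -> prune -> retrain -> combine."""
    cfg = state.config
    state.iteration += 1
    exclude = frozenset(state.proposed) if not cfg.allow_repeats else frozenset()
    remaining = [c for c in state.candidates if c not in exclude]
    if not remaining:
        state.exhausted = True
        return {"iteration": state.iteration, "status": "pool_exhausted"}

    batch, tally = vote_select(
        state.ensemble,
        state.candidates,
        state.schema,
        state.catalog,
        n_votes=cfg.n_votes,
        batch_size=cfg.batch_size,
        exclude=exclude,
        feature_matrix=state.feature_matrix,
    )
    state.proposed.update(batch)

    records, missing = _observe(batch, oracle, state)
    state.history.extend(records)

    failed = [r for r in records if r.yield_percent <= state.threshold]
    size_before = state.ensemble.n_trees
    if failed:
        scope = failed
        if cfg.prune_scope == "cumulative":
            scope = [
                r
                for r in state.history
                if r.domain == "target" and r.yield_percent <= state.threshold
            ]
        Xf = featurize_all(
            [r.condition for r in scope], state.substrate_pair, state.schema, state.catalog
        )
        state.ensemble = prune_failed(state.ensemble, Xf)
    size_after = state.ensemble.n_trees

    # retrain on target data (cumulative by default) and concatenate
    if cfg.train_window == "latest_batch":
        train_records = records
    else:
        train_records = [r for r in state.history if r.domain == "target"]
    if train_records:
        data = label_records(
            train_records, state.threshold, schema=state.schema, catalog=state.catalog
        )
        gen = train_forest_batch(
            data, cfg.model, generation=state.iteration,
            seed=cfg.model.seed + 1000 * state.iteration,
        )
        state.ensemble = combine(state.ensemble, gen)

    best_in_batch = max((r.yield_percent for r in records), default=None)
    if best_in_batch is not None:
        state.best_so_far = max(state.best_so_far, best_in_batch)
    if cfg.ratchet_threshold:
        state.threshold = max(state.threshold, state.best_so_far)

    entry = {
        "iteration": state.iteration,
        "status": "ok" if tally.warning is None else "short_batch",
        "proposed": [c.as_dict() for c in batch],
        "votes": [[c.as_dict(), n] for c, n in tally.counts.items()],
        "observed": [
            {**r.condition.as_dict(), "yield_percent": r.yield_percent} for r in records
        ],
        "missing": [c.as_dict() for c in missing],
        "n_failed": len(failed),
        "trees_before_prune": size_before,
        "trees_after_prune": size_after,
        "ensemble_members": len(state.ensemble),
        "threshold_percent": state.threshold,
        "best_so_far": state.best_so_far,
    }
    logger.info(
        "iteration %d: best_so_far=%.1f%%, trees %d -> %d, members %d",
        state.iteration, state.best_so_far, size_before, size_after,
        len(state.ensemble),
    )
    return entry


def init_campaign(
    source_records: Sequence[ReactionRecord],
    catalog: ReagentCatalog,
    substrate_pair: tuple[str, str],
    config: CampaignConfig,
) -> CampaignState:
    """Train the source ensemble and set up the candidate pool."""
    if not source_records:
        raise ValueError("source records must be non-empty")
    schema = build_schema(catalog, substrate_pair)
    data = label_records(
        source_records, config.threshold_percent, schema=schema, catalog=catalog
    )
    ensemble = train_forest_batch(data, config.model, generation=0, seed=config.model.seed)
    candidates = enumerate_space(catalog, config.fixed)
    X = featurize_all(candidates, substrate_pair, schema, catalog)
    proposed: set[Condition] = set()
    if not config.allow_repeats:
        # known experiments on the same substrate pair are not re-proposed
        proposed = {
            r.condition for r in source_records if r.substrate_pair == tuple(substrate_pair)
        }
    return CampaignState(
        catalog=catalog,
        schema=schema,
        substrate_pair=tuple(substrate_pair),
        config=config,
        ensemble=ensemble,
        candidates=candidates,
        feature_matrix=X,
        threshold=config.threshold_percent,
        history=list(source_records),
        proposed=proposed,
    )


def run_campaign(
    source_records: Sequence[ReactionRecord],
    oracle: YieldOracle,
    catalog: ReagentCatalog,
    substrate_pair: tuple[str, str],
    config: CampaignConfig,
) -> CampaignTrace:
    """Full campaign: source transfer then ``n_iterations`` voting cycles."""
    state = init_campaign(source_records, catalog, substrate_pair, config)
    trace = CampaignTrace()
    trace.entries.append(
        {
            "iteration": 0,
            "status": "source_model",
            "ensemble_members": len(state.ensemble),
            "trees": state.ensemble.n_trees,
            "n_source_records": len(source_records),
            "threshold_percent": state.threshold,
            "candidate_pool": len(state.candidates),
        }
    )
    for _ in range(config.n_iterations):
        entry = run_iteration(state, oracle)
        trace.entries.append(entry)
        if state.exhausted:
            break
    trace.summary = {
        "n_iterations_run": state.iteration,
        "best_so_far": state.best_so_far,
        "threshold_percent": state.threshold,
        "improved": state.best_so_far > config.threshold_percent,
        "ensemble_members": len(state.ensemble),
        "status": "pool_exhausted" if state.exhausted else "completed",
    }
    return trace


def suggest_batch(
    records: Sequence[ReactionRecord],
    catalog: ReagentCatalog,
    substrate_pair: tuple[str, str],
    config: CampaignConfig,
) -> tuple[list[Condition], VoteTally]:
    """Human-in-the-loop proposal from reaction records on disk.

    Source records train generation 0; target records of each recorded
    iteration train one further generation; failures observed in the latest
    target iteration prune the ensemble before voting.
    """
    source = [r for r in records if r.domain == "source"]
    target = [r for r in records if r.domain == "target"]
    state = init_campaign(source, catalog, substrate_pair, config)
    if not config.allow_repeats:
        state.proposed.update(
            r.condition for r in target if r.substrate_pair == tuple(substrate_pair)
        )
    for it in sorted({r.iteration for r in target}):
        batch = [r for r in target if r.iteration == it]
        failed = [r for r in batch if r.yield_percent <= state.threshold]
        if failed:
            Xf = featurize_all(
                [r.condition for r in failed], state.substrate_pair, state.schema,
                state.catalog,
            )
            state.ensemble = prune_failed(state.ensemble, Xf)
        state.history.extend(batch)
        cumulative = [r for r in state.history if r.domain == "target"]
        data = label_records(
            cumulative, state.threshold, schema=state.schema, catalog=state.catalog
        )
        gen = train_forest_batch(
            data, config.model, generation=it, seed=config.model.seed + 1000 * it
        )
        state.ensemble = combine(state.ensemble, gen)
    exclude = frozenset(state.proposed) if not config.allow_repeats else frozenset()
    return vote_select(
        state.ensemble,
        state.candidates,
        state.schema,
        state.catalog,
        n_votes=config.n_votes,
        batch_size=config.batch_size,
        exclude=exclude,
        feature_matrix=state.feature_matrix,
    )
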