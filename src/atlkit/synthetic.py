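"""Synthetic yield landscapes and strategy benchmarking.

Ground-truth landscapes are additive main effects per reagent identifier plus
a sparse set of pairwise interactions, Gaussian observation noise and clipping
to [0, 100].  A :class:`LandscapePair` couples a source landscape to a target
landscape that shares the ligand main effects (the transfer premise) while the
other classes diverge by a configurable amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ensemble import ModelConfig, ReactionRecord, combine, label_records, train_forest_batch
from .loop import CampaignConfig, init_campaign, run_campaign, vote_select
from .reagent_space import (
    Condition,
    ReagentCatalog,
    build_schema,
    enumerate_space,
    featurize_all,
)
from .errors import ValidationError

CLASSES = ("precatalyst", "ligand", "additive", "solvent")


@dataclass
class LandscapeSpec:
    """Scales of the generative model for one landscape pair."""

    effect_scales: dict[str, float] = field(
        default_factory=lambda: {
            # ligand dominates, mirroring the source domain's reactivity driver
            "precatalyst": 5.0,
            "ligand": 15.0,
            "additive": 5.0,
            "solvent": 5.0,
        }
    )
    interaction_density: float = 0.05
    interaction_scale_fraction: float = 0.5
    noise_sd: float = 5.0
    base_yield: float = 30.0
    shared_classes: tuple[str, ...] = ("ligand",)
    shared_fraction: float = 1.0  # 1 = identical shared-class effects
    divergence: float = 1.0  # effect-scale multiplier for redrawn classes

    def validate(self) -> None:
        missing = [c for c in CLASSES if c not in self.effect_scales]
        if missing:
            raise ValidationError(f"effect_scales missing classes: {missing}")
        if not 0.0 <= self.interaction_density <= 1.0:
            raise ValidationError("interaction_density must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValidationError("shared_fraction must be in [0, 1]")
        for c in self.shared_classes:
            if c not in CLASSES:
                raise ValidationError(f"unknown shared class {c!r}")


@dataclass
class SyntheticLandscape:
    """Deterministic ground-truth yield function over the condition space."""

    base_yield: float
    main_effects: dict[str, dict[str, float]]  # class -> id -> effect (pp)
    interactions: dict[tuple[tuple[str, str], tuple[str, str]], float]
    noise_sd: float
    seed: int

    def unclipped(self, condition: Condition) -> float:
        ids = condition.as_dict()
        y = self.base_yield
        for cls in CLASSES:
            y += self.main_effects[cls][ids[cls]]
        for ((c1, i1), (c2, i2)), eff in self.interactions.items():
            if ids[c1] == i1 and ids[c2] == i2:
                y += eff
        return y


def eval_yield(
    landscape: SyntheticLandscape,
    condition: Condition,
    noisy: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Yield percent for one condition; Gaussian noise is added pre-clipping."""
    y = landscape.unclipped(condition)
    if noisy and landscape.noise_sd > 0:
        if rng is None:
            raise ValueError("noisy evaluation requires an rng")
        y += rng.normal(0.0, landscape.noise_sd)
    return float(np.clip(y, 0.0, 100.0))


@dataclass
class LandscapePair:
    source: SyntheticLandscape
    target: SyntheticLandscape
    shared_classes: tuple[str, ...]
    shared_fraction: float


def _descriptor_table(catalog: ReagentCatalog, cls: str) -> dict[str, np.ndarray] | None:
    if cls == "ligand":
        return {x.id: np.asarray(x.descriptors) for x in catalog.ligands}
    if cls == "solvent":
        return {x.id: np.asarray(x.descriptors) for x in catalog.solvents}
    return None


def _draw_effects(
    catalog: ReagentCatalog, spec: LandscapeSpec, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Per-identifier main effects.

    Descriptor-bearing classes (ligand, solvent) get effects that are linear
    in their descriptors plus a small idiosyncratic term -- the structure a
    descriptor-splitting model can learn and transfer.  One-hot classes get
    iid effects.
    """
    out: dict[str, dict[str, float]] = {}
    for cls in CLASSES:
        scale = spec.effect_scales[cls]
        ids = catalog.class_ids(cls)
        desc = _descriptor_table(catalog, cls)
        if desc is None:
            out[cls] = {i: float(rng.normal(0.0, scale)) for i in ids}
        else:
            d = len(next(iter(desc.values())))
            w = rng.normal(size=d)
            w /= np.linalg.norm(w)  # descriptors ~N(0,1): w.x has unit variance
            out[cls] = {
                i: float(scale * (0.8 * w @ desc[i] + 0.2 * rng.normal()))
                for i in ids
            }
    return out


def _draw_interactions(
    catalog: ReagentCatalog, spec: LandscapeSpec, rng: np.random.Generator
) -> dict:
    inter = {}
    pairs = [(a, b) for i, a in enumerate(CLASSES) for b in CLASSES[i + 1 :]]
    for c1, c2 in pairs:
        ids1, ids2 = catalog.class_ids(c1), catalog.class_ids(c2)
        scale = spec.interaction_scale_fraction * np.sqrt(
            spec.effect_scales[c1] * spec.effect_scales[c2]
        )
        for i1 in ids1:
            for i2 in ids2:
                if rng.random() < spec.interaction_density:
                    inter[((c1, i1), (c2, i2))] = float(rng.normal(0.0, scale))
    return inter


def make_landscape_pair(
    catalog: ReagentCatalog, spec: LandscapeSpec, seed: int
) -> LandscapePair:
    """Draw a source/target landscape pair with shared-class main effects.

    Shared-class effects are blended: ``shared_fraction`` of the source effect
    plus the complement of an independent redraw, so 1.0 copies the source
    effects exactly and 0.0 severs the transfer signal.  Non-shared classes
    are redrawn with scale multiplied by ``divergence``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    src_effects = _draw_effects(catalog, spec, rng)
    src_inter = _draw_interactions(catalog, spec, rng)
    fresh_spec = replace(
        spec,
        effect_scales={c: s * spec.divergence for c, s in spec.effect_scales.items()},
    )
    fresh_effects = _draw_effects(catalog, fresh_spec, rng)
    tgt_effects: dict[str, dict[str, float]] = {}
    for cls in CLASSES:
        fresh = fresh_effects[cls]
        if cls in spec.shared_classes:
            f = spec.shared_fraction
            tgt_effects[cls] = {
                i: f * src_effects[cls][i] + (1.0 - f) * fresh[i] for i in fresh
            }
        else:
            tgt_effects[cls] = fresh
    tgt_inter = _draw_interactions(catalog, spec, rng)
    source = SyntheticLandscape(
        base_yield=spec.base_yield, main_effects=src_effects,
        interactions=src_inter, noise_sd=spec.noise_sd, seed=seed,
    )
    target = SyntheticLandscape(
        base_yield=spec.base_yield, main_effects=tgt_effects,
        interactions=tgt_inter, noise_sd=spec.noise_sd, seed=seed,
    )
    return LandscapePair(
        source=source, target=target,
        shared_classes=tuple(spec.shared_classes),
        shared_fraction=spec.shared_fraction,
    )


def source_dataset_from_landscape(
    landscape: SyntheticLandscape,
    catalog: ReagentCatalog,
    substrate_pair: tuple[str, str],
    n: int,
    seed: int,
    ligand_bias: tuple[str, float] | None = None,
    noisy: bool = True,
) -> list[ReactionRecord]:
    """Sample a pre-campaign source dataset from a landscape.

    ``ligand_bias = (ligand_id, p)`` draws the given ligand with probability
    ``p`` and the rest uniformly, mimicking a source dataset dominated by one
    well-performing ligand.  Conditions are sampled without replacement.
    """
    space = enumerate_space(catalog)
    if n > len(space):
        raise ValueError(f"requested {n} records but the space has {len(space)}")
    rng = np.random.default_rng(seed)
    if ligand_bias is None:
        idx = rng.choice(len(space), size=n, replace=False)
        chosen = [space[i] for i in idx]
    else:
        lig, p = ligand_bias
        if lig not in catalog.class_ids("ligand"):
            raise ValidationError(f"unknown bias ligand {lig!r}")
        mask = np.array([c.ligand == lig for c in space])
        n_lig = int(mask.sum())
        weights = np.where(mask, p / n_lig, (1.0 - p) / (len(space) - n_lig))
        weights /= weights.sum()
        idx = rng.choice(len(space), size=n, replace=False, p=weights)
        chosen = [space[i] for i in idx]
    return [
        ReactionRecord(
            substrate_pair=tuple(substrate_pair),
            condition=c,
            yield_percent=eval_yield(landscape, c, noisy=noisy, rng=rng),
            domain="source",
            iteration=0,
        )
        for c in chosen
    ]


# ---------------------------------------------------------------------------
# benchmarking strategies
# ---------------------------------------------------------------------------


def _best_observed(trace) -> list[float]:
    out = []
    best = 0.0
    for e in trace.entries:
        if e["iteration"] == 0 or e.get("status") == "pool_exhausted":
            continue
        best = max(best, max((o["yield_percent"] for o in e["observed"]), default=0.0))
        out.append(best)
    return out


def _make_oracle(
    landscape: SyntheticLandscape, rng: np.random.Generator, noisy: bool
) -> Callable[[Condition], float]:
    def oracle(c: Condition) -> float:
        return eval_yield(landscape, c, noisy=noisy, rng=rng)

    return oracle


def _run_random(space, oracle, cfg, rng) -> list[float]:
    perm = rng.permutation(len(space))
    best, out, k = 0.0, [], 0
    for _ in range(cfg.n_iterations):
        batch = [space[i] for i in perm[k : k + cfg.batch_size]]
        k += cfg.batch_size
        for c in batch:
            best = max(best, oracle(c))
        out.append(best)
    return out


def _run_active(space, oracle, catalog, pair, cfg, rng) -> list[float]:
    """Pure active learning: no source transfer; first batch uniform random."""
    schema = build_schema(catalog, pair)
    X = featurize_all(space, pair, schema, catalog)
    proposed: set[Condition] = set()
    history: list[ReactionRecord] = []
    ensemble = None
    best, out = 0.0, []
    for it in range(1, cfg.n_iterations + 1):
        if ensemble is None:
            remaining = [i for i, c in enumerate(space) if c not in proposed]
            pick = rng.choice(remaining, size=min(cfg.batch_size, len(remaining)), replace=False)
            batch = [space[i] for i in pick]
        else:
            batch, _ = vote_select(
                ensemble, space, schema, catalog,
                n_votes=cfg.n_votes, batch_size=cfg.batch_size,
                exclude=frozenset(proposed), feature_matrix=X,
            )
        proposed.update(batch)
        for c in batch:
            y = oracle(c)
            best = max(best, y)
            history.append(
                ReactionRecord(tuple(pair), c, y, domain="target", iteration=it)
            )
        out.append(best)
        data = label_records(history, cfg.threshold_percent, schema=schema, catalog=catalog)
        gen = train_forest_batch(
            data, cfg.model, generation=it, seed=cfg.model.seed + 1000 * it
        )
        ensemble = gen if ensemble is None else combine(ensemble, gen)
    return out


def _run_transfer_only(source_records, space, oracle, catalog, pair, cfg) -> list[float]:
    """Frozen source model: vote every batch, never prune or retrain."""
    state = init_campaign(source_records, catalog, pair, cfg)
    best, out = 0.0, []
    for _ in range(cfg.n_iterations):
        exclude = frozenset(state.proposed)
        batch, _ = vote_select(
            state.ensemble, state.candidates, state.schema, catalog,
            n_votes=cfg.n_votes, batch_size=cfg.batch_size,
            exclude=exclude, feature_matrix=state.feature_matrix,
        )
        state.proposed.update(batch)
        for c in batch:
            best = max(best, oracle(c))
        out.append(best)
    return out


def _run_oracle_greedy(space, landscape, oracle, cfg) -> list[float]:
    scores = np.array([landscape.unclipped(c) for c in space])
    order = np.argsort(-scores, kind="stable")
    best, out, k = 0.0, [], 0
    for _ in range(cfg.n_iterations):
        for i in order[k : k + cfg.batch_size]:
            best = max(best, oracle(space[i]))
        k += cfg.batch_size
        out.append(best)
    return out


STRATEGIES = ("atl", "random", "active", "transfer", "oracle-greedy")


def benchmark(
    strategies: Sequence[str],
    pair: LandscapePair,
    catalog: ReagentCatalog,
    substrate_pair: tuple[str, str],
    config: CampaignConfig,
    replicates: int,
    seed: int,
    n_source: int = 72,
    noisy: bool = True,
) -> pd.DataFrame:
    """Replicate campaigns per strategy; returns best-so-far per iteration.

    Output columns: strategy, replicate, iteration, best_yield.  Replicate r
    of every strategy shares the same derived seed so comparisons are paired.
    """
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}; choose from {STRATEGIES}")
    space = enumerate_space(catalog, config.fixed)
    full_space = enumerate_space(catalog)
    rows = []
    for rep in range(replicates):
        rep_seed = seed + 7919 * rep
        source_records = source_dataset_from_landscape(
            pair.source, catalog, substrate_pair, n=n_source,
            seed=rep_seed, noisy=noisy,
        )
        for strat in strategies:
            rng = np.random.default_rng(rep_seed + 13 * STRATEGIES.index(strat))
            oracle = _make_oracle(pair.target, rng, noisy=noisy)
            cfg = CampaignConfig(
                batch_size=config.batch_size,
                votes_per_model=config.votes_per_model,
                n_iterations=config.n_iterations,
                model=ModelConfig(
                    n_models=config.model.n_models,
                    trees_per_model=config.model.trees_per_model,
                    max_depth=config.model.max_depth,
                    seed=rep_seed,
                ),
                threshold_percent=config.threshold_percent,
                fixed=config.fixed,
                seed=rep_seed,
            )
            if strat == "atl":
                trace = run_campaign(source_records, oracle, catalog, substrate_pair, cfg)
                curve = _best_observed(trace)
            elif strat == "random":
                curve = _run_random(space, oracle, cfg, rng)
            elif strat == "active":
                curve = _run_active(space, oracle, catalog, substrate_pair, cfg, rng)
            elif strat == "transfer":
                curve = _run_transfer_only(
                    source_records, space, oracle, catalog, substrate_pair, cfg
                )
            else:  # oracle-greedy upper bound
                curve = _run_oracle_greedy(full_space, pair.target, oracle, cfg)
            for it, y in enumerate(curve, start=1):
                rows.append(
                    {"strategy": strat, "replicate": rep, "iteration": it, "best_yield": y}
                )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of best yield per strategy/iteration."""
    g = table.groupby(["strategy", "iteration"])["best_yield"]
    out = g.agg(
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    ).reset_index()
    return out
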