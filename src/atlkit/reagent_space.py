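"""Reagent catalogs, combinatorial condition enumeration and featurization.

A campaign varies four reagent classes -- precatalyst, ligand, additive and
solvent -- over the Cartesian product of the catalog entries.  Conditions are
encoded as fixed-width numeric vectors: continuous physical descriptors for
substrates, ligands and solvents, one-hot blocks for precatalysts, and
independent one-hot blocks for the additive's cation and anion (the designated
``none`` additive encodes as all-zero ion blocks).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ResolutionError, SchemaError, ValidationError

REAGENT_CLASSES = ("precatalyst", "ligand", "additive", "solvent")

#: identifier of the designated no-additive entry
NONE_ADDITIVE = "none"


@dataclass(frozen=True)
class Ligand:
    id: str
    descriptors: tuple[float, ...]


@dataclass(frozen=True)
class Solvent:
    id: str
    descriptors: tuple[float, ...]


@dataclass(frozen=True)
class Additive:
    """A salt additive decomposed into its cation and anion.

    The designated ``none`` additive has empty cation/anion identifiers and
    contributes all-zero ion one-hot blocks.
    """

    id: str
    cation: str | None
    anion: str | None

    @property
    def is_none(self) -> bool:
        return self.cation is None and self.anion is None


@dataclass(frozen=True)
class Substrate:
    id: str
    role: str  # "amine" | "acid"
    descriptors: tuple[float, ...]


@dataclass(frozen=True)
class Condition:
    """One point in the combinatorial reaction-condition space."""

    precatalyst: str
    ligand: str
    additive: str
    solvent: str

    def as_dict(self) -> dict[str, str]:
        return {
            "precatalyst": self.precatalyst,
            "ligand": self.ligand,
            "additive": self.additive,
            "solvent": self.solvent,
        }


def _check_unique(ids: Sequence[str], cls: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {cls} identifier: {i!r}")
        seen.add(i)


def _check_lengths(items, cls: str) -> None:
    lengths = {len(x.descriptors) for x in items}
    if len(lengths) > 1:
        raise SchemaError(
            f"{cls} descriptor vectors have inconsistent lengths: {sorted(lengths)}"
        )


@dataclass
class ReagentCatalog:
    """Inventories of the four varied reagent classes plus substrates.

    Cation and anion vocabularies are derived from the listed additives in
    order of first appearance; mix-and-match closure beyond the listed
    additives is not implied.
    """

    precatalysts: list[str]
    ligands: list[Ligand]
    additives: list[Additive]
    solvents: list[Solvent]
    substrates: list[Substrate]

    def __post_init__(self) -> None:
        _check_unique(self.precatalysts, "precatalyst")
        _check_unique([x.id for x in self.ligands], "ligand")
        _check_unique([x.id for x in self.additives], "additive")
        _check_unique([x.id for x in self.solvents], "solvent")
        _check_unique([x.id for x in self.substrates], "substrate")
        _check_lengths(self.ligands, "ligand")
        _check_lengths(self.solvents, "solvent")
        _check_lengths(self.substrates, "substrate")
        for cls in REAGENT_CLASSES:
            if not self.class_ids(cls):
                raise ValidationError(f"catalog has no {cls} entries")

    # -- vocabulary helpers -------------------------------------------------

    def class_ids(self, reagent_class: str) -> list[str]:
        if reagent_class == "precatalyst":
            return list(self.precatalysts)
        if reagent_class == "ligand":
            return [x.id for x in self.ligands]
        if reagent_class == "additive":
            return [x.id for x in self.additives]
        if reagent_class == "solvent":
            return [x.id for x in self.solvents]
        raise ValueError(f"unknown reagent class {reagent_class!r}")

    @property
    def cations(self) -> list[str]:
        out: list[str] = []
        for a in self.additives:
            if a.cation is not None and a.cation not in out:
                out.append(a.cation)
        return out

    @property
    def anions(self) -> list[str]:
        out: list[str] = []
        for a in self.additives:
            if a.anion is not None and a.anion not in out:
                out.append(a.anion)
        return out

    def ligand(self, lid: str) -> Ligand:
        for x in self.ligands:
            if x.id == lid:
                return x
        raise ResolutionError("ligand", lid)

    def solvent(self, sid: str) -> Solvent:
        for x in self.solvents:
            if x.id == sid:
                return x
        raise ResolutionError("solvent", sid)

    def additive(self, aid: str) -> Additive:
        for x in self.additives:
            if x.id == aid:
                return x
        raise ResolutionError("additive", aid)

    def substrate(self, sid: str) -> Substrate:
        for x in self.substrates:
            if x.id == sid:
                return x
        raise ResolutionError("substrate", sid)

    def resolve(self, condition: Condition) -> None:
        """Raise :class:`ResolutionError` if any identifier is unknown."""
        if condition.precatalyst not in self.precatalysts:
            raise ResolutionError("precatalyst", condition.precatalyst)
        self.ligand(condition.ligand)
        self.additive(condition.additive)
        self.solvent(condition.solvent)


def enumerate_space(
    catalog: ReagentCatalog,
    fixed: Mapping[str, str] | None = None,
) -> list[Condition]:
    """Enumerate the full Cartesian product of free reagent classes.

    ``fixed`` pins chosen classes to a single identifier; the remaining
    classes range over the whole catalog.  Order is lexicographic by
    (precatalyst, ligand, additive, solvent) catalog position, which fixes
    tie-breaking everywhere downstream.
    """
    fixed = dict(fixed or {})
    for cls, ident in fixed.items():
        if cls not in REAGENT_CLASSES:
            raise ValueError(f"unknown reagent class {cls!r} in fixed")
        if ident not in catalog.class_ids(cls):
            raise ResolutionError(cls, ident)
    axes = [
        [fixed[cls]] if cls in fixed else catalog.class_ids(cls)
        for cls in REAGENT_CLASSES
    ]
    return [Condition(*combo) for combo in itertools.product(*axes)]


@dataclass(frozen=True)
class Block:
    name: str
    reagent_class: str
    labels: tuple[str, ...]  # descriptor column names or one-hot identifiers
    kind: str  # "continuous" | "onehot"

    @property
    def width(self) -> int:
        return len(self.labels)


@dataclass
class FeaturizationSchema:
    """Fixed block layout of the condition feature vector.

    Block order: amine-substrate descriptors ++ acid-substrate descriptors ++
    ligand descriptors ++ solvent descriptors ++ precatalyst one-hot ++
    additive-cation one-hot ++ additive-anion one-hot.
    """

    substrate_pair: tuple[str, str]
    blocks: list[Block]
    _index: dict[str, tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        offset = 0
        for b in self.blocks:
            self._index[b.name] = (offset, offset + b.width)
            offset += b.width

    @property
    def width(self) -> int:
        return sum(b.width for b in self.blocks)

    def block_slice(self, name: str) -> slice:
        lo, hi = self._index[name]
        return slice(lo, hi)

    @property
    def class_of_feature(self) -> list[str]:
        out: list[str] = []
        for b in self.blocks:
            out.extend([b.reagent_class] * b.width)
        return out

    def feature_names(self) -> list[str]:
        return [f"{b.name}:{lab}" for b in self.blocks for lab in b.labels]


def build_schema(
    catalog: ReagentCatalog, substrate_pair: tuple[str, str]
) -> FeaturizationSchema:
    """Derive the feature layout for a campaign on ``substrate_pair``."""
    amine = catalog.substrate(substrate_pair[0])
    acid = catalog.substrate(substrate_pair[1])
    n_sub = len(amine.descriptors)
    n_lig = len(catalog.ligands[0].descriptors)
    n_sol = len(catalog.solvents[0].descriptors)

    def dlabels(n: int) -> tuple[str, ...]:
        return tuple(f"d{i}" for i in range(n))

    blocks = [
        Block("substrate_amine", "substrate", dlabels(n_sub), "continuous"),
        Block("substrate_acid", "substrate", dlabels(n_sub), "continuous"),
        Block("ligand", "ligand", dlabels(n_lig), "continuous"),
        Block("solvent", "solvent", dlabels(n_sol), "continuous"),
        Block("precatalyst", "precatalyst", tuple(catalog.precatalysts), "onehot"),
        Block("additive_cation", "additive", tuple(catalog.cations), "onehot"),
        Block("additive_anion", "additive", tuple(catalog.anions), "onehot"),
    ]
    return FeaturizationSchema(substrate_pair=tuple(substrate_pair), blocks=blocks)


def featurize(
    condition: Condition,
    substrate_pair: tuple[str, str],
    schema: FeaturizationSchema,
    catalog: ReagentCatalog,
) -> np.ndarray:
    """Encode one condition as a vector of ``schema.width`` reals."""
    return featurize_all([condition], substrate_pair, schema, catalog)[0]


def featurize_all(
    conditions: Iterable[Condition],
    substrate_pair: tuple[str, str],
    schema: FeaturizationSchema,
    catalog: ReagentCatalog,
) -> np.ndarray:
    """Vectorized featurization of many conditions into an (n, width) matrix."""
    conditions = list(conditions)
    amine = catalog.substrate(substrate_pair[0])
    acid = catalog.substrate(substrate_pair[1])

    lig_desc = {x.id: np.asarray(x.descriptors, dtype=float) for x in catalog.ligands}
    sol_desc = {x.id: np.asarray(x.descriptors, dtype=float) for x in catalog.solvents}
    pre_pos = {p: i for i, p in enumerate(catalog.precatalysts)}
    cat_pos = {c: i for i, c in enumerate(catalog.cations)}
    an_pos = {a: i for i, a in enumerate(catalog.anions)}
    additives = {a.id: a for a in catalog.additives}

    X = np.zeros((len(conditions), schema.width), dtype=float)
    s_am = schema.block_slice("substrate_amine")
    s_ac = schema.block_slice("substrate_acid")
    s_li = schema.block_slice("ligand")
    s_so = schema.block_slice("solvent")
    s_pr = schema.block_slice("precatalyst")
    s_ca = schema.block_slice("additive_cation")
    s_an = schema.block_slice("additive_anion")

    X[:, s_am] = np.asarray(amine.descriptors, dtype=float)
    X[:, s_ac] = np.asarray(acid.descriptors, dtype=float)
    for i, c in enumerate(conditions):
        if c.ligand not in lig_desc:
            raise ResolutionError("ligand", c.ligand)
        if c.solvent not in sol_desc:
            raise ResolutionError("solvent", c.solvent)
        if c.precatalyst not in pre_pos:
            raise ResolutionError("precatalyst", c.precatalyst)
        if c.additive not in additives:
            raise ResolutionError("additive", c.additive)
        X[i, s_li] = lig_desc[c.ligand]
        X[i, s_so] = sol_desc[c.solvent]
        X[i, s_pr.start + pre_pos[c.precatalyst]] = 1.0
        add = additives[c.additive]
        if not add.is_none:
            X[i, s_ca.start + cat_pos[add.cation]] = 1.0
            X[i, s_an.start + an_pos[add.anion]] = 1.0
    return X
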