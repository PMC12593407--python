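"""Packaged example catalog mirroring a realistic campaign's class sizes.

Five nickel precatalysts, 29 bidentate ligands, 14 salt additives (including
the designated "none" entry) and nine solvents: 5 x 29 x 14 x 9 = 18,270
reagent combinations.  Descriptor values are synthetic draws from a fixed
seed -- real physical descriptors live in external tables and are consumed
as given; nothing here depends on their provenance.
"""

from __future__ import annotations

import numpy as np

from .reagent_space import Additive, Ligand, ReagentCatalog, Solvent, Substrate

FIXTURE_SEED = 20240117

PRECATALYSTS = ["NiCl2-dme", "NiBr2-diglyme", "NiI2", "NiBr2", "Ni(acac)2"]

# 14 additives from mix-and-matched cations/anions known to matter, plus none
ADDITIVES = [
    ("none", None, None),
    ("MgCl2", "Mg", "Cl"),
    ("MgBr2", "Mg", "Br"),
    ("MgI2", "Mg", "I"),
    ("NaI", "Na", "I"),
    ("NaBr", "Na", "Br"),
    ("LiCl", "Li", "Cl"),
    ("LiBr", "Li", "Br"),
    ("KBr", "K", "Br"),
    ("KI", "K", "I"),
    ("ZnCl2", "Zn", "Cl"),
    ("ZnBr2", "Zn", "Br"),
    ("TBA-Br", "TBA", "Br"),
    ("TMS-Cl", "TMS", "Cl"),
]

SOLVENTS = ["DMA", "NMP", "THF", "dioxane", "DME", "MeCN", "2-MeTHF", "diglyme", "EtOAc"]

N_LIGANDS = 29
LIGAND_DESC_DIM = 4
SOLVENT_DESC_DIM = 3
SUBSTRATE_DESC_DIM = 2


def example_catalog(seed: int = FIXTURE_SEED) -> ReagentCatalog:
    """Deterministic toy catalog with class sizes (5, 29, 14, 9)."""
    rng = np.random.default_rng(seed)
    ligands = [
        Ligand(f"L{i + 1:02d}", tuple(np.round(rng.normal(0, 1, LIGAND_DESC_DIM), 4)))
        for i in range(N_LIGANDS)
    ]
    solvents = [
        Solvent(name, tuple(np.round(rng.normal(0, 1, SOLVENT_DESC_DIM), 4)))
        for name in SOLVENTS
    ]
    additives = [Additive(*a) for a in ADDITIVES]
    substrates = [
        Substrate("Am1", "amine", tuple(np.round(rng.normal(0, 1, SUBSTRATE_DESC_DIM), 4))),
        Substrate("Am2", "amine", tuple(np.round(rng.normal(0, 1, SUBSTRATE_DESC_DIM), 4))),
        Substrate("Ac1", "acid", tuple(np.round(rng.normal(0, 1, SUBSTRATE_DESC_DIM), 4))),
        Substrate("Ac2", "acid", tuple(np.round(rng.normal(0, 1, SUBSTRATE_DESC_DIM), 4))),
    ]
    return ReagentCatalog(
        precatalysts=list(PRECATALYSTS),
        ligands=ligands,
        additives=additives,
        solvents=solvents,
        substrates=substrates,
    )


def small_catalog(
    n_precatalysts: int = 3,
    n_ligands: int = 10,
    n_additives: int = 6,
    n_solvents: int = 5,
    seed: int = FIXTURE_SEED,
) -> ReagentCatalog:
    """Reduced catalog for fast simulation benchmarks (same structure)."""
    full = example_catalog(seed)
    return ReagentCatalog(
        precatalysts=full.precatalysts[:n_precatalysts],
        ligands=full.ligands[:n_ligands],
        additives=full.additives[:n_additives],
        solvents=full.solvents[:n_solvents],
        substrates=full.substrates,
    )
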