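"""Helpers for analyses of deposited coordinate files (opt-in, needs files).

These wrap the generic IO and analysis primitives with the naming and
selection conventions needed for deposited nucleoporin models: entity
descriptions are normalized to short nucleoporin names, and chains of the
same entity get deterministic copy labels so two deposits can be matched by
``(entity, copy, residue number)``.

Nothing here fetches data; callers must supply local mmCIF paths (see the
``fetch-and-check`` CLI command for the opt-in download).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .composite import RingPlacement, assemble_ring
from .io_formats import AtomicModel, read_model
from .struct_analysis import SuperpositionResult, model_census, superpose

__all__ = [
    "normalize_entity_name",
    "load_deposited_model",
    "nup93_anchor_distances",
    "y_complex_rmsd",
    "nup93_partners_rmsd",
]

#: short names recognized in entity descriptions, longest match first
_NUCLEOPORIN_TOKENS = [
    "Nup205", "Nup188", "Nup160", "Nup155", "Nup133", "Nup107", "Nup98",
    "Nup96", "Nup93", "Nup85", "Nup43", "Nup37", "Seh1", "Sec13", "ELYS",
    "AHCTF1", "TPR",
]

_Y_COMPLEX_ENTITIES = {
    "Nup85", "Seh1", "Nup43", "Nup160", "Nup37", "Sec13", "Nup96",
    "Nup107", "Nup133",
}

_NUP93_PARTNER_ENTITIES = {"Nup93", "Sec13", "Nup96", "Nup160", "Nup107", "Nup133"}


def normalize_entity_name(description: str) -> str:
    """Map a free-text entity description to a short nucleoporin name."""
    for token in _NUCLEOPORIN_TOKENS:
        if re.search(token, description, flags=re.IGNORECASE):
            return "ELYS" if token == "AHCTF1" else token
    return description


def load_deposited_model(path: str | Path) -> AtomicModel:
    """Read an mmCIF deposit, normalizing entity names and assigning
    deterministic copy labels (index among same-entity chains by chain id)."""
    model = read_model(path)
    for chain in model.chains:
        chain.entity_name = normalize_entity_name(chain.entity_name)
    by_entity: dict[str, list] = {}
    for chain in sorted(model.chains, key=lambda c: c.chain_id):
        by_entity.setdefault(chain.entity_name, []).append(chain)
    for chains in by_entity.values():
        for i, chain in enumerate(chains):
            chain.copy_label = str(i)
    return model


def nup93_anchor_distances(
    model: AtomicModel,
    n_sym: int = 8,
    residue_a: int = 152,
    residue_b: int = 180,
) -> tuple[float, float]:
    """(intra-subunit, minimal inter-subunit) Calpha distances between the
    two Nup93 anchor residues, the latter after ideal C8 assembly about +z.

    Assumes the deposit is positioned in the ring frame with the pore axis
    along z (the convention of subunit models aligned into a whole-ring
    reconstruction).
    """
    nup93 = [c for c in model.chains if c.entity_name == "Nup93"]
    if len(nup93) != 1:
        raise ValueError(f"expected exactly one Nup93 chain, found {len(nup93)}")
    chain_id = nup93[0].chain_id
    ca_a = nup93[0].residue(residue_a).ca
    intra = float(np.linalg.norm(ca_a - nup93[0].residue(residue_b).ca))

    ring = assemble_ring(model, RingPlacement.ideal(n_sym))
    anchor = ring.chain(f"{chain_id}_s0").residue(residue_a).ca
    inter = min(
        float(np.linalg.norm(anchor - ring.chain(f"{chain_id}_s{k}").residue(residue_b).ca))
        for k in range(1, n_sym)
    )
    return intra, inter


def _superpose_by_entities(
    model_a: AtomicModel, model_b: AtomicModel, entities: set[str]
) -> SuperpositionResult:
    def subset(model: AtomicModel) -> AtomicModel:
        chains = [c for c in model.chains if c.entity_name in entities]
        return AtomicModel(chains=chains)

    return superpose(subset(model_a), subset(model_b), policy="entity_copy_resnum")


def y_complex_rmsd(nr_model: AtomicModel, cr_model: AtomicModel) -> SuperpositionResult:
    """Calpha RMSD between the two Y complexes of two ring-subunit deposits,
    matched by (entity, copy, residue number); ELYS excluded."""
    return _superpose_by_entities(nr_model, cr_model, _Y_COMPLEX_ENTITIES)


def nup93_partners_rmsd(
    nr_model: AtomicModel, cr_model: AtomicModel
) -> SuperpositionResult:
    """Calpha RMSD between Nup93 plus its stem binding partners in two
    ring-subunit deposits."""
    return _superpose_by_entities(nr_model, cr_model, _NUP93_PARTNER_ENTITIES)


def deposited_census(model: AtomicModel, exclude: set[str] = frozenset({"Nup155"})):
    """Chain/entity/residue census with the linker nucleoporin excluded."""
    return model_census(model, exclude_entities=exclude)
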