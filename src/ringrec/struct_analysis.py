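"""Structural measurements: superposition/RMSD, contacts, linker reach, census.

These operations produce the headline numbers of composite-model analysis:
cross-model Calpha RMSDs, residue-level interface catalogues grouped by
secondary-structure elements, geometric feasibility of disordered linkers,
and chain/entity/residue censuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TransformRT
from .io_formats import AtomicModel

__all__ = [
    "SuperpositionResult",
    "ContactRecord",
    "ReachabilityReport",
    "CensusReport",
    "CA_CONTACT_CUTOFF",
    "ALL_ATOM_CONTACT_CUTOFF",
    "CA_STEP_SPAN",
    "kabsch",
    "superpose",
    "find_contacts",
    "linker_reachability",
    "model_census",
]

#: default contact cutoffs (A)
ALL_ATOM_CONTACT_CUTOFF = 4.5
CA_CONTACT_CUTOFF = 8.0
#: maximal Calpha-Calpha span per residue step (trans peptide), A
CA_STEP_SPAN = 3.8
#: average residue mass used for approximate molecular weight, Da
MEAN_RESIDUE_MASS = 110.0


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    """Least-squares rigid superposition of matched Calpha pairs.

    ``transform`` maps the first (reference) point set onto the second, i.e.
    ``rmsd = sqrt(mean |transform(a_i) - b_i|^2)``.
    """

    transform: TransformRT
    rmsd: float
    n_aligned: int
    per_residue: np.ndarray
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    note: str = ""


def kabsch(points_a: np.ndarray, points_b: np.ndarray) -> TransformRT:
    """Optimal proper rotation + translation mapping ``points_a`` onto
    ``points_b`` in the least-squares sense (reflection never returned)."""
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if len(a) < 3:
        raise ValueError("need at least 3 point pairs")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cb - rotation @ ca
    return TransformRT(rotation=rotation, translation=translation)


def _match_pairs(
    model_a: AtomicModel,
    model_b: AtomicModel,
    policy: str,
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    def keys(model: AtomicModel) -> dict:
        table = {}
        for chain in model.chains:
            for res in chain.residues:
                if policy == "entity_copy_resnum":
                    key = (chain.entity_name, chain.copy_label, res.number)
                elif policy == "chain_resnum":
                    key = (chain.chain_id, res.number)
                else:
                    raise ValueError(f"unknown correspondence policy: {policy}")
                table.setdefault(key, (chain.chain_id, res.number))
        return table

    ka = keys(model_a)
    kb = keys(model_b)
    shared = [k for k in ka if k in kb]
    return [(ka[k], kb[k]) for k in shared]


def superpose(
    model_a: AtomicModel,
    model_b: AtomicModel,
    policy: str = "chain_resnum",
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] | None = None,
) -> SuperpositionResult:
    """Kabsch superposition over matched Calpha atoms.

    ``policy`` selects the correspondence: by ``(entity, copy, residue
    number)``, by ``(chain id, residue number)``, or an explicit ``pairs``
    list of ``((chain, resnum), (chain, resnum))`` tuples.
    """
    if pairs is None:
        pairs = _match_pairs(model_a, model_b, policy)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 matched pairs, got {len(pairs)}")
    coords_a = np.array(
        [model_a.chain(c).residue(r).ca for (c, r), _ in pairs], dtype=float
    )
    coords_b = np.array(
        [model_b.chain(c).residue(r).ca for _, (c, r) in pairs], dtype=float
    )
    transform = kabsch(coords_a, coords_b)
    deviations = np.linalg.norm(transform.apply(coords_a) - coords_b, axis=1)
    rmsd = float(np.sqrt(np.mean(deviations**2)))
    return SuperpositionResult(
        transform=transform,
        rmsd=rmsd,
        n_aligned=len(pairs),
        per_residue=deviations,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactRecord:
    """Residue pair whose minimum inter-atom distance is within the cutoff."""

    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    distance: float
    mode: str
    sse_a: str | None = None
    sse_b: str | None = None


def _gather_atoms(
    model: AtomicModel, chain_ids: list[str], mode: str
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    coords = []
    owners = []
    for cid in chain_ids:
        chain = model.chain(cid)
        for res in chain.residues:
            if mode == "ca":
                coords.append(res.ca)
                owners.append((cid, res.number))
            else:
                for coord in res.atoms.values():
                    coords.append(coord)
                    owners.append((cid, res.number))
    return np.asarray(coords, dtype=float).reshape(-1, 3), owners


def find_contacts(
    model: AtomicModel,
    chain_set_a: list[str] | set[str],
    chain_set_b: list[str] | set[str],
    cutoff: float | None = None,
    mode: str = "all_atom",
) -> list[ContactRecord]:
    """All residue pairs across the two chain sets within ``cutoff``.

    ``mode="all_atom"`` uses the minimum inter-atom distance (default cutoff
    4.5 A); ``mode="ca"`` uses Calpha distances (default 8.0 A).  Spatial
    queries use a KD tree, expected O(n); SSE labels come from the model's
    annotation list when they cover the residue.
    """
    set_a = sorted(chain_set_a)
    set_b = sorted(chain_set_b)
    if set(set_a) & set(set_b):
        raise ValueError("chain sets must be disjoint")
    for cid in set_a + set_b:
        model.chain(cid)  # raises KeyError for unknown chains
    if mode not in ("all_atom", "ca"):
        raise ValueError(f"unknown contact mode: {mode}")
    if cutoff is None:
        cutoff = ALL_ATOM_CONTACT_CUTOFF if mode == "all_atom" else CA_CONTACT_CUTOFF
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    coords_a, owners_a = _gather_atoms(model, set_a, mode)
    coords_b, owners_b = _gather_atoms(model, set_b, mode)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)

    best: dict[tuple, float] = {}
    for ia, neighbors in enumerate(pairs):
        for ib in neighbors:
            dist = float(np.linalg.norm(coords_a[ia] - coords_b[ib]))
            key = (owners_a[ia], owners_b[ib])
            if dist < best.get(key, np.inf):
                best[key] = dist

    records = [
        ContactRecord(
            chain_a=ca,
            residue_a=ra,
            chain_b=cb,
            residue_b=rb,
            distance=dist,
            mode=mode,
            sse_a=model.sse_label_for(ca, ra),
            sse_b=model.sse_label_for(cb, rb),
        )
        for ((ca, ra), (cb, rb)), dist in best.items()
    ]
    records.sort(key=lambda c: (c.chain_a, c.residue_a, c.chain_b, c.residue_b))
    return records


# ---------------------------------------------------------------------------
# linker reachability
# ---------------------------------------------------------------------------


@dataclass
class ReachabilityReport:
    """Geometric feasibility of a disordered linker bridging two anchors."""

    anchor_a: tuple[str, int]
    anchor_b: tuple[str, int]
    distance: float
    n_steps: int
    per_step_span: float
    max_span: float
    feasible: bool


def linker_reachability(
    model: AtomicModel,
    anchor_a: tuple[str, int],
    anchor_b: tuple[str, int],
    per_step_span: float = CA_STEP_SPAN,
    allow_cross_entity: bool = False,
) -> ReachabilityReport:
    """Test whether ``|number_b - number_a|`` residues can bridge the
    Euclidean Calpha distance between the anchors.

    The maximal span is ``n_steps * per_step_span`` (3.8 A per trans-peptide
    Calpha step by default).  Anchors must share an entity unless
    ``allow_cross_entity`` (e.g. when measuring across assembled subunit
    copies of the same entity).
    """
    chain_a = model.chain(anchor_a[0])
    chain_b = model.chain(anchor_b[0])
    if chain_a.entity_name != chain_b.entity_name and not allow_cross_entity:
        raise ValueError(
            f"anchors lie on different entities ({chain_a.entity_name} vs "
            f"{chain_b.entity_name}); pass allow_cross_entity=True to override"
        )
    ca_a = chain_a.residue(anchor_a[1]).ca
    ca_b = chain_b.residue(anchor_b[1]).ca
    distance = float(np.linalg.norm(ca_a - ca_b))
    n_steps = abs(anchor_b[1] - anchor_a[1])
    max_span = n_steps * per_step_span
    return ReachabilityReport(
        anchor_a=anchor_a,
        anchor_b=anchor_b,
        distance=distance,
        n_steps=n_steps,
        per_step_span=per_step_span,
        max_span=max_span,
        feasible=distance <= max_span,
    )


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------


@dataclass
class CensusReport:
    n_chains: int
    n_entities: int
    n_residues: int
    approx_mass_da: float
    per_entity_chains: dict[str, int]


def model_census(
    model: AtomicModel,
    exclude_entities: set[str] | None = None,
    mean_residue_mass: float = MEAN_RESIDUE_MASS,
) -> CensusReport:
    """Count chains, distinct entities and residues (with approximate mass),
    optionally excluding entities by name."""
    exclude = set(exclude_entities or ())
    chains = [c for c in model.chains if c.entity_name not in exclude]
    per_entity: dict[str, int] = {}
    for chain in chains:
        per_entity[chain.entity_name] = per_entity.get(chain.entity_name, 0) + 1
    n_residues = sum(len(c.residues) for c in chains)
    return CensusReport(
        n_chains=len(chains),
        n_entities=len(per_entity),
        n_residues=n_residues,
        approx_mass_da=n_residues * mean_residue_mass,
        per_entity_chains=per_entity,
    )
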