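"""Enumerate and pre-screen candidate anchor mappings in a query structure.

Before any superposition, every way of assigning query residues of compatible
type to the three seed anchors is enumerated, then cheaply filtered by pairwise
Cα distance: a candidate triad survives only if each of its three inter-residue
distances deviates by less than a tolerance (default 3 Å) from the seed's.
When the number of surviving combinations is very large it is capped by
uniform random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .seed_model import SeedSite, allowed_types
from .structure_io import StructureModel

DEFAULT_PRESCREEN_TOL = 3.0  # Å
DEFAULT_MAX_COMBINATIONS = 2000


@dataclass(frozen=True, order=True)
class AnchorMapping:
    """Ordered triple of query positions assigned to the three seed anchors."""

    query_positions: tuple[int, int, int]


def enumerate_mappings(
    query: StructureModel, site: SeedSite, enforce_seed_order: bool = False
) -> list[AnchorMapping]:
    """All type-compatible assignments of query residues to the seed anchors.

    Returns the Cartesian product of per-anchor candidate sets, excluding
    tuples that reuse a query position, in lexicographic order of query
    positions.  With ``enforce_seed_order`` the query positions must follow
    the same sequence rank order as the seed anchor positions, which excludes
    circular permutants.
    """
    candidate_sets = []
    for anchor in site.anchors:
        allowed = allowed_types(site, anchor.position)
        candidates = [r.position for r in query.residues if r.aa3 in allowed]
        if not candidates:
            return []
        candidate_sets.append(candidates)

    if enforce_seed_order:
        seed_rank = np.argsort(np.argsort(site.anchor_positions))

    mappings = []
    for combo in product(*candidate_sets):
        if len(set(combo)) != 3:
            continue
        if enforce_seed_order:
            query_rank = np.argsort(np.argsort(combo))
            if not np.array_equal(query_rank, seed_rank):
                continue
        mappings.append(AnchorMapping(combo))
    mappings.sort()
    return mappings


def mapping_pair_distances(mapping: AnchorMapping, query: StructureModel) -> np.ndarray:
    """Pairwise Cα distances of the mapped query triad, order (1–2, 1–3, 2–3)."""
    a, b, c = (query.residue_at(p).ca for p in mapping.query_positions)
    return np.array(
        [
            np.linalg.norm(a - b),
            np.linalg.norm(a - c),
            np.linalg.norm(b - c),
        ]
    )


def prescreen(
    mapping: AnchorMapping,
    query: StructureModel,
    site: SeedSite,
    tolerance: float = DEFAULT_PRESCREEN_TOL,
) -> bool:
    """True iff every anchor-pair Cα distance deviates strictly less than
    ``tolerance`` from the corresponding seed distance."""
    deviations = np.abs(mapping_pair_distances(mapping, query) - site.anchor_distances)
    return bool(np.all(deviations < tolerance))


def cap_mappings(
    mappings: list[AnchorMapping],
    cap: int = DEFAULT_MAX_COMBINATIONS,
    rng_seed: int = 0,
) -> list[AnchorMapping]:
    """Cap a mapping list by uniform sampling without replacement.

    Lists within the cap are returned unchanged; larger lists are reduced to
    exactly ``cap`` mappings, reproducibly for a fixed ``rng_seed``.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if len(mappings) <= cap:
        return list(mappings)
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(mappings), size=cap, replace=False)
    return [mappings[i] for i in sorted(idx)]
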