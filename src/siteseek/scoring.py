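"""Scoring candidate mappings after superposition; selecting the best per structure.

After the anchor fit, the per-residue distance between a seed residue and its
mapped query residue is the mean of the Cα–Cα and Cβ–Cβ distances (Cα only
when either residue lacks Cβ).  The mapped set comprises the three anchors,
any additional site residues recovered in the query (allowed type, near
enough after the transform), and sequence neighbors around every mapped core
residue regardless of type.  The mapping score is

    score = mean(distances) / n_mapped

so a mapping that recovers more of the site is rewarded: failing to find the
user's additional residues shrinks ``n_mapped`` and inflates the score.  A
structure is accepted when its lowest mapping score falls below the threshold
(default 1 Å).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .candidate_search import AnchorMapping
from .seed_model import SeedSite, allowed_types
from .structure_io import Residue, StructureModel
from .superposition import RigidTransform, fit_transform, paired_anchor_points

DEFAULT_SCORE_THRESHOLD = 1.0  # Å
DEFAULT_MATCH_RADIUS = 2.0  # Å, for locating additional residues

ScoreFormula = Literal["mean_over_n", "sum_over_n"]


@dataclass(frozen=True)
class MappedResidue:
    seed_position: int
    query_position: int
    distance: float  # Å, post-transform
    kind: Literal["anchor", "additional", "neighbor"]


@dataclass
class ScoredMapping:
    mapping: AnchorMapping
    transform: RigidTransform
    mapped: list[MappedResidue]
    n_mapped: int
    score: float


def residue_distance(seed_res: Residue, query_res: Residue, t: RigidTransform) -> float:
    """Post-transform distance between two residues.

    Mean of the Cα–Cα and Cβ–Cβ distances when both residues carry a Cβ,
    otherwise the Cα–Cα distance alone.
    """
    d_ca = float(np.linalg.norm(t.rotation @ query_res.ca + t.translation - seed_res.ca))
    if seed_res.cb is None or query_res.cb is None:
        return d_ca
    d_cb = float(np.linalg.norm(t.rotation @ query_res.cb + t.translation - seed_res.cb))
    return 0.5 * (d_ca + d_cb)


def match_additional(
    query: StructureModel,
    site: SeedSite,
    t: RigidTransform,
    match_radius: float = DEFAULT_MATCH_RADIUS,
    exclude_positions: Sequence[int] = (),
) -> list[MappedResidue]:
    """Locate the site's additional residues in the transformed query.

    Each additional seed residue may claim at most one query residue of an
    allowed type within ``match_radius``; assignment is greedy by ascending
    distance, so when two seed residues compete for one query residue the
    closer pair wins.  Unfound residues are simply absent from the result —
    the score formula penalizes them through the divisor.
    """
    excluded = set(exclude_positions)
    candidates: list[tuple[float, int, int]] = []
    for seed_res in site.additional:
        allowed = allowed_types(site, seed_res.position)
        for query_res in query.residues:
            if query_res.position in excluded or query_res.aa3 not in allowed:
                continue
            d = residue_distance(seed_res, query_res, t)
            if d < match_radius:
                candidates.append((d, seed_res.position, query_res.position))
    candidates.sort()
    matched: list[MappedResidue] = []
    used_seed: set[int] = set()
    used_query: set[int] = set()
    for d, spos, qpos in candidates:
        if spos in used_seed or qpos in used_query:
            continue
        used_seed.add(spos)
        used_query.add(qpos)
        matched.append(MappedResidue(spos, qpos, d, "additional"))
    matched.sort(key=lambda m: m.seed_position)
    return matched


def match_neighbors(
    query: StructureModel,
    site: SeedSite,
    mapped_core: list[MappedResidue],
    t: RigidTransform,
    w: int,
) -> list[MappedResidue]:
    """Sequence neighbors (±1..±w) around every mapped core residue.

    Neighbor pairs follow equal sequence offset (seed s+δ ↔ query q+δ) and
    are scored regardless of amino-acid type; offsets falling outside either
    chain are skipped, and a (seed, query) pair arising from overlapping
    windows — or already present as a core pair — is counted once.
    """
    seed = site.seed_structure
    seen: set[tuple[int, int]] = {(m.seed_position, m.query_position) for m in mapped_core}
    neighbors: list[MappedResidue] = []
    for core in mapped_core:
        for delta in range(-w, w + 1):
            if delta == 0:
                continue
            spos = core.seed_position + delta
            qpos = core.query_position + delta
            if (spos, qpos) in seen:
                continue
            if not (seed.has_position(spos) and query.has_position(qpos)):
                continue
            seen.add((spos, qpos))
            d = residue_distance(seed.residue_at(spos), query.residue_at(qpos), t)
            neighbors.append(MappedResidue(spos, qpos, d, "neighbor"))
    neighbors.sort(key=lambda m: (m.seed_position, m.query_position))
    return neighbors


def combine_score(
    distances: Sequence[float], formula: ScoreFormula = "mean_over_n"
) -> float:
    """Collapse mapped-residue distances into the mapping score.

    ``mean_over_n`` (default): mean of the distances divided once more by the
    number of mapped residues, rewarding larger mapped sets.  ``sum_over_n``:
    the plain mean.
    """
    n = len(distances)
    if n == 0:
        raise ValueError("cannot score an empty mapped set")
    total = float(np.sum(distances))
    if formula == "sum_over_n":
        return total / n
    return total / n / n


def score_mapping(
    query: StructureModel,
    site: SeedSite,
    mapping: AnchorMapping,
    neighbor_window: Optional[int] = None,
    match_radius: float = DEFAULT_MATCH_RADIUS,
    include_cb_in_fit: bool = True,
    formula: ScoreFormula = "mean_over_n",
) -> ScoredMapping:
    """Fit the anchor transform and score one candidate mapping."""
    w = site.neighbor_window if neighbor_window is None else neighbor_window
    fixed, moving = paired_anchor_points(
        site.seed_structure,
        site.anchor_positions,
        query,
        mapping.query_positions,
        include_cb=include_cb_in_fit,
    )
    transform, _ = fit_transform(moving, fixed)

    mapped: list[MappedResidue] = []
    for anchor, qpos in zip(site.anchors, mapping.query_positions):
        d = residue_distance(anchor, query.residue_at(qpos), transform)
        mapped.append(MappedResidue(anchor.position, qpos, d, "anchor"))

    mapped += match_additional(
        query,
        site,
        transform,
        match_radius=match_radius,
        exclude_positions=mapping.query_positions,
    )
    mapped += match_neighbors(query, site, list(mapped), transform, w)

    score = combine_score([m.distance for m in mapped], formula)
    return ScoredMapping(
        mapping=mapping,
        transform=transform,
        mapped=mapped,
        n_mapped=len(mapped),
        score=score,
    )


def select_best(
    scored: Sequence[ScoredMapping], threshold: float = DEFAULT_SCORE_THRESHOLD
) -> Optional[ScoredMapping]:
    """Lowest-score mapping if it beats the threshold (strict <), else None.

    Ties are broken by lexicographically smallest query positions so output
    is deterministic.
    """
    if not scored:
        return None
    best = min(scored, key=lambda s: (s.score, s.mapping.query_positions))
    if best.score < threshold:
        return best
    return None
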