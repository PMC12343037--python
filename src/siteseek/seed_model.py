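"""The search template: anchor residues, additional residues, and substitution rules.

A site is defined by three *anchor* residues of the seed protein — the residues
whose geometry drives the rigid-body fit — plus optional *additional* residues
used in scoring, per-position substitution rules, and a sequence neighbor
window.  If the user supplies fewer than three anchors, the set is completed
from residues spatially close to the first one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Residue, StructureModel

DEFAULT_NEIGHBOR_WINDOW = 4
DEFAULT_AUTO_RADIUS = 10.0  # Å; typical active-site span


class SiteDefinitionError(ValueError):
    """Raised when a site definition is inconsistent with the seed structure."""


@dataclass(frozen=True)
class SubstitutionRule:
    """Amino-acid types accepted at one seed position (always incl. its own)."""

    seed_position: int
    allowed_aa3: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_aa3", frozenset(a.upper() for a in self.allowed_aa3))
        if not self.allowed_aa3:
            raise SiteDefinitionError(
                f"substitution rule for position {self.seed_position} is empty"
            )


@dataclass
class SeedSite:
    """Search template with precomputed anchor geometry.

    ``anchor_distances`` holds the three pairwise Cα–Cα distances in the fixed
    order (1–2, 1–3, 2–3); candidate triads in a query are pre-screened against
    these before any superposition.
    """

    anchors: tuple[Residue, Residue, Residue]
    additional: tuple[Residue, ...]
    substitutions: tuple[SubstitutionRule, ...]
    neighbor_window: int
    anchor_distances: np.ndarray
    seed_structure: StructureModel
    _rules_by_position: dict[int, frozenset[str]] = field(
        default=None, repr=False, compare=False  # type: ignore[arg-type]
    )

    def __post_init__(self) -> None:
        self._rules_by_position = {r.seed_position: r.allowed_aa3 for r in self.substitutions}

    @property
    def anchor_positions(self) -> tuple[int, int, int]:
        return tuple(r.position for r in self.anchors)  # type: ignore[return-value]

    @property
    def additional_positions(self) -> tuple[int, ...]:
        return tuple(r.position for r in self.additional)

    @property
    def site_positions(self) -> tuple[int, ...]:
        return self.anchor_positions + self.additional_positions


def anchor_pair_distances(anchors: tuple[Residue, Residue, Residue]) -> np.ndarray:
    """Pairwise Cα distances of the anchor triple, order (1–2, 1–3, 2–3)."""
    a, b, c = (r.ca for r in anchors)
    return np.array(
        [
            np.linalg.norm(a - b),
            np.linalg.norm(a - c),
            np.linalg.norm(b - c),
        ]
    )


def auto_complete_anchors(
    seed: StructureModel, first_position: int, radius: float = DEFAULT_AUTO_RADIUS
) -> tuple[Residue, Residue, Residue]:
    """Complete an anchor triple from a single given residue.

    The given residue stays first; it is joined by the two residues of
    smallest sequence position whose Cα lies within ``radius`` of its Cα.
    """
    if radius <= 0:
        raise SiteDefinitionError(f"auto-completion radius must be > 0, got {radius}")
    if not seed.has_position(first_position):
        raise SiteDefinitionError(
            f"seed {seed.id} has no residue at position {first_position}"
        )
    first = seed.residue_at(first_position)
    nearby = [
        r
        for r in seed.residues
        if r.position != first_position
        and np.linalg.norm(r.ca - first.ca) <= radius
    ]
    if len(nearby) < 2:
        raise SiteDefinitionError(
            f"auto-completion around position {first_position} found only "
            f"{len(nearby)} residue(s) within {radius} Å; need 2"
        )
    nearby.sort(key=lambda r: r.position)
    return (first, nearby[0], nearby[1])


def build_seed_site(
    seed: StructureModel,
    anchor_positions: list[int],
    additional_positions: list[int] | None = None,
    substitutions: list[SubstitutionRule] | None = None,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
    radius: float = DEFAULT_AUTO_RADIUS,
) -> SeedSite:
    """Assemble a :class:`SeedSite` from user-given positions.

    Three anchors are used verbatim in the given order; with fewer, the set is
    completed by :func:`auto_complete_anchors` around the first position.
    """
    additional_positions = list(additional_positions or [])
    substitutions = list(substitutions or [])
    if not anchor_positions:
        raise SiteDefinitionError("at least one anchor position is required")
    if len(anchor_positions) > 3:
        raise SiteDefinitionError(
            f"at most 3 anchor positions are allowed, got {len(anchor_positions)}"
        )
    if neighbor_window < 0:
        raise SiteDefinitionError("neighbor window must be >= 0")

    all_positions = list(anchor_positions) + additional_positions
    seen: set[int] = set()
    for pos in all_positions:
        if pos in seen:
            raise SiteDefinitionError(f"duplicate site position {pos}")
        seen.add(pos)
        if not seed.has_position(pos):
            raise SiteDefinitionError(f"seed {seed.id} has no residue at position {pos}")

    if len(anchor_positions) == 3:
        anchors = tuple(seed.residue_at(p) for p in anchor_positions)
    else:
        anchors = auto_complete_anchors(seed, anchor_positions[0], radius)
        if len(anchor_positions) == 2:
            # keep both user anchors, complete with the lowest-position third
            second = seed.residue_at(anchor_positions[1])
            completed = [r for r in anchors[1:] if r.position != second.position]
            if not completed:
                raise SiteDefinitionError(
                    f"auto-completion around position {anchor_positions[0]} "
                    "found no third anchor distinct from the given ones"
                )
            anchors = (anchors[0], second, completed[0])
        overlap = set(r.position for r in anchors) & set(additional_positions)
        if overlap:
            raise SiteDefinitionError(
                f"auto-completed anchors overlap additional positions: {sorted(overlap)}"
            )

    site_positions = {r.position for r in anchors} | set(additional_positions)
    for rule in substitutions:
        if rule.seed_position not in site_positions:
            raise SiteDefinitionError(
                f"substitution rule targets position {rule.seed_position}, "
                "which is not an anchor or additional residue"
            )

    return SeedSite(
        anchors=anchors,  # type: ignore[arg-type]
        additional=tuple(seed.residue_at(p) for p in additional_positions),
        substitutions=tuple(substitutions),
        neighbor_window=neighbor_window,
        anchor_distances=anchor_pair_distances(anchors),  # type: ignore[arg-type]
        seed_structure=seed,
    )


def allowed_types(site: SeedSite, seed_position: int) -> frozenset[str]:
    """Accepted amino-acid types at a site position.

    The substitution rule if one exists, else exactly the seed residue's type.
    """
    rule = site._rules_by_position.get(seed_position)
    if rule is not None:
        return rule
    for res in (*site.anchors, *site.additional):
        if res.position == seed_position:
            return frozenset({res.aa3})
    raise SiteDefinitionError(
        f"position {seed_position} is not part of the site "
        f"(anchors {site.anchor_positions}, additional {site.additional_positions})"
    )
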