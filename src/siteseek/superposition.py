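"""Optimal rigid-body superposition of anchor atom sets.

The transform overlaying the query triad onto the seed triad is the
least-squares optimal proper rotation plus translation, obtained in closed
form from the singular value decomposition of the cross-covariance matrix
(the Kabsch algorithm).  Reflections are rejected by flipping the sign of the
smallest singular direction, so the returned rotation always has det = +1.

By default the fitted point set is the Cα and Cβ atoms of the three anchors
(3–6 points); Cβ slots are dropped pairwise when either partner lacks the atom
(glycine, missing side chain), keeping the two sets in strict correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import StructureModel


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation (det = +1) plus translation, in Å."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def anchor_point_set(
    structure: StructureModel, positions: tuple[int, int, int], include_cb: bool = True
) -> list[np.ndarray]:
    """Cα (and present Cβ) coordinates of three residues, in fixed slot order
    (Cα1, Cβ1, Cα2, Cβ2, Cα3, Cβ3) with absent Cβ slots omitted."""
    points = []
    for pos in positions:
        res = structure.residue_at(pos)
        points.append(res.ca)
        if include_cb and res.cb is not None:
            points.append(res.cb)
    return points


def paired_anchor_points(
    seed: StructureModel,
    seed_positions: tuple[int, int, int],
    query: StructureModel,
    query_positions: tuple[int, int, int],
    include_cb: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Corresponding (fixed, moving) anchor point arrays.

    A Cβ slot is included only when both the seed and the query residue carry
    the atom, so the two arrays always have equal length (3–6 points).
    """
    fixed, moving = [], []
    for spos, qpos in zip(seed_positions, query_positions):
        sres, qres = seed.residue_at(spos), query.residue_at(qpos)
        fixed.append(sres.ca)
        moving.append(qres.ca)
        if include_cb and sres.cb is not None and qres.cb is not None:
            fixed.append(sres.cb)
            moving.append(qres.cb)
    return np.array(fixed, dtype=float), np.array(moving, dtype=float)


def fit_transform(moving, fixed) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rigid transform mapping ``moving`` onto
    ``fixed``, and the post-fit RMSD over the point pairs.

    Rank-deficient configurations (collinear points) still yield a valid
    proper rotation; the fit is then simply non-unique.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(
            f"point sets differ in shape: {moving.shape} vs {fixed.shape}"
        )
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ValueError(f"need an (n>=3, 3) point array, got shape {moving.shape}")

    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # fully degenerate covariance
        d = 1.0
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = fc - rotation @ mc
    transformed = moving @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - fixed) ** 2, axis=1))))
    return RigidTransform(rotation, translation), rmsd


def apply_transform(t: RigidTransform, points) -> np.ndarray:
    """Map each point to rotation·p + translation."""
    points = np.asarray(points, dtype=float)
    return points @ t.rotation.T + t.translation
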