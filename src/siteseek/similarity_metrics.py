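"""Whole-structure similarity metrics reported per hit.

Once a query is accepted on its active-site geometry, two auxiliary measures
describe how much of the rest of the structure agrees with the seed under the
*same* active-site transform (no further refinement):

* **structural mapping percentage** — the query Cα trace is aligned to the
  seed Cα trace by dynamic programming maximizing the number of monotone
  residue pairs closer than 2 Å after the transform; the metric is the
  percentage of query residues so paired.
* **structural local similarity** — a run-length-weighted score in [0, 1]:
  for L in {5, 10, 15, 20}, the fraction of query residues lying in
  consecutive aligned runs of length ≥ L is weighted by L and normalized by
  ΣL = 50.  It highlights locally conserved substructure even when the
  global folds differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import StructureModel
from .superposition import RigidTransform, apply_transform

PAIR_CUTOFF = 2.0  # Å
RUN_LENGTHS = (5, 10, 15, 20)


@dataclass
class CaPairing:
    """Monotone Cα–Cα pairing; every retained pair is closer than 2 Å."""

    pairs: list[tuple[int, int]]  # (seed_index, query_index), both strictly increasing
    distances: np.ndarray  # Å, per pair


def pair_ca(
    seed: StructureModel,
    query: StructureModel,
    t: RigidTransform,
    cutoff: float = PAIR_CUTOFF,
) -> CaPairing:
    """Globally align the two Cα traces, maximizing sub-cutoff pairs.

    Needleman–Wunsch with match reward 1 for a pair below ``cutoff``, 0
    otherwise, and no gap penalty; only the sub-cutoff pairs are returned.
    """
    seed_ca = seed.ca_coords()
    query_ca = apply_transform(t, query.ca_coords())
    dist = cdist(seed_ca, query_ca)
    match = (dist < cutoff).astype(np.int32)
    n, m = match.shape

    dp = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        row, prev = dp[i], dp[i - 1]
        mrow = match[i - 1]
        for j in range(1, m + 1):
            row[j] = max(prev[j], row[j - 1], prev[j - 1] + mrow[j - 1])

    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if match[i - 1, j - 1] and dp[i, j] == dp[i - 1, j - 1] + 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif dp[i, j] == dp[i - 1, j]:
            i -= 1
        elif dp[i, j] == dp[i, j - 1]:
            j -= 1
        else:
            i, j = i - 1, j - 1
    pairs.reverse()
    distances = np.array([dist[i, j] for i, j in pairs], dtype=float)
    return CaPairing(pairs=pairs, distances=distances)


def structural_mapping_percentage(pairing: CaPairing, query: StructureModel) -> float:
    """Percentage of query residues paired with a seed residue within 2 Å."""
    if len(query) == 0:
        return 0.0
    return 100.0 * len(pairing.pairs) / len(query)


def _run_lengths(pairs: list[tuple[int, int]]) -> list[int]:
    """Lengths of maximal runs where both indices advance by exactly 1."""
    runs: list[int] = []
    current = 0
    prev: tuple[int, int] | None = None
    for i, j in pairs:
        if prev is not None and i == prev[0] + 1 and j == prev[1] + 1:
            current += 1
        else:
            if current:
                runs.append(current)
            current = 1
        prev = (i, j)
    if current:
        runs.append(current)
    return runs


def local_similarity(
    pairing: CaPairing,
    query: StructureModel,
    run_lengths: tuple[int, ...] = RUN_LENGTHS,
) -> float:
    """Run-length-weighted local alignment score in [0, 1]."""
    if len(query) == 0:
        return 0.0
    runs = _run_lengths(pairing.pairs)
    total_weight = sum(run_lengths)
    value = 0.0
    for threshold in run_lengths:
        covered = sum(r for r in runs if r >= threshold)
        value += threshold * (covered / len(query))
    return value / total_weight
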