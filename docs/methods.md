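# Methods

## Problem and approach

`siteseek` answers a local question about protein structure: *which proteins
in a collection arrange a handful of residues in space the way a reference
("seed") protein's active site does?* Overall sequence identity or fold
similarity is deliberately ignored — a catalytic triad can be conserved in
geometry while the rest of the protein has diverged beyond recognition, and
conversely two near-identical folds can differ at exactly the residues that
matter.

The search template is built from three **anchor residues** chosen on the
seed, optionally extended by further **additional residues**, per-position
**substitution rules** (sets of accepted amino-acid types), and a sequence
**neighbor window** *w*. Only Cα and Cβ coordinates are used anywhere. If the
user supplies fewer than three anchors, the triple is completed by taking, in
ascending sequence position, residues whose Cα lies within a radius (default
10 Å, a typical active-site span) of the first anchor — "first in sequence"
is our concretization of an otherwise underdetermined rule, chosen for
determinism.

The per-structure pipeline is:

1. **Enumeration.** Every assignment of type-compatible query residues to
   the three anchors (Cartesian product of per-anchor candidate sets, no
   repeated positions). By default sequence order is *not* enforced, so
   circularly permuted sites can be found; `--enforce-seed-order` restricts
   candidates to the seed's rank order.
2. **Pre-screening.** A candidate triad survives only if each of its three
   pairwise Cα distances deviates strictly less than 3 Å (configurable) from
   the seed's. Cα is used because it exists for every residue. If more than
   2000 candidates survive, a uniform random subset of 2000 is kept; the RNG
   is seeded per structure from (global seed, CRC32 of the structure id), so
   batch composition and worker count cannot change any structure's sample.
3. **Superposition.** The optimal proper rigid transform overlaying the
   query triad onto the seed triad is the closed-form Kabsch solution: SVD of
   the centered cross-covariance, with the smallest singular direction
   sign-flipped when needed so the rotation determinant is +1 (mirror images
   are never matched). The fitted point set is the anchors' Cα+Cβ atoms
   (3–6 points); a Cβ slot is dropped on *both* sides whenever either partner
   lacks the atom, keeping the sets paired. `--fit-atoms ca` restricts the
   fit to Cα.
4. **Scoring.** The per-residue distance is the mean of the Cα–Cα and Cβ–Cβ
   distances after the transform (Cα only when a partner lacks Cβ). The
   mapped set contains the anchors, each additional residue matched to the
   nearest allowed-type query residue within 2 Å (greedy nearest-first,
   one-to-one; unmatched residues are simply absent), and sequence neighbors
   s±δ ↔ q±δ for δ ≤ w around every mapped core residue, type-blind, with
   window truncation at the termini and duplicates counted once. The score is

       score = mean(distances) / n_mapped

   so failing to recover additional residues shrinks `n_mapped` and inflates
   the score. The division by `n_mapped` *twice* (once inside the mean, once
   explicitly) is the literal reading of the method's published description;
   because the two readings differ by a factor of n, `--score-formula
   sum_over_n` switches to the plain mean. A structure is accepted when its
   best mapping scores strictly below the threshold (default 1 Å); ties are
   broken by lexicographic query positions.
5. **Whole-structure metrics.** With the winning transform fixed (never
   refined), the query Cα trace is aligned to the seed's by Needleman–Wunsch
   dynamic programming with match reward 1 for pairs under 2 Å, 0 otherwise,
   and zero gap penalty — a parameter-free scheme that provably maximizes
   the number of retained monotone sub-2 Å pairs. The **structural mapping
   percentage** is 100 × (retained pairs)/(query length). The **structural
   local similarity** weights maximal runs of consecutive pairs: for
   L ∈ {5, 10, 15, 20}, c_L is the fraction of query residues lying in runs
   of length ≥ L, and the score is Σ L·c_L / 50 ∈ [0, 1]. The run-length
   weights are proportional to L; they are exposed as a parameter since only
   the lengths themselves, not the weights, are fixed by the method's
   description. The query length is the denominator in both metrics.

Cavity detection and comparison is intentionally not implemented; the result
table carries only the two metrics above.

## Tunable parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `prescreen_tol` | 3.0 | Å | strict upper bound on anchor-pair distance deviation |
| `max_combinations` | 2000 | – | cap on candidate mappings per structure (random subset beyond) |
| `score_threshold` | 1.0 | Å | strict acceptance bound on the best mapping score |
| `neighbor_window` | 4 | residues | ±w sequence neighbors scored around each core residue |
| `additional_match_radius` | 2.0 | Å | max per-residue distance to claim an additional residue |
| `fit_atoms` | ca+cb | – | atoms entering the rigid fit |
| `score_formula` | mean_over_n | – | mean/n (literal) vs plain mean |
| auto-completion radius | 10.0 | Å | neighborhood for completing <3 anchors |

The neighbor window is interpreted as ±w (w residues on each side); the
alternative reading (w total) can be recovered by halving.

## Synthetic data

The fixture generator emulates single-chain models: Cα positions on an ideal
α-helical curve (rise 1.5 Å, radius 2.3 Å, 100°/residue → consecutive Cα
spacing ≈ 3.83 Å), Cβ on a fixed 1.5 Å radial offset, residue types sampled
uniformly. A three-residue site with chosen types and pairwise Cα distances
is planted at fixed well-separated positions (n/6, n/2, 5n/6), its distances
perturbed by Gaussian jitter of chosen σ, and the whole structure is given a
random proper rigid motion so superposition is always non-trivially
exercised.

Two deliberate design choices:

* **Unique planted triad.** Backbone types exclude the planted triad's
  types, making the planted site the only type-compatible triad per
  structure. This isolates the stage each decoy is built to break: a
  `wrong_types` decoy contains *no* compatible triad (must die at
  enumeration), a `wrong_geometry` decoy contains exactly one, inflated by
  +5 Å per pair (must die at the 3 Å pre-screen). Without this isolation the
  default score formula — whose divisor can reach ~27 with w = 4 — accepts
  nearly any triad that survives pre-screening, and decoy labels would not
  be meaningful.
* **What the fixtures do not model:** real folds, side-chain packing,
  Ramachandran statistics, multi-chain assemblies, missing density. Passing
  the benchmark therefore demonstrates algorithmic correctness (each stage
  rejects exactly what it is supposed to), not retrieval performance on real
  proteome-scale databases.

Benchmark study conditions used by the tests and the acceptance script:
60-residue structures, triad SER/ASP/HIS with Cα distances
(9.3, 6.8, 6.2) Å — a realistic catalytic-triad span — jitter σ = 0.3 Å for
positives, 20 positives and 200 decoys (types/geometry alternating). These
sizes keep the whole benchmark under a minute on one CPU while exercising
every pipeline stage.

## Numerical choices and degenerate inputs

* Proper rotation is enforced by the determinant sign flip; rank-deficient
  covariance (collinear anchors) still returns a valid rotation — the fit is
  then non-unique, not an error.
* Pre-screen and acceptance comparisons are strict (`<`), matching their
  stated bounds; deviation exactly equal to the tolerance fails.
* Glycine and residues with a missing Cβ fall back to Cα in every distance,
  with Cβ slots dropped pairwise in the fit.
* Residue identity is the author sequence number; insertion codes are
  rejected outright (predicted single-chain models have none).
* Nonstandard residues are mapped to parent standard codes by a fixed table
  (MSE→MET, SEC→CYS, …); unmappable amino acids are dropped with a warning.
* DP traceback prefers the diagonal on ties when it consumes a sub-2 Å pair,
  making the retained pair set deterministic; the pair *count* is optimal
  regardless of tie-breaking.
* Batch output is sorted by (score, structure id) and is invariant to input
  order and worker count; per-structure RNG seeds are kept below 2³¹.

## Known limitations

* The score has no statistical calibration (no E-value/Z-score); thresholds
  are in Å and must be chosen by the user.
* The additional-residue association rule (nearest allowed-type within 2 Å,
  greedy one-to-one) is an interpretation; the original method's exact rule
  is unpublished. Greedy assignment is not globally optimal in contrived
  geometries, though it coincides with the optimum in all tested cases.
* One chain per search; multi-model ensembles are read as model 1 only.
* Whole-structure metrics reuse the active-site transform; structures that
  match locally but hinge elsewhere will show low mapping percentages by
  design.
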