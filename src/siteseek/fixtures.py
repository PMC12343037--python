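"""Synthetic structures with planted active sites and controlled decoys.

Real structure databases are large and slow to obtain, so every stage of the
search is exercised on deterministic pseudo-proteins: Cα traces laid on an
ideal α-helical curve (rise 1.5 Å, radius 2.3 Å, 100° per residue, giving the
canonical ≈3.8 Å consecutive Cα spacing), with Cβ atoms on a fixed radial
offset.  A three-residue site with chosen types and pairwise Cα distances is
planted at fixed well-separated sequence positions, optionally perturbed by
Gaussian jitter on the distances, and the whole structure receives a random
proper rigid motion so superposition is genuinely exercised.

Backbone residue types are drawn uniformly from the standard amino acids
*excluding* the planted triad's types; the planted site is therefore the
unique type-compatible triad in each structure, which makes decoy labels
unambiguous: a ``wrong_types`` decoy contains no type-compatible triad at
all, and a ``wrong_geometry`` decoy contains exactly one, guaranteed to fail
the distance pre-screen.

These pseudo-proteins reproduce the sequence-local geometry that neighbor
scoring sees, but not real folds, side-chain packing, or Ramachandran
statistics — passing here shows algorithmic correctness, not performance on
real proteomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import gemmi
import numpy as np
import pandas as pd

from .structure_io import Residue, StructureModel, STANDARD_AA3

HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_TWIST = math.radians(100.0)  # per residue
CB_OFFSET = 1.5  # Å, Cβ placed radially outward from Cα

DecoyMode = Literal["none", "wrong_types", "wrong_geometry", "shifted_site"]


@dataclass(frozen=True)
class PlantedSite:
    """Triad to plant: three types and three target pairwise Cα distances (Å),
    in the order (1–2, 1–3, 2–3), plus Gaussian jitter on the distances."""

    aa3: tuple[str, str, str]
    distances: tuple[float, float, float]
    jitter_sigma: float = 0.0

    def __post_init__(self) -> None:
        d12, d13, d23 = self.distances
        if d12 + d13 <= d23 or d12 + d23 <= d13 or d13 + d23 <= d12:
            raise ValueError(
                f"target distances {self.distances} violate the triangle inequality"
            )
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass(frozen=True)
class FixtureSpec:
    n_residues: int
    planted_site: Optional[PlantedSite] = None
    decoy_mode: DecoyMode = "none"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise ValueError("n_residues must be >= 20")


def make_backbone(
    n: int, rng_seed: int = 0, exclude_types: frozenset[str] = frozenset()
) -> StructureModel:
    """Deterministic helical pseudo-protein of ``n`` residues.

    ``exclude_types`` removes codes from the uniform type pool (used to keep
    a planted triad unique within its structure).
    """
    if n < 3:
        raise ValueError(f"need at least 3 residues, got {n}")
    rng = np.random.default_rng(rng_seed)
    pool = sorted(STANDARD_AA3 - exclude_types)
    types = rng.choice(pool, size=n)
    residues = []
    for i in range(n):
        theta = HELIX_TWIST * i
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        ca = HELIX_RADIUS * radial + np.array([0.0, 0.0, HELIX_RISE * i])
        cb = ca + CB_OFFSET * radial
        residues.append(Residue(position=i + 1, aa3=str(types[i]), ca=ca, cb=cb))
    return StructureModel(id=f"backbone_{rng_seed}", residues=residues)


def planted_positions_for(n: int) -> tuple[int, int, int]:
    """The three well-separated 1-based positions used for planting."""
    return (n // 6 + 1, n // 2 + 1, (5 * n) // 6 + 1)


def _triangle_from_distances(d12: float, d13: float, d23: float) -> np.ndarray:
    """Vertices of a planar triangle with the given side lengths."""
    x = (d12**2 + d13**2 - d23**2) / (2.0 * d12)
    y_sq = d13**2 - x**2
    if y_sq <= 0:
        raise ValueError(
            f"distances ({d12:.3f}, {d13:.3f}, {d23:.3f}) do not form a triangle"
        )
    return np.array([[0.0, 0.0, 0.0], [d12, 0.0, 0.0], [x, math.sqrt(y_sq), 0.0]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def plant_site(
    backbone: StructureModel, spec: FixtureSpec
) -> tuple[StructureModel, tuple[int, int, int]]:
    """Plant the triad of ``spec`` into a backbone and rigidly move the result.

    The triad types overwrite the residues at fixed well-separated positions;
    their Cα atoms are moved onto a triangle realizing the target pairwise
    distances plus Gaussian jitter, centered at the original triad centroid.
    Decoy modes corrupt exactly one property: ``wrong_types`` substitutes
    non-allowed types at the planted positions, ``wrong_geometry`` inflates
    every pairwise distance by 5 Å (guaranteed pre-screen failure at the
    default 3 Å tolerance), ``shifted_site`` displaces each planted Cα by
    2.5 Å in a random direction.
    """
    if spec.planted_site is None:
        raise ValueError("spec.planted_site must be set")
    site = spec.planted_site
    rng = np.random.default_rng(spec.rng_seed)
    n = len(backbone)
    positions = planted_positions_for(n)

    distances = np.array(site.distances, dtype=float)
    if spec.decoy_mode == "wrong_geometry":
        distances = distances + 5.0
    if site.jitter_sigma > 0:
        for _ in range(20):
            jittered = distances + rng.normal(0.0, site.jitter_sigma, size=3)
            try:
                triangle = _triangle_from_distances(*jittered)
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                f"could not realize jittered distances (sigma={site.jitter_sigma})"
            )
    else:
        triangle = _triangle_from_distances(*distances)

    types: tuple[str, str, str] = site.aa3
    if spec.decoy_mode == "wrong_types":
        substitutes = sorted(STANDARD_AA3 - set(site.aa3) - {"GLY"})
        types = tuple(substitutes[:3])  # type: ignore[assignment]

    old_cas = np.array([backbone.residue_at(p).ca for p in positions])
    triangle = triangle - triangle.mean(axis=0) + old_cas.mean(axis=0)
    if spec.decoy_mode == "shifted_site":
        shift_dirs = rng.normal(size=(3, 3))
        shift_dirs /= np.linalg.norm(shift_dirs, axis=1, keepdims=True)
        triangle = triangle + 2.5 * shift_dirs

    rotation = _random_rotation(rng)
    shift = rng.uniform(-20.0, 20.0, size=3)

    center = triangle.mean(axis=0)
    residues = []
    for res in backbone.residues:
        if res.position in positions:
            k = positions.index(res.position)
            ca = triangle[k]
            outward = ca - center
            norm = np.linalg.norm(outward)
            outward = outward / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
            cb = ca + CB_OFFSET * outward
            res = Residue(position=res.position, aa3=types[k], ca=ca, cb=cb)
        ca = rotation @ res.ca + shift
        cb = None if res.cb is None else rotation @ res.cb + shift
        residues.append(Residue(position=res.position, aa3=res.aa3, ca=ca, cb=cb))
    model = StructureModel(id=backbone.id, residues=residues)
    return model, positions


def make_fixture(spec: FixtureSpec, id: Optional[str] = None) -> tuple[StructureModel, tuple[int, int, int]]:
    """Backbone generation + planting in one step."""
    if spec.planted_site is None:
        raise ValueError("spec.planted_site must be set")
    backbone = make_backbone(
        spec.n_residues,
        rng_seed=spec.rng_seed,
        exclude_types=frozenset(spec.planted_site.aa3),
    )
    model, positions = plant_site(backbone, spec)
    if id is not None:
        model = StructureModel(id=id, residues=model.residues, source_path=model.source_path)
    return model, positions


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a Cα/Cβ-only model as a standard single-chain PDB file."""
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model(1)
    chain = gemmi.Chain("A")
    serial = 1
    for res in model.residues:
        gres = gemmi.Residue()
        gres.name = res.aa3
        gres.seqid = gemmi.SeqId(res.position, " ")
        for name, coords in (("CA", res.ca), ("CB", res.cb)):
            if coords is None:
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element("C")
            atom.serial = serial
            serial += 1
            atom.pos = gemmi.Position(*coords)
            gres.add_atom(atom)
        chain.add_residue(gres)
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def make_benchmark(
    n_positives: int,
    n_decoys: int,
    spec: FixtureSpec,
    out_dir: str | Path,
    decoy_modes: tuple[DecoyMode, ...] = ("wrong_types", "wrong_geometry"),
) -> pd.DataFrame:
    """Write a labelled benchmark set of PDB files plus a manifest TSV.

    Positives plant the site of ``spec`` with its jitter; decoys cycle through
    ``decoy_modes``.  Per-structure RNG seeds are derived from ``spec.rng_seed``
    so a fixed seed yields byte-identical files across runs.  The manifest
    (``manifest.tsv``: file, label, planted_positions) is returned as a frame.
    """
    if n_positives < 0 or n_decoys < 0:
        raise ValueError("counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_positives):
        sub = FixtureSpec(
            n_residues=spec.n_residues,
            planted_site=spec.planted_site,
            decoy_mode="none",
            rng_seed=spec.rng_seed + 1 + i,
        )
        name = f"positive_{i:03d}"
        model, positions = make_fixture(sub, id=name)
        write_pdb(model, out_dir / f"{name}.pdb")
        rows.append(
            {
                "file": f"{name}.pdb",
                "label": "positive",
                "planted_positions": ";".join(map(str, positions)),
            }
        )
    for i in range(n_decoys):
        mode = decoy_modes[i % len(decoy_modes)]
        sub = FixtureSpec(
            n_residues=spec.n_residues,
            planted_site=spec.planted_site,
            decoy_mode=mode,
            rng_seed=spec.rng_seed + 100_001 + i,
        )
        name = f"decoy_{mode}_{i:03d}"
        model, positions = make_fixture(sub, id=name)
        write_pdb(model, out_dir / f"{name}.pdb")
        rows.append(
            {
                "file": f"{name}.pdb",
                "label": mode,
                "planted_positions": ";".join(map(str, positions)),
            }
        )
    manifest = pd.DataFrame(rows, columns=["file", "label", "planted_positions"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
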