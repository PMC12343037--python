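"""Shared fixtures: tiny hand-built structures and a planted-site benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from siteseek import fixtures, seed_model
from siteseek.structure_io import Residue, StructureModel


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    resseq: int,
    xyz,
    chain: str = "A",
    icode: str = " ",
    element: str = "C",
) -> str:
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} {chain}{resseq:4d}"
        f"{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def write_minimal_pdb(path, residues, chain="A"):
    """residues: list of (resseq, resname, {atom: xyz})."""
    lines = []
    serial = 1
    for resseq, resname, atoms in residues:
        for atom_name, xyz in atoms.items():
            lines.append(
                pdb_atom_line(serial, atom_name, resname, resseq, xyz, chain=chain)
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_model(entries, id="m") -> StructureModel:
    """entries: (position, aa3, ca, cb-or-None) tuples."""
    return StructureModel(
        id=id,
        residues=[
            Residue(pos, aa3, np.asarray(ca, float),
                    None if cb is None else np.asarray(cb, float))
            for pos, aa3, ca, cb in entries
        ],
    )


TRIAD_TYPES = ("SER", "ASP", "HIS")
TRIAD_DISTANCES = (9.3, 6.8, 6.2)  # Ca pairwise (1-2, 1-3, 2-3), a catalytic-triad span


@pytest.fixture(scope="session")
def planted_seed():
    """Zero-jitter planted-site pseudo-protein used as the seed, plus its site."""
    spec = fixtures.FixtureSpec(
        n_residues=60,
        planted_site=fixtures.PlantedSite(TRIAD_TYPES, TRIAD_DISTANCES, 0.0),
        rng_seed=42,
    )
    model, positions = fixtures.make_fixture(spec, id="seed")
    site = seed_model.build_seed_site(model, list(positions))
    return model, site, positions


@pytest.fixture()
def simple_triad_model():
    """Five-residue toy structure containing one Ser/Asp/His triad."""
    return make_model(
        [
            (1, "ALA", (0.0, 0.0, 0.0), (0.0, 0.0, 1.5)),
            (2, "SER", (3.8, 0.0, 0.0), (3.8, 0.0, 1.5)),
            (3, "GLY", (7.6, 0.0, 0.0), None),
            (4, "ASP", (3.8, 6.0, 0.0), (3.8, 6.0, 1.5)),
            (5, "HIS", (0.0, 4.0, 3.0), (0.0, 4.0, 4.5)),
        ]
    )
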