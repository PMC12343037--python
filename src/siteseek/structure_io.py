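"""Reading protein structures into a uniform coordinate model, and writing results.

Structures are reduced to an ordered list of residues carrying the alpha-carbon
(and, when present, beta-carbon) coordinates — the only atoms the search uses.
Parsing is delegated to :mod:`gemmi`, which handles both PDB and mmCIF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard three-letter amino-acid codes.
STANDARD_AA3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Common nonstandard residues mapped to their parent standard code.
NONSTANDARD_TO_STANDARD = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "PYL": "LYS",  # pyrrolysine
    "HYP": "PRO",  # hydroxyproline
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "CSO": "CYS",  # S-hydroxycysteine
    "MLY": "LYS",  # N-dimethyl-lysine
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be turned into a usable model."""


@dataclass(frozen=True)
class Residue:
    """One amino acid: author sequence number, type, and Cα/Cβ coordinates (Å)."""

    position: int
    aa3: str
    ca: np.ndarray
    cb: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        if self.cb is not None:
            object.__setattr__(self, "cb", np.asarray(self.cb, dtype=float))


@dataclass
class StructureModel:
    """Ordered single-chain residue list with strictly increasing positions."""

    id: str
    residues: list[Residue]
    source_path: str = ""
    _by_position: dict[int, Residue] = field(
        default=None, repr=False, compare=False  # type: ignore[arg-type]
    )

    def __post_init__(self) -> None:
        positions = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise StructureParseError(
                f"{self.id}: residue positions are not strictly increasing"
            )
        self._by_position = {r.position: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def has_position(self, position: int) -> bool:
        return position in self._by_position

    def residue_at(self, position: int) -> Residue:
        try:
            return self._by_position[position]
        except KeyError:
            raise KeyError(f"{self.id}: no residue at position {position}") from None

    @property
    def positions(self) -> list[int]:
        return [r.position for r in self.residues]

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)


def _first_atom(residue: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    # first listed altloc wins; AlphaFold-style single-conformer models have none
    for atom in residue:
        if atom.name == name:
            return atom
    return None


def parse_structure(path: str | Path, chain: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is read.  Residues without a Cα atom are dropped;
    nonstandard residues are mapped to their parent standard code when known
    and otherwise dropped with a warning.  Insertion codes are rejected since
    residue identity is the plain author sequence number.

    Parameters
    ----------
    path:
        Structure file (format detected from contents/extension by gemmi).
    chain:
        Chain name to read.  Defaults to the first chain containing amino
        acids with Cα atoms.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")
    model = st[0]
    chain_names = [ch.name for ch in model]
    if chain is not None:
        if chain not in chain_names:
            raise StructureParseError(
                f"{path}: chain {chain!r} not found; available chains: {chain_names}"
            )
        candidates = [model[chain]]
    else:
        candidates = list(model)

    for gchain in candidates:
        residues = _extract_residues(gchain, path)
        if residues:
            return StructureModel(
                id=path.stem, residues=residues, source_path=str(path)
            )
    raise StructureParseError(
        f"{path}: no residues with Cα atoms found"
        + (f" in chain {chain!r}" if chain else "")
    )


def _extract_residues(gchain: gemmi.Chain, path: Path) -> list[Residue]:
    residues: list[Residue] = []
    for gres in gchain:
        name = gres.name.upper()
        if name not in STANDARD_AA3:
            mapped = NONSTANDARD_TO_STANDARD.get(name)
            if mapped is None:
                info = gemmi.find_tabulated_residue(name)
                if info is not None and info.is_amino_acid():
                    logger.warning(
                        "%s: dropping unmappable nonstandard residue %s %d",
                        path.name, name, gres.seqid.num,
                    )
                continue  # water, ligands, unmappable residues
            name = mapped
        if gres.seqid.icode not in ("", " ", "\x00"):
            raise StructureParseError(
                f"{path}: insertion code {gres.seqid.icode!r} at residue "
                f"{gres.seqid.num} is not supported"
            )
        ca = _first_atom(gres, "CA")
        if ca is None:
            continue
        cb = _first_atom(gres, "CB")
        residues.append(
            Residue(
                position=gres.seqid.num,
                aa3=name,
                ca=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                cb=None if cb is None else np.array([cb.pos.x, cb.pos.y, cb.pos.z]),
            )
        )
    return residues


RESULT_COLUMNS = [
    "structure_id",
    "mapping",
    "score",
    "n_mapped",
    "structural_mapping_percentage",
    "structural_local_similarity",
]


def write_results(hits: Sequence, path: str | Path) -> None:
    """Write search hits as a TSV, one row per hit, sorted by ascending score.

    ``mapping`` is the semicolon-joined list of ``seedpos:querypos`` pairs for
    the anchor and additional residues of the best mapping.
    """
    rows = []
    for hit in hits:
        best = hit.best
        mapping_str = ";".join(
            f"{m.seed_position}:{m.query_position}"
            for m in best.mapped
            if m.kind != "neighbor"
        )
        rows.append(
            {
                "structure_id": hit.structure_id,
                "mapping": mapping_str,
                "score": f"{best.score:.6f}",
                "n_mapped": best.n_mapped,
                "structural_mapping_percentage": f"{hit.structural_mapping_percentage:.4f}",
                "structural_local_similarity": f"{hit.structural_local_similarity:.6f}",
            }
        )
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(frame):
        frame = frame.sort_values(
            ["score", "structure_id"], key=_sort_key
        ).reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False)


def _sort_key(col: pd.Series) -> pd.Series:
    if col.name == "score":
        return col.astype(float)
    return col


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result TSV written by :func:`write_results`."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"structure_id": str, "mapping": str},
        keep_default_na=False,
    )


def structure_from_coords(
    id: str,
    entries: Iterable[tuple[int, str, np.ndarray, Optional[np.ndarray]]],
) -> StructureModel:
    """Build a minimal synthetic model directly from coordinates.

    ``entries`` are ``(position, aa3, ca, cb-or-None)`` tuples; this supports
    seeds given as raw site coordinates rather than a structure file.
    """
    residues = [Residue(pos, aa3, ca, cb) for pos, aa3, ca, cb in entries]
    return StructureModel(id=id, residues=residues, source_path="<coords>")
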