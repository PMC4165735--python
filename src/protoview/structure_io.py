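"""Protein structure input/output and pose normalization.

Structures are reduced to the set of heavy atoms with per-element display
radii, because only the rendered molecular envelope matters downstream.
Before rendering, every model is rescaled into the unit bounding sphere so
that structures of any physical size fill the same fraction of the fixed
viewport.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .errors import DegenerateModelError, FormatError

__all__ = [
    "Atom",
    "ProteinModel",
    "ELEMENT_RADII",
    "DEFAULT_RADIUS",
    "read_pdb",
    "write_pdb",
    "normalize_model",
]

#: Van der Waals display radii (Angstrom) used to draw the molecular envelope.
ELEMENT_RADII: dict[str, float] = {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
}
DEFAULT_RADIUS = 1.7


@dataclass(frozen=True)
class Atom:
    """A single heavy atom: element symbol, position (Angstrom), display radius."""

    element: str
    position: np.ndarray  # shape (3,), float64
    radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.radius > 0:
            raise ValueError("atom radius must be positive")


@dataclass(frozen=True)
class ProteinModel:
    """A retrieval unit: an identifier plus an ordered list of atoms.

    ``label`` is an optional class identifier (a superfamily surrogate)
    used only for evaluation; ``source`` records the originating file.
    """

    model_id: str
    atoms: tuple[Atom, ...]
    label: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.model_id:
            raise ValueError("model_id must be nonempty")
        if len(self.atoms) == 0:
            raise ValueError("a model needs at least one atom")
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)


def element_radius(symbol: str) -> float:
    return ELEMENT_RADII.get(symbol.upper(), DEFAULT_RADIUS)


def read_pdb(path: str | Path, model_id: str | None = None) -> ProteinModel:
    """Read the heavy atoms of the first model of a PDB file.

    Hydrogens and waters are skipped; of alternate locations only the blank
    or 'A' conformer is kept; for multi-model (NMR) files only the first
    MODEL block is used, so each database entry contributes one shape.

    Raises ``FileNotFoundError`` for a missing file and ``FormatError``
    when no atom record survives filtering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    atoms: list[Atom] = []
    if len(structure) > 0:
        first = structure[0]  # first MODEL block only
        for chain in first:
            for residue in chain:
                if residue.is_water():
                    continue
                for atom in residue:
                    if atom.element.is_hydrogen:
                        continue
                    if atom.altloc not in ("\0", "", "A"):
                        continue
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    symbol = atom.element.name or "C"
                    atoms.append(Atom(symbol, pos, element_radius(symbol)))
    if not atoms:
        raise FormatError(f"no parseable heavy-atom records in {path}")
    return ProteinModel(
        model_id=model_id or path.stem,
        atoms=tuple(atoms),
        source=str(path),
    )


def write_pdb(model: ProteinModel, path: str | Path) -> Path:
    """Write a model as a standard PDB file (one CA-style atom per record)."""
    path = Path(path)
    structure = gemmi.Structure()
    structure.name = model.model_id
    gm = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for i, atom in enumerate(model.atoms, start=1):
        residue = gemmi.Residue()
        residue.name = "GLY"
        residue.seqid = gemmi.SeqId(i, " ")
        ga = gemmi.Atom()
        ga.name = "CA"
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*atom.position)
        residue.add_atom(ga)
        chain.add_residue(residue)
    gm.add_chain(chain)
    structure.add_model(gm)
    structure.write_pdb(str(path))
    return path


def normalize_model(model: ProteinModel) -> ProteinModel:
    """Center a model on its atom centroid and rescale into the unit sphere.

    The isotropic scale factor is chosen so that the maximum
    centroid-to-atom distance plus the largest display radius equals 1,
    i.e. the whole envelope fits a unit bounding sphere. Radii are scaled
    by the same factor, so relative geometry is unchanged.

    A single-atom model degenerates to a sphere: the atom is placed at the
    origin with radius 1. Two or more exactly coincident atoms have no
    orientation information and raise ``DegenerateModelError``.
    """
    coords = model.coordinates
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    max_dist = float(np.linalg.norm(centered, axis=1).max())
    max_radius = float(model.radii.max())
    if max_dist <= 1e-12:
        if len(model.atoms) > 1:
            raise DegenerateModelError(
                f"model {model.model_id!r}: all atoms coincide"
            )
        scale = 1.0 / max_radius
    else:
        scale = 1.0 / (max_dist + max_radius)
    new_atoms = tuple(
        replace(a, position=(a.position - centroid) * scale, radius=a.radius * scale)
        for a in model.atoms
    )
    return replace(model, atoms=new_atoms)


def model_extent(model: ProteinModel) -> float:
    """Radius of the smallest origin-centered sphere containing the envelope."""
    coords = model.coordinates
    return float((np.linalg.norm(coords, axis=1) + model.radii).max())
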