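"""Synthetic protein-like structure generator.

Produces labeled databases of CA-trace-like pseudo-atom chains whose gross
geometry differs strongly between classes — the property a superfamily-level
shape benchmark rests on — while members of a class differ by random rigid
rotation, per-atom jitter and mild parameter variation.  Five shape
families are built in:

``helix_bundle``
    three parallel alpha-helical traces (rise 1.5 A, ~100 deg per residue).
``sheet_stack``
    stacked planar layers of extended strands — a flat slab.
``globule``
    points packed quasi-uniformly into a ball.
``ring``
    a closed circular (toroidal) chain.
``rod``
    a long thin gently twisted chain.

All atoms are carbons at CA-trace spacing (3.8 A along chains) so only the
rendered envelope distinguishes the classes, not atom chemistry.  Every
model is deterministic in (family, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError
from .structure_io import Atom, ProteinModel, element_radius, write_pdb

__all__ = [
    "ShapeFamily",
    "FAMILIES",
    "generate_model",
    "generate_database",
    "read_manifest",
]

CA_SPACING = 3.8  # Angstrom between consecutive pseudo-residues


@dataclass(frozen=True)
class ShapeFamily:
    """A class of protein-like shapes; parameters are in Angstrom."""

    name: str
    n_atoms: int          # pseudo-residue count (>= 50, the benchmark floor)
    dimension: float      # characteristic size
    jitter: float         # per-atom positional noise (sigma)


FAMILIES: dict[str, ShapeFamily] = {
    "helix_bundle": ShapeFamily("helix_bundle", 75, 12.0, 0.4),
    "sheet_stack": ShapeFamily("sheet_stack", 96, 11.0, 0.4),
    "globule": ShapeFamily("globule", 80, 12.0, 0.4),
    "ring": ShapeFamily("ring", 64, 13.0, 0.4),
    "rod": ShapeFamily("rod", 60, 45.0, 0.4),
}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _helix(n: int, radius: float = 2.3, rise: float = 1.5, turn_deg: float = 100.0) -> np.ndarray:
    t = np.arange(n)
    ang = np.deg2rad(turn_deg) * t
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


def _coords_helix_bundle(fam: ShapeFamily, rng: np.random.Generator) -> np.ndarray:
    per = fam.n_atoms // 3
    offsets = fam.dimension * np.array(
        [[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]]
    )
    parts = []
    for i in range(3):
        h = _helix(per)
        h[:, 0] += offsets[i, 0]
        h[:, 1] += offsets[i, 1]
        parts.append(h)
    return np.vstack(parts)


def _coords_sheet_stack(fam: ShapeFamily, rng: np.random.Generator) -> np.ndarray:
    layers, strands, residues = 3, 4, 8
    coords = []
    for lz in range(layers):
        for sy in range(strands):
            for rx in range(residues):
                coords.append([3.5 * rx, 4.8 * sy, fam.dimension * lz / (layers - 1)])
    return np.array(coords)


def _coords_globule(fam: ShapeFamily, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(fam.n_atoms)
    direction = rng.normal(size=(fam.n_atoms, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    return fam.dimension * u[:, None] ** (1 / 3) * direction


def _coords_ring(fam: ShapeFamily, rng: np.random.Generator) -> np.ndarray:
    n = fam.n_atoms
    ang = 2 * np.pi * np.arange(n) / n
    wobble = 2.5 * np.sin(6 * ang)
    return np.column_stack(
        [fam.dimension * np.cos(ang), fam.dimension * np.sin(ang), wobble]
    )


def _coords_rod(fam: ShapeFamily, rng: np.random.Generator) -> np.ndarray:
    n = fam.n_atoms
    t = np.linspace(0, fam.dimension, n)
    ang = 2 * np.pi * t / 15.0
    return np.column_stack([2.0 * np.cos(ang), 2.0 * np.sin(ang), t])


_BUILDERS = {
    "helix_bundle": _coords_helix_bundle,
    "sheet_stack": _coords_sheet_stack,
    "globule": _coords_globule,
    "ring": _coords_ring,
    "rod": _coords_rod,
}


def generate_model(
    family: ShapeFamily | str, seed: int, model_id: str | None = None
) -> ProteinModel:
    """One deterministic pseudo-structure of the given family.

    The canonical family shape is jittered per atom, randomly rotated as a
    rigid body, and labeled with the family name.
    """
    fam = FAMILIES[family] if isinstance(family, str) else family
    if fam.name not in _BUILDERS:
        raise ParameterError(f"unknown shape family {fam.name!r}")
    rng = np.random.default_rng(seed)
    coords = _BUILDERS[fam.name](fam, rng)
    coords = coords + rng.normal(scale=fam.jitter, size=coords.shape)
    coords = coords @ _random_rotation(rng).T
    radius = element_radius("C")
    atoms = tuple(Atom("C", pos, radius) for pos in coords)
    return ProteinModel(
        model_id=model_id or f"{fam.name}_{seed:06d}",
        atoms=atoms,
        label=fam.name,
    )


def generate_database(
    n_classes: int,
    n_per_class: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[ProteinModel]:
    """A labeled database of ``n_classes * n_per_class`` models.

    Classes cycle through the built-in families; beyond five classes the
    family dimensions are perturbed so recycled classes still differ.
    When ``out_dir`` is given, each model is written as a PDB file and a
    tab-separated ``manifest.tsv`` maps model_id to label and seed.
    """
    if n_classes < 1 or n_per_class < 1:
        raise ParameterError("need at least one class and one model per class")
    names = list(FAMILIES)
    rng = np.random.default_rng(seed)
    models: list[ProteinModel] = []
    rows: list[tuple[str, str, int]] = []
    for ci in range(n_classes):
        base = FAMILIES[names[ci % len(names)]]
        cycle = ci // len(names)
        fam = base
        label = base.name
        if cycle > 0:
            fam = ShapeFamily(
                base.name, base.n_atoms, base.dimension * (1 + 0.5 * cycle), base.jitter
            )
            label = f"{base.name}_{cycle}"
        for mi in range(n_per_class):
            model_seed = int(rng.integers(0, 2**31 - 1))
            model_id = f"{label}_{mi:03d}"
            model = generate_model(fam, model_seed, model_id=model_id)
            model = ProteinModel(
                model_id=model_id, atoms=model.atoms, label=label, source=None
            )
            models.append(model)
            rows.append((model_id, label, model_seed))
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise DataError(f"cannot create output directory {out_dir}: {exc}") from exc
        for model in models:
            write_pdb(model, out_dir / f"{model.model_id}.pdb")
        with open(out_dir / "manifest.tsv", "w") as fh:
            fh.write("model_id\tlabel\tseed\n")
            for model_id, label, model_seed in rows:
                fh.write(f"{model_id}\t{label}\t{model_seed}\n")
    return models


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a ``manifest.tsv`` back as a model_id -> label mapping."""
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["model_id", "label"]:
            raise DataError(f"{path} is not a database manifest")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            labels[fields[0]] = fields[1]
    return labels
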