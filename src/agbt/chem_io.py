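"""Molecular data model and file I/O.

Molecules are element-labeled 3D point sets (coordinates in Å) with an
optional SMILES string.  Structure files are read/written as SDF V2000
(via RDKit) or plain XYZ.  The module also carries the covalent-radius
table used by the non-covalent distance constraint of the algebraic-graph
featurizer, and the dataset-level radius spread ``sigma``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Single-bond covalent radii in Å for the supported element set.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "Cl": 1.02,
    "Br": 1.20,
}

#: Canonical ordering of the default element set.
DEFAULT_ELEMENTS: tuple[str, ...] = ("H", "C", "N", "O", "S", "P", "F", "Cl", "Br")


class UnsupportedElementError(ValueError):
    """Raised when a structure contains an element outside the radius table."""


def atomic_radius(element: str, table: Mapping[str, float] | None = None) -> float:
    """Covalent radius (Å) of ``element`` from the bundled table.

    A custom ``table`` may be supplied to extend the element set.
    """
    radii = COVALENT_RADII if table is None else table
    try:
        return radii[element]
    except KeyError:
        raise UnsupportedElementError(
            f"unsupported element symbol {element!r}; known: {sorted(radii)}"
        ) from None


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, Cartesian position (Å), covalent radius (Å)."""

    element: str
    position: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @classmethod
    def of(cls, element: str, position: Sequence[float],
           table: Mapping[str, float] | None = None) -> "Atom":
        return cls(element, np.asarray(position, dtype=float), atomic_radius(element, table))


@dataclass
class Molecule:
    """An ordered collection of atoms with an id and optional SMILES."""

    id: str
    atoms: list[Atom]
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å."""
        return np.vstack([a.position for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")


@dataclass
class LabeledDataset:
    """Molecules plus per-task labels (missing labels allowed per task).

    ``labels[task][mol_id]`` holds a real value for regression tasks or
    0/1 for classification tasks.
    """

    molecules: list[Molecule]
    labels: dict[str, dict[str, float]]
    task_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {m.id for m in self.molecules}
        for task, values in self.labels.items():
            missing = set(values) - ids
            if missing:
                raise ValueError(f"task {task!r} labels reference unknown ids: {sorted(missing)}")
            kind = self.task_types.get(task, "regression")
            if kind not in ("regression", "classification"):
                raise ValueError(f"unknown task type {kind!r} for {task!r}")
            if kind == "classification" and any(v not in (0, 1) for v in values.values()):
                raise ValueError(f"classification task {task!r} has labels outside {{0,1}}")

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def label_vector(self, task: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, mask) aligned with molecule order; mask=False where missing."""
        values = np.zeros(len(self.molecules))
        mask = np.zeros(len(self.molecules), dtype=bool)
        per_id = self.labels[task]
        for i, mol in enumerate(self.molecules):
            if mol.id in per_id:
                values[i] = per_id[mol.id]
                mask[i] = True
        return values, mask


# ---------------------------------------------------------------------------
# SMILES canonicalization

def canonicalize_smiles(smiles: str) -> str:
    """Canonical SMILES via RDKit; raises ``ValueError`` on invalid input.

    Idempotent: two SMILES of the same structure map to the same string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Structure file readers / writers

def _molecule_from_rdkit(mol: Chem.Mol, idx: int,
                         table: Mapping[str, float] | None) -> Molecule:
    if mol.GetNumConformers() == 0:
        raise ValueError(f"SDF record {idx} has no coordinates")
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        try:
            radius = atomic_radius(sym, table)
        except UnsupportedElementError as exc:
            raise UnsupportedElementError(f"record {idx}: {exc}") from None
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(sym, np.array([p.x, p.y, p.z]), radius))
    name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{idx}"
    smiles = Chem.MolToSmiles(Chem.RemoveHs(mol)) if mol.GetNumAtoms() else None
    return Molecule(name, atoms, smiles=smiles)


def _read_sdf(path: Path, table: Mapping[str, float] | None) -> list[Molecule]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    molecules = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"malformed SDF record at index {idx} in {path}")
        try:
            Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
        except Exception:
            pass  # sanitization is best-effort; coordinates are what we need
        molecules.append(_molecule_from_rdkit(mol, idx, table))
    return molecules


def _read_xyz(path: Path, table: Mapping[str, float] | None) -> list[Molecule]:
    lines = path.read_text().splitlines()
    molecules = []
    i, idx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ValueError(f"malformed XYZ record at index {idx}: bad atom count line {i + 1}")
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        atom_lines = lines[i + 2:i + 2 + count]
        if len(atom_lines) < count:
            raise ValueError(f"malformed XYZ record at index {idx}: truncated atom block")
        atoms = []
        for ln in atom_lines:
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"malformed XYZ record at index {idx}: line {ln!r}")
            sym = parts[0]
            try:
                radius = atomic_radius(sym, table)
            except UnsupportedElementError as exc:
                raise UnsupportedElementError(f"record {idx}: {exc}") from None
            atoms.append(Atom(sym, np.array([float(x) for x in parts[1:4]]), radius))
        molecules.append(Molecule(comment or f"mol{idx}", atoms))
        i += 2 + count
        idx += 1
    return molecules


def read_structures(path: str | Path, format: str,
                    radius_table: Mapping[str, float] | None = None) -> list[Molecule]:
    """Read 3D molecules from an SDF V2000 or XYZ file.

    Atom order is preserved from the file; radii are filled from the
    bundled covalent table (or ``radius_table``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "sdf":
        return _read_sdf(path, radius_table)
    if format == "xyz":
        return _read_xyz(path, radius_table)
    raise ValueError(f"unsupported structure format {format!r} (expected 'sdf' or 'xyz')")


def write_structures(molecules: Iterable[Molecule], path: str | Path, format: str) -> None:
    """Write molecules to SDF V2000 or XYZ (coordinates at 1e-4 Å precision)."""
    path = Path(path)
    molecules = list(molecules)
    if format == "xyz":
        with path.open("w") as fh:
            for mol in molecules:
                fh.write(f"{len(mol)}\n{mol.id}\n")
                for atom in mol.atoms:
                    x, y, z = atom.position
                    fh.write(f"{atom.element} {x:.4f} {y:.4f} {z:.4f}\n")
        return
    if format == "sdf":
        with path.open("w") as fh:
            for mol in molecules:
                fh.write(_sdf_block(mol))
        return
    raise ValueError(f"unsupported structure format {format!r} (expected 'sdf' or 'xyz')")


def _sdf_block(mol: Molecule) -> str:
    # Minimal valid V2000 block: atom coordinates only, no bond records.
    lines = [mol.id, "  agbt", "", f"{len(mol):3d}  0  0  0  0  0  0  0  0  0999 V2000"]
    for atom in mol.atoms:
        x, y, z = atom.position
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {atom.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a .smi file: one SMILES per line, optional tab-separated id."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 else f"smi{i}"
        out.append((mol_id, smiles))
    return out


def write_smiles_file(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for mol_id, smiles in records:
            fh.write(f"{smiles}\t{mol_id}\n")


def read_label_table(path: str | Path,
                     task_types: Mapping[str, str] | None = None) -> tuple[list[str], list[str], dict[str, dict[str, float]]]:
    """Read a CSV label table.

    Requires a ``smiles`` column; an ``id`` column is optional (row index
    used otherwise); every remaining column is a task.  Empty cells are
    missing labels.  Returns (ids, smiles, labels-by-task).
    """
    with Path(path).open() as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"label table {path} must have a 'smiles' column")
        tasks = [c for c in reader.fieldnames if c not in ("id", "smiles")]
        ids, smiles_list = [], []
        labels: dict[str, dict[str, float]] = {t: {} for t in tasks}
        for i, row in enumerate(reader):
            mol_id = row.get("id") or f"row{i}"
            ids.append(mol_id)
            smiles_list.append(row["smiles"])
            for t in tasks:
                cell = (row.get(t) or "").strip()
                if cell:
                    labels[t][mol_id] = float(cell)
    return ids, smiles_list, labels


# ---------------------------------------------------------------------------
# Dataset sigma

def dataset_sigma(molecules: Sequence[Molecule]) -> float:
    """Population standard deviation of atomic radii over all atoms of the dataset.

    This is the σ added to the covalent-contact cutoff r_i + r_j + σ in the
    subgraph distance constraint.  Replicating the dataset leaves it unchanged.
    """
    if not molecules:
        raise ValueError("dataset_sigma requires at least one molecule")
    radii = np.concatenate([m.radii for m in molecules])
    return float(np.std(radii))
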