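"""Deterministic toy molecules, SMILES corpora, and synthetic labels.

Toy molecules are sampled from ~20 hand-built templates (alkanes,
alcohols, amines, halides, thiols, an ether, a phosphate, rings) whose
coordinates are laid out on idealized geometry: tetrahedral 109.47°
angles and standard single-bond lengths for acyclic skeletons, regular
polygons for rings.  Each sample gets seeded bond-length jitter
(±0.05 Å), a random rigid motion, and a random atom-order permutation,
so downstream invariance properties are exercised by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .algebraic_graph import ElementPair, KernelSpec, build_subgraph, rigidity_index
from .chem_io import Atom, Molecule, dataset_sigma

# Standard single-bond lengths in Å, keyed by unordered element pair.
BOND_LENGTHS = {
    frozenset({"C", "H"}): 1.09, frozenset({"C"}): 1.54,
    frozenset({"C", "O"}): 1.43, frozenset({"O", "H"}): 0.96,
    frozenset({"C", "N"}): 1.47, frozenset({"N", "H"}): 1.01,
    frozenset({"C", "S"}): 1.82, frozenset({"S", "H"}): 1.34,
    frozenset({"C", "Cl"}): 1.79, frozenset({"C", "Br"}): 1.94,
    frozenset({"C", "F"}): 1.39, frozenset({"P", "O"}): 1.60,
}

_TET = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.isclose(c, 1.0):
        return np.eye(3)
    if np.isclose(c, -1.0):
        # pick any perpendicular axis for the half-turn
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _bond_length(e1: str, e2: str) -> float:
    return BOND_LENGTHS[frozenset({e1, e2})]


def _tree_coordinates(spec: list[tuple[str, int | None, int]]) -> tuple[list[str], np.ndarray]:
    """Lay out a bonded tree on tetrahedral geometry.

    ``spec`` rows are (element, parent index or None, hydrogens to add).
    Children (and then hydrogens) occupy the tetrahedral slots of their
    parent that point away from the parent's own bond.
    """
    elements: list[str] = []
    coords: list[np.ndarray] = []
    slots: list[list[np.ndarray]] = []   # free bond directions per placed atom
    incoming: list[np.ndarray] = []      # unit vector parent -> atom
    parents: list[int | None] = []
    heavy_index: list[int] = []

    def place(element: str, parent: int | None, extend: bool = False) -> int:
        if parent is None:
            pos = np.zeros(3)
            frame = [d.copy() for d in _TET]
            inc = _TET[0].copy()
        else:
            grandparent = parents[parent]
            if extend and grandparent is not None:
                # anti (zig-zag) torsion: the new bond repeats the
                # grandparent->parent-chain direction two bonds back
                target = incoming[grandparent]
                best = max(range(len(slots[parent])),
                           key=lambda i: float(slots[parent][i] @ target))
            else:
                best = 0
            direction = slots[parent].pop(best)
            pos = coords[parent] + direction * _bond_length(elements[parent], element)
            rot = _rotation_onto(_TET[0], -direction)
            frame = [rot @ d for d in _TET[1:]]
            inc = direction
        elements.append(element)
        coords.append(pos)
        slots.append(frame)
        incoming.append(inc)
        parents.append(parent)
        return len(elements) - 1

    for element, parent, _ in spec:
        heavy_index.append(place(element, None if parent is None else heavy_index[parent],
                                 extend=parent is not None))
    for row, (element, _, n_h) in enumerate(spec):
        for _ in range(n_h):
            place("H", heavy_index[row])
    return elements, np.vstack(coords)


def _ring_coordinates(n: int, element: str, bond: float) -> tuple[list[str], np.ndarray]:
    """Regular planar n-gon ring with one radially placed hydrogen per atom."""
    radius = bond / (2.0 * np.sin(np.pi / n))
    angles = 2.0 * np.pi * np.arange(n) / n
    ring = np.column_stack([radius * np.cos(angles), radius * np.sin(angles),
                            np.zeros(n)])
    elements = [element] * n
    coords = [ring]
    ch = _bond_length("C", "H")
    for i in range(n):
        outward = ring[i] / np.linalg.norm(ring[i])
        coords.append((ring[i] + outward * ch)[None, :])
        elements.append("H")
    return elements, np.vstack(coords)


def _template(smiles: str, tree: list[tuple[str, int | None, int]]) -> tuple[str, list[str], np.ndarray]:
    elements, coords = _tree_coordinates(tree)
    return smiles, elements, coords


def _build_templates() -> list[tuple[str, list[str], np.ndarray]]:
    t = [
        _template("C", [("C", None, 4)]),
        _template("CC", [("C", None, 3), ("C", 0, 3)]),
        _template("CCC", [("C", None, 3), ("C", 0, 2), ("C", 1, 3)]),
        _template("CCCC", [("C", None, 3), ("C", 0, 2), ("C", 1, 2), ("C", 2, 3)]),
        _template("CC(C)C", [("C", None, 3), ("C", 0, 1), ("C", 1, 3), ("C", 1, 3)]),
        _template("CCCCC", [("C", None, 3), ("C", 0, 2), ("C", 1, 2), ("C", 2, 2), ("C", 3, 3)]),
        _template("CO", [("C", None, 3), ("O", 0, 1)]),
        _template("CCO", [("C", None, 3), ("C", 0, 2), ("O", 1, 1)]),
        _template("CCCO", [("C", None, 3), ("C", 0, 2), ("C", 1, 2), ("O", 2, 1)]),
        _template("CC(O)C", [("C", None, 3), ("C", 0, 1), ("O", 1, 1), ("C", 1, 3)]),
        _template("COC", [("C", None, 3), ("O", 0, 0), ("C", 1, 3)]),
        _template("CN", [("C", None, 3), ("N", 0, 2)]),
        _template("CCN", [("C", None, 3), ("C", 0, 2), ("N", 1, 2)]),
        _template("CNC", [("C", None, 3), ("N", 0, 1), ("C", 1, 3)]),
        _template("CCl", [("C", None, 3), ("Cl", 0, 0)]),
        _template("CCCl", [("C", None, 3), ("C", 0, 2), ("Cl", 1, 0)]),
        _template("CCBr", [("C", None, 3), ("C", 0, 2), ("Br", 1, 0)]),
        _template("CF", [("C", None, 3), ("F", 0, 0)]),
        _template("CS", [("C", None, 3), ("S", 0, 1)]),
        _template("CCS", [("C", None, 3), ("C", 0, 2), ("S", 1, 1)]),
        _template("COP(=O)(OC)OC",
                  [("C", None, 3), ("O", 0, 0), ("P", 1, 0), ("O", 2, 0),
                   ("O", 2, 0), ("C", 4, 3), ("O", 2, 0), ("C", 6, 3)]),
    ]
    elements, coords = _ring_coordinates(6, "C", 1.39)
    t.append(("c1ccccc1", elements, coords))
    return t


TEMPLATES = _build_templates()


def _rigid_motion(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # random rotation via QR of a Gaussian matrix, then a random translation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return coords @ q.T + rng.uniform(-5.0, 5.0, size=3)


def make_toy_molecules(n: int, seed: int) -> list[Molecule]:
    """Sample n molecules from the templates, with jitter, rigid motion and
    atom-order permutation; byte-reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    molecules = []
    for i in range(n):
        smiles, elements, coords = TEMPLATES[rng.integers(len(TEMPLATES))]
        coords = coords + rng.uniform(-0.05, 0.05, size=coords.shape)
        coords = _rigid_motion(coords, rng)
        perm = rng.permutation(len(elements))
        atoms = [Atom.of(elements[j], coords[j]) for j in perm]
        molecules.append(Molecule(f"toy{i:04d}", atoms, smiles=smiles))
    return molecules


# ---------------------------------------------------------------------------
# SMILES corpus

_CHAIN_ATOMS = ("C", "C", "C", "C", "N", "O", "S")
_SUBSTITUENTS = ("F", "Cl", "Br", "O", "N")
_RINGS = ("c1ccccc1", "C1CCCCC1", "C1CCCC1", "c1ccncc1")


def make_smiles_corpus(n: int, seed: int) -> list[str]:
    """Grammar-generated valid SMILES: chains of length 2-12 with optional
    branches, 5/6-rings and halogen substitutions; all tokenizable."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    corpus = []
    for _ in range(n):
        if rng.random() < 0.2:
            ring = _RINGS[rng.integers(len(_RINGS))]
            tail = "".join(rng.choice(_CHAIN_ATOMS)
                           for _ in range(rng.integers(0, 4)))
            corpus.append(ring + tail if rng.random() < 0.5 else tail + ring if tail else ring)
            continue
        length = rng.integers(2, 13)
        parts = []
        for pos in range(length):
            parts.append(str(rng.choice(_CHAIN_ATOMS)))
            if 0 < pos < length - 1 and rng.random() < 0.15:
                parts.append(f"({rng.choice(_SUBSTITUENTS)})")
        corpus.append("".join(parts))
    return corpus


# ---------------------------------------------------------------------------
# Synthetic property labels

#: Ground-truth coefficients of the linear_in_ag formula.
LINEAR_AG_COEFFS = {"CC": 1.0, "CO": 1.5}
_LINEAR_KERNEL = KernelSpec("exponential", eta=6.0, power=2.0)


@dataclass
class SyntheticProperty:
    """Labels plus the ground truth used to generate them."""

    labels: dict[str, float]
    formula: str
    coefficients: dict[str, float]
    noise_sd: float
    task_type: str


def _linear_ag_scores(mols, sigma: float) -> np.ndarray:
    scores = []
    for mol in mols:
        ri_cc = rigidity_index(build_subgraph(mol, ElementPair("C", "C"),
                                              _LINEAR_KERNEL, sigma))
        ri_co = rigidity_index(build_subgraph(mol, ElementPair("C", "O"),
                                              _LINEAR_KERNEL, sigma))
        scores.append(LINEAR_AG_COEFFS["CC"] * ri_cc + LINEAR_AG_COEFFS["CO"] * ri_co)
    return np.array(scores)


def make_synthetic_property(mols, formula: str, noise_sd: float,
                            seed: int) -> SyntheticProperty:
    """Generate labels from molecular structure.

    Formulas: ``linear_in_ag`` — a linear combination of the C-C and C-O
    rigidity indices (η=6 Å exponential kernel, dataset σ) plus Gaussian
    noise; ``atom_count`` — heavy-atom count plus noise;
    ``binary_threshold`` — 1 where the linear score exceeds its median.
    """
    rng = np.random.default_rng(seed)
    ids = [m.id for m in mols]
    if formula == "atom_count":
        y = np.array([float(m.n_heavy) for m in mols])
        y = y + rng.normal(0.0, noise_sd, size=len(y))
        return SyntheticProperty(dict(zip(ids, y)), formula, {}, noise_sd, "regression")
    sigma = dataset_sigma(mols)
    scores = _linear_ag_scores(mols, sigma)
    if formula == "linear_in_ag":
        y = scores + rng.normal(0.0, noise_sd, size=len(scores))
        return SyntheticProperty(dict(zip(ids, y)), formula, dict(LINEAR_AG_COEFFS),
                                 noise_sd, "regression")
    if formula == "binary_threshold":
        noisy = scores + rng.normal(0.0, noise_sd, size=len(scores))
        y = (noisy > np.median(noisy)).astype(float)
        return SyntheticProperty(dict(zip(ids, y)), formula, dict(LINEAR_AG_COEFFS),
                                 noise_sd, "classification")
    raise ValueError(f"unknown property formula {formula!r}")
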