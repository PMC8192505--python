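"""Element-specific multiscale weighted colored subgraphs and their spectra.

For each unordered element pair (e1, e2) a molecule is reduced to the
subgraph of its e1/e2 atoms, with an edge between an e1-atom and an
e2-atom whenever the pair is beyond covalent contact,

    ||r_i - r_j|| > r_i + r_j + sigma,

weighted by a fast-decaying radial basis kernel Psi(d; eta).  Geometric
(rigidity-index) and algebraic (Laplacian / adjacency eigenvalue)
invariants of these subgraphs form the AG fingerprint: with the default
9-element set (45 pairs), 4 kernels, both matrix kinds and 5 eigenvalue
statistics the vector has 45 * 4 * 2 * 5 = 1800 named components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np

from .chem_io import DEFAULT_ELEMENTS, Molecule

STAT_NAMES = ("sum", "min", "max", "mean", "std")


@dataclass(frozen=True)
class KernelSpec:
    """Radial basis kernel: generalized exponential or generalized Lorentz.

    exponential: Psi(d) = exp(-(d/eta)^power)
    lorentz:     Psi(d) = 1 / (1 + (d/eta)^power)

    ``eta`` is the characteristic distance (Å), ``power`` the decay
    exponent (kappa or nu).
    """

    family: str
    eta: float
    power: float

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "lorentz"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.eta <= 0 or self.power <= 0:
            raise ValueError("kernel eta and power must be positive")

    @property
    def label(self) -> str:
        fam = "exp" if self.family == "exponential" else "lor"
        return f"{fam}-k{self.power:g}-e{self.eta:g}"


#: Default multiscale kernel set: two families at two characteristic distances.
DEFAULT_KERNELS: tuple[KernelSpec, ...] = (
    KernelSpec("exponential", eta=2.0, power=2.0),
    KernelSpec("exponential", eta=6.0, power=2.0),
    KernelSpec("lorentz", eta=2.0, power=3.0),
    KernelSpec("lorentz", eta=6.0, power=3.0),
)


def kernel_value(d, spec: KernelSpec):
    """Evaluate Psi(d) for distance(s) d >= 0; Psi(0)=1, strictly decreasing."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    x = (d / spec.eta) ** spec.power
    out = np.exp(-x) if spec.family == "exponential" else 1.0 / (1.0 + x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ElementPair:
    """Unordered element-type pair, stored in lexicographic order."""

    e1: str
    e2: str

    def __post_init__(self) -> None:
        if self.e1 > self.e2:
            object.__setattr__(self, "e1", self.e2)
            object.__setattr__(self, "e2", self.e1)

    @property
    def label(self) -> str:
        return f"{self.e1}{self.e2}"


@dataclass
class ElementPairGraph:
    """Weighted colored subgraph for one (pair, kernel) combination.

    ``vertices`` holds original atom indices; ``edges`` holds
    (i, j, weight) with i < j referring to positions in ``vertices``.
    """

    pair: ElementPair
    kernel: KernelSpec
    vertices: list[int]
    edges: list[tuple[int, int, float]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def build_subgraph(mol: Molecule, pair: ElementPair, kernel: KernelSpec,
                   sigma: float) -> ElementPairGraph:
    """Construct the element-pair subgraph under the non-covalent constraint.

    Vertices are all atoms whose element is e1 or e2.  An edge joins an
    e1-atom to an e2-atom iff ||r_i - r_j|| > r_i + r_j + sigma; its
    weight is kernel_value(||r_i - r_j||).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    elements = mol.elements
    vertices = [i for i, e in enumerate(elements) if e in (pair.e1, pair.e2)]
    if len(vertices) < 2:
        return ElementPairGraph(pair, kernel, vertices, [])
    coords = mol.coordinates[vertices]
    radii = mol.radii[vertices]
    labels = [elements[i] for i in vertices]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    cutoff = radii[:, None] + radii[None, :] + sigma
    edges = []
    for a, b in combinations_with_replacement(range(len(vertices)), 2):
        if a == b:
            continue
        if {labels[a], labels[b]} != {pair.e1, pair.e2}:
            continue
        if dist[a, b] > cutoff[a, b]:
            edges.append((a, b, kernel_value(dist[a, b], kernel)))
    return ElementPairGraph(pair, kernel, vertices, edges)


def rigidity_index(g: ElementPairGraph) -> float:
    """Multiscale weighted colored subgraph rigidity.

    Sum of the per-atom centralities mu_i = sum_j Psi(i, j) over ALL
    subgraph vertices, so each undirected edge contributes at both
    endpoints; under this convention RI equals trace(laplacian(g))
    exactly.
    """
    return float(2.0 * sum(w for _, _, w in g.edges))


def laplacian(g: ElementPairGraph) -> np.ndarray:
    """Weighted colored graph Laplacian over the subgraph vertices.

    Off-diagonal L_ij = -Psi(i,j) for edges; diagonal makes every row sum
    to zero.  Symmetric, diagonally dominant, positive semi-definite.
    """
    n = g.n_vertices
    L = np.zeros((n, n))
    for i, j, w in g.edges:
        L[i, j] -= w
        L[j, i] -= w
        L[i, i] += w
        L[j, j] += w
    return L


def adjacency(g: ElementPairGraph) -> np.ndarray:
    """Weighted adjacency matrix: A_ij = Psi(i,j) on edges, zero diagonal."""
    n = g.n_vertices
    A = np.zeros((n, n))
    for i, j, w in g.edges:
        A[i, j] = w
        A[j, i] = w
    return A


def connected_component_count(g: ElementPairGraph) -> int:
    """Number of connected components by union-find (isolated vertices count)."""
    parent = list(range(g.n_vertices))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in g.edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return len({find(i) for i in range(g.n_vertices)})


def spectral_statistics(matrix: np.ndarray, kind: str) -> np.ndarray:
    """(sum, min, max, mean, std) of the selected eigenvalues.

    Laplacian kind keeps the nontrivial spectrum (eigenvalues above the
    zero-mode guard tau = 1e-10 * max(1, lambda_max), which drops ALL
    zero modes of disconnected subgraphs); adjacency kind keeps the
    positive eigenvalues.  An empty selection yields exact zeros so every
    molecule maps to a full-length fingerprint.
    """
    if kind not in ("laplacian", "adjacency"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size and not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    if matrix.shape[0] == 0:
        return np.zeros(5)
    eig = np.linalg.eigvalsh(matrix)
    tau = 1e-10 * max(1.0, float(eig.max(initial=0.0)))
    selected = eig[eig > tau]
    if selected.size == 0:
        return np.zeros(5)
    return np.array([selected.sum(), selected.min(), selected.max(),
                     selected.mean(), selected.std()])


@dataclass
class AGConfig:
    """Configuration of the AG featurizer.

    Defaults reproduce the 1800-component fingerprint:
    45 element pairs x 4 kernels x 2 matrix kinds x 5 statistics.
    """

    element_set: tuple[str, ...] = DEFAULT_ELEMENTS
    kernels: tuple[KernelSpec, ...] = DEFAULT_KERNELS
    matrix_kinds: tuple[str, ...] = ("laplacian", "adjacency")
    sigma_mode: str = "dataset"
    sigma_value: float | None = None

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("at least one kernel required")
        for k in self.matrix_kinds:
            if k not in ("laplacian", "adjacency"):
                raise ValueError(f"unknown matrix kind {k!r}")
        if self.sigma_mode not in ("dataset", "fixed"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")
        if self.sigma_mode == "fixed" and self.sigma_value is None:
            raise ValueError("sigma_mode='fixed' requires sigma_value")

    @property
    def pairs(self) -> list[ElementPair]:
        ordered = sorted(self.element_set)
        return [ElementPair(a, b) for a, b in combinations_with_replacement(ordered, 2)]

    @property
    def n_components(self) -> int:
        return len(self.pairs) * len(self.kernels) * len(self.matrix_kinds) * len(STAT_NAMES)

    def component_names(self) -> list[str]:
        names = []
        for pair in self.pairs:
            for kernel in self.kernels:
                for kind in self.matrix_kinds:
                    for stat in STAT_NAMES:
                        names.append(f"AG::{pair.label}::{kernel.label}::{kind}::{stat}")
        return names

    @classmethod
    def from_dict(cls, raw: dict) -> "AGConfig":
        kwargs: dict = {}
        if "element_set" in raw:
            kwargs["element_set"] = tuple(raw["element_set"])
        if "kernels" in raw:
            kwargs["kernels"] = tuple(
                KernelSpec(k["family"], float(k["eta"]), float(k["power"]))
                for k in raw["kernels"]
            )
        if "matrix_kinds" in raw:
            kwargs["matrix_kinds"] = tuple(raw["matrix_kinds"])
        sigma = raw.get("sigma")
        if sigma:
            kwargs["sigma_mode"] = sigma.get("mode", "dataset")
            if "value" in sigma:
                kwargs["sigma_value"] = float(sigma["value"])
        return cls(**kwargs)


@dataclass
class AGFingerprint:
    """Named real-valued AG feature vector for one molecule."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must be parallel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint contains non-finite values")


def resolve_sigma(config: AGConfig, molecules: Sequence[Molecule]) -> float:
    from .chem_io import dataset_sigma

    if config.sigma_mode == "fixed":
        return float(config.sigma_value)
    return dataset_sigma(molecules)


def ag_fingerprint(mol: Molecule, config: AGConfig | None = None,
                   sigma: float = 0.0) -> AGFingerprint:
    """Full AG fingerprint of one molecule.

    Component order: pairs sorted lexicographically, kernels in config
    order, laplacian before adjacency, statistics (sum, min, max, mean,
    std).
    """
    config = config or AGConfig()
    if len(mol) == 0:  # pragma: no cover - Molecule forbids this
        raise ValueError("molecule has no atoms")
    values = []
    for pair in config.pairs:
        for kernel in config.kernels:
            g = build_subgraph(mol, pair, kernel, sigma)
            for kind in config.matrix_kinds:
                mat = laplacian(g) if kind == "laplacian" else adjacency(g)
                values.append(spectral_statistics(mat, kind))
    return AGFingerprint(np.concatenate(values) if values else np.zeros(0),
                         config.component_names())


def ag_feature_matrix(molecules: Sequence[Molecule], config: AGConfig | None = None,
                      sigma: float | None = None):
    """AG fingerprints for a dataset as a pandas DataFrame (rows = molecule ids).

    When ``sigma`` is None it is resolved from the config (dataset mode
    computes the radius spread over ``molecules``).
    """
    import pandas as pd

    config = config or AGConfig()
    if sigma is None:
        sigma = resolve_sigma(config, molecules)
    rows = [ag_fingerprint(m, config, sigma).values for m in molecules]
    return pd.DataFrame(np.vstack(rows), index=[m.id for m in molecules],
                        columns=config.component_names())
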