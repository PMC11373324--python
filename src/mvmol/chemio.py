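"""Reading molecules and constructing their three views.

A molecule enters the pipeline as a SMILES string (optionally with 3D
coordinates from an SDF) and is turned into the three per-molecule views the
encoders consume:

* an ESPF substructure token sequence (1D), obtained by greedy longest-prefix
  segmentation of the canonical SMILES against a ranked substructure
  vocabulary;
* a topology graph (2D) carrying atom/bond features, atom degrees, and the
  all-pairs shortest-path-distance (SPD) matrix in bond counts;
* a geometry graph (3D) carrying Cartesian coordinates, the Euclidean distance
  matrix, its row sums, and Gaussian-basis kernel parameters for distance
  featurization.

Scaffold-based dataset splitting (Bemis–Murcko groups, largest-first greedy
assignment) also lives here.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform, pdist

RDLogger.DisableLog("rdApp.*")

#: Sentinel for atom pairs in different connected components (salts, mixtures).
UNREACHABLE = -1

#: Reserved atom-type index used when an atom's identity is masked out.
MASK_ATOM_TYPE = 119
NUM_ATOM_TYPES = 121  # 1..118 elements, 119 mask, 0/120 spare
NUM_CHARGE_BUCKETS = 11  # formal charge −5..+5, offset by +5
NEUTRAL_CHARGE_BUCKET = 5
NUM_BOND_TYPES = 5  # single, double, triple, aromatic, other

_BOND_TYPE_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


class EmptyInputError(ValueError):
    """Raised when an input file or molecule list yields nothing usable."""


class FeaturizationError(ValueError):
    """Raised when a molecule cannot be turned into the requested view."""


class GeometryError(ValueError):
    """Raised when 3D coordinates are required but absent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """One molecule: identity, canonical SMILES, optional coordinates/label."""

    id: str
    smiles: str
    coords: Optional[np.ndarray] = None
    label: Optional[object] = None
    planar: bool = False

    def __post_init__(self):
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise FeaturizationError(f"unparseable SMILES for {self.id!r}: {self.smiles!r}")
        self.smiles = Chem.MolToSmiles(mol)
        self._rdmol = mol
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (self.d, 3):
                raise ValueError(
                    f"coords shape {self.coords.shape} != ({self.d}, 3) for {self.id!r}"
                )

    @property
    def rdmol(self) -> Chem.Mol:
        return self._rdmol

    @property
    def d(self) -> int:
        """Heavy-atom count."""
        return self._rdmol.GetNumAtoms()


@dataclass
class Vocabulary:
    """Ranked substructure vocabulary with reserved mask/pad/unk ids."""

    substructures: list[str]
    index: dict[str, int] = field(init=False)
    pad_id: int = field(init=False)
    unk_id: int = field(init=False)
    mask_id: int = field(init=False)

    def __post_init__(self):
        if len(set(self.substructures)) != len(self.substructures):
            raise ValueError("vocabulary contains duplicate substructures")
        self.index = {s: i for i, s in enumerate(self.substructures)}
        n = len(self.substructures)
        self.pad_id, self.unk_id, self.mask_id = n, n + 1, n + 2

    def __len__(self):
        return len(self.substructures)

    @property
    def size_with_reserved(self) -> int:
        return len(self.substructures) + 3

    @property
    def max_token_len(self) -> int:
        return max((len(s) for s in self.substructures), default=1)

    def to_file(self, path):
        # '#'-initial lines are comments in this format, but '#' is a valid
        # SMILES character (triple bond): escape such substructures as '\#...'
        def enc(s: str) -> str:
            return "\\" + s if s.startswith("#") else s

        Path(path).write_text(
            "".join(enc(s) + "\n" for s in self.substructures), encoding="utf-8"
        )

    @classmethod
    def from_file(cls, path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        subs = [
            ln[1:] if ln.startswith("\\#") else ln
            for ln in lines
            if ln and not ln.startswith("#")
        ]
        return cls(substructures=subs)


@dataclass
class ESPFSequence:
    """Tokenized SMILES: vocabulary ids, 0-based positions, character spans."""

    tokens: list[int]
    positions: list[int]
    source_spans: list[tuple[int, int]]
    token_strings: list[str]

    @property
    def e(self) -> int:
        return len(self.tokens)


@dataclass
class TopologyGraph:
    atom_features: np.ndarray  # d × 2 int: [atomic number, charge bucket]
    bonds: list[tuple[int, int, int]]  # (i, j, bond-type index)
    degrees: np.ndarray  # length d
    spd: np.ndarray  # d × d int, UNREACHABLE sentinel

    @property
    def d(self) -> int:
        return self.atom_features.shape[0]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.d, self.d), dtype=bool)
        for i, j, _ in self.bonds:
            a[i, j] = a[j, i] = True
        return a


@dataclass
class GeometryGraph:
    coords: np.ndarray  # d × 3 (Å)
    dist: np.ndarray  # d × d Euclidean distances
    dist_sum: np.ndarray  # length d row sums
    kernel_params: list[tuple[float, float]]  # (μ_k, σ_k)
    atom_types: np.ndarray  # atomic numbers, length d (maskable copy)

    @property
    def d(self) -> int:
        return self.coords.shape[0]


@dataclass
class SplitResult:
    train_ids: list[str]
    valid_ids: list[str]
    test_ids: list[str]
    fractions: tuple[float, float, float]

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "partition"])
            for part, ids in (
                ("train", self.train_ids),
                ("valid", self.valid_ids),
                ("test", self.test_ids),
            ):
                for i in ids:
                    w.writerow([i, part])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_smiles(path, label_column: Optional[str] = None) -> list[Molecule]:
    """Read molecules from one-per-line SMILES text or a CSV with a header.

    Unparseable records are skipped (and counted in a warning); an input that
    yields zero molecules raises :class:`EmptyInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    first = text.splitlines()[0] if text.strip() else ""
    mols: list[Molecule] = []
    skipped = 0
    if "," in first and "smiles" in first.lower():
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            smiles_key = next(k for k in reader.fieldnames if k.lower() == "smiles")
            for i, row in enumerate(reader):
                smi = (row.get(smiles_key) or "").strip()
                label = None
                if label_column is not None and row.get(label_column, "") != "":
                    label = float(row[label_column])
                try:
                    mols.append(Molecule(id=row.get("id") or f"mol{i}", smiles=smi, label=label))
                except (FeaturizationError, ValueError):
                    skipped += 1
    else:
        for i, line in enumerate(text.splitlines()):
            smi = line.strip()
            if not smi:
                continue
            try:
                mols.append(Molecule(id=f"mol{i}", smiles=smi))
            except FeaturizationError:
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} unparseable record(s) in {path.name}")
    if not mols:
        raise EmptyInputError(f"no parseable molecules in {path} (skipped {skipped})")
    return mols


def read_sdf(path) -> list[Molecule]:
    """Read an SDF; coordinates come from each record's atom block.

    Records whose conformer is flat in z (a 2D depiction) are accepted but
    flagged ``planar``.  Malformed records are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not path.read_text(encoding="utf-8", errors="replace").strip():
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    mols: list[Molecule] = []
    skipped = 0
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            skipped += 1
            continue
        try:
            conf = rdmol.GetConformer()
        except ValueError:
            skipped += 1
            continue
        coords = np.array(conf.GetPositions(), dtype=np.float64)
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else f"sdf{i}"
        smiles = Chem.MolToSmiles(rdmol)
        try:
            mol = Molecule(id=name, smiles=smiles, coords=None)
        except FeaturizationError:
            skipped += 1
            continue
        # reorder coordinates into canonical-SMILES atom order: MolToSmiles
        # records the original indices in output-appearance order
        order = list(
            rdmol.GetPropsAsDict(includePrivate=True, includeComputed=True)[
                "_smilesAtomOutputOrder"
            ]
        )
        reordered = coords[np.asarray(order, dtype=int)]
        if reordered.shape[0] != mol.d:
            skipped += 1
            continue
        mol.coords = reordered
        mol.planar = bool(np.allclose(coords[:, 2], 0.0))
        mols.append(mol)
    if skipped:
        warnings.warn(f"skipped {skipped} malformed SDF record(s) in {path.name}")
    return mols


# ---------------------------------------------------------------------------
# 1D: ESPF tokenization
# ---------------------------------------------------------------------------


def tokenize_espf(smiles: str, vocab: Vocabulary) -> ESPFSequence:
    """Greedy longest-prefix segmentation of ``smiles`` against ``vocab``.

    At each position the longest vocabulary entry matching the remaining
    string is taken; a character matching nothing becomes a single-character
    token carried by the reserved ``unk`` id.  Spans always reassemble the
    input exactly.
    """
    if not smiles:
        raise ValueError("empty SMILES")
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    max_len = vocab.max_token_len
    tokens: list[int] = []
    strings: list[str] = []
    spans: list[tuple[int, int]] = []
    i = 0
    n = len(smiles)
    while i < n:
        match = None
        for L in range(min(max_len, n - i), 0, -1):
            cand = smiles[i : i + L]
            if cand in vocab.index:
                match = cand
                break
        if match is None:
            match = smiles[i]
            tokens.append(vocab.unk_id)
        else:
            tokens.append(vocab.index[match])
        strings.append(match)
        spans.append((i, i + len(match)))
        i += len(match)
    return ESPFSequence(
        tokens=tokens,
        positions=list(range(len(tokens))),
        source_spans=spans,
        token_strings=strings,
    )


# ---------------------------------------------------------------------------
# 2D: topology graph
# ---------------------------------------------------------------------------


def compute_spd(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distance in edge counts.

    Disconnected pairs receive the :data:`UNREACHABLE` sentinel.  Raw values
    are returned; clipping to an embedding range happens in the encoder.
    """
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError(f"adjacency must be square, got {adjacency.shape}")
    if adjacency.shape[0] == 0:
        return np.zeros((0, 0), dtype=np.int64)
    dist = shortest_path(adjacency.astype(float), method="D", unweighted=True, directed=False)
    spd = np.where(np.isinf(dist), UNREACHABLE, dist).astype(np.int64)
    return spd


def build_topology_graph(mol: Molecule) -> TopologyGraph:
    """Atom/bond features, degrees and SPD for the 2D view (heavy atoms only)."""
    rdmol = mol.rdmol
    d = rdmol.GetNumAtoms()
    feats = np.zeros((d, 2), dtype=np.int64)
    for atom in rdmol.GetAtoms():
        i = atom.GetIdx()
        feats[i, 0] = atom.GetAtomicNum()
        feats[i, 1] = int(np.clip(atom.GetFormalCharge() + 5, 0, NUM_CHARGE_BUCKETS - 1))
    bonds = []
    for bond in rdmol.GetBonds():
        t = _BOND_TYPE_INDEX.get(bond.GetBondType(), NUM_BOND_TYPES - 1)
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), t))
    degrees = np.zeros(d, dtype=np.int64)
    for i, j, _ in bonds:
        degrees[i] += 1
        degrees[j] += 1
    adj = np.zeros((d, d), dtype=bool)
    for i, j, _ in bonds:
        adj[i, j] = adj[j, i] = True
    return TopologyGraph(atom_features=feats, bonds=bonds, degrees=degrees, spd=compute_spd(adj))


# ---------------------------------------------------------------------------
# 3D: geometry graph
# ---------------------------------------------------------------------------


def default_kernel_params(n_kernel: int = 32, lo: float = 0.0, hi: float = 10.0):
    """Evenly spaced Gaussian kernels on [lo, hi] Å with width = spacing."""
    centers = np.linspace(lo, hi, n_kernel)
    sigma = (hi - lo) / max(n_kernel - 1, 1)
    return [(float(mu), float(sigma)) for mu in centers]


def gaussian_basis_expand(dist: np.ndarray, kernel_params) -> np.ndarray:
    """Unnormalized Gaussian basis: entry (..., k) = exp(−(x−μ_k)²/(2σ_k²))."""
    mus = np.array([m for m, _ in kernel_params], dtype=np.float64)
    sigmas = np.array([s for _, s in kernel_params], dtype=np.float64)
    if np.any(sigmas <= 0):
        raise ValueError("Gaussian kernel widths must be positive")
    x = np.asarray(dist, dtype=np.float64)[..., None]
    return np.exp(-((x - mus) ** 2) / (2.0 * sigmas**2))


def build_geometry_graph(mol: Molecule, kernel_params=None) -> GeometryGraph:
    """Pairwise distances, their row sums, and kernel parameters for the 3D view."""
    if mol.coords is None:
        raise GeometryError(
            f"molecule {mol.id!r} has no 3D coordinates; supply an SDF or use the "
            "fixtures module's seeded conformer generator"
        )
    if kernel_params is None:
        kernel_params = default_kernel_params()
    coords = np.asarray(mol.coords, dtype=np.float64)
    if coords.shape[0] == 1:
        dist = np.zeros((1, 1))
    else:
        dist = squareform(pdist(coords))
    atom_types = np.array([a.GetAtomicNum() for a in mol.rdmol.GetAtoms()], dtype=np.int64)
    return GeometryGraph(
        coords=coords,
        dist=dist,
        dist_sum=dist.sum(axis=1),
        kernel_params=list(kernel_params),
        atom_types=atom_types,
    )


# ---------------------------------------------------------------------------
# Scaffold splitting
# ---------------------------------------------------------------------------


def bemis_murcko_scaffold(smiles: str) -> str:
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)


def scaffold_split(
    mols: Sequence[Molecule],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitResult:
    """Bemis–Murcko scaffold split with largest-group-first greedy assignment.

    Groups are ordered by descending size with ties broken by scaffold SMILES;
    each group goes to train until the train fraction is reached, then valid,
    then test, so no scaffold ever crosses partitions.  The ordering is fully
    deterministic; ``seed`` is recorded for interface compatibility only.
    """
    if not mols:
        raise EmptyInputError("scaffold_split got an empty molecule list")
    f_train, f_valid, f_test = fractions
    if min(fractions) <= 0 or not math.isclose(sum(fractions), 1.0, rel_tol=1e-9):
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    groups: dict[str, list[str]] = {}
    for m in mols:
        groups.setdefault(bemis_murcko_scaffold(m.smiles), []).append(m.id)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(mols)
    n_train = f_train * n
    n_valid = f_valid * n
    train: list[str] = []
    valid: list[str] = []
    test: list[str] = []
    for _, ids in ordered:
        if len(train) < n_train:
            train.extend(ids)
        elif len(valid) < n_valid:
            valid.extend(ids)
        else:
            test.extend(ids)
    return SplitResult(train_ids=train, valid_ids=valid, test_ids=test, fractions=fractions)
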