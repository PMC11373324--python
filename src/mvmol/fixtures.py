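"""Deterministic toy inputs: molecules with seeded 3D conformers, a toy ESPF
vocabulary covering them, constructed labels, and synthetic contrastive
embeddings.

The bundled pool is a curated set of small drug-like molecules (2–30 heavy
atoms) spanning a wide range of Bemis–Murcko scaffolds, including
multi-fragment species (salts) so the UNREACHABLE shortest-path bucket is
exercised.  Coordinates come from a seeded distance-geometry (ETKDG)
embedding computed at run time — deterministic for a fixed spec — so no
conformer files need to ship.  Label rules are test instruments, not
chemistry claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import Molecule, Vocabulary
from .contrast import ContrastBatch, VIEW_LABELS

__all__ = [
    "FixtureSpec",
    "FIXTURE_SMILES",
    "builtin_molecules",
    "toy_vocab",
    "label_for",
    "synthetic_embeddings",
]

# Curated drug-like pool: common drugs, fragments, heterocycles, and a few
# salts/mixtures. Kept small (2–30 heavy atoms) so every stage runs on a desk.
FIXTURE_SMILES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",     # caffeine
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "c1ccccc1",                        # benzene
    "c1ccncc1",                        # pyridine
    "c1ccc2ccccc2c1",                  # naphthalene
    "c1ccc2[nH]ccc2c1",                # indole
    "c1ccc2ncccc2c1",                  # quinoline
    "c1cnc2[nH]ccc2c1",                # azaindole
    "c1cc[nH]c1",                      # pyrrole
    "c1ccoc1",                         # furan
    "c1ccsc1",                         # thiophene
    "c1cnc[nH]1",                      # imidazole
    "c1cn[nH]c1",                      # pyrazole
    "c1ocnc1",                         # oxazole
    "c1scnc1",                         # thiazole
    "c1cncnc1",                        # pyrimidine
    "C1CCCCC1",                        # cyclohexane
    "C1CCCC1",                         # cyclopentane
    "C1CCNCC1",                        # piperidine
    "C1CNCCN1",                        # piperazine
    "C1COCCN1",                        # morpholine
    "C1CCOC1",                         # tetrahydrofuran
    "c1ccc2[nH]cnc2c1",                # benzimidazole
    "CCO",
    "CCN",
    "CCOC(=O)C",
    "CC(C)O",
    "CC(N)C(=O)O",                     # alanine
    "NCC(=O)O",                        # glycine
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",   # salbutamol
    "CN1CCC[C@H]1c1cccnc1",            # nicotine
    "Clc1ccccc1",
    "Brc1ccccc1",
    "Fc1ccccc1",
    "Ic1ccccc1",
    "Oc1ccccc1",
    "Nc1ccccc1",
    "Cc1ccccc1",
    "COc1ccccc1",
    "CC(=O)c1ccccc1",
    "O=C(O)c1ccccc1",
    "N#Cc1ccccc1",
    "O=[N+]([O-])c1ccccc1",
    "CS(=O)(=O)c1ccccc1",
    "NS(=O)(=O)c1ccccc1",
    "O=C(N)c1ccccc1",
    "CNC(=O)c1ccccc1",
    "c1ccc(-c2ccccc2)cc1",             # biphenyl
    "c1ccc(Cc2ccccc2)cc1",             # diphenylmethane
    "c1ccc(Oc2ccccc2)cc1",             # diphenyl ether
    "c1ccc(Nc2ccccc2)cc1",             # diphenylamine
    "O=C(Nc1ccccc1)c1ccccc1",          # benzanilide
    "O=S(=O)(Nc1ccccc1)c1ccccc1",
    "CC(C)NCC(O)COc1ccccc1",           # propranolol fragment
    "CN(C)CCc1ccccc1",
    "NCCc1ccc(O)c(O)c1",               # dopamine
    "NCCc1c[nH]c2ccccc12",             # tryptamine
    "OCCN1CCN(CC1)C",
    "CC(=O)NC1CCCCC1",
    "O=C1CCCCC1",                      # cyclohexanone
    "OC1CCCCC1",                       # cyclohexanol
    "NC1CCCCC1",                       # cyclohexylamine
    "O=C1CCCN1",                       # pyrrolidinone
    "O=C1NC(=O)NC(=O)C1",              # barbituric acid
    "Cn1ccnc1",
    "Cc1ncc[nH]1",
    "CCn1ccnc1C",
    "Cc1cccnc1",
    "Cc1ccncc1",
    "Nc1ccncc1",
    "Oc1ccncc1",
    "Clc1ccncc1",
    "Cc1cncnc1",
    "Nc1ncccn1",
    "Nc1nc[nH]c1",
    "CC1CCNCC1",
    "CN1CCNCC1",
    "CC1CCOC1",
    "CC(=O)N1CCCC1",
    "O=C(O)C1CCNCC1",
    "NC(=O)C1CCCN1",
    "CC(C)C",
    "CCC(C)C",
    "CCCCC",
    "CC(C)(C)C",
    "CCCO",
    "CCCN",
    "OCCO",
    "NCCO",
    "NCCN",
    "OCC(O)CO",                        # glycerol
    "CC(O)C(=O)O",                     # lactic acid
    "OC(=O)CC(=O)O",                   # malonic acid
    "OC(=O)CCC(=O)O",                  # succinic acid
    "OC(=O)C=CC(=O)O",                 # fumaric acid
    "CC(=O)CC(=O)C",                   # acetylacetone
    "CSC",
    "CS(=O)C",
    "CC#N",
    "C=CC=C",
    "C#CC",
    "COC(=O)c1ccc(N)cc1",              # benzocaine
    "CCOC(=O)c1ccccc1",
    "COc1ccc(CCN)cc1",
    "COc1ccc(C=O)cc1",
    "Oc1ccc(Cl)cc1",
    "Nc1ccc(F)cc1",
    "Cc1ccc(S(N)(=O)=O)cc1",
    "Clc1ccc(Cl)cc1",
    "Oc1ccc(O)cc1",                    # hydroquinone
    "Nc1ccc(N)cc1",
    "Oc1ccccc1O",                      # catechol
    "Oc1cccc(O)c1",
    "O=Cc1ccccc1O",                    # salicylaldehyde
    "OCc1ccccc1",
    "OCCc1ccccc1",
    "O=CCc1ccccc1",
    "CC(N)c1ccccc1",
    "CC(O)c1ccccc1",
    "CC(C)(N)Cc1ccccc1",               # phentermine
    "CNC(C)Cc1ccccc1",                 # methamphetamine skeleton
    "NC(Cc1ccccc1)C(=O)O",             # phenylalanine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",     # tryptophan
    "NC(Cc1ccc(O)cc1)C(=O)O",          # tyrosine
    "CC(C)CC(N)C(=O)O",                # leucine
    "CC(N)Cc1ccccc1",                  # amphetamine
    "[Na+].CC(=O)[O-]",                # sodium acetate (salt, 2 fragments)
    "[Na+].[O-]C(=O)c1ccccc1",         # sodium benzoate
    "[NH4+].[Cl-]",                    # ammonium chloride
    "CC(=O)O.OCCN",                    # acid/amine mixture
    "C1CC1",                           # cyclopropane
    "C1CCC1",                          # cyclobutane
    "C1CO1",                           # oxirane
    "C1CN1",                           # aziridine
    "CC1CO1",
    "CCOCC",
    "CN(C)C=O",                        # DMF
    "CC(=O)N(C)C",
    "O=C(O)C(F)(F)F",                  # TFA
    "FC(F)(F)c1ccccc1",
    "CC(C)Oc1ccccc1",
    "CCc1ccc(O)cc1",
    "Cn1cnc2c1c(=O)[nH]c(=O)n2C",      # theobromine isomer
    "OCC1OC(O)C(O)C(O)C1O",            # glucose (pyranose)
    "COc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC",        # erlotinib core (26 heavy atoms)
    "CC(=O)Nc1ccc(OCC(O)CNC(C)C)cc1",               # practolol (21)
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",                   # procainamide (17)
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",               # atenolol (19)
    "CN1CCN(CC1)c1ccc(N)c(Cl)c1",                   # arylpiperazine (16)
    "O=C(O)c1ccccc1Nc1cccc(C(F)(F)F)c1",            # flufenamic acid (22)
    "CC(C)Cc1ccc(cc1)C(C)C(=O)NCCO",                # ibuprofen amide (18)
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",                 # naproxen (17)
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",                # imipramine (23)
    "OC(=O)CCc1ccc(OCCN2CCCC2)cc1",                 # aryl ether acid (21)
)


@dataclass(frozen=True)
class FixtureSpec:
    """A deterministic recipe for a fixture set."""

    n_molecules: int = 64
    seed: int = 7
    coordinate_mode: str = "generated"  # generated (seeded ETKDG) | none
    label_rule: str = "contains_nitrogen"


def _embed_coords(smiles: str, seed: int) -> np.ndarray:
    """Seeded distance-geometry conformer for the canonical heavy-atom order."""
    mol = Chem.MolFromSmiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)  # atom order = canonical appearance order
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    ok = AllChem.EmbedMolecule(molh, params)
    if ok == 0:
        try:
            AllChem.MMFFOptimizeMolecule(molh, maxIters=200)
        except Exception:
            pass
        molh = Chem.RemoveHs(molh)
        return np.array(molh.GetConformer().GetPositions(), dtype=np.float64)
    # rare embedding failure: fall back to a seeded random (still deterministic) cloud
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 2.0, size=(mol.GetNumAtoms(), 3))


def label_for(mol: Molecule, rule: str, rng: np.random.Generator | None = None) -> float:
    """Label rules used by the tests; simple and documented, nothing more."""
    rdmol = mol.rdmol
    if rule == "contains_nitrogen":
        return float(any(a.GetAtomicNum() == 7 for a in rdmol.GetAtoms()))
    if rule == "contains_ring":
        return float(rdmol.GetRingInfo().NumRings() > 0)
    if rule == "heavy_gt_median":  # resolved against the set median by the caller
        return float(rdmol.GetNumAtoms())
    raise ValueError(f"unknown label rule {rule!r}")


@lru_cache(maxsize=32)
def _cached_pool(n: int, seed: int, mode: str, rule: str) -> tuple:
    mols = []
    for i in range(n):
        smi = FIXTURE_SMILES[i]
        coords = None
        if mode == "generated":
            coords = _embed_coords(smi, seed * 10007 + i)
        mol = Molecule(id=f"fix{i:03d}", smiles=smi, coords=coords)
        mols.append(mol)
    if rule == "heavy_gt_median":
        sizes = np.array([m.d for m in mols], dtype=float)
        med = np.median(sizes)
        for m in mols:
            m.label = float(m.d > med)
    else:
        for m in mols:
            m.label = label_for(m, rule)
    return tuple(mols)


def builtin_molecules(spec: FixtureSpec) -> list[Molecule]:
    """The first ``n_molecules`` pool members with seeded coordinates and labels."""
    if spec.n_molecules > len(FIXTURE_SMILES):
        raise ValueError(
            f"requested {spec.n_molecules} molecules; pool has {len(FIXTURE_SMILES)}"
        )
    if spec.coordinate_mode not in ("generated", "none"):
        raise ValueError(f"unknown coordinate mode {spec.coordinate_mode!r}")
    pool = _cached_pool(spec.n_molecules, spec.seed, spec.coordinate_mode, spec.label_rule)
    return [
        Molecule(
            id=m.id,
            smiles=m.smiles,
            coords=None if m.coords is None else m.coords.copy(),
            label=m.label,
        )
        for m in pool
    ]


@lru_cache(maxsize=1)
def toy_vocab() -> Vocabulary:
    """A ~200-entry substructure vocabulary covering the fixture pool.

    All single characters occurring in the pool's canonical SMILES are
    included (so tokenization never falls back to unk on fixtures), plus the
    most frequent multi-character substrings so that segmentation genuinely
    merges characters into substructures.
    """
    canon = [Molecule(id=f"v{i}", smiles=s).smiles for i, s in enumerate(FIXTURE_SMILES)]
    chars = sorted({c for s in canon for c in s})
    counts: dict[str, int] = {}
    for s in canon:
        n = len(s)
        for L in range(2, 7):
            for i in range(n - L + 1):
                sub = s[i : i + L]
                counts[sub] = counts.get(sub, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1] * len(kv[0]), kv[0]))
    multi = [s for s, c in ranked if c >= 3][:180]
    return Vocabulary(substructures=multi + [c for c in chars if c not in multi])


def synthetic_embeddings(
    n_molecules: int,
    n_views: int,
    dim: int,
    alignment: float,
    seed: int,
) -> tuple[ContrastBatch, ContrastBatch]:
    """Seeded embedding batches for exercising the contrastive loss.

    Each molecule gets a latent unit vector; each view's embedding is the
    normalized mix ``alignment·latent + (1−alignment)·noise``.  Returns a
    (local, global) pair built with independent noise.
    """
    if dim < 2:
        raise ValueError("dim must be ≥ 2")
    if not 0.0 <= alignment <= 1.0:
        raise ValueError("alignment must lie in [0, 1]")
    views = list(VIEW_LABELS[:n_views])
    rng = np.random.default_rng(seed)

    def build(level: str) -> ContrastBatch:
        zs, mol_of, view_of = [], [], []
        latents = rng.normal(size=(n_molecules, dim))
        latents /= np.linalg.norm(latents, axis=1, keepdims=True)
        for a in range(n_molecules):
            for v in views:
                noise = rng.normal(size=dim)
                noise /= np.linalg.norm(noise)
                vec = alignment * latents[a] + (1.0 - alignment) * noise
                vec /= np.linalg.norm(vec)
                zs.append(vec)
                mol_of.append(f"m{a}")
                view_of.append(v)
        return ContrastBatch(z=np.array(zs), mol_of=mol_of, view_of=view_of, level=level)

    return build("local"), build("global")
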