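"""Molecular fingerprints and the bit -> atom-environment mapping.

Hashed circular fingerprints (ECFP on atom-type invariants, FCFP on
pharmacophoric feature invariants, diameter = 2 x radius) plus MACCS
structural keys.  ``bit_atom_map`` exposes which atom environments set each
bit, which is what the per-atom attribution maps are built on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

FAMILIES = ("ecfp", "fcfp", "maccs")
MACCS_NBITS = 166  # RDKit emits 167 with key 0 always unset; we drop it


@dataclass(frozen=True)
class FingerprintSpec:
    """Which fingerprint to compute.

    ``ecfp``/``fcfp`` are hashed circular fingerprints; ``radius=2`` is the
    classic diameter-4 variant.  ``nbits`` is ignored for maccs (fixed 166).
    """

    family: str = "ecfp"
    radius: int = 2
    nbits: int = 1024

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown fingerprint family {self.family!r}")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.family != "maccs" and (self.nbits <= 0 or self.nbits & (self.nbits - 1)):
            raise ValueError("nbits must be a power of two for hashed families")

    @property
    def width(self) -> int:
        return MACCS_NBITS if self.family == "maccs" else self.nbits

    def key(self) -> str:
        if self.family == "maccs":
            return "maccs"
        return f"{self.family}{2 * self.radius}-{self.nbits}"

    def as_dict(self) -> dict:
        return {"family": self.family, "radius": self.radius, "nbits": self.nbits}


@dataclass
class FingerprintMatrix:
    """Binary compounds x bits matrix with row identifiers."""

    bits: np.ndarray
    spec: FingerprintSpec
    ids: list[str]

    def __post_init__(self):
        if self.bits.shape[0] != len(self.ids):
            raise ValueError("row count must equal id count")


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return mol


def _generator(spec: FingerprintSpec):
    kwargs = {"radius": spec.radius, "fpSize": spec.nbits}
    if spec.family == "fcfp":
        kwargs["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
    return rdFingerprintGenerator.GetMorganGenerator(**kwargs)


def fingerprint(smiles: str, spec: FingerprintSpec) -> np.ndarray:
    """Binary fingerprint vector (uint8, length ``spec.width``)."""
    mol = _mol(smiles)
    if spec.family == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(167, dtype=np.uint8)
        for b in bv.GetOnBits():
            arr[b] = 1
        return arr[1:]  # key 0 is a placeholder, never set
    bv = _generator(spec).GetFingerprint(mol)
    arr = np.zeros(spec.nbits, dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return arr


def featurize_dataset(dataset, spec: FingerprintSpec) -> FingerprintMatrix:
    """Fingerprint every compound of a curated dataset, preserving order."""
    smiles = getattr(dataset, "smiles", dataset)
    rows = [fingerprint(s, spec) for s in smiles]
    bits = np.array(rows, dtype=np.uint8) if rows else np.zeros((0, spec.width), np.uint8)
    return FingerprintMatrix(bits=bits, spec=spec, ids=list(smiles))


def bit_atom_map(smiles: str, spec: FingerprintSpec) -> dict[int, list[frozenset[int]]]:
    """Map each on-bit to the atom environments that set it.

    An environment is the frozenset of atom indices within ``spec.radius``
    bonds of the central atom (indices refer to the molecule as parsed from
    ``smiles``).  A hashed bit hit by several environments (a collision)
    maps to all of them.  Only circular families support this.
    """
    if spec.family == "maccs":
        raise ValueError("bit_atom_map requires a hashed circular family (ecfp/fcfp)")
    mol = _mol(smiles)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    _generator(spec).GetFingerprint(mol, additionalOutput=ao)
    mapping: dict[int, list[frozenset[int]]] = {}
    for bit, envs in ao.GetBitInfoMap().items():
        env_atoms = []
        for center, radius in envs:
            if radius == 0:
                atoms = frozenset([center])
            else:
                bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
                atoms = {center}
                for bid in bond_ids:
                    bond = mol.GetBondWithIdx(bid)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
                atoms = frozenset(atoms)
            env_atoms.append(atoms)
        mapping[bit] = env_atoms
    return mapping


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |A & B| / |A | B| of two binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)
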