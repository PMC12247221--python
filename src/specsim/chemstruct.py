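"""Structure standardization, fingerprints and Tanimoto similarity.

Chemical identity throughout the package is the planar (2-D) structure:
salts are stripped, charges neutralized where chemically possible,
stereochemistry removed, and the canonical tautomer selected. Two spectra
annotate "the same compound" exactly when their standardized structures
share the first InChIKey block (``inchikey14``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

FINGERPRINT_BITS = 2048

__all__ = [
    "Structure",
    "SimilarityMatrix",
    "SmilesParseError",
    "DuplicateStructureError",
    "UndefinedSimilarityError",
    "standardize_structure",
    "fingerprint",
    "tanimoto",
    "pairwise_similarity_matrix",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the offending text."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class DuplicateStructureError(ValueError):
    """Raised when structures expected to be unique share an inchikey14."""


class UndefinedSimilarityError(ValueError):
    """Raised for the Tanimoto of two all-zero fingerprints (0/0)."""


@dataclass(frozen=True)
class Structure:
    """A standardized 2-D molecule.

    ``canonical_smiles`` is the single largest covalently bonded fragment,
    neutralized, stereochemistry-free, in its canonical tautomeric form.
    ``residual_charge`` flags molecules whose net charge could not be
    neutralized (e.g. quaternary ammonium); they are kept as-is.
    """

    raw_smiles: str
    canonical_smiles: str
    inchikey: str
    inchikey14: str = field(init=False)
    monoisotopic_mass: float = 0.0
    residual_charge: int = 0

    def __post_init__(self):
        object.__setattr__(self, "inchikey14", self.inchikey[:14])


@dataclass
class SimilarityMatrix:
    """All-pairs Tanimoto similarity over a list of unique structures."""

    structure_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.structure_ids)}

    def get(self, id_a: str, id_b: str) -> float:
        try:
            return float(self.values[self._index[id_a], self._index[id_b]])
        except KeyError as exc:
            raise KeyError(f"unknown structure id: {exc.args[0]}") from None

    def __contains__(self, structure_id: str) -> bool:
        return structure_id in self._index

    def index_of(self, structure_id: str) -> int:
        if structure_id not in self._index:
            raise KeyError(f"unknown structure id: {structure_id}")
        return self._index[structure_id]


_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Largest covalently bonded fragment; ties broken by heavy-atom count
    then lexicographically smallest canonical SMILES, so salt stripping is
    deterministic."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]
    return max(
        frags,
        key=lambda f: (f.GetNumHeavyAtoms(), _neg_lex(Chem.MolToSmiles(f))),
    )


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smaller SMILES."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def standardize_structure(raw_smiles: str) -> Structure:
    """Standardize a raw SMILES into the package's canonical 2-D form.

    Steps, in order: largest-fragment (salt removal), charge
    neutralization, stereochemistry removal, canonical-tautomer selection.
    Molecules that cannot be fully neutralized (permanent cations such as
    quaternary ammonium) are kept with their charge and flagged via
    ``residual_charge``.

    Raises
    ------
    SmilesParseError
        If ``raw_smiles`` does not parse.
    """
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise SmilesParseError(raw_smiles)
    mol = _largest_fragment(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.RemoveStereochemistry(mol)
    mol = _TAUTOMER_ENUMERATOR.Canonicalize(mol)
    residual = Chem.GetFormalCharge(mol)
    if residual != 0:
        logger.debug("structure %s retains formal charge %+d", raw_smiles, residual)
    return Structure(
        raw_smiles=raw_smiles,
        canonical_smiles=Chem.MolToSmiles(mol),
        inchikey=Chem.MolToInchiKey(mol),
        monoisotopic_mass=Descriptors.ExactMolWt(mol),
        residual_charge=residual,
    )


def fingerprint(structure: Structure) -> np.ndarray:
    """2048-bit RDKit path (Daylight-like) fingerprint of the canonical SMILES.

    Path length and branching parameters are the toolkit defaults
    (minPath=1, maxPath=7, nBitsPerHash=2).
    """
    mol = Chem.MolFromSmiles(structure.canonical_smiles)
    if mol is None:  # canonical SMILES should always re-parse
        raise SmilesParseError(structure.canonical_smiles)
    bv = Chem.RDKFingerprint(mol, fpSize=FINGERPRINT_BITS)
    arr = np.zeros(FINGERPRINT_BITS, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary fingerprints.

    Raises
    ------
    UndefinedSimilarityError
        If both fingerprints are all-zero (0/0 is undefined).
    ValueError
        On length mismatch.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise UndefinedSimilarityError("Tanimoto of two empty fingerprints is undefined")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def pairwise_similarity_matrix(structures: list[Structure]) -> SimilarityMatrix:
    """All-pairs Tanimoto matrix over structures unique by inchikey14.

    Raises
    ------
    DuplicateStructureError
        If two input structures share an inchikey14.
    """
    ids = [s.inchikey14 for s in structures]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for k in ids:
            (dupes if k in seen else seen).add(k)
        raise DuplicateStructureError(f"duplicate inchikey14 entries: {sorted(dupes)}")
    n = len(structures)
    fps = np.zeros((n, FINGERPRINT_BITS), dtype=np.float64)
    for i, s in enumerate(structures):
        fps[i] = fingerprint(s)
    # |a AND b| via dot product; |a OR b| = |a| + |b| - |a AND b|
    inter = fps @ fps.T
    counts = fps.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    if np.any(union == 0):
        raise UndefinedSimilarityError("structure with empty fingerprint in matrix")
    values = inter / union
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(structure_ids=ids, values=values)
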