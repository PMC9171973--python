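"""Molecular encodings: structural fingerprints and 0D-2D descriptors.

This module is the single place where chemical structure is turned into
numbers. Every downstream stage (curation, model training, fingerprint
assembly, similarity) consumes the :class:`BitVector` / :class:`DescriptorVector`
containers produced here, so the whole pipeline runs identically on real
SMILES-backed molecules and on molecules that carry injected, precomputed
vectors (the ``synthetic`` encoding used by the fixture generators).

Supported encodings
-------------------
``maccs``
    MACCS substructure keys as produced by RDKit. RDKit's vector has 167
    positions (key 0 is unused by convention); the actual length is recorded
    on the returned vector rather than hard-coded anywhere downstream.
``morgan``
    Circular (ECFP4-style) fingerprint, radius 2, hashed to 1024 bits.
``mol_fp``
    A default panel of 118 real-valued 0D-2D descriptors (topological
    indices, composition counts, EState/VSA bins, Crippen LogP/MR and a few
    fragment counts). The list is configurable; descriptor vectors are used
    downstream only through rank correlation, so no scaling is applied.
``synthetic``
    Verbatim passthrough of a precomputed vector attached to the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Molecule",
    "BitVector",
    "DescriptorVector",
    "MoleculeError",
    "EncodingError",
    "encode",
    "molecular_weight",
    "DEFAULT_DESCRIPTORS",
    "BIT_ENCODING_LENGTHS",
]


class MoleculeError(ValueError):
    """A molecule could not be parsed or is missing required data."""


class EncodingError(ValueError):
    """Unknown encoding name or encoding not applicable to the molecule."""


@dataclass(frozen=True)
class Molecule:
    """A compound identified by an opaque id.

    At least one of ``smiles`` / ``precomputed`` must be present. Entries in
    ``precomputed`` (keyed by encoding name, plus the optional scalar key
    ``"mw"``) always shadow anything computed from the structure, which is
    what makes chemistry-free synthetic pipelines possible.
    """

    id: str
    smiles: str | None = None
    precomputed: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if self.smiles is None and not self.precomputed:
            raise MoleculeError(
                f"molecule {self.id!r}: need a SMILES or a precomputed vector"
            )


@dataclass(frozen=True)
class BitVector:
    """Fixed-length binary fingerprint."""

    bits: np.ndarray
    encoding: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("bits must be a non-empty 1-D sequence")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        object.__setattr__(self, "bits", arr)

    @property
    def length(self) -> int:
        return int(self.bits.size)

    def count(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class DescriptorVector:
    """Ordered real-valued descriptor vector with unique names."""

    values: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if np.isnan(arr).any():
            raise ValueError("descriptor vector contains missing values")
        names = tuple(self.names) if self.names else tuple(
            f"d{i}" for i in range(arr.size)
        )
        if len(names) != arr.size or len(set(names)) != len(names):
            raise ValueError("names must be unique and match the value count")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "names", names)

    @property
    def length(self) -> int:
        return int(self.values.size)


# Default Mol_fp panel: 118 RDKit 0D-2D descriptors. Charge-derived
# descriptors (Gasteiger/BCUT) are excluded because they can be undefined
# for exotic atoms; everything here is defined for any sanitizable molecule.
DEFAULT_DESCRIPTORS: tuple[str, ...] = (
    "MaxAbsEStateIndex", "MaxEStateIndex", "MinAbsEStateIndex",
    "MinEStateIndex", "MolWt", "HeavyAtomMolWt", "ExactMolWt",
    "NumValenceElectrons", "BalabanJ", "BertzCT",
    "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n", "Chi1v",
    "Chi2n", "Chi2v", "Chi3n", "Chi3v", "Chi4n", "Chi4v",
    "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3", "LabuteASA",
    "PEOE_VSA1", "PEOE_VSA10", "PEOE_VSA11", "PEOE_VSA12", "PEOE_VSA13",
    "PEOE_VSA14", "PEOE_VSA2", "PEOE_VSA3", "PEOE_VSA4", "PEOE_VSA5",
    "PEOE_VSA6", "PEOE_VSA7", "PEOE_VSA8", "PEOE_VSA9",
    "SMR_VSA1", "SMR_VSA10", "SMR_VSA2", "SMR_VSA3", "SMR_VSA4",
    "SMR_VSA5", "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9",
    "SlogP_VSA1", "SlogP_VSA10", "SlogP_VSA11", "SlogP_VSA12",
    "SlogP_VSA2", "SlogP_VSA3", "SlogP_VSA4", "SlogP_VSA5",
    "SlogP_VSA6", "SlogP_VSA7", "SlogP_VSA8", "SlogP_VSA9",
    "TPSA",
    "EState_VSA1", "EState_VSA10", "EState_VSA11", "EState_VSA2",
    "EState_VSA3", "EState_VSA4", "EState_VSA5", "EState_VSA6",
    "EState_VSA7", "EState_VSA8", "EState_VSA9",
    "VSA_EState1", "VSA_EState10", "VSA_EState2", "VSA_EState3",
    "VSA_EState4", "VSA_EState5", "VSA_EState6", "VSA_EState7",
    "VSA_EState8", "VSA_EState9",
    "FractionCSP3", "HeavyAtomCount", "NHOHCount", "NOCount",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
    "NumAliphaticRings", "NumAromaticCarbocycles",
    "NumAromaticHeterocycles", "NumAromaticRings",
    "NumHAcceptors", "NumHDonors", "NumHeteroatoms", "NumRotatableBonds",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "NumSaturatedRings", "RingCount", "MolLogP", "MolMR",
    "fr_NH2", "fr_NH1", "fr_NH0", "fr_ether", "fr_ester", "fr_halogen",
    "fr_benzene", "fr_phenol", "fr_amide", "fr_aniline", "fr_ketone",
    "fr_pyridine", "fr_piperdine",
)

#: Nominal bit lengths for computed bit encodings (maccs is toolkit-defined
#: and read off the computed vector; recorded here after first use).
BIT_ENCODING_LENGTHS = {"morgan": 1024}

_MORGAN_RADIUS = 2
_MORGAN_NBITS = 1024


def _rdkit_mol(molecule: Molecule):
    from rdkit import Chem

    if molecule.smiles is None:
        raise MoleculeError(
            f"molecule {molecule.id!r}: no SMILES and no precomputed entry "
            "for the requested encoding"
        )
    mol = Chem.MolFromSmiles(molecule.smiles)
    if mol is None:
        raise MoleculeError(
            f"molecule {molecule.id!r}: unparseable SMILES {molecule.smiles!r}"
        )
    return mol


def _maccs_bits(mol) -> np.ndarray:
    from rdkit.Chem import MACCSkeys

    fp = MACCSkeys.GenMACCSKeys(mol)
    return np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0")


def _morgan_bits(mol) -> np.ndarray:
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=_MORGAN_RADIUS, fpSize=_MORGAN_NBITS
    )
    return np.array(gen.GetFingerprint(mol), dtype=np.uint8)


def _descriptor_values(mol, names: Sequence[str]) -> np.ndarray:
    from rdkit.Chem import Descriptors

    funcs = dict(Descriptors._descList)
    try:
        vals = [float(funcs[name](mol)) for name in names]
    except KeyError as exc:  # unknown descriptor name in a custom panel
        raise EncodingError(f"unknown descriptor {exc.args[0]!r}") from None
    return np.asarray(vals, dtype=float)


def encode(
    molecule: Molecule,
    encoding: str,
    descriptor_names: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> BitVector | DescriptorVector:
    """Encode a molecule; precomputed vectors shadow computed ones.

    Parameters
    ----------
    molecule
        The compound to encode.
    encoding
        One of ``maccs``, ``morgan``, ``mol_fp``, ``synthetic`` — or any
        key present in ``molecule.precomputed``.
    descriptor_names
        Descriptor panel for ``mol_fp``; defaults to the 118-name panel.
    """
    pre = molecule.precomputed or {}
    if encoding in pre:
        vec = np.asarray(pre[encoding])
        if encoding == "mol_fp":
            return DescriptorVector(values=vec)
        return BitVector(bits=vec, encoding=encoding)
    if encoding == "synthetic":
        raise MoleculeError(
            f"molecule {molecule.id!r}: no precomputed 'synthetic' vector"
        )
    if encoding == "maccs":
        bits = _maccs_bits(_rdkit_mol(molecule))
        BIT_ENCODING_LENGTHS.setdefault("maccs", int(bits.size))
        return BitVector(bits=bits, encoding="maccs")
    if encoding == "morgan":
        return BitVector(bits=_morgan_bits(_rdkit_mol(molecule)), encoding="morgan")
    if encoding == "mol_fp":
        vals = _descriptor_values(_rdkit_mol(molecule), descriptor_names)
        return DescriptorVector(values=vals, names=tuple(descriptor_names))
    raise EncodingError(f"unknown encoding {encoding!r}")


def molecular_weight(molecule: Molecule) -> float:
    """Average molecular weight in Daltons (precomputed ``mw`` wins)."""
    pre = molecule.precomputed or {}
    if "mw" in pre:
        mw = float(pre["mw"])  # type: ignore[arg-type]
    else:
        from rdkit.Chem import Descriptors

        mw = float(Descriptors.MolWt(_rdkit_mol(molecule)))
    if mw <= 0:
        raise MoleculeError(f"molecule {molecule.id!r}: non-positive weight {mw}")
    return mw
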