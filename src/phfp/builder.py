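"""Ph-fp assembly: 50-replicate bagged majority voting per retained assay.

A compound's pharmacological affinity fingerprint (Ph-fp) is a binary
vector with one bit per retained assay model. For each assay, 50 replicate
classifiers are trained, each on a freshly drawn 90% subsample (without
replacement) of the assay's labeled data, and each replicate predicts the
compound active or inactive. The bit is set iff a strict majority of the
replicates (> 25 of 50) predicts active; an exact tie counts as inactive.

Replicate ensembles are trained once per registry entry and cached, so
building fingerprints for a whole compound set costs 50 fits per assay
regardless of the number of compounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import Molecule
from .curation import AssayKey
from .training import ModelRegistry, RegistryEntry, feature_matrix

__all__ = ["PhFp", "ReplicateEnsemble", "predict_bit", "build_phfp", "active_assay_count"]


@dataclass(frozen=True)
class PhFp:
    """Binary pharmacological affinity fingerprint for one compound."""

    molecule_id: str
    bits: np.ndarray
    assay_slugs: tuple[str, ...]
    variant: str  # e.g. "p5_morgan": cutoff 5, models trained on Morgan

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.size != len(self.assay_slugs):
            raise ValueError("bit count must equal assay count")
        object.__setattr__(self, "bits", arr)

    @property
    def length(self) -> int:
        return int(self.bits.size)


def active_assay_count(phfp: PhFp) -> int:
    """Number of assays the compound is predicted active in (1-bits)."""
    return int(phfp.bits.sum())


class ReplicateEnsemble:
    """The 50 subsample-trained replicate models for one registry entry."""

    def __init__(
        self,
        entry: RegistryEntry,
        encoding: str,
        model_factory,
        n_replicates: int = 50,
        seed: int = 0,
        train_fraction: float = 0.9,
    ):
        self.key: AssayKey = entry.key
        self.n_replicates = n_replicates
        X = feature_matrix(entry.dataset.molecules, encoding)
        y = entry.dataset.labels
        n_train = max(2, int(round(train_fraction * len(y))))
        rng = np.random.default_rng(seed)
        self.models = []
        for r in range(n_replicates):
            idx = rng.choice(len(y), size=n_train, replace=False)
            clf = model_factory(entry.n_trees, int(rng.integers(0, 2**31 - 1)))
            clf.fit(X[idx], y[idx])
            self.models.append(clf)
        self._encoding = encoding

    def votes(self, compounds: Sequence[Molecule]) -> np.ndarray:
        """Active-vote count per compound across replicates."""
        Xq = feature_matrix(compounds, self._encoding)
        votes = np.zeros(len(compounds), dtype=int)
        for clf in self.models:
            votes += (np.asarray(clf.predict(Xq)) == 1).astype(int)
        return votes

    def predict_bits(self, compounds: Sequence[Molecule]) -> np.ndarray:
        """Majority vote: 1 iff strictly more than half the replicates agree."""
        return (self.votes(compounds) * 2 > self.n_replicates).astype(np.uint8)


def _entry_seed(seed: int, index: int) -> int:
    return (seed * 9973 + index * 7919 + 1) % (2**31 - 1)


def predict_bit(
    entry: RegistryEntry,
    compound: Molecule,
    encoding: str,
    model_factory,
    n_replicates: int = 50,
    seed: int = 0,
) -> int:
    """Single-assay majority-vote activity bit for one compound."""
    ens = ReplicateEnsemble(
        entry, encoding, model_factory, n_replicates=n_replicates, seed=seed
    )
    return int(ens.predict_bits([compound])[0])


def build_phfp(
    compounds: Sequence[Molecule],
    registry: ModelRegistry,
    seed: int = 0,
    n_replicates: int = 50,
) -> list[PhFp]:
    """Assemble one Ph-fp per compound over all registry assays.

    Bit i depends only on registry entry i (its data, tree count and the
    seed derived from its position) and on the compound — never on other
    entries. Compounds whose encoding fails are skipped, not imputed.
    """
    if len(registry) == 0:
        raise ValueError("empty model registry: no retained assays")
    encodable: list[Molecule] = []
    for mol in compounds:
        try:
            feature_matrix([mol], registry.encoding)
            encodable.append(mol)
        except Exception:
            import logging

            logging.getLogger(__name__).warning(
                "compound %s skipped: cannot encode with %s",
                mol.id, registry.encoding,
            )
    bit_cols = []
    for i, entry in enumerate(registry.entries):
        ens = ReplicateEnsemble(
            entry,
            registry.encoding,
            registry.model_factory,
            n_replicates=n_replicates,
            seed=_entry_seed(seed, i),
        )
        bit_cols.append(ens.predict_bits(encodable))
    bits = np.stack(bit_cols, axis=1)  # (n_compounds, n_assays)
    variant = f"p{registry.cutoff}_{registry.encoding}"
    slugs = registry.assay_slugs
    return [
        PhFp(molecule_id=mol.id, bits=bits[j], assay_slugs=slugs, variant=variant)
        for j, mol in enumerate(encodable)
    ]
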