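"""Bioactivity record curation: filtering, aggregation, assay assembly.

Raw ChEMBL-style activity tables are reduced to per-assay classification
datasets in five steps:

1. **Filter** records on seven independent criteria (single-protein target,
   organism whitelist, activity type Ki/IC50/EC50, Binding assay, exact "="
   relation, standard nM units, molecular weight <= 900 Da).
2. **Aggregate** duplicate measurements of the same compound in the same
   assay by the arithmetic mean on the nM scale.
3. **Label** actives by pX = 9 - log10(value_nM) >= cutoff (cutoff 5, 6 or
   7, i.e. 10 uM / 1 uM / 100 nM).
4. **Sample decoys** 4:1 from a decoy pool, excluding any candidate whose
   structural Tanimoto similarity to an active exceeds 0.9.
5. **Assemble** one labeled dataset per assay key (target accession,
   organism, activity type), discarding assays with fewer than 50 distinct
   actives.

Filters drop records, they never fail; per-rule drop counts are logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem import BitVector, Molecule, encode, molecular_weight
from .similarity import tanimoto_cross

__all__ = [
    "ActivityRecord",
    "AssayKey",
    "AssayDataset",
    "CurationConfig",
    "CurationError",
    "filter_records",
    "aggregate_duplicates",
    "p_activity",
    "label_actives",
    "sample_decoys",
    "assemble_assays",
]

log = logging.getLogger(__name__)


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class AssayKey:
    """Dataset identity: one model per (target, organism, activity type)."""

    target_accession: str
    organism: str
    activity_type: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.target_accession, self.organism, self.activity_type)

    def slug(self) -> str:
        org = self.organism.replace(" ", "-")
        return f"{self.target_accession}_{org}_{self.activity_type}"


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement."""

    molecule: Molecule
    target_accession: str
    organism: str
    activity_type: str
    relation: str
    value: float  # standard value, nM
    units: str = "nM"
    target_type: str = "SINGLE PROTEIN"
    assay_type: str = "Binding"

    @property
    def key(self) -> AssayKey:
        return AssayKey(self.target_accession, self.organism, self.activity_type)


@dataclass(frozen=True)
class AssayDataset:
    """Labeled actives + decoys for one assay key."""

    key: AssayKey
    actives: tuple[Molecule, ...]
    decoys: tuple[Molecule, ...]
    cutoff: int

    def __post_init__(self) -> None:
        ids = [m.id for m in self.actives] + [m.id for m in self.decoys]
        if len(set(ids)) != len(ids):
            raise CurationError(f"assay {self.key.slug()}: duplicate molecule ids")

    @property
    def molecules(self) -> tuple[Molecule, ...]:
        return self.actives + self.decoys

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.actives), dtype=int), np.zeros(len(self.decoys), dtype=int)]
        )

    @property
    def n(self) -> int:
        return len(self.actives) + len(self.decoys)


@dataclass(frozen=True)
class CurationConfig:
    organisms: tuple[str, ...] = ("Homo sapiens", "Rattus norvegicus", "Mus musculus")
    activity_types: tuple[str, ...] = ("Ki", "IC50", "EC50")
    assay_type: str = "Binding"
    relation: str = "="
    units: str = "nM"
    max_mw: float = 900.0
    target_type: str = "SINGLE PROTEIN"
    min_actives: int = 50
    decoy_ratio: int = 4
    decoy_similarity_threshold: float = 0.9
    # Encoding used for the decoy Tanimoto exclusion filter; the circular
    # fingerprint is the sharper discriminator, hence the default.
    decoy_filter_encoding: str = "morgan"


def _mw_ok(record: ActivityRecord, max_mw: float) -> bool:
    try:
        return molecular_weight(record.molecule) <= max_mw
    except Exception:
        return False


def filter_records(
    records: Iterable[ActivityRecord],
    config: CurationConfig = CurationConfig(),
) -> list[ActivityRecord]:
    """Apply the seven retention criteria; returns the kept records.

    The criteria are conjunctive and independent, so the kept set does not
    depend on evaluation order. Per-rule drop counts are logged at INFO.
    """
    rules = {
        "single_protein_target": lambda r: r.target_type.upper() == config.target_type,
        "organism": lambda r: r.organism in config.organisms,
        "activity_type": lambda r: r.activity_type in config.activity_types,
        "assay_type": lambda r: r.assay_type == config.assay_type,
        "relation": lambda r: r.relation == config.relation,
        "units": lambda r: r.units == config.units,
        "mw": lambda r: _mw_ok(r, config.max_mw),
    }
    drops = dict.fromkeys(rules, 0)
    kept: list[ActivityRecord] = []
    for rec in records:
        failed = [name for name, rule in rules.items() if not rule(rec)]
        if failed:
            for name in failed:
                drops[name] += 1
        else:
            kept.append(rec)
    for name, n in drops.items():
        log.info("curation filter %s dropped %d records", name, n)
    return kept


def aggregate_duplicates(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """One record per (molecule, assay key); value = mean on the nM scale."""
    groups: dict[tuple[str, tuple[str, str, str]], list[ActivityRecord]] = {}
    order: list[tuple[str, tuple[str, str, str]]] = []
    for rec in records:
        gk = (rec.molecule.id, rec.key.as_tuple())
        if gk not in groups:
            groups[gk] = []
            order.append(gk)
        groups[gk].append(rec)
    out = []
    for gk in order:
        grp = groups[gk]
        first = grp[0]
        if len(grp) == 1:
            out.append(first)
        else:
            mean_val = float(np.mean([g.value for g in grp]))
            out.append(
                ActivityRecord(
                    molecule=first.molecule,
                    target_accession=first.target_accession,
                    organism=first.organism,
                    activity_type=first.activity_type,
                    relation=first.relation,
                    value=mean_val,
                    units=first.units,
                    target_type=first.target_type,
                    assay_type=first.assay_type,
                )
            )
    return out


def p_activity(value_nM: float) -> float:
    """pX = 9 - log10(value in nM); 10 uM -> 5, 1 uM -> 6, 1 nM -> 9."""
    if value_nM <= 0:
        raise CurationError(f"non-positive activity value {value_nM}")
    return 9.0 - math.log10(value_nM)


def label_actives(
    records: Sequence[ActivityRecord], cutoff: int
) -> dict[AssayKey, list[Molecule]]:
    """Active iff pX >= cutoff; returns actives grouped by assay key."""
    if cutoff not in (5, 6, 7):
        raise CurationError(f"cutoff must be 5, 6 or 7, got {cutoff}")
    actives: dict[AssayKey, list[Molecule]] = {}
    for rec in records:
        if p_activity(rec.value) >= cutoff:
            actives.setdefault(rec.key, []).append(rec.molecule)
    return actives


def _structural_bits(mol: Molecule, encoding: str) -> np.ndarray:
    fp = encode(mol, encoding)
    if not isinstance(fp, BitVector):
        raise CurationError(f"decoy filter needs a bit encoding, got {encoding!r}")
    return fp.bits


def sample_decoys(
    actives: Sequence[Molecule],
    decoy_pool: Sequence[Molecule],
    ratio: int = 4,
    seed: int = 0,
    encoding: str = "morgan",
    similarity_threshold: float = 0.9,
    assay_name: str = "?",
) -> list[Molecule]:
    """Sample ``ratio`` decoys per active, without replacement.

    Candidates with Tanimoto similarity strictly greater than
    ``similarity_threshold`` to *any* active are excluded before sampling;
    a candidate at exactly the threshold remains eligible.
    """
    n_needed = ratio * len(actives)
    act_bits = np.stack([_structural_bits(m, encoding) for m in actives])
    pool_bits = np.stack([_structural_bits(m, encoding) for m in decoy_pool])
    max_sim = tanimoto_cross(pool_bits, act_bits).max(axis=1)
    eligible = [m for m, s in zip(decoy_pool, max_sim) if s <= similarity_threshold]
    if len(eligible) < n_needed:
        raise CurationError(
            f"assay {assay_name}: only {len(eligible)} eligible decoys, "
            f"need {n_needed}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n_needed, replace=False)
    return [eligible[i] for i in sorted(idx)]


def assemble_assays(
    records: Sequence[ActivityRecord],
    decoy_pool: Sequence[Molecule],
    cutoff: int,
    seed: int = 0,
    config: CurationConfig = CurationConfig(),
) -> list[AssayDataset]:
    """Full curation: filter -> aggregate -> label -> decoy sampling.

    Assays with fewer than ``config.min_actives`` distinct actives are
    discarded. Output order is canonical (sorted assay key), and each assay
    draws its decoys with a seed derived from the master seed and its
    position, so any subset of assays is reproducible.
    """
    kept = filter_records(records, config)
    aggregated = aggregate_duplicates(kept)
    by_key = label_actives(aggregated, cutoff)
    datasets: list[AssayDataset] = []
    for i, key in enumerate(sorted(by_key, key=AssayKey.as_tuple)):
        actives = by_key[key]
        if len(actives) < config.min_actives:
            log.info(
                "assay %s discarded: %d actives < %d",
                key.slug(), len(actives), config.min_actives,
            )
            continue
        decoys = sample_decoys(
            actives,
            decoy_pool,
            ratio=config.decoy_ratio,
            seed=seed * 100003 + i,
            encoding=config.decoy_filter_encoding,
            similarity_threshold=config.decoy_similarity_threshold,
            assay_name=key.slug(),
        )
        datasets.append(
            AssayDataset(
                key=key, actives=tuple(actives), decoys=tuple(decoys), cutoff=cutoff
            )
        )
    return datasets
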