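"""CSV/JSON interchange for molecules, records, fingerprints and matrices.

All tabular interchange is plain CSV with header rows; similarity and
distance matrices are CSV with molecule ids as header row and first
column, accompanied by a JSON sidecar recording the metric. Precomputed
vectors (the ``synthetic`` encoding and precomputed molecular weights)
travel in a JSON sidecar keyed by molecule id.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .builder import PhFp
from .chem import Molecule
from .curation import ActivityRecord, AssayDataset, AssayKey
from .similarity import SimilarityMatrix

RECORD_COLUMNS = [
    "molecule_id", "smiles", "target_accession", "target_type", "organism",
    "assay_type", "activity_type", "relation", "standard_value",
    "standard_units",
]


def _vec_entry(mol: Molecule) -> dict | None:
    if not mol.precomputed:
        return None
    out = {}
    for key, val in mol.precomputed.items():
        out[key] = float(val) if np.isscalar(val) else np.asarray(val).tolist()
    return out


def write_vectors(molecules: Sequence[Molecule], path: Path) -> None:
    data = {}
    for mol in molecules:
        entry = _vec_entry(mol)
        if entry:
            data[mol.id] = entry
    Path(path).write_text(json.dumps(data))


def read_vectors(path: Path | None) -> dict[str, dict]:
    if path is None or not Path(path).exists():
        return {}
    raw = json.loads(Path(path).read_text())
    out = {}
    for mid, entry in raw.items():
        out[mid] = {
            k: (float(v) if np.isscalar(v) else np.asarray(v, dtype=np.uint8))
            for k, v in entry.items()
        }
    return out


def _molecule(mid: str, smiles, vectors: Mapping[str, dict]) -> Molecule:
    smi = None if smiles is None or pd.isna(smiles) or smiles == "" else str(smiles)
    return Molecule(id=str(mid), smiles=smi, precomputed=vectors.get(str(mid)))


def write_records_csv(
    records: Sequence[ActivityRecord], path: Path, vectors_path: Path | None = None
) -> None:
    rows = [
        {
            "molecule_id": r.molecule.id,
            "smiles": r.molecule.smiles or "",
            "target_accession": r.target_accession,
            "target_type": r.target_type,
            "organism": r.organism,
            "assay_type": r.assay_type,
            "activity_type": r.activity_type,
            "relation": r.relation,
            "standard_value": r.value,
            "standard_units": r.units,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)
    if vectors_path is not None:
        seen, mols = set(), []
        for r in records:
            if r.molecule.id not in seen:
                seen.add(r.molecule.id)
                mols.append(r.molecule)
        write_vectors(mols, vectors_path)


def read_records_csv(path: Path, vectors_path: Path | None = None
                     ) -> list[ActivityRecord]:
    df = pd.read_csv(path)
    vectors = read_vectors(vectors_path)
    return [
        ActivityRecord(
            molecule=_molecule(row.molecule_id, row.smiles, vectors),
            target_accession=str(row.target_accession),
            organism=str(row.organism),
            activity_type=str(row.activity_type),
            relation=str(row.relation),
            value=float(row.standard_value),
            units=str(row.standard_units),
            target_type=str(row.target_type),
            assay_type=str(row.assay_type),
        )
        for row in df.itertuples()
    ]


def write_molecules_csv(
    molecules: Sequence[Molecule], path: Path, vectors_path: Path | None = None,
    labels: Sequence[str] | None = None,
) -> None:
    data = {
        "molecule_id": [m.id for m in molecules],
        "smiles": [m.smiles or "" for m in molecules],
    }
    if labels is not None:
        data["label"] = list(labels)
    pd.DataFrame(data).to_csv(path, index=False)
    if vectors_path is not None:
        write_vectors(molecules, vectors_path)


def read_molecules_csv(path: Path, vectors_path: Path | None = None
                       ) -> tuple[list[Molecule], list[str] | None]:
    df = pd.read_csv(path)
    vectors = read_vectors(vectors_path)
    smiles = df["smiles"] if "smiles" in df else [None] * len(df)
    mols = [
        _molecule(mid, smi, vectors)
        for mid, smi in zip(df["molecule_id"], smiles)
    ]
    labels = df["label"].astype(str).tolist() if "label" in df else None
    return mols, labels


def read_labels_csv(path: Path) -> tuple[list[str], list[str]]:
    """Read only (molecule_id, label) pairs; structures are not required."""
    df = pd.read_csv(path)
    if "label" not in df:
        raise ValueError(f"{path}: no 'label' column")
    return df["molecule_id"].astype(str).tolist(), df["label"].astype(str).tolist()


def write_assay_datasets(datasets: Sequence[AssayDataset], out_dir: Path) -> None:
    """One `{accession}_{organism}_{activity_type}.csv` per assay + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"assays": [], "cutoff": datasets[0].cutoff if datasets else None}
    seen: dict[str, Molecule] = {}
    for ds in datasets:
        rows = [
            {"molecule_id": m.id, "smiles": m.smiles or "", "label": int(lab)}
            for m, lab in zip(ds.molecules, ds.labels)
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"{ds.key.slug()}.csv", index=False)
        for m in ds.molecules:
            seen.setdefault(m.id, m)
        manifest["assays"].append(
            {
                "slug": ds.key.slug(),
                "target_accession": ds.key.target_accession,
                "organism": ds.key.organism,
                "activity_type": ds.key.activity_type,
                "n_actives": len(ds.actives),
                "n_decoys": len(ds.decoys),
            }
        )
    write_vectors(list(seen.values()), out_dir / "vectors.json")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_assay_datasets(in_dir: Path) -> list[AssayDataset]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    vectors = read_vectors(in_dir / "vectors.json")
    datasets = []
    for meta in manifest["assays"]:
        df = pd.read_csv(in_dir / f"{meta['slug']}.csv")
        mols = [
            _molecule(mid, smi, vectors)
            for mid, smi in zip(df["molecule_id"], df["smiles"])
        ]
        actives = tuple(m for m, lab in zip(mols, df["label"]) if lab == 1)
        decoys = tuple(m for m, lab in zip(mols, df["label"]) if lab == 0)
        key = AssayKey(
            target_accession=meta["target_accession"],
            organism=meta["organism"],
            activity_type=meta["activity_type"],
        )
        datasets.append(
            AssayDataset(key=key, actives=actives, decoys=decoys,
                         cutoff=manifest["cutoff"])
        )
    return datasets


def write_phfp_csv(phfps: Sequence[PhFp], path: Path) -> None:
    """molecule_id, variant, then one 0/1 column per assay slug."""
    if not phfps:
        raise ValueError("no fingerprints to write")
    slugs = phfps[0].assay_slugs
    rows = []
    for fp in phfps:
        row = {"molecule_id": fp.molecule_id, "variant": fp.variant}
        row.update({s: int(b) for s, b in zip(slugs, fp.bits)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phfp_csv(path: Path) -> list[PhFp]:
    df = pd.read_csv(path)
    slugs = tuple(c for c in df.columns if c not in ("molecule_id", "variant"))
    return [
        PhFp(
            molecule_id=str(row["molecule_id"]),
            bits=np.array([int(row[s]) for s in slugs], dtype=np.uint8),
            assay_slugs=slugs,
            variant=str(row["variant"]),
        )
        for _, row in df.iterrows()
    ]


def write_matrix_csv(matrix: SimilarityMatrix, path: Path) -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.ids),
                      columns=list(matrix.ids))
    df.to_csv(path)
    Path(str(path) + ".meta.json").write_text(json.dumps({"metric": matrix.metric}))


def read_matrix_csv(path: Path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    meta_path = Path(str(path) + ".meta.json")
    metric = "unknown"
    if meta_path.exists():
        metric = json.loads(meta_path.read_text()).get("metric", "unknown")
    return SimilarityMatrix(
        values=df.to_numpy(dtype=float),
        ids=tuple(str(c) for c in df.columns),
        metric=metric,
    )
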