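"""Dataset directories: geometries, property files, and the manifest CSV.

A dataset directory contains::

    geometries/<id>.xyz      one XYZ per dimer (comment carries natoms_A)
    properties/<id>.txt      per-atom property records in dimer atom order
    manifest.csv             dimer_id, paths, reference components, class, split
    truth_params.csv         (synthetic sets only) generating parameters
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .chem import dimer_to_xyz, parse_dimer_xyz
from .energy import GlobalParameters, SaptRecord, System
from .fitting import TrainingRecord
from .properties import load_properties, save_properties

__all__ = ["write_dataset", "load_manifest"]

_MANIFEST_COLUMNS = [
    "dimer_id", "geometry", "properties",
    "Elst", "Exch", "Indu", "Disp", "Total", "class", "split",
]


def _record_class(rec: TrainingRecord) -> str:
    a = rec.system.dimer.monomer_a.class_label or ""
    b = rec.system.dimer.monomer_b.class_label or ""
    return a if a == b else f"{a}+{b}"


def write_dataset(
    directory: str | Path,
    records: list[TrainingRecord],
    truth: GlobalParameters | None = None,
    splits: list[str] | None = None,
) -> Path:
    """Write a complete dataset directory; returns the manifest path."""
    directory = Path(directory)
    (directory / "geometries").mkdir(parents=True, exist_ok=True)
    (directory / "properties").mkdir(parents=True, exist_ok=True)
    if splits is None:
        splits = ["train" if r.is_homodimer else "test" for r in records]
    rows = []
    for rec, split in zip(records, splits, strict=True):
        did = rec.system.dimer.id or f"dimer{len(rows)}"
        geom_rel = f"geometries/{did}.xyz"
        prop_rel = f"properties/{did}.txt"
        (directory / geom_rel).write_text(dimer_to_xyz(rec.system.dimer))
        save_properties(rec.system.props, directory / prop_rel)
        ref = rec.reference
        rows.append(
            {
                "dimer_id": did, "geometry": geom_rel, "properties": prop_rel,
                "Elst": ref.elst, "Exch": ref.exch, "Indu": ref.indu,
                "Disp": ref.disp, "Total": ref.total,
                "class": _record_class(rec), "split": split,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(
        manifest, index=False, float_format="%.12g"
    )
    if truth is not None:
        truth.to_csv(directory / "truth_params.csv")
    return manifest


def load_manifest(
    manifest_path: str | Path, split: str | None = None
) -> list[TrainingRecord]:
    """Load records listed in a manifest; optionally filter by split tag."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        if split is not None and row["split"] != split:
            continue
        dimer = parse_dimer_xyz((root / row["geometry"]).read_text())
        dimer.id = row["dimer_id"]
        props = load_properties(root / row["properties"], dimer.n_atoms)
        ref = SaptRecord(row["Elst"], row["Exch"], row["Indu"], row["Disp"])
        if abs(ref.total - row["Total"]) > 1e-6:
            raise ValueError(
                f"{row['dimer_id']}: manifest Total inconsistent with "
                f"component sum"
            )
        records.append(TrainingRecord(System(dimer, props), ref))
    return records
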