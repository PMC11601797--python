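"""Readers and writers for compound tables, SDF conformers, and hierarchies.

Compound tables are UTF-8 delimited text (CSV/TSV) with columns
``compound_id,smiles,inchi,<screen_id>...``; outcomes are coded
``A/I/Q/U``.  Screen hierarchies are YAML or JSON mappings.  SDF files
are MDL V2000, read and written through RDKit.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from . import __version__
from .chem import inchi_has_stereo_layer, parse_smiles, smiles_has_stereo
from .types import CompoundRecord, Outcome, ScreenHierarchy, ScreenNode, Stage, StatsReport

STANDARD_INCHI_PREFIX = "InChI=1S/"
_ID_COLUMN, _SMILES_COLUMN, _INCHI_COLUMN = "compound_id", "smiles", "inchi"


def read_compound_table(path: str | Path,
                        hierarchy: ScreenHierarchy) -> list[CompoundRecord]:
    """Read a delimited compound table into :class:`CompoundRecord` objects.

    Every row yields one record; nothing is silently dropped.  Two audit
    flags are attached where representations are suspect:

    - ``"non-isomeric-smiles"`` — the InChI has a stereo layer but the
      SMILES carries no stereo marks;
    - ``"nonstandard-inchi"`` — the InChI does not start ``InChI=1S/``.

    Raises
    ------
    ValueError
        If a required column is missing (the error names the column) or
        an outcome column references a screen the hierarchy does not
        declare.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"cannot read compound table {path}: {exc}") from exc

    for required in (_ID_COLUMN, _SMILES_COLUMN, _INCHI_COLUMN):
        if required not in frame.columns:
            raise ValueError(f"missing required column {required!r} in {path}")
    outcome_columns = [c for c in frame.columns
                       if c not in (_ID_COLUMN, _SMILES_COLUMN, _INCHI_COLUMN)]
    undeclared = sorted(set(outcome_columns) - hierarchy.screen_ids)
    if undeclared:
        raise ValueError(
            f"outcome columns {undeclared} not declared in the hierarchy"
        )

    if frame.empty:
        warnings.warn(f"compound table {path} has a header but no rows")
        return []

    records: list[CompoundRecord] = []
    for values in frame.to_numpy(dtype=object):
        data = dict(zip(frame.columns, values))
        smiles = data[_SMILES_COLUMN].strip()
        inchi = data[_INCHI_COLUMN].strip()
        flags: set[str] = set()
        if inchi and not inchi.startswith(STANDARD_INCHI_PREFIX):
            flags.add("nonstandard-inchi")
        if inchi and smiles and inchi_has_stereo_layer(inchi) \
                and not smiles_has_stereo(smiles):
            flags.add("non-isomeric-smiles")
        outcomes = {}
        for col in outcome_columns:
            raw = data[col]
            outcome = Outcome.from_string(raw)
            if raw.strip().upper() not in ("A", "I", "Q", "U", "ACTIVE",
                                           "INACTIVE", "INCONCLUSIVE",
                                           "UNTESTED", ""):
                warnings.warn(
                    f"unknown outcome {raw!r} for {data[_ID_COLUMN]} in screen "
                    f"{col}; coded as inconclusive"
                )
            outcomes[col] = outcome
        records.append(CompoundRecord(
            compound_id=data[_ID_COLUMN].strip(), smiles=smiles,
            inchi=inchi, outcomes=outcomes, flags=flags,
        ))
    return records


def write_compound_table(records: list[CompoundRecord], path: str | Path,
                         screen_ids: list[str] | None = None) -> None:
    """Write records back to CSV (deterministic: sorted by compound id)."""
    if screen_ids is None:
        seen: set[str] = set()
        for rec in records:
            seen.update(rec.outcomes)
        screen_ids = sorted(seen)
    rows = []
    for rec in sorted(records, key=lambda r: r.compound_id):
        row = {_ID_COLUMN: rec.compound_id, _SMILES_COLUMN: rec.smiles,
               _INCHI_COLUMN: rec.inchi}
        for sid in screen_ids:
            row[sid] = rec.outcomes.get(sid, Outcome.UNTESTED).value
        rows.append(row)
    pd.DataFrame(rows, columns=[_ID_COLUMN, _SMILES_COLUMN, _INCHI_COLUMN,
                                *screen_ids]).to_csv(path, index=False)


def read_sdf_conformers(path: str | Path) -> dict[str, tuple[np.ndarray, list[str]]]:
    """Read 3D conformers from an SDF file.

    Returns a map ``compound_id -> (n_atoms x 3 coordinates in Å,
    element symbol list)``.  The id is taken from the molecule title or,
    failing that, a ``compound_id`` property.  Coordinates and hydrogens
    are preserved exactly as read.  Duplicate ids: the last occurrence
    wins with a warning.  Molecules whose coordinates are all zero are
    kept but noted with a warning (flat/placeholder geometry).
    """
    out: dict[str, tuple[np.ndarray, list[str]]] = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"SDF record {i} in {path} could not be read; skipped")
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not name and mol.HasProp("compound_id"):
            name = mol.GetProp("compound_id")
        if not name:
            warnings.warn(f"SDF record {i} in {path} has no id; skipped")
            continue
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        if conf is None:
            warnings.warn(f"SDF record {name} has no coordinates; skipped")
            continue
        coords = np.array(conf.GetPositions(), dtype=float)
        if np.allclose(coords, 0.0) and mol.GetNumAtoms() > 1:
            warnings.warn(f"SDF record {name}: all-zero coordinates (no-3d)")
        if name in out:
            warnings.warn(f"duplicate id {name} in {path}; last occurrence kept")
        out[name] = (coords, [a.GetSymbol() for a in mol.GetAtoms()])
    return out


def write_sdf_conformers(conformers: dict[str, tuple[np.ndarray, list[str]]],
                         path: str | Path) -> None:
    """Write a conformer map to a V2000 SDF (ids sorted, no bonds).

    Intended for round-tripping coordinate sets; molecules are emitted
    as atom clouds without connectivity.
    """
    writer = Chem.SDWriter(str(path))
    try:
        for cid in sorted(conformers):
            coords, elements = conformers[cid]
            mol = Chem.RWMol()
            for sym in elements:
                atom = Chem.Atom(sym)
                atom.SetNoImplicit(True)
                mol.AddAtom(atom)
            conf = Chem.Conformer(len(elements))
            for i, xyz in enumerate(np.asarray(coords, dtype=float)):
                conf.SetAtomPosition(i, [float(v) for v in xyz])
            mol.AddConformer(conf)
            mol = mol.GetMol()
            mol.SetProp("_Name", cid)
            mol.UpdatePropertyCache(strict=False)
            writer.write(mol)
    finally:
        writer.close()


def write_curated_dataset(records: list[CompoundRecord], directory: str | Path,
                          formats: set[str] | None = None) -> dict:
    """Write a curated (labeled) dataset in the requested formats.

    ``formats`` is a subset of ``{"smiles_csv", "inchi_csv", "sdf"}``.
    Output is deterministic: records sorted by compound id.  Returns a
    manifest dict listing files, record counts and the toolkit version.
    """
    if formats is None:
        formats = {"smiles_csv", "inchi_csv"}
    unknown = formats - {"smiles_csv", "inchi_csv", "sdf"}
    if unknown:
        raise ValueError(f"unknown output formats: {sorted(unknown)}")
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {directory}: {exc}") from exc

    ordered = sorted((r for r in records), key=lambda r: r.compound_id)
    manifest: dict = {"files": {}, "n_records": len(ordered),
                      "version": __version__}
    if "smiles_csv" in formats:
        frame = pd.DataFrame(
            [{"compound_id": r.compound_id, "smiles": r.smiles,
              "label": r.label or ""} for r in ordered])
        frame.to_csv(directory / "curated_smiles.csv", index=False)
        manifest["files"]["curated_smiles.csv"] = len(ordered)
    if "inchi_csv" in formats:
        frame = pd.DataFrame(
            [{"compound_id": r.compound_id, "inchi": r.inchi,
              "label": r.label or ""} for r in ordered])
        frame.to_csv(directory / "curated_inchi.csv", index=False)
        manifest["files"]["curated_inchi.csv"] = len(ordered)
    if "sdf" in formats:
        writer = Chem.SDWriter(str(directory / "curated.sdf"))
        n_written = 0
        try:
            for rec in ordered:
                mol, err = parse_smiles(rec.smiles)
                if mol is None:
                    warnings.warn(
                        f"{rec.compound_id}: not writable to SDF ({err})")
                    continue
                mol.SetProp("_Name", rec.compound_id)
                if rec.label:
                    mol.SetProp("label", rec.label)
                writer.write(mol)
                n_written += 1
        finally:
            writer.close()
        manifest["files"]["curated.sdf"] = n_written
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def dataset_stats(records: list[CompoundRecord], scaffold_fn=None) -> StatsReport:
    """Summary statistics for a labeled dataset.

    ``scaffold_fn`` maps a record to a scaffold string (typically
    :func:`htscurate.splits.murcko_scaffold`); unique scaffolds are
    counted over its distinct return values.  With no ``scaffold_fn``
    the scaffold count is 0.
    """
    if not records:
        warnings.warn("dataset_stats called on zero records")
        return StatsReport(0, 0, 0)
    n_actives = sum(1 for r in records if r.label == "active")
    n_scaffolds = 0
    if scaffold_fn is not None:
        n_scaffolds = len({scaffold_fn(r) for r in records})
    return StatsReport(len(records), n_actives, n_scaffolds)


# ---------------------------------------------------------------------------
# Screen hierarchy serialization

def read_hierarchy(path: str | Path) -> ScreenHierarchy:
    """Load a screen hierarchy from YAML or JSON.

    Expected shape::

        screens:
          "626":  {stage: primary}
          "1488": {stage: confirmatory, parents: ["626"]}
          "1741": {stage: counter, parents: ["1488"]}
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    return hierarchy_from_dict(data)


def hierarchy_from_dict(data: dict) -> ScreenHierarchy:
    screens = data.get("screens", data)
    nodes = []
    for sid, spec in screens.items():
        nodes.append(ScreenNode(
            screen_id=str(sid),
            stage=Stage(spec["stage"]),
            parent_ids=tuple(str(p) for p in spec.get("parents", [])),
            description=spec.get("description", ""),
        ))
    return ScreenHierarchy(nodes)


def hierarchy_to_dict(hierarchy: ScreenHierarchy) -> dict:
    return {"screens": {
        sid: {"stage": node.stage.value,
              "parents": list(node.parent_ids),
              **({"description": node.description} if node.description else {})}
        for sid, node in sorted(hierarchy.nodes.items())
    }}


def write_hierarchy(hierarchy: ScreenHierarchy, path: str | Path) -> None:
    path = Path(path)
    data = hierarchy_to_dict(hierarchy)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(data, fh, sort_keys=True)
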