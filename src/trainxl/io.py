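"""Readers and writers for the pipeline's external formats.

Structures (mmCIF/PDB) and density maps (MRC/CCP4) go through gemmi;
cross-link tables are CSV in the residue-pair dialect exported by common
cross-link FDR tools (columns ``Protein1, Residue1, Protein2, Residue2``
plus optional ``Score`` and ``Decoy``).  Reports are plain TSV and
ChimeraX pseudobond (.pb) files for visual inspection.
"""

from __future__ import annotations

import logging
import os
from typing import TYPE_CHECKING, Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .core import (AssemblyModel, ChainMap, CrossLinkRecord, DensityGrid,
                   FormatError, SchemaError)

if TYPE_CHECKING:  # pragma: no cover
    from .validate import DistanceReport

logger = logging.getLogger("trainxl")

_SATISFIED_COLOR = "green"
_VIOLATED_COLOR = "purple"


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def read_structure(path: str | os.PathLike, fmt: str | None = None) -> AssemblyModel:
    """Read an mmCIF or PDB file into an :class:`AssemblyModel`.

    Author residue numbering is preserved.  Multi-model files use the first
    model (a warning is logged).  B-factors are kept per atom; downstream
    stages average them per residue when a confidence score is needed.
    """
    path = os.fspath(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(path)
        else:
            fmt_map = {"pdb": gemmi.CoorFormat.Pdb,
                       "mmcif": gemmi.CoorFormat.Mmcif}
            try:
                coor_fmt = fmt_map[fmt.lower()]
            except KeyError:
                raise FormatError(f"unknown structure format {fmt!r}")
            st = gemmi.read_structure(path, format=coor_fmt)
    except FormatError:
        raise
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read structure {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    if len(st) > 1:
        logger.warning("%s has %d models; using the first", path, len(st))
    model = st[0]
    chain_ids, res_ids, res_names, atom_names, elements = [], [], [], [], []
    coords, bfac = [], []
    for chain in model:
        for residue in chain:
            for atom in residue:
                chain_ids.append(chain.name)
                res_ids.append(residue.seqid.num)
                res_names.append(residue.name)
                atom_names.append(atom.name)
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                bfac.append(atom.b_iso)
    if not chain_ids:
        raise FormatError(f"no atoms in {path}")
    return AssemblyModel(
        chain_ids=np.array(chain_ids, dtype=object),
        res_ids=np.array(res_ids),
        res_names=np.array(res_names, dtype=object),
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        coords=np.array(coords),
        b_factors=np.array(bfac),
        source=path,
    )


def write_structure(model: AssemblyModel, path: str | os.PathLike) -> None:
    """Write a model as mmCIF (``.cif``/``.mmcif``) or PDB (``.pdb``)."""
    path = os.fspath(path)
    st = gemmi.Structure()
    st.name = "trainxl"
    gm = gemmi.Model("1")
    # gemmi copies on add_*, so group atoms first and build bottom-up
    chains: dict[str, dict[int, list[int]]] = {}
    for i in range(model.n_atoms):
        cid = str(model.chain_ids[i])
        chains.setdefault(cid, {}).setdefault(int(model.res_ids[i]), []).append(i)
    for cid, residues in chains.items():
        chain = gemmi.Chain(cid)
        for res_id, atom_idx in residues.items():
            res = gemmi.Residue()
            res.name = str(model.res_names[atom_idx[0]])
            res.seqid = gemmi.SeqId(res_id, " ")
            for i in atom_idx:
                atom = gemmi.Atom()
                atom.name = str(model.atom_names[i])
                atom.element = gemmi.Element(str(model.elements[i]) or "C")
                atom.pos = gemmi.Position(*model.coords[i])
                atom.b_iso = float(model.b_factors[i])
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


# ---------------------------------------------------------------------------
# Cross-link tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("protein1", "residue1", "protein2", "residue2")
_DECOY_TRUE = {"1", "true", "yes", "t", "d", "decoy"}


def read_crosslinks(path: str | os.PathLike) -> list[CrossLinkRecord]:
    """Read a residue-pair cross-link CSV.

    Required columns (case-insensitive): Protein1, Residue1, Protein2,
    Residue2.  Optional: Score, Decoy.  Decoy rows are dropped; rows whose
    residue numbers do not parse are skipped with the row index logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in _REQUIRED_COLUMNS if c not in colmap]
    if missing:
        raise SchemaError(f"cross-link table missing columns: {missing}")
    records: list[CrossLinkRecord] = []
    for idx, row in df.iterrows():
        if "decoy" in colmap:
            if str(row[colmap["decoy"]]).strip().lower() in _DECOY_TRUE:
                continue
        try:
            res_a = int(float(row[colmap["residue1"]]))
            res_b = int(float(row[colmap["residue2"]]))
        except (TypeError, ValueError):
            logger.warning("row %d: unparseable residue number, skipped", idx)
            continue
        score = None
        if "score" in colmap:
            raw = str(row[colmap["score"]]).strip()
            if raw:
                try:
                    score = float(raw)
                except ValueError:
                    score = None
        try:
            records.append(CrossLinkRecord(
                protein_a=str(row[colmap["protein1"]]).strip(),
                residue_a=res_a,
                protein_b=str(row[colmap["protein2"]]).strip(),
                residue_b=res_b,
                score=score,
            ))
        except ValueError as exc:
            logger.warning("row %d rejected: %s", idx, exc)
    return records


def write_crosslinks(records: Iterable[CrossLinkRecord],
                     path: str | os.PathLike) -> None:
    rows = [{"Protein1": r.protein_a, "Residue1": r.residue_a,
             "Protein2": r.protein_b, "Residue2": r.residue_b,
             "Score": "" if r.score is None else r.score}
            for r in records]
    pd.DataFrame(rows, columns=["Protein1", "Residue1", "Protein2",
                                "Residue2", "Score"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Chain maps (YAML)
# ---------------------------------------------------------------------------

def read_chainmap(path: str | os.PathLike) -> ChainMap:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError("chain map YAML must be a mapping of chains")
    return ChainMap.from_dict(data)


def write_chainmap(chainmap: ChainMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(chainmap.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

def read_density(path: str | os.PathLike) -> DensityGrid:
    """Read an MRC/CCP4 map; voxel size and origin come from the header."""
    try:
        ccp4 = gemmi.read_ccp4_map(os.fspath(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read density map {path}: {exc}") from exc
    grid = ccp4.grid
    data = np.array(grid, copy=True)
    cell = grid.unit_cell
    voxel = np.array([cell.a / grid.nu, cell.b / grid.nv, cell.c / grid.nw])
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    return DensityGrid(data=data, voxel=voxel, origin=origin)


def write_density(grid: DensityGrid, path: str | os.PathLike) -> None:
    data = np.ascontiguousarray(grid.data, dtype=np.float32)
    fg = gemmi.FloatGrid(data)
    nx, ny, nz = data.shape
    fg.set_unit_cell(gemmi.UnitCell(nx * grid.voxel[0], ny * grid.voxel[1],
                                    nz * grid.voxel[2], 90.0, 90.0, 90.0))
    fg.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fg
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(os.fspath(path))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ["Protein1", "Residue1", "Protein2", "Residue2", "LinkClass",
                   "Distance", "ChainA", "ChainB", "Classification",
                   "Rescued", "RescueReason"]


def write_report(reports: Sequence["DistanceReport"],
                 path: str | os.PathLike) -> None:
    """Write per-link classification results as TSV (header always present)."""
    rows = []
    for r in reports:
        rows.append({
            "Protein1": r.record.protein_a,
            "Residue1": r.record.residue_a,
            "Protein2": r.record.protein_b,
            "Residue2": r.record.residue_b,
            "LinkClass": r.record.link_class,
            "Distance": "" if r.distance is None else f"{r.distance:.2f}",
            "ChainA": r.chain_a or "",
            "ChainB": r.chain_b or "",
            "Classification": r.classification,
            "Rescued": "yes" if r.rescued else "no",
            "RescueReason": r.rescue_reason or "",
        })
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, sep="\t",
                                                       index=False)


def write_pseudobonds(reports: Sequence["DistanceReport"],
                      path: str | os.PathLike) -> None:
    """ChimeraX pseudobond file: one Cα–Cα bond per mapped link.

    Satisfied links are drawn green, violated ones purple, matching the
    common convention for the 35 Å DSSO criterion.  Unmapped links are
    skipped (there is nothing to attach the bond to).
    """
    lines = ["; trainxl cross-link pseudobonds"]
    for r in reports:
        if r.classification == "unmapped" or r.chain_a is None:
            continue
        color = (_SATISFIED_COLOR if r.classification == "satisfied"
                 else _VIOLATED_COLOR)
        lines.append(f"/{r.chain_a}:{r.record.residue_a}@CA "
                     f"/{r.chain_b}:{r.record.residue_b}@CA {color}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
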