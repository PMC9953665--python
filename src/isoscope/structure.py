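"""Atomic-coordinate parsing, inter-chain contacts and metal coordination.

Distance-only criteria replace any hydrogen-bond geometry: residue pairs on
different chains are interface contacts when any heavy-atom pair is within
the cutoff (default 4.0 A); a residue coordinates a metal when any of its
N/O/S atoms is within the metal cutoff (default 2.8 A).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

DEFAULT_INTERFACE_CUTOFF = 4.0
DEFAULT_METAL_CUTOFF = 2.8
DEFAULT_METALS = ("ZN", "CA", "MG", "MN", "FE", "CU", "NI", "CO", "NA", "K")

CONTACT_COLUMNS = [
    "chain_i",
    "residue_i",
    "resname_i",
    "chain_j",
    "residue_j",
    "resname_j",
    "min_distance",
    "kind",
    "structure_id",
]


@dataclass
class StructureModel:
    structure_id: str
    atoms: struc.AtomArray

    @property
    def n_chains(self) -> int:
        return len(set(self.atoms.chain_id))

    def residues(self) -> List[Tuple[str, int, str]]:
        seen = []
        prev = None
        for chain, res, name in zip(
            self.atoms.chain_id, self.atoms.res_id, self.atoms.res_name
        ):
            key = (str(chain), int(res), str(name))
            if key != prev:
                if key not in seen:
                    seen.append(key)
                prev = key
        return seen


class PDBParseError(ValueError):
    pass


def load_structure(
    pdb_text_or_path: str | os.PathLike,
    model: int = 1,
    structure_id: str = "structure",
    all_models: bool = False,
) -> StructureModel | List[StructureModel]:
    """Parse PDB text or a PDB file path.

    By default the first model of a multi-model file is selected; with
    ``all_models`` every model is returned.  Altloc conflicts keep the
    highest-occupancy conformer.
    """
    text: str
    if isinstance(pdb_text_or_path, (str,)) and "\n" in pdb_text_or_path:
        text = pdb_text_or_path
    else:
        with open(pdb_text_or_path) as fh:
            text = fh.read()
    if "ATOM" not in text and "HETATM" not in text:
        raise PDBParseError("no ATOM/HETATM records found")
    try:
        pdb = PDBFile.read(io.StringIO(text))
        if all_models:
            stack = pdb.get_structure(altloc="occupancy")
            return [
                StructureModel(f"{structure_id}#model{i + 1}", stack[i])
                for i in range(stack.stack_depth())
            ]
        atoms = pdb.get_structure(model=model, altloc="occupancy")
    except PDBParseError:
        raise
    except Exception as exc:  # biotite raises various error types
        raise PDBParseError(f"malformed PDB input: {exc}") from exc
    return StructureModel(structure_id, atoms)


def _heavy_mask(atoms: struc.AtomArray) -> np.ndarray:
    return np.char.upper(atoms.element.astype("U3")) != "H"


def inter_chain_contacts(
    s: StructureModel, cutoff: float = DEFAULT_INTERFACE_CUTOFF
) -> pd.DataFrame:
    """Residue pairs on different chains with any heavy-atom pair <= cutoff.

    Rows are canonically ordered (chain_i, residue_i) < (chain_j, residue_j)
    and report the minimum heavy-atom distance.
    """
    atoms = s.atoms[_heavy_mask(s.atoms)]
    if len(atoms) == 0 or len(set(atoms.chain_id)) < 2:
        return pd.DataFrame(columns=CONTACT_COLUMNS)
    coords = atoms.coord
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    best: Dict[Tuple, Tuple[float, str, str]] = {}
    for i, j in pairs:
        ci, cj = str(atoms.chain_id[i]), str(atoms.chain_id[j])
        if ci == cj:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        ri, rj = int(atoms.res_id[i]), int(atoms.res_id[j])
        ni, nj = str(atoms.res_name[i]), str(atoms.res_name[j])
        a, b = (ci, ri, ni), (cj, rj, nj)
        if (b[0], b[1]) < (a[0], a[1]):
            a, b = b, a
        key = (a[0], a[1], b[0], b[1])
        if key not in best or d < best[key][0]:
            best[key] = (d, a[2], b[2])
    rows = [
        {
            "chain_i": k[0],
            "residue_i": k[1],
            "resname_i": v[1],
            "chain_j": k[2],
            "residue_j": k[3],
            "resname_j": v[2],
            "min_distance": v[0],
            "kind": "interface",
            "structure_id": s.structure_id,
        }
        for k, v in sorted(best.items())
    ]
    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)


def metal_coordination(
    s: StructureModel,
    metals: Sequence[str] = DEFAULT_METALS,
    cutoff: float = DEFAULT_METAL_CUTOFF,
) -> pd.DataFrame:
    """Residues whose N/O/S atoms lie within ``cutoff`` of a metal atom."""
    atoms = s.atoms
    elements = np.char.upper(atoms.element.astype("U3"))
    metal_set = {m.upper() for m in metals}
    is_metal = np.isin(elements, sorted(metal_set))
    donors = np.isin(elements, ["N", "O", "S"]) & ~is_metal
    if not is_metal.any() or not donors.any():
        return pd.DataFrame(columns=CONTACT_COLUMNS)
    m_atoms = atoms[is_metal]
    d_atoms = atoms[donors]
    tree = cKDTree(d_atoms.coord)
    rows: Dict[Tuple, Dict] = {}
    for mi in range(len(m_atoms)):
        for di in tree.query_ball_point(m_atoms.coord[mi], cutoff):
            d = float(np.linalg.norm(m_atoms.coord[mi] - d_atoms.coord[di]))
            key = (
                str(d_atoms.chain_id[di]),
                int(d_atoms.res_id[di]),
                str(m_atoms.chain_id[mi]),
                int(m_atoms.res_id[mi]),
            )
            if key not in rows or d < rows[key]["min_distance"]:
                rows[key] = {
                    "chain_i": key[0],
                    "residue_i": key[1],
                    "resname_i": str(d_atoms.res_name[di]),
                    "chain_j": key[2],
                    "residue_j": key[3],
                    "resname_j": str(m_atoms.res_name[mi]),
                    "min_distance": d,
                    "kind": "metal-coordination",
                    "structure_id": s.structure_id,
                }
    return pd.DataFrame(
        [rows[k] for k in sorted(rows)], columns=CONTACT_COLUMNS
    )


def variant_interface_table(
    contact_tables: Sequence[pd.DataFrame],
    residue_to_precursor: Mapping[Tuple[str, int], int],
    variant_positions: Mapping[int, str],
) -> pd.DataFrame:
    """Join variant precursor positions to contacts across structures.

    ``residue_to_precursor`` maps (chain_id, residue_number) to the 1-based
    precursor position; ``variant_positions`` maps precursor position to a
    variant source label.  One output row per (precursor position, source)
    with an x-mark column per structure; contact residues missing from the
    numbering map produce warning rows instead of failing.
    """
    structures: List[str] = []
    per_position: Dict[int, Dict[str, str]] = {}
    warnings: List[Dict] = []
    for table in contact_tables:
        for _, row in table.iterrows():
            sid = row["structure_id"]
            if sid not in structures:
                structures.append(sid)
            for chain_col, res_col in (("chain_i", "residue_i"), ("chain_j", "residue_j")):
                key = (row[chain_col], int(row[res_col]))
                if key not in residue_to_precursor:
                    warnings.append(
                        {
                            "precursor_position": -1,
                            "variant_source": f"unmapped:{key[0]}:{key[1]}",
                            "structures": sid,
                            "warning": "unmapped_residue",
                        }
                    )
                    continue
                pos = residue_to_precursor[key]
                per_position.setdefault(pos, {})[sid] = "x"

    rows: List[Dict] = []
    for pos, source in sorted(variant_positions.items()):
        if pos not in per_position:
            continue
        row: Dict = {
            "precursor_position": pos,
            "variant_source": source,
            "structures": ";".join(s for s in structures if s in per_position[pos]),
            "warning": "",
        }
        for sid in structures:
            row[sid] = per_position[pos].get(sid, "")
        rows.append(row)
    for w in warnings:
        for sid in structures:
            w.setdefault(sid, "")
        rows.append(w)
    cols = ["precursor_position", "variant_source", "structures", "warning"] + structures
    return pd.DataFrame(rows, columns=cols)
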