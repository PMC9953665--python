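"""Toy multi-chain structure generator with a known contact graph and metal site."""

from __future__ import annotations

import io
from typing import Dict, List, Set, Tuple

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .config import StructureSpec


class GenerationError(ValueError):
    """The requested geometry is infeasible for this generator."""


def simulate_structure(spec: StructureSpec, seed: int) -> Tuple[str, Set[Tuple[str, int, str, int]], List[Tuple[str, int]]]:
    """Place residues so configured contacts sit at ``contact_distance`` (3.5 A)
    and all other inter-residue pairs are >= 6 A; one optional Zn site has
    designated first-chain residues with N atoms at ``metal_distance``.

    Returns (PDB text, canonical inter-chain contact set, metal residues).
    Limits: a residue may appear in at most one contact pair, and contact
    pairs must be inter-chain.
    """
    rng = np.random.default_rng([seed, 3])
    chains = list(spec.chains)
    involved: Dict[Tuple[str, int], int] = {}
    for idx, (a, b) in enumerate(spec.contacts):
        if a[0] == b[0]:
            raise GenerationError(f"contact pair {a}-{b} is intra-chain")
        for r in (a, b):
            if r[0] not in spec.chains or not 1 <= r[1] <= spec.chains[r[0]]:
                raise GenerationError(f"contact residue {r} outside chain spec")
            if r in involved:
                raise GenerationError(f"residue {r} appears in multiple contact pairs")
            involved[r] = idx
    metal_chain = chains[0] if spec.metal_residues else None
    for r in spec.metal_residues:
        if not 1 <= r <= spec.chains[chains[0]]:
            raise GenerationError(f"metal residue {r} outside chain {chains[0]}")
        if (chains[0], r) in involved:
            raise GenerationError("metal residues may not also be contact residues")

    atoms: List[struc.Atom] = []

    def add_atom(chain: str, res_id: int, res_name: str, atom_name: str,
                 element: str, coord: np.ndarray, hetero: bool = False) -> None:
        atoms.append(
            struc.Atom(
                coord,
                chain_id=chain,
                res_id=res_id,
                res_name=res_name,
                atom_name=atom_name,
                element=element,
                hetero=hetero,
            )
        )

    # default grid placement, one CA per residue, chains well separated
    for ci, chain in enumerate(chains):
        for r in range(1, spec.chains[chain] + 1):
            if (chain, r) in involved:
                continue
            if metal_chain == chain and r in spec.metal_residues:
                continue
            coord = np.array([spec.grid_spacing * r, 40.0 * ci, 0.0])
            add_atom(chain, r, "GLY", "CA", "C", coord)

    # contact pairs in a dedicated region, 50 A apart from each other
    for idx, (a, b) in enumerate(spec.contacts):
        base = np.array([500.0 + 25.0 * idx, 0.0, 0.0])
        add_atom(a[0], a[1], "ALA", "CA", "C", base)
        add_atom(b[0], b[1], "ALA", "CA", "C", base + np.array([spec.contact_distance, 0.0, 0.0]))

    # metal site: Zn plus HIS nitrogens at metal_distance, on the first chain
    metal_residues: List[Tuple[str, int]] = []
    if spec.metal_residues:
        zn_pos = np.array([-500.0, 0.0, 0.0])
        directions = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0], [0, -1, 0], [0, 0, -1]],
            dtype=float,
        )
        if len(spec.metal_residues) > len(directions):
            raise GenerationError("at most 6 metal-coordinating residues supported")
        for k, r in enumerate(spec.metal_residues):
            d = directions[k]
            add_atom(metal_chain, r, "HIS", "ND1", "N", zn_pos + d * spec.metal_distance)
            add_atom(metal_chain, r, "HIS", "CA", "C", zn_pos + d * (spec.metal_distance + 1.5))
            metal_residues.append((metal_chain, r))
        zn_res_id = spec.chains[metal_chain] + 1
        add_atom(metal_chain, zn_res_id, "ZN", "ZN", "ZN", zn_pos, hetero=True)

    array = struc.array(atoms)
    pdb = PDBFile()
    pdb.set_structure(array)
    buf = io.StringIO()
    pdb.write(buf)

    contact_set: Set[Tuple[str, int, str, int]] = set()
    for a, b in spec.contacts:
        if (b[0], b[1]) < (a[0], a[1]):
            a, b = b, a
        contact_set.add((a[0], a[1], b[0], b[1]))
    return buf.getvalue(), contact_set, metal_residues
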