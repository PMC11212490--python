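"""Shared fixtures: programmatic structure builders and SASA oracles.

All structure fixtures are generated at test time — an ideal α-helix
backbone writer for PDB-format inputs and a Bio.PDB builder for bare atom
clusters — plus an independent Monte-Carlo solvent-accessibility sampler
used as the oracle for the Shrake–Rupley implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio.PDB.Atom import Atom
from Bio.PDB.Chain import Chain
from Bio.PDB.Model import Model
from Bio.PDB.Residue import Residue
from Bio.PDB.Structure import Structure

AA_3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

_BACKBONE = (
    # (atom name, element, radius offset Å, angle offset deg, z offset Å)
    ("N", "N", 1.6, -28.0, -0.6),
    ("CA", "C", 2.3, 0.0, 0.0),
    ("C", "C", 2.0, 26.0, 0.5),
    ("O", "O", 2.1, 40.0, 1.1),
    # pseudo side chain pointing outward, so surface residues reach
    # realistic SASA values (~1-2 nm²)
    ("CB", "C", 3.4, -10.0, 0.2),
    ("CG", "C", 4.7, -12.0, 0.4),
)


def helix_pdb_text(
    sequence: str,
    chain_id: str = "A",
    start: int = 1,
    gap_after: int | None = None,
    gap_size: int = 5,
    mse_at: int | None = None,
) -> str:
    """PDB text for an ideal α-helix backbone (N, CA, C, O per residue).

    ``gap_after`` introduces a numbering gap of ``gap_size`` after that
    many residues; ``mse_at`` (1-based) replaces that residue with a
    selenomethionine HETATM record.
    """
    lines = []
    serial = 1
    resseq = start
    for i, aa in enumerate(sequence):
        if gap_after is not None and i == gap_after:
            resseq += gap_size
        is_mse = mse_at is not None and i == mse_at - 1
        resname = "MSE" if is_mse else AA_3[aa]
        record = "HETATM" if is_mse else "ATOM  "
        theta0 = math.radians(i * 100.0)
        z0 = i * 1.5
        for name, element, r, dtheta, dz in _BACKBONE:
            theta = theta0 + math.radians(dtheta)
            x, y, z = r * math.cos(theta), r * math.sin(theta), z0 + dz
            name_field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"{record}{serial:5d} {name_field} {resname:>3s} {chain_id}"
                f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}\n"
            )
            serial += 1
        resseq += 1
    lines.append("END\n")
    return "".join(lines)


def atom_cluster(coords: np.ndarray, elements: list[str]) -> Structure:
    """A bare Bio.PDB structure holding one pseudo-residue of free atoms."""
    structure = Structure("cluster")
    model = Model(0)
    chain = Chain("A")
    residue = Residue((" ", 1, " "), "UNK", "")
    for i, (xyz, element) in enumerate(zip(np.asarray(coords, float), elements)):
        atom = Atom(
            name=f"X{i}",
            coord=np.asarray(xyz, dtype=float),
            bfactor=0.0,
            occupancy=1.0,
            altloc=" ",
            fullname=f" X{i:<2d}"[:4],
            serial_number=i + 1,
            element=element,
        )
        residue.add(atom)
    chain.add(residue)
    model.add(chain)
    structure.add(model)
    return structure


def monte_carlo_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Independent per-atom SASA oracle by uniform random surface sampling.

    For each atom, points are drawn uniformly on its probe-expanded sphere
    and counted as accessible when outside every other atom's expanded
    sphere; SASA is the accessible fraction times the sphere area (Å²).
    """
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    expanded = np.asarray(radii, float) + probe
    n_atoms = len(coords)
    out = np.empty(n_atoms)
    for i in range(n_atoms):
        directions = rng.normal(size=(n_points, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        points = coords[i] + expanded[i] * directions
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        out[i] = accessible.mean() * 4.0 * math.pi * expanded[i] ** 2
    return out


@pytest.fixture
def helix_pdb(tmp_path):
    """Factory fixture: write a helix PDB file and return its path."""

    def make(sequence: str, filename: str = "helix.pdb", **kwargs):
        path = tmp_path / filename
        path.write_text(helix_pdb_text(sequence, **kwargs))
        return path

    return make
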