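"""Per-residue solvent-accessible surface area and its sequence smoothing.

SASA is computed with the Shrake–Rupley rolling-probe algorithm as
implemented in Biopython (quasi-uniform sphere points on each atom's
probe-expanded van der Waals sphere; unoccluded fraction × sphere area),
with the element-radius table from :mod:`memsense.constants`. Values are
aggregated per residue and reported in nm² (Ų/100).

Surface exposure of a single residue is a noisy quantity; the screening
pipeline therefore smooths it along the sequence, assigning residue n the
mean raw SASA of the n−4..n+4 vicinity (truncated at fragment ends).
"""

from __future__ import annotations

import math
from typing import Sequence

from Bio.PDB.SASA import ShrakeRupley

from .constants import VDW_DEFAULT, VDW_RADII

#: Default probe radius in Å (water).
PROBE_RADIUS = 1.4

#: Default number of sphere sample points per atom.
SPHERE_POINTS = 960

#: Default half-width of the sequence smoothing window (residues).
SMOOTHING_HALF_WIDTH = 4

ResidueKey = tuple[str, int, str]  # (chain id, author number, insertion code)


def _radii_for(model) -> dict[str, float]:
    """Radius table covering every element present in the model."""
    radii = dict(VDW_RADII)
    for atom in model.get_atoms():
        element = (atom.element or "").upper().strip()
        if element and element not in radii:
            radii[element] = VDW_DEFAULT
    return radii


def compute_sasa(
    model,
    probe_radius: float = PROBE_RADIUS,
    sphere_points: int = SPHERE_POINTS,
) -> dict[ResidueKey, float]:
    """Per-residue SASA (nm²) for every residue of a Bio.PDB model.

    All atoms present in the model act as occluders, including ligands and
    waters if the caller kept them (they genuinely bury protein surface).
    Hydrogens should be stripped by the caller beforehand if undesired.
    """
    sr = ShrakeRupley(
        probe_radius=probe_radius,
        n_points=sphere_points,
        radii_dict=_radii_for(model),
    )
    sr.compute(model, level="R")
    out: dict[ResidueKey, float] = {}
    for chain in model:
        for residue in chain:
            _, resseq, icode = residue.id
            out[(chain.id, resseq, icode)] = residue.sasa / 100.0  # Å² → nm²
    return out


def smooth_sasa(
    values: Sequence[float | None], half_width: int = SMOOTHING_HALF_WIDTH
) -> list[float | None]:
    """Sequence-local mean of per-residue SASA over one contiguous fragment.

    Residue n receives the mean of positions n−h..n+h, truncated at the
    fragment ends; ``None`` entries (residues without coordinates) are
    excluded from neighbours' means and stay ``None`` themselves.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    n = len(values)
    out: list[float | None] = []
    for i in range(n):
        if values[i] is None:
            out.append(None)
            continue
        window = [
            v
            for v in values[max(0, i - half_width) : min(n, i + half_width + 1)]
            if v is not None
        ]
        out.append(sum(window) / len(window))
    return out


def sphere_area(radius: float) -> float:
    """Surface area 4πr² — the single-atom SASA with r = vdW + probe (Å²)."""
    return 4.0 * math.pi * radius * radius
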