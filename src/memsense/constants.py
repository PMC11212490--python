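"""Fitted constants of the membrane-interaction free-energy model.

The model chains four transformations of a peptide's relative
curvature-sensing free energy ΔΔF (kJ/mol, from coarse-grained MD or a
sequence regressor):

1. length extrapolation to the 24-residue reference,
2. a per-unit-charge correction for anionic membranes,
3. an affine map plus strain-scaled curvature correction to the absolute
   vesicle-binding free energy ΔFsm(R),
4. a sigmoid switch from ΔFsm to the bound probability Pm.

All constants were fitted against coarse-grained MD / thermodynamic
integration data upstream of this package; they are bundled here as frozen
defaults and may be overridden via :func:`PhysicsConstants.from_file`.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path


class _Flat:
    """Sentinel for a flat (infinite-radius) membrane."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "FLAT"


#: Flat-membrane sentinel: pass as a radius to select the zero-strain limit.
FLAT = _Flat()


class ConstantsError(ValueError):
    """Raised when a constants set violates its internal consistency rules."""


@dataclasses.dataclass(frozen=True)
class PhysicsConstants:
    """The fitted constants of the free-energy chain and the class thresholds.

    Attributes
    ----------
    aL, bL
        Slope (kJ/mol per residue) and intercept (kJ/mol) of the linear
        length dependence of ΔΔF used for extrapolation to 24 residues.
    cz
        Free-energy shift per unit of peptide net charge on anionic
        membranes (kJ/mol); negative, so cationic peptides gain affinity.
    alpha, beta
        Slope (dimensionless) and intercept (kJ/mol) of the affine
        ΔΔF → ΔFsm map for a flat membrane.
    eps_ref
        Relative strain of the stretched reference membrane (dimensionless);
        divides ΔΔF in the curvature-correction term.
    ns_over_nm
        Ratio of solvent to membrane-bound microstate counts entering the
        binding-probability sigmoid.
    thermal_energy
        RT in kJ/mol (default 2.478, i.e. 298.15 K).
    sensor_hi, sensor_lo
        Class boundaries on ΔΔF (kJ/mol): non-binder above ``sensor_hi``,
        binder below ``sensor_lo``, sensor in between (inclusive).
    ref_radius
        Default vesicle radius in nm for reporting ΔFsm and Pm.
    ref_length
        Reference peptide length (residues) of the underlying dataset.
    """

    aL: float = -1.03
    bL: float = 3.28
    cz: float = -0.93
    alpha: float = 3.83
    beta: float = 12.27
    eps_ref: float = 0.165
    ns_over_nm: float = 5.2e3
    thermal_energy: float = 2.478
    sensor_hi: float = -6.4
    sensor_lo: float = -10.0
    ref_radius: float = 50.0
    ref_length: int = 24

    def __post_init__(self) -> None:
        if not self.aL < 0:
            raise ConstantsError("length slope aL must be negative")
        if not self.eps_ref > 0:
            raise ConstantsError("reference strain eps_ref must be positive")
        if not self.ns_over_nm > 1:
            raise ConstantsError("ns_over_nm must exceed 1")
        if not (self.sensor_lo < self.sensor_hi < 0):
            raise ConstantsError("need sensor_lo < sensor_hi < 0")
        if self.ref_length != 24:
            raise ConstantsError("reference length is fixed at 24 residues")
        if not self.thermal_energy > 0:
            raise ConstantsError("thermal energy must be positive")
        # the extrapolation denominator aL*L + bL must not vanish on [7, 24]
        for L in range(7, 25):
            if abs(self.aL * L + self.bL) < 1e-9:
                raise ConstantsError(
                    f"length-extrapolation denominator vanishes at L={L}"
                )

    @property
    def half_occupancy_dF(self) -> float:
        """ΔFsm at which the bound probability is exactly 1/2 (kJ/mol)."""
        return -self.thermal_energy * math.log(self.ns_over_nm)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhysicsConstants":
        """Load constants from a ``key = value`` text file.

        Unknown keys raise; missing keys keep their defaults. Lines that are
        blank or start with ``#`` are ignored.
        """
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        overrides: dict[str, float | int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise ConstantsError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = stripped.partition("=")
            key = key.strip()
            if key not in fields:
                raise ConstantsError(
                    f"{path}:{lineno}: unknown constant {key!r}; "
                    f"valid keys: {', '.join(sorted(fields))}"
                )
            overrides[key] = int(value) if key == "ref_length" else float(value)
        return cls(**overrides)

    def as_dict(self) -> dict[str, float | int]:
        return dataclasses.asdict(self)


#: Default constants instance shared across the package.
DEFAULT_CONSTANTS = PhysicsConstants()


# Fauchère & Pliška (1983) side-chain hydrophobicity scale, π = log P
# (octanol/water) relative to glycine. Dimensionless; used for the mean
# hydrophobicity descriptor and inside the hydrophobic moment.
FAUCHERE_PLISKA: dict[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: The 20 natural amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

# Per-element van der Waals radii (Å) used for solvent-accessible surface
# area; the Bondi/standard set also used by common SASA implementations.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "FE": 1.94,
    "NA": 2.27, "K": 2.75, "MN": 1.97, "CU": 1.40,
}

#: Fallback vdW radius (Å) for elements missing from the table.
VDW_DEFAULT: float = 1.80
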