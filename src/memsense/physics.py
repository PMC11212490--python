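"""Free-energy transforms: length extrapolation, charge correction,
curvature-dependent binding free energy, binding probability, and the
three-class activity call (non-binder / curvature sensor / binder).

The chain, for a peptide with raw relative sensing free energy ΔΔF,
length L and net charge z, on a vesicle of radius R (nm):

    ΔΔF_L24 = [(aL·24 + bL) / (aL·L + bL)] · ΔΔF
    ΔΔF_adj = ΔΔF_L24 + cz·z                     (anionic membranes only)
    ΔFsm(R) = α·ΔΔF_eff + β + (ΔΔF_eff/ε_ref)·(1/R² + 2/R)
    Pm      = 1 / (1 + (Ns/Nm)·exp(ΔFsm / RT))

where ΔΔF_eff is ΔΔF_L24 for neutral membranes and ΔΔF_adj for anionic
ones. Class thresholds act on ΔΔF_eff: > −6.4 non-binder, in
[−10.0, −6.4] sensor (inclusive), < −10.0 binder.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Literal, Sequence

from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS, FLAT, ConstantsError, PhysicsConstants, _Flat

logger = logging.getLogger(__name__)

Radius = "float | _Flat"
Label = Literal["non-binder", "sensor", "binder"]

#: Valid class labels, in order of increasing membrane affinity.
LABELS: tuple[str, ...] = ("non-binder", "sensor", "binder")


class LengthDomainError(ValueError):
    """Peptide length outside the supported 7-24 residue range."""


class RadiusDomainError(ValueError):
    """Non-positive vesicle radius."""


@dataclasses.dataclass(frozen=True)
class MembraneContext:
    """Target membrane: surface chemistry and curvature.

    ``kind`` selects whether the charge correction applies ("anionic") or
    not ("neutral"); ``radius`` is the vesicle radius in nm, or the FLAT
    sentinel for a planar membrane.
    """

    kind: Literal["neutral", "anionic"] = "neutral"
    radius: "float | _Flat" = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("neutral", "anionic"):
            raise ValueError(f"membrane kind must be neutral|anionic, got {self.kind!r}")
        if not isinstance(self.radius, _Flat) and not self.radius > 0:
            raise RadiusDomainError(f"vesicle radius must be positive, got {self.radius}")

    @property
    def is_anionic(self) -> bool:
        return self.kind == "anionic"


def length_extrapolate(
    ddF: float, L: int, constants: PhysicsConstants = DEFAULT_CONSTANTS
) -> float:
    """Extrapolate a raw ΔΔF measured at length ``L`` to the 24-residue
    reference length.

    ΔΔF scales linearly with length, so the extrapolation is the ratio of
    the linear trend evaluated at 24 and at L. Identity at L = 24.
    """
    if not (7 <= L <= 24):
        raise LengthDomainError(f"peptide length must be in [7, 24], got {L}")
    if not math.isfinite(ddF):
        raise ValueError("ddF must be finite")
    denom = constants.aL * L + constants.bL
    if abs(denom) < 1e-9:
        raise ConstantsError(f"extrapolation denominator vanishes at L={L}")
    return (constants.aL * constants.ref_length + constants.bL) / denom * ddF


def charge_adjust(
    ddF_L24: float, z: int, constants: PhysicsConstants = DEFAULT_CONSTANTS
) -> float:
    """Apply the anionic-membrane charge correction: ΔΔF_adj = ΔΔF_L24 + cz·z.

    Each unit of positive charge lowers ΔΔF by |cz| = 0.93 kJ/mol. Charges
    outside the range the underlying data covered trigger a logged caution.
    """
    if not math.isfinite(ddF_L24):
        raise ValueError("ddF_L24 must be finite")
    if z > 4 or z < -1:
        logger.warning(
            "net charge z=%+d is outside the well-sampled range [-1, +4]; "
            "the linear charge correction may extrapolate poorly", z,
        )
    return ddF_L24 + constants.cz * z


def vesicle_strain(R: "float | _Flat") -> float:
    """Relative strain ε(R) = 1/R² + 2/R of a vesicle of radius R (nm).

    Returns 0 for a flat membrane; strictly decreasing in R.
    """
    if isinstance(R, _Flat):
        return 0.0
    if not R > 0:
        raise RadiusDomainError(f"vesicle radius must be positive, got {R}")
    return 1.0 / (R * R) + 2.0 / R


def binding_free_energy(
    ddF_eff: float,
    R: "float | _Flat",
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Absolute vesicle-binding free energy ΔFsm(R) in kJ/mol.

    Affine in ΔΔF_eff at fixed R: the flat-membrane part α·ΔΔF_eff + β
    plus the curvature correction (ΔΔF_eff / ε_ref)·ε(R).
    """
    if not math.isfinite(ddF_eff):
        raise ValueError("ddF_eff must be finite")
    strain = vesicle_strain(R)
    return (
        constants.alpha * ddF_eff
        + constants.beta
        + (ddF_eff / constants.eps_ref) * strain
    )


# exp() overflows near 710; clamp the dimensionless exponent well before that.
_EXP_CLAMP = 700.0


def binding_probability(
    dFsm: float, constants: PhysicsConstants = DEFAULT_CONSTANTS
) -> float:
    """Equilibrium membrane-bound probability Pm = 1/(1 + (Ns/Nm)·e^{ΔFsm/RT}).

    Strictly decreasing in ΔFsm; saturates smoothly to 0/1 for extreme
    arguments instead of overflowing. Equals 1/2 at ΔFsm = −RT·ln(Ns/Nm).
    """
    if not math.isfinite(dFsm):
        raise ValueError("dFsm must be finite")
    x = dFsm / constants.thermal_energy
    x = max(-_EXP_CLAMP, min(_EXP_CLAMP, x))
    return 1.0 / (1.0 + constants.ns_over_nm * math.exp(x))


def classify(
    ddF_eff: float, constants: PhysicsConstants = DEFAULT_CONSTANTS
) -> str:
    """Three-class activity call on the effective ΔΔF (kJ/mol).

    non-binder above −6.4; sensor in [−10.0, −6.4] (both ends inclusive);
    binder below −10.0.
    """
    if not math.isfinite(ddF_eff):
        raise ValueError("ddF_eff must be finite")
    if ddF_eff > constants.sensor_hi:
        return "non-binder"
    if ddF_eff >= constants.sensor_lo:
        return "sensor"
    return "binder"


def pm_radius_curve(
    ddF_eff: float,
    radii: Iterable[float],
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> list[tuple[float, float]]:
    """Binding probability as a function of vesicle radius.

    Returns ``[(R, Pm(R)), ...]`` for each radius in order. For a sensing
    peptide (ΔΔF_eff < 0) Pm decreases with R: small vesicles are more
    strained and bind more strongly.
    """
    return [
        (R, binding_probability(binding_free_energy(ddF_eff, R, constants), constants))
        for R in radii
    ]


def derive_class_boundaries(
    p_low: float = 0.05,
    p_high: float = 0.95,
    R: "float | _Flat" = 50.0,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Recover the ΔΔF values whose binding probability at radius R equals
    ``p_low`` and ``p_high``.

    With defaults (0.05, 0.95, R = 50 nm) this root-finding reproduces the
    classification thresholds (−6.4, −10.0) to one decimal — a consistency
    check tying the sigmoid, the affine map and the thresholds together.
    Returns (ddF at p_low, ddF at p_high); the first is the non-binder/
    sensor boundary, the second the sensor/binder boundary.
    """
    if not (0.0 < p_low < p_high < 1.0):
        raise ValueError("need 0 < p_low < p_high < 1")

    def solve(p: float) -> float:
        def f(ddF: float) -> float:
            return (
                binding_probability(binding_free_energy(ddF, R, constants), constants)
                - p
            )

        lo, hi = -200.0, 200.0
        if f(lo) * f(hi) > 0:
            raise ArithmeticError("probability root not bracketed in [-200, 200]")
        return brentq(f, lo, hi, xtol=1e-10)

    return solve(p_low), solve(p_high)


@dataclasses.dataclass(frozen=True)
class FreeEnergyProfile:
    """The full free-energy chain for one peptide on one membrane."""

    ddF: float
    length: int
    charge: int
    ddF_L24: float
    ddF_adj: float
    ddF_eff: float
    dFsm_at_ref: float
    pm_at_ref: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.pm_at_ref <= 1.0):
            raise ValueError("pm_at_ref must be a probability")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def free_energy_profile(
    ddF: float,
    length: int,
    charge: int,
    membrane: MembraneContext | None = None,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> FreeEnergyProfile:
    """Run the full chain for one peptide and return every intermediate.

    ΔFsm and Pm are reported at the reference radius (``constants.ref_radius``)
    regardless of the membrane's own radius, matching how results are
    conventionally quoted; the membrane kind selects neutral vs anionic.
    """
    membrane = membrane or MembraneContext()
    ddF_L24 = length_extrapolate(ddF, length, constants)
    ddF_adj = charge_adjust(ddF_L24, charge, constants)
    ddF_eff = ddF_adj if membrane.is_anionic else ddF_L24
    dFsm = binding_free_energy(ddF_eff, constants.ref_radius, constants)
    pm = binding_probability(dFsm, constants)
    return FreeEnergyProfile(
        ddF=ddF,
        length=length,
        charge=charge,
        ddF_L24=ddF_L24,
        ddF_adj=ddF_adj,
        ddF_eff=ddF_eff,
        dFsm_at_ref=dFsm,
        pm_at_ref=pm,
        label=classify(ddF_eff, constants),
    )
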