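"""Predictor interface and simple deterministic predictors.

Anything with ``predict(sequence) -> float`` (kJ/mol raw ΔΔF at the
sequence's own length) is a predictor: the trained transformer results,
the additive baseline results, or the stubs below. The stubs make the
screening and reporting pipelines fully testable without any training.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

from ..constants import FAUCHERE_PLISKA


@runtime_checkable
class DdgPredictor(Protocol):
    def predict(self, sequence: str) -> float:  # pragma: no cover - protocol
        ...


class ConstantPredictor:
    """Returns the same ΔΔF for every sequence."""

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, sequence: str) -> float:
        return self.value

    def __repr__(self) -> str:
        return f"ConstantPredictor({self.value})"


class AdditivePredictor:
    """Sum of per-residue coefficients (kJ/mol per occurrence)."""

    def __init__(self, coefficients: dict[str, float]):
        self.coefficients = dict(coefficients)

    def predict(self, sequence: str) -> float:
        return sum(self.coefficients[aa] for aa in sequence)

    def __repr__(self) -> str:
        return f"AdditivePredictor({len(self.coefficients)} coefficients)"


class HydrophobicityPredictor:
    """Crude physical stub: ΔΔF proportional to summed hydrophobicity.

    Scaled so a fully hydrophobic 24-mer lands near the theoretical
    optimum (≈ −30 kJ/mol). Useful for smoke tests that want sequence-
    dependent but training-free behaviour.
    """

    def __init__(self, scale: float = -0.55):
        self.scale = scale

    def predict(self, sequence: str) -> float:
        return self.scale * sum(FAUCHERE_PLISKA[aa] for aa in sequence)

    def __repr__(self) -> str:
        return f"HydrophobicityPredictor(scale={self.scale})"


def predictor_fingerprint(predictor: object) -> str:
    """Short provenance string for run manifests."""
    fp = getattr(predictor, "dataset_fingerprint", None)
    base = type(predictor).__name__
    return f"{base}[{fp}]" if fp else repr(predictor)
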