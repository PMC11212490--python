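"""Peptide sequence validation and physicochemical descriptors.

Descriptors match the conventions of helical-wheel web tools: net side-chain
charge, mean Fauchère–Pliška hydrophobicity, and Eisenberg's hydrophobic
moment on an ideal α-helix (100° per residue).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .constants import AMINO_ACIDS, FAUCHERE_PLISKA

#: Minimum/maximum direct-query peptide length supported by the predictor.
MIN_LENGTH = 7
MAX_LENGTH = 24

_VALID = set(AMINO_ACIDS)

# Side-chain charge at neutral pH; His counted neutral, termini ignored
# (the underlying free-energy data used fixed-length peptides).
CHARGE_BY_RESIDUE: dict[str, int] = {"K": +1, "R": +1, "D": -1, "E": -1}

# Coarse residue classes for wheel rendering.
_HYDROPHOBIC = set("AILMFWVCY")
_CHARGED = set("DEKR")


class SequenceAlphabetError(ValueError):
    """Sequence contains a character outside the 20 natural amino acids."""


class SequenceLengthError(ValueError):
    """Sequence length outside the supported range."""


def validate_sequence(
    raw: str, min_length: int = MIN_LENGTH, max_length: int = MAX_LENGTH
) -> str:
    """Normalize and validate a peptide sequence.

    Uppercases, strips whitespace, and enforces the natural-amino-acid
    alphabet and the length bounds (defaults 7-24, the predictor's domain).
    Internal callers that window protein chains may relax the bounds.
    """
    if not raw or not raw.strip():
        raise SequenceLengthError("empty sequence")
    seq = "".join(raw.split()).upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in _VALID:
            raise SequenceAlphabetError(
                f"illegal residue {ch!r} at position {i}: only the 20 natural "
                f"one-letter codes are accepted"
            )
    if not (min_length <= len(seq) <= max_length):
        raise SequenceLengthError(
            f"sequence length {len(seq)} outside [{min_length}, {max_length}]"
        )
    return seq


def net_charge(sequence: str) -> int:
    """Net side-chain charge: #(K,R) − #(D,E); His neutral, termini ignored."""
    return sum(CHARGE_BY_RESIDUE.get(ch, 0) for ch in sequence)


def mean_hydrophobicity(sequence: str) -> float:
    """Arithmetic mean of per-residue Fauchère–Pliška hydrophobicities."""
    return sum(FAUCHERE_PLISKA[ch] for ch in sequence) / len(sequence)


def hydrophobic_moment(sequence: str, angle_per_residue: float = 100.0) -> float:
    """Eisenberg hydrophobic moment, reported as the per-residue mean.

    Residue k (0-based) sits at angle k·θ on the helical wheel (θ = 100°
    for an ideal α-helix); the moment is the magnitude of the vector sum of
    hydrophobicities divided by the number of residues. Amphipathic helices
    — hydrophobic on one face, polar on the other — score high.
    """
    theta = math.radians(angle_per_residue)
    x = sum(FAUCHERE_PLISKA[ch] * math.cos(k * theta) for k, ch in enumerate(sequence))
    y = sum(FAUCHERE_PLISKA[ch] * math.sin(k * theta) for k, ch in enumerate(sequence))
    return math.hypot(x, y) / len(sequence)


def total_hydrophobic_moment(sequence: str, angle_per_residue: float = 100.0) -> float:
    """Unnormalized moment magnitude (the vector-sum length itself)."""
    return hydrophobic_moment(sequence, angle_per_residue) * len(sequence)


def residue_class(residue: str) -> str:
    """Coarse class tag for wheel plots: hydrophobic / charged / polar."""
    if residue in _HYDROPHOBIC:
        return "hydrophobic"
    if residue in _CHARGED:
        return "charged"
    return "polar"


def helical_wheel(sequence: str) -> list[tuple[int, float, str, str]]:
    """Helical-wheel coordinates: (index, angle°, residue, class) per residue.

    Residue k is placed at k·100° modulo 360°, the ideal α-helix geometry.
    """
    return [
        (k, (k * 100.0) % 360.0, ch, residue_class(ch))
        for k, ch in enumerate(sequence)
    ]


@dataclasses.dataclass(frozen=True)
class DescriptorSet:
    """The physicochemical descriptors reported alongside a prediction."""

    length: int
    net_charge: int
    mean_hydrophobicity: float
    hydrophobic_moment: float
    wheel: list[tuple[int, float, str, str]]


def describe(sequence: str) -> DescriptorSet:
    """Compute the full descriptor set for a validated sequence."""
    return DescriptorSet(
        length=len(sequence),
        net_charge=net_charge(sequence),
        mean_hydrophobicity=mean_hydrophobicity(sequence),
        hydrophobic_moment=hydrophobic_moment(sequence),
        wheel=helical_wheel(sequence),
    )


def read_fasta_peptides(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, validated sequence) for each FASTA record.

    Each record is one peptide query and must satisfy the 7-24 residue
    contract; violations raise with the record id in the message.
    """
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            yield record.id, validate_sequence(str(record.seq))
        except (SequenceAlphabetError, SequenceLengthError) as exc:
            raise type(exc)(f"record {record.id!r}: {exc}") from exc


def plot_helical_wheel(sequence: str, ax=None):
    """Render the helical wheel with matplotlib; returns the axes.

    Plotting sugar over :func:`helical_wheel`; the tested contract is the
    coordinate table, not the figure.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    colors = {"hydrophobic": "#f4c20d", "charged": "#4285f4", "polar": "#bdbdbd"}
    for k, angle, residue, cls in helical_wheel(sequence):
        rad = math.radians(angle)
        r = 1.0 + 0.05 * (k // 18)  # spiral outward after 5 full turns
        x, y = r * math.cos(rad), r * math.sin(rad)
        ax.scatter([x], [y], s=600, c=colors[cls], edgecolors="k", zorder=2)
        ax.annotate(residue, (x, y), ha="center", va="center", zorder=3)
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
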