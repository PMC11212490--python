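"""Integer tokenization of peptide sequences for the neural regressor."""

from __future__ import annotations

import numpy as np

from ..constants import AMINO_ACIDS

#: Padding token id; residues occupy 1..20.
PAD = 0

#: Vocabulary size: 20 residues + padding.
VOCAB_SIZE = len(AMINO_ACIDS) + 1

#: Maximum (reference) sequence length.
MAX_LENGTH = 24

_TOKEN_OF = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
_RESIDUE_OF = {i + 1: aa for i, aa in enumerate(AMINO_ACIDS)}


def tokenize(sequence: str, max_length: int = MAX_LENGTH) -> np.ndarray:
    """Encode a validated sequence as a fixed-length int vector.

    Right-pads with the PAD token; bijective on the residue portion.
    """
    if len(sequence) > max_length:
        raise ValueError(
            f"sequence length {len(sequence)} exceeds max_length {max_length}"
        )
    tokens = np.full(max_length, PAD, dtype=np.int64)
    for i, aa in enumerate(sequence):
        try:
            tokens[i] = _TOKEN_OF[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}") from None
    return tokens


def detokenize(tokens: np.ndarray) -> str:
    """Inverse of :func:`tokenize`; ignores trailing padding."""
    out = []
    for t in np.asarray(tokens).ravel():
        if t == PAD:
            break
        out.append(_RESIDUE_OF[int(t)])
    return "".join(out)


def tokenize_batch(sequences: list[str], max_length: int = MAX_LENGTH) -> np.ndarray:
    """Stack tokenized sequences into a (batch, max_length) array."""
    return np.stack([tokenize(s, max_length) for s in sequences])
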