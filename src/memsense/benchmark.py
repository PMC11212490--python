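"""Segment-based binary benchmarking of membrane-interaction predictions.

Chains are cut into consecutive non-overlapping fragments (default 15
residues, trailing remainder dropped). A fragment is *positive* when it
contains at least ``min_hits`` flagged residues — sensor and binder calls
both count as hits on the prediction side — and *negative* otherwise; the
same rule is applied to user-supplied reference regions. Agreement is then
summarized by the Matthews correlation coefficient, the false discovery
rate FP/(FP+TP) and the false omission rate FN/(FN+TN).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default fragment size (residues), matching the screening window default.
FRAGMENT_SIZE = 15


@dataclasses.dataclass(frozen=True)
class FragmentLabel:
    """One benchmark fragment with its predicted and reference calls."""

    chain_id: str
    start: int  # 1-based inclusive
    end: int
    predicted: bool
    reference: bool


@dataclasses.dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and the derived MCC/FDR/FOR statistics.

    ``degenerate`` lists the statistics whose denominator was zero (their
    value is reported as 0.0 by convention).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float
    fdr: float
    for_: float
    degenerate: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def fragment_sequence(length: int, size: int = FRAGMENT_SIZE) -> list[tuple[int, int]]:
    """1-based inclusive bounds of consecutive fragments; remainder dropped."""
    if size < 1:
        raise ValueError("fragment size must be >= 1")
    n_frag = length // size
    if length % size:
        logger.info(
            "dropping trailing remainder of %d residues (< fragment size %d)",
            length % size, size,
        )
    return [(i * size + 1, (i + 1) * size) for i in range(n_frag)]


def label_fragments(
    predicted_flags: Sequence[bool],
    reference_flags: Sequence[bool],
    size: int = FRAGMENT_SIZE,
    min_hits: int = 1,
    chain_id: str = "A",
) -> list[FragmentLabel]:
    """Cut aligned per-residue flag tracks into labelled fragments.

    A fragment is positive when it contains ≥ ``min_hits`` flagged
    residues. The default of 1 treats any hit as positive; ``min_hits=2``
    gives the stricter reading in which a lone flagged residue does not
    qualify.
    """
    if len(predicted_flags) != len(reference_flags):
        raise ValueError(
            f"flag tracks are misaligned: {len(predicted_flags)} predicted vs "
            f"{len(reference_flags)} reference residues"
        )
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    labels = []
    for start, end in fragment_sequence(len(predicted_flags), size):
        pred_hits = sum(predicted_flags[start - 1 : end])
        ref_hits = sum(reference_flags[start - 1 : end])
        labels.append(
            FragmentLabel(
                chain_id=chain_id,
                start=start,
                end=end,
                predicted=pred_hits >= min_hits,
                reference=ref_hits >= min_hits,
            )
        )
    return labels


def confusion_stats(labels: Sequence[FragmentLabel]) -> ConfusionSummary:
    """MCC, FDR and FOR over a set of labelled fragments.

    Statistics with a zero denominator are reported as 0.0 and flagged in
    ``degenerate`` rather than raising.
    """
    if not labels:
        raise ValueError("no fragments to score")
    tp = sum(1 for l in labels if l.predicted and l.reference)
    fp = sum(1 for l in labels if l.predicted and not l.reference)
    tn = sum(1 for l in labels if not l.predicted and not l.reference)
    fn = sum(1 for l in labels if not l.predicted and l.reference)

    degenerate: list[str] = []
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        mcc = 0.0
        degenerate.append("mcc")
    else:
        mcc = (tp * tn - fp * fn) / denom
    if fp + tp == 0:
        fdr = 0.0
        degenerate.append("fdr")
    else:
        fdr = fp / (fp + tp)
    if fn + tn == 0:
        for_ = 0.0
        degenerate.append("for")
    else:
        for_ = fn / (fn + tn)
    return ConfusionSummary(tp, fp, tn, fn, mcc, fdr, for_, tuple(degenerate))


# ---------------------------------------------------------------------------
# file plumbing


def read_reference_regions(path: str | Path) -> pd.DataFrame:
    """Read reference membrane-interaction regions: columns chain, start, end.

    Delimited text (tab or comma) with a header; start/end are 1-based
    inclusive author residue numbers.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in frame.columns}
    missing = {"chain", "start", "end"} - set(cols)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return pd.DataFrame(
        {
            "chain": frame[cols["chain"]].astype(str),
            "start": frame[cols["start"]].astype(int),
            "end": frame[cols["end"]].astype(int),
        }
    )


def reference_flags_for(
    regions: pd.DataFrame, chain_id: str, residue_numbers: Sequence[int]
) -> list[bool]:
    """Per-residue reference flags for one chain's author numbering."""
    spans = [
        (row.start, row.end)
        for row in regions.itertuples()
        if str(row.chain) == str(chain_id)
    ]
    return [any(s <= num <= e for s, e in spans) for num in residue_numbers]


def benchmark_tables(
    residue_table: pd.DataFrame,
    regions: pd.DataFrame,
    size: int = FRAGMENT_SIZE,
    min_hits: int = 1,
    positive_labels: tuple[str, ...] = ("sensor", "binder"),
) -> tuple[list[FragmentLabel], ConfusionSummary]:
    """Benchmark a per-residue screening table against reference regions.

    ``residue_table`` is the screen's per-residue output (columns chain,
    residue_number, label); predictions count as positive when the label
    is in ``positive_labels``.
    """
    all_labels: list[FragmentLabel] = []
    for chain_id, group in residue_table.groupby("chain", sort=True):
        group = group.sort_values("residue_number")
        predicted = [lbl in positive_labels for lbl in group["label"]]
        reference = reference_flags_for(
            regions, str(chain_id), list(group["residue_number"])
        )
        all_labels.extend(
            label_fragments(predicted, reference, size, min_hits, str(chain_id))
        )
    return all_labels, confusion_stats(all_labels)


def summary_text(summary: ConfusionSummary) -> str:
    lines = [
        "Segment-based benchmark",
        f"  fragments: {summary.n}  "
        f"(TP {summary.tp}, FP {summary.fp}, TN {summary.tn}, FN {summary.fn})",
        f"  MCC: {summary.mcc:+.3f}",
        f"  FDR: {summary.fdr:.3f}",
        f"  FOR: {summary.for_:.3f}",
    ]
    if summary.degenerate:
        lines.append(f"  degenerate (zero denominator): {', '.join(summary.degenerate)}")
    return "\n".join(lines)
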