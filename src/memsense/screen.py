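"""Screening protein structures for membrane-sensing and -binding regions.

The pipeline slides a window (default 15 residues) along each chain's
sequence, predicts a curvature-sensing free energy ΔΔF for every window,
length-extrapolates each window score to the 24-residue reference (plus
the charge correction on anionic membranes), averages the overlapping
window scores onto single residues, and gates the per-residue class call
by solvent exposure (smoothed SASA ≥ threshold). Results are emitted as
per-residue and per-segment tables and as a PDB whose B-factor column
encodes the call: 0.0 non-binder/inaccessible, 0.5 sensor, 1.0 binder.

The order of operations matters and is pinned by tests: thresholds are
applied to the length-extrapolated (and, if anionic, charge-adjusted)
ΔΔF, never to the raw window score.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from pathlib import Path

import pandas as pd
from Bio.Data.PDBData import protein_letters_3to1_extended
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.PDBIO import PDBIO
from Bio.PDB.Structure import Structure

from . import sasa as sasa_mod
from .constants import DEFAULT_CONSTANTS, PhysicsConstants
from .physics import MembraneContext, charge_adjust, classify, length_extrapolate
from .sequence import AMINO_ACIDS, net_charge

logger = logging.getLogger(__name__)

_STANDARD = set(AMINO_ACIDS)

#: Predictor domain bounds for window sizes.
MIN_WINDOW, MAX_WINDOW = 7, 24


class StructureFormatError(ValueError):
    """Unparseable or polymer-free structure file."""


@dataclasses.dataclass(frozen=True)
class ScreenConfig:
    """Knobs of the structure screen (defaults follow the web-tool ones)."""

    window: int = 15
    sasa_threshold: float = 0.8  # nm², smoothed per-residue SASA
    smoothing_half_width: int = 4
    membrane: MembraneContext = dataclasses.field(default_factory=MembraneContext)
    probe_radius: float = sasa_mod.PROBE_RADIUS  # Å
    sphere_points: int = sasa_mod.SPHERE_POINTS
    ignore_hydrogens: bool = True
    het_occluders: bool = True  # keep ligands/waters as SASA occluders

    def __post_init__(self) -> None:
        if not MIN_WINDOW <= self.window <= MAX_WINDOW:
            raise ValueError(
                f"window must be in [{MIN_WINDOW}, {MAX_WINDOW}], got {self.window}"
            )
        if self.sasa_threshold < 0:
            raise ValueError("sasa_threshold must be >= 0")
        if self.smoothing_half_width < 0:
            raise ValueError("smoothing_half_width must be >= 0")


@dataclasses.dataclass(frozen=True)
class ChainFragment:
    """A contiguous stretch of standard residues within one chain."""

    chain_id: str
    sequence: str
    residue_ids: tuple[tuple[int, str], ...]  # author (number, insertion code)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.residue_ids):
            raise ValueError("sequence and residue numbering are misaligned")


@dataclasses.dataclass(frozen=True)
class SegmentScore:
    """One scored sliding-window segment."""

    chain_id: str
    start: int  # 1-based inclusive within the fragment's chain sequence
    end: int
    sequence: str
    ddF: float  # raw predictor output at window length
    ddF_eff: float  # after length extrapolation (+ charge correction if anionic)
    label: str


@dataclasses.dataclass(frozen=True)
class ResidueAnnotation:
    """Final per-residue screening result."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue: str
    per_residue_ddF: float  # NaN when the fragment was too short to screen
    sasa_raw: float | None
    sasa_smoothed: float | None
    exposed: bool
    label: str  # class label, "not accessible", or "not screened"
    bfactor_out: float


# ---------------------------------------------------------------------------
# structure reading


def load_structure(path: str | Path) -> Structure:
    """Parse a PDB or mmCIF file (by extension, falling back to the other)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    parsers = (
        [MMCIFParser(QUIET=True), PDBParser(QUIET=True)]
        if suffix in {".cif", ".mmcif"}
        else [PDBParser(QUIET=True), MMCIFParser(QUIET=True)]
    )
    last_error: Exception | str | None = None
    for parser in parsers:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # try the other grammar
            last_error = exc
            continue
        if any(True for _ in structure.get_atoms()):
            return structure
        last_error = "no atoms found"  # permissive parser swallowed garbage
    raise StructureFormatError(f"cannot parse {path}: {last_error}")


def _one_letter(resname: str) -> str | None:
    code = protein_letters_3to1_extended.get(resname.strip().upper())
    if code is not None and len(code) == 1 and code in _STANDARD:
        return code
    return None


def extract_chain_sequences(structure: Structure) -> list[ChainFragment]:
    """One-letter sequences per chain, split into contiguous fragments.

    Standard residues (and nonstandard ones with a standard parent, e.g.
    selenomethionine → M) are kept; anything else — ligands, waters,
    unmappable residues — and gaps in the author numbering break the chain
    into fragments that are screened independently.
    """
    model = next(iter(structure), None)
    if model is None:
        raise StructureFormatError("structure contains no models")
    fragments: list[ChainFragment] = []
    any_polymer = False
    for chain in model:
        seq: list[str] = []
        ids: list[tuple[int, str]] = []
        prev_num: int | None = None

        def flush() -> None:
            if seq:
                fragments.append(
                    ChainFragment(chain.id, "".join(seq), tuple(ids))
                )
                seq.clear()
                ids.clear()

        for residue in chain:
            _, resseq, icode = residue.id
            code = _one_letter(residue.get_resname())
            if code is None:
                flush()
                prev_num = None
                continue
            any_polymer = True
            if prev_num is not None and resseq > prev_num + 1:
                flush()  # numbering gap: unresolved stretch
            seq.append(code)
            ids.append((resseq, icode))
            prev_num = resseq
        flush()
    if not any_polymer:
        raise StructureFormatError("no polymer (amino-acid) chains found")
    return fragments


def strip_hydrogens(structure: Structure) -> None:
    """Remove hydrogen/deuterium atoms in place."""
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in [a for a in residue if a.element in ("H", "D")]:
                    residue.detach_child(atom.id)


# ---------------------------------------------------------------------------
# window scoring


def sliding_segments(length: int, window: int) -> list[tuple[int, int]]:
    """(start, end) 1-based inclusive bounds of all stride-1 windows.

    A fragment shorter than the window but at least 7 residues long is
    scored as a single segment of its own length; shorter fragments yield
    no segments (the predictor's domain starts at 7 residues).
    """
    if length >= window:
        return [(s, s + window - 1) for s in range(1, length - window + 2)]
    if length >= MIN_WINDOW:
        logger.info(
            "fragment of %d residues is shorter than the %d-residue window; "
            "scoring it as a single segment", length, window,
        )
        return [(1, length)]
    logger.warning(
        "fragment of %d residues is below the 7-residue predictor minimum; skipped",
        length,
    )
    return []


def per_residue_score(
    segments: list[SegmentScore], length: int
) -> list[float]:
    """Average the overlapping segment scores onto each residue.

    Residue n receives the unweighted mean of ``ddF_eff`` over all
    segments covering n; termini are covered by fewer windows. Returns NaN
    for residues no segment covers (unscreenable fragments).
    """
    sums = [0.0] * length
    counts = [0] * length
    for seg in segments:
        for pos in range(seg.start - 1, seg.end):
            sums[pos] += seg.ddF_eff
            counts[pos] += 1
    return [s / c if c else math.nan for s, c in zip(sums, counts)]


def score_fragment(
    fragment: ChainFragment,
    predictor,
    config: ScreenConfig,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> list[SegmentScore]:
    """Predict and post-process every sliding window of one fragment."""
    scores: list[SegmentScore] = []
    for start, end in sliding_segments(len(fragment.sequence), config.window):
        window_seq = fragment.sequence[start - 1 : end]
        ddF = float(predictor.predict(window_seq))
        ddF_eff = length_extrapolate(ddF, len(window_seq), constants)
        if config.membrane.is_anionic:
            ddF_eff = charge_adjust(ddF_eff, net_charge(window_seq), constants)
        scores.append(
            SegmentScore(
                chain_id=fragment.chain_id,
                start=start,
                end=end,
                sequence=window_seq,
                ddF=ddF,
                ddF_eff=ddF_eff,
                label=classify(ddF_eff, constants),
            )
        )
    return scores


# ---------------------------------------------------------------------------
# full annotation


def annotate_structure(
    structure: Structure | str | Path,
    predictor,
    config: ScreenConfig | None = None,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> tuple[list[ResidueAnnotation], list[SegmentScore]]:
    """Run the full screen on a structure (object or file path).

    SASA is computed once on the whole assembly (chains occlude each
    other); window scoring and smoothing run per chain fragment. Returns
    per-residue annotations and the underlying segment scores.
    """
    config = config or ScreenConfig()
    if not isinstance(structure, Structure):
        structure = load_structure(structure)
    if config.ignore_hydrogens:
        strip_hydrogens(structure)
    if not config.het_occluders:
        _strip_non_polymer(structure)

    model = next(iter(structure))
    fragments = extract_chain_sequences(structure)
    sasa_by_residue = sasa_mod.compute_sasa(
        model, probe_radius=config.probe_radius, sphere_points=config.sphere_points
    )

    annotations: list[ResidueAnnotation] = []
    all_segments: list[SegmentScore] = []
    for fragment in fragments:
        segments = score_fragment(fragment, predictor, config, constants)
        all_segments.extend(segments)
        ddF_per_residue = per_residue_score(segments, len(fragment.sequence))
        raw = [
            sasa_by_residue.get((fragment.chain_id, num, icode))
            for num, icode in fragment.residue_ids
        ]
        smoothed = sasa_mod.smooth_sasa(raw, config.smoothing_half_width)
        for i, (num, icode) in enumerate(fragment.residue_ids):
            ddF = ddF_per_residue[i]
            s_smooth = smoothed[i]
            exposed = s_smooth is not None and s_smooth >= config.sasa_threshold
            if math.isnan(ddF):
                label = "not screened"
            elif not exposed:
                label = "not accessible"
            else:
                label = classify(ddF, constants)
            bfactor = {"sensor": 0.5, "binder": 1.0}.get(label, 0.0)
            annotations.append(
                ResidueAnnotation(
                    chain_id=fragment.chain_id,
                    residue_number=num,
                    insertion_code=icode,
                    residue=fragment.sequence[i],
                    per_residue_ddF=ddF,
                    sasa_raw=raw[i],
                    sasa_smoothed=s_smooth,
                    exposed=exposed,
                    label=label,
                    bfactor_out=bfactor,
                )
            )
    return annotations, all_segments


def _strip_non_polymer(structure: Structure) -> None:
    for model in structure:
        for chain in model:
            for residue in [r for r in chain if _one_letter(r.get_resname()) is None]:
                chain.detach_child(residue.id)


# ---------------------------------------------------------------------------
# output


def annotations_frame(annotations: list[ResidueAnnotation]) -> pd.DataFrame:
    """Per-residue results as a DataFrame (one row per residue)."""
    return pd.DataFrame(
        {
            "chain": [a.chain_id for a in annotations],
            "residue_number": [a.residue_number for a in annotations],
            "insertion_code": [a.insertion_code.strip() for a in annotations],
            "residue": [a.residue for a in annotations],
            "ddF_per_residue": [a.per_residue_ddF for a in annotations],
            "sasa_raw_nm2": [a.sasa_raw for a in annotations],
            "sasa_smoothed_nm2": [a.sasa_smoothed for a in annotations],
            "exposed": [a.exposed for a in annotations],
            "label": [a.label for a in annotations],
            "bfactor": [a.bfactor_out for a in annotations],
        }
    )


def segments_frame(segments: list[SegmentScore]) -> pd.DataFrame:
    """Per-segment results as a DataFrame (one row per window)."""
    return pd.DataFrame(
        {
            "chain": [s.chain_id for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "sequence": [s.sequence for s in segments],
            "ddF": [s.ddF for s in segments],
            "ddF_eff": [s.ddF_eff for s in segments],
            "label": [s.label for s in segments],
        }
    )


def write_annotated_pdb(
    source: str | Path | Structure,
    annotations: list[ResidueAnnotation],
    out_path: str | Path,
) -> None:
    """Write a PDB whose B-factor column encodes the per-residue call.

    When the source is a PDB file, only columns 61-66 of ATOM/HETATM
    records are rewritten and every other byte is preserved. For mmCIF
    sources (or in-memory structures) a fresh PDB is emitted instead.
    Residues without an annotation (ligands, waters) get 0.00.
    """
    bmap = {
        (a.chain_id, a.residue_number, a.insertion_code): a.bfactor_out
        for a in annotations
    }
    out_path = Path(out_path)
    if isinstance(source, (str, Path)) and Path(source).suffix.lower() not in (
        ".cif",
        ".mmcif",
    ):
        _rewrite_pdb_bfactors(Path(source), bmap, out_path)
        return
    structure = source if isinstance(source, Structure) else load_structure(source)
    for model in structure:
        for chain in model:
            for residue in chain:
                _, resseq, icode = residue.id
                b = bmap.get((chain.id, resseq, icode), 0.0)
                for atom in residue:
                    atom.bfactor = b
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_path))


def _rewrite_pdb_bfactors(
    source: Path, bmap: dict[tuple[str, int, str], float], out_path: Path
) -> None:
    lines_out = []
    for line in source.read_text().splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")) and len(line.rstrip("\n")) >= 66:
            chain_id = line[21]
            try:
                resseq = int(line[22:26])
            except ValueError:
                lines_out.append(line)
                continue
            icode = line[26] if line[26] != " " else " "
            b = bmap.get((chain_id, resseq, icode), 0.0)
            line = line[:60] + f"{b:6.2f}" + line[66:]
        lines_out.append(line)
    out_path.write_text("".join(lines_out))
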