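"""End-to-end peptide and structure workflows and their output bundles."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_CONSTANTS, PhysicsConstants
from .physics import (
    MembraneContext,
    binding_free_energy,
    binding_probability,
    charge_adjust,
    classify,
    length_extrapolate,
    pm_radius_curve,
)
from .regression.predictors import predictor_fingerprint
from .screen import (
    ScreenConfig,
    annotate_structure,
    annotations_frame,
    segments_frame,
    write_annotated_pdb,
)
from .sequence import DescriptorSet, describe, validate_sequence

logger = logging.getLogger(__name__)

#: Radius grid (nm) for the Pm-vs-R curve: logarithmic, 10-500 nm.
RADIUS_GRID: tuple[float, ...] = tuple(np.logspace(np.log10(10), np.log10(500), 50))


@dataclasses.dataclass(frozen=True)
class PeptideReport:
    """Everything the peptide workflow reports for one query."""

    sequence: str
    membrane: MembraneContext
    ddF: float
    ddF_L24: float
    ddF_adj: float | None  # anionic membranes only
    ddF_eff: float
    dFsm_at_ref: float
    pm_at_ref: float
    label: str
    descriptors: DescriptorSet
    pm_curve: list[tuple[float, float]]

    def to_text(self) -> str:
        d = self.descriptors
        lines = [
            f"sequence            : {self.sequence}",
            f"membrane            : {self.membrane.kind}",
            f"ddF (raw)           : {self.ddF:.2f} kJ/mol",
            f"ddF_L24             : {self.ddF_L24:.2f} kJ/mol",
        ]
        if self.ddF_adj is not None:
            lines.append(f"ddF_adj             : {self.ddF_adj:.2f} kJ/mol")
        lines += [
            f"dFsm (R=50 nm)      : {self.dFsm_at_ref:.2f} kJ/mol",
            f"Pm   (R=50 nm)      : {self.pm_at_ref:.3g}",
            f"class               : {self.label}",
            f"length              : {d.length}",
            f"net charge          : {d.net_charge:+d}",
            f"mean hydrophobicity : {d.mean_hydrophobicity:.3f}",
            f"hydrophobic moment  : {d.hydrophobic_moment:.3f}",
        ]
        return "\n".join(lines)

    def to_record(self) -> dict:
        """Machine-readable record (full precision, same numbers as the text)."""
        d = self.descriptors
        return {
            "sequence": self.sequence,
            "membrane": self.membrane.kind,
            "ddF": self.ddF,
            "ddF_L24": self.ddF_L24,
            "ddF_adj": self.ddF_adj,
            "ddF_eff": self.ddF_eff,
            "dFsm_at_ref": self.dFsm_at_ref,
            "pm_at_ref": self.pm_at_ref,
            "label": self.label,
            "length": d.length,
            "net_charge": d.net_charge,
            "mean_hydrophobicity": d.mean_hydrophobicity,
            "hydrophobic_moment": d.hydrophobic_moment,
        }


def run_peptide(
    raw_sequence: str,
    membrane: MembraneContext | None = None,
    predictor=None,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
    radius_grid: tuple[float, ...] = RADIUS_GRID,
) -> PeptideReport:
    """The peptide workflow: validate → predict → transform → classify.

    The charge correction applies only on anionic membranes; the class
    label, ΔFsm and Pm are computed from the resulting effective ΔΔF at
    the reference radius (50 nm).
    """
    if predictor is None:
        raise ValueError("a ΔΔF predictor is required (trained model or stub)")
    sequence = validate_sequence(raw_sequence)
    membrane = membrane or MembraneContext()
    descriptors = describe(sequence)
    ddF = float(predictor.predict(sequence))
    ddF_L24 = length_extrapolate(ddF, len(sequence), constants)
    if membrane.is_anionic:
        ddF_adj = charge_adjust(ddF_L24, descriptors.net_charge, constants)
        ddF_eff = ddF_adj
    else:
        ddF_adj, ddF_eff = None, ddF_L24
    dFsm = binding_free_energy(ddF_eff, constants.ref_radius, constants)
    return PeptideReport(
        sequence=sequence,
        membrane=membrane,
        ddF=ddF,
        ddF_L24=ddF_L24,
        ddF_adj=ddF_adj,
        ddF_eff=ddF_eff,
        dFsm_at_ref=dFsm,
        pm_at_ref=binding_probability(dFsm, constants),
        label=classify(ddF_eff, constants),
        descriptors=descriptors,
        pm_curve=pm_radius_curve(ddF_eff, radius_grid, constants),
    )


def run_screen(
    structure_path: str | Path,
    predictor,
    config: ScreenConfig | None = None,
    out_dir: str | Path = "screen_out",
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> dict[str, Path]:
    """The structure workflow: annotate and write the output bundle.

    Produces, in ``out_dir``: the B-factor-annotated PDB, the per-residue
    and per-segment tables (tab-separated), and a JSON manifest recording
    the configuration, constants, predictor fingerprint, input hash and
    package version — enough to reproduce the run.
    """
    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FileNotFoundError(structure_path)
    config = config or ScreenConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    annotations, segments = annotate_structure(
        structure_path, predictor, config, constants
    )
    paths = {
        "annotated_pdb": out_dir / f"{structure_path.stem}_annotated.pdb",
        "residues": out_dir / f"{structure_path.stem}_residues.tsv",
        "segments": out_dir / f"{structure_path.stem}_segments.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_annotated_pdb(structure_path, annotations, paths["annotated_pdb"])
    annotations_frame(annotations).to_csv(paths["residues"], sep="\t", index=False)
    segments_frame(segments).to_csv(paths["segments"], sep="\t", index=False)

    manifest = {
        "version": __version__,
        "input": structure_path.name,
        "input_sha256": hashlib.sha256(structure_path.read_bytes()).hexdigest(),
        "predictor": predictor_fingerprint(predictor),
        "config": {
            "window": config.window,
            "sasa_threshold": config.sasa_threshold,
            "smoothing_half_width": config.smoothing_half_width,
            "membrane": config.membrane.kind,
            "probe_radius": config.probe_radius,
            "sphere_points": config.sphere_points,
            "ignore_hydrogens": config.ignore_hydrogens,
            "het_occluders": config.het_occluders,
        },
        "constants": constants.as_dict(),
        "n_residues": len(annotations),
        "n_segments": len(segments),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def pm_curve_frame(report: PeptideReport) -> pd.DataFrame:
    """The Pm-vs-radius series of a peptide report as a DataFrame."""
    return pd.DataFrame(report.pm_curve, columns=["radius_nm", "pm"])
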