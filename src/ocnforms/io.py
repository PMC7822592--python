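"""Readers and writers for the pipeline's file dialects.

Proteins come in as FASTA plus a YAML side-car listing the disulfide pairs,
carboxylation-eligible glutamates and candidate O-glycosylation sites.
Deconvoluted peak lists and concentration time courses are plain TSV/CSV
with snake_case columns.  Writers round-trip losslessly with the readers
(full float precision; human-style rounding is presentation-only).

The package also ships reference inputs: the mouse and human mature
osteocalcin chains, and the published intact-mass ledgers for
differentiated-osteoblast supernatant and mouse bone homogenate.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .assignment import (
    Assignment,
    MassObservation,
    modification_label,
    oligosaccharide_label,
)
from .kinetics import DecayCurve, HalfLifeEstimate
from .masscalc import ProteinSpec, monoisotopic_mass

__all__ = [
    "read_protein",
    "read_peaklist",
    "read_timecourse",
    "write_assignments",
    "write_estimates",
    "builtin_protein",
    "builtin_peaklist",
    "data_path",
]

#: Packaged reference datasets: short name -> (fasta, sidecar) or TSV file.
_PROTEINS = {
    "mouse": ("ocn_mouse.fasta", "ocn_mouse.yaml"),
    "human": ("ocn_human.fasta", "ocn_human.yaml"),
}
_PEAKLISTS = {
    "osteoblast_supernatant": "osteoblast_supernatant.tsv",
    "bone_homogenate": "bone_homogenate.tsv",
}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    ref = resources.files("ocnforms") / "data" / name
    return Path(str(ref))


def read_protein(
    fasta_path: str | Path,
    sidecar_path: str | Path,
    *,
    verify_anchor: float | None = None,
    anchor_tolerance: float = 0.05,
) -> ProteinSpec:
    """Load a :class:`ProteinSpec` from FASTA plus a YAML site side-car.

    The side-car carries ``disulfide_bonds`` (list of 2-lists),
    ``gla_sites`` and ``glycosites`` (1-based positions on the mature chain),
    and optionally ``anchor_mass_da``: a known theoretical mass of the fully
    carboxylated, disulfide-formed form used to validate the transcription of
    the sequence.  ``verify_anchor`` overrides the side-car anchor.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    record = records[0]
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh) or {}
    spec = ProteinSpec(
        id=record.id,
        residues=str(record.seq),
        disulfide_bonds=tuple(tuple(b) for b in meta.get("disulfide_bonds", [])),
        gla_sites=tuple(meta.get("gla_sites", [])),
        glycosites=tuple(meta.get("glycosites", [])),
    )
    anchor = verify_anchor if verify_anchor is not None else meta.get("anchor_mass_da")
    if anchor is not None:
        from .masscalc import ProteoformComposition

        carboxylated = ProteoformComposition({"Gla": len(spec.gla_sites)})
        theo = monoisotopic_mass(spec, carboxylated)
        if abs(theo - float(anchor)) > anchor_tolerance:
            raise ValueError(
                f"anchor check failed for {spec.id}: computed {theo:.4f} Da vs "
                f"expected {anchor} ± {anchor_tolerance} Da"
            )
    return spec


def builtin_protein(name: str, *, verify_anchor: bool = True) -> ProteinSpec:
    """One of the packaged proteins: ``"mouse"`` or ``"human"`` mature osteocalcin."""
    if name not in _PROTEINS:
        raise KeyError(f"unknown protein {name!r}; choose from {sorted(_PROTEINS)}")
    fasta, sidecar = _PROTEINS[name]
    spec = read_protein(data_path(fasta), data_path(sidecar))
    return spec


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"no records in {path}")
    return df


def read_peaklist(path: str | Path) -> list[MassObservation]:
    """Read a deconvoluted neutral-mass list (TSV/CSV).

    Requires a ``neutral_mass_da`` column; ``relative_abundance_pct`` and
    ``label`` are optional.
    """
    df = _read_table(path)
    if "neutral_mass_da" not in df.columns:
        raise ValueError(f"{path}: missing required column 'neutral_mass_da'")
    out = []
    for _, row in df.iterrows():
        abundance = row.get("relative_abundance_pct")
        if abundance is not None and pd.isna(abundance):
            abundance = None
        out.append(
            MassObservation(
                neutral_mass=float(row["neutral_mass_da"]),
                relative_abundance=None if abundance is None else float(abundance),
                source_label=str(row.get("label", "")),
            )
        )
    return out


def builtin_peaklist(name: str) -> list[MassObservation]:
    """A packaged intact-mass ledger: ``"osteoblast_supernatant"`` or ``"bone_homogenate"``."""
    if name not in _PEAKLISTS:
        raise KeyError(f"unknown peak list {name!r}; choose from {sorted(_PEAKLISTS)}")
    return read_peaklist(data_path(_PEAKLISTS[name]))


def read_timecourse(path: str | Path, *, baseline_time: float = 0.0) -> DecayCurve:
    """Read a concentration time course (columns time_min, conc_ng_ml, replicate_id)."""
    df = _read_table(path)
    missing = {"time_min", "conc_ng_ml", "replicate_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return DecayCurve(df[["time_min", "conc_ng_ml", "replicate_id"]].copy(),
                      baseline_time=baseline_time)


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Tabular view of assignments (one row per observation, rank-1 candidate)."""
    rows = []
    for a in assignments:
        best = a.best
        rows.append({
            "label": a.observation.source_label,
            "neutral_mass_da": a.observation.neutral_mass,
            "relative_abundance_pct": a.observation.relative_abundance,
            "status": a.status,
            "modification": modification_label(best) if best else "unassigned",
            "oligosaccharide": oligosaccharide_label(best) if best else "NA",
            "composition": str(best) if best else "",
            "ppm_error": a.best_ppm if a.best_ppm is not None else math.nan,
            "residual_mass_da": best.residual_mass if best else math.nan,
            "n_candidates": len(a.candidates),
        })
    return pd.DataFrame(rows)


def write_assignments(assignments: Sequence[Assignment], path: str | Path) -> None:
    """Write an assignment table as TSV (full precision)."""
    assignments_frame(assignments).to_csv(path, sep="\t", index=False)


def estimates_frame(estimates: dict[str, HalfLifeEstimate]) -> pd.DataFrame:
    rows = []
    for label, est in estimates.items():
        rows.append({
            "analyte": label,
            "t_half_min": est.t_half,
            "rate_k_per_min": est.rate_k,
            "ci_low_min": est.ci_low,
            "ci_high_min": est.ci_high,
            "method": est.method,
            "mode": est.mode,
            "n_replicates": est.n_replicates,
            "stable": est.stable,
        })
    return pd.DataFrame(rows)


def write_estimates(estimates: dict[str, HalfLifeEstimate], path: str | Path) -> None:
    """Write a half-life estimate table as CSV."""
    estimates_frame(estimates).to_csv(path, index=False)
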