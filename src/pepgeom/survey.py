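"""Per-residue survey records and Ramachandran-binned statistics.

The survey turns structures into one record per residue carrying the
backbone torsions (phi, psi), the following peptide bond's omega, omega_3,
delta-omega and theta_C, the residue's mean main-chain B-factor, and a full
audit of why a residue is excluded.  Records are never silently dropped:
``included`` is simply "the exclusion-reason set is empty".

Filters mirror a high-resolution database survey:

* Gly and Pro excluded (unique backbone chemistry);
* residues with any partially occupied main-chain atom excluded;
* residues whose mean main-chain B exceeds 1.3x the mean main-chain B of
  the entire protein (all chains pooled) excluded;
* cis peptide bonds excluded (trans-only analysis);
* termini and chain breaks (C_i...N_{i+1} further than 1.8 A) leave the
  relevant torsions undefined and exclude the record.

The convention tying a bond to a residue: omega / delta-omega / theta_C of
the bond between residues i and i+1 are attributed to residue i's (phi,
psi) — psi_i shares the N_{i+1} atom with that bond, which is what makes
the psi-dependence of the planarity deviation well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import geometry
from .io import (
    BACKBONE_ATOMS,
    Residue,
    StructureModel,
    backbone_atoms,
    mainchain_b_factor,
)

__all__ = [
    "FilterConfig",
    "SurveyRecord",
    "GridBin",
    "EmptyProfileError",
    "extract_records",
    "bin_records",
    "psi_profile",
    "records_to_frame",
    "passes_entry_criteria",
]

EXCLUSION_REASONS = (
    "gly_pro",
    "partial_occupancy",
    "high_b",
    "cis",
    "missing_atoms",
    "chain_break",
    "terminal",
)


class EmptyProfileError(ValueError):
    """No bins qualify for the marginal psi profile."""


@dataclass
class FilterConfig:
    """Survey filter thresholds.

    ``b_factor_ratio`` — a residue is excluded when its mean main-chain B
    exceeds this multiple of the protein-wide mean main-chain B.
    ``min_resolution`` / ``max_r_factor`` gate whole entries (header-based).
    ``chain_break_distance`` — C_i..N_{i+1} distances above this (A) break
    the chain; ~1.33 A when bonded.
    """

    b_factor_ratio: float = 1.3
    min_resolution: float = 1.6
    max_r_factor: float = 0.20
    exclude_residues: frozenset = frozenset({"GLY", "PRO"})
    trans_only: bool = True
    chain_break_distance: float = 1.8

    def __post_init__(self):
        if self.b_factor_ratio <= 0:
            raise ValueError("b_factor_ratio must be positive")
        if self.chain_break_distance <= 0:
            raise ValueError("chain_break_distance must be positive")


@dataclass
class SurveyRecord:
    entry_id: str
    chain_id: str
    seq_number: int
    residue_name: str
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None
    omega3: Optional[float] = None
    delta_omega: Optional[float] = None
    theta_c: Optional[float] = None
    theta_n: Optional[float] = None
    b_mainchain_residue: Optional[float] = None
    exclusion_reasons: Set[str] = field(default_factory=set)

    @property
    def included(self) -> bool:
        return not self.exclusion_reasons


@dataclass
class GridBin:
    """One Ramachandran grid cell: centre, count, circular means, dispersion."""

    phi_center: float
    psi_center: float
    count: int
    mean_delta_omega: float
    mean_theta_c: float
    dispersion: float  # resultant length of the delta-omega mean
    below_threshold: bool = False


def _protein_mainchain_b(model: StructureModel) -> Optional[float]:
    bs = [
        a.b_factor
        for r in model.residues()
        for a in r.atoms
        if a.name in BACKBONE_ATOMS
    ]
    return float(np.mean(bs)) if bs else None


def _safe_dihedral(*pts):
    try:
        return geometry.dihedral(*pts)
    except geometry.DegenerateGeometryError:
        return None


def extract_records(model: StructureModel, config: Optional[FilterConfig] = None) -> List[SurveyRecord]:
    """One audited :class:`SurveyRecord` per residue of every chain.

    Problems never raise: they become exclusion reasons on the record.
    """
    config = config or FilterConfig()
    b_protein = _protein_mainchain_b(model)
    records: List[SurveyRecord] = []

    for chain_id, residues in model.chains.items():
        n = len(residues)
        bb = []
        for r in residues:
            try:
                mapping, missing = backbone_atoms(r)
            except Exception:
                mapping, missing = {}, list(BACKBONE_ATOMS)
            bb.append((mapping, missing))

        def bonded(i: int, j: int) -> bool:
            """C_i and N_j present and within the chain-break cutoff."""
            ci = bb[i][0].get("C")
            nj = bb[j][0].get("N")
            if ci is None or nj is None:
                return False
            return float(np.linalg.norm(ci.coord - nj.coord)) <= config.chain_break_distance

        for i, r in enumerate(residues):
            rec = SurveyRecord(
                entry_id=model.entry_id,
                chain_id=chain_id,
                seq_number=r.seq_number,
                residue_name=r.name,
                b_mainchain_residue=mainchain_b_factor(r),
            )
            mapping, missing = bb[i]
            reasons = rec.exclusion_reasons

            if missing:
                reasons.add("missing_atoms")
            if i == 0 or i == n - 1:
                reasons.add("terminal")

            # phi needs the preceding peptide bond
            if i > 0:
                if bonded(i - 1, i):
                    prev_map = bb[i - 1][0]
                    if all(k in mapping for k in ("N", "CA", "C")) and "C" in prev_map:
                        rec.phi = _safe_dihedral(
                            prev_map["C"].coord,
                            mapping["N"].coord,
                            mapping["CA"].coord,
                            mapping["C"].coord,
                        )
                else:
                    reasons.add("chain_break")

            # psi, omega, omega_3, theta_C need the following peptide bond
            if i < n - 1:
                if bonded(i, i + 1):
                    next_map = bb[i + 1][0]
                    have = all(k in mapping for k in ("N", "CA", "C"))
                    if have and "N" in next_map:
                        rec.psi = _safe_dihedral(
                            mapping["N"].coord,
                            mapping["CA"].coord,
                            mapping["C"].coord,
                            next_map["N"].coord,
                        )
                    if have and all(k in next_map for k in ("N", "CA")):
                        rec.omega = _safe_dihedral(
                            mapping["CA"].coord,
                            mapping["C"].coord,
                            next_map["N"].coord,
                            next_map["CA"].coord,
                        )
                        if rec.omega is not None and "O" in mapping:
                            rec.omega3 = _safe_dihedral(
                                mapping["O"].coord,
                                mapping["C"].coord,
                                next_map["N"].coord,
                                next_map["CA"].coord,
                            )
                        if rec.omega is not None and "H" in next_map:
                            om_h = _safe_dihedral(
                                mapping["CA"].coord,
                                mapping["C"].coord,
                                next_map["N"].coord,
                                next_map["H"].coord,
                            )
                            rec.theta_n = geometry.theta_n(om_h, rec.omega)
                else:
                    reasons.add("chain_break")

            if rec.omega is not None:
                isomer = geometry.classify_isomer(rec.omega)
                rec.delta_omega = geometry.delta_omega(rec.omega, isomer)
                if rec.omega3 is not None:
                    rec.theta_c = geometry.theta_c(rec.omega, rec.omega3)
                if config.trans_only and isomer == "cis":
                    reasons.add("cis")

            if r.name in config.exclude_residues:
                reasons.add("gly_pro")
            if r.partial_occupancy:
                reasons.add("partial_occupancy")
            if (
                b_protein is not None
                and rec.b_mainchain_residue is not None
                and rec.b_mainchain_residue > config.b_factor_ratio * b_protein
            ):
                reasons.add("high_b")

            # anything that left a needed angle undefined excludes the record
            if not reasons and None in (rec.phi, rec.psi, rec.omega, rec.theta_c):
                reasons.add("missing_atoms")

            records.append(rec)
    return records


def _cell_center(angle: float, step: float) -> float:
    """Nearest grid centre on the step lattice; cells half-open [c-s/2, c+s/2)."""
    return geometry.wrap(math.floor((angle + step / 2.0) / step) * step)


def bin_records(
    records: Iterable[SurveyRecord],
    grid_step: float = 15.0,
    min_count: int = 100,
) -> List[GridBin]:
    """Assign included records to square (phi, psi) cells and average per cell.

    Cells are centred on multiples of ``grid_step`` and half-open on both
    axes, so assignment is total and unique.  Bins with fewer than
    ``min_count`` records are kept but flagged ``below_threshold`` and are
    omitted from profiles and trend fits.
    """
    if not (360.0 / grid_step).is_integer():
        raise ValueError(f"grid_step {grid_step} does not divide 360")
    cells: Dict[Tuple[float, float], List[SurveyRecord]] = {}
    for rec in records:
        if not rec.included:
            continue
        key = (_cell_center(rec.phi, grid_step), _cell_center(rec.psi, grid_step))
        cells.setdefault(key, []).append(rec)
    bins: List[GridBin] = []
    for (pc, sc), members in sorted(cells.items()):
        dw = geometry.circular_mean([m.delta_omega for m in members])
        tc = geometry.circular_mean([m.theta_c for m in members])
        bins.append(
            GridBin(
                phi_center=pc,
                psi_center=sc,
                count=len(members),
                mean_delta_omega=dw.mean,
                mean_theta_c=tc.mean,
                dispersion=dw.resultant,
                below_threshold=len(members) < min_count,
            )
        )
    return bins


def psi_profile(bins: Sequence[GridBin]) -> pd.DataFrame:
    """Marginal over phi: count-weighted circular means per psi column.

    Only bins meeting the per-cell count threshold contribute.  Returns a
    DataFrame with columns (psi_center, mean_delta_omega, mean_theta_c,
    count); raises :class:`EmptyProfileError` when no bin qualifies.
    """
    qualifying = [b for b in bins if not b.below_threshold]
    if not qualifying:
        raise EmptyProfileError("no bins meet the per-cell count threshold")
    rows = []
    by_psi: Dict[float, List[GridBin]] = {}
    for b in qualifying:
        by_psi.setdefault(b.psi_center, []).append(b)
    for psi_c in sorted(by_psi):
        group = by_psi[psi_c]
        w = [b.count for b in group]
        dw = geometry.circular_mean([b.mean_delta_omega for b in group], weights=w)
        tc = geometry.circular_mean([b.mean_theta_c for b in group], weights=w)
        rows.append(
            {
                "psi_center": psi_c,
                "mean_delta_omega": dw.mean,
                "mean_theta_c": tc.mean,
                "count": int(sum(w)),
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    """Tabulate records (one row each); exclusion reasons semicolon-joined."""
    rows = []
    for r in records:
        rows.append(
            {
                "entry_id": r.entry_id,
                "chain_id": r.chain_id,
                "seq_number": r.seq_number,
                "residue_name": r.residue_name,
                "phi": r.phi,
                "psi": r.psi,
                "omega": r.omega,
                "omega3": r.omega3,
                "delta_omega": r.delta_omega,
                "theta_c": r.theta_c,
                "theta_n": r.theta_n,
                "b_mainchain_residue": r.b_mainchain_residue,
                "included": r.included,
                "exclusion_reasons": ";".join(sorted(r.exclusion_reasons)),
            }
        )
    return pd.DataFrame(rows)


def passes_entry_criteria(model: StructureModel, config: Optional[FilterConfig] = None) -> Tuple[bool, List[str]]:
    """Header-based entry gate: resolution and R-factor against the config.

    Entries lacking a header value pass that particular check (selection-time
    culling, as with a pre-culled chain list, may already have applied it).
    """
    config = config or FilterConfig()
    reasons = []
    if model.resolution is not None and model.resolution > config.min_resolution:
        reasons.append("resolution")
    if model.r_factor is not None and model.r_factor >= config.max_r_factor:
        reasons.append("r_factor")
    return (not reasons, reasons)
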