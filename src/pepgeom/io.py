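"""Reading and writing protein coordinate files.

Thin layer over gemmi that exposes exactly what the survey needs: ordered
chains of residues with backbone atoms, B-factors, occupancies, resolved
altlocs, and the header resolution / R-factor used for entry-level gating.

Policies (crystallographic norms, applied uniformly):

* multi-model files keep model 1 only (NMR ensembles are outside the
  X-ray survey's scope);
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altloc letter, 'A' first), and the residue is flagged
  partial-occupancy whenever any main-chain atom has occupancy < 1;
* "main-chain" means {N, CA, C, O}; hydrogens are read when deposited,
  never constructed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "StructureFormatError",
    "EmptyModelError",
    "AmbiguousAtomError",
    "BACKBONE_ATOMS",
    "read_structure",
    "write_pdb",
    "backbone_atoms",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: names accepted for the amide hydrogen across deposition conventions
_AMIDE_H_NAMES = ("H", "HN", "1H", "H1")


class StructureFormatError(ValueError):
    """File could not be parsed under the requested coordinate standard."""


class EmptyModelError(ValueError):
    """Parsed file contains no coordinates."""


class AmbiguousAtomError(ValueError):
    """A backbone atom name is duplicated after altloc resolution."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    name: str
    atoms: List[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def partial_occupancy(self) -> bool:
        """True when any main-chain atom has occupancy below 1."""
        return any(
            a.occupancy < 1.0 for a in self.atoms if a.name in BACKBONE_ATOMS
        )


@dataclass
class StructureModel:
    entry_id: str = ""
    chains: Dict[str, List[Residue]] = field(default_factory=dict)
    resolution: Optional[float] = None
    r_factor: Optional[float] = None

    @property
    def n_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())

    def residues(self):
        for rs in self.chains.values():
            yield from rs


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _resolve_altlocs(res: gemmi.Residue) -> List[Atom]:
    """Keep one atom per name: highest occupancy, ties to the earlier altloc."""
    by_name: Dict[str, List[gemmi.Atom]] = {}
    for at in res:
        by_name.setdefault(at.name, []).append(at)
    out: List[Atom] = []
    for name, group in by_name.items():
        if len(group) == 1:
            chosen = [group[0]]
        else:
            alts = {a.altloc for a in group}
            if len(alts) == len(group):
                best = max(group, key=lambda a: (a.occ, -ord(a.altloc or "~")))
                chosen = [best]
            else:
                # duplicated name without distinguishing altlocs: keep all,
                # backbone_atoms() will refuse to pick one
                chosen = group
        for at in chosen:
            out.append(
                Atom(
                    name=at.name,
                    element=at.element.name,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    b_factor=at.b_iso,
                    occupancy=at.occ,
                    altloc=at.altloc or "",
                )
            )
    return out


_PDB_RFACTOR_RE = re.compile(
    r"REMARK   3\s+R VALUE\s+\((?:WORKING SET|WORKING \+ TEST SET)\)\s*:\s*([0-9.]+)"
)


_MMCIF_RESOLUTION_TAGS = ("_refine.ls_d_res_high", "_reflns.d_resolution_high")


def _resolution_from_header(st: gemmi.Structure, doc) -> Optional[float]:
    if st.resolution and st.resolution > 0:
        return float(st.resolution)
    if doc is not None:
        block = doc.sole_block()
        for tag in _MMCIF_RESOLUTION_TAGS:
            val = block.find_value(tag)
            if val not in (None, "?", "."):
                try:
                    return float(val)
                except ValueError:
                    pass
    return None


def _r_factor_from_header(st: gemmi.Structure, doc) -> Optional[float]:
    for remark in st.raw_remarks:
        m = _PDB_RFACTOR_RE.search(remark)
        if m:
            return float(m.group(1))
    if doc is not None:
        block = doc.sole_block()
        for tag in ("_refine.ls_R_factor_R_work", "_refine.ls_R_factor_obs"):
            val = block.find_value(tag)
            if val not in (None, "?", "."):
                try:
                    return float(val)
                except ValueError:
                    pass
    return None


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only model 1 of multi-model files is kept; altlocs are resolved (see
    module docstring); header resolution and R-factor are captured when
    present.  Raises :class:`StructureFormatError` on unparseable input and
    :class:`EmptyModelError` when no coordinates are found.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")
    if not path.exists():
        raise FileNotFoundError(path)
    doc = gemmi.cif.Document()
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format], save_doc=doc)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise EmptyModelError(f"{path}: no coordinates found")
    st.setup_entities()

    model = StructureModel(entry_id=st.name or path.stem)
    try:
        header_doc = doc if len(doc) else None
        model.resolution = _resolution_from_header(st, header_doc)
        model.r_factor = _r_factor_from_header(st, header_doc)
    except Exception:
        pass

    first = st[0]  # model 1 only
    for chain in first:
        residues: List[Residue] = []
        for res in chain:
            if res.het_flag == "W" or res.name == "HOH":
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    name=res.name,
                    atoms=_resolve_altlocs(res),
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
            model.chains[chain.name] = residues
    if not model.chains:
        raise EmptyModelError(f"{path}: no polymer residues found")
    return model


def write_pdb(model: StructureModel, path) -> None:
    """Write standard PDB ATOM records (3-decimal coordinates, 2-decimal B)."""
    if model.n_residues == 0:
        raise EmptyModelError("write_pdb: empty model")
    st = gemmi.Structure()
    st.name = model.entry_id or "SYNT"
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        if len(chain_id) > 2:
            raise ValueError(f"chain id {chain_id!r} exceeds PDB format limits")
        ch = gemmi.Chain(chain_id)
        for r in residues:
            if r.seq_number > 9999:
                raise ValueError("residue number exceeds PDB format limits")
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seq_number, r.insertion_code or " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or a.name[0])
                ga.pos = gemmi.Position(*a.coord)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                ga.altloc = a.altloc or "\0"
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def backbone_atoms(residue: Residue) -> Tuple[Dict[str, Atom], List[str]]:
    """Map backbone names {N, CA, C, O} (+ H if deposited) to single atoms.

    Returns ``(mapping, missing_names)``; missing atoms are reported, never
    invented.  Raises :class:`AmbiguousAtomError` if a backbone name remains
    duplicated after altloc resolution.
    """
    mapping: Dict[str, Atom] = {}
    missing: List[str] = []
    for name in BACKBONE_ATOMS:
        hits = [a for a in residue.atoms if a.name == name]
        if len(hits) > 1:
            raise AmbiguousAtomError(
                f"{residue.chain_id}/{residue.seq_number} {residue.name}: "
                f"duplicate backbone atom {name}"
            )
        if hits:
            mapping[name] = hits[0]
        else:
            missing.append(name)
    for hname in _AMIDE_H_NAMES:
        hits = [a for a in residue.atoms if a.name == hname]
        if len(hits) == 1:
            mapping["H"] = hits[0]
            break
    return mapping, missing


def mainchain_b_factor(residue: Residue) -> Optional[float]:
    """Mean B over the residue's present main-chain atoms; None if none present."""
    bs = [a.b_factor for a in residue.atoms if a.name in BACKBONE_ATOMS]
    if not bs:
        return None
    return float(np.mean(bs))
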