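"""Internal-coordinate backbone machinery and the synthetic-data generator.

Backbones are represented in two interconvertible forms:

* Cartesian (:class:`~pepgeom.io.StructureModel`), and
* internal coordinates (:class:`InternalCoordinateChain`): per atom a
  (bond length, bond angle, torsion) triplet, with the first three atoms
  (N, CA, C of residue 1) anchoring the frame.  ``build_backbone`` and
  ``extract_internal`` are exact inverses at numerical tolerance, which is
  what makes torsion-editing experiments well defined: edit one internal
  coordinate, rebuild, and every downstream atom moves rigidly.

The carbonyl oxygen of residue i is placed by the omega_3 torsion
(O_i-C_i-N_{i+1}-CA_{i+1}), so the carbonyl-carbon pyramidalization
theta_C is directly controllable by the generator; theta_C = 0 puts the
C=O bond eclipsing N-CA_{i+1} across the amide plane.

The ensemble generator draws (phi, psi) from a Ramachandran sampler and
imposes the statistical structure seen in high-resolution surveys: a
period-120 sinusoid of delta-omega in psi (sign alternating every 60 deg)
and a linear coupling of theta_C to delta-omega, each with Gaussian noise.

``idealize_omega`` reproduces the cumulative-distortion experiment: every
trans omega torsion is set to exactly 180 deg, all other internal
coordinates are preserved, and the chain is rebuilt from the same anchor;
the report carries per-residue CA displacements in the common anchor
frame, their mean and max, and the Kabsch RMSD after optimal superposition
— all candidate readings of a "trace difference".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from . import geometry
from .geometry import DegenerateGeometryError, wrap
from .io import Atom, Residue, StructureModel, backbone_atoms

__all__ = [
    "COVALENT_GEOMETRY",
    "ResidueIC",
    "InternalCoordinateChain",
    "EnsembleSpec",
    "EnsembleResult",
    "Basin",
    "DistortionReport",
    "ExtractionError",
    "place_atom",
    "build_backbone",
    "extract_internal",
    "synthesize_ensemble",
    "idealize_omega",
    "kabsch_superpose",
    "add_amide_hydrogens",
]

#: Engh–Huber-style covalent backbone geometry (lengths in A, angles in deg);
#: community defaults, overridable per residue in the internal coordinates.
COVALENT_GEOMETRY: Dict[str, float] = {
    "len_n_ca": 1.458,
    "len_ca_c": 1.525,
    "len_c_n": 1.329,
    "len_c_o": 1.231,
    "ang_n_ca_c": 111.2,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_o_c_n": 123.0,  # N_{i+1}-C_i-O_i, used to place O by the omega_3 torsion
    "ang_ca_c_o": 120.8,  # terminal O placement
}


class ExtractionError(ValueError):
    """Backbone incomplete or broken where internal coordinates are required."""


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d bonded to c.

    Returns d with |d-c| = bond_length, angle(b,c,d) = bond_angle and
    dihedral(a,b,c,d) = torsion.  Raises on a collinear anchor frame.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    if not 0.0 < bond_angle < 180.0:
        raise ValueError("bond_angle must be in (0, 180)")
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nbc < 1e-10 or nn < 1e-10 * max(np.linalg.norm(ab) * nbc, 1e-30):
        raise DegenerateGeometryError("place_atom: collinear anchor frame a, b, c")
    bc_hat = bc / nbc
    n_hat = n / nn
    m_hat = np.cross(n_hat, bc_hat)
    ang = math.radians(bond_angle)
    tor = math.radians(torsion)
    # local frame: x along bc, y in the abc plane, z normal
    d_local = bond_length * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


@dataclass
class ResidueIC:
    """Internal coordinates owned by one residue.

    Torsions (degrees): ``phi`` places C_i (None for the first residue —
    anchored); ``psi`` places N_{i+1}; ``omega`` places CA_{i+1};
    ``omega3`` places O_i via the frame (CA_{i+1}, N_{i+1}, C_i) so that
    dihedral(O_i, C_i, N_{i+1}, CA_{i+1}) = omega3.  The last residue has
    psi/omega/omega3 None and its O placed by ``o_torsion_terminal`` =
    dihedral(N_i, CA_i, C_i, O_i).
    """

    name: str = "ALA"
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None
    omega3: Optional[float] = None
    o_torsion_terminal: Optional[float] = None
    len_n_ca: float = COVALENT_GEOMETRY["len_n_ca"]
    len_ca_c: float = COVALENT_GEOMETRY["len_ca_c"]
    len_c_o: float = COVALENT_GEOMETRY["len_c_o"]
    len_c_n: Optional[float] = COVALENT_GEOMETRY["len_c_n"]
    ang_n_ca_c: float = COVALENT_GEOMETRY["ang_n_ca_c"]
    ang_ca_c_n: Optional[float] = COVALENT_GEOMETRY["ang_ca_c_n"]
    ang_c_n_ca: Optional[float] = COVALENT_GEOMETRY["ang_c_n_ca"]
    ang_o: float = COVALENT_GEOMETRY["ang_o_c_n"]

    def validate(self, is_first: bool, is_last: bool) -> None:
        for L in (self.len_n_ca, self.len_ca_c, self.len_c_o):
            if L <= 0:
                raise ValueError("bond lengths must be positive")
        for A in (self.ang_n_ca_c, self.ang_o):
            if not 0 < A < 180:
                raise ValueError("bond angles must be in (0, 180)")
        if not is_first and self.phi is None:
            raise ValueError("non-initial residue requires phi")
        if not is_last:
            for name in ("psi", "omega", "omega3", "len_c_n", "ang_ca_c_n", "ang_c_n_ca"):
                if getattr(self, name) is None:
                    raise ValueError(f"non-terminal residue requires {name}")
        elif self.o_torsion_terminal is None:
            raise ValueError("last residue requires o_torsion_terminal")


@dataclass
class InternalCoordinateChain:
    """A backbone as anchor coordinates plus per-residue internal coordinates."""

    residues: List[ResidueIC]
    anchor_n: np.ndarray = field(default_factory=lambda: np.zeros(3))
    anchor_ca: Optional[np.ndarray] = None
    anchor_c: Optional[np.ndarray] = None
    chain_id: str = "A"
    entry_id: str = "SYNT"

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("chain needs at least 2 residues")
        r0 = self.residues[0]
        if self.anchor_ca is None:
            # canonical frame: N at origin, CA on +x, C in the xy-plane
            self.anchor_ca = self.anchor_n + np.array([r0.len_n_ca, 0.0, 0.0])
        if self.anchor_c is None:
            ang = math.radians(r0.ang_n_ca_c)
            self.anchor_c = self.anchor_ca + r0.len_ca_c * np.array(
                [-math.cos(ang), math.sin(ang), 0.0]
            )
        self.anchor_n = np.asarray(self.anchor_n, dtype=float)
        self.anchor_ca = np.asarray(self.anchor_ca, dtype=float)
        self.anchor_c = np.asarray(self.anchor_c, dtype=float)

    def validate(self) -> None:
        n = len(self.residues)
        for i, r in enumerate(self.residues):
            r.validate(is_first=(i == 0), is_last=(i == n - 1))


def build_backbone(ic: InternalCoordinateChain, b_factor: float = 10.0) -> StructureModel:
    """Deterministic Cartesian rebuild of an internal-coordinate chain.

    Re-measuring phi, psi, omega, omega_3 on the result reproduces the
    input torsions; the first three atoms sit exactly on the anchor.
    """
    ic.validate()
    n = len(ic.residues)
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    O = [None] * n
    N[0], CA[0], C[0] = ic.anchor_n, ic.anchor_ca, ic.anchor_c
    for i in range(n - 1):
        r = ic.residues[i]
        rn = ic.residues[i + 1]
        N[i + 1] = place_atom(N[i], CA[i], C[i], r.len_c_n, r.ang_ca_c_n, r.psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], rn.len_n_ca, r.ang_c_n_ca, r.omega)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], rn.len_ca_c, rn.ang_n_ca_c, rn.phi)
        # O_i so that dihedral(O_i, C_i, N_{i+1}, CA_{i+1}) = omega3 (reversal-invariant)
        O[i] = place_atom(CA[i + 1], N[i + 1], C[i], r.len_c_o, r.ang_o, r.omega3)
    last = ic.residues[-1]
    O[n - 1] = place_atom(N[n - 1], CA[n - 1], C[n - 1], last.len_c_o, last.ang_o,
                          last.o_torsion_terminal)

    residues = []
    for i, r in enumerate(ic.residues):
        atoms = [
            Atom("N", "N", N[i], b_factor, 1.0),
            Atom("CA", "C", CA[i], b_factor, 1.0),
            Atom("C", "C", C[i], b_factor, 1.0),
            Atom("O", "O", O[i], b_factor, 1.0),
        ]
        residues.append(Residue(ic.chain_id, i + 1, "", r.name, atoms))
    return StructureModel(entry_id=ic.entry_id, chains={ic.chain_id: residues})


def extract_internal(model: StructureModel, chain_id: Optional[str] = None) -> InternalCoordinateChain:
    """Measure the internal coordinates of one complete, unbroken chain.

    Exact inverse of :func:`build_backbone` (the anchor coordinates are
    retained, so the rebuild reproduces the Cartesian chain, not just its
    shape).  Raises :class:`ExtractionError` naming the offending residue
    on missing atoms or chain breaks.
    """
    if chain_id is None:
        chain_id = next(iter(model.chains))
    residues = model.chains[chain_id]
    n = len(residues)
    if n < 2:
        raise ExtractionError("chain too short for internal coordinates")
    coords = []
    for r in residues:
        mapping, missing = backbone_atoms(r)
        if missing:
            raise ExtractionError(
                f"residue {r.chain_id}/{r.seq_number} {r.name} missing {missing}"
            )
        coords.append({k: mapping[k].coord for k in ("N", "CA", "C", "O")})
    for i in range(n - 1):
        d = float(np.linalg.norm(coords[i]["C"] - coords[i + 1]["N"]))
        if d > 1.8:
            raise ExtractionError(
                f"chain break between residues {residues[i].seq_number} and "
                f"{residues[i + 1].seq_number} (C-N distance {d:.2f} A)"
            )

    ics: List[ResidueIC] = []
    for i, r in enumerate(residues):
        c = coords[i]
        ric = ResidueIC(
            name=r.name,
            len_n_ca=float(np.linalg.norm(c["CA"] - c["N"])),
            len_ca_c=float(np.linalg.norm(c["C"] - c["CA"])),
            len_c_o=float(np.linalg.norm(c["O"] - c["C"])),
            ang_n_ca_c=geometry.bond_angle(c["N"], c["CA"], c["C"]),
        )
        if i > 0:
            p = coords[i - 1]
            ric.phi = geometry.dihedral(p["C"], c["N"], c["CA"], c["C"])
        if i < n - 1:
            nx = coords[i + 1]
            ric.len_c_n = float(np.linalg.norm(nx["N"] - c["C"]))
            ric.ang_ca_c_n = geometry.bond_angle(c["CA"], c["C"], nx["N"])
            ric.ang_c_n_ca = geometry.bond_angle(c["C"], nx["N"], nx["CA"])
            ric.ang_o = geometry.bond_angle(nx["N"], c["C"], c["O"])
            ric.psi = geometry.dihedral(c["N"], c["CA"], c["C"], nx["N"])
            ric.omega = geometry.dihedral(c["CA"], c["C"], nx["N"], nx["CA"])
            ric.omega3 = geometry.dihedral(c["O"], c["C"], nx["N"], nx["CA"])
        else:
            ric.len_c_n = None
            ric.ang_ca_c_n = None
            ric.ang_c_n_ca = None
            ric.ang_o = geometry.bond_angle(c["CA"], c["C"], c["O"])
            ric.o_torsion_terminal = geometry.dihedral(c["N"], c["CA"], c["C"], c["O"])
        ics.append(ric)

    return InternalCoordinateChain(
        residues=ics,
        anchor_n=coords[0]["N"].copy(),
        anchor_ca=coords[0]["CA"].copy(),
        anchor_c=coords[0]["C"].copy(),
        chain_id=chain_id,
        entry_id=model.entry_id,
    )


@dataclass
class Basin:
    """One Gaussian Ramachandran basin of the (phi, psi) sampler."""

    phi: float
    psi: float
    phi_sd: float = 10.0
    psi_sd: float = 10.0
    weight: float = 1.0


#: default sampler: the three populated Ramachandran regions of globular
#: proteins (right-handed alpha, beta, polyproline II)
DEFAULT_BASINS = (
    Basin(phi=-63.0, psi=-43.0, phi_sd=10.0, psi_sd=10.0, weight=0.35),
    Basin(phi=-120.0, psi=135.0, phi_sd=20.0, psi_sd=25.0, weight=0.45),
    Basin(phi=-70.0, psi=150.0, phi_sd=12.0, psi_sd=12.0, weight=0.20),
)


@dataclass
class EnsembleSpec:
    """Generative conditions for a synthetic backbone ensemble.

    delta_omega(psi) = amplitude_A * sin(3 (psi - phase)) + N(0, noise_omega_sd);
    theta_C = thetaC_slope * delta_omega + thetaC_intercept + N(0, noise_thetaC_sd);
    omega = 180 + delta_omega (trans chains); omega_3 follows from theta_C.
    """

    n_chains: int = 25
    chain_length: int = 82
    phipsi_sampler: object = "basins"  # "basins", ("fixed", phi, psi), or list[Basin]
    basins: Sequence[Basin] = DEFAULT_BASINS
    amplitude_A: float = 2.0
    phase: float = 0.0
    noise_omega_sd: float = 1.0
    thetaC_slope: float = 0.6
    thetaC_intercept: float = 0.0
    noise_thetaC_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.chain_length < 4:
            raise ValueError("chain_length must be >= 4")
        if self.noise_omega_sd < 0 or self.noise_thetaC_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if isinstance(self.phipsi_sampler, (list, tuple)) and self.phipsi_sampler \
                and isinstance(self.phipsi_sampler[0], Basin):
            self.basins = tuple(self.phipsi_sampler)
            self.phipsi_sampler = "basins"
        if self.phipsi_sampler == "basins":
            w = np.array([b.weight for b in self.basins], dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("basin weights must be non-negative with positive sum")


@dataclass
class EnsembleResult:
    models: List[StructureModel]
    truth: "pd.DataFrame"  # per-residue generating values


def _sample_phipsi(spec: EnsembleSpec, rng: np.random.Generator) -> Tuple[float, float]:
    s = spec.phipsi_sampler
    if isinstance(s, tuple) and len(s) == 3 and s[0] == "fixed":
        return float(s[1]), float(s[2])
    w = np.array([b.weight for b in spec.basins], dtype=float)
    b = spec.basins[rng.choice(len(spec.basins), p=w / w.sum())]
    return (
        wrap(rng.normal(b.phi, b.phi_sd)),
        wrap(rng.normal(b.psi, b.psi_sd)),
    )


def synthesize_ensemble(spec: EnsembleSpec) -> EnsembleResult:
    """Generate reproducible backbone models with the spec's statistics.

    Returns the models plus a truth table of per-residue generating values
    (phi, psi, delta_omega, theta_C, omega, omega_3) — the reference the
    survey/fit pipeline is validated against.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    models: List[StructureModel] = []
    rows = []
    for ci in range(spec.n_chains):
        entry = f"SYN{ci:04d}"
        ics: List[ResidueIC] = []
        L = spec.chain_length
        phis = [None] + [None] * (L - 1)
        for i in range(L):
            phi_i, psi_i = _sample_phipsi(spec, rng)
            ric = ResidueIC(phi=(phi_i if i > 0 else None))
            if i < L - 1:
                dw = spec.amplitude_A * math.sin(math.radians(3.0 * (psi_i - spec.phase)))
                dw += rng.normal(0.0, spec.noise_omega_sd) if spec.noise_omega_sd else 0.0
                tc = spec.thetaC_slope * dw + spec.thetaC_intercept
                tc += rng.normal(0.0, spec.noise_thetaC_sd) if spec.noise_thetaC_sd else 0.0
                omega = wrap(180.0 + dw)
                omega3 = wrap(omega + 180.0 - tc)
                ric.psi = psi_i
                ric.omega = omega
                ric.omega3 = omega3
                rows.append(
                    {
                        "entry_id": entry,
                        "seq_number": i + 1,
                        "phi": phi_i if i > 0 else np.nan,
                        "psi": psi_i,
                        "delta_omega": dw,
                        "theta_c": tc,
                        "omega": omega,
                        "omega3": omega3,
                    }
                )
            else:
                ric.o_torsion_terminal = 180.0
            ics.append(ric)
        ic = InternalCoordinateChain(residues=ics, chain_id="A", entry_id=entry)
        models.append(build_backbone(ic))
    truth = pd.DataFrame(rows)
    return EnsembleResult(models=models, truth=truth)


@dataclass
class DistortionReport:
    """All candidate readings of a CA-trace difference after torsion editing."""

    per_residue_ca_displacement: List[float]
    mean_displacement: float
    max_displacement: float
    kabsch_rmsd: float
    n_atoms: int

    @property
    def unsuperposed_rms(self) -> float:
        d = np.asarray(self.per_residue_ca_displacement)
        return float(np.sqrt(np.mean(d**2)))


def idealize_omega(model: StructureModel, chain_id: Optional[str] = None) -> Tuple[StructureModel, DistortionReport]:
    """Set every trans omega torsion to exactly 180 deg and rebuild.

    cis bonds are left untouched; all other internal coordinates are
    preserved; the rebuild starts from the same anchored first three atoms,
    so the unsuperposed per-residue CA displacement is well defined.
    """
    if chain_id is None:
        chain_id = next(iter(model.chains))
    ic = extract_internal(model, chain_id)
    for r in ic.residues:
        if r.omega is not None and geometry.classify_isomer(r.omega) == "trans":
            r.omega = 180.0
    rebuilt = build_backbone(ic)

    orig_ca = np.array(
        [r.atom("CA").coord for r in model.chains[chain_id]]
    )
    new_ca = np.array(
        [r.atom("CA").coord for r in rebuilt.chains[ic.chain_id]]
    )
    disp = np.linalg.norm(orig_ca - new_ca, axis=1)
    _, _, rmsd = kabsch_superpose(orig_ca, new_ca)
    report = DistortionReport(
        per_residue_ca_displacement=[float(d) for d in disp],
        mean_displacement=float(disp.mean()),
        max_displacement=float(disp.max()),
        kabsch_rmsd=rmsd,
        n_atoms=len(disp),
    )
    return rebuilt, report


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of Q onto P.

    Returns ``(R, t, rmsd)`` with R a proper rotation (det +1) such that
    ``R @ q + t`` best matches p over the paired points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("point sets must be paired (same shape)")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 paired 3D points")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(P - pc, Q - qc)
    R = rot.as_matrix()
    t = pc - R @ qc
    rmsd = float(rssd / math.sqrt(P.shape[0]))
    return R, t, rmsd


def add_amide_hydrogens(model: StructureModel, chain_id: Optional[str] = None,
                        bond_length: float = 1.01, angle: float = 119.0) -> StructureModel:
    """Add exactly in-plane amide hydrogens (theta_N = 0) to residues 2..n.

    H on N_{i+1} is placed with torsion CA_i-C_i-N_{i+1}-H = omega - 180,
    which makes theta_N = wrap(omega_H - omega + 180) exactly zero — a
    test scaffold for the nitrogen-pyramidalization path, not a physical
    hydrogen-placement model.
    """
    if chain_id is None:
        chain_id = next(iter(model.chains))
    residues = model.chains[chain_id]
    for i in range(len(residues) - 1):
        cur, nxt = residues[i], residues[i + 1]
        m_cur, miss_cur = backbone_atoms(cur)
        m_nxt, miss_nxt = backbone_atoms(nxt)
        if miss_cur or "N" not in m_nxt or "CA" not in m_nxt:
            continue
        omega = geometry.dihedral(
            m_cur["CA"].coord, m_cur["C"].coord, m_nxt["N"].coord, m_nxt["CA"].coord
        )
        h = place_atom(
            m_cur["CA"].coord, m_cur["C"].coord, m_nxt["N"].coord,
            bond_length, angle, wrap(omega - 180.0),
        )
        nxt.atoms.append(Atom("H", "H", h, 0.0, 1.0))
    return model
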