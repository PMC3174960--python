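"""Vector geometry of the peptide unit.

All angles are in degrees, wrapped to the half-open interval (-180, +180]
(the crystallographic convention that puts a trans peptide at omega = +180
rather than -180). Torsion signs follow IUPAC-IUB: looking from atom 2 to
atom 3, a clockwise rotation of the far bond relative to the near bond is
positive.

The module defines the two planarity/pyramidalization statistics used
throughout the package:

* ``delta_omega`` -- the signed departure of the peptide torsion omega
  (CA_i-C_i-N_{i+1}-CA_{i+1}) from its ideal isomer value, 180 deg for a
  trans bond and 0 deg for a cis bond;
* ``theta_c`` -- pyramidalization of the carbonyl carbon,
  (omega - omega_3 + 180) mod 360, where omega_3 is the torsion
  O_i-C_i-N_{i+1}-CA_{i+1}.  theta_c is 0 for a planar sp2 carbon.
* ``theta_n`` -- pyramidalization of the amide nitrogen, defined by the
  analogous construction from the amide-hydrogen torsion; it requires an
  H position and is therefore usually unavailable in X-ray structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "wrap",
    "dihedral",
    "bond_angle",
    "delta_omega",
    "theta_c",
    "theta_n",
    "classify_isomer",
    "circular_mean",
    "CircularMean",
    "PeptideUnit",
]


class DegenerateGeometryError(ValueError):
    """Raised when a torsion or frame is undefined (collinear/coincident atoms)."""


def wrap(x):
    """Wrap an angle in degrees to the half-open interval (-180, 180].

    Accepts scalars or numpy arrays.  Idempotent and 360-periodic:
    ``wrap(wrap(x)) == wrap(x)`` and ``wrap(x + 360) == wrap(x)``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap: angle must be finite")
    w = np.mod(x, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    if w.ndim == 0:
        return float(w)
    return w


_COLLINEAR_TOL = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """IUPAC-signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Computed as ``atan2(((b1 x b2) x (b2 x b3)) . b2_hat, (b1 x b2) . (b2 x b3))``
    with b_i the successive bond vectors.  Raises
    :class:`DegenerateGeometryError` when either atom triple is collinear or
    consecutive points coincide, rather than returning NaN -- silent NaNs
    would corrupt downstream circular means.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < _COLLINEAR_TOL:
        raise DegenerateGeometryError("dihedral: central atoms p2, p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale1 = np.linalg.norm(b1) * nb2
    scale2 = np.linalg.norm(b3) * nb2
    if scale1 < _COLLINEAR_TOL or np.linalg.norm(n1) < _COLLINEAR_TOL * scale1:
        raise DegenerateGeometryError("dihedral: atoms p1, p2, p3 are collinear")
    if scale2 < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL * scale2:
        raise DegenerateGeometryError("dihedral: atoms p2, p3, p4 are collinear")
    m = np.cross(n1, n2)
    y = np.dot(m, b2 / nb2)
    x = np.dot(n1, n2)
    return wrap(math.degrees(math.atan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Valence angle p1-p2-p3 in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COLLINEAR_TOL or nv < _COLLINEAR_TOL:
        raise DegenerateGeometryError("bond_angle: coincident atoms")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def classify_isomer(omega: float) -> str:
    """Classify a peptide bond as ``"trans"`` or ``"cis"`` from its omega torsion.

    trans iff |wrap(omega - 180)| <= 90; the 90 deg boundary goes to trans.
    Only near-planar bonds survive the survey filters, so the tie rule is
    inert in practice.
    """
    return "trans" if abs(wrap(omega - 180.0)) <= 90.0 else "cis"


def delta_omega(omega: float, isomer: Optional[str] = None) -> float:
    """Signed deviation of omega from its ideal isomer value (180 trans, 0 cis)."""
    if isomer is None:
        isomer = classify_isomer(omega)
    if isomer == "trans":
        return wrap(omega - 180.0)
    if isomer == "cis":
        return wrap(omega)
    raise ValueError(f"unknown isomer {isomer!r}")


def theta_c(omega: float, omega3: float) -> float:
    """Carbonyl-carbon pyramidalization: wrap(omega - omega3 + 180).

    Zero for a planar carbonyl carbon (the O-C bond eclipsing the
    N-CA_{i+1} bond across the amide plane).
    """
    return wrap(omega - omega3 + 180.0)


def theta_n(omega_h: Optional[float], omega: float) -> Optional[float]:
    """Amide-nitrogen pyramidalization: wrap(omega_H - omega + 180).

    ``omega_H`` is the torsion CA_i-C_i-N_{i+1}-H_{i+1}.  Returns ``None``
    when the amide hydrogen is absent (the usual case in X-ray models);
    zero for a planar nitrogen.  The construction mirrors ``theta_c`` on
    the nitrogen side of the bond and is a convention of this package.
    """
    if omega_h is None:
        return None
    return wrap(omega_h - omega + 180.0)


@dataclass(frozen=True)
class CircularMean:
    """Circular mean of a set of angles plus its resultant length.

    ``resultant`` in [0, 1] is the mean resultant vector length; values
    near 1 indicate tight clustering, near 0 a dispersed or antipodal set
    for which the mean direction is meaningless (``defined`` is False).
    """

    mean: float
    resultant: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mean)


_ZERO_RESULTANT = 1e-12


def circular_mean(angles: Iterable[float], weights: Optional[Sequence[float]] = None) -> CircularMean:
    """Circular (directional) mean of angles in degrees.

    Raises ValueError on an empty input.  A (near-)zero resultant yields a
    NaN mean with ``defined == False`` rather than an arbitrary direction.
    """
    a = np.asarray(list(angles) if not isinstance(angles, np.ndarray) else angles, dtype=float)
    if a.size == 0:
        raise ValueError("circular_mean: empty input")
    rad = np.radians(a)
    if weights is None:
        s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise ValueError("circular_mean: weights shape mismatch")
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError("circular_mean: non-positive total weight")
        s, c = np.sum(w * np.sin(rad)) / wsum, np.sum(w * np.cos(rad)) / wsum
    r = math.hypot(s, c)
    if r < _ZERO_RESULTANT:
        return CircularMean(math.nan, r)
    return CircularMean(wrap(math.degrees(math.atan2(s, c))), r)


@dataclass(frozen=True)
class PeptideUnit:
    """The six-atom neighbourhood of one C-N peptide bond with derived angles.

    Built from coordinates via :meth:`from_coords`; the stored angles always
    satisfy ``theta_c == wrap(omega - omega3 + 180)`` and recomputing omega
    and omega_3 from the stored atoms reproduces the stored values exactly.
    """

    ca_i: np.ndarray
    c_i: np.ndarray
    o_i: np.ndarray
    n_next: np.ndarray
    ca_next: np.ndarray
    h_next: Optional[np.ndarray] = None
    omega: float = field(default=math.nan)
    omega3: float = field(default=math.nan)
    delta_omega: float = field(default=math.nan)
    theta_c: float = field(default=math.nan)
    theta_n: Optional[float] = None
    isomer: str = "trans"

    @classmethod
    def from_coords(cls, ca_i, c_i, o_i, n_next, ca_next, h_next=None) -> "PeptideUnit":
        ca_i, c_i, o_i, n_next, ca_next = (
            np.asarray(p, dtype=float) for p in (ca_i, c_i, o_i, n_next, ca_next)
        )
        om = dihedral(ca_i, c_i, n_next, ca_next)
        om3 = dihedral(o_i, c_i, n_next, ca_next)
        iso = classify_isomer(om)
        om_h = None
        if h_next is not None:
            h_next = np.asarray(h_next, dtype=float)
            om_h = dihedral(ca_i, c_i, n_next, h_next)
        return cls(
            ca_i=ca_i,
            c_i=c_i,
            o_i=o_i,
            n_next=n_next,
            ca_next=ca_next,
            h_next=h_next,
            omega=om,
            omega3=om3,
            delta_omega=delta_omega(om, iso),
            theta_c=theta_c(om, om3),
            theta_n=theta_n(om_h, om),
            isomer=iso,
        )
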