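"""Shared fixtures: shipped coordinate files and programmatic backbones."""

from pathlib import Path

import numpy as np
import pytest

from pepgeom import backbone as bb
from pepgeom import survey as sv

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


def make_chain(n, phi=-60.0, psi=-45.0, omega=180.0, theta_c=0.0, names=None,
               entry_id="SYNT"):
    """Uniform-torsion backbone: omega3 chosen so theta_C has the given value."""
    from pepgeom.geometry import wrap

    ics = []
    for i in range(n):
        r = bb.ResidueIC(name=(names[i] if names else "ALA"),
                         phi=(phi if i > 0 else None))
        if i < n - 1:
            r.psi = psi
            r.omega = omega
            r.omega3 = wrap(omega + 180.0 - theta_c)
        else:
            r.o_torsion_terminal = 180.0
        ics.append(r)
    return bb.build_backbone(bb.InternalCoordinateChain(residues=ics, entry_id=entry_id))


def random_ic_chain(rng, n=8):
    """Random but valid internal-coordinate chain (torsions and geometry jittered)."""
    ics = []
    for i in range(n):
        r = bb.ResidueIC(
            phi=(float(rng.uniform(-180, 180)) if i > 0 else None),
            len_n_ca=float(rng.uniform(1.40, 1.52)),
            len_ca_c=float(rng.uniform(1.47, 1.58)),
            len_c_o=float(rng.uniform(1.20, 1.26)),
            ang_n_ca_c=float(rng.uniform(105, 117)),
        )
        if i < n - 1:
            r.psi = float(rng.uniform(-180, 180))
            r.omega = float(rng.uniform(-180, 180))
            r.omega3 = float(rng.uniform(-180, 180))
            r.len_c_n = float(rng.uniform(1.28, 1.38))
            r.ang_ca_c_n = float(rng.uniform(110, 122))
            r.ang_c_n_ca = float(rng.uniform(116, 127))
            r.ang_o = float(rng.uniform(118, 127))
        else:
            r.o_torsion_terminal = float(rng.uniform(-180, 180))
            r.len_c_n = None
            r.ang_ca_c_n = None
            r.ang_c_n_ca = None
            r.ang_o = float(rng.uniform(115, 126))
        ics.append(r)
    return bb.InternalCoordinateChain(residues=ics)


@pytest.fixture
def helix_model():
    return make_chain(10)


@pytest.fixture(scope="session")
def default_ensemble():
    """The study-condition ensemble: A=2 deg, sigma_omega=1 deg, slope 0.6,
    sigma_thetaC=0.5 deg, 2000 interior records, fixed seed."""
    return bb.synthesize_ensemble(bb.EnsembleSpec(seed=7))


@pytest.fixture(scope="session")
def default_ensemble_records(default_ensemble):
    records = []
    for m in default_ensemble.models:
        records.extend(sv.extract_records(m))
    return [r for r in records if r.included]
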