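#!/usr/bin/env python
"""Stage 4: the cumulative-distortion experiment.

Small per-bond planarity deviations accumulate: each delta_omega rotates
everything downstream of its peptide bond, so over a protein-sized chain
a few degrees of twist per bond moves the far end by angstroms.  This
stage builds one 121-residue chain whose omega angles carry Gaussian
noise of sd 6.8 deg (a realistic omega spread for an ultra-high
resolution structure), imposes omega = 180 on every trans bond, rebuilds
from the same anchor, and reports the CA-trace difference under all
candidate metrics (mean/max unsuperposed displacement, Kabsch RMSD).
"""

import dataclasses
import json
from pathlib import Path

from pepgeom import backbone as bb
from pepgeom import io as sio
from pepgeom import survey as sv

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
SEED = 8
CHAIN_LENGTH = 121
OMEGA_SD = 6.8


def main() -> None:
    spec = bb.EnsembleSpec(
        n_chains=1, chain_length=CHAIN_LENGTH,
        amplitude_A=0.0, noise_omega_sd=OMEGA_SD, noise_thetaC_sd=0.0,
        seed=SEED,
    )
    model = bb.synthesize_ensemble(spec).models[0]
    dw = [r.delta_omega for r in sv.extract_records(model) if r.delta_omega is not None]
    omega_sd = float(np.std(dw, ddof=1))

    idealized, report = bb.idealize_omega(model)

    out_dir = ROOT / "scratch" / "idealize"
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.write_pdb(model, out_dir / "original.pdb")
    sio.write_pdb(idealized, out_dir / "idealized.pdb")

    payload = {
        "chain_length": CHAIN_LENGTH,
        "omega_noise_sd_deg": OMEGA_SD,
        "measured_omega_sd_deg": round(omega_sd, 3),
        "seed": SEED,
        **{k: (round(v, 4) if isinstance(v, float) else v)
           for k, v in dataclasses.asdict(report).items()
           if k != "per_residue_ca_displacement"},
        "unsuperposed_rms_A": round(report.unsuperposed_rms, 4),
        "ca_displacement_profile_A": [round(d, 3) for d in
                                      report.per_residue_ca_displacement[::10]],
    }
    out = ROOT / "results" / "04_distortion_report.json"
    out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"omega sd {omega_sd:.2f} deg over {CHAIN_LENGTH - 1} bonds")
    print(f"idealizing all trans omega to 180 moves the CA trace by "
          f"{report.mean_displacement:.2f} A on average "
          f"(max {report.max_displacement:.2f} A, Kabsch RMSD "
          f"{report.kabsch_rmsd:.2f} A over {report.n_atoms} CA)")
    print(f"report -> {out}")


if __name__ == "__main__":
    main()
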