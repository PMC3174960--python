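#!/usr/bin/env python
"""Stage 3: fit the planarity trends on the surveyed records.

Fits the fixed-period (120 deg) harmonic of delta_omega and theta_C
against psi on the per-record values, locates the psi values where the
fitted peptide is planar (zero crossings, expected 60 deg apart), and
regresses theta_C on delta_omega.  Results go to results/03_trend_fits.json.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pepgeom import trends as tr

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    records_path = ROOT / "scratch" / "survey" / "records.tsv"
    if not records_path.exists():
        raise SystemExit("no survey records found; run 02_survey.py first")
    df = pd.read_csv(records_path, sep="\t")
    df = df[df["included"]]

    report = {}
    for target in ("delta_omega", "theta_c"):
        fit = tr.fit_harmonic(df["psi"].to_numpy(), df[target].to_numpy())
        roots = tr.zero_crossings(fit)
        report[f"harmonic_{target}"] = {
            **dataclasses.asdict(fit),
            "zero_crossings_deg": [round(r, 2) for r in roots],
            "mean_spacing_deg": round(float(np.mean(np.diff(roots + [roots[0] + 360]))), 3),
        }
    lfit = tr.fit_linear(df["delta_omega"].to_numpy(), df["theta_c"].to_numpy())
    report["linear_thetaC_on_delta_omega"] = dataclasses.asdict(lfit)

    out = ROOT / "results" / "03_trend_fits.json"
    out.write_text(json.dumps(report, indent=2) + "\n")

    h = report["harmonic_delta_omega"]
    print(f"delta_omega(psi): amplitude {h['amplitude']:.3f} deg, "
          f"phase {h['phase']:.2f} deg, offset {h['offset']:.3f} deg "
          f"(n={h['n']}); planar at psi = {h['zero_crossings_deg']}")
    print(f"theta_C = {lfit.slope:.3f} x delta_omega + {lfit.intercept:.3f} "
          f"(r = {lfit.r:.3f}, n = {lfit.n})")
    print(f"full report -> {out}")


if __name__ == "__main__":
    main()
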