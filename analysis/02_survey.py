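#!/usr/bin/env python
"""Stage 2: run the filtered survey over the simulated ensemble.

Reads the chains written by 01_simulate.py, extracts one audited record
per residue (terminal/cis/Gly-Pro/B-factor/occupancy filters), bins the
included records on the 15 x 15 deg Ramachandran grid, and computes the
psi-marginal profile of the circular mean delta_omega and theta_C.

The per-cell count threshold is 20 here rather than the database-scale
100: a 2000-record ensemble cannot populate 15-degree cells a hundred
deep, and the threshold only controls which cells enter the binned
profile.  Full per-residue records go to scratch/; the compact profile
and summary go to results/.
"""

import json
from pathlib import Path

from pepgeom import io as sio
from pepgeom import survey as sv

ROOT = Path(__file__).resolve().parents[1]
MIN_COUNT = 20


def main() -> None:
    sim_dir = ROOT / "scratch" / "sim"
    paths = sorted(sim_dir.glob("SYN*.pdb"))
    if not paths:
        raise SystemExit("no simulated chains found; run 01_simulate.py first")

    records = []
    for p in paths:
        records.extend(sv.extract_records(sio.read_structure(p)))
    included = [r for r in records if r.included]

    out_dir = ROOT / "scratch" / "survey"
    out_dir.mkdir(parents=True, exist_ok=True)
    sv.records_to_frame(records).to_csv(out_dir / "records.tsv", sep="\t",
                                        index=False, float_format="%.6f")

    bins = sv.bin_records(records, grid_step=15.0, min_count=MIN_COUNT)
    profile = sv.psi_profile(bins)
    profile.to_csv(ROOT / "results" / "02_psi_profile.tsv", sep="\t",
                   index=False, float_format="%.4f")

    reason_counts = {}
    for r in records:
        for reason in r.exclusion_reasons:
            reason_counts[reason] = reason_counts.get(reason, 0) + 1
    summary = {
        "n_structures": len(paths),
        "n_records": len(records),
        "n_included": len(included),
        "exclusion_reason_counts": reason_counts,
        "n_bins": len(bins),
        "n_bins_qualifying": sum(not b.below_threshold for b in bins),
        "min_count": MIN_COUNT,
    }
    (ROOT / "results" / "02_survey_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    print(f"records -> {out_dir/'records.tsv'}; psi profile -> results/02_psi_profile.tsv")


if __name__ == "__main__":
    main()
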