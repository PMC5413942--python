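#!/usr/bin/env python
"""Wild-type pulling study: partial unfolding before unbinding.

Simulates constant-velocity retractions of the wild-type receptor scenario
(weak plug subdomain releasing 50 residues, then complex unbinding), runs
the full analysis chain, and reports the per-curve contour-length
increment.  The modal dLc of ~20 nm corresponds to unfolding of ~50
residues at 0.4 nm per stretched amino acid.

Writes: results/wildtype_summary.json, results/wildtype_delta_lc.tsv
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from forcespec.pipeline import summary_dict
from forcespec.polymer import length_to_residues
from forcespec.workflows import wildtype_delta_lc_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-curves", type=int, default=250)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    analysis = wildtype_delta_lc_study(seed=args.seed, n_curves=args.n_curves)
    summary = summary_dict(analysis)
    (args.out / "wildtype_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    pd.DataFrame(
        {
            "curve_id": [r.curve_id for r in analysis.delta_lc_records],
            "Lc1_nm": [r.Lc_values_nm[0] for r in analysis.delta_lc_records],
            "Lc2_nm": [r.Lc_values_nm[1] for r in analysis.delta_lc_records],
            "delta_Lc1_nm": [r.delta_Lc1_nm for r in analysis.delta_lc_records],
        }
    ).to_csv(args.out / "wildtype_delta_lc.tsv", sep="\t", index=False)

    mode = analysis.delta_lc_mode
    n_res = length_to_residues(mode.mode)
    print(
        f"{analysis.n_curves} curves -> {len(analysis.delta_lc_records)} "
        f"double-rupture records"
    )
    print(
        f"modal dLc = {mode.mode:.1f} nm (sigma {mode.sigma:.1f}, "
        f"{mode.n} records) -> ~{n_res} residues unfolded before unbinding"
    )


if __name__ == "__main__":
    main()
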