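#!/usr/bin/env python
"""Crosslink and destabilization scenarios: locating the unfolding region.

Compares the contour-length increments recovered for the four mechanical
scenarios: wild-type (50 residues unfold), XL_barrel (unfolding blocked by
a plug-to-barrel crosslink, single ruptures only), XL_loop (a covalent
15-residue loop shortens the increment by ~6 nm), and 3A (the
destabilized strong subdomain adds a second ~26 nm unfolding, triple
ruptures, with dLc_total = dLc1 + dLc2).

Writes: results/scenario_delta_lc.json
"""

import argparse
import json
from pathlib import Path

import numpy as np

from forcespec.ensemble import fit_gaussian_mode
from forcespec.workflows import scenario_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-curves", type=int, default=150)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    report = {}
    for scenario in ("wild-type", "XL_barrel", "XL_loop", "3A"):
        analysis = scenario_study(scenario, seed=args.seed, n_curves=args.n_curves)
        counts = [c.n_accepted_events for c in analysis.classifications]
        entry = {
            "n_curves": analysis.n_curves,
            "fraction_single": float(np.mean([c == 1 for c in counts])),
            "fraction_double": float(np.mean([c == 2 for c in counts])),
            "fraction_triple": float(np.mean([c >= 3 for c in counts])),
            "modal_Lc_nm": analysis.lc_mode.mode if analysis.lc_mode else None,
            "modal_dLc1_nm": (
                analysis.delta_lc_mode.mode if analysis.delta_lc_mode else None
            ),
        }
        triples = [
            r for r in analysis.delta_lc_records if r.delta_Lc2_nm is not None
        ]
        if len(triples) >= 30:
            entry["modal_dLc2_nm"] = fit_gaussian_mode(
                [r.delta_Lc2_nm for r in triples], 2.0
            ).mode
            entry["modal_dLc_total_nm"] = fit_gaussian_mode(
                [r.delta_Lc_total_nm for r in triples], 2.0
            ).mode
        report[scenario] = entry
        print(f"{scenario}: {json.dumps(entry)}")

    wt = report["wild-type"]["modal_dLc1_nm"]
    loop = report["XL_loop"]["modal_dLc1_nm"]
    print(f"\nXL_loop shortens dLc by {wt - loop:.1f} nm "
          f"(15 residues x 0.4 nm = 6.0 nm expected)")
    (args.out / "scenario_delta_lc.json").write_text(
        json.dumps(report, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
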