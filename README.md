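# forcespec

Analysis pipeline for single-molecule force spectroscopy of
receptor–ligand complexes that partially unfold under load, with a
matching microscale-thermophoresis (MST) binding analysis and a
Monte-Carlo data generator.

## The scientific problem

TonB-dependent transporters (TBDTs) are outer-membrane β-barrels whose
lumen is occluded by a plug domain. Import requires the inner-membrane
protein TonB, which grips the plug's N-terminal Ton box and applies
force. AFM pulling experiments on the TonB–BtuB system show that before
the non-covalent TonB–Ton box complex lets go, part of the plug domain
unfolds: retraction curves show two rupture events, and the contour-length
increment between them measures how much polypeptide unfolded. This
package implements the complete analysis chain for such experiments:

* **frame conversion** — piezo/deflection traces to force versus
  tip–sample separation, with baseline and hard-contact zeroing;
* **event analysis** — rupture detection on the force derivative,
  per-event worm-like-chain (WLC) fits with fixed persistence length
  (0.4 nm), loading rates from the differentiated WLC, and the standard
  acceptance filters (≥ 10 nm separation, contour length beyond the
  19 nm PEG24 linker pair, non-linear WLC-like profile);
* **ensemble statistics** — single-Gaussian modal fits of rupture-force
  and contour-length histograms, per-curve ΔLc, triplicate aggregation
  (mean ± half-range), Lc–F density hotspots as a specificity check, and
  Bell–Evans dynamic force spectra (x_β = k_BT/slope, k₀ from the
  intercept);
* **MST binding** — exact 1:1 law-of-mass-action fraction bound with
  ligand depletion, fitted to 16-point serial-dilution titrations;
* **synthetic data** — a constant-velocity pulling simulator (cantilever
  in series with a WLC, Bell-kinetics rupture, scenario presets for the
  crosslinked and destabilized receptor variants) and an MST titration
  generator, both seeded and with full ground-truth logs.

The core elasticity model is the Marko–Siggia WLC interpolation

    F(x) = (k_B T / p) [ ¼ (1 − x/L_c)⁻² − ¼ + x/L_c ],

with persistence length p fixed at 0.4 nm and the contour length L_c the
only free parameter per rupture edge. A ΔL_c of 20 nm corresponds to
unfolding of 50 residues at 0.4 nm per stretched amino acid.

## Worked example

Simulate a wild-type force map, analyze it, and read off the unfolding
increment:

```sh
forcespec simulate --scenario wild-type --n-curves 60 \
    --specific-fraction 1.0 --seed 7 --out map/
forcespec analyze map/ --out analysis/
```

which prints

```
wrote 60 curves to map
60 curves, 104 accepted events, hit rate 1.000
```

and `analysis/summary.json` contains (abridged)

```json
{
  "hit_rate": 1.0,
  "curves_by_event_count": {"2": 44, "1": 16},
  "modal_Lc_nm":        {"mode": 66.1, "bin_width": 2.0, "n": 104},
  "modal_delta_Lc_nm":  {"mode": 20.0, "bin_width": 2.0, "n": 44}
}
```

The modal ΔL_c of ≈ 20 nm is the generator's 50 released residues
× 0.4 nm recovered through the full detect → fit → filter → histogram
chain. The same chain in Python:

```python
from forcespec.workflows import wildtype_delta_lc_study
analysis = wildtype_delta_lc_study(seed=1, n_curves=250)
print(analysis.delta_lc_mode.mode)   # 20.06 (nm)
```

The numbered drivers under `analysis/` run the complete studies and
write their tables to `results/`:

```sh
python analysis/01_wildtype_unfolding.py       # modal dLc ~ 20 nm -> 50 residues
python analysis/02_crosslink_scenarios.py      # XL_barrel single events; XL_loop dLc 14 nm; 3A triples
python analysis/03_dynamic_force_spectrum.py   # Bell-Evans fits, two routes
python analysis/04_mst_binding.py              # KD = 9.36 +/- 0.31 uM (true 9.4)
python analysis/05_specificity_hotspots.py     # hit rate ~ 0.075, Lc-FU hotspots
```

For example, `02_crosslink_scenarios.py --seed 1` ends with

```
XL_loop shortens dLc by 6.0 nm (15 residues x 0.4 nm = 6.0 nm expected)
```

— the covalent 15-residue loop inside the unfolding region shortens the
increment by exactly its sequestered length, which is how the unfolding
region is localized.

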