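#!/usr/bin/env python
"""Curve-level analyses: lipid fold change, Boltzmann voltage activation,
dose-response constants and the pipeline I/V conductance.

Computes (a) the PS/PC open-probability fold change of the reference channel
from the bundled bilayer summary table, (b) generate-and-refit checks of the
Boltzmann fits at the two published parameter sets, (c) the same for the
saturating-exponential dose-response fits of conductance and open
probability, and (d) the unitary conductance recovered by the full
simulate -> detect -> I/V pipeline for a 92-pS ohmic channel.  Writes
results/curve_fits.json.
"""

import json
from pathlib import Path

from kcvgate.datasets import po_fold_change
from kcvgate.protocols import (boltzmann_refit, dose_response_refit,
                               ohmic_iv_study)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 1

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out = {}

    fold = po_fold_change("Kcv_S", "PS", "PC", "po")
    out["po_fold_change_ps_vs_pc"] = round(fold, 3)
    print(f"P_O fold change PS/PC (summary table): {fold:.2f}")

    for label, vh in (("mutant_pc", -37.0), ("wt_ps", -57.0)):
        f = boltzmann_refit(0.9, 0.05, 0.8, vh)
        out[f"boltzmann_{label}"] = {"v_half_mv": f.v_half, "z": f.z,
                                     "p_max": f.p_max, "p_min": f.p_min}
        print(f"Boltzmann refit {label}: V_1/2 = {f.v_half:.1f} mV, "
              f"z = {f.z:.2f}")

    fg = dose_response_refit(36.8, 15.0, 92.0)
    fp = dose_response_refit(0.48, 25.5, 0.40)
    out["dose_response_conductance"] = {"k_pct": fg.k,
                                        "fold_increase": fg.fold_increase}
    out["dose_response_po"] = {"k_pct": fp.k, "fold_increase": fp.fold_increase}
    print(f"dose constants: conductance k = {fg.k:.1f}% "
          f"(fold {fg.fold_increase:.2f}), P_O k = {fp.k:.1f}% "
          f"(fold {fp.fold_increase:.2f})")

    iv = ohmic_iv_study(conductance_ps=92.0, seed=SEED)
    out["pipeline_conductance_ps"] = iv.conductance_ps
    print(f"pipeline I/V conductance: {iv.conductance_ps:.1f} pS "
          f"(generated with 92 pS)")

    (RESULTS / "curve_fits.json").write_text(json.dumps(out, indent=2))
    print(f"\nwrote {RESULTS / 'curve_fits.json'}")

if __name__ == "__main__":
    main()
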