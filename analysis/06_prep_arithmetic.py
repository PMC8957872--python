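"""Preparative arithmetic for the study's stock solutions and reverse
micelles, recomputed from the printed masses and volumes.
Report: results/prep.json.
"""

import json
from pathlib import Path

from quinonefold import datasets
from quinonefold.sampleprep import (dilute, molar_mass, molarity,
                                    molecules_per_micelle, pD_correction,
                                    percent_yield, w0_ratio)

prep = datasets.PREP
uq2_mw = molar_mass(prep["uq2_formula"])
aot_mw = molar_mass(prep["aot_formula"])
d2o_mw = molar_mass(prep["d2o_formula"])

c_uq2 = molarity(prep["uq2_stock"]["mass_mg"], uq2_mw,
                 prep["uq2_stock"]["volume_ml"])
c_aot = molarity(prep["aot_stock"]["mass_mg"], aot_mw,
                 prep["aot_stock"]["volume_ml"])
mix = prep["rm_mix"]
c_rm = dilute(mix["stock_conc_mM"], mix["stock_ul"], mix["total_ul"])
w0 = w0_ratio(mix["d2o_ul"], mix["d2o_density_g_ml"], d2o_mw,
              c_aot / 1000.0, mix["stock_ul"] / 1000.0)

print(f"UQ-2 stock: {uq2_mw:.2f} g/mol -> {c_uq2:.1f} mM")
print(f"AOT stock: {aot_mw:.2f} g/mol -> {c_aot / 1000:.2f} M")
print(f"RM mixture: {c_rm:.1f} mM lipoquinone; computed w0 {w0:.1f} "
      "(nominal label 12 — the computed ratio is reported separately)")
print(f"pD of the pH-7.0 meter reading: {pD_correction(7.0):.1f}"
      " -- note the water pool is prepared at pH 7.0 on the meter")

report = {
    "uq2_molar_mass_g_mol": round(uq2_mw, 2),
    "aot_molar_mass_g_mol": round(aot_mw, 2),
    "uq2_stock_mM": round(c_uq2, 1),
    "aot_stock_M": round(c_aot / 1000.0, 2),
    "rm_uq2_mM": round(c_rm, 1),
    "rm_w0_computed": round(w0, 1),
    "rm_w0_nominal": 12,
    "pD_at_meter_pH_7": round(pD_correction(7.0), 1),
    "yields_pct": {k: round(percent_yield(**v), 1)
                   for k, v in prep["yields"].items()},
    # the aggregation number is not printed; 29 molecules/RM corresponds to
    # one particular choice, exposed here as an explicit parameter scan
    "molecules_per_micelle_vs_Nagg": {
        str(n): round(molecules_per_micelle(
            c_rm, dilute(c_aot, mix["stock_ul"], mix["total_ul"]), n), 1)
        for n in (50, 100, 130, 150)},
}
Path("results").mkdir(exist_ok=True)
Path("results/prep.json").write_text(json.dumps(report, indent=2) + "\n")
print("wrote results/prep.json")
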