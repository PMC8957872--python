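"""Generate every synthetic input the downstream analyses consume.

Writes, under results/synthetic/:
  * NOESY peak tables simulated from the three reference conformers
    (zero-noise and cv = 0.2 replicas);
  * replicate compression isotherms for a pure film and a 50:50 mixed film
    with a known 21 mN/m collapse and a 12% built-in expansion;
  * chemical-shift tables for probes with known organic / interface /
    aqueous locations.
"""

import sys
from pathlib import Path

from quinonefold.io import (write_isotherm_csv, write_peak_csv,
                            write_shift_csv)
from quinonefold.model import reference_conformer
from quinonefold.synth import (IsothermPhaseModel, NoiseModel,
                               simulate_isotherm, simulate_peak_table,
                               simulate_shift_table)
from quinonefold.topology import build_topology

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)

uq2 = build_topology("UQ", 2)

for kind in ("flat_extended", "folded_extended", "u_shaped"):
    conf = reference_conformer(uq2, kind)
    for cv, tag in [(0.0, "clean"), (0.2, "noisy")]:
        table = simulate_peak_table(conf, ("H_W", "H_MN"),
                                    NoiseModel(cv=cv, seed=SEED),
                                    environment=f"synthetic-{kind}")
        path = OUT / f"noe_{kind}_{tag}.csv"
        write_peak_csv(path, table, conformer=kind, cv=cv, seed=SEED)
        print(f"{path}: {len(table)} peaks (truth {kind}, cv={cv})")

pure = IsothermPhaseModel(replicate_sd=1.0)
mixed = IsothermPhaseModel(knots=tuple(
    (a * 0.5 * 1.12, p) for a, p in pure.knots), replicate_sd=0.6)
write_isotherm_csv(OUT / "isotherm_pure.csv",
                   simulate_isotherm(pure, n_replicates=3, seed=SEED),
                   x=1.0, lipid="DPPE-like")
write_isotherm_csv(OUT / "isotherm_mixed.csv",
                   simulate_isotherm(mixed, n_replicates=3, seed=SEED + 1),
                   x=0.5, lipid="DPPE-like", additive="lipoquinone")
print(f"{OUT}/isotherm_*.csv: collapse truth {pure.collapse_pressure} mN/m, "
      "mixed film built 12% expanded at x=0.5")

for location in ("organic", "interface", "aqueous"):
    path = OUT / f"shifts_{location}.csv"
    write_shift_csv(path, simulate_shift_table(location, seed=SEED),
                    location=location)
    print(f"{path}: truth {location}")
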