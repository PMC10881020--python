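#!/usr/bin/env python
"""Serial-transfer fate of the sensitive species along the LA gradient.

Simulates 72 h / 100-fold-dilution transfer cycles (model 2 reference
system) in mono- and co-culture across initial LA concentrations and
records At's extinction transfer.  The headline numbers: at 0.75 au LA,
mono-culture At washes out within a few transfers while the co-culture
persists into the 6-10 transfer window; at low LA the partner instead
shortens At's tenure (competitive exclusion).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crtox.model_core import CultureState
from crtox.reference import INOCULUM, reference_params, reference_protocol
from crtox.simulate import extinction_vs_concentration, run_serial_transfers

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

species, ab, spec = reference_params("model2")

# per-transfer tables at the two experimental concentrations
rows = []
for c0 in (0.1, 0.75):
    for culture, b_ct in (("mono", 0.0), ("co", INOCULUM)):
        protocol = reference_protocol(C0=c0, n_transfers=15)
        _, table = run_serial_transfers(
            CultureState(B_At=INOCULUM, B_Ct=b_ct, C=c0), species["At"],
            species["Ct"], spec, protocol, ab=ab, keep_trajectories=False)
        table.insert(0, "culture", culture)
        table.insert(0, "concentration_au", c0)
        rows.append(table)
pd.concat(rows, ignore_index=True).to_csv(OUT / "transfer_tables.csv", index=False)

# extinction transfer vs initial LA, mono vs co (long horizon)
grid = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.75, 1.0])
ext = extinction_vs_concentration(grid, species["At"], species["Ct"], spec,
                                  reference_protocol(), horizon=60, ab=ab,
                                  inoculum=INOCULUM)
ext.to_csv(OUT / "extinction_vs_la.csv", index=False)
print(ext.to_string(index=False))
print("\n(-1 = persisted for the whole 60-transfer horizon)")
row = ext[ext.C0_au == 0.75].iloc[0]
print(f"at 0.75 au: mono extinct at transfer {row.at_ext_mono}, "
      f"co-culture at {row.at_ext_co} -> facilitation extends survival")
row = ext[ext.C0_au == 0.1].iloc[0]
print(f"at 0.10 au: mono {row.at_ext_mono}, co {row.at_ext_co} "
      f"-> competitive exclusion by the partner")
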