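#!/usr/bin/env python
"""Export the N-control modifier response curves for plotting.

Tabulates K_P, K_1 and K_M against soil mineral N in both legacy mode
(rise to 1 at 2 g N m⁻², flat beyond) and saturation mode (decline beyond
N_MS to the parameterized floors at N_Mmax), using each site's derived
thresholds.
"""

import argparse
from pathlib import Path

import pandas as pd

from nsatcn import ModelParams, ModifierCurve, curves_frame

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

params = ModelParams()
nms = pd.read_csv(args.results / "nms.csv")
frames = []
for _, row in nms.drop_duplicates("n_ms").iterrows():
    curve = ModifierCurve(n_ms=row.n_ms, n_mmax=row.n_mmax,
                          kp_floor=params.kp_floor, km_floor=params.km_floor,
                          k1_floor=params.k1_floor)
    frames.append(curves_frame(curve).assign(site_id=row.site_id,
                                             n_ms=row.n_ms, n_mmax=row.n_mmax))
out = pd.concat(frames, ignore_index=True)
out.to_csv(args.results / "modifier_curves.csv", index=False)
print(f"wrote {len(out)} curve points for {out.site_id.nunique()} distinct "
      f"thresholds to {args.results}/modifier_curves.csv")
print("floors at N_Mmax: K_P %.3f, K_1 %.2f, K_M %.2f"
      % (params.kp_floor, params.k1_floor, params.km_floor))
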