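#!/usr/bin/env python
"""Run the three-stage protocol under all six factorial scenarios.

Each run spins to carbon equilibrium under repeating climatology with
pre-industrial deposition (0.05 g N m⁻² yr⁻¹), crosses the historical stage
(1901–1969, deposition held at its 1970 level) and the analysis stage
(1970–2009) with one driver frozen per scenario. Writes the full per-site
annual output and a per-scenario summary of analysis-window means.
"""

import argparse
from pathlib import Path

import pandas as pd

from nsatcn import ModelParams
from nsatcn.experiments import run_all_scenarios
from nsatcn.sites import SiteEnsemble, generate_ensemble_forcing

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

ensemble = SiteEnsemble.read_csv(args.results / "sites.csv")
forcing = generate_ensemble_forcing(ensemble, (1851, 2009), args.seed)
runs = run_all_scenarios(ensemble, forcing, ModelParams(), seed=args.seed)

frames = []
for name, run in runs.items():
    frames.append(run.data.assign(scenario=name))
data = pd.concat(frames, ignore_index=True)
data.to_csv(args.results / "runs.csv", index=False)

window = data[(data.year >= 1970) & (data.year <= 2009)]
summary = (window.groupby("scenario")[["npp", "nep", "rh", "soil_mineral_n"]]
           .mean().round(3))
summary.to_csv(args.results / "scenario_summary.csv")
print(summary.to_string())
print(f"\n6 scenarios × {len(ensemble.sites)} sites × "
      f"{data.year.nunique()} years; wrote {args.results}/runs.csv")
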