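"""Generate a synthetic observation bundle and write it as CSV.

Emulates the greenhouse experiment: daily theta/h sensor series and
destructive soil/tissue samplings with replicate-level noise, plus the
truth record the observations were generated from.
"""

from pathlib import Path

import soilplant as sp
from soilplant import io as sp_io

out = Path("synthetic_bundle")
out.mkdir(exist_ok=True)

scenario = sp.default_scenario()
forcing = sp.generate_forcing(seed=7, scenario=scenario)
observations, truth, result = sp.generate_observations(
    scenario, forcing, seed=7, n_elements=50)

sp_io.write_forcing_csv(forcing, out / "forcing.csv")
sp_io.write_observations_csv(observations, out / "observations.csv")

print(f"wrote {out}/forcing.csv and {out}/observations.csv")
print(f"{len(observations)} observation sets:")
for obs in observations:
    print(f"  {obs.label:<12s} k = {obs.k:3d}  sigma = {obs.sigma:.3g}")
print("\nsigma is the per-set replicate-level noise the likelihood uses;")
print("the noiseless truth series are kept alongside for recovery tests.")
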