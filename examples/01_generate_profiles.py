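"""Generate idealized and perturbed denticle-row profiles.

Builds the ~20-denticle idealized row (cusps pointing upstream), its
caudally facing mirror image, and a seeded "empirical-like" row with
per-denticle shape variation, then writes them as CSV polylines.
"""

from pathlib import Path

from denticleflow import (DenticleParams, make_idealized_profile,
                          make_empirical_profile, mirror_profile)
from denticleflow.io_viz import write_profile_csv

out = Path("profiles")
out.mkdir(exist_ok=True)

ideal = make_idealized_profile(DenticleParams())
print(f"idealized rostral: L = {ideal.model_length_L:.4g} m "
      f"({ideal.n_denticles} denticles, area {ideal.area:.3g} m^2)")

caudal = mirror_profile(ideal)
print(f"mirrored:          orientation = {caudal.orientation}, "
      f"L = {caudal.model_length_L:.4g} m (unchanged)")

emp = make_empirical_profile(DenticleParams(perturbation_cv=0.25, seed=1))
print(f"empirical-like:    L = {emp.model_length_L:.4g} m "
      "(targets the shorter published model, 2.35 mm)")

for name, prof in [("idealized_rostral", ideal), ("idealized_caudal", caudal),
                   ("empirical_rostral", emp)]:
    write_profile_csv(prof, out / f"{name}.csv")
print(f"profiles written to {out}/")
# The model length L enters the Reynolds number U*L/nu; the default rows
# reproduce the published L = 2.5 mm (idealized) and 2.35 mm (empirical).
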