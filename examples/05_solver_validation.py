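"""Solver validation against closed-form flows and internal oracles.

Prints the measured errors for plane Poiseuille and Couette flow, global
mass conservation, wall drag vs analytic shear, mirror equivalence, and
Stokes-regime linearity.  These are the contracts the denticle
simulations rest on.
"""

from denticleflow import validation as V

err, sol = V.poiseuille_case()
print(f"Poiseuille profile max deviation: {err:.3%} (bound 2%)")
print(f"mass conservation error: {V.mass_conservation_error(sol):.2e} "
      "(bound 0.1%)")

err, _ = V.couette_case()
print(f"Couette vorticity deviation from -U/h: {err:.2e} (bound 2%)")

err_wall, err_cv, fd, analytic = V.poiseuille_wall_drag_case()
print(f"floor drag vs 6*mu*U/h*l: {err_wall:.3%} (bound 3%); "
      f"control-volume check: {err_cv:.3%} (bound 5%)")

print(f"mirror equivalence error: {V.mirror_equivalence_error():.2e}")
print(f"Stokes linearity error: {V.stokes_linearity_error():.2e} (bound 1%)")
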