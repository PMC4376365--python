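"""Validate the diffusion/uptake/FBA loop against a closed-form oxygen
microprofile.

A column of packed cells consuming oxygen at a constant volumetric rate Q
under an air interface relaxes to the classic zero-order-consumption
parabola C(z) = C0 (1 - z/z_p)^2 with penetration depth
z_p = sqrt(2 D C0 / Q).  The same steady-state machinery that drives the
colony simulations reproduces it to a fraction of a percent of C0.
"""

import numpy as np

from dfba3d.driver import steady_state_cycle
from dfba3d.fixtures import analytic_column_scenario

C0 = 2.6e-4   # dissolved O2 under air, M
Q = 1.48e-3   # volumetric consumption of a packed colony, M/s

lattice, table, analytic = analytic_column_scenario(q_vol=Q, c0=C0, rho=0.65)
steady_state_cycle(lattice, table, dtau=1e-3, t_ss=3.0)

sim = lattice.ext_field("oxygen")[0, 0, :][analytic.cell_ks]
print(f"penetration depth z_p = {analytic.z_p * 1e6:.1f} um")
print(f"{'depth um':>9} {'simulated':>12} {'analytic':>12}")
for depth, value in list(zip(analytic.depths, sim))[::-1][:6]:
    print(f"{depth * 1e6:9.0f} {value:12.3e} {analytic(depth):12.3e}")

sel = analytic.depths <= 0.8 * analytic.z_p
err = np.abs(sim[sel] - analytic(analytic.depths[sel])).max() / C0
print(f"max deviation for z <= 0.8 z_p: {100 * err:.2f}% of C0")
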