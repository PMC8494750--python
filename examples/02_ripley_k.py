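"""Measure spatial correlation with Ripley's K-function.

Compares K(r)/r^2 of a simulated colony at N = 98 against the CSR value pi:
values above pi mean cells cluster beyond what random placement explains.
"""

import numpy as np

from cellcolony import (
    SimulationParams,
    generate_poisson_null,
    k_over_r2,
    pair_correlation,
    ripley_k,
    run_until,
    PointPattern,
)

params = SimulationParams(seed=2)
traj = run_until(params, N_target=98)
colony = PointPattern(traj.final.positions, (0, 0, params.L, params.L))
csr = generate_poisson_null(98, (0, 0, params.L, params.L), seed=2)

k_colony = ripley_k(colony, edge_correction="periodic")
k_csr = ripley_k(csr, edge_correction="periodic")

print(f"{'r [um]':>7} {'colony K/r^2':>13} {'CSR K/r^2':>10}   (pi = {np.pi:.3f})")
for r, a, b in zip(k_colony.r, k_over_r2(k_colony), k_over_r2(k_csr)):
    print(f"{r:7.0f} {a:13.3f} {b:10.3f}")

g = pair_correlation(k_colony)
print(f"\npair correlation g(r) at r = 20 um: {g[1]:.3f} (CSR: 1)")
print("\nThe colony curve starts well above pi at short range - offspring "
      "are deposited 20 um from their parents and adhesion keeps them "
      "nearby - and decays toward pi at long range; the uniform pattern "
      "sits at pi throughout.")
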