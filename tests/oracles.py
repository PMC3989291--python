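"""Independent brute-force oracles shared across test modules."""

import numpy as np

from lagoonconnect.transport import SwimmingParams, TracerField, step_transport


def one_step_matrix(grid, flow, dt, kh, kz):
    """Brute-force one-step transition matrix over (cell-layers + ocean)."""
    vol = grid.cell_volumes()
    states = [(k, j, i) for k in range(grid.n_sigma)
              for j, i in zip(*np.nonzero(grid.wet))]
    n = len(states) + 1  # + ocean
    P = np.zeros((n, n))
    swim = SwimmingParams(enabled=False)
    for col, st in enumerate(states + ["ocean"]):
        conc = np.zeros((1, grid.n_sigma, grid.ny, grid.nx))
        ocean = np.zeros(1)
        if st == "ocean":
            ocean[0] = 1.0
        else:
            k, j, i = st
            conc[0, k, j, i] = 1.0 / vol[k, j, i]
        t = TracerField(grid=grid, conc=conc, source_labels=[0],
                        ocean_mass=ocean, release_total=np.ones(1))
        out = step_transport(t, flow, dt, kh=kh, kz=kz, swim=swim)
        masses = out.conc[0] * vol
        for row, (k, j, i) in enumerate(states):
            P[row, col] = masses[k, j, i]
        P[-1, col] = out.ocean_mass[0]
    return P, states
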