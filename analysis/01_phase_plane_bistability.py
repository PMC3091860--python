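"""Phase-plane and bifurcation structure of the reduced two-variable model.

Finds the coexisting healthy and autoimmune equilibria at the default
(high-avidity) parameters, traces the equilibrium branches in the
reciprocal-avidity parameter k1 and in the beta-cell fraction eta, and
locates the saddle-node bifurcations that bound the bistable regime.

Writes: results/fixed_points.csv, results/branch_k1.csv,
        results/branch_eta.csv, results/basin_map.csv
"""

import pathlib

import numpy as np

from t1dsim.cli_io import write_table
from t1dsim.model_core import ReducedParams
from t1dsim.phase_bifurcation import (basin_map, continue_branch, fixed_points,
                                      saddle_node)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rp = ReducedParams()  # k1 = 0.25, eta = 1: bistable, high avidity
fps = fixed_points(rp)
write_table([{"t": f.t, "q": f.q, "classification": f.classification,
              "residual": f.residual} for f in fps],
            OUT / "fixed_points.csv")
print(f"k1={rp.k1}: {len(fps)} fixed points "
      f"({sum(f.stable for f in fps)} stable):")
for f in fps:
    print(f"  t={f.t:.6g} q={f.q:.6g}  {f.classification}")

k1_star = saddle_node(rp, "k1", (rp.k1, 2.0))
eta_star = saddle_node(rp, "eta", (1.0, 0.05))
print(f"saddle-node: k1* = {k1_star:.4f} (closed-form cross-check "
      f"{rp.saddle_node_k1_closed_form():.4f}); eta* = {eta_star:.4f}")

for par, rng, step, fn in (("k1", (0.05, 2.0), 0.02, "branch_k1.csv"),
                           ("eta", (0.06, 1.0), 0.01, "branch_eta.csv")):
    recs = []
    for br in continue_branch(rp, par, rng, step):
        for i in range(len(br)):
            recs.append({"parameter": par, "value": br.values[i],
                         "t": br.states[i, 0], "q": br.states[i, 1],
                         "stability": br.stability[i],
                         "fold": i in br.fold_indices})
    write_table(recs, OUT / fn)
    print(f"{par} continuation: {len(recs)} branch points -> results/{fn}")

t_grid = np.linspace(1e-5, 0.08, 12)
q_grid = np.linspace(0.0, 0.3, 4)
labels = basin_map(rp, t_grid, q_grid)
recs = [{"t0": t_grid[i], "q0": q_grid[j], "attractor": labels[i, j]}
        for i in range(len(t_grid)) for j in range(len(q_grid))]
write_table(recs, OUT / "basin_map.csv")
n_auto = sum(r["attractor"] == "autoimmune" for r in recs)
print(f"basin map: {n_auto}/{len(recs)} initial conditions reach the "
      f"autoimmune state (separatrix is the vertical line through the saddle)")
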