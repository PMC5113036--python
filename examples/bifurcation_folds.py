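"""Where does the pattern switch as neighbour DLL shifts?  Saddle-node map.

Continues the pre-patterned A:I equilibrium along the overtaking path
(Dext1 rising, Dext2 falling), reporting the saddle-node (fold) points
where the state jumps A:I -> pI:pI -> I:A, and demonstrates hysteresis
between the folds.
"""

import numpy as np

import tipstalk as ts

path = ts.DextPath()  # Dext1 = s*12, Dext2 = (1-s)*12 c.u. at V = 1 c.u.
equilibria = ts.find_equilibria(path.inputs_at(0.0), n_seeds=2)
start = max((e for e in equilibria if e.stable), key=lambda e: e.state[2])
branch = ts.continue_branch(start, path)

print(f"folds at s = {[round(f[0], 3) for f in branch.folds]} "
      f"(Dext1 = {[round(f[0] * path.Dmax, 2) for f in branch.folds]} c.u.)")
for pvals, eqs in branch.segments():
    d1 = [e.dll[0] for e in eqs]
    d2 = [e.dll[1] for e in eqs]
    print(
        f"  segment s in [{pvals[0]:.3f}, {pvals[-1]:.3f}]: "
        f"DLL_cell1 in [{min(d1):.2f}, {max(d1):.2f}], "
        f"DLL_cell2 in [{min(d2):.2f}, {max(d2):.2f}]"
    )

s1, s2 = sorted(f[0] for f in branch.folds)
mid = path.inputs_at(0.5 * (s1 + s2))
fwd = ts.integrate(branch.equilibria[0].state, mid).final_state
bwd = ts.integrate(ts.swap_cells(branch.equilibria[0].state), mid).final_state
print(
    f"\nhysteresis at the path midpoint: coming from A:I the pair sits at "
    f"DLL = ({fwd[2]:.2f}, {fwd[10]:.2f}); coming from I:A at "
    f"({bwd[2]:.2f}, {bwd[10]:.2f})"
)
print(
    "Each cell must cross two saddle-nodes (A <-> pI <-> I) to complete a "
    "full role swap, so a brief excursion past the first fold is "
    "reversible — the cell falls back instead of committing."
)
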