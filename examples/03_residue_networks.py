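"""Dynamic residue networks: reachability L, its drift, and betweenness.

Per frame, residues within 6.7 A (representative atoms) are connected; L_i is
the mean shortest-path length from residue i to every reachable residue, and
betweenness counts how often a residue carries shortest-path traffic.
Averaging over the frame sequence keeps only persistent features.
"""

import numpy as np

from allodyn import (
    SyntheticSpec,
    average_over_drn,
    build_drn,
    generate_trajectory,
    select_representatives,
)

spec = SyntheticSpec(n_res_per_domain=10, n_frames=100, seed=0)
ens, truth = generate_trajectory(spec)
rfs = select_representatives(ens, "CA", truth.domain_map)

drn = build_drn(rfs, cutoff=6.7)
profile, bc_mean = average_over_drn(drn)  # default drift sign: later-minus-first

print(f"frames in the DRN: {len(drn.rins)} (every {drn.interval_ps:g} ps)")
print(f"L_mean: min {np.nanmin(profile.L_mean):.1f} (well-connected core), "
      f"max {np.nanmax(profile.L_mean):.1f} (chain termini)")
print(f"reachability drift |dL|: max {np.abs(profile.deltaL_time).max():.2f} "
      f"(near zero: the toy network is statistically stationary)")
print(f"unreachable pair-slots per residue (total): "
      f"{profile.unreachable_count.max():.0f} max")
top = np.argsort(bc_mean)[-3:][::-1]
print(f"highest mean betweenness at residues {[int(i) + 1 for i in top]} "
      f"(the CTD vertex bridging the two protomers)")
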