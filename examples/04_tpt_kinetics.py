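"""Transition-path theory on a small conformational network.

Builds a 6-state reversible chain with two parallel open->closed routes,
computes committors and the net reactive flux, decomposes the flux into
bottleneck-ranked pathways, and reports transition times as
lag / (minimum net flux) — the estimator used for receptor state kinetics.
"""

import numpy as np

from msmkin import tpt

# two parallel routes 0-1-2-5 (wide) and 0-3-4-5 (narrow)
t = np.zeros((6, 6))
for i, j, p in [(0, 1, 0.05), (1, 2, 0.04), (2, 5, 0.05),
                (0, 3, 0.012), (3, 4, 0.010), (4, 5, 0.012)]:
    t[i, j] = t[j, i] = p
np.fill_diagonal(t, 1.0 - t.sum(axis=1))

flux = tpt.reactive_flux(t, [0], [5])
print("forward committor q+:", np.round(flux.q_plus, 3))
print(f"total reactive flux: {flux.total_flux:.5f} per lag")

for rank, path in enumerate(tpt.top_pathways(flux), start=1):
    print(f"pathway {rank}: {' -> '.join(map(str, path.states))}  "
          f"bottleneck flux {path.bottleneck_flux:.5f}")

lag_ns = 1.2   # the kind of lag at which such models are validated
dom = tpt.transition_time(flux, lag_ns, mode="dominant")
tot = tpt.transition_time(flux, lag_ns, mode="total")
print(f"\ntransition time 0 -> 5 at lag {lag_ns} ns:")
print(f"  dominant-path bottleneck: {dom.time_ns:8.1f} ns")
print(f"  total reactive flux:      {tot.time_ns:8.1f} ns")
print("-> the dominant-path reading is slower because a single route's")
print("   bottleneck carries less probability than the whole network.")
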