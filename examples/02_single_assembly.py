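"""One assembly simulation from an empty network.

Twenty colonization events, each introducing three candidate plants and
three candidate pollinators (half specialist on average), with adaptive
foraging switched on.  Prints the establishment ledger and the final
binary network structure.
"""

from pollinet import AssemblyConfig, run_assembly, structure

cfg = AssemblyConfig(
    p_spec_plant=0.5, p_spec_poll=0.5, n_events=20, seed=42, adaptive=True
)
result = run_assembly(cfg)

counts = result.counts()
for guild in ("plant", "pollinator"):
    c = counts[guild]
    print(
        f"{guild:>10}s: {c['introduced']} attempted, {c['established']} established, "
        f"{c['extinct']} extinct, {c['final_richness']} extant at t = {cfg.total_time:.0f}"
    )

rep = structure(result.snapshots[-1].post)
print(
    f"\nfinal network: {rep.n_plants} plants x {rep.n_polls} pollinators, "
    f"connectance {rep.connectance:.3f}, NODF {rep.nodf:.1f}, "
    f"pollinator:plant ratio {rep.poll_plant_ratio:.2f}"
)
print(
    "\nMost attempted colonizers fail; the persistent core grows by a few\n"
    "species per event while connectance declines as specialists accumulate."
)
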