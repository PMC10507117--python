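"""Adaptive foraging versus fixed foraging on a small probability grid.

Runs a 2x2 grid of specialism probabilities for both model variants and
compares final network structure cell-by-cell with paired one-sided
t-tests (plus unpaired Welch tests).  With more cells and seeds the
contrasts sharpen; this is a quick illustration.
"""

from dataclasses import replace

from pollinet import AssemblyConfig, compare_models, run_grid, structure

base = AssemblyConfig(n_events=15, seed=3)
values = {}
for adaptive in (True, False):
    grid = run_grid(replace(base, adaptive=adaptive), [0.25, 0.75])
    values[adaptive] = {
        key: structure(res.snapshots[-1].post)
        for key, res in grid.items()
        if res.final.n_plants and res.final.n_polls
    }

shared = set(values[True]) & set(values[False])
for metric, alt in (("richness", "greater"), ("connectance", "less")):
    rep = compare_models(
        {k: getattr(values[True][k], metric) for k in shared},
        {k: getattr(values[False][k], metric) for k in shared},
        metric=metric,
        alternative=alt,
    )
    direction = "higher" if alt == "greater" else "lower"
    print(
        f"{metric:>12}: adaptive {rep.mean_a:7.3f} vs fixed {rep.mean_b:7.3f} "
        f"(testing adaptive {direction}; paired p = {rep.paired_p:.3f}, "
        f"Welch p = {rep.welch_p:.3f})"
    )
print(
    "\nAdaptive foraging yields sparser networks by sustaining specialists;\n"
    "small grids give noisy p-values, the full design uses 121 cells."
)
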