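"""Sensitivity of the trade-off to the evaporation half-life.

Sweeps the trail half-life over 6-72 h in a small community and applies
the Pareto rule (minimise TTHR, then Gini) to pick an operating point.
"""

from trailmap import SimulationConfig, pareto_select, sensitivity_sweep

config = SimulationConfig(
    n_agents=100,
    duration_hours=240.0,
    request_rate_per_seeker_per_day=3.0,
    interaction_duration_mean_min=7.0,
)
sweep = sensitivity_sweep(
    config, half_lives=[6, 12, 24, 48, 72], seeds=[1, 2, 3, 4, 5]
)

print(sweep.table.to_string(index=False))
print("\nPareto-selected half-life:", pareto_select(sweep), "h")
# Short half-lives forget trails before they can guide routing (higher
# TTHR but flatter load); long half-lives build strong, stable trails
# (lower TTHR, more concentration).  The Pareto rule returns the
# non-dominated half-life with the lowest TTHR, ties broken by equity.
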