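"""Simulate the study system: an autocorrelated environmental landscape,
a cohort of virtual tree species with known niche geometry, and the 3 GCM x
3 SRES future-climate scenario set for three periods.

Writes the landscape layers (.asc), one presence CSV per species, and a
table of each species' realized prevalence and niche parameters under
results/simulation/.
"""

import sys
from pathlib import Path

import pandas as pd

from consensus_sdm.grids import save_env_grid, save_species
from consensus_sdm.pipeline import species_cohort, stage_seed
from consensus_sdm.synthetic import (default_landscape_specs,
                                     default_scenario_deltas, gen_landscape,
                                     gen_scenarios, gen_virtual_species)

SEED = 20150318
ROWS = COLS = 50
N_SPECIES = 12
PREVALENCE = 0.15

OUT = Path(__file__).resolve().parents[1] / "results" / "simulation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    env = gen_landscape(ROWS, COLS, default_landscape_specs(),
                        seed=stage_seed(SEED, "landscape"))
    save_env_grid(env, OUT / "landscape")

    scenarios = gen_scenarios(env, default_scenario_deltas())
    print(f"landscape: {ROWS}x{COLS} cells, {len(env.layer_names)} layers "
          f"({', '.join(env.layer_names)})")
    print(f"scenarios: {len(scenarios.scenario_grids)} future grids "
          f"({len(scenarios.periods)} periods x 9 GCM/SRES combinations)")

    specs = species_cohort(env, N_SPECIES, PREVALENCE, "threshold",
                           seed=stage_seed(SEED, "cohort"))
    rows = []
    for i, spec in enumerate(specs):
        species, _ = gen_virtual_species(env, spec)
        save_species(species, OUT / f"species_{i:02d}.csv")
        rows.append({
            "species": i,
            "realized_prevalence": species.prevalence,
            "n_presences": species.n_presences,
            **{f"optimum_{k}": v for k, v in spec.optimum.items()},
            **{f"breadth_{k}": v for k, v in spec.breadth.items()},
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "species_cohort.csv", index=False)
    print(f"\ncohort of {N_SPECIES} virtual species "
          f"(target prevalence {PREVALENCE}):")
    print(table[["species", "realized_prevalence", "n_presences"]]
          .to_string(index=False))
    print(f"\nwrote layers, species grids and cohort table to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
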