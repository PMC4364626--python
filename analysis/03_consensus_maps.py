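"""Combine the retained projection ensemble into the three consensual maps.

Average, frequency (fraction of projections predicting presence at the 0.5
threshold), and the two-step median (PCA): per (bout, scenario) block the
projection most aligned with the oriented first principal component is
selected (81 selections for the future period, 9 at baseline), then the
cellwise median is taken.

Writes each consensus probability map as .asc plus a provenance JSON under
results/consensus/.
"""

import importlib
import json
import sys
from pathlib import Path

from consensus_sdm.grids import write_ascii_grid

fit_script = importlib.import_module("02_fit_and_evaluate")

OUT = Path(__file__).resolve().parents[1] / "results" / "consensus"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    env, run = fit_script.focal_run()
    provenance = {}
    for period, maps in run.consensus.items():
        for method, cmap in maps.items():
            write_ascii_grid(OUT / f"{method}_{period}.asc", cmap.probs,
                             env.mask, env.cell_size_km, env.origin_latlon)
            if method == "median_pca":
                provenance[period] = cmap.provenance
                print(f"{period}: median-PCA combined "
                      f"{cmap.provenance['n_selected']} selected projections")
            else:
                n = len(cmap.provenance.get("keys", []))
                print(f"{period}: {method} combined {n} projections")
    with open(OUT / "median_pca_provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    print(f"\nwrote consensus maps and provenance to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
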