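"""Generate the synthetic input bundle for the analysis chain.

Writes the dated family tree, region table, species checklist and
occurrence records (plus the generator's ground truth) under
results/bundle/.  Everything downstream (02-05) consumes this bundle.
"""

from pathlib import Path

from natdiv import io as nio
from natdiv.simulate import SimulationConfig, simulate_bundle

SEED = 1
OUT = Path("results/bundle")


def main():
    cfg = SimulationConfig()
    tree, regions, data, truth = simulate_bundle(cfg, SEED)
    paths = nio.write_bundle(OUT, tree, regions, data, truth)
    print(f"simulated {tree.n_tips} families, {len(data.species)} species, "
          f"{len(data.occurrences)} occurrence records")
    print(f"true coefficients: {truth['beta']}, "
          f"sigma2_p={truth['sigma2_p']}, sigma2_e={truth['sigma2_e']}")
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
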