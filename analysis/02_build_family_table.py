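"""Aggregate species tables into the per-family analysis dataset.

Applies the inclusion filter (>= 50 accepted species, present in the
tree, has a stem age, has range data), computes diversification rates at
relative extinction 0.9 (and 0.0 for comparison), range/horticulture
metrics and the naturalization-success index, and reports the exclusion
bookkeeping.  Writes results/family_dataset.csv.
"""

from pathlib import Path

from natdiv import io as nio
from natdiv.metrics import build_family_dataset

BUNDLE = Path("results/bundle")
OUT = Path("results")


def main():
    tree, regions, data, _ = nio.read_bundle(BUNDLE)
    dataset, exclusions = build_family_dataset(data, regions, tree,
                                               epsilon=0.9, min_richness=50)
    dataset.to_csv(OUT / "family_dataset.csv", index=False)
    exclusions.to_csv(OUT / "exclusions.csv", index=False)
    print(f"retained {len(dataset)} families")
    print(exclusions["reason"].value_counts().to_string())
    rich = dataset[dataset["n_species"] >= 1000]
    if len(rich):
        rel = ((rich["div_rate_eps0"] - rich["div_rate"])
               / rich["div_rate_eps0"])
        print(f"species-rich families (n >= 1000): relative rate difference "
              f"eps=0 vs eps=0.9 at most {rel.max():.3f} "
              f"(the two extinction bounds track each other)")


if __name__ == "__main__":
    main()
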