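"""Reading and writing the input bundle and result tables.

A *bundle* directory holds everything one analysis run consumes:
``tree.nwk`` (Newick, branch lengths in Myr), ``regions.csv``,
``species.csv``, ``occurrences.csv`` and — for synthetic bundles — a
``truth.json`` with the generator's ground truth.  All tables are UTF-8
CSV with a header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import RegionTable, SpeciesData
from .phylo import Phylogeny, read_newick

__all__ = ["write_bundle", "read_bundle", "read_inputs", "file_sha256"]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_bundle(outdir, tree: Phylogeny, regions: RegionTable,
                 data: SpeciesData, truth: dict | None = None) -> dict:
    """Write the full input bundle; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(tree.to_newick())
    paths["regions"] = outdir / "regions.csv"
    regions.frame.reset_index(drop=True).to_csv(paths["regions"], index=False)
    paths["species"] = outdir / "species.csv"
    data.species.to_csv(paths["species"], index=False)
    paths["occurrences"] = outdir / "occurrences.csv"
    data.occurrences.to_csv(paths["occurrences"], index=False)

    if truth is not None:
        serializable = {}
        for key, val in truth.items():
            if isinstance(val, pd.DataFrame):
                serializable[key] = val.to_dict(orient="list")
            elif isinstance(val, pd.Series):
                serializable[key] = {str(k): float(v) for k, v in val.items()}
            elif isinstance(val, dict):
                serializable[key] = {str(k): (float(v) if np.isscalar(v) else v)
                                     for k, v in val.items()}
            elif isinstance(val, (list, tuple)):
                serializable[key] = list(val)
            else:
                serializable[key] = val
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(serializable, indent=1))
        fd = truth.get("family_dataset")
        if fd is not None:
            paths["family_truth"] = outdir / "family_dataset_truth.csv"
            fd.to_csv(paths["family_truth"], index=False)
    return {k: str(v) for k, v in paths.items()}


def read_bundle(indir):
    """Read a bundle directory -> (tree, regions, data, truth-or-None)."""
    indir = Path(indir)
    tree = read_newick((indir / "tree.nwk").read_text())
    regions = RegionTable(pd.read_csv(indir / "regions.csv"))
    species = pd.read_csv(indir / "species.csv")
    occurrences = pd.read_csv(indir / "occurrences.csv")
    data = SpeciesData(species=species, occurrences=occurrences)
    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    return tree, regions, data, truth


def read_inputs(tree_path, regions_path, species_path, occurrences_path):
    """Read explicitly listed input files -> (tree, regions, data)."""
    tree = read_newick(Path(tree_path).read_text())
    regions = RegionTable(pd.read_csv(regions_path))
    data = SpeciesData(species=pd.read_csv(species_path),
                       occurrences=pd.read_csv(occurrences_path))
    return tree, regions, data
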