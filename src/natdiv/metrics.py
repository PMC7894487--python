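"""Family-level variables from species-level checklists.

Everything the regression consumes is aggregated here from three tables:

* a **region table** (non-overlapping regions with total area and its
  tropical/temperate split, km²),
* a **species table** (species → family/order membership, accepted-name
  flag, horticultural-use flag, coverage flag), and
* a long-format **occurrence table** of (species, region, status) records
  with status ``native`` or ``naturalized``.

The derived family variables are: the net diversification rate from the
stem-age method-of-moments estimator, mean native range size (total and by
climatic zone), the proportion of horticulturally used species, and the
naturalization-success index — the proportion of naturalized species times
the family's total count of naturalized (species, region) records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "RegionTable",
    "SpeciesData",
    "stem_diversification_rate",
    "species_range_size",
    "species_zonal_range",
    "mean_family_range",
    "coverage_subset_ranges",
    "naturalization_success",
    "horticultural_use",
    "build_family_dataset",
]

SPECIES_COLUMNS = ["species_id", "family", "order", "accepted",
                   "horticultural", "coverage_flag"]
OCCURRENCE_COLUMNS = ["species_id", "region_id", "status"]
REGION_COLUMNS = ["region_id", "area_km2", "tropical_km2", "temperate_km2"]


@dataclass
class RegionTable:
    """Non-overlapping regions with precomputed areas (km²).

    ``tropical_km2 + temperate_km2`` must equal ``area_km2`` for each
    region (the tropical/temperate split is an input, not computed here).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = [c for c in REGION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"region table missing columns {missing}")
        if df["region_id"].duplicated().any():
            raise ValueError("duplicate region_id in region table")
        if (df["area_km2"] <= 0).any():
            raise ValueError("region areas must be positive")
        if (df["tropical_km2"] < 0).any() or (df["temperate_km2"] < 0).any():
            raise ValueError("zonal areas must be non-negative")
        resid = df["tropical_km2"] + df["temperate_km2"] - df["area_km2"]
        if (resid.abs() > 1e-6 * df["area_km2"]).any():
            raise ValueError("tropical + temperate areas do not sum to total")
        self.frame = df.set_index("region_id", drop=False)

    @property
    def region_ids(self) -> set:
        return set(self.frame["region_id"])

    def areas(self, region_ids) -> pd.DataFrame:
        unknown = sorted(set(region_ids) - self.region_ids)
        if unknown:
            raise KeyError(f"unknown region ids: {unknown}")
        return self.frame.loc[list(region_ids)]


@dataclass
class SpeciesData:
    """Species checklist plus long-format occurrence records."""

    species: pd.DataFrame
    occurrences: pd.DataFrame
    _native: pd.DataFrame = field(init=False, repr=False)
    _naturalized: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self):
        sp, occ = self.species, self.occurrences
        missing = [c for c in SPECIES_COLUMNS if c not in sp.columns]
        if missing:
            raise ValueError(f"species table missing columns {missing}")
        missing = [c for c in OCCURRENCE_COLUMNS if c not in occ.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        if sp["species_id"].duplicated().any():
            raise ValueError("duplicate species_id")
        bad = set(occ["status"]) - {"native", "naturalized"}
        if bad:
            raise ValueError(f"unknown occurrence status values: {sorted(bad)}")
        orphan = set(occ["species_id"]) - set(sp["species_id"])
        if orphan:
            raise ValueError(f"occurrences for unknown species: {sorted(orphan)[:5]}")
        self._native = occ[occ["status"] == "native"]
        self._naturalized = occ[occ["status"] == "naturalized"]

    def native_regions(self, species_id) -> set:
        return set(self._native.loc[self._native["species_id"] == species_id,
                                    "region_id"])

    def naturalized_regions(self, species_id) -> set:
        return set(self._naturalized.loc[
            self._naturalized["species_id"] == species_id, "region_id"])


# -- diversification ---------------------------------------------------


def stem_diversification_rate(n, t, epsilon):
    """Net diversification rate r = ln(n(1−ε)+ε)/t for a stem clade.

    Method-of-moments estimator: ``n`` extant species richness, ``t`` stem
    age (Myr), ``epsilon`` the relative extinction μ/λ in [0, 1).  At
    ε = 0 this collapses to ln(n)/t; at n = 1 it is exactly 0.
    """
    n = np.asarray(n, dtype=float)
    t = np.asarray(t, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    if not (np.all(np.isfinite(n)) and np.all(np.isfinite(t))
            and np.all(np.isfinite(epsilon))):
        raise ValueError("arguments must be finite")
    if np.any(n < 1) or np.any(np.abs(n - np.round(n)) > 1e-9):
        raise ValueError("richness n must be an integer >= 1")
    if np.any(t <= 0):
        raise ValueError("stem age t must be positive")
    if np.any(epsilon < 0) or np.any(epsilon >= 1):
        raise ValueError("relative extinction must lie in [0, 1)")
    r = np.log(n * (1.0 - epsilon) + epsilon) / t
    return float(r) if r.ndim == 0 else r


# -- range sizes -------------------------------------------------------


def species_range_size(species_id, data: SpeciesData, regions: RegionTable) -> float:
    """Cumulative area (km²) of the species' native regions; 0 if none."""
    native = data.native_regions(species_id)
    if not native:
        return 0.0
    return float(regions.areas(native)["area_km2"].sum())


def species_zonal_range(species_id, data: SpeciesData,
                        regions: RegionTable) -> tuple[float, float]:
    """(tropical, temperate) km² sums over the species' native regions."""
    native = data.native_regions(species_id)
    if not native:
        return (0.0, 0.0)
    sub = regions.areas(native)
    return (float(sub["tropical_km2"].sum()), float(sub["temperate_km2"].sum()))


def _per_species_ranges(family: str, data: SpeciesData, regions: RegionTable,
                        accepted_only: bool = True) -> pd.DataFrame:
    """Per-species total/tropical/temperate range for one family.

    Species with no native-region records are excluded: a missing
    distribution is not a zero range.
    """
    sp = data.species
    mask = sp["family"] == family
    if accepted_only:
        mask &= sp["accepted"].astype(bool)
    ids = sp.loc[mask, "species_id"]
    native = data._native[data._native["species_id"].isin(ids)]
    if native.empty:
        return pd.DataFrame(columns=["species_id", "range_km2",
                                     "tropical_km2", "temperate_km2"])
    joined = native.merge(regions.frame.reset_index(drop=True),
                          on="region_id", how="left")
    if joined["area_km2"].isna().any():
        unknown = sorted(joined.loc[joined["area_km2"].isna(), "region_id"].unique())
        raise KeyError(f"unknown region ids: {unknown}")
    agg = joined.groupby("species_id", sort=True).agg(
        range_km2=("area_km2", "sum"),
        tropical_km2=("tropical_km2", "sum"),
        temperate_km2=("temperate_km2", "sum"),
    ).reset_index()
    return agg


def mean_family_range(family: str, data: SpeciesData, regions: RegionTable,
                      zone: str = "all") -> float:
    """Mean species range size (km²) over the family's species.

    ``zone`` selects total (``all``), ``tropical`` or ``temperate`` area.
    Returns NaN when no species has distribution data (the family is then
    dropped at the merge step).
    """
    col = {"all": "range_km2", "tropical": "tropical_km2",
           "temperate": "temperate_km2"}.get(zone)
    if col is None:
        raise ValueError(f"unknown zone {zone!r}")
    agg = _per_species_ranges(family, data, regions)
    if agg.empty:
        return float("nan")
    return float(agg[col].mean())


def coverage_subset_ranges(family: str, data: SpeciesData, regions: RegionTable,
                           subset: str = "all") -> list[float]:
    """Species range sizes restricted to a coverage subset.

    Subsets: ``all`` species with range data, ``global_coverage`` (complete
    global distribution information), ``partial_coverage`` (incomplete).
    Used to audit whether incomplete range records bias the family means.
    """
    if subset not in {"all", "global_coverage", "partial_coverage"}:
        raise ValueError(f"unknown coverage subset {subset!r}")
    agg = _per_species_ranges(family, data, regions)
    if agg.empty:
        return []
    flags = data.species.set_index("species_id")["coverage_flag"]
    agg = agg.assign(coverage=agg["species_id"].map(flags))
    if subset == "global_coverage":
        agg = agg[agg["coverage"] == "complete"]
    elif subset == "partial_coverage":
        agg = agg[agg["coverage"] != "complete"]
    return agg["range_km2"].tolist()


# -- naturalization / horticulture ------------------------------------


def naturalization_success(n_nat: int, n_total: int, region_records: int) -> float:
    """(naturalized / total species) × naturalized (species, region) records.

    ``region_records`` is the sum over the family's naturalized species of
    the number of regions each is naturalized in; shared regions are not
    deduplicated across species.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_nat <= n_total):
        raise ValueError(f"n_nat={n_nat} outside [0, n_total={n_total}]")
    if n_nat > 0 and region_records < n_nat:
        raise ValueError("each naturalized species occupies >= 1 region")
    if n_nat == 0:
        return 0.0
    return (n_nat / n_total) * region_records


def horticultural_use(n_hort: int, n_total: int) -> float:
    """Proportion of the family's species present in the horticulture set."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_hort <= n_total):
        raise ValueError(f"n_hort={n_hort} outside [0, n_total={n_total}]")
    return n_hort / n_total


# -- assembly ----------------------------------------------------------


def build_family_dataset(data: SpeciesData, regions: RegionTable, tree,
                         stem_ages: dict[str, float] | None = None,
                         epsilon: float = 0.9,
                         min_richness: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-family analysis table.

    A family is retained when it has >= ``min_richness`` accepted species,
    is a tip of ``tree``, has a stem age, and has at least one species with
    native-range data.  Returns ``(dataset, exclusions)``: the analysis
    table (one row per retained family) and a log of excluded families
    with the first failing criterion.

    ``stem_ages`` defaults to ages read off the tree; an explicit mapping
    (e.g. from a published age table) overrides it.
    """
    if stem_ages is None:
        stem_ages = tree.stem_ages() if tree is not None else {}
    tree_tips = set(tree.tips) if tree is not None else set()

    sp = data.species
    accepted = sp[sp["accepted"].astype(bool)]
    fam_of = accepted.set_index("species_id")["family"]
    nat = data._naturalized[data._naturalized["species_id"].isin(fam_of.index)]
    nat_counts = nat.groupby("species_id")["region_id"].nunique().to_frame("k")
    nat_counts["family"] = nat_counts.index.map(fam_of)
    fam_nat = nat_counts.groupby("family")["k"].agg(
        n_naturalized="count", region_records="sum")

    # one global per-species range aggregation (accepted species only)
    native = data._native[data._native["species_id"].isin(
        accepted["species_id"])]
    joined = native.merge(regions.frame.reset_index(drop=True),
                          on="region_id", how="left")
    if joined["area_km2"].isna().any():
        unknown = sorted(joined.loc[joined["area_km2"].isna(),
                                    "region_id"].unique())
        raise KeyError(f"unknown region ids: {unknown}")
    per_species = joined.groupby("species_id", sort=True)[
        ["area_km2", "tropical_km2", "temperate_km2"]].sum()
    per_species["family"] = per_species.index.map(
        accepted.set_index("species_id")["family"])
    fam_ranges = per_species.groupby("family")[
        ["area_km2", "tropical_km2", "temperate_km2"]].mean()

    rows, dropped = [], []
    for family, grp in accepted.groupby("family", sort=True):
        n_species = len(grp)
        if n_species < min_richness:
            dropped.append((family, "min_richness"))
            continue
        if family not in tree_tips:
            dropped.append((family, "no_phylogeny"))
            continue
        t_stem = stem_ages.get(family)
        if t_stem is None or not math.isfinite(t_stem) or t_stem <= 0:
            dropped.append((family, "no_stem_age"))
            continue
        if family not in fam_ranges.index:
            dropped.append((family, "no_range_data"))
            continue
        ranges = fam_ranges.loc[family]

        if family in fam_nat.index:
            n_naturalized = int(fam_nat.loc[family, "n_naturalized"])
            region_records = int(fam_nat.loc[family, "region_records"])
        else:
            n_naturalized = region_records = 0
        n_hort = int(grp["horticultural"].astype(bool).sum())
        orders = grp["order"].dropna().unique()
        order = orders[0] if len(orders) else ""

        rows.append({
            "family": family,
            "order": order,
            "n_species": n_species,
            "n_naturalized": n_naturalized,
            "naturalized_region_records": region_records,
            "stem_age": float(t_stem),
            "div_rate": stem_diversification_rate(n_species, t_stem, epsilon),
            "div_rate_eps0": stem_diversification_rate(n_species, t_stem, 0.0),
            "mean_range_km2": float(ranges["area_km2"]),
            "mean_tropical_km2": float(ranges["tropical_km2"]),
            "mean_temperate_km2": float(ranges["temperate_km2"]),
            "hort_prop": horticultural_use(n_hort, n_species),
            "nat_success": naturalization_success(
                n_naturalized, n_species, region_records),
        })

    exclusions = pd.DataFrame(dropped, columns=["family", "reason"])
    for family, reason in dropped:
        log.info("excluded family %s: %s", family, reason)
    if not rows:
        raise ValueError("no family passes the inclusion criteria")
    dataset = pd.DataFrame(rows)
    return dataset, exclusions
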