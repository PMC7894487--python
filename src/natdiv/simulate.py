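"""Synthetic inputs with known ground truth for the whole pipeline.

Generates every input the analysis consumes — a dated family-level tree,
a region table, and species checklists with native/naturalized occurrence
records and horticulture flags — from explicit parameters and a master
seed.  The naturalization response is built by *inverse construction*:
a latent family score

    s_f = intercept + x_f' beta + u_f + e_f

is drawn on the sqrt-index scale (standardized predictors ``x_f``,
Brownian tip effects ``u`` with covariance sigma2_p * A, Gaussian noise
``e``), and naturalized counts are then chosen so that the pipeline's
recomputed naturalization-success index, after the sqrt transform,
reproduces ``s_f`` up to integer rounding of the counts.  This makes the
Gaussian phylogenetic mixed model exactly well specified on the generated
data, so parameter recovery is directly testable.

The master seed spawns per-component seeds by hashing the component name
(CRC-32) together with the seed, so the tree, regions and tables are each
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .metrics import RegionTable, SpeciesData
from .phylo import Phylogeny, phylo_covariance, read_newick

__all__ = [
    "SimulationConfig", "simulate_tree", "simulate_lineage_count",
    "simulate_regions", "simulate_species_tables", "simulate_bundle",
    "brownian_effects", "component_rng",
]


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component generator derived from the master seed."""
    sub = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(seed), sub)))


# -- birth-death tree --------------------------------------------------


class _Lineage:
    __slots__ = ("t_start", "t_end", "children", "extant")

    def __init__(self, t_start):
        self.t_start = t_start
        self.t_end = None
        self.children = []
        self.extant = False


def _grow(rng, birth, death, n_tips):
    """Forward Gillespie from one stem lineage until n_tips are extant.

    Stops at the first moment the extant count reaches ``n_tips`` and
    extends all extant lineages by an Exp(n (birth+death)) time — i.e. up
    to (just before) the next event — so terminal branches have positive
    length.  Returns the root lineage, or None on total extinction.
    """
    root = _Lineage(0.0)
    active = [root]
    t = 0.0
    total = birth + death
    while True:
        k = len(active)
        if k == 0:
            return None
        if k >= n_tips:
            tau = rng.exponential(1.0 / (k * total))
            t_end = t + tau
            for lin in active:
                lin.t_end = t_end
                lin.extant = True
            return root
        t += rng.exponential(1.0 / (k * total))
        i = rng.integers(k)
        lin = active.pop(i)
        lin.t_end = t
        if rng.random() < birth / total:
            lin.children = [_Lineage(t), _Lineage(t)]
            active.extend(lin.children)
        # else: death; lineage simply ends


def _prune_extinct(node):
    """Drop extinct subtrees; collapse single-child chains (lengths sum)."""
    if not node.children:
        return node if node.extant else None
    kids = [_prune_extinct(c) for c in node.children]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        kids[0].t_start = node.t_start
        return kids[0]
    node.children = kids
    return node


def _to_newick(node, label_iter) -> str:
    length = node.t_end - node.t_start
    if not node.children:
        return f"{next(label_iter)}:{length:.10f}"
    inner = ",".join(_to_newick(c, label_iter) for c in node.children)
    return f"({inner}):{length:.10f}"


def simulate_tree(n_tips: int, birth: float, death: float, seed,
                  max_retries: int = 100) -> Phylogeny:
    """Complete birth-death tree conditioned on ``n_tips`` extant families.

    Branch lengths are in Myr; tips are labelled F0001..  Extinct lineages
    are pruned, so per-tip stem ages (read off the tree) are divergence
    times from the extant sister clade.  Retries on total extinction up to
    ``max_retries``.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if not (birth > death >= 0):
        raise ValueError("require birth > death >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    for _ in range(max_retries):
        root = _grow(rng, birth, death, n_tips)
        if root is None:
            continue
        root = _prune_extinct(root)
        if root is None:
            continue
        labels = iter(f"F{i + 1:04d}" for i in range(n_tips))
        if not root.children:  # single surviving lineage; cannot form a tree
            continue
        body = ",".join(_to_newick(c, labels) for c in root.children)
        return read_newick(f"({body});")
    raise RuntimeError(
        f"total extinction in every one of {max_retries} attempts")


def simulate_lineage_count(duration: float, birth: float, death: float,
                           seed) -> int:
    """Number of extant lineages after ``duration`` Myr (may be zero).

    Pure count process of the same birth-death model; used to check the
    exponential-growth expectation E[N(t)] = exp((birth-death) t).
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    total = birth + death
    t, k = 0.0, 1
    while k > 0:
        t += rng.exponential(1.0 / (k * total))
        if t >= duration:
            break
        k += 1 if rng.random() < birth / total else -1
    return k


# -- regions -----------------------------------------------------------


def simulate_regions(n_regions: int, area_params=(12.0, 1.2),
                     tropical_params=(0.8, 0.8), seed=0) -> RegionTable:
    """Log-normal region areas with a Beta-distributed tropical fraction."""
    if n_regions < 2:
        raise ValueError("need >= 2 regions")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    mu, sigma = area_params
    a, b = tropical_params
    area = rng.lognormal(mu, sigma, n_regions)
    frac = rng.beta(a, b, n_regions) if a > 0 and b > 0 else np.zeros(n_regions)
    trop = area * frac
    frame = pd.DataFrame({
        "region_id": [f"R{i + 1:03d}" for i in range(n_regions)],
        "area_km2": area,
        "tropical_km2": trop,
        "temperate_km2": area - trop,
    })
    return RegionTable(frame)


# -- Brownian tip effects ---------------------------------------------


def brownian_effects(tree: Phylogeny, sigma2: float, seed,
                     order=None) -> pd.Series:
    """Draw u ~ N(0, sigma2 * A) over the tree's tips (A = correlation)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    labels = list(order) if order is not None else tree.tips
    if sigma2 == 0:
        return pd.Series(np.zeros(len(labels)), index=labels)
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    A = phylo_covariance(tree, labels).matrix
    lam, Q = np.linalg.eigh(A)
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal(len(labels))
    u = Q @ (np.sqrt(sigma2 * lam) * z)
    return pd.Series(u, index=labels)


# -- species tables ----------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic input bundle.

    Defaults emulate the scale of the real analysis: 168 analysis families
    on a dated angiosperm-family tree, per-family net diversification
    around 0.05 per Myr, regression coefficients at the magnitudes the
    analysis is designed to detect, and unit phylogenetic/residual
    variances on the sqrt-index scale.
    """

    n_families: int = 200          # tips simulated; ~168 survive the filter
    birth: float = 0.06            # per Myr, family-level tree
    death: float = 0.03
    n_regions: int = 60
    area_params: tuple = (12.0, 1.2)       # log-normal (mu, sigma) of km^2
    tropical_params: tuple = (0.8, 0.8)    # Beta(a, b) tropical fraction
    richness_logmean: float = float(np.log(400.0))  # family species richness
    richness_logsd: float = 1.2
    max_richness: int = 30_000
    richness_noise_sd: float = 0.3         # log-normal perturbation of n_f
    small_family_frac: float = 0.15        # forced below the 50-species filter
    extra_unaccepted_rate: float = 0.03    # unaccepted names per family
    hort_beta: tuple = (2.0, 4.0)          # family horticulture rate prior
    coverage_complete_rate: float = 0.8
    epsilon: float = 0.9
    min_richness: int = 50
    beta: dict = field(default_factory=lambda: {
        "div_rate": 0.5, "mean_range": 0.4, "hort": 0.38})
    intercept: float = 6.0                 # sqrt-index scale
    sigma2_p: float = 1.0
    sigma2_e: float = 1.0
    nat_frac: float = 0.2                  # target naturalized fraction
    n_orders: int = 25
    y_floor: float = 0.2                   # min latent sqrt-index
    resample_cap: int = 50


def _family_richness(cfg, stem_ages, rng):
    """Per-family richness and the matching true net diversification rate.

    A richness target is drawn on a log-normal spanning the realistic
    family range, the true rate is its implied r = ln(n)/t, and the
    realized richness re-derives from round(exp(r t) * noise) — so the
    stem estimator at eps = 0 recovers r_true up to the noise.
    """
    fams = sorted(stem_ages)
    n_small = int(round(cfg.small_family_frac * len(fams)))
    small = set(rng.choice(fams, size=n_small, replace=False)) if n_small else set()
    richness, r_true = {}, {}
    for f in fams:
        t = stem_ages[f]
        if f in small:
            target = int(rng.integers(5, cfg.min_richness))
        else:
            target = int(np.clip(
                np.round(rng.lognormal(cfg.richness_logmean, cfg.richness_logsd)),
                cfg.min_richness, cfg.max_richness))
        r = np.log(target) / t
        n = int(np.round(np.exp(r * t)
                         * rng.lognormal(0.0, cfg.richness_noise_sd)))
        if f in small:
            n = int(np.clip(n, 2, cfg.min_richness - 1))
        else:
            n = int(np.clip(n, cfg.min_richness, None))
        richness[f] = n
        r_true[f] = r
    return richness, r_true, small


def simulate_species_tables(tree: Phylogeny, regions: RegionTable,
                            config: SimulationConfig, seed):
    """Species/occurrence tables plus the ground-truth record.

    Returns ``(SpeciesData, truth)`` where ``truth`` holds the true
    coefficients, variance components, Brownian effects, the latent
    response, and the family dataset the pipeline must reproduce.
    """
    cfg = config
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    stem_ages = tree.stem_ages()
    fams = sorted(stem_ages)
    region_ids = sorted(regions.region_ids)
    region_area = regions.frame["area_km2"].to_dict()
    region_trop = regions.frame["tropical_km2"].to_dict()
    region_temp = regions.frame["temperate_km2"].to_dict()

    richness, r_true, small = _family_richness(cfg, stem_ages, rng)
    # order labels: contiguous chunks of the tree's tip ordering
    tip_order = tree.tips
    order_of = {f: f"O{(i * cfg.n_orders) // len(tip_order) + 1:03d}"
                for i, f in enumerate(tip_order)}

    sp_rows, native_rows = [], []
    fam_range_sums = {}   # family -> per-species (total, trop, temp) lists
    fam_hort = {}
    for f in fams:
        n = richness[f]
        pool_size = int(rng.integers(3, min(cfg.n_regions, 25) + 1))
        pool = list(rng.choice(region_ids, size=pool_size, replace=False))
        p_hort = rng.beta(*cfg.hort_beta)
        n_extra = rng.binomial(n, cfg.extra_unaccepted_rate)
        totals, trops, temps = [], [], []
        n_hort = 0
        for i in range(n + n_extra):
            accepted = i < n
            sid = f"{f}_sp{i + 1:04d}"
            k = min(1 + rng.poisson(2.0), pool_size)
            occ = list(rng.choice(pool, size=k, replace=False))
            hort = bool(rng.random() < p_hort) and accepted
            n_hort += hort
            coverage = ("complete" if rng.random() < cfg.coverage_complete_rate
                        else "partial")
            sp_rows.append((sid, f, order_of[f], accepted, hort, coverage))
            for r in occ:
                native_rows.append((sid, r, "native"))
            if accepted:
                totals.append(sum(region_area[r] for r in occ))
                trops.append(sum(region_trop[r] for r in occ))
                temps.append(sum(region_temp[r] for r in occ))
        fam_range_sums[f] = (totals, trops, temps)
        fam_hort[f] = n_hort

    # -- family-level predictors for the latent model ------------------
    retained = [f for f in fams if richness[f] >= cfg.min_richness]
    pred = pd.DataFrame({
        "family": retained,
        "div_rate": [np.log(richness[f] * (1 - cfg.epsilon) + cfg.epsilon)
                     / stem_ages[f] for f in retained],
        "mean_range_km2": [np.mean(fam_range_sums[f][0]) for f in retained],
        "mean_tropical_km2": [np.mean(fam_range_sums[f][1]) for f in retained],
        "mean_temperate_km2": [np.mean(fam_range_sums[f][2]) for f in retained],
        "hort_prop": [fam_hort[f] / richness[f] for f in retained],
    }).set_index("family")

    effects = list(cfg.beta)
    X_cols = {}
    for eff in effects:
        col = design.COLUMN_MAP[eff]
        method = design.DEFAULT_TRANSFORMS.get(eff, "identity")
        X_cols[eff] = design.standardize(design.transform(pred[col], method))
    X = np.column_stack([X_cols[e] for e in effects])
    beta_vec = np.array([cfg.beta[e] for e in effects])

    sub = tree.prune(retained) if len(retained) < len(fams) else tree
    u = brownian_effects(sub, cfg.sigma2_p, rng, order=retained)
    e = rng.normal(0.0, np.sqrt(cfg.sigma2_e), len(retained))

    latent = cfg.intercept + X @ beta_vec + u.to_numpy() + e
    # resample residuals that drive the sqrt-index negative
    n_resampled = 0
    for _ in range(cfg.resample_cap):
        low = latent < cfg.y_floor
        if not low.any():
            break
        n_resampled += int(low.sum())
        e[low] = rng.normal(0.0, np.sqrt(cfg.sigma2_e), int(low.sum()))
        latent = cfg.intercept + X @ beta_vec + u.to_numpy() + e
    else:
        raise RuntimeError(
            f"inverse construction infeasible: latent sqrt-index still below "
            f"{cfg.y_floor} after {cfg.resample_cap} resampling rounds")

    # -- invert the latent score to naturalized counts ------------------
    nat_rows = []
    fam_counts = {}
    for f, s in zip(retained, latent):
        n = richness[f]
        index = s * s  # target naturalization-success index
        lo = max(1, int(np.ceil(np.sqrt(index * n / cfg.n_regions))))
        hi = min(n, int(np.floor(np.sqrt(index * n))))
        if lo > hi:
            raise RuntimeError(
                f"no feasible naturalized count for family {f} "
                f"(index {index:.2f}, n {n})")
        n_nat = int(np.clip(int(round(cfg.nat_frac * n)), lo, hi))
        rr = int(np.clip(round(index * n / n_nat), n_nat, n_nat * cfg.n_regions))
        fam_counts[f] = (n_nat, rr)
        accepted_ids = [f"{f}_sp{i + 1:04d}" for i in range(n)]
        chosen = rng.choice(accepted_ids, size=n_nat, replace=False)
        base, rem = divmod(rr, n_nat)
        for j, sid in enumerate(chosen):
            k = base + (1 if j < rem else 0)
            regs = rng.choice(region_ids, size=k, replace=False)
            for r in regs:
                nat_rows.append((sid, r, "naturalized"))

    # small families: background naturalization so the filter has work to do
    for f in fams:
        if f in fam_counts:
            continue
        n = richness[f]
        for i in range(n):
            if rng.random() < 0.1:
                k = int(rng.integers(1, 4))
                for r in rng.choice(region_ids, size=k, replace=False):
                    nat_rows.append((f"{f}_sp{i + 1:04d}", r, "naturalized"))

    species = pd.DataFrame(sp_rows, columns=[
        "species_id", "family", "order", "accepted", "horticultural",
        "coverage_flag"])
    occurrences = pd.DataFrame(native_rows + nat_rows,
                               columns=["species_id", "region_id", "status"])
    data = SpeciesData(species=species, occurrences=occurrences)

    # -- ground-truth family dataset (independent bookkeeping) ----------
    truth_rows = []
    for f in retained:
        n = richness[f]
        n_nat, rr = fam_counts[f]
        totals, trops, temps = fam_range_sums[f]
        truth_rows.append({
            "family": f, "order": order_of[f], "n_species": n,
            "n_naturalized": n_nat, "naturalized_region_records": rr,
            "stem_age": stem_ages[f],
            "div_rate": float(pred.loc[f, "div_rate"]),
            "mean_range_km2": float(np.mean(totals)),
            "mean_tropical_km2": float(np.mean(trops)),
            "mean_temperate_km2": float(np.mean(temps)),
            "hort_prop": fam_hort[f] / n,
            "nat_success": (n_nat / n) * rr,
        })
    family_dataset = pd.DataFrame(truth_rows)

    truth = {
        "beta": dict(cfg.beta),
        "intercept": cfg.intercept,
        "sigma2_p": cfg.sigma2_p,
        "sigma2_e": cfg.sigma2_e,
        "u": u,
        "e": pd.Series(e, index=retained),
        "latent": pd.Series(latent, index=retained),
        "X": pd.DataFrame(X, index=retained, columns=effects),
        "r_true": r_true,
        "richness": richness,
        "small_families": sorted(small),
        "retained": retained,
        "family_dataset": family_dataset,
        "n_resampled": n_resampled,
    }
    return data, truth


def simulate_bundle(config: SimulationConfig, seed: int):
    """Full input bundle: (tree, regions, species data, truth)."""
    tree = simulate_tree(config.n_families, config.birth, config.death,
                         component_rng(seed, "tree"))
    regions = simulate_regions(config.n_regions, config.area_params,
                               config.tropical_params,
                               component_rng(seed, "regions"))
    data, truth = simulate_species_tables(tree, regions, config,
                                          component_rng(seed, "species"))
    return tree, regions, data, truth
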