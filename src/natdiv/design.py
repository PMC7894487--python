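"""Response/predictor assembly for the three naturalization models.

Predictors are transformed (log10(x+1) for areas, sqrt for proportions),
then standardized to mean 0 / SD 1; interaction columns are products of
the standardized main effects and are not re-standardized, so main-effect
coefficients stay interpretable at the interaction's zero point.  The
response (naturalization success) is sqrt-transformed and left on that
scale.

Model 1: div_rate + mean_range + hort.
Model 2: div_rate + trop_range + temp_range + hort
         + div_rate×trop_range + div_rate×temp_range.
Model 3: div_rate + trop_range + temp_range + hort + div_rate×hort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "model1", "model2", "model3",
    "transform", "standardize", "build_design", "predictor_correlations",
    "DEFAULT_TRANSFORMS", "COLUMN_MAP",
]

# short effect names -> FamilyDataset columns
COLUMN_MAP = {
    "div_rate": "div_rate",
    "mean_range": "mean_range_km2",
    "trop_range": "mean_tropical_km2",
    "temp_range": "mean_temperate_km2",
    "hort": "hort_prop",
    "nat_success": "nat_success",
}

DEFAULT_TRANSFORMS = {
    "div_rate": "identity",
    "mean_range": "log10p",
    "trop_range": "log10p",
    "temp_range": "log10p",
    "hort": "sqrt",
    "nat_success": "sqrt",
}


@dataclass
class ModelSpec:
    name: str
    response: str = "nat_success"
    main_effects: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    transform_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    standardize_response: bool = False

    def __post_init__(self):
        if "div_rate" not in self.main_effects:
            raise ValueError("div_rate must be a main effect in every model")
        for a, b in self.interactions:
            for eff in (a, b):
                if eff not in self.main_effects:
                    raise ValueError(
                        f"interaction term references {eff!r}, absent from main effects")

    @property
    def design_labels(self) -> list[str]:
        return (["intercept"] + list(self.main_effects)
                + [f"{a}:{b}" for a, b in self.interactions])


def model1() -> ModelSpec:
    return ModelSpec(name="model1",
                     main_effects=["div_rate", "mean_range", "hort"])


def model2() -> ModelSpec:
    return ModelSpec(name="model2",
                     main_effects=["div_rate", "trop_range", "temp_range", "hort"],
                     interactions=[("div_rate", "trop_range"),
                                   ("div_rate", "temp_range")])


def model3() -> ModelSpec:
    return ModelSpec(name="model3",
                     main_effects=["div_rate", "trop_range", "temp_range", "hort"],
                     interactions=[("div_rate", "hort")])


def transform(values, method: str) -> np.ndarray:
    """Apply ``identity``, ``log10p`` (log10(x+1)) or ``sqrt`` elementwise."""
    x = np.asarray(values, dtype=float)
    if method == "identity":
        return x
    if method in ("log10p", "sqrt"):
        if np.any(x < 0):
            bad = np.where(x < 0)[0].tolist()
            raise ValueError(f"{method} requires non-negative values; "
                             f"negative at rows {bad}")
        return np.log10(x + 1.0) if method == "log10p" else np.sqrt(x)
    raise ValueError(f"unknown transform {method!r}")


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (n−1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("standardize requires >= 2 distinct values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """(y, X, labels) for a model: intercept, standardized mains, interactions.

    Column order is intercept, main effects in spec order, then interaction
    products.  The response is transformed but not re-standardized unless
    ``spec.standardize_response``.
    """
    n = len(data)
    if n < 3:
        raise ValueError("need >= 3 rows")

    def col(effect):
        column = COLUMN_MAP.get(effect, effect)
        if column not in data.columns:
            raise KeyError(f"column {column!r} for effect {effect!r} missing")
        vals = data[column].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing values in column {column!r}")
        return vals

    mains = {}
    for eff in spec.main_effects:
        method = spec.transform_map.get(eff, "identity")
        mains[eff] = standardize(transform(col(eff), method))

    cols = [np.ones(n)] + [mains[e] for e in spec.main_effects]
    cols += [mains[a] * mains[b] for a, b in spec.interactions]
    X = np.column_stack(cols)

    y = transform(col(spec.response),
                  spec.transform_map.get(spec.response, "identity"))
    if spec.standardize_response:
        y = standardize(y)
    return y, X, spec.design_labels


def predictor_correlations(X: np.ndarray, labels=None):
    """Pearson correlations of predictor columns (no intercept).

    Returns ``(corr DataFrame, strongest)`` where ``strongest`` is the
    off-diagonal entry of maximum absolute value — the collinearity audit
    reported alongside the models.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 rows")
    if np.any(X.std(axis=0) == 0):
        bad = np.where(X.std(axis=0) == 0)[0].tolist()
        raise ValueError(f"constant predictor columns at {bad}")
    corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    if labels is None:
        labels = [f"x{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(corr, index=labels, columns=labels)
    off = corr.copy()
    np.fill_diagonal(off, 0.0)
    i, j = np.unravel_index(np.abs(off).argmax(), off.shape)
    strongest = float(corr[i, j]) if X.shape[1] > 1 else 0.0
    return frame, strongest
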