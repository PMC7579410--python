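"""Presence filtering, log2 transform, imputation, and normalisation.

The presence filter retains a protein only when it was quantified in at least
``min_present`` of the sampling days for *every* individual, restricting the
analysis to consistently measured proteins.  Missing values in the retained
set are imputed on the log2 scale; the default imputer is an iterative
random-forest scheme in the style of missForest, with per-day-mean and k-NN
imputers available for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

from ._rand import child_seed
from .datatypes import AbundanceTensor

__all__ = [
    "PresenceFilterSpec",
    "filter_presence",
    "log2_transform",
    "inverse_log2_transform",
    "impute_missing",
    "day0_normalize",
    "mean_igm_profile",
]


@dataclass
class PresenceFilterSpec:
    min_present: int = 7
    of_days: int = 10
    require_all_individuals: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_present <= self.of_days:
            raise ValueError("need 1 <= min_present <= of_days")


def filter_presence(
    tensor: AbundanceTensor, spec: PresenceFilterSpec | None = None
) -> tuple[AbundanceTensor, pd.DataFrame]:
    """Retain proteins present >= ``min_present`` days in every individual.

    Returns the filtered tensor plus a per-protein report of presence counts
    per individual and the retention decision.
    """
    if spec is None:
        spec = PresenceFilterSpec()
    fish = tensor.individuals
    days = tensor.days
    if len(days) != spec.of_days:
        raise ValueError(f"tensor has {len(days)} days, filter spec expects {spec.of_days}")
    if not tensor.is_complete_design():
        raise ValueError("tensor is missing an (individual, day) sample column")
    cols_of = {f: [tensor.sample_index(f, d) for d in days] for f in fish}
    counts = pd.DataFrame(
        {f: tensor.mask[:, cols_of[f]].sum(axis=1) for f in fish}, index=tensor.proteins
    )
    if spec.require_all_individuals:
        retained = (counts >= spec.min_present).all(axis=1)
    else:
        retained = (counts >= spec.min_present).any(axis=1)
    report = counts.copy()
    report["retained"] = retained
    kept = [p for p, r in zip(tensor.proteins, retained) if r]
    return tensor.subset(kept), report


def log2_transform(tensor: AbundanceTensor) -> AbundanceTensor:
    """log2 the observed entries of a linear tensor; the mask is untouched."""
    if tensor.scale != "linear":
        raise ValueError("tensor is not on the linear scale")
    bad = tensor.mask & (tensor.values <= 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive observed value for {tensor.proteins[i]} in "
            f"{tensor.samples[j].label}"
        )
    out = tensor.copy()
    np.log2(out.values, out=out.values, where=out.mask)
    out.scale = "log2"
    return out


def inverse_log2_transform(tensor: AbundanceTensor) -> AbundanceTensor:
    if tensor.scale != "log2":
        raise ValueError("tensor is not on the log2 scale")
    out = tensor.copy()
    out.values = np.where(out.mask, np.exp2(out.values), out.values)
    out.scale = "linear"
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def _day_mean_fill(tensor: AbundanceTensor) -> np.ndarray:
    """Initial fill: per-(protein, day) observed mean; falls back to the
    protein's overall observed mean when a day has no observations."""
    values = tensor.values.copy()
    days = np.array([s.day for s in tensor.samples])
    for i in range(len(tensor.proteins)):
        row_mask = tensor.mask[i]
        if not row_mask.any():
            raise ValueError(f"{tensor.proteins[i]}: no observed values to impute from")
        row_mean = tensor.values[i, row_mask].mean()
        for d in np.unique(days):
            cols = days == d
            miss = cols & ~row_mask
            if not miss.any():
                continue
            obs = cols & row_mask
            fill = tensor.values[i, obs].mean() if obs.any() else row_mean
            values[i, miss] = fill
    return values


def impute_missing(
    tensor: AbundanceTensor,
    method: str = "random_forest",
    max_iter: int = 10,
    n_trees: int = 100,
    n_neighbors: int = 5,
    seed: int = 0,
) -> AbundanceTensor:
    """Fill masked entries of a log2 tensor; observed entries are untouched.

    ``random_forest`` is a missForest-style iterative imputer: missing
    entries start at the per-(protein, day) observed mean, then proteins are
    revisited in increasing-missingness order, each regressed (samples as
    rows) on all other proteins with a forest of ``n_trees`` trees; the loop
    stops when the relative change of the imputed values rises, or after
    ``max_iter`` sweeps, returning the previous sweep's values.  ``knn``
    imputes from the ``n_neighbors`` most similar samples; ``day_mean`` keeps
    the initial fill.  The result carries ``mask`` all-True and an
    ``imputed`` flag matrix.
    """
    if tensor.scale != "log2":
        raise ValueError("impute on the log2 scale (call log2_transform first)")
    if method not in ("random_forest", "knn", "day_mean"):
        raise ValueError(f"unknown method {method!r}")
    out = tensor.copy()
    missing = ~tensor.mask
    out.imputed = missing.copy()
    if not missing.any():
        out.mask = np.ones_like(out.mask)
        return out

    filled = _day_mean_fill(tensor)

    if method == "day_mean":
        out.values = filled
    elif method == "knn":
        imputer = KNNImputer(n_neighbors=n_neighbors)
        x = np.where(tensor.mask, tensor.values, np.nan)
        out.values = imputer.fit_transform(x.T).T
    else:
        out.values = _missforest(tensor, filled, max_iter, n_trees, seed)
    out.mask = np.ones_like(out.mask)
    out.validate()
    return out


def _missforest(
    tensor: AbundanceTensor, filled: np.ndarray, max_iter: int, n_trees: int, seed: int
) -> np.ndarray:
    missing = ~tensor.mask
    x = filled.T.copy()  # samples x proteins
    miss_t = missing.T
    targets = np.flatnonzero(miss_t.any(axis=0))
    targets = targets[np.argsort(miss_t[:, targets].sum(axis=0), kind="stable")]
    prev = x.copy()
    prev_delta = np.inf
    for _ in range(max_iter):
        for j in targets:
            rows_obs = ~miss_t[:, j]
            rows_mis = miss_t[:, j]
            features = np.delete(np.arange(x.shape[1]), j)
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=child_seed(seed, "rf", int(j)),
                n_jobs=1,
            )
            forest.fit(x[rows_obs][:, features], x[rows_obs, j])
            x[rows_mis, j] = forest.predict(x[rows_mis][:, features])
        num = float(((x - prev)[miss_t] ** 2).sum())
        den = float((x[miss_t] ** 2).sum()) or 1.0
        delta = num / den
        if delta >= prev_delta:
            return prev.T  # last sweep made things worse; keep the previous fill
        prev = x.copy()
        prev_delta = delta
    return x.T


# ---------------------------------------------------------------------------
# normalisation and aggregation
# ---------------------------------------------------------------------------

def day0_normalize(tensor: AbundanceTensor) -> AbundanceTensor:
    """Express each fish's timecourse relative to its own day-0 baseline.

    On the log2 scale this is a subtraction of the fish's day-0 value, the
    exact equivalent of the linear-scale ratio day d / day 0; day-0 entries
    become exactly zero.
    """
    if tensor.scale != "log2":
        raise ValueError("day0_normalize expects a log2 tensor")
    if not tensor.mask.all():
        raise ValueError("tensor must be complete (impute first)")
    if 0 not in tensor.days:
        raise ValueError("day 0 is absent from the design")
    out = tensor.copy()
    for f in tensor.individuals:
        j0 = tensor.sample_index(f, 0)
        cols = [j for j, s in enumerate(tensor.samples) if s.individual == f]
        out.values[:, cols] -= tensor.values[:, [j0]]
    return out


def mean_igm_profile(tensor: AbundanceTensor, igm_accessions: set[str]) -> pd.DataFrame:
    """Mean log2 abundance of the flagged IgM proteins per (fish, day).

    Averaging on the log2 scale corresponds to a geometric mean of the linear
    intensities — the appropriate aggregate for a family of closely related
    proteins quantified on a multiplicative scale.
    """
    if not igm_accessions:
        raise ValueError("igm_accessions must be non-empty")
    missing = set(igm_accessions) - set(tensor.proteins)
    if missing:
        raise ValueError(f"accessions not in tensor: {sorted(missing)}")
    if not tensor.mask.all():
        raise ValueError("tensor must be complete (impute first)")
    idx = [tensor.protein_index(a) for a in sorted(igm_accessions)]
    mean = tensor.values[idx].mean(axis=0)
    return pd.DataFrame(
        {
            "individual": [s.individual for s in tensor.samples],
            "day": [s.day for s in tensor.samples],
            "mean_igm": mean,
        }
    )
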