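"""Per-protein population statistics for the longitudinal design.

Each protein is tested with a one-way ANOVA using sampling day as a fixed
factor, treating the individuals within a day as replicates (matching the
original analysis design; the repeated-measures caveat is documented in the
methods note).  R^2 = SS_between / SS_total summarises the variance explained
by sampling day, Benjamini-Hochberg adjustment controls the FDR across the
protein panel, and for a balanced design the BH cutoff maps onto an exact R^2
boundary.  Post-hoc day contrasts are summarised as a compact letter display
from Tukey's studentized-range test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTensor

__all__ = [
    "AnovaRecord",
    "ThresholdSpec",
    "anova_by_day",
    "bh_adjust",
    "r2_threshold_for_q",
    "tukey_cld",
    "assumption_checks",
    "anderson_darling",
    "pca_scores",
    "spearman_corr",
    "anova_panel",
]


@dataclass
class AnovaRecord:
    protein: str
    F: float
    p: float
    r2: float
    p_bh: float = np.nan
    significant: bool = False
    letters: dict[int, str] | None = None


@dataclass
class ThresholdSpec:
    """Design constants for the BH-to-R^2 boundary: m tests at FDR level q,
    k day groups with r replicates each."""

    m: int = 278
    q: float = 0.05
    k: int = 10
    r: int = 6

    def __post_init__(self) -> None:
        if self.m < 1 or self.k < 2 or self.r < 2 or not 0 < self.q < 1:
            raise ValueError("invalid threshold spec")


def _as_groups(groups: Mapping[int, np.ndarray] | Sequence[np.ndarray]) -> list[np.ndarray]:
    if isinstance(groups, Mapping):
        return [np.asarray(groups[k], float) for k in sorted(groups)]
    return [np.asarray(g, float) for g in groups]


def anova_by_day(groups: Mapping[int, np.ndarray] | Sequence[np.ndarray]) -> tuple[float, float, float]:
    """One-way ANOVA decomposition: returns (F, p, R^2)."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least two values")
    all_vals = np.concatenate(gs)
    n, k = len(all_vals), len(gs)
    grand = all_vals.mean()
    ss_total = float(((all_vals - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ValueError("degenerate input: all values identical")
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in gs))
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        return math.inf, 0.0, 1.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p, ss_between / ss_total


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def r2_threshold_for_q(spec: ThresholdSpec, n_rejected: int) -> float:
    """The R^2 boundary equivalent to the BH cutoff in a balanced design.

    With ``n_rejected`` of ``m`` tests rejected at level ``q``, the step-up
    raw-p boundary is ``n_rejected * q / m``; inverting the F(k-1, k(r-1))
    tail at that probability and mapping F to R^2 gives the boundary
    ``R^2* = (k-1) F* / ((k-1) F* + k(r-1))``.
    """
    if not 1 <= n_rejected <= spec.m:
        raise ValueError("n_rejected must be in [1, m]")
    df_b, df_w = spec.k - 1, spec.k * (spec.r - 1)
    p_bound = n_rejected * spec.q / spec.m
    f_star = float(sps.f.isf(min(p_bound, 1.0), df_b, df_w))
    return df_b * f_star / (df_b * f_star + df_w)


# ---------------------------------------------------------------------------
# Tukey compact letter display
# ---------------------------------------------------------------------------

def _tukey_pvalues(gs: list[np.ndarray]) -> np.ndarray:
    """All-pairs p-values from the studentized range (Tukey-Kramer)."""
    k = len(gs)
    n = sum(len(g) for g in gs)
    df_w = n - k
    means = np.array([g.mean() for g in gs])
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(ms_within / 2 * (1 / len(gs[i]) + 1 / len(gs[j])))
            if se == 0.0:
                p = 0.0 if means[i] != means[j] else 1.0
            else:
                q_obs = abs(means[i] - means[j]) / se
                p = float(sps.studentized_range.sf(q_obs, k, df_w))
            pmat[i, j] = pmat[j, i] = p
    return pmat


def tukey_cld(
    groups: Mapping[int, np.ndarray] | Sequence[np.ndarray], alpha: float = 0.05
) -> dict[int, str]:
    """Compact letter display: two days share a letter iff their Tukey
    pairwise comparison is not significant at ``alpha``.

    Uses the insert-and-absorb construction: start from one letter covering
    all groups, split it for each significant pair, and drop columns that
    become subsets of others.
    """
    if isinstance(groups, Mapping):
        keys = sorted(groups)
        gs = [np.asarray(groups[kk], float) for kk in keys]
    else:
        keys = list(range(len(groups)))
        gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least two values")
    k = len(gs)
    pmat = _tukey_pvalues(gs)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if pmat[i, j] > alpha:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.extend((col - {i}, col - {j}))
            columns = [
                c
                for c in columns
                if not any(c < other for other in columns)
            ]
            # deduplicate while preserving construction order
            uniq: list[set[int]] = []
            for c in columns:
                if c not in uniq:
                    uniq.append(c)
            columns = uniq
    # letters ordered by each column's first group in key order
    columns.sort(key=min)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {key: "" for key in keys}
    for letter, col in zip(alphabet, columns):
        for g in sorted(col):
            letters[keys[g]] += letter
    return letters


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def anderson_darling(sample: Sequence[float]) -> tuple[float, float]:
    """Anderson-Darling normality test with estimated mean and variance.

    Returns the A^2 statistic and an approximate p-value from the standard
    small-sample-corrected formula (A^2* = A^2 (1 + 0.75/n + 2.25/n^2)).
    """
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance sample")
    z = (x - x.mean()) / sd
    cdf = sps.norm.cdf(z)
    cdf = np.clip(cdf, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1])))
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star > 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    return float(a2), float(min(max(p, 0.0), 1.0))


def assumption_checks(
    residuals: Sequence[float],
    groups: Mapping[int, np.ndarray] | Sequence[np.ndarray],
) -> dict[str, float]:
    """Normality of residuals (Anderson-Darling) and homogeneity of variance
    across groups (Brown-Forsythe median-centred Levene)."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    a2, p_ad = anderson_darling(residuals)
    w, p_lev = sps.levene(*gs, center="median")
    return {"ad_stat": a2, "ad_p": p_ad, "levene_stat": float(w), "levene_p": float(p_lev)}


# ---------------------------------------------------------------------------
# PCA and rank correlation
# ---------------------------------------------------------------------------

def pca_scores(
    matrix: np.ndarray, center: bool = True, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """SVD-based principal component scores (samples x components) and the
    proportion of variance per component (prcomp semantics: centred,
    unscaled by default)."""
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples and features")
    if np.isnan(x).any():
        raise ValueError("missing values present — impute first")
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot scale a zero-variance feature")
        x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    total = float((s**2).sum())
    if total == 0.0:
        raise ValueError("zero total variance")
    return scores, s**2 / total


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks on ties; p via the t
    approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors of length >= 4")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# panel-level pipeline
# ---------------------------------------------------------------------------

def anova_panel(
    tensor: AbundanceTensor, q: float = 0.05, alpha: float = 0.05,
    letters: bool = True,
) -> pd.DataFrame:
    """Per-protein ANOVA over sampling days with BH adjustment; Tukey letters
    are computed only for proteins passing the BH cutoff.

    Returns a DataFrame with columns protein, F, p, r2, p_bh, significant,
    letters (semicolon-joined ``day:letters`` for significant proteins).
    """
    if not tensor.mask.all():
        raise ValueError("tensor must be complete (impute first)")
    recs = []
    by_day_groups = {}
    for prot in tensor.proteins:
        groups = tensor.by_day(prot)
        by_day_groups[prot] = groups
        f, p, r2 = anova_by_day(groups)
        recs.append({"protein": prot, "F": f, "p": p, "r2": r2})
    frame = pd.DataFrame(recs)
    frame["p_bh"] = bh_adjust(frame["p"].to_numpy())
    frame["significant"] = frame["p_bh"] <= q
    letters_col = []
    for _, row in frame.iterrows():
        if letters and row["significant"]:
            cld = tukey_cld(by_day_groups[row["protein"]], alpha=alpha)
            letters_col.append(";".join(f"{d}:{cld[d]}" for d in sorted(cld)))
        else:
            letters_col.append("")
    frame["letters"] = letters_col
    return frame
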