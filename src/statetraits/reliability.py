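"""Group-mean reliability of aggregated scores: ICC1, ICC2, permutation null.

ICC1 is the one-way random-effects intraclass correlation — the fraction of
individual-score variance attributable to unit membership — estimated from
the ANOVA mean squares on (possibly unbalanced) groups:

    ICC1 = (MS_between - MS_within) / (MS_between + (k - 1) * MS_within)

with k the average group size. ICC2, the reliability of the group means, is
the Spearman-Brown step-up of ICC1 at k:

    ICC2 = k * ICC1 / (1 + (k - 1) * ICC1)

The permutation null reassigns participants to units at random without
replacement (group sizes held fixed) and recomputes both coefficients per
iteration, quantifying how much apparent group-mean reliability arises from
aggregation alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import ScaleScores
from .units import resolve_units

__all__ = [
    "ICCResult",
    "PermutationNullResult",
    "anova_icc",
    "spearman_brown",
    "spearman_brown_inverse",
    "permutation_null",
    "icc_table",
    "permutation_null_table",
]


@dataclass
class ICCResult:
    trait: str | None
    icc1: float
    icc2: float
    k: float
    n_units: int
    n_total: int
    ms_between: float
    ms_within: float
    k_method: str = "mean"


@dataclass
class PermutationNullResult:
    iterations: int
    icc1_draws: np.ndarray
    icc2_draws: np.ndarray
    mean_icc1: float
    mean_icc2: float
    k: float
    n_units: int
    seed: int | None


def spearman_brown(icc1: float, k: float) -> float:
    """Step up a single-observation reliability to the reliability of a mean of k.

    Raises on the degenerate case where the denominator 1 + (k-1)*icc1 is
    nonpositive (a strongly negative icc1 combined with a large k).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if icc1 > 1:
        raise ValueError(f"icc1 must be <= 1, got {icc1}")
    denom = 1.0 + (k - 1.0) * icc1
    if denom <= 0:
        raise ValueError(
            f"Spearman-Brown denominator nonpositive for icc1={icc1}, k={k}"
        )
    return k * icc1 / denom


def spearman_brown_inverse(icc2: float, k: float) -> float:
    """Solve the Spearman-Brown relation for the single-observation reliability."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    denom = k - (k - 1.0) * icc2
    if denom == 0:
        raise ValueError(f"degenerate inversion for icc2={icc2}, k={k}")
    return icc2 / denom


def _group_stats(values: np.ndarray, codes: np.ndarray, n_groups: int):
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    return counts, sums


def anova_icc(
    values,
    units,
    k_method: str = "mean",
    trait: str | None = None,
) -> ICCResult:
    """One-way random-effects ANOVA ICC1 (and its ICC2) on unbalanced groups.

    Missing values are dropped first; groups left empty are dropped. ``k`` is
    the arithmetic mean group size (``k_method='mean'``) or the
    unbalanced-design effective size k0 = (N - sum(n_j^2)/N) / (J - 1)
    (``k_method='k0'``).
    """
    if k_method not in ("mean", "k0"):
        raise ValueError(f"unknown k_method {k_method!r}")
    v = np.asarray(values, dtype=float)
    u = np.asarray(units)
    mask = np.isfinite(v)
    v, u = v[mask], u[mask]
    labels, codes = np.unique(u, return_inverse=True)
    n_groups = len(labels)
    n = len(v)
    if n_groups < 2 or n < 2:
        raise ValueError("need at least 2 units and 2 observations")
    counts, sums = _group_stats(v, codes, n_groups)
    grand = v.sum() / n
    sst = float(np.sum((v - grand) ** 2))
    ssb = float(np.sum(sums**2 / counts) - n * grand**2)
    ssw = sst - ssb
    msb = ssb / (n_groups - 1)
    msw = ssw / (n - n_groups)
    if msb <= 0 and msw <= 0:
        raise ValueError("all observations identical; ICC undefined")
    if k_method == "mean":
        k = n / n_groups
    else:
        k = (n - float(np.sum(counts**2)) / n) / (n_groups - 1)
    icc1 = (msb - msw) / (msb + (k - 1.0) * msw)
    try:
        icc2 = spearman_brown(icc1, k)
    except ValueError:
        warnings.warn("ICC2 undefined (Spearman-Brown denominator nonpositive)", stacklevel=2)
        icc2 = float("nan")
    return ICCResult(
        trait=trait,
        icc1=float(icc1),
        icc2=float(icc2),
        k=float(k),
        n_units=int(n_groups),
        n_total=int(n),
        ms_between=float(msb),
        ms_within=float(msw),
        k_method=k_method,
    )


def permutation_null(
    values,
    units,
    iterations: int = 1000,
    seed: int | None = None,
    k_method: str = "mean",
) -> PermutationNullResult:
    """Null distribution of ICC1/ICC2 under random reassignment to units.

    Each iteration permutes the unit labels over participants (equivalently,
    permutes scores over the fixed label vector), preserving the multiset of
    group sizes exactly, and recomputes both coefficients. The total sum of
    squares is permutation-invariant, so only group sums are recomputed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    v = np.asarray(values, dtype=float)
    u = np.asarray(units)
    mask = np.isfinite(v)
    v, u = v[mask], u[mask]
    labels, codes = np.unique(u, return_inverse=True)
    n_groups, n = len(labels), len(v)
    if n_groups < 2 or n < 2:
        raise ValueError("need at least 2 units and 2 observations")
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    grand = v.sum() / n
    sst = float(np.sum((v - grand) ** 2))
    k = n / n_groups if k_method == "mean" else (n - float(np.sum(counts**2)) / n) / (n_groups - 1)

    rng = np.random.default_rng(seed)
    icc1_draws = np.empty(iterations)
    icc2_draws = np.empty(iterations)
    for it in range(iterations):
        perm = rng.permutation(v)
        sums = np.bincount(codes, weights=perm, minlength=n_groups)
        ssb = float(np.sum(sums**2 / counts) - n * grand**2)
        msb = ssb / (n_groups - 1)
        msw = (sst - ssb) / (n - n_groups)
        icc1 = (msb - msw) / (msb + (k - 1.0) * msw)
        denom = 1.0 + (k - 1.0) * icc1
        icc1_draws[it] = icc1
        icc2_draws[it] = k * icc1 / denom if denom > 0 else np.nan
    return PermutationNullResult(
        iterations=iterations,
        icc1_draws=icc1_draws,
        icc2_draws=icc2_draws,
        mean_icc1=float(icc1_draws.mean()),
        mean_icc2=float(np.nanmean(icc2_draws)),
        k=float(k),
        n_units=n_groups,
        seed=seed,
    )


def icc_table(
    scores: ScaleScores,
    unit_subset=None,
    k_method: str = "mean",
) -> pd.DataFrame:
    """Per-trait ICC summary for one inventory's scores.

    The cross-trait mean row averages the per-trait ICC1s and the per-trait
    ICC2s arithmetically; because the Spearman-Brown relation is nonlinear
    these two summaries are not interchangeable (the mean ICC2 is not the
    step-up of the mean ICC1).
    """
    subset = resolve_units(unit_subset)
    units = scores.units
    keep = units.isin(subset) if subset is not None else slice(None)
    rows = []
    for t in scores.traits:
        col = scores.scores[t]
        res = anova_icc(col[keep], units[keep], k_method=k_method, trait=t)
        rows.append(res.__dict__)
    df = pd.DataFrame(rows).set_index("trait")
    return df


def permutation_null_table(
    scores: ScaleScores,
    iterations: int = 1000,
    seed: int | None = None,
    unit_subset=None,
    k_method: str = "mean",
) -> pd.DataFrame:
    """Permutation null per trait; seeds are derived per trait from ``seed``."""
    subset = resolve_units(unit_subset)
    units = scores.units
    keep = units.isin(subset) if subset is not None else slice(None)
    ss = np.random.SeedSequence(seed).spawn(len(scores.traits))
    rows = []
    for child, t in zip(ss, scores.traits):
        col = scores.scores[t]
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = permutation_null(
            col[keep], units[keep], iterations=iterations, seed=sub_seed, k_method=k_method
        )
        rows.append(
            {
                "trait": t,
                "mean_icc1": res.mean_icc1,
                "mean_icc2": res.mean_icc2,
                "iterations": res.iterations,
                "k": res.k,
                "n_units": res.n_units,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
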