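"""How representative a sample is of the unit universe.

Two checks: per-unit participant counts against census populations, and
within-unit demographic composition (ethnicity, age bands, education) against
census margins. Both are unweighted Pearson correlations across units, since
weighting only enters downstream convergence analyses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import EDUCATION_ORDER, ResponseTable

__all__ = [
    "count_representativeness",
    "composition_representativeness",
    "attainment_representativeness",
    "summarize_sample",
]

MAD_NORMAL_CONSISTENCY = 1.4826


def count_representativeness(responses: ResponseTable, census: pd.Series) -> float:
    """Correlate per-unit participant counts with census populations.

    Invariant to rescaling the census populations by any positive constant.
    """
    counts = responses.unit_counts()
    common = counts.index.intersection(census.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common units")
    x = counts.loc[common].to_numpy(dtype=float)
    y = census.loc[common].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate variance in counts or census populations")
    return float(stats.pearsonr(x, y).statistic)


def composition_representativeness(
    responses: ResponseTable,
    margins: pd.DataFrame,
    dimension: str,
    min_age: int | None = None,
) -> pd.Series:
    """Per-category correlation of sample composition with census margins.

    For each category of ``dimension`` (a column of the participant roster),
    correlates across units the sample percentage with the census margin
    percentage. Margins may be given as counts or proportions (rows are
    renormalized). Categories absent from the sample are reported missing
    with a warning; categories with no cross-unit variance are reported
    missing (degenerate).
    """
    roster = responses.participants
    if dimension not in roster.columns:
        raise KeyError(f"dimension {dimension!r} not in participant roster")
    if min_age is not None:
        roster = roster[roster["age"] > min_age]
    margins = margins.div(margins.sum(axis=1), axis=0)
    sample = (
        pd.crosstab(roster["unit"], roster[dimension], normalize="index")
        .reindex(margins.index)
    )
    out = {}
    for cat in margins.columns:
        if cat not in sample.columns:
            warnings.warn(f"category {cat!r} absent from sample", stacklevel=2)
            out[cat] = np.nan
            continue
        x = sample[cat].to_numpy(dtype=float)
        y = margins[cat].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            warnings.warn(f"category {cat!r}: degenerate variance", stacklevel=2)
            out[cat] = np.nan
            continue
        out[cat] = float(stats.pearsonr(x[ok], y[ok]).statistic)
    return pd.Series(out, name=f"r_{dimension}")


def attainment_representativeness(
    responses: ResponseTable,
    margins_education: pd.DataFrame,
    level: str = "bachelor_or_higher",
    min_age: int = 24,
    order=EDUCATION_ORDER,
) -> float:
    """Correlate per-unit percent of age-eligible participants attaining at
    least ``level`` with the census margin for the same cumulative measure.

    Only participants older than ``min_age`` enter the sample percentage,
    matching the convention of restricting attainment comparisons to the
    age-eligible population.
    """
    if level not in order:
        raise KeyError(f"unknown education level {level!r}")
    at_least = set(order[order.index(level):])
    roster = responses.participants
    roster = roster[roster["age"] > min_age]
    grp = roster.groupby("unit", observed=True)["education"]
    sample_pct = grp.apply(lambda s: s.isin(at_least).mean())
    margins = margins_education.div(margins_education.sum(axis=1), axis=0)
    census_pct = margins[[c for c in margins.columns if c in at_least]].sum(axis=1)
    common = sample_pct.index.intersection(census_pct.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common units")
    return float(
        stats.pearsonr(sample_pct.loc[common], census_pct.loc[common]).statistic
    )


def summarize_sample(responses: ResponseTable) -> dict:
    """Descriptive summary: counts, sex/ethnicity/education percentages,
    median age with its median absolute deviation (reported both raw and with
    the 1.4826 normal-consistency scaling)."""
    roster = responses.participants
    out: dict[str, object] = {
        "n_participants": len(roster),
        "n_units": int(roster["unit"].nunique()),
    }
    if "sex" in roster.columns and roster["sex"].notna().any():
        out["pct_female"] = float((roster["sex"] == "female").mean() * 100)
    if "age" in roster.columns and roster["age"].notna().any():
        ages = roster["age"].dropna().to_numpy(dtype=float)
        med = float(np.median(ages))
        mad = float(np.median(np.abs(ages - med)))
        out["median_age"] = med
        out["age_mad"] = mad
        out["age_mad_scaled"] = mad * MAD_NORMAL_CONSISTENCY
    for dim in ("ethnicity", "education"):
        if dim in roster.columns and roster[dim].notna().any():
            pct = roster[dim].value_counts(normalize=True) * 100
            out[f"pct_{dim}"] = pct.to_dict()
    return out
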