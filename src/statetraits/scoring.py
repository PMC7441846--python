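"""Scale scoring under planned missingness and aggregation to unit score tables.

Individual trait scores are the simple mean of a participant's observed items
for that trait within one inventory, after reflecting reverse-keyed items as
``likert_min + likert_max - response``. Unit (state) scores are unweighted
means of individual scores over the participants residing in the unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ResponseTable
from .units import resolve_units

__all__ = ["ScaleScores", "score_scales", "aggregate_states", "state_dispersion"]


@dataclass
class ScaleScores:
    """Per-participant trait scores from one inventory.

    ``scores`` is participant x trait with NaN where fewer than ``min_items``
    items were observed; ``n_items`` counts observed items per cell; ``units``
    maps participants to their geographic unit.
    """

    scores: pd.DataFrame
    n_items: pd.DataFrame
    units: pd.Series
    likert_min: int
    likert_max: int
    inventory: str
    sample_id: str
    min_items: int = 1

    @property
    def traits(self) -> list[str]:
        return list(self.scores.columns)


def score_scales(
    responses: ResponseTable,
    bank: pd.DataFrame,
    inventory: str,
    min_items: int = 1,
) -> ScaleScores:
    """Score one inventory's traits for every participant.

    Reverse-keyed items are reflected before averaging. Traits with fewer
    than ``min_items`` observed items are left missing. Item ids appearing in
    the responses but unknown to the bank are skipped with a warning.
    """
    if min_items < 1:
        raise ValueError("min_items must be >= 1")
    if inventory not in set(bank["inventory"]):
        raise KeyError(f"inventory {inventory!r} not present in item bank")
    sub = bank.loc[bank["inventory"] == inventory, ["item_id", "trait", "keying"]]

    resp = responses.responses
    known = set(bank["item_id"])
    resp_ids = resp["item_id"].unique()
    unknown = [i for i in resp_ids if i not in known]
    if unknown:
        warnings.warn(
            f"{len(unknown)} unknown item id(s) skipped (e.g. {unknown[:3]})",
            stacklevel=2,
        )

    merged = resp.merge(sub, on="item_id", how="inner")
    lo, hi = responses.likert_min, responses.likert_max
    vals = merged["value"].to_numpy(dtype=float)
    keyed = np.where(merged["keying"].to_numpy() < 0, lo + hi - vals, vals)
    merged = merged.assign(keyed=keyed)

    grouped = merged.groupby(["participant_id", "trait"], observed=True)[
        "keyed"
    ].agg(["mean", "count"])
    score_tab = grouped["mean"].unstack("trait")
    count_tab = grouped["count"].unstack("trait").fillna(0).astype(int)

    traits = [t for t in sub["trait"].unique()]
    pids = responses.participants.index
    score_tab = score_tab.reindex(index=pids, columns=traits)
    count_tab = count_tab.reindex(index=pids, columns=traits).fillna(0).astype(int)
    score_tab = score_tab.where(count_tab >= min_items)

    sample_ids = responses.participants["sample_id"].unique()
    sample_id = sample_ids[0] if len(sample_ids) == 1 else "mixed"
    return ScaleScores(
        scores=score_tab,
        n_items=count_tab,
        units=responses.participants["unit"].copy(),
        likert_min=lo,
        likert_max=hi,
        inventory=inventory,
        sample_id=sample_id,
        min_items=min_items,
    )


def aggregate_states(
    scores: ScaleScores,
    min_n: int = 1,
    unit_subset=None,
) -> pd.DataFrame:
    """Aggregate individual scores to a unit x trait state-score table.

    Each unit's trait mean is the unweighted mean over participants with a
    non-missing score for that trait. ``n`` counts participants contributing
    at least one trait score; units with ``n`` below ``min_n`` (or outside
    ``unit_subset``) are excluded. The average participants per included unit
    is recorded as ``attrs['k']``.
    """
    subset = resolve_units(unit_subset)
    df = scores.scores.copy()
    df["unit"] = scores.units
    if subset is not None:
        df = df[df["unit"].isin(subset)]
    traits = scores.traits
    grouped = df.groupby("unit", observed=True)
    means = grouped[traits].mean()
    n = grouped.apply(lambda g: int(g[traits].notna().any(axis=1).sum()), include_groups=False)
    n.name = "n"

    empty = n.index[n == 0]
    if len(empty):
        warnings.warn(f"{len(empty)} unit(s) with no scored participants excluded", stacklevel=2)
    keep = n.index[(n >= max(min_n, 1))]
    table = means.loc[keep].join(n.loc[keep])
    table = table.sort_index()
    table.index.name = "unit"
    table.attrs["k"] = float(table["n"].mean()) if len(table) else float("nan")
    table.attrs["sample_id"] = scores.sample_id
    table.attrs["inventory"] = scores.inventory
    return table


def state_dispersion(scores: ScaleScores, table: pd.DataFrame) -> pd.DataFrame:
    """Dispersion of scores at the individual and unit level, per trait.

    Reports SD, range and extremes at both levels, identifying the units
    holding the unit-level minimum and maximum. With a single unit the
    unit-level SD is undefined and reported missing.
    """
    if table.empty:
        raise ValueError("state score table is empty")
    traits = [t for t in scores.traits if t in table.columns]
    rows = []
    for t in traits:
        ind = scores.scores[t].dropna()
        unit_means = table[t].dropna()
        if unit_means.empty:
            warnings.warn(f"trait {t!r}: no unit means available", stacklevel=2)
            continue
        single = len(unit_means) < 2
        rows.append(
            {
                "trait": t,
                "individual_mean": ind.mean(),
                "individual_sd": ind.std(ddof=1),
                "individual_min": ind.min(),
                "individual_max": ind.max(),
                "individual_range": ind.max() - ind.min(),
                "state_sd": float("nan") if single else unit_means.std(ddof=1),
                "state_min": unit_means.min(),
                "state_max": unit_means.max(),
                "state_range": unit_means.max() - unit_means.min(),
                "state_min_unit": unit_means.idxmin(),
                "state_max_unit": unit_means.idxmax(),
            }
        )
    return pd.DataFrame(rows).set_index("trait")
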