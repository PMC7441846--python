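"""Unit-level trait/sociodemographic correlations and their replicability.

Each sample's unit trait scores are correlated (population-weighted) with
unit-level sociodemographic variables, partialling the sample's other traits.
Replicability across studies is the "correlation of correlations": pair every
original sample's (trait, variable) correlation with every new sample's, and
correlate the pairs. A critical-r helper gives the smallest correlation that
would reach a two-sided significance level at the unit count, as a
descriptive yardstick (no multiple-testing correction is applied anywhere;
the analysis reasons through patterns and means of correlations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .convergence import weighted_pearson
from .units import resolve_units

__all__ = [
    "weighted_partial_correlation",
    "build_panel",
    "replication_correlation",
    "correlation_range",
    "replication_summary",
    "critical_r",
    "SingularControlsError",
]


class SingularControlsError(np.linalg.LinAlgError):
    """The control block of the correlation matrix is singular (collinear controls)."""


def _weighted_corr_matrix(columns: np.ndarray, w: np.ndarray) -> np.ndarray:
    w = w / w.sum()
    mu = w @ columns
    dev = columns - mu
    cov = dev.T @ (dev * w[:, None])
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise ValueError("zero weighted variance in at least one column")
    return cov / np.outer(sd, sd)


def weighted_partial_correlation(
    y,
    x,
    controls=None,
    w=None,
    control_names: Sequence[str] | None = None,
) -> float:
    """Weighted partial correlation of x and y given controls.

    Computed from the weighted correlation matrix of (x, y, controls) through
    the inverse of the control block (the Schur-complement form of inverting
    the full matrix). With no controls this reduces to the weighted Pearson
    correlation. A singular control block raises
    :class:`SingularControlsError` naming the collinear columns. When x or y
    is an exact linear function of the controls the partial correlation is a
    0/0 limit; it is returned as 0.0 with a warning (residuals of zero
    variance are orthogonal to everything by convention).
    """
    if isinstance(controls, pd.DataFrame):
        control_names = list(controls.columns)
        ctrl_cols = [controls[c] for c in controls.columns]
    elif controls is None:
        ctrl_cols = []
    else:
        ctrl_cols = [np.asarray(c) for c in controls]
    if w is None:
        first = np.asarray(x, float) if not isinstance(x, pd.Series) else x
        w = pd.Series(1.0, index=x.index) if isinstance(x, pd.Series) else np.ones(len(first))

    # align everything pairwise-complete on the common index
    if isinstance(x, pd.Series) or isinstance(y, pd.Series):
        frames = {"__x": pd.Series(x), "__y": pd.Series(y), "__w": pd.Series(w)}
        for i, c in enumerate(ctrl_cols):
            frames[f"__c{i}"] = pd.Series(c)
        df = pd.DataFrame(frames).dropna()
        xv = df["__x"].to_numpy(float)
        yv = df["__y"].to_numpy(float)
        wv = df["__w"].to_numpy(float)
        cv = [df[f"__c{i}"].to_numpy(float) for i in range(len(ctrl_cols))]
    else:
        arrs = [np.asarray(x, float), np.asarray(y, float), np.asarray(w, float)] + [
            np.asarray(c, float) for c in ctrl_cols
        ]
        mask = np.all([np.isfinite(a) for a in arrs], axis=0)
        xv, yv, wv = arrs[0][mask], arrs[1][mask], arrs[2][mask]
        cv = [a[mask] for a in arrs[3:]]

    p = len(cv)
    if len(xv) < p + 3:
        raise ValueError(f"need at least {p + 3} observations for {p} controls, got {len(xv)}")
    if p == 0:
        return weighted_pearson(xv, yv, wv)

    cols = np.column_stack([xv, yv] + cv)
    R = _weighted_corr_matrix(cols, wv)
    C = R[2:, 2:]
    rxc = R[0, 2:]
    ryc = R[1, 2:]
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        names = control_names or [f"control_{i}" for i in range(p)]
        raise SingularControlsError(
            f"collinear control columns: {list(names)}"
        ) from None
    if np.linalg.cond(C) > 1e12:
        names = control_names or [f"control_{i}" for i in range(p)]
        raise SingularControlsError(f"collinear control columns: {list(names)}")
    num = R[0, 1] - rxc @ Cinv @ ryc
    den_x = 1.0 - rxc @ Cinv @ rxc
    den_y = 1.0 - ryc @ Cinv @ ryc
    tol = 1e-10
    if den_x < tol or den_y < tol:
        if abs(num) < tol:
            warnings.warn(
                "x or y exactly explained by the controls; partial correlation "
                "returned as 0 by convention",
                stacklevel=2,
            )
            return 0.0
        raise ValueError("residual variance of x or y vanishes; partial correlation undefined")
    return float(num / np.sqrt(den_x * den_y))


def build_panel(
    tables: Mapping[str, pd.DataFrame],
    sociodemo: pd.DataFrame,
    w: pd.Series,
    unit_subset=None,
    partialled: bool = True,
    traits: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long panel of (sample, trait, variable) weighted [partial] correlations.

    For every sample's trait and every sociodemographic variable, the
    weighted correlation of the unit trait score with the variable,
    controlling for the sample's other traits when ``partialled``. Units are
    handled pairwise-complete (rows missing any involved column are dropped,
    with a warning counting them).
    """
    subset = resolve_units(unit_subset)
    rows = []
    dropped_total = 0
    for sample_id, table in tables.items():
        cols = [c for c in table.columns if c != "n"]
        use_traits = list(traits) if traits is not None else cols
        use_vars = list(variables) if variables is not None else list(sociodemo.columns)
        t = table
        s = sociodemo
        if subset is not None:
            t = t.loc[t.index.isin(subset)]
            s = s.loc[s.index.isin(subset)]
        common = t.index.intersection(s.index)
        for trait in use_traits:
            others = [c for c in cols if c != trait]
            for var in use_vars:
                need = pd.concat(
                    [t.loc[common, [trait] + (others if partialled else [])],
                     s.loc[common, [var]], w.reindex(common).rename("__w")],
                    axis=1,
                )
                complete = need.dropna()
                dropped_total += len(need) - len(complete)
                if partialled:
                    r = weighted_partial_correlation(
                        complete[var],
                        complete[trait],
                        controls=complete[others],
                        w=complete["__w"],
                    )
                else:
                    r = weighted_pearson(complete[trait], complete[var], complete["__w"])
                rows.append(
                    {
                        "sample": sample_id,
                        "trait": trait,
                        "variable": var,
                        "r": r,
                        "partialled": partialled,
                        "n_units": len(complete),
                    }
                )
    if dropped_total:
        warnings.warn(
            f"{dropped_total} incomplete unit row(s) dropped pairwise across cells",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def _pair_values(panel_old: pd.DataFrame, panel_new: pd.DataFrame, trait: str):
    po = panel_old[panel_old["trait"] == trait]
    pn = panel_new[panel_new["trait"] == trait]
    if po.empty or pn.empty:
        raise KeyError(f"trait {trait!r} absent from a panel")
    merged = po.merge(pn, on=["trait", "variable"], suffixes=("_old", "_new"))
    return merged["r_old"].to_numpy(float), merged["r_new"].to_numpy(float)


def replication_correlation(
    panel_old: pd.DataFrame, panel_new: pd.DataFrame, trait: str
) -> tuple[float, int]:
    """Correlation of correlations for one trait.

    Forms every (old sample, new sample, variable) pair of correlation values
    and returns the Pearson correlation over the pairs with the pair count.
    """
    old_r, new_r = _pair_values(panel_old, panel_new, trait)
    n_pairs = len(old_r)
    if n_pairs < 3:
        raise ValueError(f"need at least 3 pairs, got {n_pairs}")
    if np.std(old_r) == 0 or np.std(new_r) == 0:
        raise ValueError("degenerate variance among paired correlations")
    return float(stats.pearsonr(old_r, new_r).statistic), n_pairs


def correlation_range(
    panel: pd.DataFrame, trait: str, panel_new: pd.DataFrame | None = None
) -> float:
    """Max minus min over a trait's correlation values (both panels pooled
    when a second panel is given)."""
    vals = panel.loc[panel["trait"] == trait, "r"].to_numpy(float)
    if panel_new is not None:
        vals = np.concatenate(
            [vals, panel_new.loc[panel_new["trait"] == trait, "r"].to_numpy(float)]
        )
    if vals.size == 0:
        raise KeyError(f"trait {trait!r} absent from panel")
    return float(np.nanmax(vals) - np.nanmin(vals))


def replication_summary(
    panel_old: pd.DataFrame, panel_new: pd.DataFrame, traits: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-trait replication correlation, pair count, and pooled range."""
    if traits is None:
        traits = list(dict.fromkeys(panel_old["trait"]))
    rows = []
    for t in traits:
        r, n = replication_correlation(panel_old, panel_new, t)
        rows.append(
            {
                "trait": t,
                "replication_r": r,
                "n_pairs": n,
                "correlation_range": correlation_range(panel_old, t, panel_new),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| reaching two-sided significance ``alpha`` at sample size n,
    via the t transform r = t / sqrt(t**2 + n - 2)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(t**2 + n - 2))
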