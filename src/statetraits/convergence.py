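"""Cross-sample convergence of unit-level scores.

Same-trait convergent correlations between samples' state score tables are
population-weighted Pearson correlations over a shared unit subset, pooled
via the Fisher z transform (atanh -> mean -> tanh). Sample pairs are grouped
by whether they share a personality inventory, a research project, and a
data-collection period. Cross-inventory convergence within one sample is
estimated by a split-half bootstrap (score each half, aggregate, correlate
across halves), with the same-inventory cross-half correlation serving as a
reliability whose square root disattenuates the cross-inventory cells.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import ScaleScores, score_scales
from .synthetic import ResponseTable
from .units import resolve_units

__all__ = [
    "SampleMeta",
    "PairDesign",
    "SplitHalfResult",
    "weighted_pearson",
    "fisher_z",
    "fisher_mean",
    "classify_pair_design",
    "pairwise_convergence",
    "group_means",
    "GroupMeans",
    "split_half_bootstrap",
    "disattenuate",
    "plot_pair_matrix",
]

_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class SampleMeta:
    """Design attributes of one sample: inventory, project, collection period."""

    sample_id: str
    inventory: str
    project: str
    period_start: int
    period_end: int

    def __post_init__(self) -> None:
        if self.period_start > self.period_end:
            raise ValueError(
                f"sample {self.sample_id!r}: period_start after period_end"
            )


@dataclass(frozen=True)
class PairDesign:
    """Design class of a sample pair: S(ame)/D(ifferent) inventory and project,
    S(ame)/A(djacent)/N(on-adjacent) time period."""

    inventory: str
    project: str
    time: str

    @property
    def label(self) -> str:
        return f"Inv:{self.inventory}, Proj:{self.project}, Time:{self.time}"


def classify_pair_design(a: SampleMeta, b: SampleMeta, gap_years: int = 5) -> PairDesign:
    """Classify a sample pair by inventory, project, and time relation.

    Periods sharing more than a boundary year are Same; periods that touch at
    a single year or are separated by less than ``gap_years`` are Adjacent;
    gaps of ``gap_years`` or more are Non-adjacent.
    """
    overlap = min(a.period_end, b.period_end) - max(a.period_start, b.period_start)
    if overlap > 0:
        time = "S"
    elif -overlap < gap_years:
        time = "A"
    else:
        time = "N"
    return PairDesign(
        inventory="S" if a.inventory == b.inventory else "D",
        project="S" if a.project == b.project else "D",
        time=time,
    )


def _align_weighted(x, y, w):
    if isinstance(x, pd.Series) or isinstance(y, pd.Series) or isinstance(w, pd.Series):
        x = pd.Series(x) if not isinstance(x, pd.Series) else x
        y = pd.Series(y) if not isinstance(y, pd.Series) else y
        w = pd.Series(w) if not isinstance(w, pd.Series) else w
        idx = x.index.intersection(y.index).intersection(w.index)
        x, y, w = x.loc[idx].to_numpy(float), y.loc[idx].to_numpy(float), w.loc[idx].to_numpy(float)
    else:
        x, y, w = np.asarray(x, float), np.asarray(y, float), np.asarray(w, float)
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(w)
    return x[mask], y[mask], w[mask]


def weighted_pearson(x, y, w) -> float:
    """Pearson correlation with frequency-normalized observation weights.

    Series inputs are aligned on their common index; non-finite entries are
    dropped pairwise. Requires at least 3 common observations and nonzero
    weighted variance in both variables.
    """
    x, y, w = _align_weighted(x, y, w)
    if len(x) < 3:
        raise ValueError(f"need >= 3 common finite observations, got {len(x)}")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    w = w / w.sum()
    mx, my = w @ x, w @ y
    vx = w @ (x - mx) ** 2
    vy = w @ (y - my) ** 2
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance; correlation undefined")
    cov = w @ ((x - mx) * (y - my))
    # clamp floating-point overshoot just beyond +/-1
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def fisher_z(r):
    """atanh, with |r| = 1 clipped to +/-(1 - 1e-12) (warned)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations outside [-1, 1]")
    if np.any(np.abs(r) >= _CLIP):
        warnings.warn("|r| = 1 clipped before atanh", stacklevel=2)
        r = np.clip(r, -_CLIP, _CLIP)
    return np.arctanh(r)


def fisher_mean(rs) -> float:
    """Pool correlations: atanh each, average, tanh back."""
    rs = np.asarray(list(np.atleast_1d(rs)), dtype=float)
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        raise ValueError("no correlations to pool")
    return float(np.tanh(np.mean(fisher_z(rs))))


def pairwise_convergence(
    tables: Mapping[str, pd.DataFrame],
    meta: Mapping[str, SampleMeta] | Sequence[SampleMeta],
    w: pd.Series,
    unit_subset=None,
    traits: Sequence[str] | None = None,
    gap_years: int = 5,
    design_overrides: Mapping[tuple[str, str], PairDesign] | None = None,
) -> pd.DataFrame:
    """Weighted same-trait correlations for every unordered sample pair.

    ``tables`` maps sample id to a unit x trait state-score table. Each pair
    row carries the per-trait weighted correlation (over the unit subset
    common to both tables), the Fisher-pooled pair mean, and the design class
    derived from ``meta`` (or taken from ``design_overrides`` when the true
    collection design is known not to follow the period-geometry rule).
    """
    if not isinstance(meta, Mapping):
        meta = {m.sample_id: m for m in meta}
    subset = resolve_units(unit_subset)
    ids = list(tables)
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    if traits is None:
        traits = list(dict.fromkeys(itertools.chain.from_iterable(
            [c for c in t.columns if c != "n"] for t in tables.values()
        )))
    rows = []
    for a, b in itertools.combinations(ids, 2):
        ta, tb = tables[a], tables[b]
        if subset is not None:
            ta = ta.loc[ta.index.isin(subset)]
            tb = tb.loc[tb.index.isin(subset)]
        design = None
        if design_overrides is not None:
            design = design_overrides.get((a, b)) or design_overrides.get((b, a))
        if design is None:
            design = classify_pair_design(meta[a], meta[b], gap_years=gap_years)
        row: dict[str, object] = {
            "sample_a": a,
            "sample_b": b,
            "inventory_class": design.inventory,
            "project_class": design.project,
            "time_class": design.time,
            "design": design.label,
        }
        cells = []
        for t in traits:
            if t not in ta.columns or t not in tb.columns:
                warnings.warn(f"trait {t!r} missing for pair ({a}, {b})", stacklevel=2)
                row[t] = np.nan
                continue
            r = weighted_pearson(ta[t], tb[t], w)
            row[t] = r
            cells.append(r)
        row["pair_mean"] = fisher_mean(cells) if cells else np.nan
        rows.append(row)
    panel = pd.DataFrame(rows)
    panel.attrs["traits"] = list(traits)
    return panel


@dataclass
class GroupMeans:
    """Fisher-pooled convergence summaries by design class and trait."""

    by_class: pd.DataFrame  # class x (traits..., mean, n_pairs)
    by_trait: pd.Series  # trait -> pooled mean over all pairs
    grand: float  # pooled mean over all (pair, trait) cells


def group_means(panel: pd.DataFrame, traits: Sequence[str] | None = None) -> GroupMeans:
    """Pool a convergence panel by design class, by trait, and overall."""
    if panel.empty:
        raise ValueError("empty convergence panel")
    if traits is None:
        traits = panel.attrs.get("traits")
    if traits is None:
        raise ValueError("trait columns must be given or stored in panel.attrs")
    cls_rows = {}
    for label, grp in panel.groupby("design"):
        row = {}
        for t in traits:
            vals = grp[t].dropna()
            if vals.empty:
                warnings.warn(f"design class {label!r}: no values for trait {t!r}", stacklevel=2)
                row[t] = np.nan
            else:
                row[t] = fisher_mean(vals)
        all_cells = grp[list(traits)].to_numpy().ravel()
        row["mean"] = fisher_mean(all_cells[np.isfinite(all_cells)])
        row["n_pairs"] = len(grp)
        cls_rows[label] = row
    by_class = pd.DataFrame(cls_rows).T
    by_class.index.name = "design"
    by_trait = pd.Series(
        {t: fisher_mean(panel[t].dropna()) for t in traits}, name="pooled_r"
    )
    cells = panel[list(traits)].to_numpy().ravel()
    grand = fisher_mean(cells[np.isfinite(cells)])
    return GroupMeans(by_class=by_class, by_trait=by_trait, grand=grand)


def disattenuate(r: float, rel_a: float, rel_b: float) -> float:
    """Correct a correlation for unreliability: r / sqrt(rel_a * rel_b).

    Values may exceed 1 and are reported unclipped.
    """
    if not (0 < rel_a <= 1) or not (0 < rel_b <= 1):
        raise ValueError(f"reliabilities must be in (0, 1], got {rel_a}, {rel_b}")
    return float(r / np.sqrt(rel_a * rel_b))


@dataclass
class SplitHalfResult:
    """Cross-inventory split-half convergence within one sample.

    ``raw[trait]`` is an inventory x inventory matrix of Fisher-pooled mean
    cross-half weighted correlations whose diagonal holds the same-inventory
    cross-half reliability; ``adjusted[trait]`` divides each off-diagonal cell
    by the square root of the product of the two diagonal reliabilities.
    """

    raw: dict[str, pd.DataFrame]
    adjusted: dict[str, pd.DataFrame]
    iterations: int
    seed: int | None
    pooling: str
    dropped_unit_events: int

    @property
    def traits(self) -> list[str]:
        return list(self.raw)

    def reliability(self, trait: str) -> pd.Series:
        return pd.Series(np.diag(self.raw[trait]), index=self.raw[trait].index)

    def combined_table(self, trait: str) -> pd.DataFrame:
        """Raw cells below the diagonal, reliabilities on it, adjusted above."""
        raw, adj = self.raw[trait], self.adjusted[trait]
        out = raw.copy()
        invs = list(raw.index)
        for i, a in enumerate(invs):
            for j, b in enumerate(invs):
                if i < j:
                    out.iloc[i, j] = adj.iloc[i, j]
        return out

    def mean_raw(self) -> float:
        """Fisher-pooled mean of all off-diagonal raw cells across traits."""
        cells = []
        for t in self.traits:
            m = self.raw[t].to_numpy()
            cells.extend(m[np.triu_indices_from(m, k=1)])
        return fisher_mean(cells)

    def mean_reliability(self) -> float:
        cells = []
        for t in self.traits:
            cells.extend(np.diag(self.raw[t]))
        return fisher_mean(cells)


def _half_unit_means(
    scores: np.ndarray, codes: np.ndarray, half: np.ndarray, n_units: int
) -> np.ndarray:
    """Unit means of one score column over a participant subset (NaN-aware)."""
    v = scores[half]
    c = codes[half]
    ok = np.isfinite(v)
    sums = np.bincount(c[ok], weights=v[ok], minlength=n_units)
    cnts = np.bincount(c[ok], minlength=n_units).astype(float)
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)


def split_half_bootstrap(
    responses: ResponseTable,
    bank: pd.DataFrame,
    inventories: Sequence[str],
    iterations: int = 1000,
    seed: int | None = None,
    w: pd.Series | None = None,
    unit_subset=None,
    min_items: int = 1,
    pooling: str = "fisher",
    degenerate: bool = False,
) -> SplitHalfResult:
    """Cross-inventory convergence by repeated random sample bisection.

    Each iteration splits participants uniformly at random into two halves,
    aggregates each half's inventory scores to unit means, and correlates
    (weighted) inventory A in one half with inventory B in the other; the two
    orderings are both recorded. The diagonal (A with itself across halves)
    is the split-half reliability of the aggregated scores. Cells are pooled
    across iterations via Fisher z (``pooling='fisher'``) or raw averaging.

    ``degenerate=True`` is a test hook that places the whole sample in both
    halves, so every cell reduces to the full-sample cross-inventory weighted
    correlation.
    """
    if len(inventories) < 2 and not degenerate:
        raise ValueError("need at least two inventories")
    if pooling not in ("fisher", "raw"):
        raise ValueError(f"unknown pooling {pooling!r}")
    subset = resolve_units(unit_subset)

    scored: dict[str, ScaleScores] = {
        inv: score_scales(responses, bank, inv, min_items=min_items) for inv in inventories
    }
    traits = scored[inventories[0]].traits
    units = responses.participants["unit"].to_numpy()
    unit_labels, codes = np.unique(units, return_inverse=True)
    if subset is not None:
        in_sub = np.isin(unit_labels, subset)
    else:
        in_sub = np.ones(len(unit_labels), dtype=bool)
    n_units = len(unit_labels)
    if w is None:
        w_arr = np.ones(n_units)
    else:
        w_arr = w.reindex(unit_labels).to_numpy(dtype=float)
    score_mats = {inv: scored[inv].scores[traits].to_numpy() for inv in inventories}

    n = len(responses.participants)
    rng = np.random.default_rng(seed)
    if degenerate:
        iterations = 1
    draws: dict[tuple[str, str, str], list[float]] = {
        (t, a, b): [] for t in traits for a in inventories for b in inventories
    }
    dropped = 0
    for _ in range(iterations):
        if degenerate:
            h1 = h2 = np.arange(n)
        else:
            perm = rng.permutation(n)
            h1, h2 = perm[: n // 2], perm[n // 2 :]
        for ti, t in enumerate(traits):
            m1 = {a: _half_unit_means(score_mats[a][:, ti], codes, h1, n_units) for a in inventories}
            m2 = {a: _half_unit_means(score_mats[a][:, ti], codes, h2, n_units) for a in inventories}
            for a in inventories:
                for b in inventories:
                    x, y = m1[a], m2[b]
                    ok = np.isfinite(x) & np.isfinite(y) & in_sub & (w_arr > 0)
                    if ok.sum() < in_sub.sum():
                        dropped += int(in_sub.sum() - ok.sum())
                    if ok.sum() < 3:
                        continue
                    draws[(t, a, b)].append(
                        weighted_pearson(x[ok], y[ok], w_arr[ok])
                    )

    def pool(vals: list[float]) -> float:
        if not vals:
            return float("nan")
        if pooling == "fisher":
            return fisher_mean(vals)
        return float(np.mean(vals))

    raw: dict[str, pd.DataFrame] = {}
    adjusted: dict[str, pd.DataFrame] = {}
    for t in traits:
        mat = pd.DataFrame(index=list(inventories), columns=list(inventories), dtype=float)
        for a in inventories:
            for b in inventories:
                if a == b:
                    mat.loc[a, b] = pool(draws[(t, a, a)])
                else:
                    # average the two orderings (A-half1 x B-half2, B-half1 x A-half2)
                    mat.loc[a, b] = pool(draws[(t, a, b)] + draws[(t, b, a)])
        adj = mat.copy()
        rel = np.diag(mat)
        for i, a in enumerate(inventories):
            for j, b in enumerate(inventories):
                if i != j and rel[i] > 0 and rel[j] > 0:
                    adj.loc[a, b] = disattenuate(mat.loc[a, b], min(rel[i], 1.0), min(rel[j], 1.0))
                elif i != j:
                    adj.loc[a, b] = np.nan
        raw[t] = mat
        adjusted[t] = adj
    return SplitHalfResult(
        raw=raw,
        adjusted=adjusted,
        iterations=iterations,
        seed=seed,
        pooling=pooling,
        dropped_unit_events=dropped,
    )


def plot_pair_matrix(matrix: pd.DataFrame, path: str, title: str = "") -> None:
    """Render a correlation matrix heatmap to an image file (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix.columns), 1 + 0.6 * len(matrix)))
    im = ax.imshow(matrix.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
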