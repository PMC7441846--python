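"""Synthetic questionnaire data with known state-level structure.

Emulates the data-generating situation of large online Big Five assessments
aggregated to U.S. states: ~50 geographic units with very unequal populations,
a tiny fraction of individual trait variance carried by unit membership
(ICC1 on the order of 0.001-0.015), 1-6 Likert items with positive and
reverse keying, and several overlapping inventories administered by random
item sampling at inventory-specific rates ("planned missingness": each
participant answers only a random subset of each inventory's items).

Every generated artifact is a deterministic function of a single integer
seed; independent sub-streams for the item bank, unit assignment, latent
traits, item responses, census margins, sociodemographics, and participant
demographics are derived from it via ``numpy.random.SeedSequence.spawn`` in
a fixed documented order, so fixing the seed fixes every artifact
bit-for-bit.

The generative model:

* unit latent mean  mu_ut = m_t + Normal(0, between_unit_sd_t)
* participant trait tau_pt = mu_{u(p),t} + Normal(0, within_unit_sd_t)
* item response (positively keyed) = clip(round(m_t + loading * (tau_pt - m_t)
  + Normal(0, item_noise_sd)), likert_min, likert_max); reverse-keyed items
  generate the reflected value likert_min + likert_max - (.)

so the implied latent intraclass correlation per trait is
``between_unit_sd**2 / (between_unit_sd**2 + within_unit_sd**2)``, recorded
as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .units import default_unit_labels

__all__ = [
    "BIG_FIVE",
    "InventorySpec",
    "SociodemoSpec",
    "SyntheticConfig",
    "GroundTruth",
    "ResponseTable",
    "CensusTables",
    "ConfigError",
    "zipf_weights",
    "default_sociodemo_specs",
    "generate_item_bank",
    "generate_responses",
    "generate_sociodemographics",
    "generate_census",
    "draw_unit_truth",
]

BIG_FIVE: tuple[str, ...] = (
    "Conscientiousness",
    "Agreeableness",
    "Neuroticism",
    "Openness",
    "Extraversion",
)

#: default latent trait means on the 1-6 response scale, in the range seen for
#: Big Five scale means in large web samples
DEFAULT_TRAIT_MEANS: dict[str, float] = {
    "Conscientiousness": 4.2,
    "Agreeableness": 4.7,
    "Neuroticism": 3.6,
    "Openness": 4.55,
    "Extraversion": 3.85,
}

ETHNICITY_BASE = {
    "white": 0.64,
    "african_american": 0.12,
    "hispanic": 0.16,
    "asian": 0.05,
    "native": 0.01,
    "other": 0.02,
}
AGE_BAND_BASE = {"18-24": 0.13, "25-44": 0.35, "45-64": 0.34, "65+": 0.18}
AGE_BAND_RANGES = {"18-24": (18, 24), "25-44": (25, 44), "45-64": (45, 64), "65+": (65, 90)}
EDUCATION_BASE = {"no_highschool": 0.13, "highschool": 0.57, "bachelor_or_higher": 0.30}
EDUCATION_ORDER = ("no_highschool", "highschool", "bachelor_or_higher")

# fixed spawn order of the per-artifact random sub-streams
_STREAMS = ("bank", "units", "traits", "responses", "census", "sociodemo", "demographics")

# Spread of per-unit census margins around the national base composition.
# Real state-level ethnic composition varies widely (minority shares range
# from under 1% to over a third of a state); a Dirichlet concentration of 15
# reproduces that order of cross-unit spread.
_DIRICHLET_CONCENTRATION = 15.0


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def between_sd_for_icc(icc1: float, within_sd: float = 1.1) -> float:
    """Between-unit SD giving a target latent ICC1 at a fixed within-unit SD."""
    if not 0 <= icc1 < 1:
        raise ConfigError("target icc1 must be in [0, 1)")
    return within_sd * float(np.sqrt(icc1 / (1.0 - icc1)))


def zipf_weights(n_units: int, exponent: float = 1.0) -> np.ndarray:
    """Rank-size population weights, w_r proportional to 1 / r**exponent.

    With exponent 1 over 51 units the largest/smallest ratio is 51, close to
    the ~66 ratio of real U.S. state populations.
    """
    w = 1.0 / np.arange(1, n_units + 1, dtype=float) ** exponent
    return w / w.sum()


@dataclass(frozen=True)
class InventorySpec:
    """One inventory: items per trait, and the random item sampling rate.

    ``overlap_with``/``overlap_fraction`` let an inventory reuse a fraction of
    a previously defined inventory's items per trait, mirroring item pools in
    which several inventories draw on a common public-domain repository.
    """

    name: str
    items_per_trait: int
    sampling_rate: float
    overlap_with: str | None = None
    overlap_fraction: float = 0.0


@dataclass(frozen=True)
class SociodemoSpec:
    """One unit-level sociodemographic variable.

    ``trait_r`` maps trait names to the target correlation between the
    variable and the unit latent trait means. With ``noise_sd=None`` the
    residual SD is auto-calibrated to ``sqrt(1 - sum(r**2))`` so targets hold
    in expectation; with an explicit ``noise_sd`` the trait loadings are
    rescaled accordingly (``noise_sd=0`` makes the variable a deterministic
    combination of the standardized trait means).
    """

    name: str
    trait_r: Mapping[str, float]
    noise_sd: float | None = None


def default_sociodemo_specs(trait_names: Sequence[str] = BIG_FIVE) -> tuple[SociodemoSpec, ...]:
    """Thirteen synthetic unit-level variables on a per-capita/percentage footing.

    Loadings are moderate on Conscientiousness, Neuroticism and Openness and
    weak on Extraversion and Agreeableness, emulating the empirical pattern
    that only some traits show consistent sociodemographic correlates.
    """
    c, a, n, o, e = trait_names
    specs = [
        SociodemoSpec("cancer_deaths", {n: 0.40, c: -0.30}),
        SociodemoSpec("heart_disease_deaths", {n: 0.40, c: -0.35}),
        SociodemoSpec("violent_crime", {a: -0.25, n: 0.30}),
        SociodemoSpec("property_crime", {a: -0.20, o: 0.20}),
        SociodemoSpec("arts_jobs", {o: 0.50}),
        SociodemoSpec("business_jobs", {e: 0.20, c: 0.30}),
        SociodemoSpec("compsci_jobs", {o: 0.45, e: -0.15}),
        SociodemoSpec("health_jobs", {c: 0.35, a: 0.15}),
        SociodemoSpec("patents", {o: 0.50, c: 0.20}),
        SociodemoSpec("pct_liberal", {o: 0.55, n: 0.20}),
        SociodemoSpec("religiosity", {o: -0.45, a: 0.20}),
        SociodemoSpec("wellbeing_index", {n: -0.50, c: 0.25}),
        SociodemoSpec("community_recognition", {e: 0.25, a: 0.15}),
    ]
    return tuple(specs)


def _per_trait(value, trait_names: Sequence[str], what: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [t for t in trait_names if t not in value]
        if missing:
            raise ConfigError(f"{what} missing traits {missing}")
        return {t: float(value[t]) for t in trait_names}
    return {t: float(value) for t in trait_names}


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic study.

    Defaults describe the emulated study conditions: 51 units with rank-size
    population weights, small between-unit trait variance (latent ICC1 ~
    0.003), 1-6 Likert items, and one 100-item inventory (20 items per trait)
    sampled at 30%.
    """

    n_units: int = 51
    n_participants: int = 20_000
    trait_names: tuple[str, ...] = BIG_FIVE
    trait_means: Mapping[str, float] | float | None = None
    between_unit_sd: Mapping[str, float] | float = 0.06
    within_unit_sd: Mapping[str, float] | float = 1.1
    inventories: tuple[InventorySpec, ...] = (InventorySpec("BFFM", 20, 0.30),)
    item_loading: float = 1.0
    item_noise_sd: float = 0.8
    reverse_key_fraction: float = 0.3
    likert_min: int = 1
    likert_max: int = 6
    sociodemo_specs: tuple[SociodemoSpec, ...] = ()
    unit_weights: Sequence[float] | None = None
    unit_labels: Sequence[str] | None = None
    assignment: str = "multinomial"  # or "quota": fixed per-unit counts
    total_population: int = 234_000_000
    sample_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ConfigError("need at least 2 units")
        if self.likert_min >= self.likert_max:
            raise ConfigError("likert_min must be < likert_max")
        if self.assignment not in ("multinomial", "quota"):
            raise ConfigError(f"unknown assignment mode {self.assignment!r}")
        self.trait_names = tuple(self.trait_names)
        if self.trait_means is None:
            mid = 0.5 * (self.likert_min + self.likert_max)
            self.trait_means = {
                t: DEFAULT_TRAIT_MEANS.get(t, mid) for t in self.trait_names
            }
        self.trait_means = _per_trait(self.trait_means, self.trait_names, "trait_means")
        self.between_unit_sd = _per_trait(self.between_unit_sd, self.trait_names, "between_unit_sd")
        self.within_unit_sd = _per_trait(self.within_unit_sd, self.trait_names, "within_unit_sd")
        for t in self.trait_names:
            if self.between_unit_sd[t] < 0 or self.within_unit_sd[t] <= 0:
                raise ConfigError(f"nonpositive SD for trait {t!r}")
        self.inventories = tuple(self.inventories)
        if not self.inventories:
            raise ConfigError("need at least one inventory")
        for inv in self.inventories:
            if inv.items_per_trait < 1:
                raise ConfigError(f"inventory {inv.name!r} has zero items per trait")
            if not 0.0 <= inv.sampling_rate <= 1.0:
                raise ConfigError(f"inventory {inv.name!r} sampling rate outside [0, 1]")
            if not 0.0 <= inv.overlap_fraction <= 1.0:
                raise ConfigError(f"inventory {inv.name!r} overlap fraction outside [0, 1]")
        if not 0.0 <= self.reverse_key_fraction <= 1.0:
            raise ConfigError("reverse_key_fraction outside [0, 1]")
        self.sociodemo_specs = tuple(self.sociodemo_specs)
        for spec in self.sociodemo_specs:
            rs = np.array([spec.trait_r.get(t, 0.0) for t in self.trait_names])
            if np.any(np.abs(rs) > 1.0):
                raise ConfigError(f"sociodemo {spec.name!r} requests |correlation| > 1")
            if spec.noise_sd is None and np.sum(rs**2) > 1.0:
                raise ConfigError(
                    f"sociodemo {spec.name!r}: sum of squared target correlations exceeds 1"
                )
        if self.unit_labels is None:
            self.unit_labels = default_unit_labels(self.n_units)
        self.unit_labels = tuple(self.unit_labels)
        if len(self.unit_labels) != self.n_units:
            raise ConfigError("unit_labels length differs from n_units")
        if self.unit_weights is None:
            # rank-size weights assigned to units in a seed-shuffled order
            w = zipf_weights(self.n_units)
            order = self.rng("units").permutation(self.n_units)
            self.unit_weights = w[order]
        self.unit_weights = np.asarray(self.unit_weights, dtype=float)
        if self.unit_weights.shape != (self.n_units,):
            raise ConfigError("unit_weights length differs from n_units")
        if np.any(self.unit_weights < 0):
            raise ConfigError("unit_weights must be nonnegative")
        if abs(self.unit_weights.sum() - 1.0) > 1e-9:
            raise ConfigError("unit_weights must sum to 1 within 1e-9")

    def rng(self, stream: str) -> np.random.Generator:
        """Seeded generator for one named sub-stream."""
        idx = _STREAMS.index(stream)
        child = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[idx]
        return np.random.default_rng(child)

    @property
    def true_icc1(self) -> pd.Series:
        """Implied latent intraclass correlation per trait."""
        vals = {
            t: self.between_unit_sd[t] ** 2
            / (self.between_unit_sd[t] ** 2 + self.within_unit_sd[t] ** 2)
            for t in self.trait_names
        }
        return pd.Series(vals, name="true_icc1")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Latent quantities behind one generated dataset."""

    unit_trait_means: pd.DataFrame  # unit x trait
    participant_traits: pd.DataFrame  # participant x trait
    true_icc1: pd.Series
    sociodemo_true_r: pd.DataFrame  # trait x variable target correlations


@dataclass
class ResponseTable:
    """Participant roster plus sparse long-format item responses."""

    participants: pd.DataFrame  # index participant_id; unit, sample_id, demographics
    responses: pd.DataFrame  # participant_id, item_id, value
    likert_min: int = 1
    likert_max: int = 6

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def unit_counts(self) -> pd.Series:
        return self.participants["unit"].value_counts()


@dataclass
class CensusTables:
    """Unit population counts and per-unit demographic composition margins."""

    populations: pd.Series  # unit -> population count
    margins: dict[str, pd.DataFrame]  # dimension -> unit x category proportions


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` by ``weights``."""
    exact = weights * total
    base = np.floor(exact).astype(int)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:short]] += 1
    return base


def generate_item_bank(config: SyntheticConfig) -> pd.DataFrame:
    """Build the item bank: one row per (inventory, item).

    Keying direction is drawn deterministically from the seed, with
    ``round(reverse_key_fraction * n)`` reverse-keyed items per (inventory,
    trait) cell. Items shared between inventories keep a single keying.
    """
    rng = config.rng("bank")
    rows: list[tuple[str, str, str, int, float]] = []
    item_keying: dict[str, int] = {}
    items_by_cell: dict[tuple[str, str], list[str]] = {}
    for inv in config.inventories:
        for trait in config.trait_names:
            n = inv.items_per_trait
            shared: list[str] = []
            if inv.overlap_with is not None:
                src = items_by_cell.get((inv.overlap_with, trait))
                if src is None:
                    raise ConfigError(
                        f"inventory {inv.name!r} overlaps with undefined inventory "
                        f"{inv.overlap_with!r} (define it earlier in the list)"
                    )
                n_shared = min(int(round(inv.overlap_fraction * n)), len(src), n)
                shared = src[:n_shared]
            n_new = n - len(shared)
            new_ids = [f"{inv.name}.{trait[:5]}.{i:03d}" for i in range(1, n_new + 1)]
            n_rev = int(round(config.reverse_key_fraction * n_new))
            keyings = rng.permutation([-1] * n_rev + [1] * (n_new - n_rev))
            for item_id, keying in zip(new_ids, keyings):
                item_keying[item_id] = int(keying)
            cell_items = shared + new_ids
            items_by_cell[(inv.name, trait)] = cell_items
            for item_id in cell_items:
                rows.append(
                    (item_id, inv.name, trait, item_keying[item_id], inv.sampling_rate)
                )
    bank = pd.DataFrame(
        rows, columns=["item_id", "inventory", "trait", "keying", "sampling_rate"]
    )
    bank["keying"] = bank["keying"].astype(np.int8)
    return bank


def draw_unit_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the unit x trait latent means (the ``traits`` sub-stream)."""
    rng = config.rng("traits")
    t = config.trait_names
    means = np.array([config.trait_means[x] for x in t])
    bsd = np.array([config.between_unit_sd[x] for x in t])
    m = means + rng.normal(0.0, 1.0, size=(config.n_units, len(t))) * bsd
    return pd.DataFrame(m, index=pd.Index(config.unit_labels, name="unit"), columns=t)


def _census_margins(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    rng = config.rng("census")
    out: dict[str, pd.DataFrame] = {}
    for dim, base in (
        ("ethnicity", ETHNICITY_BASE),
        ("age_band", AGE_BAND_BASE),
        ("education", EDUCATION_BASE),
    ):
        alpha = np.array(list(base.values())) * _DIRICHLET_CONCENTRATION
        mat = rng.dirichlet(alpha, size=config.n_units)
        out[dim] = pd.DataFrame(
            mat, index=pd.Index(config.unit_labels, name="unit"), columns=list(base)
        )
    return out


def generate_census(config: SyntheticConfig) -> CensusTables:
    """Census fixture: unit populations proportional to the unit weights, plus
    per-unit demographic composition margins (rows sum to 1 per dimension)."""
    pops = _apportion(config.total_population, config.unit_weights)
    populations = pd.Series(
        pops, index=pd.Index(config.unit_labels, name="unit"), name="population"
    )
    return CensusTables(populations=populations, margins=_census_margins(config))


def _assign_units(config: SyntheticConfig) -> np.ndarray:
    rng = config.rng("units")
    # the first draw of this stream is reserved for the default weight-order
    # permutation; consume it unconditionally so assignment is identical
    # whether weights were defaulted or given explicitly
    rng.permutation(config.n_units)
    n = config.n_participants
    if config.assignment == "quota":
        counts = _apportion(n, config.unit_weights)
        idx = np.repeat(np.arange(config.n_units), counts)
        rng.shuffle(idx)
        return idx
    return rng.choice(config.n_units, size=n, p=config.unit_weights)


def _sample_demographics(
    config: SyntheticConfig, unit_idx: np.ndarray, margins: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    rng = config.rng("demographics")
    n = config.n_participants
    out: dict[str, np.ndarray] = {}
    out["sex"] = np.where(rng.random(n) < 0.64, "female", "male")
    for dim in ("ethnicity", "age_band", "education"):
        table = margins[dim]
        cats = np.array(table.columns)
        codes = np.empty(n, dtype=int)
        for u in range(config.n_units):
            mask = unit_idx == u
            if not mask.any():
                continue
            codes[mask] = rng.choice(len(cats), size=int(mask.sum()), p=table.iloc[u].to_numpy())
        out[dim] = cats[codes]
    lo = np.array([AGE_BAND_RANGES[b][0] for b in out["age_band"]])
    hi = np.array([AGE_BAND_RANGES[b][1] for b in out["age_band"]])
    out["age"] = rng.integers(lo, hi + 1)
    return pd.DataFrame(out)


def generate_responses(
    config: SyntheticConfig, bank: pd.DataFrame
) -> tuple[ResponseTable, GroundTruth]:
    """Generate the participant roster and sparse item responses.

    Participants are assigned to units multinomially by weight (or by fixed
    quota), receive latent traits as unit mean plus individual deviation, and
    see each inventory's items independently at that inventory's sampling
    rate; unobserved cells are simply absent from the long response table.
    """
    traits = config.trait_names
    n = config.n_participants
    unit_idx = _assign_units(config)
    unit_truth = draw_unit_truth(config)
    rng_t = config.rng("traits")
    # reproduce the unit-mean draw so participant deviations continue the stream
    rng_t.normal(0.0, 1.0, size=(config.n_units, len(traits)))
    wsd = np.array([config.within_unit_sd[t] for t in traits])
    taus = unit_truth.to_numpy()[unit_idx] + rng_t.normal(0.0, 1.0, size=(n, len(traits))) * wsd

    pids = pd.Index([f"P{i:06d}" for i in range(1, n + 1)], name="participant_id")
    margins = _census_margins(config)
    demo = _sample_demographics(config, unit_idx, margins)
    participants = pd.DataFrame(
        {
            "unit": np.array(config.unit_labels)[unit_idx],
            "sample_id": config.sample_id,
            **{c: demo[c].to_numpy() for c in ("sex", "age", "age_band", "ethnicity", "education")},
        },
        index=pids,
    )

    # sparse responses, inventory by inventory, deduplicated for shared items
    item_ids = bank["item_id"].drop_duplicates().to_numpy()
    item_pos = {iid: j for j, iid in enumerate(item_ids)}
    first = bank.drop_duplicates("item_id").set_index("item_id")
    trait_pos = {t: j for j, t in enumerate(traits)}
    item_trait = np.array([trait_pos[first.loc[i, "trait"]] for i in item_ids])
    item_key = np.array([first.loc[i, "keying"] for i in item_ids], dtype=np.int8)

    rng_r = config.rng("responses")
    pid_parts: list[np.ndarray] = []
    item_parts: list[np.ndarray] = []
    chunk = 10_000
    for inv in config.inventories:
        sub = bank.loc[bank["inventory"] == inv.name, "item_id"].to_numpy()
        gidx = np.array([item_pos[i] for i in sub])
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            mask = rng_r.random((stop - start, len(sub))) < inv.sampling_rate
            p, j = np.nonzero(mask)
            pid_parts.append(p + start)
            item_parts.append(gidx[j])
    pid_all = np.concatenate(pid_parts) if pid_parts else np.array([], dtype=int)
    item_all = np.concatenate(item_parts) if item_parts else np.array([], dtype=int)
    keys = pid_all.astype(np.int64) * len(item_ids) + item_all
    uniq = np.unique(keys)
    pid_obs = uniq // len(item_ids)
    item_obs = uniq % len(item_ids)

    t_idx = item_trait[item_obs]
    mean_vec = np.array([config.trait_means[t] for t in traits])
    mu = mean_vec[t_idx] + config.item_loading * (taus[pid_obs, t_idx] - mean_vec[t_idx])
    neg = item_key[item_obs] < 0
    mu = np.where(neg, config.likert_min + config.likert_max - mu, mu)
    raw = mu + rng_r.normal(0.0, config.item_noise_sd, size=mu.shape)
    vals = np.clip(np.rint(raw), config.likert_min, config.likert_max).astype(np.int8)

    responses = pd.DataFrame(
        {
            "participant_id": pd.Categorical.from_codes(pid_obs, categories=pids),
            "item_id": pd.Categorical.from_codes(item_obs, categories=item_ids),
            "value": vals,
        }
    )

    truth = GroundTruth(
        unit_trait_means=unit_truth,
        participant_traits=pd.DataFrame(taus, index=pids, columns=traits),
        true_icc1=config.true_icc1,
        sociodemo_true_r=pd.DataFrame(
            {
                spec.name: [spec.trait_r.get(t, 0.0) for t in traits]
                for spec in config.sociodemo_specs
            },
            index=pd.Index(traits, name="trait"),
        ),
    )
    table = ResponseTable(
        participants=participants,
        responses=responses,
        likert_min=config.likert_min,
        likert_max=config.likert_max,
    )
    return table, truth


def generate_sociodemographics(config: SyntheticConfig, truth: GroundTruth) -> pd.DataFrame:
    """Unit-level sociodemographic variables with configured trait correlations.

    Each variable is a loading-weighted combination of the standardized unit
    trait means plus Gaussian noise; loadings are calibrated so that the
    configured correlations hold in expectation. Realized correlations are
    recorded in ``table.attrs['realized_r']``.
    """
    rng = config.rng("sociodemo")
    traits = list(config.trait_names)
    m = truth.unit_trait_means[traits].to_numpy()
    sd = m.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [t for t, s in zip(traits, sd) if s == 0]
        raise ConfigError(f"zero between-unit variance for traits {flat}; cannot standardize")
    z = (m - m.mean(axis=0)) / sd
    cols: dict[str, np.ndarray] = {}
    for spec in config.sociodemo_specs:
        r = np.array([spec.trait_r.get(t, 0.0) for t in traits])
        if np.any(np.abs(r) > 1.0):
            raise ConfigError(f"sociodemo {spec.name!r} requests |correlation| > 1")
        ssq = float(np.sum(r**2))
        if spec.noise_sd is None:
            if ssq > 1.0:
                raise ConfigError(f"sociodemo {spec.name!r}: target correlations imply variance > 1")
            beta, eps_sd = r, float(np.sqrt(max(0.0, 1.0 - ssq)))
        elif spec.noise_sd == 0:
            beta, eps_sd = r, 0.0
        else:
            if ssq >= 1.0:
                raise ConfigError(f"sociodemo {spec.name!r}: target correlations imply variance > 1")
            beta = r * spec.noise_sd / np.sqrt(1.0 - ssq)
            eps_sd = float(spec.noise_sd)
        cols[spec.name] = z @ beta + rng.normal(0.0, eps_sd, size=config.n_units)
    table = pd.DataFrame(cols, index=truth.unit_trait_means.index)
    if cols:
        realized = pd.DataFrame(
            {
                v: [np.corrcoef(z[:, j], table[v])[0, 1] for j in range(len(traits))]
                for v in table.columns
            },
            index=pd.Index(traits, name="trait"),
        )
    else:
        realized = pd.DataFrame(index=pd.Index(traits, name="trait"))
    table.attrs["realized_r"] = realized
    return table


def sapa2015_like(
    n_participants: int = 50_000, seed: int = 0, **overrides
) -> SyntheticConfig:
    """A four-inventory configuration emulating a multi-inventory web sample:
    one primary 100-item inventory sampled at 30%, a 300-item inventory at 9%,
    a short 75-item inventory at 15% partially overlapping the primary pool,
    and a 240-item six-factor-style inventory at 11% (five shared traits)."""
    inventories = (
        InventorySpec("BFFM", 20, 0.30),
        InventorySpec("NEO", 60, 0.09),
        InventorySpec("SPI", 15, 0.15, overlap_with="BFFM", overlap_fraction=0.4),
        InventorySpec("HEXACO", 40, 0.11),
    )
    kwargs = dict(
        n_participants=n_participants,
        inventories=inventories,
        sociodemo_specs=default_sociodemo_specs(),
        sample_id="SAPA2015-like",
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)
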