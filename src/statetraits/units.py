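"""Geographic unit universes.

Units are labelled with two-letter USPS codes plus ``DC``. Different analysis
stages use different universes: all 51 units, the contiguous 48 plus DC (49),
or the contiguous 48 alone, depending on which units the input tables cover.
"""

from __future__ import annotations

from typing import Iterable, Sequence

US_STATES_51: tuple[str, ...] = (
    "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "DC", "FL",
    "GA", "HI", "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME",
    "MD", "MA", "MI", "MN", "MS", "MO", "MT", "NE", "NV", "NH",
    "NJ", "NM", "NY", "NC", "ND", "OH", "OK", "OR", "PA", "RI",
    "SC", "SD", "TN", "TX", "UT", "VT", "VA", "WA", "WV", "WI",
    "WY",
)

CONTIGUOUS_49: tuple[str, ...] = tuple(u for u in US_STATES_51 if u not in ("AK", "HI"))
CONTIGUOUS_48: tuple[str, ...] = tuple(u for u in CONTIGUOUS_49 if u != "DC")

_UNIVERSES = {
    "all51": US_STATES_51,
    "contiguous49": CONTIGUOUS_49,
    "contiguous48": CONTIGUOUS_48,
}


def unit_universe(name: str) -> tuple[str, ...]:
    """Return the named unit universe (``all51``, ``contiguous49`` or ``contiguous48``)."""
    try:
        return _UNIVERSES[name]
    except KeyError:
        raise KeyError(
            f"unknown unit universe {name!r}; choose from {sorted(_UNIVERSES)}"
        ) from None


def resolve_units(subset: str | Iterable[str] | None) -> tuple[str, ...] | None:
    """Resolve a universe name or an explicit label collection to a tuple of labels."""
    if subset is None:
        return None
    if isinstance(subset, str):
        return unit_universe(subset)
    return tuple(subset)


def default_unit_labels(n_units: int) -> tuple[str, ...]:
    """Labels for ``n_units`` synthetic units: postal codes when 51, generic otherwise."""
    if n_units == len(US_STATES_51):
        return US_STATES_51
    return tuple(f"U{i:02d}" for i in range(1, n_units + 1))
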