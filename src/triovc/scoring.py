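"""Subscale scoring for item-level externalizing ratings.

Items are ordinal 1-4 frequency ratings.  Each subscale score is the sum
of its items; an individual missing at least half of a subscale's items
gets a missing score for that subscale, otherwise each missing item is
replaced by the item's mean over the individuals who answered it
(respondent sample mean, not the person's own mean) before summing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConfigurationError, InputError

__all__ = ["SubscaleDef", "DEFAULT_SUBSCALES", "score_subscales"]

# canonical item counts for the disruptive-behavior rating subscales
_CANONICAL_COUNTS = {
    "conduct": 8,
    "inattention": 9,
    "hyperactivity": 9,
    "oppositional": 8,
}


@dataclass(frozen=True)
class SubscaleDef:
    """A named subscale and the ordered item columns that compose it."""

    name: str
    item_columns: tuple[str, ...]
    item_range: tuple[int, int] = (1, 4)

    def __post_init__(self):
        if len(self.item_columns) < 1:
            raise ConfigurationError("a subscale needs at least one item")
        expected = _CANONICAL_COUNTS.get(self.name)
        if expected is not None and len(self.item_columns) != expected:
            raise ConfigurationError(
                f"subscale {self.name!r} has {expected} items, "
                f"got {len(self.item_columns)}"
            )

    @property
    def n_items(self) -> int:
        return len(self.item_columns)


def _default_def(name: str) -> SubscaleDef:
    k = _CANONICAL_COUNTS[name]
    return SubscaleDef(name, tuple(f"{name}_item{j + 1}" for j in range(k)))


DEFAULT_SUBSCALES: tuple[SubscaleDef, ...] = tuple(
    _default_def(n) for n in _CANONICAL_COUNTS
)


def score_subscales(
    items: pd.DataFrame,
    defs: tuple[SubscaleDef, ...] | list[SubscaleDef] = DEFAULT_SUBSCALES,
) -> pd.DataFrame:
    """Score subscales with the 50%-missing rule and item-mean imputation.

    Returns one row per input row with a ``<name>`` score column and a
    ``<name>_n_missing`` count per subscale, carrying over any ``trio``
    and ``sex`` columns.  Completeness statistics live in
    ``result.attrs["completeness"]``.
    """
    defs = [d for d in defs if set(d.item_columns) <= set(items.columns)]
    if not defs:
        raise InputError("no subscale's item columns are present in the table")

    out = pd.DataFrame(index=items.index)
    for col in ("trio", "sex"):
        if col in items.columns:
            out[col] = items[col]

    completeness = {}
    for d in defs:
        block = items.loc[:, list(d.item_columns)].astype(float)
        lo, hi = d.item_range
        observed = block.notna()
        bad = observed & ((block < lo) | (block > hi))
        if bad.any().any():
            r = bad.any(axis=1).idxmax()
            c = bad.loc[r].idxmax()
            raise InputError(
                f"item value out of [{lo}, {hi}] at row {r!r}, column {c!r}: "
                f"{block.loc[r, c]!r}"
            )
        n_missing = (~observed).sum(axis=1)
        scoreable = n_missing < 0.5 * d.n_items  # strictly less than half missing
        item_means = block.mean(axis=0)  # per-item mean over respondents
        imputed = block.fillna(item_means)
        scores = imputed.sum(axis=1).where(scoreable)
        out[d.name] = scores
        out[f"{d.name}_n_missing"] = n_missing
        completeness[d.name] = {
            "n": int(len(block)),
            "n_complete": int((n_missing == 0).sum()),
            "n_imputed": int((scoreable & (n_missing > 0)).sum()),
            "n_excluded": int((~scoreable).sum()),
            "prop_missing_score": float((~scoreable).mean()),
        }
    out.attrs["completeness"] = completeness
    return out
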