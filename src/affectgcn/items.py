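"""Canonical mood items.

Six feelings rated on a 1-7 Likert scale at every ESM beep, in a fixed
canonical order: three negative-polarity items first, then three
positive-polarity items.  All matrices and feature vectors in this package
index feelings in this order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeelingItem",
    "FEELING_ITEMS",
    "FEELINGS",
    "NEGATIVE_FEELINGS",
    "POSITIVE_FEELINGS",
    "NEGATIVE_IDX",
    "N_FEELINGS",
    "LIKERT_MIN",
    "LIKERT_MAX",
]


@dataclass(frozen=True)
class FeelingItem:
    """One self-reported mood item."""

    name: str
    polarity: str  # "negative" or "positive"
    index: int


FEELING_ITEMS: tuple[FeelingItem, ...] = (
    FeelingItem("angry", "negative", 0),
    FeelingItem("fearful", "negative", 1),
    FeelingItem("sad", "negative", 2),
    FeelingItem("event_pleasantness", "positive", 3),
    FeelingItem("cheerful", "positive", 4),
    FeelingItem("relaxed", "positive", 5),
)

FEELINGS: tuple[str, ...] = tuple(it.name for it in FEELING_ITEMS)
NEGATIVE_FEELINGS: tuple[str, ...] = tuple(
    it.name for it in FEELING_ITEMS if it.polarity == "negative"
)
POSITIVE_FEELINGS: tuple[str, ...] = tuple(
    it.name for it in FEELING_ITEMS if it.polarity == "positive"
)
NEGATIVE_IDX = np.array([it.index for it in FEELING_ITEMS if it.polarity == "negative"])

N_FEELINGS = len(FEELING_ITEMS)
LIKERT_MIN = 1
LIKERT_MAX = 7
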