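"""Dietary-guild classification and foraging-behaviour scoring.

Diet
----
Species' resource use comes as percentages over 10 raw food categories
(EltonTraits-style): terrestrial invertebrates, three terrestrial-vertebrate
columns (ectotherm / endotherm / unknown), fish, carrion, fruit, seeds,
nectar and other plant material. These are merged to 8 ecological
categories — the vertebrate columns are pooled, and fish plus (optionally
separately scored) aquatic invertebrates form an "aquatic animal" category.
A species is assigned to the dietary group matching any merged category
providing at least 60% (inclusive) of its resources; species with no such
majority resource are omnivores, giving 9 dietary groups in total.

Foraging behaviour
------------------
Qualitative foraging descriptions, pre-structured as ordered
(behaviour, frequency-qualifier) statements over a 30-name controlled
vocabulary, are converted to semi-quantitative per-species scores summing
to 10. A sole strategy scores 10; with multiple strategies, qualifiers set
base weights (mostly=7, sometimes=2, occasionally=1, unqualified=3) and any
remainder is handed out one unit at a time starting from the
earliest-listed strategy, so order encodes relative importance when the
description gives none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# --- raw food categories (resource tables) ---------------------------------

VERTEBRATE_CATEGORIES = ("vertebrates_ectotherm", "vertebrates_endotherm", "vertebrates_unknown")
AQUATIC_CATEGORIES = ("fish", "aquatic_invertebrates")

#: The 10 canonical raw columns; ``aquatic_invertebrates`` is additionally
#: recognised for tables where aquatic prey was scored apart from fish.
RAW_CATEGORIES = (
    "invertebrates",                 # terrestrial invertebrates
    *VERTEBRATE_CATEGORIES,
    "fish",
    "carrion",
    "fruit",
    "seeds",
    "nectar",
    "other_plants",
)
OPTIONAL_RAW_CATEGORIES = ("aquatic_invertebrates",)

MERGED_CATEGORIES = (
    "terrestrial_invertebrates",
    "aquatic_animals",
    "vertebrates",
    "carrion",
    "fruit",
    "seeds",
    "nectar",
    "other_plants",
)

#: merged category -> dietary group name (plus the "omnivore" fallback).
DIET_GROUPS = {
    "terrestrial_invertebrates": "invertivore",
    "aquatic_animals": "aquatic_predator",
    "vertebrates": "vertivore",
    "carrion": "scavenger",
    "fruit": "frugivore",
    "seeds": "granivore",
    "nectar": "nectarivore",
    "other_plants": "herbivore",
}
OMNIVORE = "omnivore"
ALL_DIET_GROUPS = tuple(DIET_GROUPS.values()) + (OMNIVORE,)

# --- foraging vocabulary (30 behaviours) ------------------------------------

FORAGING_BEHAVIOURS = (
    "glean_arboreal", "glean_ground", "glean_bark", "probe_ground", "probe_crevice",
    "probe_flowers", "sally_air", "sally_surface", "hawk_aerial", "screen_aerial",
    "pursuit_dive", "plunge_dive", "surface_dip", "surface_seize", "filter_feed",
    "dabble", "foot_trawl", "wade_stalk", "mud_sift", "graze",
    "browse", "dig_excavate", "scratch_litter", "pounce_ground", "stoop_aerial",
    "hover_glean", "nectar_hover", "nectar_perch", "crack_seeds", "scavenge_carrion",
)

QUALIFIER_WEIGHTS = {
    "sole": 10,
    "mostly": 7,      # smallest integer consistent with "mostly > 6"
    "sometimes": 2,
    "occasionally": 1,
    "unqualified": 3,
}

TOTAL_FORAGING_SCORE = 10


@dataclass(frozen=True)
class DietAssignment:
    """Merged resource scores and the resulting dietary group for one species."""

    species: str
    merged_scores: dict[str, float]          # percent over MERGED_CATEGORIES
    group: str


@dataclass(frozen=True)
class ForagingStatement:
    """Ordered (behaviour, qualifier) entries for one species' description."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty foraging statement")
        for behaviour, qualifier in self.entries:
            if behaviour not in FORAGING_BEHAVIOURS:
                raise ValueError(f"unknown foraging behaviour {behaviour!r}")
            if qualifier not in QUALIFIER_WEIGHTS:
                raise ValueError(
                    f"unknown qualifier {qualifier!r}; valid: {sorted(QUALIFIER_WEIGHTS)}"
                )


def merge_resource_categories(raw: Mapping[str, float]) -> dict[str, float]:
    """Merge a 10-category raw resource row to the 8 ecological categories.

    The three terrestrial-vertebrate columns pool to ``vertebrates``; fish
    (plus an ``aquatic_invertebrates`` column when present) pool to
    ``aquatic_animals``; everything else passes through. The total is
    preserved exactly.
    """
    valid = set(RAW_CATEGORIES) | set(OPTIONAL_RAW_CATEGORIES)
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"unknown raw food categories: {unknown}")
    if any(v < 0 for v in raw.values()):
        raise ValueError("negative resource score")
    total = float(sum(raw.values()))
    if total <= 0:
        raise ValueError("all-zero resource row (scores must sum to ~100)")
    merged = {
        "terrestrial_invertebrates": float(raw.get("invertebrates", 0.0)),
        "aquatic_animals": float(sum(raw.get(c, 0.0) for c in AQUATIC_CATEGORIES)),
        "vertebrates": float(sum(raw.get(c, 0.0) for c in VERTEBRATE_CATEGORIES)),
        "carrion": float(raw.get("carrion", 0.0)),
        "fruit": float(raw.get("fruit", 0.0)),
        "seeds": float(raw.get("seeds", 0.0)),
        "nectar": float(raw.get("nectar", 0.0)),
        "other_plants": float(raw.get("other_plants", 0.0)),
    }
    return merged


def assign_diet_group(merged: Mapping[str, float], threshold: float = 0.60) -> str:
    """Dietary group of a merged resource row: majority rule with omnivore fallback.

    A category qualifies if it holds at least ``threshold`` (default 60%,
    inclusive) of the row total — the rule is scale-invariant, so percent
    and fractional scores behave identically.
    """
    unknown = sorted(set(merged) - set(MERGED_CATEGORIES))
    if unknown:
        raise ValueError(f"unknown merged categories: {unknown}")
    total = float(sum(merged.values()))
    if total <= 0:
        raise ValueError("all-zero merged resource row")
    qualifying = [c for c in MERGED_CATEGORIES if merged.get(c, 0.0) / total >= threshold]
    if len(qualifying) > 1:
        # impossible for threshold > 0.5 with a valid row sum
        raise ValueError(f"multiple majority categories {qualifying}: inconsistent scores")
    if qualifying:
        return DIET_GROUPS[qualifying[0]]
    return OMNIVORE


def score_foraging(statement: ForagingStatement | Sequence[tuple[str, str]]) -> dict[str, float]:
    """Score one species' foraging statement over the 30-behaviour vocabulary.

    Returns a full vocabulary row summing to exactly 10. A single-entry
    statement scores 10 outright. Multi-entry statements start from the
    qualifier base weights; a positive remainder is distributed one unit at
    a time cycling from the earliest-listed entry, while a base total above
    10 is rescaled proportionally.
    """
    if not isinstance(statement, ForagingStatement):
        statement = ForagingStatement(tuple(statement))
    scores = {b: 0.0 for b in FORAGING_BEHAVIOURS}
    entries = statement.entries
    if len(entries) == 1:
        scores[entries[0][0]] = float(TOTAL_FORAGING_SCORE)
        return scores
    base = [float(QUALIFIER_WEIGHTS[q]) for _, q in entries]
    remainder = TOTAL_FORAGING_SCORE - sum(base)
    if remainder >= 0:
        for k in range(int(round(remainder))):
            base[k % len(base)] += 1.0
    else:
        base = [b * TOTAL_FORAGING_SCORE / sum(base) for b in base]
    for (behaviour, _), value in zip(entries, base):
        scores[behaviour] += value
    return scores


def classify_diet_table(
    resources: pd.DataFrame, threshold: float = 0.60
) -> tuple[pd.DataFrame, list[DietAssignment]]:
    """Classify every species of a raw resource table.

    Returns a DataFrame (index species; merged category columns plus a
    ``diet_group`` column) and the per-species :class:`DietAssignment`
    records, in input order.
    """
    assignments: list[DietAssignment] = []
    rows = []
    for species, row in resources.iterrows():
        merged = merge_resource_categories(row.to_dict())
        group = assign_diet_group(merged, threshold=threshold)
        assignments.append(DietAssignment(str(species), merged, group))
        rows.append({**merged, "diet_group": group})
    table = pd.DataFrame(rows, index=resources.index)
    table.index.name = "species"
    return table, assignments


def foraging_table_from_statements(
    statements: Mapping[str, ForagingStatement | Sequence[tuple[str, str]]]
) -> pd.DataFrame:
    """Score a set of species' statements into a 30-column foraging table."""
    table = pd.DataFrame(
        {sp: score_foraging(st) for sp, st in statements.items()}
    ).T.reindex(columns=list(FORAGING_BEHAVIOURS))
    table.index.name = "species"
    return table
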