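"""Crime incident classification and block-level aggregation.

Reported incidents arrive as planar points with a free-text offense label.
Labels are mapped (exact, case-insensitive lookup) into five major
categories — violent, property, vice, theft, vehicular — plus a flagged
``unclassified`` bucket for labels absent from the mapping.  Incidents are
assigned to census blocks by point-in-polygon and counted per block and
category; ``total`` counts every incident in the block regardless of
category.  A packaged illustrative mapping is provided, but any real
deployment should supply the local police department's own label scheme.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from .spatial import assign_points_to_blocks, validate_blocks

__all__ = [
    "CATEGORIES",
    "UNCLASSIFIED",
    "default_offense_mapping",
    "load_offense_mapping",
    "classify_offense",
    "assign_to_block",
    "aggregate_crime",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("violent", "property", "vice", "theft", "vehicular")
UNCLASSIFIED = "unclassified"
COUNT_COLUMNS = CATEGORIES + (UNCLASSIFIED, "total")


def load_offense_mapping(source: Union[str, Path]) -> dict[str, str]:
    """Read a label -> category mapping from CSV (columns: label, category)."""
    frame = pd.read_csv(source, dtype=str)
    missing = {"label", "category"} - set(frame.columns)
    if missing:
        raise ValueError(f"offense mapping missing columns: {sorted(missing)}")
    mapping: dict[str, str] = {}
    for label, category in zip(frame["label"], frame["category"]):
        category = str(category).strip().lower()
        if category not in CATEGORIES:
            raise ValueError(
                f"offense {label!r}: unknown category {category!r}; valid: {CATEGORIES}"
            )
        mapping[str(label).strip().upper()] = category
    return mapping


def default_offense_mapping() -> dict[str, str]:
    """The packaged illustrative offense-label mapping."""
    ref = resources.files("blockscape.data").joinpath("default_offense_mapping.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_offense_mapping(fh)


def classify_offense(offense_label: str, mapping: Mapping[str, str]) -> str:
    """Category for one offense label: exact case-insensitive lookup.

    Unmapped labels return ``unclassified`` and log a warning.
    """
    key = str(offense_label).strip().upper()
    category = mapping.get(key)
    if category is None:
        logger.warning("offense label %r not in mapping; classified as unclassified",
                       offense_label)
        return UNCLASSIFIED
    return category


def assign_to_block(point: tuple, blocks) -> Union[str, None]:
    """Block containing one (x, y) point, or None if outside all blocks.

    Boundary points go to the lexicographically smallest block_id.
    """
    x, y = point
    return assign_points_to_blocks([x], [y], blocks)[0]


def aggregate_crime(
    incidents: pd.DataFrame,
    blocks,
    mapping: Mapping[str, str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-block crime counts by category.

    ``incidents`` needs columns incident_id, x, y, offense_label.  Returns
    ``(counts, unassigned)``: counts is indexed by block_id (every block
    present, zeros included) with columns violent, property, vice, theft,
    vehicular, unclassified, total; unassigned holds the incidents falling
    outside every block, never silently dropped.  Conservation holds:
    ``counts["total"].sum() + len(unassigned) == len(incidents)``.
    """
    validate_blocks(blocks)
    if mapping is None:
        mapping = default_offense_mapping()
    required = {"incident_id", "x", "y", "offense_label"}
    missing = required - set(incidents.columns)
    if missing:
        raise ValueError(f"incident table missing columns: {sorted(missing)}")

    counts = pd.DataFrame(0, index=pd.Index(list(blocks), name="block_id"),
                          columns=list(COUNT_COLUMNS), dtype=int)
    if len(incidents) == 0:
        return counts, incidents.copy()

    work = incidents.copy()
    work["category"] = [classify_offense(lbl, mapping) for lbl in work["offense_label"]]
    work["block_id"] = assign_points_to_blocks(work["x"], work["y"], blocks)

    unassigned = work[work["block_id"].isna()].drop(columns=["block_id"])
    assigned = work[work["block_id"].notna()]

    per_cat = assigned.groupby(["block_id", "category"]).size()
    for (bid, cat), n in per_cat.items():
        counts.loc[bid, cat] = n
    totals = assigned.groupby("block_id").size()
    counts.loc[totals.index, "total"] = totals.values
    return counts, unassigned
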