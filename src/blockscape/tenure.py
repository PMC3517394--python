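"""Owner- vs renter-occupancy from tax-assessor address matching.

Tax rolls carry two addresses per parcel: the situs (geographic) address of
the parcel itself and the mailing address of its owner.  When the two match
the parcel is treated as owner-occupied; when they do not, as
renter-occupied.  Matching is scored, not exact: both addresses are
canonicalized (case, punctuation, directional and street-type abbreviations,
unit designators) and compared component-wise with configurable weights.
A score at or above the decision threshold (default 0.85) yields an
owner-occupied call.

The functional form and weights are package decisions, surfaced in
:class:`MatchWeights` so the classification is auditable and tunable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "AddressCanonical",
    "MatchWeights",
    "TenureCall",
    "normalize_address",
    "match_score",
    "classify_tenure",
    "DEFAULT_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.85

OWNER_OCCUPIED = "owner_occupied"
RENTER_OCCUPIED = "renter_occupied"
UNKNOWN = "unknown"

# Canonical forms map to themselves so normalization is idempotent.
_DIRECTIONALS = {
    "NORTH": "N", "SOUTH": "S", "EAST": "E", "WEST": "W",
    "NORTHEAST": "NE", "NORTHWEST": "NW", "SOUTHEAST": "SE", "SOUTHWEST": "SW",
    "N": "N", "S": "S", "E": "E", "W": "W",
    "NE": "NE", "NW": "NW", "SE": "SE", "SW": "SW",
}

_STREET_TYPES = {
    "STREET": "ST", "ST": "ST",
    "AVENUE": "AVE", "AV": "AVE", "AVE": "AVE",
    "ROAD": "RD", "RD": "RD",
    "DRIVE": "DR", "DR": "DR",
    "LANE": "LN", "LN": "LN",
    "BOULEVARD": "BLVD", "BLVD": "BLVD",
    "COURT": "CT", "CT": "CT",
    "CIRCLE": "CIR", "CIR": "CIR",
    "PLACE": "PL", "PL": "PL",
    "TERRACE": "TER", "TER": "TER",
    "PARKWAY": "PKWY", "PKWY": "PKWY",
    "HIGHWAY": "HWY", "HWY": "HWY",
    "TRAIL": "TRL", "TRL": "TRL",
    "WAY": "WAY",
    "ALLEY": "ALY", "ALY": "ALY",
    "LOOP": "LOOP",
    "SQUARE": "SQ", "SQ": "SQ",
}

_UNIT_DESIGNATORS = {"APT", "APARTMENT", "UNIT", "STE", "SUITE", "#", "NO", "NUM"}

_PUNCT_RE = re.compile(r"[^\w#]+")


@dataclass(frozen=True)
class AddressCanonical:
    """Canonical decomposition of one street address."""

    house_number: str = ""
    directional: str = ""
    street_name: tuple = ()
    street_type: str = ""
    unit: str = ""
    raw: str = ""

    @property
    def is_empty(self) -> bool:
        return not (
            self.house_number or self.directional or self.street_name
            or self.street_type or self.unit
        )

    @property
    def canonical_text(self) -> str:
        parts = [self.house_number, self.directional, *self.street_name, self.street_type]
        if self.unit:
            parts += ["#", self.unit]
        return " ".join(p for p in parts if p)


def normalize_address(raw: Optional[str]) -> AddressCanonical:
    """Canonicalize a raw address string.

    Uppercases, strips punctuation, maps directionals (NORTH -> N) and
    street types (STREET -> ST) to canonical abbreviations, and splits unit
    designators (APT 4, UNIT B, #12) into the unit field.  Idempotent:
    normalizing a canonical rendering reproduces the same fields.  Empty or
    missing input yields an empty canonical form.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        raw = ""
    text = _PUNCT_RE.sub(" ", str(raw).upper()).strip()
    # keep "#" attached-number forms tokenized: "#12" -> "# 12"
    text = re.sub(r"#\s*", "# ", text)
    tokens = text.split()

    house = ""
    unit = ""
    if tokens and tokens[0].isdigit():
        house = tokens.pop(0)

    # unit designator and its value, anywhere after the house number
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in _UNIT_DESIGNATORS:
            if i + 1 < len(tokens):
                unit = tokens[i + 1]
                del tokens[i : i + 2]
            else:
                del tokens[i]
            continue
        i += 1

    directional = ""
    if tokens and tokens[0] in _DIRECTIONALS and len(tokens) > 1:
        directional = _DIRECTIONALS[tokens.pop(0)]

    street_type = ""
    if tokens and tokens[-1] in _STREET_TYPES and len(tokens) > 1:
        street_type = _STREET_TYPES[tokens.pop()]

    return AddressCanonical(
        house_number=house,
        directional=directional,
        street_name=tuple(tokens),
        street_type=street_type,
        unit=unit,
        raw=str(raw),
    )


@dataclass(frozen=True)
class MatchWeights:
    """Component weights for the address match score.

    The weighted components sum to 1.  When both house numbers are present
    and disagree the total score is capped at ``house_mismatch_cap``: two
    addresses on the same street but at different numbers are different
    parcels, whatever else agrees.
    """

    house: float = 0.20
    name: float = 0.50
    directional: float = 0.15
    street_type: float = 0.15
    house_mismatch_cap: float = 0.20


def match_score(
    a: AddressCanonical,
    b: AddressCanonical,
    weights: MatchWeights = MatchWeights(),
) -> float:
    """Similarity of two canonical addresses, in [0, 1].

    Symmetric; 1.0 for identical non-empty forms; 0.0 when either side is
    empty.  Each component contributes its weight when the two sides agree
    (two empty components count as agreement, so e.g. two addresses without
    directionals are not penalized).
    """
    if a.is_empty or b.is_empty:
        return 0.0
    score = 0.0
    if a.house_number == b.house_number:
        score += weights.house
    if a.street_name == b.street_name:
        score += weights.name
    if a.directional == b.directional:
        score += weights.directional
    if a.street_type == b.street_type:
        score += weights.street_type
    if a.house_number and b.house_number and a.house_number != b.house_number:
        score = min(score, weights.house_mismatch_cap)
    return round(min(score, 1.0), 12)


@dataclass(frozen=True)
class TenureCall:
    """Owner/renter decision for one parcel."""

    parcel_id: str
    score: float
    call: str
    threshold_used: float


def classify_tenure(
    parcels: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    weights: MatchWeights = MatchWeights(),
    strict: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Classify each parcel as owner- or renter-occupied.

    ``parcels`` needs columns parcel_id, situs_address, owner_address.
    A parcel is owner-occupied iff match_score(situs, owner) >= threshold.
    Missing owner address yields a renter call at score 0 (with a warning),
    or an ``unknown`` call under ``strict=True``.  Parcels with a missing
    situs address are skipped; their ids come back in the error list.

    Returns ``(calls, errors)`` where calls has columns parcel_id, score,
    call, threshold_used.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    required = {"parcel_id", "situs_address", "owner_address"}
    missing = required - set(parcels.columns)
    if missing:
        raise ValueError(f"parcel table missing columns: {sorted(missing)}")

    rows = []
    errors: list[str] = []
    for rec in parcels[["parcel_id", "situs_address", "owner_address"]].itertuples(index=False):
        pid = str(rec.parcel_id)
        situs = normalize_address(rec.situs_address)
        if situs.is_empty:
            errors.append(f"parcel {pid}: missing situs address")
            continue
        owner = normalize_address(rec.owner_address)
        if owner.is_empty:
            logger.warning("parcel %s: missing owner address; coded as renter", pid)
            call = UNKNOWN if strict else RENTER_OCCUPIED
            rows.append((pid, 0.0, call, threshold))
            continue
        score = match_score(situs, owner, weights)
        call = OWNER_OCCUPIED if score >= threshold else RENTER_OCCUPIED
        rows.append((pid, score, call, threshold))
    calls = pd.DataFrame(rows, columns=["parcel_id", "score", "call", "threshold_used"])
    return calls, errors


def renter_counts_by_block(
    calls: pd.DataFrame, parcels: pd.DataFrame, block_ids: Iterable[str]
) -> pd.Series:
    """Per-block count of renter-occupied calls (the tenure index input).

    ``parcels`` must carry parcel_id and block_id; blocks with no parcels get
    an explicit 0.  ``unknown`` calls (strict mode) are excluded.
    """
    merged = calls.merge(
        parcels[["parcel_id", "block_id"]].astype({"parcel_id": str}),
        on="parcel_id",
        how="left",
    )
    renters = merged[merged["call"] == RENTER_OCCUPIED]
    counts = renters.groupby("block_id").size()
    return counts.reindex(list(block_ids), fill_value=0).astype(int)
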