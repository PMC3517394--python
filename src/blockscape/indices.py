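"""Seven neighborhood indices at block, PAC, and SAC scales.

Parcel observations, public-space nuisance points, tenure calls, and crime
counts are summed to census blocks and then re-aggregated over the
moving-window communities:

* nuisances          — total public-space nuisance observations;
* housing_damage     — presences of the 13 housing-damage variables;
* property_disorder  — presences of the 14 property-disorder variables;
* territoriality     — presences of the 6 territoriality variables;
* vacancy            — parcels flagged unoccupied/demolished or vacant lots;
* tenure             — parcels called renter-occupied;
* crime              — total reported incidents.

Indices are raw counts (window values therefore grow mechanically with
window size); per-parcel rates are carried alongside for fair cross-scale
comparison.  The window value for a focal block is the sum of member-block
values, so by construction block <= PAC <= SAC for every count index, and
the sum of block values equals the raw input total.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .registry import Applicability, Domain, SchemaError, ValueKind, VariableRegistry
from .spatial import CommunityWindow, all_windows, assign_points_to_blocks

__all__ = [
    "INDEX_COLUMNS",
    "LEVELS",
    "PROPERTY_TYPES",
    "RESIDENTIAL_SUBTYPES",
    "assign_parcels_to_blocks",
    "block_variable_counts",
    "vacancy_flags",
    "domain_index",
    "build_block_indices",
    "aggregate_to_windows",
    "build_index_table",
    "wide_table",
    "correlate_indices",
    "summarize_roster",
]

INDEX_COLUMNS = (
    "nuisances",
    "housing_damage",
    "property_disorder",
    "territoriality",
    "vacancy",
    "tenure",
    "crime",
)

LEVELS = ("block", "pac", "sac")
_LEVEL_ORDER = {"block": 0, "pac": 1, "sac": 2}

PROPERTY_TYPES = (
    "residential", "commercial", "religious", "community", "unoccupied_lot", "other",
)
RESIDENTIAL_SUBTYPES = ("single_family", "apartment", "senior_care_duplex_other")
OCCUPANCY_STATES = ("occupied", "unoccupied", "demolished")

#: parcel-table columns that are structure, not observations
_STRUCTURAL = {
    "parcel_id", "nuisance_id", "situs_address", "owner_address", "property_type",
    "property_subtype", "occupancy", "x", "y", "block_id", "excluded",
}


# ---------------------------------------------------------------------------
# block assignment and per-variable counting
# ---------------------------------------------------------------------------

def assign_parcels_to_blocks(
    parcels: pd.DataFrame, blocks
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Point-in-polygon assignment of parcel centroids to blocks.

    Returns ``(assigned, unassigned)``; ``assigned`` is a copy of the input
    with a ``block_id`` column (boundary ties broken toward the smallest
    block_id, as for crime points), ``unassigned`` the parcels outside every
    block — reported, never dropped.
    """
    out = parcels.copy()
    out["block_id"] = assign_points_to_blocks(out["x"], out["y"], blocks)
    unassigned = out[out["block_id"].isna()]
    return out[out["block_id"].notna()], unassigned


def _observation_columns(frame: pd.DataFrame, registry: VariableRegistry,
                         applicability: Applicability) -> list[str]:
    obs = [c for c in frame.columns if c not in _STRUCTURAL]
    bad = [c for c in obs if c not in registry]
    if bad:
        raise SchemaError(f"observation columns not in registry: {bad}")
    wrong = [c for c in obs if registry[c].applicability is not applicability]
    if wrong:
        raise SchemaError(
            f"observation columns with wrong applicability for this table: {wrong}"
        )
    return obs


def _presence(series: pd.Series, kind: ValueKind) -> pd.Series:
    """0/1 presence per record; unobserved (NaN) defaults to 0 = No."""
    if kind is ValueKind.BINARY:
        values = pd.to_numeric(series, errors="coerce").fillna(0)
        if not values.isin([0, 1]).all():
            bad = sorted(set(values[~values.isin([0, 1])]))
            raise SchemaError(
                f"binary variable {series.name!r} has values outside {{0,1}}: {bad}"
            )
        return values.astype(int)
    # categorical / text: present when non-missing and non-empty
    return series.notna().astype(int) * (series.astype(str).str.strip() != "").astype(int)


def block_variable_counts(
    parcels: pd.DataFrame,
    nuisances: Optional[pd.DataFrame],
    registry: VariableRegistry,
    block_ids: Iterable[str],
) -> pd.DataFrame:
    """Per-block presence counts for every registry variable.

    Parcel observation columns count toward parcel variables, nuisance-point
    columns toward public-space variables.  The vacancy-domain variables
    (occupied / unoccupied / demolished) are derived from the parcel
    ``occupancy`` column when not supplied as explicit columns.  Every block
    appears in the result, zero rows included.
    """
    index = pd.Index(list(block_ids), name="block_id")
    counts = pd.DataFrame(0, index=index, columns=registry.names, dtype=int)

    def _tally(frame: pd.DataFrame, applicability: Applicability) -> None:
        if frame is None or len(frame) == 0:
            return
        if "block_id" not in frame.columns:
            raise ValueError("input table must be block-assigned first")
        obs = _observation_columns(frame, registry, applicability)
        work = pd.DataFrame(index=frame.index)
        for col in obs:
            work[registry[col].name] = _presence(frame[col], registry[col].value_kind)
        if applicability is Applicability.PARCEL:
            if "occupancy" in frame.columns:
                for state in OCCUPANCY_STATES:
                    if state not in work.columns:
                        work[state] = (frame["occupancy"] == state).astype(int)
            for struct in ("property_type", "property_subtype"):
                if struct in frame.columns and struct in registry and struct not in work.columns:
                    work[struct] = _presence(frame[struct], ValueKind.CATEGORICAL)
        work["block_id"] = frame["block_id"].values
        summed = work.groupby("block_id").sum()
        common = [c for c in summed.columns if c in counts.columns]
        counts.loc[summed.index, common] += summed[common].astype(int)

    _tally(parcels, Applicability.PARCEL)
    _tally(nuisances, Applicability.PUBLIC_SPACE)
    return counts


def vacancy_flags(parcels: pd.DataFrame) -> pd.Series:
    """Per-parcel vacancy indicator.

    1 iff the parcel is unoccupied or demolished (any property type —
    residential, commercial, religious, or community), or is a vacant lot.
    """
    occ = parcels.get("occupancy", pd.Series("", index=parcels.index))
    ptype = parcels.get("property_type", pd.Series("", index=parcels.index))
    flag = occ.isin(["unoccupied", "demolished"]) | (ptype == "unoccupied_lot")
    return flag.astype(int)


def domain_index(
    block_counts: pd.DataFrame,
    registry: VariableRegistry,
    domain: Union[Domain, str],
) -> pd.Series:
    """Per-block sum of variable counts over one registry domain."""
    variables = [v.name for v in registry.domain_variables(domain)]
    present = [v for v in variables if v in block_counts.columns]
    return block_counts[present].sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# index construction
# ---------------------------------------------------------------------------

def build_block_indices(
    parcels: pd.DataFrame,
    nuisances: Optional[pd.DataFrame],
    registry: VariableRegistry,
    block_ids: Iterable[str],
    crime_counts: Optional[pd.DataFrame] = None,
    tenure_calls: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Block-level values for the seven indices plus a parcel-count column.

    ``parcels`` and ``nuisances`` must be block-assigned.  ``crime_counts``
    is the per-block table from :func:`blockscape.crime.aggregate_crime`
    (its ``total`` column feeds the crime index); ``tenure_calls`` the table
    from :func:`blockscape.tenure.classify_tenure`.  Missing inputs yield
    zero columns so partial pipelines still produce a complete table.
    """
    block_ids = list(block_ids)
    index = pd.Index(block_ids, name="block_id")
    counts = block_variable_counts(parcels, nuisances, registry, block_ids)

    table = pd.DataFrame(0, index=index, columns=list(INDEX_COLUMNS) + ["n_parcels"],
                         dtype=int)
    table["nuisances"] = domain_index(counts, registry, Domain.NUISANCE)
    table["housing_damage"] = domain_index(counts, registry, Domain.HOUSING_DAMAGE)
    table["property_disorder"] = domain_index(counts, registry, Domain.PROPERTY_DISORDER)
    table["territoriality"] = domain_index(counts, registry, Domain.TERRITORIALITY)

    if len(parcels):
        vac = vacancy_flags(parcels).groupby(parcels["block_id"].values).sum()
        table.loc[vac.index, "vacancy"] = vac.astype(int)
        table["n_parcels"] = (
            parcels.groupby("block_id").size().reindex(block_ids, fill_value=0).astype(int)
        )

    if tenure_calls is not None and len(tenure_calls):
        from .tenure import renter_counts_by_block

        table["tenure"] = renter_counts_by_block(tenure_calls, parcels, block_ids)

    if crime_counts is not None and len(crime_counts):
        table["crime"] = (
            crime_counts["total"].reindex(block_ids, fill_value=0).astype(int)
        )
    return table


def aggregate_to_windows(
    block_index: pd.DataFrame,
    windows: Mapping[str, CommunityWindow],
) -> pd.DataFrame:
    """Window value per focal block = sum of member-block values.

    Every window member must have a row in ``block_index``.
    """
    focals = list(windows)
    for w in windows.values():
        missing = [m for m in w.members if m not in block_index.index]
        if missing:
            raise KeyError(
                f"window of {w.focal!r} has members missing from block index: {missing}"
            )
    rows = [block_index.loc[list(windows[f].members)].sum() for f in focals]
    out = pd.DataFrame(rows, index=pd.Index(focals, name="block_id"))
    return out.astype(block_index.dtypes)


def build_index_table(
    block_index: pd.DataFrame,
    graph: nx.Graph,
    levels: Iterable[str] = LEVELS,
) -> pd.DataFrame:
    """Long-format index table over the requested aggregation levels.

    Columns: block_id, level, index, value, n_parcels, rate.  ``rate`` is
    value / parcels-in-window; for windows containing zero parcels it is
    missing (NaN), never 0.
    """
    records = []
    for level in levels:
        if level not in _LEVEL_ORDER:
            raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
        order = _LEVEL_ORDER[level]
        agg = (
            block_index
            if order == 0
            else aggregate_to_windows(block_index, all_windows(graph, order))
        )
        n_parcels = agg["n_parcels"] if "n_parcels" in agg.columns else None
        for name in INDEX_COLUMNS:
            for bid, value in agg[name].items():
                n = int(n_parcels.loc[bid]) if n_parcels is not None else 0
                rate = float(value) / n if n > 0 else np.nan
                records.append((bid, level, name, int(value), n, rate))
    return pd.DataFrame(
        records, columns=["block_id", "level", "index", "value", "n_parcels", "rate"]
    )


def wide_table(index_table: pd.DataFrame, level: str, column: str = "value") -> pd.DataFrame:
    """Blocks x indices matrix for one aggregation level."""
    sub = index_table[index_table["level"] == level]
    if sub.empty:
        raise ValueError(f"no rows at level {level!r}")
    wide = sub.pivot(index="block_id", columns="index", values=column)
    return wide[[c for c in INDEX_COLUMNS if c in wide.columns]]


def correlate_indices(
    index_table: pd.DataFrame,
    level: str,
    method: str = "pearson",
) -> pd.DataFrame:
    """Between-index correlation matrix across blocks at one level.

    Symmetric with unit diagonal; a zero-variance index has undefined
    correlations, reported as NaN and listed in ``result.attrs["degenerate"]``
    rather than forced to 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    wide = wide_table(index_table, level)
    if len(wide) < 3:
        raise ValueError("need at least 3 blocks to correlate indices")
    degenerate = [c for c in wide.columns if wide[c].nunique() <= 1]
    corr = wide.astype(float).corr(method=method)
    corr.loc[degenerate, :] = np.nan
    corr.loc[:, degenerate] = np.nan
    np.fill_diagonal(corr.values, [np.nan if c in degenerate else 1.0 for c in corr.columns])
    corr.attrs["degenerate"] = degenerate
    return corr


# ---------------------------------------------------------------------------
# survey roster accounting
# ---------------------------------------------------------------------------

def summarize_roster(parcels: pd.DataFrame) -> dict[str, int]:
    """Exclusion and property-category accounting for an assessment roster.

    Mirrors the field-campaign bookkeeping: parcels flagged ``excluded``
    (unsafe or not visible from the public right of way) are removed, the
    remainder are assessable; assessable parcels are tabulated by property
    type, with the residual after the named categories reported as ``other``;
    residential parcels are tabulated by subtype, with the residual after
    single-family homes and apartments reported as
    ``residual_residential`` (senior housing, care facilities, duplexes,
    multi-address homes, or other).
    """
    total = len(parcels)
    excluded = int(parcels["excluded"].astype(bool).sum()) if "excluded" in parcels else 0
    roster = parcels[~parcels["excluded"].astype(bool)] if "excluded" in parcels else parcels
    assessable = len(roster)

    ptype = roster.get("property_type", pd.Series("", index=roster.index))
    named = {t: int((ptype == t).sum()) for t in PROPERTY_TYPES if t != "other"}
    other = assessable - sum(named.values())

    res = roster[ptype == "residential"]
    subtype = res.get("property_subtype", pd.Series("", index=res.index))
    single_family = int((subtype == "single_family").sum())
    apartments = int((subtype == "apartment").sum())
    residual_residential = len(res) - single_family - apartments

    return {
        "total_parcels": total,
        "excluded_parcels": excluded,
        "assessable_parcels": assessable,
        **{f"{t}_parcels": n for t, n in named.items()},
        "other_parcels": other,
        "single_family_parcels": single_family,
        "apartment_parcels": apartments,
        "residual_residential_parcels": residual_residential,
    }
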