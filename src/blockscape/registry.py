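"""Variable schema for the built-environment audit.

The audit instrument records, for every tax parcel and every public-space
nuisance point, a fixed list of condition variables (boarded windows, litter,
security signage, ...).  Each variable belongs to exactly one substantive
domain — housing damage, property disorder, territoriality, vacancy, public
nuisances, or a residual "miscellaneous" group — and originated either from
the prior audit literature, from community input, or from the project leads.
Most variables are presence/absence (1 = observed, 0 = not observed); a few
are categorical (e.g. property type) and the open-ended "other" items are
free text, counted as present when non-empty.

The domains are disjoint by construction.  Features assessed both on private
parcels and in public space (high weeds, broken glass, ...) appear as two
distinct variables, one per applicability.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Union

import pandas as pd

__all__ = [
    "Domain",
    "Source",
    "Applicability",
    "ValueKind",
    "VariableDef",
    "VariableRegistry",
    "SchemaError",
    "default_registry",
    "load_registry",
    "dump_registry",
    "domain_variables",
]


class SchemaError(ValueError):
    """A variable registry (or a document describing one) violates the schema."""


class Domain(str, enum.Enum):
    HOUSING_DAMAGE = "housing_damage"
    PROPERTY_DISORDER = "property_disorder"
    TERRITORIALITY = "territoriality"
    VACANCY = "vacancy"
    NUISANCE = "nuisance"
    MISCELLANEOUS = "miscellaneous"


class Source(str, enum.Enum):
    LITERATURE = "literature"
    COMMUNITY = "community"
    PROJECT_LEADERS = "project_leaders"


class Applicability(str, enum.Enum):
    PARCEL = "parcel"
    PUBLIC_SPACE = "public_space"


class ValueKind(str, enum.Enum):
    BINARY = "binary"
    CATEGORICAL = "categorical"
    TEXT = "text"


#: Domains observed on private parcels; NUISANCE is public-space only.
PARCEL_DOMAINS = frozenset(
    {
        Domain.HOUSING_DAMAGE,
        Domain.PROPERTY_DISORDER,
        Domain.TERRITORIALITY,
        Domain.VACANCY,
        Domain.MISCELLANEOUS,
    }
)


def _coerce(value, enum_cls, field: str):
    try:
        return enum_cls(value)
    except ValueError:
        valid = ", ".join(m.value for m in enum_cls)
        raise SchemaError(f"unknown {field} {value!r}; valid: {valid}") from None


@dataclass(frozen=True)
class VariableDef:
    """One audit variable: its name, domain, provenance, and value type."""

    name: str
    domain: Domain
    source: Source
    applicability: Applicability
    value_kind: ValueKind = ValueKind.BINARY

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise SchemaError("variable name must be non-empty")
        object.__setattr__(self, "domain", _coerce(self.domain, Domain, "domain"))
        object.__setattr__(self, "source", _coerce(self.source, Source, "source"))
        object.__setattr__(
            self, "applicability", _coerce(self.applicability, Applicability, "applicability")
        )
        object.__setattr__(
            self, "value_kind", _coerce(self.value_kind, ValueKind, "value_kind")
        )
        if self.domain is Domain.NUISANCE:
            if self.applicability is not Applicability.PUBLIC_SPACE:
                raise SchemaError(
                    f"{self.name!r}: nuisance variables apply to public spaces only"
                )
        elif self.applicability is not Applicability.PARCEL:
            raise SchemaError(
                f"{self.name!r}: domain {self.domain.value} applies to parcels only"
            )

    @property
    def key(self) -> str:
        """Case-insensitive lookup key (display casing is preserved in .name)."""
        return self.name.casefold()


class VariableRegistry:
    """Ordered, validated collection of :class:`VariableDef`.

    Names are unique case-insensitively; domains are disjoint by virtue of
    each variable carrying exactly one domain.
    """

    def __init__(self, variables: Iterable[VariableDef], version: str = "0") -> None:
        self.version = str(version)
        self._vars: dict[str, VariableDef] = {}
        for var in variables:
            if not isinstance(var, VariableDef):
                var = VariableDef(*var)
            if var.key in self._vars:
                raise SchemaError(f"duplicate variable name {var.name!r}")
            self._vars[var.key] = var

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[VariableDef]:
        return iter(self._vars.values())

    def __len__(self) -> int:
        return len(self._vars)

    def __contains__(self, name: str) -> bool:
        return str(name).casefold() in self._vars

    def __getitem__(self, name: str) -> VariableDef:
        try:
            return self._vars[str(name).casefold()]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariableRegistry):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"<VariableRegistry: {len(self)} variables, version {self.version!r}>"

    # -- queries ------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [v.name for v in self]

    def domain_variables(self, domain: Union[Domain, str]) -> list[VariableDef]:
        """Variables assigned to *domain*, in registry order."""
        domain = _coerce(domain, Domain, "domain")
        return [v for v in self if v.domain is domain]

    def applicable(self, applicability: Union[Applicability, str]) -> list[VariableDef]:
        applicability = _coerce(applicability, Applicability, "applicability")
        return [v for v in self if v.applicability is applicability]

    @property
    def parcel_variables(self) -> list[VariableDef]:
        return self.applicable(Applicability.PARCEL)

    @property
    def public_space_variables(self) -> list[VariableDef]:
        return self.applicable(Applicability.PUBLIC_SPACE)

    def domain_sizes(self) -> dict[str, int]:
        return {d.value: len(self.domain_variables(d)) for d in Domain}

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [v.name for v in self],
                "domain": [v.domain.value for v in self],
                "source": [v.source.value for v in self],
                "applicability": [v.applicability.value for v in self],
                "value_kind": [v.value_kind.value for v in self],
            }
        )


def domain_variables(registry: VariableRegistry, domain) -> list[VariableDef]:
    """Module-level convenience for :meth:`VariableRegistry.domain_variables`."""
    return registry.domain_variables(domain)


_REQUIRED_COLUMNS = ("name", "domain", "source", "applicability", "value_kind")


def load_registry(source: Union[str, Path, io.IOBase, pd.DataFrame]) -> VariableRegistry:
    """Read a registry from a flat CSV document (one row per variable).

    Required columns: name, domain, source, applicability, value_kind.
    Duplicate names (case-insensitive) and domain/applicability mismatches
    are rejected with :class:`SchemaError`.
    """
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        frame = pd.read_csv(source, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"registry document missing columns: {missing}")
    variables = [
        VariableDef(
            name=row["name"],
            domain=row["domain"],
            source=row["source"],
            applicability=row["applicability"],
            value_kind=row["value_kind"],
        )
        for row in frame[list(_REQUIRED_COLUMNS)].to_dict("records")
    ]
    return VariableRegistry(variables)


def dump_registry(registry: VariableRegistry, path: Union[str, Path, io.IOBase]) -> None:
    """Write a registry to CSV; ``load_registry`` round-trips the result."""
    registry.to_frame().to_csv(path, index=False)


def default_registry() -> VariableRegistry:
    """The packaged audit schema: 53 parcel variables and 26 public-space
    nuisance variables (housing damage 13, property disorder 14,
    territoriality 6, vacancy 3, miscellaneous 17, nuisances 26)."""
    ref = resources.files("blockscape.data").joinpath("default_registry.csv")
    with ref.open("r", encoding="utf-8") as fh:
        reg = load_registry(fh)
    reg.version = "default-1"
    return reg
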